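"""Reporting conventions and run manifests.

Percentages are printed with half-up decimal rounding (so 1108/92589 ->
"1.20%" at two decimals); underlying TSVs always carry full precision.
The run manifest records the configuration hash, seeds, stage parameters
and SHA-256 checksums of every input and output file, so that a run can be
reproduced bit-identically from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .core import ValidationError


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """``100 * numerator / denominator`` rounded half-up, with a trailing %."""
    if denominator == 0:
        raise ValidationError("format_percent: zero denominator")
    if decimals < 0:
        raise ValidationError("format_percent: decimals must be >= 0")
    pct = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quantum, rounding=ROUND_HALF_UP)}%"


def percent_value(numerator: int, denominator: int, decimals: int = 1) -> float:
    """The numeric value behind :func:`format_percent` (same rounding)."""
    return float(format_percent(numerator, denominator, decimals).rstrip("%"))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def build_manifest(
    config: dict,
    seed: int,
    stage_params: dict,
    input_files: dict[str, str | Path],
    output_files: dict[str, str | Path],
) -> dict:
    return {
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "stage_params": stage_params,
        "inputs": {k: {"path": str(p), "sha256": sha256_file(p)} for k, p in input_files.items()},
        "outputs": {k: {"path": str(p), "sha256": sha256_file(p)} for k, p in output_files.items()},
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
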