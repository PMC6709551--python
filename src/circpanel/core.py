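"""Core domain types, coordinate conventions, and TSV readers/writers.

Conventions
-----------
All backsplice-junction coordinates are stored 0-based, half-open
(``[start, end)``), whatever the convention of the detector that produced
them.  Each registered input *dialect* declares its own coordinate base and
column layout and is converted on ingest, so "same circRNA" reduces to
equality of ``(chrom, start, end, strand)`` — no fuzzy matching.

Identifiers (cell lines, genes, tools, lineages) are case-sensitive
strings.  Strand is one of ``+``, ``-``, ``.``; ``.`` matches only ``.``.

The canonical string form of a junction is ``chrom:start-end:strand``,
e.g. ``chr8:128752711-128752871:+``; it is used as the row index of the
circRNA × cell-line matrix and in every TSV the pipeline writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("circpanel")

STRANDS = frozenset({"+", "-", "."})

#: columns of a validated tool-call table
TOOL_CALL_COLUMNS = ["tool", "cell_line", "chrom", "start", "end", "strand", "reads"]


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError):
    """Bad configuration: unknown dialect, missing library size, bad parameter."""


class ValidationError(PipelineError):
    """Input data violates an invariant (reported with offending rows/lines)."""


# ---------------------------------------------------------------------------
# CircKey
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class CircKey:
    """Genomic identity of one backsplice junction (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("CircKey: chrom must be non-empty")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValidationError("CircKey: start/end must be integers")
        if not self.start < self.end:
            raise ValidationError(
                f"CircKey: require start < end, got {self.start} >= {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"CircKey: strand must be one of {sorted(STRANDS)}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id

    @classmethod
    def parse(cls, text: str) -> "CircKey":
        """Parse the canonical ``chrom:start-end:strand`` form."""
        try:
            chrom, span, strand = text.rsplit(":", 2)
            start_s, end_s = span.split("-", 1)
            return cls(chrom, int(start_s), int(end_s), strand)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"cannot parse circRNA id {text!r}") from exc


def circ_id(chrom: str, start: int, end: int, strand: str) -> str:
    """Canonical id string without constructing a CircKey (fast path)."""
    return f"{chrom}:{start}-{end}:{strand}"


# ---------------------------------------------------------------------------
# Dialects (per-detector input conventions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Input convention of one junction-call file format.

    ``one_based`` — coordinates are 1-based inclusive (converted on ingest);
    ``layout`` — ``"bed6"`` (chrom, start, end, name, reads, strand; no
    header; one file per tool × cell line) or ``"tidy"`` (headered TSV with
    columns cell_line, chrom, start, end, strand, reads; one file per tool).
    """

    name: str
    one_based: bool = False
    layout: str = "bed6"

    def to_internal(self, start: int, end: int) -> tuple[int, int]:
        return (start - 1, end) if self.one_based else (start, end)

    def from_internal(self, start: int, end: int) -> tuple[int, int]:
        return (start + 1, end) if self.one_based else (start, end)


DIALECTS: dict[str, Dialect] = {}


def register_dialect(dialect: Dialect) -> Dialect:
    DIALECTS[dialect.name] = dialect
    return dialect


register_dialect(Dialect("bed6", one_based=False, layout="bed6"))
register_dialect(Dialect("bed6_1based", one_based=True, layout="bed6"))
register_dialect(Dialect("tool_tsv", one_based=False, layout="tidy"))
register_dialect(Dialect("tool_tsv_1based", one_based=True, layout="tidy"))


def get_dialect(name: str) -> Dialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {name!r}; registered: {sorted(DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Tool-call tables
# ---------------------------------------------------------------------------


def _validate_call_frame(df: pd.DataFrame, line_offset: int, source: str) -> pd.DataFrame:
    """Validate parsed calls; raise ValidationError naming offending lines."""
    problems: list[str] = []
    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    reads = pd.to_numeric(df["reads"], errors="coerce")
    chrom_bad = df["chrom"].astype(str).str.len() == 0
    strand_bad = ~df["strand"].astype(str).isin(sorted(STRANDS))
    for idx in df.index:
        line_no = idx + line_offset
        msgs = []
        if chrom_bad.loc[idx]:
            msgs.append("empty chrom")
        if pd.isna(start.loc[idx]) or pd.isna(end.loc[idx]):
            msgs.append("non-integer coordinates")
        elif start.loc[idx] >= end.loc[idx]:
            msgs.append(f"start >= end ({int(start.loc[idx])} >= {int(end.loc[idx])})")
        if pd.isna(reads.loc[idx]) or reads.loc[idx] < 0:
            msgs.append(f"invalid read count {df['reads'].loc[idx]!r}")
        if strand_bad.loc[idx]:
            msgs.append(f"invalid strand {df['strand'].loc[idx]!r}")
        if msgs:
            problems.append(f"{source}:{line_no}: " + "; ".join(msgs))
        if len(problems) >= 20:
            problems.append("... (further problems suppressed)")
            break
    if problems:
        raise ValidationError("malformed tool-call rows:\n" + "\n".join(problems))
    out = df.copy()
    out["start"] = start.astype(np.int64)
    out["end"] = end.astype(np.int64)
    out["reads"] = reads.astype(np.int64)
    return out


def read_tool_calls(
    path: str | Path,
    dialect: str | Dialect = "bed6",
    tool: str | None = None,
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Read one junction-call file into the validated internal call table.

    Returns a DataFrame with columns ``tool, cell_line, chrom, start, end,
    strand, reads, circ_id`` in internal (0-based half-open) coordinates.
    ``tool`` is required for every layout; ``cell_line`` is required for the
    per-cell-line ``bed6`` layouts.
    """
    d = get_dialect(dialect) if isinstance(dialect, str) else dialect
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"tool-call file not found: {path}")
    if tool is None:
        raise ConfigurationError("read_tool_calls: 'tool' identifier is required")
    if d.layout == "bed6":
        if cell_line is None:
            raise ConfigurationError(
                "read_tool_calls: 'cell_line' is required for bed6 layouts"
            )
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            names=["chrom", "start", "end", "name", "reads", "strand"],
        )
        raw["tool"] = tool
        raw["cell_line"] = cell_line
        line_offset = 1
    elif d.layout == "tidy":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        required = {"cell_line", "chrom", "start", "end", "strand", "reads"}
        missing = required - set(raw.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        raw["tool"] = tool
        line_offset = 2  # header consumes line 1
    else:  # pragma: no cover - defensive
        raise ConfigurationError(f"dialect {d.name!r} has unknown layout {d.layout!r}")

    raw = raw.reset_index(drop=True)
    df = _validate_call_frame(raw, line_offset, str(path))
    starts, ends = d.to_internal(df["start"].to_numpy(), df["end"].to_numpy())
    df["start"], df["end"] = starts, ends
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: start >= end after coordinate conversion")
    df = df[TOOL_CALL_COLUMNS]
    dup = df.duplicated(subset=["tool", "cell_line", "chrom", "start", "end", "strand"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (tool, cell_line, junction) rows at "
            f"{list(df.index[dup][:5])}"
        )
    df["circ_id"] = make_circ_ids(df)
    return df


def make_circ_ids(df: pd.DataFrame) -> pd.Series:
    """Vectorized canonical ids from chrom/start/end/strand columns."""
    return (
        df["chrom"].astype(str)
        + ":" + df["start"].astype(str)
        + "-" + df["end"].astype(str)
        + ":" + df["strand"].astype(str)
    )


def write_tool_calls(df: pd.DataFrame, path: str | Path, dialect: str | Dialect = "tool_tsv") -> None:
    """Write a call table for one tool in the given dialect (inverse of the reader)."""
    d = get_dialect(dialect) if isinstance(dialect, str) else dialect
    out = df.copy()
    starts, ends = d.from_internal(out["start"].to_numpy(), out["end"].to_numpy())
    out["start"], out["end"] = starts, ends
    if d.layout == "tidy":
        out[["cell_line", "chrom", "start", "end", "strand", "reads"]].to_csv(
            path, sep="\t", index=False
        )
    elif d.layout == "bed6":
        out = out.assign(name=".")
        out[["chrom", "start", "end", "name", "reads", "strand"]].to_csv(
            path, sep="\t", index=False, header=False
        )
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown layout {d.layout!r}")


# ---------------------------------------------------------------------------
# Panel metadata
# ---------------------------------------------------------------------------


@dataclass
class PanelMeta:
    """Cell-line → lineage map, library sizes, and circRNA → parental-gene map."""

    lineage_of: dict[str, str]
    library_size: dict[str, int]
    gene_of_circ: dict[str, str] = field(default_factory=dict)

    def validate_cell_lines(self, cell_lines: Iterable[str]) -> None:
        missing_lib = [c for c in cell_lines if c not in self.library_size]
        if missing_lib:
            raise ConfigurationError(
                f"cell lines without library size: {missing_lib[:10]}"
            )
        missing_lin = [c for c in self.library_size if c not in self.lineage_of]
        if missing_lin:
            raise ConfigurationError(f"cell lines without lineage: {missing_lin[:10]}")
        bad = [c for c, n in self.library_size.items() if n <= 0]
        if bad:
            raise ConfigurationError(f"non-positive library sizes for: {bad[:10]}")

    def lineages(self) -> list[str]:
        return sorted(set(self.lineage_of.values()))


def read_lineages(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["cell_line"], df["lineage"]))


def write_lineages(lineage_of: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_line": list(lineage_of), "lineage": list(lineage_of.values())}
    ).to_csv(path, sep="\t", index=False)


def read_library_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "library_size": np.int64})
    return dict(zip(df["cell_line"], df["library_size"].astype(int)))


def write_library_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_line": list(sizes), "library_size": list(sizes.values())}
    ).to_csv(path, sep="\t", index=False)


def read_circ_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["circ_id"], df["gene"]))


def write_circ_gene_map(gene_of_circ: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"circ_id": list(gene_of_circ), "gene": list(gene_of_circ.values())}
    ).to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = [
    "gene_length", "exon_count", "exon_length", "intron_length",
    "mean_expression", "rbp_peaks", "actionable",
]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check gene-annotation invariants; fill intron_length where derivable.

    Requires index = gene id; invariants: gene_length >= exon_length >= 0,
    exon_count >= 1, intron_length == gene_length - exon_length.
    """
    ann = ann.copy()
    if (ann["exon_length"] < 0).any() or (ann["gene_length"] < ann["exon_length"]).any():
        bad = ann.index[
            (ann["exon_length"] < 0) | (ann["gene_length"] < ann["exon_length"])
        ]
        raise ValidationError(f"gene_length >= exon_length >= 0 violated for {list(bad[:10])}")
    if (ann["exon_count"] < 1).any():
        bad = ann.index[ann["exon_count"] < 1]
        raise ValidationError(f"exon_count < 1 for {list(bad[:10])}")
    derived = ann["gene_length"] - ann["exon_length"]
    if "intron_length" not in ann.columns or ann["intron_length"].isna().all():
        ann["intron_length"] = derived
    else:
        mism = ann["intron_length"].notna() & (ann["intron_length"] != derived)
        if mism.any():
            raise ValidationError(
                f"intron_length != gene_length - exon_length for {list(ann.index[mism][:10])}"
            )
        ann["intron_length"] = derived
    return ann


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if "actionable" in df.columns:
        df["actionable"] = df["actionable"].astype(bool)
    return validate_annotation(df)


def write_gene_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# CircMatrix
# ---------------------------------------------------------------------------


class CircMatrix:
    """Consensus circRNA × cell-line matrix of normalized backsplice reads.

    ``values`` is a float DataFrame (rows: canonical circ ids, columns: cell
    lines); absent calls are 0.  ``support`` optionally records the set of
    detecting tools per nonzero (circ, cell line) entry.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        support: dict[tuple[str, str], tuple[str, ...]] | None = None,
    ) -> None:
        self.values = values.astype(float)
        self.support = support or {}

    # -- basic queries ------------------------------------------------------

    @property
    def circ_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)

    def presence(self) -> pd.DataFrame:
        return self.values > 0

    def tools_for(self, circ: str, cell_line: str) -> tuple[str, ...]:
        return self.support.get((circ, cell_line), ())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CircMatrix):
            return NotImplemented
        return self.values.equals(other.values)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Dense TSV: header of cell lines, first column the circ id."""
        self.values.to_csv(path, sep="\t", index_label="circ_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CircMatrix":
        df = pd.read_csv(path, sep="\t", index_col="circ_id", float_precision="round_trip")
        df.index = df.index.astype(str)
        return cls(df)

    def to_triplets(self, path: str | Path) -> None:
        """Sparse triplet TSV (zeros omitted), with tool support preserved."""
        rows = []
        arr = self.values.to_numpy()
        nz = np.argwhere(arr != 0)
        for i, j in nz:
            circ = self.values.index[i]
            cell = self.values.columns[j]
            rows.append(
                (circ, cell, arr[i, j], ",".join(self.tools_for(circ, cell)))
            )
        out = pd.DataFrame(rows, columns=["circ_id", "cell_line", "value", "tools"])
        header_note = pd.DataFrame(
            {"circ_id": [], "cell_line": [], "value": [], "tools": []}
        )
        (out if len(rows) else header_note).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_triplets(
        cls,
        path: str | Path,
        circ_ids: list[str] | None = None,
        cell_lines: list[str] | None = None,
    ) -> "CircMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "cell_line": str, "tools": str}, float_precision="round_trip")
        if circ_ids is None:
            circ_ids = sorted(df["circ_id"].unique())
        if cell_lines is None:
            cell_lines = sorted(df["cell_line"].unique())
        values = pd.DataFrame(0.0, index=pd.Index(circ_ids, name="circ_id"), columns=cell_lines)
        support: dict[tuple[str, str], tuple[str, ...]] = {}
        for row in df.itertuples(index=False):
            values.loc[row.circ_id, row.cell_line] = row.value
            if isinstance(row.tools, str) and row.tools:
                support[(row.circ_id, row.cell_line)] = tuple(row.tools.split(","))
        return cls(values, support)


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
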