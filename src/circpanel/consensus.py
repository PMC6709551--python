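"""Consensus backsplice-junction calling from multi-tool detector outputs.

A circRNA is accepted in a cell line only when at least ``min_tools``
detectors each report it with at least ``min_reads`` backsplice-spanning
reads; its abundance is the arithmetic mean of the read counts over those
detecting tools, normalized to the cell line's sequencing depth (reads per
million mapped reads by default).

Two readings of the read threshold are implemented:

``per_tool`` (default)
    a tool "detects" the junction only if its own count is >= ``min_reads``;
    the mean is taken over detecting tools only.
``mean``
    every reporting tool counts toward ``min_tools`` and the mean over all
    of them must be >= ``min_reads``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CircMatrix, ConfigurationError, PanelMeta, ValidationError, logger

CONSENSUS_COLUMNS = ["cell_line", "circ_id", "n_tools", "tools", "mean_reads"]


def merge_calls(
    calls: pd.DataFrame,
    min_tools: int = 2,
    min_reads: int = 2,
    threshold: str = "per_tool",
) -> pd.DataFrame:
    """Apply the ensemble rule to a validated tool-call table.

    Parameters
    ----------
    calls
        Table with columns ``tool, cell_line, circ_id, reads`` (extra
        columns ignored).
    min_tools, min_reads
        Detection requires >= ``min_tools`` tools (each with >= ``min_reads``
        reads under the default ``per_tool`` threshold).
    threshold
        ``"per_tool"`` or ``"mean"`` (see module docstring).

    Returns
    -------
    DataFrame with one row per accepted (cell_line, circ_id):
    ``cell_line, circ_id, n_tools, tools`` (comma-joined, sorted),
    ``mean_reads``.
    """
    if min_tools < 1:
        raise ConfigurationError("min_tools must be >= 1")
    if min_reads < 0:
        raise ConfigurationError("min_reads must be >= 0")
    if threshold not in ("per_tool", "mean"):
        raise ConfigurationError(f"unknown threshold mode {threshold!r}")
    if calls.empty:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)
    if (calls["reads"] < 0).any():
        raise ValidationError("negative read counts in call table")

    df = calls
    if threshold == "per_tool":
        df = df[df["reads"] >= min_reads]
        if df.empty:
            return pd.DataFrame(columns=CONSENSUS_COLUMNS)

    # group by (cell_line, circ_id) with integer codes; (tool, cell, key) is
    # unique, so the group size equals the number of detecting tools
    cell = df["cell_line"].to_numpy(dtype=object)
    circ = df["circ_id"].to_numpy(dtype=object)
    tools_arr = df["tool"].to_numpy(dtype=object)
    reads = df["reads"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(pd.Index(cell + "\t" + circ), sort=True)
    order = np.lexsort((tools_arr, codes))
    codes_s, tools_s, reads_s = codes[order], tools_arr[order], reads[order]
    n_groups = len(uniques)
    n_tools = np.bincount(codes_s, minlength=n_groups)
    mean_reads = np.bincount(codes_s, weights=reads_s, minlength=n_groups) / n_tools
    starts = np.searchsorted(codes_s, np.arange(n_groups))
    bounds = np.append(starts, len(codes_s))
    keep = n_tools >= min_tools
    if threshold == "mean":
        keep &= mean_reads >= min_reads
    kept = np.flatnonzero(keep)
    tool_strings = [",".join(tools_s[bounds[i]:bounds[i + 1]]) for i in kept]
    pairs = uniques[kept].str.split("\t")
    out = pd.DataFrame(
        {
            "cell_line": [p[0] for p in pairs],
            "circ_id": [p[1] for p in pairs],
            "n_tools": n_tools[kept],
            "tools": tool_strings,
            "mean_reads": mean_reads[kept],
        }
    )
    logger.debug(
        "merge_calls: %d consensus calls, %d candidate junction/line pairs rejected",
        len(out), n_groups - len(out),
    )
    return out[CONSENSUS_COLUMNS]


def normalize_reads(
    consensus: pd.DataFrame,
    meta: PanelMeta,
    scale: float = 1e6,
    cell_lines: list[str] | None = None,
) -> CircMatrix:
    """Scale mean backsplice reads by library size into a CircMatrix.

    ``norm_reads = mean_reads / library_size * scale`` (reads per million at
    the default scale).  ``cell_lines`` fixes the column set (cell lines
    with zero consensus calls still get a column); defaults to the cell
    lines present in the consensus table.
    """
    if cell_lines is None:
        cell_lines = sorted(consensus["cell_line"].unique()) if len(consensus) else []
    missing = [c for c in cell_lines if c not in meta.library_size]
    if len(consensus):
        missing += [
            c for c in consensus["cell_line"].unique()
            if c not in meta.library_size and c not in missing
        ]
    if missing:
        raise ConfigurationError(f"missing library size for cell lines: {missing[:10]}")
    bad = [c for c in cell_lines if meta.library_size.get(c, 1) <= 0]
    if bad:
        raise ConfigurationError(f"non-positive library size for: {bad[:10]}")

    if consensus.empty:
        values = pd.DataFrame(
            np.zeros((0, len(cell_lines))), index=pd.Index([], name="circ_id"),
            columns=cell_lines,
        )
        return CircMatrix(values)

    libs = consensus["cell_line"].map(meta.library_size).astype(float)
    norm = consensus["mean_reads"] / libs * scale
    tall = consensus.assign(norm_reads=norm)
    values = tall.pivot_table(
        index="circ_id", columns="cell_line", values="norm_reads", fill_value=0.0,
        aggfunc="first",
    )
    values = values.reindex(columns=cell_lines, fill_value=0.0)
    values = values.sort_index()
    values.index.name = "circ_id"
    values.columns.name = None
    support = {
        (row.circ_id, row.cell_line): tuple(row.tools.split(","))
        for row in tall.itertuples(index=False)
    }
    return CircMatrix(values, support)


def total_backsplice_load(m: CircMatrix) -> pd.Series:
    """Per cell line, the sum of normalized backsplice reads over all circRNAs."""
    return m.values.sum(axis=0)


def count_circ_per_line(m: CircMatrix) -> pd.Series:
    """Per cell line, the number of distinct circRNAs detected (nonzero entries)."""
    return (m.values > 0).sum(axis=0)


def per_line_summary(m: CircMatrix, meta: PanelMeta | None = None) -> pd.DataFrame:
    """Cell-line summary table: circRNA count, total load, lineage."""
    out = pd.DataFrame(
        {
            "n_circ": count_circ_per_line(m),
            "total_load": total_backsplice_load(m),
        }
    )
    out.index.name = "cell_line"
    if meta is not None:
        out["lineage"] = pd.Series(meta.lineage_of).reindex(out.index)
    return out
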