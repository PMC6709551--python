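import numpy as np
import pandas as pd
import pytest

import circpanel as cp
from circpanel.core import CircMatrix, PanelMeta


@pytest.fixture(scope="session")
def small_panel():
    """A small but fully structured synthetic panel, shared across tests."""
    cfg = cp.PanelConfig(
        seed=7, n_lineages=4, lines_per_lineage=10, n_genes=400, n_circ=600,
        n_drugs=10, n_planted_drug_effects=2,
    )
    return cp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_panel):
    merged = cp.merge_calls(small_panel.tool_calls)
    return cp.normalize_reads(
        merged, small_panel.meta, cell_lines=small_panel.cell_lines
    )


def make_matrix(values: dict[str, dict[str, float]]) -> CircMatrix:
    """Build a CircMatrix from {circ_id: {cell_line: value}} (absent = 0)."""
    df = pd.DataFrame(values).T.fillna(0.0)
    df.index.name = "circ_id"
    return CircMatrix(df)


def make_meta(
    lineage_of: dict[str, str],
    library_size: dict[str, int] | None = None,
    gene_of_circ: dict[str, str] | None = None,
) -> PanelMeta:
    if library_size is None:
        library_size = {c: 1_000_000 for c in lineage_of}
    return PanelMeta(lineage_of, library_size, gene_of_circ or {})


def calls_frame(rows):
    """Rows of (tool, cell_line, circ_id, reads) -> validated call table."""
    df = pd.DataFrame(rows, columns=["tool", "cell_line", "circ_id", "reads"])
    return df


def brute_force_consensus(rows, min_tools=2, min_reads=2, threshold="per_tool"):
    """Independent oracle for merge_calls: direct per-pair enumeration.

    rows: (tool, cell_line, circ_id, reads) tuples.  Returns
    {(cell_line, circ_id): (frozenset(tools), mean_reads)}.
    """
    by_pair: dict[tuple, dict[str, int]] = {}
    for tool, cell, circ, reads in rows:
        by_pair.setdefault((cell, circ), {})[tool] = reads
    out = {}
    for pair, per_tool in by_pair.items():
        if threshold == "per_tool":
            qual = {t: r for t, r in per_tool.items() if r >= min_reads}
            if len(qual) >= min_tools:
                out[pair] = (
                    frozenset(qual),
                    sum(qual.values()) / len(qual),
                )
        else:  # threshold on the mean over all reporting tools
            mean = sum(per_tool.values()) / len(per_tool)
            if len(per_tool) >= min_tools and mean >= min_reads:
                out[pair] = (frozenset(per_tool), mean)
    return out
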