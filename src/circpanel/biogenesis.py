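"""Screens for circRNA biogenesis regulators and condition comparisons.

Candidate regulator genes (e.g. spliceosome factors, 3' end processing
factors, RNA helicases, RNA-binding proteins) are screened by Spearman
correlation between their expression and the per-cell-line total normalized
backsplice load; a gene is flagged when |Rs| > ``rs_min`` (default 0.3) and
its Benjamini-Hochberg adjusted p-value < ``q_max`` (default 0.05).  BH is
applied within each analysis stratum (the panel-wide candidate list, or
each lineage separately), never pooled across strata.

Also provided: a mesenchymal-minus-epithelial EMT score from marker
z-scores, the circRNA-high/low median split of cell lines, a two-sample
Student's t comparison of load between treatment conditions, and export of
expression + phenotype-label files (GCT/CLS) for an external gene-set
enrichment tool; the enrichment statistic itself is not re-implemented.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, PanelMeta, ValidationError, logger

#: Default EMT marker panels. The canonical-marker composition is a
#: documented reconstruction (config-driven; override freely).
MESENCHYMAL_MARKERS = ("VIM", "FN1", "CDH2", "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1")
EPITHELIAL_MARKERS = ("CDH1", "CLDN3", "CLDN4", "CLDN7")

GROUP_HIGH = "circRNA-high"
GROUP_LOW = "circRNA-low"

CORRELATION_COLUMNS = ["gene", "lineage", "n", "rs", "p", "q", "significant", "status"]


def _correlate(
    expr: pd.DataFrame,
    load: pd.Series,
    genes: Sequence[str],
    rs_min: float,
    q_max: float,
    lineage: str,
    min_n: int = 3,
) -> pd.DataFrame:
    cells = [c for c in expr.columns if c in load.index]
    if len(cells) < min_n:
        raise ConfigurationError(
            f"need >= {min_n} shared cell lines between expression and load, got {len(cells)}"
        )
    y = load[cells].to_numpy(dtype=float)
    rows = []
    for gene in genes:
        if gene not in expr.index:
            rows.append((gene, lineage, 0, np.nan, np.nan, "missing"))
            continue
        x = expr.loc[gene, cells].to_numpy(dtype=float)
        res = stats.spearmanr(x, y)
        rs, p = float(res.statistic), float(res.pvalue)
        if np.isnan(rs):  # constant vector
            rows.append((gene, lineage, len(cells), np.nan, np.nan, "degenerate"))
        else:
            rows.append((gene, lineage, len(cells), rs, p, "ok"))
    df = pd.DataFrame(rows, columns=["gene", "lineage", "n", "rs", "p", "status"])
    ok = df["status"] == "ok"
    q = pd.Series(np.nan, index=df.index)
    if ok.any():
        q[ok] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["q"] = q
    df["significant"] = ok & (df["rs"].abs() > rs_min) & (df["q"] < q_max)
    return df[CORRELATION_COLUMNS]


def correlate_regulators(
    expr: pd.DataFrame,
    load: pd.Series | Mapping[str, float],
    genes: Sequence[str],
    rs_min: float = 0.3,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen of candidate genes against total backsplice load.

    Ranks are tie-corrected; p-values two-sided; BH q computed across the
    candidate list only.  Genes absent from the expression matrix are
    recorded with status "missing", never silently dropped.
    """
    if not len(genes):
        raise ConfigurationError("candidate gene list is empty")
    load = pd.Series(load)
    return _correlate(expr, load, genes, rs_min, q_max, lineage="all")


def per_lineage_correlations(
    expr: pd.DataFrame,
    load: pd.Series | Mapping[str, float],
    meta: PanelMeta,
    genes: Sequence[str],
    rs_min: float = 0.3,
    q_max: float = 0.05,
    min_lines: int = 10,
) -> pd.DataFrame:
    """Regulator screen stratified by lineage (BH within each lineage).

    Only lineages with at least ``min_lines`` cell lines (shared between
    expression and load) are tested.
    """
    load = pd.Series(load)
    shared = [c for c in expr.columns if c in load.index]
    by_lineage: dict[str, list[str]] = {}
    for c in shared:
        lin = meta.lineage_of.get(c)
        if lin is None:
            raise ConfigurationError(f"cell line {c!r} has no lineage")
        by_lineage.setdefault(lin, []).append(c)
    frames = []
    for lin in sorted(by_lineage):
        cells = by_lineage[lin]
        if len(cells) < min_lines:
            logger.debug("per_lineage_correlations: skipping %s (%d lines)", lin, len(cells))
            continue
        frames.append(
            _correlate(expr[cells], load[cells], genes, rs_min, q_max, lineage=lin)
        )
    if not frames:
        return pd.DataFrame(columns=CORRELATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def emt_score(
    z: pd.DataFrame,
    mesenchymal: Sequence[str] = MESENCHYMAL_MARKERS,
    epithelial: Sequence[str] = EPITHELIAL_MARKERS,
) -> pd.Series:
    """Per cell line: mean mesenchymal marker z-score minus mean epithelial.

    ``z`` is a gene × cell-line matrix of expression z-scores.  Positive
    scores indicate a more mesenchymal state.
    """
    if not len(mesenchymal) or not len(epithelial):
        raise ConfigurationError("marker lists must be non-empty")
    missing = [g for g in [*mesenchymal, *epithelial] if g not in z.index]
    if missing:
        raise ConfigurationError(f"markers absent from z-score matrix: {missing}")
    return z.loc[list(mesenchymal)].mean(axis=0) - z.loc[list(epithelial)].mean(axis=0)


def split_high_low(load: pd.Series | Mapping[str, float]) -> pd.Series:
    """Median split of cell lines by total backsplice load.

    Strictly above the panel median -> ``circRNA-high``; ties at the median
    go to ``circRNA-low``.
    """
    load = pd.Series(load)
    if len(load) < 2:
        raise ConfigurationError("need >= 2 cell lines to split")
    med = load.median()
    return pd.Series(np.where(load > med, GROUP_HIGH, GROUP_LOW), index=load.index)


def compare_load_groups(
    load: pd.Series | Mapping[str, float],
    groups: pd.Series | Mapping[str, str],
) -> tuple[float, float]:
    """Two-sided equal-variance Student's t test of load between two conditions.

    Degenerate rule: zero variance in both groups with equal means -> (0.0,
    1.0); zero pooled variance with unequal means is an error.
    """
    load = pd.Series(load)
    groups = pd.Series(groups)
    shared = load.index.intersection(groups.index)
    labels = sorted(groups[shared].unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 conditions, got {labels}")
    a = load[shared][groups[shared] == labels[0]].to_numpy(dtype=float)
    b = load[shared][groups[shared] == labels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each condition needs >= 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValidationError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# GCT/CLS export for the external enrichment tool
# ---------------------------------------------------------------------------


def export_gsea_inputs(
    expr: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write ``<prefix>.gct`` (expression) and ``<prefix>.cls`` (two-class labels).

    Samples are ordered as in ``expr``; every expression column must have a
    group label.  Returns the two written paths.
    """
    groups = pd.Series(groups)
    missing = [c for c in expr.columns if c not in groups.index]
    if missing:
        raise ConfigurationError(f"samples without group label: {missing[:10]}")
    labels = groups[expr.columns]
    classes = list(dict.fromkeys(labels))  # order of first appearance
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    prefix = Path(out_prefix)
    gct_path = prefix.with_suffix(".gct")
    cls_path = prefix.with_suffix(".cls")
    with open(gct_path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
        body = expr.copy()
        body.insert(0, "DESCRIPTION", "na")
        body.to_csv(fh, sep="\t", index_label="NAME")
    with open(cls_path, "w") as fh:
        fh.write(f"{expr.shape[1]} 2 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels) + "\n")
    return gct_path, cls_path


def read_cls(path: str | Path, sample_names: Sequence[str]) -> pd.Series:
    """Parse a two-class CLS phenotype file back into a sample -> label map."""
    lines = Path(path).read_text().splitlines()
    n, n_classes, _ = lines[0].split()
    labels = lines[2].split()
    if int(n) != len(labels) or len(labels) != len(sample_names):
        raise ValidationError(f"{path}: sample count mismatch")
    if int(n_classes) != len(set(labels)):
        raise ValidationError(f"{path}: declared class count mismatch")
    return pd.Series(labels, index=list(sample_names))
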