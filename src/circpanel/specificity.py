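"""Lineage-specificity scoring of genes and detection-breadth classification of circRNAs.

The specificity score of gene *j* for lineage *l* is

    s = (median expression in lineage l  -  panel-wide median) / panel-wide IQR,

with the IQR computed as Q3 - Q1 using linearly interpolated quantiles.  A
gene with ``s > cutoff`` (default 0.5) is called specific to that lineage.
Genes whose panel-wide IQR is zero get an undefined score and no call.

The score is on whatever scale the expression matrix is on; it is invariant
under panel-wide affine rescaling of one gene (x -> a*x + b, a > 0) but not
under a log transform, so callers must be consistent about the input scale.

circRNAs are classified by detection breadth: *lineage-specific* when
detected (nonzero consensus-matrix entry) in exactly one lineage,
*ubiquitous* when detected in at least ``ubiquity_min`` lineages (default
15), *intermediate* otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CircMatrix, ConfigurationError, PanelMeta

CATEGORY_SPECIFIC = "lineage_specific"
CATEGORY_UBIQUITOUS = "ubiquitous"
CATEGORY_INTERMEDIATE = "intermediate"


def _lineage_columns(columns: pd.Index, meta: PanelMeta) -> dict[str, list[str]]:
    missing = [c for c in columns if c not in meta.lineage_of]
    if missing:
        raise ConfigurationError(f"cell lines without lineage: {missing[:10]}")
    groups: dict[str, list[str]] = {}
    for c in columns:
        groups.setdefault(meta.lineage_of[c], []).append(c)
    return groups


def call_specific_genes(
    expr: pd.DataFrame,
    meta: PanelMeta,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Score every (gene, lineage) pair of an expression matrix.

    Returns a long DataFrame with columns ``gene, lineage, s, defined,
    specific``.  ``defined`` is False (and ``specific`` False, ``s`` NaN)
    where the panel-wide IQR is zero.
    """
    groups = _lineage_columns(expr.columns, meta)
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 lineages to score specificity")
    med_all = expr.median(axis=1)
    q1 = expr.quantile(0.25, axis=1, interpolation="linear")
    q3 = expr.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    frames = []
    for lineage in sorted(groups):
        med_l = expr[groups[lineage]].median(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (med_l - med_all) / iqr
        defined = iqr > 0
        s = s.where(defined, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "lineage": lineage,
                    "s": s.to_numpy(),
                    "defined": defined.to_numpy(),
                    "specific": (defined & (s > cutoff)).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def specificity_score(
    expr: pd.DataFrame,
    meta: PanelMeta,
    gene: str,
    lineage: str,
    cutoff: float = 0.5,
) -> dict:
    """Score one gene for one lineage (see module docstring for the formula)."""
    if gene not in expr.index:
        raise ConfigurationError(f"gene {gene!r} not in expression matrix")
    groups = _lineage_columns(expr.columns, meta)
    if lineage not in groups:
        raise ConfigurationError(f"unknown lineage {lineage!r}")
    x = expr.loc[gene]
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if iqr == 0:
        return {"gene": gene, "lineage": lineage, "s": np.nan, "defined": False,
                "specific": False}
    s = (x[groups[lineage]].median() - x.median()) / iqr
    return {"gene": gene, "lineage": lineage, "s": float(s), "defined": True,
            "specific": bool(s > cutoff)}


def calibrate_cutoff(
    expr: pd.DataFrame,
    meta: PanelMeta,
    cutoffs: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """Scan cutoffs; report the fraction of genes specific in >= 1 lineage.

    Supports choosing a cutoff such that roughly half of the genes come out
    tissue-specific somewhere; the pipeline default stays the fixed 0.5.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.1, 2.01, 0.1), 2)
    table = call_specific_genes(expr, meta, cutoff=-np.inf)
    s_max = table[table["defined"]].groupby("gene")["s"].max()
    n_genes = expr.shape[0]
    rows = [
        {"cutoff": float(c), "frac_specific_somewhere": float((s_max > c).sum()) / n_genes}
        for c in cutoffs
    ]
    return pd.DataFrame(rows)


def classify_breadth(
    m: CircMatrix,
    meta: PanelMeta,
    ubiquity_min: int = 15,
) -> pd.DataFrame:
    """Count detecting lineages per circRNA and assign a breadth category.

    Returns a DataFrame indexed by circ_id with columns ``n_lineages,
    category, lineage`` where ``lineage`` is the single detecting lineage
    for lineage-specific circRNAs and "" otherwise.
    """
    groups = _lineage_columns(m.values.columns, meta)
    lineages = sorted(groups)
    present = m.values > 0
    by_lineage = pd.DataFrame(
        {lin: present[groups[lin]].any(axis=1) for lin in lineages}
    )
    n_lineages = by_lineage.sum(axis=1)
    category = pd.Series(CATEGORY_INTERMEDIATE, index=m.values.index)
    category[n_lineages == 1] = CATEGORY_SPECIFIC
    category[n_lineages >= ubiquity_min] = CATEGORY_UBIQUITOUS
    single = by_lineage.idxmax(axis=1).where(n_lineages == 1, "")
    out = pd.DataFrame(
        {"n_lineages": n_lineages, "category": category, "lineage": single}
    )
    out.index.name = "circ_id"
    return out


def specific_overlap_fraction(
    breadth: pd.DataFrame,
    spec_genes: pd.DataFrame,
    meta: PanelMeta,
) -> pd.DataFrame:
    """Per lineage, the fraction of lineage-specific circRNAs whose parental
    gene is specific to that same lineage.

    circRNAs without a parental-gene assignment are excluded from both the
    numerator and the denominator.  Lineages with no assigned
    lineage-specific circRNAs get NaN (undefined), with ``n_circ`` = 0.
    """
    specific_sets = {
        lin: set(sub[sub["specific"]]["gene"])
        for lin, sub in spec_genes.groupby("lineage")
    }
    rows = []
    ls = breadth[breadth["category"] == CATEGORY_SPECIFIC]
    lineages = sorted(set(meta.lineage_of.values()))
    for lin in lineages:
        circs = ls.index[ls["lineage"] == lin]
        genes = [meta.gene_of_circ[c] for c in circs if c in meta.gene_of_circ]
        n = len(genes)
        hits = sum(g in specific_sets.get(lin, set()) for g in genes)
        rows.append(
            {
                "lineage": lin,
                "n_circ": n,
                "n_overlap": hits,
                "fraction": (hits / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
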