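"""Matched-covariate permutation tests for gene-set statistics.

Tests whether a focal gene set (e.g. the 135 clinically actionable cancer
genes) is enriched for a set-level statistic — the fraction of genes that
form a circRNA, or the median RNA-binding-protein (RBP) peak count —
relative to random gene sets of the same size drawn from a background pool
matched on one covariate (gene length, exon length, intron length, exon
count, or mean expression; matching means "covariate within the focal
set's [min, max] range").

Empirical p-values use the add-one convention

    p = (1 + #{permuted >= observed}) / (1 + n_perm),

so the minimum attainable p at 10,000 permutations is 1/10,001 (< 1e-4)
and p is never zero.  A Pearson chi-squared helper (no continuity
correction) covers the companion 2x2 rate comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CircMatrix, ConfigurationError, PanelMeta, ValidationError

MATCH_COVARIATES = (
    "gene_length", "exon_length", "intron_length", "exon_count", "mean_expression",
)

#: background-pool convention: a gene enters the circRNA-rate background only
#: if its circRNAs are expressed in at least this many samples
BACKGROUND_MIN_SAMPLES = 5


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    n_perm: int
    n_as_extreme: int
    p_emp: float
    covariate: str
    seed: int
    tail: str
    perm_mean: float
    perm_sd: float
    permuted: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "permuted"}
        return pd.DataFrame([d])


# ---------------------------------------------------------------------------
# Set statistics
# ---------------------------------------------------------------------------


def genes_forming_circ(m: CircMatrix, meta: PanelMeta) -> frozenset[str]:
    """Genes with >= 1 circRNA row detected (nonzero) in >= 1 cell line."""
    expressed = m.values.index[(m.values > 0).any(axis=1)]
    return frozenset(
        meta.gene_of_circ[c] for c in expressed if c in meta.gene_of_circ
    )


def circ_gene_rate(
    genes: Sequence[str] | frozenset[str],
    m: CircMatrix,
    meta: PanelMeta,
) -> float:
    """Fraction of the gene set that forms a circRNA in >= 1 cell line."""
    genes = set(genes)
    if not genes:
        raise ValidationError("circ_gene_rate: empty gene set")
    forming = genes_forming_circ(m, meta)
    return len(genes & forming) / len(genes)


def median_rbp_peaks(genes: Sequence[str] | frozenset[str], ann: pd.DataFrame) -> float:
    """Median RBP binding-peak count over the gene set."""
    genes = list(genes)
    if not genes:
        raise ValidationError("median_rbp_peaks: empty gene set")
    missing = [g for g in genes if g not in ann.index or pd.isna(ann.loc[g, "rbp_peaks"])]
    if missing:
        raise ValidationError(f"genes without rbp_peaks annotation: {missing[:10]}")
    return float(ann.loc[genes, "rbp_peaks"].median())


def make_rate_statistic(m: CircMatrix, meta: PanelMeta) -> Callable[[Sequence[str]], float]:
    """Bind circ_gene_rate to a matrix/meta pair (precomputes the forming set)."""
    forming = genes_forming_circ(m, meta)

    def stat(genes: Sequence[str]) -> float:
        gs = set(genes)
        return len(gs & forming) / len(gs)

    stat.__name__ = "circ_gene_rate"
    return stat


def make_rbp_statistic(ann: pd.DataFrame) -> Callable[[Sequence[str]], float]:
    peaks = ann["rbp_peaks"]

    def stat(genes: Sequence[str]) -> float:
        return float(peaks.loc[list(genes)].median())

    stat.__name__ = "median_rbp_peaks"
    return stat


# ---------------------------------------------------------------------------
# Matched background pool and permutation engine
# ---------------------------------------------------------------------------


def matched_pool(
    focal: Sequence[str] | frozenset[str],
    background: Sequence[str] | frozenset[str],
    ann: pd.DataFrame,
    covariate: str,
) -> list[str]:
    """Background genes whose covariate lies within the focal [min, max] range.

    The range is inclusive at both ends.  Returns a sorted list (stable
    order for reproducible sampling).
    """
    if covariate not in MATCH_COVARIATES:
        raise ConfigurationError(
            f"covariate must be one of {MATCH_COVARIATES}, got {covariate!r}"
        )
    focal, background = set(focal), set(background)
    overlap = focal & background
    if overlap:
        raise ValidationError(
            f"background must exclude focal genes; overlap: {sorted(overlap)[:10]}"
        )
    missing = [g for g in (focal | background) if g not in ann.index]
    if missing:
        raise ValidationError(f"genes without annotation: {missing[:10]}")
    v = ann[covariate]
    lo, hi = v.loc[list(focal)].min(), v.loc[list(focal)].max()
    pool = sorted(g for g in background if lo <= v.loc[g] <= hi)
    if len(pool) < len(focal):
        raise ValidationError(
            f"matched pool ({len(pool)} genes) smaller than focal set ({len(focal)}); "
            f"cannot sample without replacement"
        )
    return pool


def matched_permutation(
    focal: Sequence[str] | frozenset[str],
    background: Sequence[str] | frozenset[str],
    ann: pd.DataFrame,
    covariate: str,
    statistic: Callable[[Sequence[str]], float],
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "greater",
) -> PermutationResult:
    """Permutation test of a set statistic against matched random gene sets.

    Draws ``n_perm`` gene sets of size ``len(focal)`` uniformly without
    replacement from the matched background pool, evaluates ``statistic``
    on each, and returns the add-one empirical p for the requested tail
    (``"greater"`` tests enrichment, ``"less"`` depletion).  Fully
    reproducible given ``seed``.
    """
    if tail not in ("greater", "less"):
        raise ConfigurationError(f"tail must be 'greater' or 'less', got {tail!r}")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    focal_sorted = sorted(set(focal))
    pool = matched_pool(focal_sorted, background, ann, covariate)
    observed = float(statistic(focal_sorted))
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool, dtype=object)
    k = len(focal_sorted)
    permuted = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        draw = rng.choice(pool_arr, size=k, replace=False)
        permuted[i] = statistic(draw)
    if tail == "greater":
        n_extreme = int((permuted >= observed).sum())
    else:
        n_extreme = int((permuted <= observed).sum())
    p_emp = (1 + n_extreme) / (1 + n_perm)
    return PermutationResult(
        statistic_name=getattr(statistic, "__name__", "statistic"),
        observed=observed,
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        p_emp=p_emp,
        covariate=covariate,
        seed=seed,
        tail=tail,
        perm_mean=float(permuted.mean()),
        perm_sd=float(permuted.std(ddof=1)) if n_perm > 1 else 0.0,
        permuted=permuted,
    )


def rate_background(
    m: CircMatrix,
    meta: PanelMeta,
    all_genes: Sequence[str],
    focal: Sequence[str] | frozenset[str],
    min_samples: int = BACKGROUND_MIN_SAMPLES,
) -> list[str]:
    """Background gene universe for the circRNA-rate test.

    Genes (excluding the focal set) with a circRNA expressed in at least
    ``min_samples`` cell lines.
    """
    presence = m.values > 0
    n_samples = presence.sum(axis=1)
    per_gene: dict[str, int] = {}
    for c, n in n_samples.items():
        g = meta.gene_of_circ.get(c)
        if g is not None:
            per_gene[g] = max(per_gene.get(g, 0), int(n))
    focal = set(focal)
    return sorted(
        g for g in all_genes
        if g not in focal and per_gene.get(g, 0) >= min_samples
    )


def contingency_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValidationError("contingency counts must be >= 0")
    if table.sum() == 0:
        raise ValidationError("contingency table is all zero")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("a row or column of the 2x2 table sums to 0")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
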