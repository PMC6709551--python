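"""circRNA-feature association screening (drug AUC, mRNA, protein, mutation).

For each circRNA, cell lines are split into positive/negative groups either
by the row median of normalized backsplice reads (zeros included; strictly
above the median is positive) or by presence (nonzero entry).  Continuous
features (drug response AUC, mRNA or protein expression) are compared
between groups with the two-sided Wilcoxon rank-sum (Mann-Whitney) test and
the effect is the positive-minus-negative mean difference; binary mutation
features use Fisher's exact test with an odds-ratio effect.  p-values from
the whole screen are Benjamini-Hochberg adjusted jointly (per-feature
adjustment available by flag) and associations with q < 0.05 are flagged.

The screen's rank-sum p-values use the normal approximation with tie
correction and continuity correction; because the split is over the same
cell-line universe for every feature, rank sums reduce to a matrix product
of per-feature global ranks with the group-mask matrix, which keeps screens
over thousands of circRNAs fast.  Features containing missing values fall
back to a per-pair path with pairwise dropping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CircMatrix, ConfigurationError, ValidationError, logger

CONTINUOUS_KINDS = ("drug_auc", "mrna", "protein")
BINARY_KINDS = ("mutation",)

RECORD_COLUMNS = [
    "circ_id", "feature", "kind", "n_pos", "n_neg",
    "effect", "direction", "p", "q", "significant", "status",
]


@dataclass
class FeatureMatrix:
    """A feature × cell-line matrix with a declared kind.

    ``kind`` is one of drug_auc / mrna / protein (continuous) or mutation
    (binary 0/1).  AUC values must be >= 0; mutation values in {0, 1}.
    """

    kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in CONTINUOUS_KINDS + BINARY_KINDS:
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        arr = self.values.to_numpy(dtype=float)
        if self.kind == "mutation":
            ok = np.isin(arr[~np.isnan(arr)], (0.0, 1.0)).all()
            if not ok:
                raise ValidationError("mutation matrix values must be 0/1")
        if self.kind == "drug_auc" and np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("AUC values must be >= 0")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(kind, df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# Grouping rules
# ---------------------------------------------------------------------------


def _row(m: CircMatrix, circ: str) -> pd.Series:
    if circ not in m.values.index:
        raise ConfigurationError(f"circRNA {circ!r} not in matrix")
    if m.values.shape[1] < 4:
        raise ValidationError("need >= 4 cell lines to form groups")
    return m.values.loc[circ]


def group_by_median(m: CircMatrix, circ: str) -> pd.Series:
    """positive = normalized reads strictly above the row median (zeros included)."""
    row = _row(m, circ)
    med = row.median()
    return pd.Series(np.where(row > med, "positive", "negative"), index=row.index)


def group_by_presence(m: CircMatrix, circ: str) -> pd.Series:
    """positive = nonzero consensus entry."""
    row = _row(m, circ)
    return pd.Series(np.where(row > 0, "positive", "negative"), index=row.index)


GROUPINGS = {"median": group_by_median, "presence": group_by_presence}


# ---------------------------------------------------------------------------
# Single-pair test
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    effect: float
    p: float
    n_pos: int
    n_neg: int
    status: str = "ok"
    reason: str = ""


def test_association(
    groups: pd.Series,
    feature_values: pd.Series,
    kind: str,
    min_group: int = 3,
    method: str = "auto",
) -> TestResult:
    """Test one circRNA grouping against one feature.

    Continuous kinds: two-sided Wilcoxon rank-sum (scipy ``mannwhitneyu``;
    ``method="auto"`` uses the exact null for small untied samples and the
    tie-corrected, continuity-corrected normal approximation otherwise);
    effect = mean(positive) - mean(negative).  Mutation kind: Fisher's
    exact test on the 2x2 presence table; effect = odds ratio (may be
    ``inf`` for a perfect association).  Groups smaller than ``min_group``
    after pairwise dropping yield a skipped record, not a p-value.
    """
    values = pd.Series(feature_values).dropna()
    shared = groups.index.intersection(values.index)
    g = groups[shared]
    v = values[shared].astype(float)
    pos = v[g == "positive"]
    neg = v[g == "negative"]
    if len(pos) < min_group or len(neg) < min_group:
        return TestResult(
            np.nan, np.nan, len(pos), len(neg), status="skipped",
            reason=f"group below min_group={min_group}",
        )
    if kind in CONTINUOUS_KINDS:
        if pos.nunique() == 1 and neg.nunique() == 1 and pos.iloc[0] == neg.iloc[0]:
            return TestResult(0.0, 1.0, len(pos), len(neg))
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
        effect = float(pos.mean() - neg.mean())
        return TestResult(effect, float(res.pvalue), len(pos), len(neg))
    elif kind in BINARY_KINDS:
        a = int((pos == 1).sum())  # positive group, mutated
        b = int((pos == 0).sum())
        c = int((neg == 1).sum())
        d = int((neg == 0).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return TestResult(float(odds), float(p), len(pos), len(neg))
    raise ConfigurationError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# Vectorized screen
# ---------------------------------------------------------------------------


def _masks_for(m: CircMatrix, circs: pd.Index, cells: list[str], grouping: str) -> np.ndarray:
    sub = m.values.loc[circs, cells].to_numpy(dtype=float)
    if grouping == "presence":
        return sub > 0
    med = np.median(sub, axis=1, keepdims=True)
    return sub > med


def _ranksum_block(values: np.ndarray, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided tie-corrected, continuity-corrected rank-sum p-values.

    values: (n_features, n_cells) with no NaN; masks: (n_circ, n_cells)
    boolean positive-group membership.  Returns (p, effect) each of shape
    (n_circ, n_features).
    """
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)
    # tie term per feature: sum over tie groups of (t^3 - t)
    tie = np.empty(values.shape[0])
    for i, row in enumerate(np.sort(values, axis=1)):
        _, counts = np.unique(row, return_counts=True)
        tie[i] = float((counts.astype(float) ** 3 - counts).sum())
    n1 = masks.sum(axis=1).astype(float)  # (n_circ,)
    n2 = n - n1
    rank_sums = masks.astype(float) @ ranks.T  # (n_circ, n_features)
    u1 = rank_sums - (n1 * (n1 + 1) / 2)[:, None]
    mu = (n1 * n2 / 2)[:, None]
    sigma2 = (n1 * n2 / 12)[:, None] * ((n + 1) - tie[None, :] / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    diff = u1 - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(diff) - 0.5) / sigma
    p = 2 * stats.norm.sf(z)
    p = np.where(sigma == 0, 1.0, np.clip(p, 0.0, 1.0))
    # mean difference effect
    sums_pos = masks.astype(float) @ values.T
    total = values.sum(axis=1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_pos = sums_pos / n1[:, None]
        mean_neg = (total - sums_pos) / n2[:, None]
    effect = mean_pos - mean_neg
    return p, effect


def association_screen(
    m: CircMatrix,
    features: FeatureMatrix,
    grouping: Literal["median", "presence"] = "median",
    min_prevalence: int = 5,
    min_group: int = 3,
    q_max: float = 0.05,
    bh_scope: Literal["screen", "per_feature"] = "screen",
) -> pd.DataFrame:
    """Screen all (circRNA, feature) pairs; BH-adjust and flag q < ``q_max``.

    circRNAs enter the screen only if detected in >= ``min_prevalence`` of
    the shared cell lines; pairs whose positive or negative group ends up
    below ``min_group`` are recorded with status "skipped" and excluded
    from the BH family.
    """
    if grouping not in GROUPINGS:
        raise ConfigurationError(f"grouping must be one of {sorted(GROUPINGS)}")
    cells = [c for c in m.values.columns if c in features.values.columns]
    if len(cells) < 2 * min_group:
        raise ConfigurationError(
            f"need >= {2 * min_group} shared cell lines, got {len(cells)}"
        )
    presence = (m.values[cells] > 0).sum(axis=1)
    circs = m.values.index[presence >= min_prevalence]
    logger.debug(
        "association_screen: %d/%d circRNAs pass min_prevalence=%d on %d shared lines",
        len(circs), m.values.shape[0], min_prevalence, len(cells),
    )
    if len(circs) == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    fvals = features.values[cells]
    records: list[pd.DataFrame] = []
    masks = _masks_for(m, circs, cells, grouping)
    n1 = masks.sum(axis=1)
    n2 = len(cells) - n1
    testable = (n1 >= min_group) & (n2 >= min_group)

    clean = fvals.dropna(axis=0)
    dirty = fvals.loc[fvals.index.difference(clean.index)]

    if features.kind in CONTINUOUS_KINDS and len(clean) and testable.any():
        p, effect = _ranksum_block(clean.to_numpy(dtype=float), masks[testable])
        tcircs = circs[testable]
        idx = pd.MultiIndex.from_product([tcircs, clean.index])
        records.append(
            pd.DataFrame(
                {
                    "circ_id": np.repeat(tcircs, len(clean)),
                    "feature": np.tile(clean.index, len(tcircs)),
                    "n_pos": np.repeat(n1[testable], len(clean)),
                    "n_neg": np.repeat(n2[testable], len(clean)),
                    "effect": effect.ravel(),
                    "p": p.ravel(),
                    "status": "ok",
                }
            )
        )
        slow_features = dirty.index
    else:
        slow_features = fvals.index

    # per-pair path: binary kinds, NaN-containing features, and skip records
    slow_rows = []
    grouping_fn = GROUPINGS[grouping]
    sub_matrix = CircMatrix(m.values.loc[circs, cells])
    need_slow = len(slow_features) > 0 or (~testable).any()
    if need_slow:
        for ci, circ in enumerate(circs):
            feats = slow_features if testable[ci] else fvals.index
            if not len(feats):
                continue
            groups = grouping_fn(sub_matrix, circ)
            for feat in feats:
                r = test_association(
                    groups, fvals.loc[feat], features.kind, min_group=min_group
                )
                slow_rows.append(
                    (circ, feat, r.n_pos, r.n_neg, r.effect, r.p, r.status)
                )
    if slow_rows:
        records.append(
            pd.DataFrame(
                slow_rows,
                columns=["circ_id", "feature", "n_pos", "n_neg", "effect", "p", "status"],
            )
        )
    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    out["kind"] = features.kind
    out["direction"] = np.sign(out["effect"]).where(np.isfinite(out["effect"]), 1.0)

    out["q"] = np.nan
    ok = out["status"] == "ok"
    if ok.any():
        if bh_scope == "screen":
            out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        elif bh_scope == "per_feature":
            for feat, sub in out[ok].groupby("feature"):
                out.loc[sub.index, "q"] = multipletests(sub["p"], method="fdr_bh")[1]
        else:
            raise ConfigurationError(f"unknown bh_scope {bh_scope!r}")
    out["significant"] = ok & (out["q"] < q_max)
    return out[RECORD_COLUMNS].sort_values(["circ_id", "feature"]).reset_index(drop=True)


def summarize_per_feature(records: pd.DataFrame) -> pd.DataFrame:
    """Per feature: counts of significant positive / negative associations."""
    sig = records[records["significant"]]
    if sig.empty:
        feats = records["feature"].unique() if len(records) else []
        return pd.DataFrame(
            {"feature": feats, "n_positive": 0, "n_negative": 0, "n_total": 0}
        )
    grouped = sig.groupby("feature")
    out = pd.DataFrame(
        {
            "n_positive": grouped.apply(
                lambda s: int((s["direction"] > 0).sum()), include_groups=False
            ),
            "n_negative": grouped.apply(
                lambda s: int((s["direction"] < 0).sum()), include_groups=False
            ),
        }
    )
    out["n_total"] = out["n_positive"] + out["n_negative"]
    return out.sort_values("n_total", ascending=False).reset_index()
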