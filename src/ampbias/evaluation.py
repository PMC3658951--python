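"""Evaluation statistics for probe-level corrections.

Three views of data quality, all on the linear intensity scale:

* per-probe-set coefficient of variation (CV = sd / mean over the probes of
  a set) — probes of one set measure one transcript, so a good correction
  makes them more alike;
* a paired one-sided Wilcoxon signed-rank test of whether CV decreased;
* inter-sample Pearson correlation of probe-set summaries, plus average-
  linkage hierarchical clustering of samples at distance 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "probe_set_cv",
    "cv_table",
    "cv_wilcoxon",
    "sample_correlation_matrix",
    "cluster_samples",
    "cut_clusters",
    "linkage_to_newick",
    "EvaluationReport",
    "evaluate_adjustment",
]

EXACT_WILCOXON_MAX_N = 25


def probe_set_cv(pm_values) -> float:
    """Sample-sd (n-1 denominator) over mean; NaN when undefined.

    Undefined for fewer than 2 values or non-positive mean; scale-invariant
    by construction.
    """
    x = np.asarray(pm_values, dtype=float)
    if x.size < 2:
        return float("nan")
    m = x.mean()
    if m <= 0:
        return float("nan")
    return float(x.std(ddof=1) / m)


def cv_table(df: pd.DataFrame, value_col: str = "pm") -> pd.Series:
    """CV per (sample_id, probeset_id) from a long probe table.

    Sets with an undefined CV come back as NaN (callers drop or flag them).
    """
    grp = df.groupby(["sample_id", "probeset_id"], sort=False)[value_col]
    agg = grp.agg(["mean", "std", "size"])
    cv = agg["std"] / agg["mean"]
    cv[(agg["size"] < 2) | (agg["mean"] <= 0)] = np.nan
    cv.name = "cv"
    return cv


def cv_wilcoxon(cv_before, cv_after) -> tuple[float, float, bool]:
    """One-sided paired Wilcoxon signed-rank test that CV decreased.

    Tests median(before - after) > 0; zero differences are dropped first.
    Exact null distribution up to n = 25 pairs, normal approximation with
    continuity correction above.  Returns ``(statistic, p_value, degenerate)``
    where ``degenerate`` marks the all-zero-difference case (p = 1).
    """
    before = np.asarray(cv_before, dtype=float)
    after = np.asarray(cv_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must pair up element-wise")
    keep = np.isfinite(before) & np.isfinite(after)
    d = before[keep] - after[keep]
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0, True
    method = "exact" if d.size <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(
        d, alternative="greater", correction=True, method=method, zero_method="wilcox"
    )
    return float(res.statistic), float(res.pvalue), False


def sample_correlation_matrix(
    expression: pd.DataFrame, subset=None
) -> pd.DataFrame:
    """Pearson correlation between sample columns of a probe-set x sample
    summary matrix, optionally restricted to a probe-set subset.

    Constant columns yield NaN entries (Pearson undefined); the diagonal is
    forced to 1 for valid columns.
    """
    mat = expression if subset is None else expression.loc[list(subset)]
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if mat.empty:
        raise ValueError("empty probe-set subset")
    corr = mat.corr(method="pearson")
    return corr


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    root = hierarchy.to_tree(link)

    def build(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = build(node.get_left(), node.dist)
        right = build(node.get_right(), node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    if root.is_leaf():
        return f"{labels[root.id]};"
    return f"({build(root.get_left(), root.dist)},{build(root.get_right(), root.dist)});"


def cluster_samples(
    corr: pd.DataFrame, linkage_method: str = "average"
) -> tuple[np.ndarray, str]:
    """Agglomerative clustering of samples at distance ``1 - r``.

    Returns the SciPy linkage matrix and a Newick rendering.  Deterministic:
    SciPy resolves equal-distance merges by lowest cluster index.
    """
    if not np.allclose(corr.values, corr.values.T, atol=1e-12, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return link, linkage_to_newick(link, list(corr.columns))


def cut_clusters(link: np.ndarray, labels: list[str], k: int) -> dict[str, int]:
    """Flat k-group assignment from a linkage matrix, keyed by sample label."""
    assign = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return dict(zip(labels, (int(c) for c in assign)))


@dataclass
class EvaluationReport:
    """Before/after comparison bundle produced by :func:`evaluate_adjustment`."""

    cv_pairs: pd.DataFrame  # sample_id, probeset_id, cv_before, cv_after
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    degenerate: bool
    median_cv_before: float
    median_cv_after: float
    corr_before: pd.DataFrame | None = None
    corr_after: pd.DataFrame | None = None
    newick_before: str | None = None
    newick_after: str | None = None


def evaluate_adjustment(
    before: pd.DataFrame,
    after: pd.DataFrame,
    value_before: str = "pm",
    value_after: str = "pm_adj",
    present_only: bool = True,
) -> EvaluationReport:
    """Pair per-probe-set CVs before/after correction and test the decrease.

    ``before`` and ``after`` are long probe tables (``after`` may be the
    same frame carrying both columns).  Only present-flagged probe sets are
    scored when a ``present`` column exists.
    """
    if present_only and "present" in before.columns:
        before = before[before["present"] == 1]
    if present_only and "present" in after.columns:
        after = after[after["present"] == 1]
    cv_b = cv_table(before, value_before).rename("cv_before")
    cv_a = cv_table(after, value_after).rename("cv_after")
    pairs = pd.concat([cv_b, cv_a], axis=1, join="inner").dropna()
    if pairs.empty:
        raise ValueError("no probe sets with defined CV in both tables")
    stat, pval, degen = cv_wilcoxon(pairs["cv_before"], pairs["cv_after"])
    return EvaluationReport(
        cv_pairs=pairs.reset_index(),
        wilcoxon_statistic=stat,
        wilcoxon_pvalue=pval,
        degenerate=degen,
        median_cv_before=float(pairs["cv_before"].median()),
        median_cv_after=float(pairs["cv_after"].median()),
    )
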