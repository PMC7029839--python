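"""Group-level inference: rank tests, Bonferroni correction, pain regression.

Two independent groups (healthy controls CN vs failed-back-surgery-syndrome
FBSS patients) are compared on each network-pair connectivity strength with
the two-sided Wilcoxon rank-sum (Mann-Whitney) test — exact enumeration for
small tie-free samples, tie-corrected normal approximation otherwise — and
the family of comparisons is Bonferroni-corrected.  The striatum
connectivity index is regressed on the visual-analog pain score (PL) with
ordinary least squares:  index = beta0 + beta1 * PL + eps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group label, pain score and striatum connectivity index.

    ``vas_pain`` (0-10 visual-analog scale) and ``stm_index`` may be missing
    (None); control subjects have no pain score, and a patient's index may be
    unavailable (e.g. imaging artifacts).
    """

    subject_id: str
    group: str
    vas_pain: float | None = None
    stm_index: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("CN", "FBSS"):
            raise ValueError(f"group must be CN or FBSS, got {self.group!r}")
        if self.vas_pain is not None and not 0 <= self.vas_pain <= 10:
            raise ValueError(f"vas_pain must lie in [0, 10], got {self.vas_pain}")


@dataclass(frozen=True)
class GroupTestResult:
    """One group comparison with its Bonferroni-adjusted p-value."""

    label: str
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int
    significant: bool


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of the index-on-pain model with slope inference."""

    beta0: float
    beta1: float
    r_squared: float
    p_value: float
    n: int
    excluded: tuple[str, ...] = ()


def _exact_ranksum_p(ranks_a: np.ndarray, n_total: int) -> float:
    """Two-sided exact p for the rank-sum W of group A (no ties, ranks 1..n).

    Counts, by dynamic programming over the rank values, the number of
    nA-subsets of {1..n} with each possible rank sum, and doubles the smaller
    tail at the observed W.
    """
    n_a = len(ranks_a)
    w_obs = int(round(ranks_a.sum()))
    max_sum = n_total * (n_total + 1) // 2
    # counts[k][s] = number of k-subsets of the ranks seen so far summing to s
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(n_a, r), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    dist = counts[n_a]
    total = dist.sum()
    p_low = dist[: w_obs + 1].sum() / total
    p_high = dist[w_obs:].sum() / total
    return min(1.0, 2.0 * min(p_low, p_high))


def rank_group_test(
    vals_a, vals_b, exact_limit: int = 12
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for independent groups.

    Returns ``(statistic, p)`` where the statistic is the Mann-Whitney U of
    the first sample.  When the pooled size is at most ``exact_limit`` and
    there are no ties, the p-value is computed by exact enumeration of the
    rank-sum null distribution; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_a = ranks[: a.size].sum()
    u_a = w_a - a.size * (a.size + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= exact_limit and not has_ties:
        p = _exact_ranksum_p(ranks[: a.size], pooled.size)
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return float(u_a), float(p)


def bonferroni_adjust(
    pvals: dict[str, tuple[float, float]] | dict[str, float],
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Bonferroni-correct a batch of comparisons.

    ``pvals`` maps comparison label -> raw p (or ``(statistic, raw p)``).
    The correction factor m is the batch size; adjusted p = min(1, m*p) and a
    comparison is significant when its adjusted p < alpha.
    """
    m = len(pvals)
    out = []
    for label, value in pvals.items():
        stat, p = value if isinstance(value, tuple) else (math.nan, value)
        if not 0 < p <= 1:
            raise ValueError(f"p-value for {label!r} must lie in (0, 1], got {p}")
        adj = min(1.0, m * p)
        out.append(GroupTestResult(label, stat, p, adj, m, adj < alpha))
    return out


def regress_index_on_pain(records: list[SubjectRecord]) -> RegressionResult:
    """OLS of the striatum index on pain score over patient records.

    Records missing either variable are excluded (and reported in the
    result).  The slope p-value is the two-sided t-test with n-2 degrees of
    freedom.
    """
    import statsmodels.api as sm

    usable, excluded = [], []
    for r in records:
        if r.vas_pain is None or r.stm_index is None:
            excluded.append(r.subject_id)
        else:
            usable.append(r)
    if len(usable) < 3:
        raise ValueError("need at least 3 records with both index and pain")
    pain = np.array([r.vas_pain for r in usable])
    idx = np.array([r.stm_index for r in usable])
    if np.ptp(pain) == 0:
        raise ValueError("pain scores have zero variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(idx, sm.add_constant(pain)).fit()
        r2 = float(fit.rsquared)
        p = float(fit.pvalues[1])
    # Degenerate case: constant response -> zero slope, no explained variance.
    if not np.isfinite(r2):
        r2 = 0.0
    if not np.isfinite(p):
        p = 1.0
    return RegressionResult(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        r_squared=r2,
        p_value=p,
        n=len(usable),
        excluded=tuple(excluded),
    )


def group_summary(records: list[SubjectRecord]) -> dict[str, dict[str, float]]:
    """Mean, sample SD (n-1 denominator) and n of the index, per group."""
    out: dict[str, dict[str, float]] = {}
    for group in ("CN", "FBSS"):
        vals = np.array(
            [r.stm_index for r in records if r.group == group and r.stm_index is not None]
        )
        if vals.size == 0:
            continue
        if vals.size < 2:
            raise ValueError(f"group {group} needs >= 2 indices for an SD")
        out[group] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n": int(vals.size),
        }
    return out


def records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    """Build SubjectRecords from a metadata table.

    Expects columns subject_id, group, vas_pain, stm_index; NaN means
    missing.
    """
    recs = []
    for row in df.itertuples(index=False):
        pain = getattr(row, "vas_pain", None)
        idx = getattr(row, "stm_index", None)
        recs.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                vas_pain=None if pain is None or pd.isna(pain) else float(pain),
                stm_index=None if idx is None or pd.isna(idx) else float(idx),
            )
        )
    return recs
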