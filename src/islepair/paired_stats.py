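"""Paired island-mainland inference on relative values.

The unit of analysis is the relative island value
``X'(island) = X(island) / (X(island) + X(mainland))``, which is 0.5 when the
island and mainland statistics are equal.  Departures from symmetry about 0.5
are tested with a Wilcoxon signed-rank test (exact null by enumeration for
small samples), and uncertainty in the mean relative value is quantified with
a percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSummary",
    "relative_value",
    "wilcoxon_signed_rank",
    "bootstrap_mean_ci",
    "correlate",
    "EXACT_THRESHOLD",
]

#: Largest number of nonzero differences for which the exact signed-rank null
#: distribution is enumerated; beyond this the normal approximation (with tie
#: and continuity corrections) is used.
EXACT_THRESHOLD = 20

TAILS = ("less", "greater", "two_sided")


@dataclass(frozen=True)
class PairedSummary:
    """One statistic's dataset-level paired summary (one table row)."""

    statistic_name: str
    n_comparisons: int
    mean_island: float
    mean_mainland: float
    mean_relative_island: float
    ci_lower: float
    ci_upper: float
    wilcoxon_p: float
    tail: str


def relative_value(x_island: float, x_mainland: float) -> float | None:
    """x_island / (x_island + x_mainland); ``None`` when both are zero.

    A ``None`` marks the comparison as uninformative and excluded downstream.
    """
    if x_island < 0 or x_mainland < 0:
        raise ValueError(
            f"relative_value requires nonnegative inputs, got ({x_island}, {x_mainland})"
        )
    total = x_island + x_mainland
    if total == 0:
        return None
    return x_island / total


def _exact_signed_rank_cdf(ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ = sum of positive-signed ranks over all 2^m signs.

    Mid-ranks are half-integers at worst, so doubling makes them integers; the
    distribution is built by dynamic-programming convolution.  Returns the
    probability mass function over 2*W+ = 0 .. 2*sum(ranks).
    """
    doubled = np.round(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(
    values,
    null_center: float = 0.5,
    tail: str = "less",
    exact_threshold: int = EXACT_THRESHOLD,
) -> float:
    """Signed-rank P value for departure of ``values`` from ``null_center``.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    For ``m <= exact_threshold`` nonzero differences the exact null
    distribution is enumerated; otherwise a normal approximation with tie
    correction and a 0.5 continuity correction is used.

    ``tail='less'`` tests the alternative that values fall below the center
    (small W+); ``'greater'`` the reverse; ``'two_sided'`` doubles the smaller
    tail, capped at 1.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    diffs = np.asarray(values, dtype=float) - null_center
    diffs = diffs[diffs != 0]
    m = diffs.size
    if m == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())

    if m <= exact_threshold:
        pmf = _exact_signed_rank_cdf(ranks)
        idx = int(round(2 * w_plus))
        p_greater = float(pmf[idx:].sum())
        p_less = float(pmf[: idx + 1].sum())
    else:
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        sd = np.sqrt(var)
        p_greater = float(sps.norm.sf((w_plus - mu - 0.5) / sd))
        p_less = float(sps.norm.cdf((w_plus - mu + 0.5) / sd))

    if tail == "greater":
        return min(1.0, p_greater)
    if tail == "less":
        return min(1.0, p_less)
    return min(1.0, 2.0 * min(p_less, p_greater))


def bootstrap_mean_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean: (sample mean, lower, upper).

    The point estimate is the plain sample mean; the interval is the
    percentile interval of ``n_boot`` resampled means, deterministic given
    ``seed``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("bootstrap requires at least 2 values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot_means = arr[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lower, upper = np.quantile(boot_means, [alpha, 1 - alpha])
    return float(arr.mean()), float(lower), float(upper)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its t-distribution P value.

    Pairs with a missing (NaN) member are dropped (pairwise-complete); ranks
    use mid-ranks for ties.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation requires at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize(
    statistic_name: str,
    island_values,
    mainland_values,
    tail: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PairedSummary:
    """Build a full :class:`PairedSummary` row from paired raw statistics.

    Pairs whose relative value is undefined (both zero, or a missing member)
    are excluded; ``n_comparisons`` reflects the exclusions.
    """
    island = []
    mainland = []
    rel = []
    for xi, xm in zip(island_values, mainland_values, strict=True):
        if xi is None or xm is None or np.isnan(xi) or np.isnan(xm):
            continue
        r = relative_value(xi, xm)
        if r is None:
            continue
        island.append(xi)
        mainland.append(xm)
        rel.append(r)
    n = len(rel)
    if n == 0:
        return PairedSummary(statistic_name, 0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, tail)
    try:
        p = wilcoxon_signed_rank(rel, tail=tail)
    except ValueError:  # all relative values exactly 0.5
        p = 1.0
    if n >= 2:
        mean_rel, lo, hi = bootstrap_mean_ci(rel, n_boot=n_boot, seed=seed)
    else:
        mean_rel, lo, hi = rel[0], np.nan, np.nan
    return PairedSummary(
        statistic_name=statistic_name,
        n_comparisons=n,
        mean_island=float(np.mean(island)),
        mean_mainland=float(np.mean(mainland)),
        mean_relative_island=mean_rel,
        ci_lower=lo,
        ci_upper=hi,
        wilcoxon_p=p,
        tail=tail,
    )
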