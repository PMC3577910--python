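"""Variance-component estimation and resampling inference.

The inferential target throughout is the among-line variance of chromosome
copy number: how much replicate cell lines have diverged from one another,
over and above measurement noise within a line.  Copy numbers spanning two
orders of magnitude are log transformed first.  The balanced one-way
random-effects model is estimated by method of moments (for balanced
designs this agrees with REML whenever the between-line mean square exceeds
the within-line one), intervals come from a nonparametric bootstrap over
lines, and experiment-versus-simulation contrasts use permutation Welch
t-tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VarianceComponents",
    "IntervalEstimate",
    "log_transform",
    "among_line_variance",
    "variance_components_from_table",
    "bootstrap_ci",
    "classify_interval",
    "permutation_welch_test",
    "bonferroni",
    "change_in_mean",
]


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects decomposition for k lines x m replicates."""

    sigma_sq_line: float
    sigma_sq_resid: float
    k: int
    m: int


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a percentile bootstrap interval."""

    point: float
    lo: float
    hi: float
    alpha: float = 0.05
    n_boot: int = 1000


def log_transform(data):
    """Natural-log transform of copies-per-cell values.

    Accepts an array-like or a DataFrame carrying a ``CNPC`` column (the
    copies-per-cell measurement); returns the same shape with values
    logged.  Nonpositive values are a data error and the offending record
    is named.
    """
    if isinstance(data, pd.DataFrame):
        bad = data.index[data["CNPC"] <= 0]
        if len(bad):
            raise ValueError(f"nonpositive CNPC at record(s) {list(bad[:5])}")
        out = data.copy()
        out["CNPC"] = np.log(out["CNPC"].to_numpy(dtype=float))
        return out
    arr = np.asarray(data, dtype=float)
    if np.any(arr <= 0):
        bad = np.flatnonzero(arr.ravel() <= 0)
        raise ValueError(f"nonpositive value at flat position(s) {bad[:5].tolist()}")
    return np.log(arr)


def among_line_variance(values: np.ndarray) -> VarianceComponents:
    """Method-of-moments variance components for a balanced k x m layout.

    MSB = m * sum_i (ybar_i - ybar)^2 / (k - 1)
    MSW = sum_ij (y_ij - ybar_i)^2 / (k (m - 1))
    sigma_sq_line = max(0, (MSB - MSW) / m);  sigma_sq_resid = MSW

    Negative moment estimates are truncated at zero, the standard
    convention for variance components.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2-D array: lines x replicates")
    k, m = y.shape
    if k < 2 or m < 2:
        raise ValueError("need at least 2 lines and 2 replicates per line")
    line_means = y.mean(axis=1)
    grand = y.mean()
    msb = m * np.sum((line_means - grand) ** 2) / (k - 1)
    msw = np.sum((y - line_means[:, None]) ** 2) / (k * (m - 1))
    return VarianceComponents(
        sigma_sq_line=max(0.0, (msb - msw) / m),
        sigma_sq_resid=float(msw),
        k=k,
        m=m,
    )


def variance_components_from_table(
    table: pd.DataFrame, line_col: str = "Cell.line", value_col: str = "CNPC"
) -> VarianceComponents:
    """Pivot a long table to the balanced layout and estimate components.

    Raises on unbalanced data: the caller must aggregate to equal replicate
    counts per line first.
    """
    counts = table.groupby(line_col)[value_col].count()
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced design: replicate counts per line are {dict(counts)}")
    wide = np.stack([g[value_col].to_numpy(float) for _, g in table.groupby(line_col)])
    return among_line_variance(wide)


def bootstrap_ci(
    values: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> IntervalEstimate:
    """Percentile bootstrap interval, resampling over axis-0 units.

    The resampling unit is the cell line: pass line-level values (or a
    2-D array whose rows are lines, so within-line replicates travel with
    their line).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 resampling units")
    if rng is None:
        rng = np.random.default_rng()
    n = values.shape[0]
    point = float(statistic(values))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = statistic(values[rng.integers(0, n, size=n)])
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return IntervalEstimate(point, float(lo), float(hi), alpha=alpha, n_boot=n_boot)


def classify_interval(est: IntervalEstimate) -> str:
    """'increase' if the interval sits above 0, 'decrease' below, else 'no change'."""
    if est.lo > 0:
        return "increase"
    if est.hi < 0:
        return "decrease"
    return "no change"


def _welch_t(mean_a, var_a, n_a, mean_b, var_b, n_b):
    denom = np.sqrt(var_a / n_a + var_b / n_b)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        # zero variance in both groups: equal means -> t = 0, else +-inf
        t = np.where(denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t


def permutation_welch_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for the Welch t statistic.

    The null is built by pooling both samples and re-splitting the labels
    ``n_perm`` times at the original group sizes;
    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), so p is never zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    na, nb = a.size, b.size
    t_obs = _welch_t(a.mean(), a.var(ddof=1) if na > 1 else 0.0, na,
                     b.mean(), b.var(ddof=1) if nb > 1 else 0.0, nb)

    pooled = np.concatenate([a, b])
    idx = rng.permuted(np.tile(np.arange(na + nb), (n_perm, 1)), axis=1)
    perm = pooled[idx]
    pa, pb = perm[:, :na], perm[:, na:]
    t_perm = _welch_t(
        pa.mean(axis=1), pa.var(axis=1, ddof=1) if na > 1 else np.zeros(n_perm), na,
        pb.mean(axis=1), pb.var(axis=1, ddof=1) if nb > 1 else np.zeros(n_perm), nb,
    )
    exceed = np.count_nonzero(np.abs(t_perm) >= abs(t_obs))
    return float((1 + exceed) / (n_perm + 1))


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjusted p-values (min(1, p*n)) and significance calls."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return pd.DataFrame({"p": p, "p_adjusted": p_adj, "significant": reject})


def change_in_mean(
    initial: np.ndarray,
    final: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> IntervalEstimate:
    """Bootstrap interval for mean(final) - mean(initial), paired by line.

    Lines are resampled as units so each resample keeps initial/final
    measurements of a line together.  Classify the interval with
    :func:`classify_interval`.
    """
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if initial.shape != final.shape:
        raise ValueError("initial and final must be paired by line (same shape)")
    paired = np.column_stack([initial, final])
    return bootstrap_ci(
        paired, lambda rows: rows[:, 1].mean() - rows[:, 0].mean(), n_boot=n_boot, rng=rng
    )
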