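"""Paired condition comparisons of entropy metrics.

Two treatment conditions measured in the same independent experiments are
compared by the paired two-tailed t statistic on the per-experiment
differences d_i = x_i - y_i,

    t = dbar / (s_d / sqrt(n)),   df = n - 1,

together with a percentile bootstrap confidence interval of the mean
difference (resampling the differences with replacement).  Wells within an
experiment are averaged before pairing — wells on the same plate are not
independent replicates.  No multiple-testing correction is applied by
default (comparisons are few and predefined); a Holm adjustment is available
as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateComparisonError(ValueError):
    """All paired differences identical: s_d = 0, t undefined."""


@dataclass(frozen=True)
class ConditionComparison:
    """Result of one paired comparison of a metric between two conditions."""

    metric: str
    condition_a: str
    condition_b: str
    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def paired_t(
    x: np.ndarray,
    y: np.ndarray,
    metric: str = "",
    condition_a: str = "A",
    condition_b: str = "B",
) -> ConditionComparison:
    """Paired two-tailed t-test on matched vectors x, y (same unit order)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("paired values must be finite (filter undefined metrics upstream)")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateComparisonError(
            f"all {n} paired differences equal {mean_diff}; t statistic undefined"
        )
    t = mean_diff / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return ConditionComparison(
        metric=metric,
        condition_a=condition_a,
        condition_b=condition_b,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd,
        t_stat=float(t),
        df=df,
        p_value=p,
    )


def bootstrap_ci(
    diffs: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean of paired differences.

    Resamples the n differences with replacement ``n_boot`` times and takes
    the (1-level)/2 and (1+level)/2 percentiles of the resampled means.
    Deterministic under a fixed seed.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 differences")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    means = d[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def compare_with_ci(
    x: np.ndarray,
    y: np.ndarray,
    metric: str = "",
    condition_a: str = "A",
    condition_b: str = "B",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> ConditionComparison:
    """Paired t-test plus percentile bootstrap CI on the same pairs."""
    cmp_ = paired_t(x, y, metric=metric, condition_a=condition_a, condition_b=condition_b)
    lo, hi = bootstrap_ci(np.asarray(x, float) - np.asarray(y, float), n_boot, level, seed)
    return ConditionComparison(
        **{**cmp_.to_dict(), "ci_low": lo, "ci_high": hi, "n_boot": n_boot, "seed": seed}
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def summarize(
    metrics: pd.DataFrame,
    group_keys: tuple[str, ...] = ("condition", "metric", "alpha", "tau"),
    value_col: str = "value",
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    """Per-group mean +/- SEM table.

    Well-level values are averaged within each experiment first, then the
    mean and SEM (s/sqrt(n), ddof=1) are taken across experiments.  Groups
    with a single experiment report SEM as missing; empty/all-NaN groups are
    dropped with a warning.
    """
    df = metrics.dropna(subset=[value_col])
    dropped = len(metrics) - len(df)
    if dropped:
        warnings.warn(f"summarize: dropped {dropped} undefined metric values", RuntimeWarning)
    keys = [k for k in group_keys if k in df.columns]
    per_exp = (
        df.groupby(keys + [experiment_col], dropna=False, sort=False)[value_col]
        .mean()
        .reset_index()
    )
    out = (
        per_exp.groupby(keys, dropna=False, sort=False)[value_col]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n_experiments="count")
        .reset_index()
    )
    return out
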