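"""Per-subject behavioural bias statistics.

Central tendency (regression of response on stimulus), sequential dependence
(regression of the current error on the previous stimulus), the analytic
relation between the two under the simple iterative model, partial and lagged
correlations, and one-sample group tests.  All regressions are computed in
the linear stimulus domain on raw trial data; trial 1 is dropped wherever a
predecessor is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .sequences import TrialSequence

__all__ = [
    "BiasSummary",
    "GroupSummary",
    "central_tendency",
    "sequential_dependence",
    "iterative_prediction_curve",
    "partial_correlation",
    "lagged_dependence",
    "group_summary",
    "summarize_bias",
    "slope_with_se",
]


class LagDependence(NamedTuple):
    slope: float
    correlation: float


@dataclass
class BiasSummary:
    """Bias metrics for one subject × condition."""

    c: float
    s: float
    partial_r_prev: float
    partial_r_curr: float
    lag_slopes: dict[int, float] = field(default_factory=dict)


@dataclass
class GroupSummary:
    mean: float
    sd: float
    t: float
    p: float
    cohens_d: float
    n: int


def slope_with_se(x, y) -> tuple[float, float]:
    """OLS slope of y on x and its standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def central_tendency(trials: TrialSequence) -> float:
    """1 − slope of response on stimulus.

    0 for veridical reproduction, 1 when responses ignore the stimulus
    entirely; intermediate values measure regression toward the mean.
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    slope, _ = slope_with_se(trials.stimulus_values, trials.responses)
    return 1.0 - slope


def sequential_dependence(trials: TrialSequence) -> float:
    """Slope of the current error on the previous stimulus (trials 2..n)."""
    if len(trials) < 4:
        raise ValueError("need at least 4 trials")
    err = trials.errors
    stim = trials.stimulus_values
    slope, _ = slope_with_se(stim[:-1], err[1:])
    return slope


def iterative_prediction_curve(c) -> np.ndarray | float:
    """Sequential dependence the simple iterative model predicts: s = (1−c)·c.

    Valid for randomly presented stimuli; a parabola with maximum 0.25 at
    c = 0.5.
    """
    c_arr = np.asarray(c, float)
    if np.any(c_arr < 0) or np.any(c_arr > 1):
        raise ValueError("central tendency must lie in [0, 1]")
    out = (1.0 - c_arr) * c_arr
    return float(out) if np.isscalar(c) else out


def _partial_from_pairwise(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if denom == 0:
        raise ValueError("degenerate correlation structure")
    return (r_xy - r_xz * r_yz) / denom


def partial_correlation(trials: TrialSequence, target: str = "prev") -> float:
    """First-order partial correlation of the error with one stimulus.

    ``target='prev'``: correlation between current error and previous
    stimulus controlling for the current stimulus; ``target='curr'``: error
    vs current stimulus controlling for the previous one.
    """
    if target not in ("prev", "curr"):
        raise ValueError("target must be 'prev' or 'curr'")
    if len(trials) < 5:
        raise ValueError("need at least 5 trials")
    err = trials.errors[1:]
    curr = trials.stimulus_values[1:]
    prev = trials.stimulus_values[:-1]
    for name, col in [("error", err), ("current stimulus", curr),
                      ("previous stimulus", prev)]:
        if np.ptp(col) == 0:
            raise ValueError(f"{name} column has zero variance")
    x, z = (prev, curr) if target == "prev" else (curr, prev)
    r_xy = stats.pearsonr(x, err).statistic
    r_xz = stats.pearsonr(x, z).statistic
    r_yz = stats.pearsonr(err, z).statistic
    return float(_partial_from_pairwise(r_xy, r_xz, r_yz))


def lagged_dependence(trials: TrialSequence, max_lag: int = 3) -> dict[int, LagDependence]:
    """Error vs stimulus j trials back, for lags 1..max_lag.

    Returns both the regression slope and the plain correlation per lag;
    lag 1 equals :func:`sequential_dependence` by construction.
    """
    n = len(trials)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= n / 4:
        raise ValueError(f"max_lag {max_lag} too large for {n} trials")
    err = trials.errors
    stim = trials.stimulus_values
    out: dict[int, LagDependence] = {}
    for lag in range(1, max_lag + 1):
        x = stim[:-lag]
        y = err[lag:]
        slope, _ = slope_with_se(x, y)
        # a constant error column carries no association; call it zero
        corr = 0.0 if np.ptp(y) == 0 else stats.pearsonr(x, y).statistic
        out[lag] = LagDependence(slope=float(slope), correlation=float(corr))
    return out


def group_summary(values, null_value: float = 0.0) -> GroupSummary:
    """One-sample two-sided t-test of per-subject metrics against a null.

    Cohen's d is (mean − null)/SD.
    """
    vals = np.asarray(values, float)
    if vals.size < 2:
        raise ValueError("need at least 2 subjects")
    sd = vals.std(ddof=1)
    scale = max(float(np.abs(vals).max()), abs(null_value), 1e-300)
    if sd <= 1e-12 * scale:
        if np.allclose(vals, null_value):
            return GroupSummary(float(vals.mean()), 0.0, 0.0, 1.0, 0.0, vals.size)
        raise ValueError("zero variance with nonzero effect; t undefined")
    t, p = stats.ttest_1samp(vals, null_value)
    d = (vals.mean() - null_value) / sd
    return GroupSummary(float(vals.mean()), float(sd), float(t), float(p),
                        float(d), int(vals.size))


def summarize_bias(trials: TrialSequence, max_lag: int = 3) -> BiasSummary:
    """All per-subject bias metrics in one container."""
    lags = lagged_dependence(trials, max_lag=max_lag)
    return BiasSummary(
        c=central_tendency(trials),
        s=sequential_dependence(trials),
        partial_r_prev=partial_correlation(trials, "prev"),
        partial_r_curr=partial_correlation(trials, "curr"),
        lag_slopes={lag: ld.slope for lag, ld in lags.items()},
    )
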