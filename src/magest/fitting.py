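"""Model fitting, confidence intervals, model selection and prediction.

Observer parameters are estimated by nonlinear least squares in the linear
stimulus domain: the filter is run on the full stimulus time course in the
presented order, and the squared distance between observed and simulated
responses is minimized over the model kind's free parameters.  Model classes
are compared with a leave-one-out cross-validation adapted to time series
(a window of k trials around each validation point is excluded from the
loss), and fitted parameters can be applied unchanged to a new condition as
a zero-free-parameter prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import BiasSummary, summarize_bias
from .observer import FREE_PARAMS, ObserverParams, simulate_response_timecourse
from .sequences import TrialSequence

__all__ = [
    "FitResult",
    "ModelSelection",
    "fit_model",
    "parameter_confidence_intervals",
    "loo_timeseries",
    "predict_condition",
    "r_squared",
    "binned_average",
]

#: default box constraints on the free parameters
DEFAULT_BOUNDS = {
    "v_over_r": (0.0, np.inf),
    "q_over_r": (0.0, np.inf),
    "delta_x": (-np.inf, np.inf),
}

#: number of free parameters per model kind (used for tie-breaking)
N_FREE = {kind: len(names) for kind, names in FREE_PARAMS.items()}


@dataclass
class FitResult:
    """Outcome of one least-squares fit."""

    params: ObserverParams
    ci: dict[str, tuple[float, float]]
    sse: float
    simulated: np.ndarray
    n_trials: int
    success: bool = True
    message: str = ""

    def ci_covers(self, name: str, value: float) -> bool:
        lo, hi = self.ci[name]
        return lo <= value <= hi


@dataclass
class ModelSelection:
    """Windowed-LOO comparison across model kinds."""

    window_k: int
    per_model_cv_error: dict[str, float]
    chosen: str
    per_model_fit: dict[str, FitResult] = field(default_factory=dict)


def _residuals_factory(trials: TrialSequence, template: ObserverParams,
                       weight_mask: np.ndarray | None = None):
    stim = trials.stimulus_values
    resp = trials.responses

    def residuals(theta: np.ndarray) -> np.ndarray:
        sim = simulate_response_timecourse(stim, template.with_free_values(theta))
        res = sim - resp
        if weight_mask is not None:
            res = res[weight_mask]
        return res

    return residuals


def _starting_points(model_kind: str, d0: float) -> list[ObserverParams]:
    """Multi-start grid: 8 log-spaced starts over the variance ratios, Δx = 0."""
    if model_kind == "two_state":
        ratios = np.geomspace(0.03, 3.0, 3)
        starts = [ObserverParams("two_state", v_over_r=v, q_over_r=q, d0=d0)
                  for v in ratios for q in ratios]
        del starts[4]  # drop the grid center, keeping 8 starts
        return starts
    grid = np.geomspace(0.01, 10.0, 8)
    if model_kind == "static":
        return [ObserverParams("static", v_over_r=v, d0=d0) for v in grid]
    return [ObserverParams("iterative", q_over_r=q, d0=d0) for q in grid]


def _bounds_arrays(names, bounds: dict | None):
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    lo = np.array([merged[n][0] for n in names])
    hi = np.array([merged[n][1] for n in names])
    return lo, hi


def fit_model(trials: TrialSequence, model_kind: str,
              init: ObserverParams | None = None,
              bounds: dict | None = None, d0: float | None = None,
              compute_ci: bool = True) -> FitResult:
    """Fit one observer model to a trial sequence by linear-domain least squares.

    Free parameters: static (v/r, Δx), iterative (q/r, Δx), two-state
    (v/r, q/r, Δx); variance ratios are constrained nonnegative.  When no
    explicit ``init`` is given, 8 starts from a log-spaced grid over the
    ratios guard against local minima and the best solution is kept.
    """
    if len(trials) < 10:
        raise ValueError("need at least 10 trials for fitting")
    if d0 is None:
        d0 = init.d0 if init is not None else 1.0
    starts = [init] if init is not None else _starting_points(model_kind, d0)
    template = starts[0]
    if template.model_kind != model_kind:
        raise ValueError("init.model_kind does not match model_kind")
    names = FREE_PARAMS[model_kind]
    lo, hi = _bounds_arrays(names, bounds)
    residuals = _residuals_factory(trials, template)

    best = None
    failures = []
    for start in starts:
        theta0 = np.clip(start.free_values(), lo, hi)
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                         method="trf")
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            failures.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(
            f"least-squares failed from every start for {model_kind}: {failures}"
        )
    params = template.with_free_values(best.x)
    sim = simulate_response_timecourse(trials.stimulus_values, params)
    sse = float(np.sum((sim - trials.responses) ** 2))
    fit = FitResult(params=params, ci={}, sse=sse, simulated=sim,
                    n_trials=len(trials), success=bool(best.success),
                    message=str(best.message))
    if compute_ci:
        fit.ci = parameter_confidence_intervals(fit, trials)
    return fit


def _jacobian(residuals, theta: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Finite-difference Jacobian of the residual vector at theta.

    Central differences, switching to forward differences against the lower
    bound for parameters sitting at it.
    """
    f0 = residuals(theta)
    J = np.empty((f0.size, theta.size))
    for j in range(theta.size):
        h = 1e-6 * max(abs(theta[j]), 1e-3)
        t_plus = theta.copy()
        t_minus = theta.copy()
        t_plus[j] += h
        if theta[j] - h >= lo[j]:
            t_minus[j] -= h
            J[:, j] = (residuals(t_plus) - residuals(t_minus)) / (2 * h)
        else:
            J[:, j] = (residuals(t_plus) - f0) / h
    return J


def parameter_confidence_intervals(fit: FitResult, trials: TrialSequence,
                                   level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Linearized confidence intervals at the least-squares optimum.

    Computed from the residual variance and the Jacobian of the residuals:
    cov(θ) = s²·(JᵀJ)⁻¹ with s² = SSE/(n − p), intervals θ ± t·SE.  If JᵀJ is
    singular, the unidentified parameters get unbounded intervals.
    """
    names = fit.params.free_names
    theta = fit.params.free_values()
    lo, _ = _bounds_arrays(names, None)
    residuals = _residuals_factory(trials, fit.params)
    J = _jacobian(residuals, theta, lo)
    n, p = len(trials), len(names)
    dof = max(n - p, 1)
    s2 = fit.sse / dof
    JtJ = J.T @ J
    tcrit = stats.t.ppf(0.5 + level / 2, dof)
    ci: dict[str, tuple[float, float]] = {}
    rank = np.linalg.matrix_rank(JtJ)
    if rank < p:
        warnings.warn("singular Jacobian: some parameters are unidentified")
        cov = np.linalg.pinv(JtJ) * s2
        null_mask = _null_space_mask(JtJ)
    else:
        cov = np.linalg.inv(JtJ) * s2
        null_mask = np.zeros(p, bool)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    for j, name in enumerate(names):
        if null_mask[j]:
            ci[name] = (-np.inf, np.inf)
        else:
            ci[name] = (float(theta[j] - tcrit * se[j]), float(theta[j] + tcrit * se[j]))
    return ci


def _null_space_mask(JtJ: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Parameters with appreciable weight in near-null singular directions."""
    u, s, _ = np.linalg.svd(JtJ)
    small = s < rtol * s.max()
    if not small.any():
        return np.zeros(JtJ.shape[0], bool)
    return (np.abs(u[:, small]) > 1e-6).any(axis=1)


def loo_timeseries(trials: TrialSequence, model_kinds=("static", "iterative", "two_state"),
                   window_k: int = 11, d0: float = 1.0) -> ModelSelection:
    """Windowed leave-one-out cross-validation across model kinds.

    For each validation center t (every trial except the first), the k trials
    centered on t are excluded from the fitting loss — the filter still
    consumes the full stimulus sequence, since stimuli are known to the
    observer — and the squared prediction error at t alone is recorded.  The
    model with the smallest mean validation error wins; near-ties go to the
    model with fewer free parameters.  ``window_k=1`` is plain LOO.
    """
    if window_k < 1 or window_k % 2 == 0:
        raise ValueError("window_k must be odd and >= 1")
    n = len(trials)
    if n <= 2 * window_k:
        raise ValueError(f"need more than {2 * window_k} trials for window_k={window_k}")
    half = window_k // 2
    stim = trials.stimulus_values
    resp = trials.responses

    per_model_cv: dict[str, float] = {}
    per_model_fit: dict[str, FitResult] = {}
    names_lo_hi = {}
    for kind in model_kinds:
        full_fit = fit_model(trials, kind, d0=d0, compute_ci=False)
        per_model_fit[kind] = full_fit
        names = FREE_PARAMS[kind]
        lo, hi = _bounds_arrays(names, None)
        names_lo_hi[kind] = (lo, hi)
        theta_full = full_fit.params.free_values()
        errors = np.empty(n - 1)
        for idx, t in enumerate(range(1, n)):
            mask = np.ones(n, bool)
            mask[max(0, t - half): t + half + 1] = False
            residuals = _residuals_factory(trials, full_fit.params, weight_mask=mask)
            res = optimize.least_squares(residuals, np.clip(theta_full, lo, hi),
                                         bounds=(lo, hi), method="trf")
            refit = full_fit.params.with_free_values(res.x)
            sim = simulate_response_timecourse(stim, refit)
            errors[idx] = (sim[t] - resp[t]) ** 2
        per_model_cv[kind] = float(errors.mean())

    chosen = _choose_model(per_model_cv, list(model_kinds))
    return ModelSelection(window_k=window_k, per_model_cv_error=per_model_cv,
                          chosen=chosen, per_model_fit=per_model_fit)


def _choose_model(cv: dict[str, float], order: list[str], rel_tol: float = 1e-12) -> str:
    best_err = min(cv.values())
    scale = max(abs(best_err), 1e-300)
    tied = [k for k in order if (cv[k] - best_err) / scale < rel_tol]
    tied.sort(key=lambda k: (N_FREE[k], order.index(k)))
    return tied[0]


def predict_condition(params: ObserverParams, new_trials: TrialSequence,
                      max_lag: int = 3) -> tuple[np.ndarray, BiasSummary]:
    """Zero-free-parameter prediction of a new condition.

    Runs the fitted observer on the new stimulus order and summarizes the
    biases of the predicted time course.
    """
    predicted = simulate_response_timecourse(new_trials.stimulus_values, params)
    pred_trials = TrialSequence(new_trials.subject_id, new_trials.condition,
                                new_trials.stimuli, predicted)
    return predicted, summarize_bias(pred_trials, max_lag=max_lag)


def r_squared(observed, modeled) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    1 for a perfect model, 0 for the baseline predicting the mean of the
    data, negative for models worse than that baseline.
    """
    obs = np.asarray(observed, float)
    mod = np.asarray(modeled, float)
    if obs.size != mod.size or obs.size < 2:
        raise ValueError("need equal-length arrays of at least 2 points")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = np.sum((obs - mod) ** 2)
    return float(1.0 - ss_res / ss_tot)


def binned_average(cohort: list[TrialSequence], bin_edges,
                   lag: int = 0) -> pd.DataFrame:
    """Cross-subject binned averages of the reproduction error.

    Errors are first averaged per subject within stimulus bins (binning on
    the stimulus ``lag`` trials before the error's trial), then averaged
    across subjects; SEM is across subjects.  Bins no subject populates are
    kept with ``n_subjects = 0``; single-subject bins have undefined SEM.
    """
    edges = np.asarray(bin_edges, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least 2 edges")
    n_bins = edges.size - 1
    per_subject = np.full((len(cohort), n_bins), np.nan)
    for i, trials in enumerate(cohort):
        err = trials.errors[lag:]
        stim = trials.stimulus_values[: len(trials) - lag if lag else None]
        idx = np.digitize(stim, edges) - 1
        ok = (idx >= 0) & (idx < n_bins)
        for b in range(n_bins):
            sel = ok & (idx == b)
            if sel.any():
                per_subject[i, b] = err[sel].mean()
    n_subj = np.sum(~np.isnan(per_subject), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_subject, axis=0)
        sd = np.nanstd(per_subject, axis=0, ddof=1)
    sem = np.where(n_subj > 1, sd / np.sqrt(np.maximum(n_subj, 1)), np.nan)
    mean = np.where(n_subj > 0, mean, np.nan)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "mean_error": mean,
        "sem": sem,
        "n_subjects": n_subj,
    })
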