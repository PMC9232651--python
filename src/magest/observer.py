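"""Bayesian observer models for magnitude estimation.

Three generative beliefs about how successive stimulus magnitudes arise, and
the estimator each belief implies:

* **static** — stimuli are i.i.d. draws from a fixed distribution; the optimal
  estimate is a fixed weighted average of the current measurement and the
  distribution mean.
* **iterative** — each stimulus equals the previous one plus a random change
  (a random walk); the optimal estimator is exponential smoothing with the
  steady-state Kalman gain.
* **two_state** — stimuli are drawn around a mean that itself drifts as a
  random walk; the optimal estimator is a two-state Kalman filter that tracks
  both the current stimulus and the drifting mean.

All three are special cases of one discrete Kalman filter with state
``X = [x, m]`` (current stimulus and distribution mean), transition
``F = [[0, 1], [0, 1]]``, observation ``H = [1, 0]``, process covariance
``Q = diag(v, q)`` and measurement-noise variance ``r``.  Only the ratios
``v/r`` and ``q/r`` are identifiable, so ``r`` is fixed to 1 throughout.
The static model is the constraint ``q = 0``; the simple iterative model is
``v = 0``.

Estimation runs in logarithmic coordinates ``z = ln(1 + d/d0)`` to honour the
Weber–Fechner law (variability grows with magnitude), and estimates are mapped
back to linear units with a free log-domain shift ``Δx`` that absorbs global
over- or under-reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "MODEL_KINDS",
    "ObserverParams",
    "FilterState",
    "FilterTrace",
    "log_transform",
    "back_transform",
    "static_estimate",
    "iterative_estimate",
    "kalman_filter_two_state",
    "steady_state_gains",
    "simulate_response_timecourse",
]

MODEL_KINDS = ("static", "iterative", "two_state")

#: free parameters per model kind, in optimizer order
FREE_PARAMS = {
    "static": ("v_over_r", "delta_x"),
    "iterative": ("q_over_r", "delta_x"),
    "two_state": ("v_over_r", "q_over_r", "delta_x"),
}

_GAIN_TOL = 1e-12  # time-varying gains are frozen once they change less than this
_SS_TOL = 1e-10
_SS_MAX_ITER = 10_000


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one observer.

    ``v_over_r`` is the variance of the stimulus distribution relative to the
    measurement noise; ``q_over_r`` the variance of the trial-to-trial change
    of the distribution mean relative to the measurement noise; ``delta_x``
    the log-domain response shift; ``d0`` the fixed linear constant of the
    logarithmic transform (not a free parameter).
    """

    model_kind: str
    v_over_r: float = 0.0
    q_over_r: float = 0.0
    delta_x: float = 0.0
    d0: float = 1.0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.v_over_r < 0 or self.q_over_r < 0:
            raise ValueError("variance ratios must be nonnegative")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.model_kind == "static" and self.q_over_r != 0:
            raise ValueError("static model requires q_over_r = 0")
        if self.model_kind == "iterative" and self.v_over_r != 0:
            raise ValueError("iterative model requires v_over_r = 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.model_kind]

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.free_names])

    def with_free_values(self, theta) -> "ObserverParams":
        return replace(self, **dict(zip(self.free_names, np.asarray(theta, float))))


@dataclass
class FilterState:
    """Filter state after one update: estimates, error covariance and gains."""

    x_hat: float
    m_hat: float
    P: np.ndarray
    k1: float
    k2: float

    def __post_init__(self) -> None:
        P = np.asarray(self.P, float)
        if P.shape != (2, 2):
            raise ValueError("P must be 2x2")
        self.P = P


@dataclass
class FilterTrace:
    """Per-trial record of the Kalman recursion (arrays of length n)."""

    x_hat: np.ndarray
    m_hat: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    P: np.ndarray  # shape (n, 2, 2), posterior covariance

    def state(self, i: int) -> FilterState:
        return FilterState(self.x_hat[i], self.m_hat[i], self.P[i], self.k1[i], self.k2[i])


def log_transform(d, d0: float):
    """Map linear magnitude ``d`` to log coordinates ``z = ln(1 + d/d0)``."""
    d = np.asarray(d, float)
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if np.any(d < 0):
        raise ValueError("magnitudes must be nonnegative")
    return np.log1p(d / d0)


def back_transform(x_hat, d0: float, delta_x: float = 0.0, *, paper_literal_inverse: bool = False):
    """Map a log-domain estimate back to linear units, applying the shift Δx.

    The default is the exact inverse of :func:`log_transform`,
    ``d = d0·(exp(x + Δx) − 1)``, so that the Δx = 0 roundtrip is the
    identity.  ``paper_literal_inverse=True`` selects the convention
    ``d = d0·exp(x + Δx)`` instead; the two agree for ``d ≫ d0``.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    x = np.asarray(x_hat, float) + delta_x
    if paper_literal_inverse:
        return d0 * np.exp(x)
    return d0 * np.expm1(x)


def static_estimate(x_seq, w: float, prior_mean: float):
    """Static-observer estimate ``y_i = w·x_i + (1 − w)·x̄``.

    Each response depends only on the current measurement; the central
    tendency of the output is ``1 − w``.
    """
    if not 0 <= w <= 1:
        raise ValueError("w must lie in [0, 1]")
    x = np.asarray(x_seq, float)
    return w * x + (1 - w) * prior_mean


def iterative_estimate(z_seq, k: float, y0: float):
    """Simple-iterative estimate ``y_i = k·z_i + (1 − k)·y_{i−1}``.

    Exponential smoothing from ``y0`` with the steady-state Kalman gain ``k``
    of the random-walk (local-level) observer.
    """
    if not 0 <= k <= 1:
        raise ValueError("k must lie in [0, 1]")
    z = np.asarray(z_seq, float)
    if k == 0:
        return np.full_like(z, y0)
    # IIR filter y[i] = k z[i] + (1-k) y[i-1], seeded so y[-1] = y0
    y, _ = lfilter([k], [1.0, -(1.0 - k)], z, zi=[(1.0 - k) * y0])
    return y


def _riccati_step(p: float, v: float, q: float) -> tuple[float, float, float]:
    """One covariance/gain step of the two-state filter, reduced to a scalar.

    The prediction covariance depends on the posterior only through its (m, m)
    element ``p``: P_pred = [[p+v, p], [p, p+q]].  Returns (k1, k2, next p).
    """
    s = p + v + 1.0  # innovation variance, r = 1
    k1 = (p + v) / s
    k2 = p / s
    p_next = p + q - p * p / s
    return k1, k2, p_next


def _initial_p(v: float, q: float) -> float:
    # diffuse start: P0 = diag(10·(v + q + 1))
    return 10.0 * (v + q + 1.0)


def steady_state_gains(params: ObserverParams, tol: float = _SS_TOL,
                       max_iter: int = _SS_MAX_ITER) -> tuple[float, float]:
    """Fixed-point gains (k1, k2) of the covariance recursion.

    Satisfy ``0 ≤ k2 ≤ k1 ≤ 1``.  For ``v = 0`` the two gains coincide and the
    filter reduces to exponential smoothing; for ``q = 0`` the mean gain k2
    vanishes and k1 → v/(v+1), the static weight.
    """
    v, q = params.v_over_r, params.q_over_r
    # the fixed point of p -> p + q - p^2/(p+v+1) solves p^2 = q (p + v + 1);
    # take its nonnegative root and polish by iterating, which also guards
    # against the slow harmonic tail of the recursion when q = 0.
    p = 0.5 * (q + np.sqrt(q * q + 4.0 * q * (v + 1.0)))
    k1 = k2 = np.inf
    for _ in range(max_iter):
        k1_new, k2_new, p = _riccati_step(p, v, q)
        if abs(k1_new - k1) < tol and abs(k2_new - k2) < tol:
            return k1_new, k2_new
        k1, k2 = k1_new, k2_new
    raise RuntimeError(
        f"gain recursion did not converge within {max_iter} iterations "
        f"(v/r={v}, q/r={q})"
    )


def _gain_sequences(v: float, q: float, n: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Time-varying gains for n trials; returns (k1, k2, index where frozen).

    The gains do not depend on the data, only on (v, q); they converge within
    a few trials, after which they are held constant.
    """
    k1 = np.empty(n)
    k2 = np.empty(n)
    p = _initial_p(v, q)
    frozen = n
    for i in range(n):
        k1[i], k2[i], p = _riccati_step(p, v, q)
        if i > 0 and abs(k1[i] - k1[i - 1]) < _GAIN_TOL and abs(k2[i] - k2[i - 1]) < _GAIN_TOL:
            frozen = i
            k1[i:] = k1[i]
            k2[i:] = k2[i]
            break
    return k1, k2, frozen


def _filter_estimates(z: np.ndarray, v: float, q: float) -> np.ndarray:
    """Log-domain stimulus estimates x̂ of the unified filter (fast path).

    Runs the exact recursion with time-varying gains until the gains have
    converged, then switches to the constant-gain form, which vectorizes:
    the mean estimate is an exponential smoother and x̂ follows from it.
    """
    n = z.size
    k1, k2, frozen = _gain_sequences(v, q, n)
    # m_prev[i] holds m̂_{i-1}, the mean estimate entering trial i;
    # the filter starts from m̂ = z[0] (diffuse covariance).
    m_prev = np.empty(n)
    m = z[0]
    m_prev[0] = m
    stop = min(frozen + 1, n)
    for i in range(stop):
        m = m + k2[i] * (z[i] - m)
        if i + 1 < n:
            m_prev[i + 1] = m
    if stop < n:
        # gains constant from here on: m̂ is an exponential smoother
        kc = k2[-1]
        tail, _ = lfilter([kc], [1.0, -(1.0 - kc)], z[stop:], zi=[(1.0 - kc) * m])
        m_prev[stop + 1:] = tail[:-1]
    x_hat = m_prev + k1 * (z - m_prev)
    return x_hat


def kalman_filter_two_state(z_seq, params: ObserverParams,
                            init: FilterState | None = None) -> tuple[np.ndarray, FilterTrace]:
    """Full two-state Kalman recursion over a log-domain measurement sequence.

    Prediction uses ``F = [[0, 1], [0, 1]]`` (both states predicted by the
    previous mean estimate), so the update reads::

        x̂_i = m̂_{i−1} + k1·(z_i − m̂_{i−1})
        m̂_i = m̂_{i−1} + k2·(z_i − m̂_{i−1})

    with trial-varying gains from the Riccati recursion.  Model-kind
    constraints (``q = 0`` static, ``v = 0`` iterative) enter through
    ``params``.  Returns the per-trial stimulus estimates and the full state
    trace.  By default the filter starts from the first measurement with a
    diffuse covariance; pass ``init`` to override.
    """
    z = np.asarray(z_seq, float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z_seq must be a nonempty 1-d sequence")
    if not np.all(np.isfinite(z)):
        raise ValueError("measurements must be finite")
    v, q = params.v_over_r, params.q_over_r
    n = z.size

    if init is None:
        m = z[0]
        P = np.diag([_initial_p(v, q), _initial_p(v, q)])
    else:
        m = init.m_hat
        P = np.asarray(init.P, float)
        if not np.allclose(P, P.T):
            raise ValueError("init.P must be symmetric")

    F = np.array([[0.0, 1.0], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    Q = np.diag([v, q])
    I2 = np.eye(2)

    x_hat = np.empty(n)
    m_hat = np.empty(n)
    k1s = np.empty(n)
    k2s = np.empty(n)
    Ps = np.empty((n, 2, 2))
    X = np.array([z[0], m])
    for i in range(n):
        Xp = F @ X
        Pp = F @ P @ F.T + Q
        S = float(Pp[0, 0] + 1.0)  # r = 1
        K = Pp @ H.T / S
        innov = z[i] - Xp[0]
        X = Xp + (K * innov).ravel()
        P = (I2 - K @ H) @ Pp
        P = 0.5 * (P + P.T)  # keep symmetric against roundoff
        x_hat[i] = X[0]
        m_hat[i] = X[1]
        k1s[i] = K[0, 0]
        k2s[i] = K[1, 0]
        Ps[i] = P
    return x_hat, FilterTrace(x_hat, m_hat, k1s, k2s, Ps)


def simulate_response_timecourse(stimuli, params: ObserverParams, *,
                                 paper_literal_inverse: bool = False) -> np.ndarray:
    """Deterministic model responses to a stimulus time course (linear units).

    Composition log-transform → unified Kalman filter → back-transform with
    shift Δx.  No measurement or response noise is applied; this is the
    quantity minimized against observed responses during fitting, and the
    zero-free-parameter prediction for a new condition.
    """
    d = np.asarray(stimuli, float)
    z = log_transform(d, params.d0)
    x_hat = _filter_estimates(z, params.v_over_r, params.q_over_r)
    return back_transform(x_hat, params.d0, params.delta_x,
                          paper_literal_inverse=paper_literal_inverse)
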