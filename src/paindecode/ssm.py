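"""Latent linear-Gaussian state-space decoder for pain onset.

Model
-----
A univariate latent Markov process drives the three band-amplitude
observations in each 100 ms bin:

    state equation        z_k = a z_{k-1} + eps_k,      eps_k ~ N(0, sigma^2)
    measurement equation  y_k = c z_k + d + v_k,        v_k   ~ N(0, Sigma)

with 0 < |a| < 1, c and d 3-vectors, and Sigma a 3x3 observation-noise
covariance.  The Kalman filter yields the posterior mean z_{k|k} and
variance Q_{k|k} of the latent state; EM alternates exact latent-state
inference (Kalman filter + Rauch-Tung-Striebel smoother) with closed-form
parameter updates.  The filtered state is standardized against a
pre-stimulus baseline (Z-score) and pain onset is declared when the
confidence-bound criterion  Z - CI > threshold  or  Z + CI < -threshold
holds, with threshold 3.38 by default.

Scale convention: the latent scale is not identifiable (c z is invariant
under z -> alpha z, c -> c / alpha), so EM fixes sigma^2 = 1 and lets c
absorb the scale.  All reported quantities (Z-scores, latencies, observation
moments) are invariant under this choice.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .core import (
    DegenerateBaselineError,
    DegenerateInputError,
    InconsistentInputError,
    InsufficientDataError,
    InternalConsistencyError,
    InvalidCovarianceError,
    InvalidWindowError,
    SingularCovarianceError,
)
from .features import DEFAULT_BIN_S, FeatureSeries

#: Confidence-bound Z threshold for onset detection.
DEFAULT_THRESHOLD = 3.38

#: Default EM settings.
EM_MAX_ITER = 500
EM_TOL = 1e-6

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class SSMParams:
    """Parameters Theta = {a, c, d, sigma2, Sigma} of the decoder model."""

    a: float
    c: np.ndarray
    d: np.ndarray
    sigma2: float
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float).ravel()
        self.d = np.asarray(self.d, dtype=float).ravel()
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        # the generative model assumes 0 < |a| < 1; a = 0 is admitted here so
        # degenerate (memoryless) cases can be filtered and tested directly
        if not abs(self.a) < 1:
            raise ValueError(f"autoregressive coefficient must satisfy |a|<1, got {self.a}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.c.shape != self.d.shape:
            raise InconsistentInputError("c and d must have the same length")
        m = self.c.size
        if self.Sigma.shape != (m, m):
            raise InconsistentInputError("Sigma shape does not match c/d length")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise InvalidCovarianceError("Sigma is not symmetric")
        w = np.linalg.eigvalsh(self.Sigma)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise InvalidCovarianceError("Sigma is not positive semi-definite")

    @property
    def stationary_var(self) -> float:
        """Stationary latent variance sigma^2 / (1 - a^2)."""
        return self.sigma2 / (1.0 - self.a**2)


@dataclass
class LatentStateEstimate:
    """Per-bin Kalman quantities (prediction and filtering passes)."""

    pred_mean: np.ndarray    # z_{k|k-1}
    pred_var: np.ndarray     # Q_{k|k-1}
    pred_obs: np.ndarray     # y_{k|k-1}, shape (K, m)
    gain: np.ndarray         # G_k, shape (K, m)
    filt_mean: np.ndarray    # z_{k|k}
    filt_var: np.ndarray     # Q_{k|k}
    innovation: np.ndarray   # y_k - y_{k|k-1}
    loglik_trace: np.ndarray  # cumulative innovations-form log-likelihood
    z0: float
    Q0: float
    t0: float = 0.0
    bin_size: float = DEFAULT_BIN_S

    @property
    def n_bins(self) -> int:
        return self.filt_mean.size

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + self.bin_size * np.arange(self.n_bins)


@dataclass
class SmoothedEstimate:
    """RTS-smoothed moments, including the initial state and lag-one terms."""

    mean: np.ndarray       # E[z_k | y_{1:K}], k = 1..K
    var: np.ndarray        # Var[z_k | y_{1:K}]
    lag_one: np.ndarray    # Cov[z_k, z_{k-1} | y_{1:K}], k = 1..K (k=1 pairs with z0)
    mean0: float           # E[z_0 | y_{1:K}]
    var0: float            # Var[z_0 | y_{1:K}]


@dataclass
class DetectionConfig:
    """Detection threshold and confidence level for the Z-score criterion."""

    threshold: float = DEFAULT_THRESHOLD
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class ZScoreSeries:
    """Standardized filtered latent state with per-bin confidence half-widths."""

    z_value: np.ndarray
    ci_half_width: np.ndarray
    baseline_mean: float
    baseline_sd: float
    baseline_window: tuple[float, float]
    bin_size: float = DEFAULT_BIN_S
    t0: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.z_value.size

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + self.bin_size * np.arange(self.n_bins)


@dataclass
class DetectionResult:
    """Outcome of the confidence-bound onset test within a response window."""

    detected: bool
    onset_time: float | None
    peak_latency: float | None
    peak_z: float
    direction: str  # "positive" | "negative"


def _as_obs(y) -> tuple[np.ndarray, float, float]:
    """Coerce a FeatureSeries or array to (K, m) with timing metadata."""
    if isinstance(y, FeatureSeries):
        return y.values, y.t0, y.bin_size
    arr = np.atleast_2d(np.asarray(y, dtype=float))
    if arr.shape[0] == 1 and arr.size > arr.shape[1]:
        arr = arr.T
    return arr, 0.0, DEFAULT_BIN_S


def kalman_filter(
    params: SSMParams,
    y,
    z0: float = 0.0,
    Q0: float | None = None,
) -> LatentStateEstimate:
    """Run the Kalman filter recursions on an observation sequence.

    Implements, for k = 1..K:

        z_{k|k-1} = a z_{k-1|k-1}
        Q_{k|k-1} = a^2 Q_{k-1|k-1} + sigma^2
        y_{k|k-1} = c z_{k|k-1} + d
        G_k       = Q_{k|k-1} c^T (Q_{k|k-1} c c^T + Sigma)^{-1}
        z_{k|k}   = z_{k|k-1} + G_k (y_k - y_{k|k-1})
        Q_{k|k}   = Q_{k|k-1} (1 - G_k c)

    and accumulates the innovations-form log-likelihood.  Because the state
    is scalar, the gain is evaluated with the matrix-inversion lemma:
    G_k = [Q_p / (1 + Q_p s)] c^T Sigma^{-1} with s = c^T Sigma^{-1} c, so
    the per-step cost is O(m) after one Cholesky factorization of Sigma.

    ``Q0`` defaults to the stationary latent variance sigma^2 / (1 - a^2).
    """
    obs, t0, bin_size = _as_obs(y)
    K, m = obs.shape
    if K < 1:
        raise InsufficientDataError("need at least one observation bin")
    if Q0 is None:
        Q0 = params.stationary_var
    if Q0 < 0:
        raise ValueError("Q0 must be >= 0")

    a, c, d, s2 = params.a, params.c, params.d, params.sigma2
    try:
        cho = sla.cho_factor(params.Sigma)
    except sla.LinAlgError:
        raise SingularCovarianceError(
            "observation covariance Sigma is singular; innovation covariance "
            "Q c c^T + Sigma cannot be stably inverted"
        ) from None
    Sigma_inv_c = sla.cho_solve(cho, c)
    s = float(c @ Sigma_inv_c)
    logdet_Sigma = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

    resid = obs - d  # (K, m)
    u = resid @ Sigma_inv_c  # c^T Sigma^{-1} (y_k - d)
    quad_full = np.einsum("ki,ki->k", resid, sla.cho_solve(cho, resid.T).T)

    pred_var = np.empty(K)
    filt_var = np.empty(K)
    pred_mean = np.empty(K)
    filt_mean = np.empty(K)
    coef = np.empty(K)

    zf, Qf = float(z0), float(Q0)
    for k in range(K):
        zp = a * zf
        Qp = a * a * Qf + s2
        ck = Qp / (1.0 + Qp * s)
        zf = zp + ck * (u[k] - s * zp)
        Qf = Qp * (1.0 - ck * s)
        pred_mean[k], pred_var[k] = zp, Qp
        filt_mean[k], filt_var[k] = zf, Qf
        coef[k] = ck

    gain = coef[:, None] * Sigma_inv_c[None, :]
    pred_obs = pred_mean[:, None] * c[None, :] + d
    innovation = obs - pred_obs

    # innovations log-likelihood: S_k = Q_p c c^T + Sigma
    # log det S_k = log det Sigma + log(1 + Q_p s)
    # e^T S_k^{-1} e = e^T Sigma^{-1} e - Q_p (c^T Sigma^{-1} e)^2 / (1 + Q_p s)
    we = innovation @ Sigma_inv_c
    quad_e = (
        quad_full
        - 2.0 * pred_mean * u
        + pred_mean**2 * s
        - pred_var * we**2 / (1.0 + pred_var * s)
    )
    # note: e = resid - c z_p, so e^T Sigma^{-1} e expands as above
    logdet = logdet_Sigma + np.log1p(pred_var * s)
    ll_steps = -0.5 * (m * _LOG2PI + logdet + quad_e)
    return LatentStateEstimate(
        pred_mean=pred_mean,
        pred_var=pred_var,
        pred_obs=pred_obs,
        gain=gain,
        filt_mean=filt_mean,
        filt_var=filt_var,
        innovation=innovation,
        loglik_trace=np.cumsum(ll_steps),
        z0=float(z0),
        Q0=float(Q0),
        t0=t0,
        bin_size=bin_size,
    )


def rts_smooth(params: SSMParams, filt: LatentStateEstimate) -> SmoothedEstimate:
    """Backward Rauch-Tung-Striebel pass over a filtered estimate.

    Returns smoothed means/variances for k = 1..K plus the smoothed initial
    state and the lag-one covariances Cov(z_k, z_{k-1} | y_{1:K}) needed by
    the exact EM M-step.
    """
    K = filt.n_bins
    for arr in (filt.pred_mean, filt.pred_var, filt.filt_var):
        if arr.size != K:
            raise InconsistentInputError("filtered estimate arrays disagree in length")
    a = params.a
    mean = np.empty(K)
    var = np.empty(K)
    lag_one = np.empty(K)
    mean[-1] = filt.filt_mean[-1]
    var[-1] = filt.filt_var[-1]
    for k in range(K - 2, -1, -1):
        J = filt.filt_var[k] * a / filt.pred_var[k + 1]
        mean[k] = filt.filt_mean[k] + J * (mean[k + 1] - filt.pred_mean[k + 1])
        var[k] = filt.filt_var[k] + J * J * (var[k + 1] - filt.pred_var[k + 1])
        lag_one[k + 1] = J * var[k + 1]
    J0 = filt.Q0 * a / filt.pred_var[0]
    mean0 = filt.z0 + J0 * (mean[0] - filt.pred_mean[0])
    var0 = filt.Q0 + J0 * J0 * (var[0] - filt.pred_var[0])
    lag_one[0] = J0 * var[0]
    return SmoothedEstimate(mean=mean, var=var, lag_one=lag_one, mean0=mean0, var0=var0)


def default_init(obs: np.ndarray, a0: float = 0.5) -> SSMParams:
    """Moment-based EM starting point.

    ``d`` is the feature mean, ``c`` the first principal direction of the
    centered features scaled so that the latent (with sigma^2 = 1 and the
    initial ``a``) explains the leading variance, and ``Sigma`` the diagonal
    of the residual covariance.
    """
    d = obs.mean(axis=0)
    X = obs - d
    C = np.cov(X.T) if obs.shape[0] > 1 else np.eye(obs.shape[1])
    C = np.atleast_2d(C)
    w, V = np.linalg.eigh(C)
    lam, u = float(w[-1]), V[:, -1]
    stat_var = 1.0 / (1.0 - a0**2)
    c = u * np.sqrt(max(lam, 1e-12) / stat_var)
    resid_diag = np.clip(np.diag(C) - c**2 * stat_var, 1e-8 * max(lam, 1e-12), None)
    return SSMParams(a=a0, c=c, d=d, sigma2=1.0, Sigma=np.diag(resid_diag))


def em_fit(
    y,
    init: SSMParams | str = "default",
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> tuple[SSMParams, np.ndarray]:
    """Fit the state-space model by expectation-maximization.

    E-step: exact latent posteriors from the Kalman filter and RTS smoother
    (sufficient statistics include smoothed lag-one covariances).  M-step:
    closed-form updates of a, c, d and Sigma; sigma^2 is held at 1 to fix
    the latent scale.  The initial state prior (z0 = 0, Q0 stationary under
    the starting ``a``) is held fixed across iterations so each iteration
    maximizes the same likelihood and the log-likelihood trace is
    non-decreasing.

    Returns the fitted parameters and the per-iteration log-likelihood trace.
    """
    obs, t0, bin_size = _as_obs(y)
    K, m = obs.shape
    if K < 10:
        raise InsufficientDataError(f"EM requires at least 10 bins, got {K}")
    if not np.all(np.isfinite(obs)):
        raise DegenerateInputError("features contain non-finite values")
    if np.all(obs.var(axis=0) < 1e-300):
        raise DegenerateInputError("features have zero variance")

    params = default_init(obs) if isinstance(init, str) else init
    z0, Q0 = 0.0, params.stationary_var

    ll_trace: list[float] = []
    for _ in range(max_iter):
        filt = kalman_filter(params, obs, z0=z0, Q0=Q0)
        ll = filt.loglik
        if ll_trace and ll < ll_trace[-1] - 1e-9:
            raise InternalConsistencyError(
                f"EM log-likelihood decreased: {ll_trace[-1]:.9f} -> {ll:.9f}"
            )
        converged = bool(ll_trace) and abs(ll - ll_trace[-1]) < tol
        ll_trace.append(ll)
        if converged:
            break

        sm = rts_smooth(params, filt)
        m_all = np.concatenate(([sm.mean0], sm.mean))
        v_all = np.concatenate(([sm.var0], sm.var))
        Ez2 = v_all + m_all**2
        # transition sufficient statistics over k = 1..K (index 0 = z_0)
        S00 = float(Ez2[:-1].sum())
        S10 = float((sm.lag_one + sm.mean * m_all[:-1]).sum())
        a_new = float(np.clip(S10 / S00, -0.999, 0.999))
        if a_new == 0.0:
            a_new = 1e-6

        # joint (c, d) regression of y on the smoothed latent
        Szz = float(Ez2[1:].sum())
        Sz = float(sm.mean.sum())
        Szy = sm.mean @ obs
        Sy = obs.sum(axis=0)
        A = np.array([[Szz, Sz], [Sz, float(K)]])
        sol = np.linalg.solve(A, np.vstack([Szy, Sy]))
        c_new, d_new = sol[0], sol[1]

        resid = obs - sm.mean[:, None] * c_new[None, :] - d_new
        Sigma_new = (resid.T @ resid + np.outer(c_new, c_new) * sm.var.sum()) / K
        Sigma_new = 0.5 * (Sigma_new + Sigma_new.T)
        Sigma_new += 1e-12 * max(np.trace(Sigma_new) / m, 1e-30) * np.eye(m)

        params = SSMParams(a=a_new, c=c_new, d=d_new, sigma2=1.0, Sigma=Sigma_new)

    return params, np.asarray(ll_trace)


def zscore_trajectory(
    params: SSMParams,
    estimate: LatentStateEstimate,
    baseline_window: tuple[float, float],
    config: DetectionConfig | None = None,
) -> ZScoreSeries:
    """Standardize the filtered state against a pre-stimulus baseline.

    Z_k = (z_{k|k} - mean(z_baseline)) / SD(z_baseline); the confidence
    half-width is the normal quantile at ``ci_level`` times the posterior SD
    sqrt(Q_{k|k}), divided by the baseline SD so that it lives on the same
    Z scale.
    """
    config = config or DetectionConfig()
    starts = estimate.bin_starts
    eps = 1e-9
    in_base = (starts >= baseline_window[0] - eps) & (
        starts + estimate.bin_size <= baseline_window[1] + eps
    )
    if in_base.sum() < 2:
        raise InvalidWindowError(
            f"baseline window {baseline_window} contains fewer than 2 bins"
        )
    base = estimate.filt_mean[in_base]
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateBaselineError("baseline filtered state has zero variance")
    q = float(stats.norm.ppf(0.5 * (1.0 + config.ci_level)))
    return ZScoreSeries(
        z_value=(estimate.filt_mean - mu) / sd,
        ci_half_width=q * np.sqrt(np.clip(estimate.filt_var, 0, None)) / sd,
        baseline_mean=mu,
        baseline_sd=sd,
        baseline_window=baseline_window,
        bin_size=estimate.bin_size,
        t0=estimate.t0,
    )


def detect_onset(
    zs: ZScoreSeries,
    stimulus_time: float,
    config: DetectionConfig | None = None,
    response_window: tuple[float, float] | None = None,
) -> DetectionResult:
    """Apply the confidence-bound criterion within a response window.

    A bin fires when  Z - CI > threshold  or  Z + CI < -threshold.  The
    onset is the start of the first firing bin; the peak latency is the time
    (bin start) of the maximum |Z| within the response window, relative to
    ``stimulus_time``.
    """
    config = config or DetectionConfig()
    if response_window is None:
        response_window = (stimulus_time, zs.t0 + zs.bin_size * zs.n_bins)
    starts = zs.bin_starts
    eps = 1e-9
    in_resp = (starts >= response_window[0] - eps) & (starts < response_window[1] - eps)
    if not in_resp.any():
        raise InvalidWindowError(f"response window {response_window} contains no bins")

    z = zs.z_value[in_resp]
    ci = zs.ci_half_width[in_resp]
    t = starts[in_resp]
    fired = (z - ci > config.threshold) | (z + ci < -config.threshold)
    detected = bool(fired.any())
    onset_time = float(t[np.argmax(fired)]) if detected else None
    peak_idx = int(np.argmax(np.abs(z)))
    peak_z = float(z[peak_idx])
    return DetectionResult(
        detected=detected,
        onset_time=onset_time,
        peak_latency=float(t[peak_idx] - stimulus_time),
        peak_z=peak_z,
        direction="positive" if peak_z >= 0 else "negative",
    )
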