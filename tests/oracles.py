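"""Independent reference implementations used to cross-check the package.

These deliberately avoid the recursions under test: latent-state moments
are obtained by dense joint-Gaussian conditioning over the whole trial, and
ERP candidate peaks by an exhaustive scan over every local extremum.
"""
from __future__ import annotations

import numpy as np


def dense_gaussian_moments(params, obs: np.ndarray, z0: float, Q0: float):
    """Filtered and smoothed latent moments by brute-force conditioning.

    Builds the exact joint Gaussian of (z_1..z_K, y_1..y_K) given
    z_0 ~ delta(z0) with prior variance Q0 on the first transition, then
    conditions z_k on y_{1:k} (filtered) and on y_{1:K} (smoothed).

    Returns (filt_mean, filt_var, smooth_mean, smooth_var).
    """
    obs = np.asarray(obs, dtype=float)
    K, m = obs.shape
    a, c, Sig = params.a, params.c, params.Sigma
    s2 = params.sigma2

    mz = np.empty(K)
    var = np.empty(K)
    mz[0] = a * z0
    var[0] = a * a * Q0 + s2
    for k in range(1, K):
        mz[k] = a * mz[k - 1]
        var[k] = a * a * var[k - 1] + s2
    Vz = np.empty((K, K))
    for j in range(K):
        for k in range(j, K):
            Vz[j, k] = Vz[k, j] = a ** (k - j) * var[j]

    my = (mz[:, None] * c[None, :] + params.d).ravel()
    Cyy = np.kron(Vz, np.outer(c, c)) + np.kron(np.eye(K), Sig)
    Czy = np.zeros((K, K * m))
    for k in range(K):
        for j in range(K):
            Czy[k, j * m : (j + 1) * m] = Vz[k, j] * c
    resid = obs.ravel() - my

    filt_mean = np.empty(K)
    filt_var = np.empty(K)
    for k in range(K):
        n = (k + 1) * m
        S = Cyy[:n, :n]
        filt_mean[k] = mz[k] + Czy[k, :n] @ np.linalg.solve(S, resid[:n])
        filt_var[k] = Vz[k, k] - Czy[k, :n] @ np.linalg.solve(S, Czy[k, :n])

    sol = np.linalg.solve(Cyy, resid)
    smooth_mean = mz + Czy @ sol
    smooth_var = np.diag(Vz - Czy @ np.linalg.solve(Cyy, Czy.T))
    return filt_mean, filt_var, smooth_mean, smooth_var


def brute_force_first_peak(
    trace: np.ndarray,
    times: np.ndarray,
    stimulus_time: float,
    baseline_mask: np.ndarray,
    criterion_sd: float = 3.0,
    half_width: int = 2,
):
    """Exhaustive scan for the earliest supra-criterion local extremum.

    Examines every response sample, classifies it as a local max/min of its
    +-``half_width`` neighborhood (plateaus to their first sample), applies
    the |deviation| > criterion_sd * SD rule, and returns the earliest
    qualifying time (or None) plus all candidate times.
    """
    base = trace[baseline_mask]
    mu, sd = base.mean(), base.std(ddof=1)
    cands = []
    for i in range(1, trace.size):
        if times[i] < stimulus_time:
            continue
        lo = max(0, i - half_width)
        seg = trace[lo : i + half_width + 1]
        is_max = trace[i] >= seg.max() and trace[i] > trace[i - 1]
        is_min = trace[i] <= seg.min() and trace[i] < trace[i - 1]
        if (is_max or is_min) and abs(trace[i] - mu) > criterion_sd * sd:
            cands.append(times[i])
    return (cands[0] if cands else None), cands


def paired_t_closed_form(diffs: np.ndarray) -> tuple[float, float]:
    """Textbook paired t statistic and two-sided p-value from differences."""
    from scipy import stats

    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
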