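"""Synthetic two-region LFP sessions with planted response latencies.

The generator emulates the features of noxious-stimulation recordings that
the downstream analysis consumes:

* background LFP = broadband 1/f^beta Gaussian noise (beta = 1 by default)
  plus an ongoing constant-amplitude theta-range oscillation (4-7 Hz,
  slowly drifting frequency).  The rhythm dominates the baseline variance,
  as in rodent cortical LFP, which is what makes a per-trial
  "3 SD above baseline" ERP criterion selective;
* stimulus-locked ERP deflections: a single-cycle 10 Hz cosine under a
  narrow Gaussian window, peaking at stimulus onset + planted latency;
* stimulus-locked band-power transients: the background's own 30-50,
  50-100 and 300-500 Hz components are amplitude-modulated from onset +
  latency, with a sharp step-and-exponential-decay profile (mechanical
  pinprick) or a slow linear ramp up to paw withdrawal (thermal).

Per-trial randomness (latency jitter, withdrawal time) is drawn from
fixed-counter substreams of the master seed, so a session is bit-identical
for a given protocol and changing the trial count does not reshuffle
earlier trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


from .core import (
    InvalidSamplingRateError,
    LFPRecording,
    OutOfRangeError,
    ProtocolInfeasibleError,
)
from .features import band_by_name, bandpass
from .ssm import SSMParams

#: Defaults shared by the protocol factories.
DEFAULT_FS = 2000.0
DEFAULT_NOISE_LEVEL = 50.0       # broadband RMS, microvolts
RHYTHM_RATIO = 3.0               # theta amplitude as multiple of broadband RMS
RHYTHM_BAND = (4.0, 7.0)         # Hz
ERP_CYCLE_FREQ = 10.0            # Hz, carrier of the ERP deflection
DEFAULT_ERP_WIDTH = 0.006        # s, Gaussian envelope SD; narrow enough that
                                 # the 4-100 Hz ERP filter leaves the pulse
                                 # effectively monophasic (no anticipatory lobe)
STEP_DECAY_TAU = 0.5             # s, mechanical transient decay constant
WITHDRAWAL_SD = 0.3              # s, trial-to-trial withdrawal spread
WITHDRAWAL_RANGE = (3.0, 5.0)    # s, truncation bounds
LEAD_IN_S = 2.0                  # s before the first stimulus


@dataclass
class SimProtocol:
    """Study conditions for one simulated session."""

    modality: str                      # "mechanical" | "thermal"
    n_trials: int = 96
    inter_trial_interval: float = 3.0
    region_latency: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.15, "ACC": 0.25}
    )
    erp_amplitude: float = 700.0       # microvolts, 0 disables ERP injection
    band_gain: dict[str, float] = field(
        default_factory=lambda: {"30-50": 4.0, "50-100": 4.0, "300-500": 4.0}
    )
    response_duration: float = 0.5     # s, mechanical transient support
    ramp_time: float | None = None     # s, nominal thermal ramp duration
    withdrawal_time: float | None = None  # s, nominal withdrawal (thermal)
    noise_level: float = DEFAULT_NOISE_LEVEL
    seed: int = 0
    jitter_sd: float = 0.03            # s, per-trial latency jitter SD
    erp_width: float = DEFAULT_ERP_WIDTH
    rhythm_amplitude: float | None = None  # default RHYTHM_RATIO * noise_level
    n_channels: int = 2
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.modality not in ("mechanical", "thermal"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if any(v < 0 for v in self.region_latency.values()):
            raise ValueError("planted latencies must be >= 0")
        if any(g < 1 for g in self.band_gain.values()):
            raise ValueError("band gains must be >= 1")
        for name in self.band_gain:
            band_by_name(name)  # raises InvalidBandError for unknown keys
        if self.modality == "thermal":
            if self.withdrawal_time is None:
                self.withdrawal_time = 4.0
            if self.ramp_time is None:
                self.ramp_time = self.withdrawal_time
            if self.ramp_time <= 0:
                raise ValueError("ramp_time must be > 0 for thermal protocols")
        if self.rhythm_amplitude is None:
            self.rhythm_amplitude = RHYTHM_RATIO * self.noise_level


def mechanical_protocol(**overrides) -> SimProtocol:
    """Pinprick-like session: 96 trials, sharp transients, clear ERPs."""
    return SimProtocol(modality="mechanical", **overrides)


def thermal_protocol(**overrides) -> SimProtocol:
    """Hargreaves-like session: slow ramp to withdrawal near 4 s, no ERPs."""
    defaults = dict(
        n_trials=48,
        inter_trial_interval=10.0,
        region_latency={"S1": 0.2, "ACC": 0.2},
        erp_amplitude=0.0,
        withdrawal_time=4.0,
        jitter_sd=0.05,
    )
    defaults.update(overrides)
    return SimProtocol(modality="thermal", **defaults)


@dataclass
class SimulatedTrajectory:
    """An exact draw from the state-space model, with its noise realization."""

    latent: np.ndarray        # z_k, k = 1..K
    observations: np.ndarray  # y_k, (K, m)
    state_noise: np.ndarray   # eps_k
    obs_noise: np.ndarray     # v_k, (K, m)
    params: SSMParams
    z0: float
    seed: int


def _shaped_noise(n: int, fs: float, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with power ~ 1/f^beta for f >= 1 Hz."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.where(f >= 1.0, np.maximum(f, 1.0) ** (-beta / 2.0), 1.0)
    scale[0] = 0.0
    x = np.fft.irfft(W * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _drifting_rhythm(
    n: int, fs: float, rng: np.random.Generator, band: tuple[float, float] = RHYTHM_BAND
) -> np.ndarray:
    """Unit-amplitude oscillation whose frequency wanders slowly in ``band``."""
    u = signal.sosfiltfilt(
        signal.butter(2, 0.5, fs=fs, output="sos"), rng.standard_normal(n)
    )
    sd = u.std()
    u = np.tanh(u / sd) if sd > 0 else np.zeros(n)
    lo, hi = band
    f_inst = 0.5 * (lo + hi) + 0.5 * (hi - lo) * u
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phase)


def generate_baseline_lfp(
    n_channels: int,
    duration: float,
    fs: float,
    noise_level: float,
    seed,
    beta: float = 1.0,
    rhythm_amplitude: float = 0.0,
) -> LFPRecording:
    """Stimulus-free background LFP.

    Each channel is independent 1/f^beta Gaussian noise scaled to an exact
    RMS of ``noise_level`` microvolts; if ``rhythm_amplitude`` > 0 an
    ongoing theta-range oscillation of that amplitude is superimposed.
    """
    if fs < 1000:
        raise InvalidSamplingRateError(
            f"fs={fs} Hz cannot support the 300-500 Hz band (need >= 1000 Hz)"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        x = noise_level * _shaped_noise(n, fs, beta, rng)
        if rhythm_amplitude > 0:
            x = x + rhythm_amplitude * _drifting_rhythm(n, fs, rng)
        data[ch] = x
    return LFPRecording(data=data, fs=fs)


def erp_waveform(
    fs: float, amplitude: float, width: float, cycle_freq: float = ERP_CYCLE_FREQ
) -> tuple[np.ndarray, int]:
    """Gaussian-windowed single-cycle cosine; returns (waveform, peak index).

    The extremum (value ``amplitude``) sits at the center sample.  The
    Gaussian SD ``width`` is kept narrow relative to the carrier period so
    the side lobes stay far below typical detection criteria and the
    deflection is effectively monophasic.
    """
    half = int(round(5.0 * width * fs))
    t = np.arange(-half, half + 1) / fs
    w = amplitude * np.cos(2.0 * np.pi * cycle_freq * t) * np.exp(
        -0.5 * (t / width) ** 2
    )
    return w, half


def inject_erp(
    rec: LFPRecording,
    event_time: float,
    latency: float,
    amplitude: float,
    width: float,
) -> LFPRecording:
    """Add an ERP-like deflection peaking at ``event_time + latency``.

    The deflection is added coherently to every channel; samples outside its
    support are untouched.  Returns a new recording.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out = rec.copy()
    if amplitude == 0:
        return out
    w, half = erp_waveform(rec.fs, amplitude, width)
    peak = rec.sample_index(event_time + latency)
    lo, hi = peak - half, peak + half + 1
    if lo < 0 or hi > rec.n_samples:
        raise OutOfRangeError("ERP deflection window exceeds the recording")
    out.data[:, lo:hi] += w
    return out


def _profile(
    t_rel: np.ndarray, profile: str, gain: float, duration: float, tau: float
) -> np.ndarray:
    """Multiplicative modulation minus one, over times relative to onset."""
    if profile == "step_decay":
        return (gain - 1.0) * np.exp(-t_rel / tau)
    if profile == "ramp":
        return (gain - 1.0) * t_rel / duration
    raise ValueError(f"unknown profile {profile!r}")


def inject_band_power_transient(
    rec: LFPRecording,
    event_time: float,
    latency: float,
    profile: str,
    gain: dict[str, float],
    duration: float,
    decay_tau: float = STEP_DECAY_TAU,
) -> LFPRecording:
    """Amplitude-modulate the recording's own band-limited components.

    Starting at ``event_time + latency`` and for ``duration`` seconds, the
    content of each listed band is scaled by a time profile: ``step_decay``
    jumps to ``gain`` and decays exponentially (mechanical); ``ramp`` rises
    linearly to ``gain`` (thermal).  Samples outside the window are
    bit-identical to the input.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    out = rec.copy()
    t_on = event_time + latency
    i0 = rec.sample_index(t_on)
    i1 = rec.sample_index(t_on + duration)
    if i0 < 0 or i1 > rec.n_samples:
        raise OutOfRangeError("transient window exceeds the recording")
    t_rel = (np.arange(i0, i1) - (t_on - rec.t0) * rec.fs) / rec.fs
    for name, g in gain.items():
        band = band_by_name(name)
        if g == 1.0:
            continue
        mod = _profile(t_rel, profile, g, duration, decay_tau)
        for ch in range(rec.n_channels):
            comp = bandpass(rec.data[ch], rec.fs, band.low, band.high)
            out.data[ch, i0:i1] += mod * comp[i0:i1]
    return out


def _session_duration(protocol: SimProtocol) -> tuple[float, float]:
    """(total duration, maximum response span) for a protocol."""
    if protocol.modality == "mechanical":
        span = protocol.response_duration
    else:
        span = WITHDRAWAL_RANGE[1]
    total = LEAD_IN_S + (protocol.n_trials - 1) * protocol.inter_trial_interval + span + 2.0
    return total, span


def generate_session(
    protocol: SimProtocol,
    regions: tuple[str, ...] = ("S1", "ACC"),
) -> tuple[dict[str, LFPRecording], pd.DataFrame, pd.DataFrame]:
    """Simulate a full two-region session under ``protocol``.

    Every trial receives, in each region, an ERP deflection (if
    ``erp_amplitude`` > 0) and a band-power transient at that region's
    planted latency (regional latency plus per-trial Gaussian jitter).
    Band modulation envelopes are applied to the band components of the
    clean background, so non-overlapping trials do not interact.

    Returns ``(recordings, events, ground_truth)`` where ``events`` has one
    row per trial (trial_id, modality, stimulus_onset_s, withdrawal_s) and
    ``ground_truth`` one row per (trial, region) with the planted latency.
    """
    missing = [r for r in regions if r not in protocol.region_latency]
    if missing:
        raise ValueError(f"protocol lacks latencies for regions {missing}")
    total, span = _session_duration(protocol)
    # next trial's pre-stimulus baseline must not overlap this trial's response
    if protocol.inter_trial_interval < span + 1.0:
        raise ProtocolInfeasibleError(
            f"inter_trial_interval {protocol.inter_trial_interval} s too short for "
            f"a {span} s response span"
        )

    onsets = LEAD_IN_S + protocol.inter_trial_interval * np.arange(protocol.n_trials)

    # per-trial draws from fixed-counter substreams
    # absolute paw-withdrawal times (stimulus onset + truncated-Gaussian draw)
    withdrawals = np.full(protocol.n_trials, np.nan)
    if protocol.modality == "thermal":
        for i in range(protocol.n_trials):
            rng = np.random.default_rng([protocol.seed, 1, i])
            withdrawals[i] = onsets[i] + float(
                np.clip(
                    protocol.withdrawal_time + WITHDRAWAL_SD * rng.standard_normal(),
                    *WITHDRAWAL_RANGE,
                )
            )

    latencies = np.empty((protocol.n_trials, len(regions)))
    for i in range(protocol.n_trials):
        for r, _ in enumerate(regions):
            rng = np.random.default_rng([protocol.seed, 2, i, r])
            jitter = protocol.jitter_sd * rng.standard_normal()
            latencies[i, r] = max(0.0, protocol.region_latency[regions[r]] + jitter)

    recordings: dict[str, LFPRecording] = {}
    gt_rows = []
    for r, region in enumerate(regions):
        rec = generate_baseline_lfp(
            protocol.n_channels,
            total,
            protocol.fs,
            protocol.noise_level,
            seed=[protocol.seed, 0, r],
            beta=1.0,
            rhythm_amplitude=protocol.rhythm_amplitude,
        )
        rec.region = region

        # band-power transients: one modulation envelope per band across all
        # trials, applied to the clean background's band components
        for name, g in protocol.band_gain.items():
            if g == 1.0:
                continue
            band = band_by_name(name)
            mod = np.zeros(rec.n_samples)
            for i in range(protocol.n_trials):
                t_on = onsets[i] + latencies[i, r]
                if protocol.modality == "mechanical":
                    dur = protocol.response_duration
                    prof = "step_decay"
                else:
                    dur = withdrawals[i] - t_on
                    prof = "ramp"
                i0 = rec.sample_index(t_on)
                i1 = rec.sample_index(t_on + dur)
                t_rel = (np.arange(i0, i1) - (t_on - rec.t0) * rec.fs) / rec.fs
                mod[i0:i1] = _profile(t_rel, prof, g, dur, STEP_DECAY_TAU)
            for ch in range(rec.n_channels):
                comp = bandpass(rec.data[ch], rec.fs, band.low, band.high)
                rec.data[ch] += mod * comp

        # ERP deflections
        if protocol.erp_amplitude > 0:
            w, half = erp_waveform(rec.fs, protocol.erp_amplitude, protocol.erp_width)
            for i in range(protocol.n_trials):
                peak = rec.sample_index(onsets[i] + latencies[i, r])
                rec.data[:, peak - half : peak + half + 1] += w

        recordings[region] = rec
        for i in range(protocol.n_trials):
            gt_rows.append(
                {
                    "trial_id": i,
                    "region": region,
                    "modality": protocol.modality,
                    "stimulus_onset_s": onsets[i],
                    "withdrawal_s": withdrawals[i],
                    "planted_latency_s": latencies[i, r],
                }
            )

    events = pd.DataFrame(
        {
            "trial_id": np.arange(protocol.n_trials),
            "modality": protocol.modality,
            "stimulus_onset_s": onsets,
            "withdrawal_s": withdrawals,
        }
    )
    ground_truth = pd.DataFrame(gt_rows)
    return recordings, events, ground_truth


def simulate_ssm(
    params: SSMParams, K: int, z0: float = 0.0, seed: int = 0
) -> SimulatedTrajectory:
    """Exact draw of latent and observations from the state-space model."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    m = params.c.size
    eps = np.sqrt(params.sigma2) * rng.standard_normal(K)
    w, V = np.linalg.eigh(params.Sigma)  # PSD validated by SSMParams
    L = V * np.sqrt(np.clip(w, 0.0, None))
    v = rng.standard_normal((K, m)) @ L.T
    z = np.empty(K)
    prev = z0
    for k in range(K):
        prev = params.a * prev + eps[k]
        z[k] = prev
    y = z[:, None] * params.c[None, :] + params.d + v
    return SimulatedTrajectory(
        latent=z,
        observations=y,
        state_noise=eps,
        obs_noise=v,
        params=params,
        z0=z0,
        seed=seed,
    )
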