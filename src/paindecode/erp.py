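"""Single-trial event-related potential (ERP) peak-latency measurement.

The trial trace (average of the selected channels, band-pass filtered
4-100 Hz) is split into a 0.5 s pre-stimulus baseline and a response
window: 0.5 s after onset for mechanical stimuli, or onset-to-withdrawal
for thermal stimuli.  Candidate peaks are local extrema of the response
whose absolute deviation from the baseline mean exceeds 3 baseline SDs;
the ERP latency is the time of the earliest candidate relative to stimulus
onset (an automated form of the first-peak rule).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateBaselineError,
    InsufficientDataError,
    LFPRecording,
    OutOfRangeError,
)
from .features import bandpass

#: ERP band edges in Hz (removes both slow drift and high-frequency noise).
ERP_BAND = (4.0, 100.0)

#: Baseline / mechanical-response window lengths, seconds.
BASELINE_S = 0.5
RESPONSE_S = 0.5

#: Deviation criterion in baseline SDs.
PEAK_CRITERION_SD = 3.0

#: Local-extremum neighborhood half-width in samples.
EXTREMUM_HALF_WIDTH = 2

MIN_BASELINE_SAMPLES = 50


@dataclass
class TrialWindow:
    """One trial's filtered trace with its baseline and response windows."""

    trace: np.ndarray
    fs: float
    t0: float                       # time of trace[0]
    stimulus_time: float
    baseline: tuple[float, float]
    response: tuple[float, float]
    modality: str

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.trace.size) / self.fs


@dataclass
class ERPResult:
    """Single-trial ERP statistics."""

    latency: float | None           # s after stimulus onset; None if no peak
    peak_time: float
    peak_value: float               # microvolts
    baseline_mean: float
    baseline_sd: float
    n_candidate_peaks: int


def extract_trial(
    rec: LFPRecording,
    event,
    channels: list[str],
    modality: str,
    baseline_s: float = BASELINE_S,
    response_s: float = RESPONSE_S,
    erp_band: tuple[float, float] = ERP_BAND,
) -> TrialWindow:
    """Average the listed channels, filter, and slice one trial.

    ``event`` is a mapping with ``stimulus_onset_s`` and, for thermal
    trials, ``withdrawal_s``.  The full-length channel average is filtered
    (zero-phase) before slicing so filter transients stay at the recording
    edges, far from the trial.
    """
    if not channels:
        raise ValueError("need at least one channel")
    stim = float(event["stimulus_onset_s"])
    if modality == "thermal":
        end = float(event["withdrawal_s"])
        if not np.isfinite(end):
            raise ValueError("thermal trial lacks a withdrawal time")
    else:
        end = stim + response_s
    start = stim - baseline_s
    if start < rec.t0 or end > rec.t_end:
        raise OutOfRangeError(
            f"trial window ({start:.3f}, {end:.3f}) outside recording"
        )
    avg = np.mean([rec.channel(ch) for ch in channels], axis=0)
    filt = bandpass(avg, rec.fs, *erp_band)
    i0, i1 = rec.sample_index(start), rec.sample_index(end)
    return TrialWindow(
        trace=filt[i0:i1],
        fs=rec.fs,
        t0=start,
        stimulus_time=stim,
        baseline=(start, stim),
        response=(stim, end),
        modality=modality,
    )


def _local_extrema(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Indices in [lo, hi) that are extrema of a +-EXTREMUM_HALF_WIDTH window.

    A sample is an extremum when it attains the window maximum (or minimum)
    and strictly exceeds (or falls below) its predecessor, which resolves
    plateaus to their first sample.
    """
    h = EXTREMUM_HALF_WIDTH
    idx = []
    for i in range(max(lo, 1), hi):
        seg = x[max(0, i - h) : i + h + 1]
        if (x[i] >= seg.max() and x[i] > x[i - 1]) or (
            x[i] <= seg.min() and x[i] < x[i - 1]
        ):
            idx.append(i)
    return np.asarray(idx, dtype=int)


def erp_peak_latency(tw: TrialWindow) -> ERPResult:
    """First-peak ERP latency under the 3-SD deviation criterion.

    Candidates are response-window local extrema with
    ``|x - baseline_mean| > 3 * baseline_sd``; the earliest candidate gives
    the latency.  When no candidate exists the latency is ``None`` and the
    reported peak is the largest absolute deviation in the response.
    """
    t = tw.times
    base = tw.trace[t < tw.stimulus_time]
    if base.size < MIN_BASELINE_SAMPLES:
        raise InsufficientDataError(
            f"baseline has {base.size} samples (< {MIN_BASELINE_SAMPLES})"
        )
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    if sd <= 0:
        raise DegenerateBaselineError("baseline SD is zero")

    lo = int(np.searchsorted(t, tw.stimulus_time))
    hi = tw.trace.size
    ext = _local_extrema(tw.trace, lo, hi)
    dev = np.abs(tw.trace - mu)
    cand = ext[dev[ext] > PEAK_CRITERION_SD * sd] if ext.size else ext

    if cand.size:
        first = int(cand[0])
        latency = float(t[first] - tw.stimulus_time)
        peak_time, peak_value = float(t[first]), float(tw.trace[first])
    else:
        j = lo + int(np.argmax(dev[lo:hi]))
        latency = None
        peak_time, peak_value = float(t[j]), float(tw.trace[j])
    return ERPResult(
        latency=latency,
        peak_time=peak_time,
        peak_value=peak_value,
        baseline_mean=mu,
        baseline_sd=sd,
        n_candidate_peaks=int(cand.size),
    )
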