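"""Band-limited amplitude features for the pain decoder.

A continuous LFP channel is converted into a binned multi-band amplitude
series: each band is band-pass filtered (zero-phase), the instantaneous
amplitude is taken as the magnitude of the analytic signal, and amplitudes
are averaged within fixed-width time bins (100 ms by default).  The three
canonical bands are low gamma (30-50 Hz), high gamma (50-100 Hz) and the
ultra-high-frequency / spiking-band range (300-500 Hz).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    DegenerateBaselineError,
    InvalidBandError,
    InvalidWindowError,
    LFPRecording,
    NoValidChannelError,
    OutOfRangeError,
)

#: Zero-phase Butterworth order used for every band-pass in the package.
FILTER_ORDER = 4

#: Padding added on each side of a feature window before filtering, then
#: discarded, to suppress filter edge transients.
EDGE_PAD_S = 0.5

#: Default feature bin width (seconds).
DEFAULT_BIN_S = 0.1

#: Artifact screen: a channel is rejected when more than this fraction of
#: samples exceeds ARTIFACT_MAD_FACTOR robust SDs.
ARTIFACT_FRACTION = 1e-3
ARTIFACT_MAD_FACTOR = 10.0
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class BandDef:
    """A frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise InvalidBandError(f"invalid band edges {self.low}-{self.high} Hz")


CANONICAL_BANDS: tuple[BandDef, ...] = (
    BandDef("30-50", 30.0, 50.0),
    BandDef("50-100", 50.0, 100.0),
    BandDef("300-500", 300.0, 500.0),
)

_BANDS_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def band_by_name(name: str) -> BandDef:
    """Look up one of the canonical decoder bands by its name."""
    try:
        return _BANDS_BY_NAME[name]
    except KeyError:
        raise InvalidBandError(
            f"unknown band {name!r}; known bands: {sorted(_BANDS_BY_NAME)}"
        ) from None


@dataclass
class FeatureSeries:
    """Binned band-amplitude observations for one channel.

    ``values`` is a (K, n_bands) matrix of non-negative mean analytic
    amplitudes; row ``k`` covers the time interval
    ``[t0 + k*bin_size, t0 + (k+1)*bin_size)``.
    """

    values: np.ndarray
    bin_size: float = DEFAULT_BIN_S
    t0: float = 0.0
    bands: tuple[BandDef, ...] = CANONICAL_BANDS
    channel_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + self.bin_size * np.arange(self.n_bins)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_bin_start_s": self.bin_starts}
        for j, b in enumerate(self.bands):
            cols[f"amp_{b.name.replace('-', '_')}"] = self.values[:, j]
        return pd.DataFrame(cols)


def bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass filter.

    Applied forward-backward (``sosfiltfilt``), so the output has no group
    delay and latency measurements downstream are unbiased.  Output length
    equals input length.
    """
    if not (0 < low < high < fs / 2):
        raise InvalidBandError(
            f"band {low}-{high} Hz infeasible at fs={fs} Hz (need high < fs/2)"
        )
    sos = signal.butter(FILTER_ORDER, [low, high], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def band_envelope(x: np.ndarray, fs: float, band: BandDef) -> np.ndarray:
    """Instantaneous amplitude of ``x`` within ``band``.

    Magnitude of the analytic signal (Hilbert transform) of the band-passed
    trace; non-negative by construction.
    """
    return np.abs(signal.hilbert(bandpass(x, fs, band.low, band.high)))


def band_amplitude_features(
    rec: LFPRecording,
    channel: str,
    bands: tuple[BandDef, ...] = CANONICAL_BANDS,
    bin_size: float = DEFAULT_BIN_S,
    window: tuple[float, float] | None = None,
) -> FeatureSeries:
    """Binned band-amplitude features for one channel of a recording.

    The segment is padded by ``EDGE_PAD_S`` on each side (clipped to the
    recording bounds) before filtering; the padding is discarded after the
    envelope is computed.
    """
    x = rec.channel(channel)
    if window is None:
        window = (rec.t0, rec.t0 + rec.n_samples / rec.fs)
    start, end = window
    if start < rec.t0 - 0.5 / rec.fs or end > rec.t_end + 0.5 / rec.fs:
        raise OutOfRangeError(
            f"window {window} outside recording [{rec.t0}, {rec.t_end}]"
        )
    if end <= start:
        raise InvalidWindowError(f"empty window {window}")
    n_bins = int(round((end - start) / bin_size))
    if n_bins < 1 or abs((end - start) - n_bins * bin_size) > 1.0 / rec.fs:
        raise InvalidWindowError(
            f"bin size {bin_size} s does not divide window {window} "
            "to within one sample"
        )

    i0 = rec.sample_index(start)
    i1 = rec.sample_index(end)
    pad = int(round(EDGE_PAD_S * rec.fs))
    j0 = max(0, i0 - pad)
    j1 = min(rec.n_samples, i1 + pad)
    seg = x[j0:j1]

    per_bin = int(round(bin_size * rec.fs))
    offsets = i0 - j0 + per_bin * np.arange(n_bins + 1)
    values = np.empty((n_bins, len(bands)))
    for j, band in enumerate(bands):
        env = band_envelope(seg, rec.fs, band)
        cum = np.concatenate(([0.0], np.cumsum(env)))
        counts = np.diff(offsets)
        values[:, j] = np.diff(cum[offsets]) / counts
    return FeatureSeries(
        values=values,
        bin_size=bin_size,
        t0=start,
        bands=tuple(bands),
        channel_id=channel,
        region=rec.region,
    )


def _artifact_fraction(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    thresh = ARTIFACT_MAD_FACTOR * MAD_TO_SD * mad
    if thresh == 0:
        return 1.0
    return float(np.mean(np.abs(x - np.median(x)) > thresh))


def select_channel(
    rec: LFPRecording,
    events: pd.DataFrame,
    baseline_s: float = 0.5,
    response_s: float = 0.5,
    bands: tuple[BandDef, ...] = CANONICAL_BANDS,
) -> tuple[str, pd.DataFrame]:
    """Pick the channel with the best event-locked band-amplitude SNR.

    Channels failing the artifact screen (more than ``ARTIFACT_FRACTION`` of
    samples beyond ``ARTIFACT_MAD_FACTOR`` robust SDs) are excluded.  For the
    remaining channels the summed three-band envelope is compared between the
    post-onset response window and the pre-onset baseline for every event:

        SNR = mean over events of (mean(response) - mean(baseline)) / SD(baseline)

    Returns the winning channel label and a per-channel report with columns
    ``channel``, ``artifact_fraction``, ``excluded`` and ``snr``.
    """
    if len(events) == 0:
        raise InvalidWindowError("no events supplied for channel selection")
    onsets = np.asarray(events["stimulus_onset_s"], dtype=float)

    rows = []
    best_label, best_snr = None, -np.inf
    for label in rec.channel_labels:
        x = rec.channel(label)
        frac = _artifact_fraction(x)
        excluded = frac > ARTIFACT_FRACTION
        snr = np.nan
        if not excluded:
            env = np.zeros_like(x)
            for band in bands:
                env += band_envelope(x, rec.fs, band)
            scores = []
            for on in onsets:
                b0, b1 = rec.sample_index(on - baseline_s), rec.sample_index(on)
                r0, r1 = b1, rec.sample_index(on + response_s)
                if b0 < 0 or r1 > rec.n_samples:
                    continue
                base, resp = env[b0:b1], env[r0:r1]
                sd = base.std()
                if sd == 0:
                    raise DegenerateBaselineError(
                        f"zero baseline envelope SD on channel {label!r}"
                    )
                scores.append((resp.mean() - base.mean()) / sd)
            if not scores:
                raise OutOfRangeError("no event window falls inside the recording")
            snr = float(np.mean(scores))
            if snr > best_snr:
                best_label, best_snr = label, snr
        rows.append(
            {
                "channel": label,
                "artifact_fraction": frac,
                "excluded": excluded,
                "snr": snr,
            }
        )
    report = pd.DataFrame(rows)
    if best_label is None:
        raise NoValidChannelError("all channels rejected by the artifact screen")
    return best_label, report
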