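"""Shared containers and error types.

All voltages are in microvolts, times in seconds, frequencies in Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_SAMPLING_RATE_HZ = 1000.0  # must support the 300-500 Hz feature band


class PainDecodeError(Exception):
    """Base class for all package errors."""


class InvalidSamplingRateError(PainDecodeError):
    """Sampling rate too low for the analysis bands."""


class OutOfRangeError(PainDecodeError):
    """A requested time window falls outside the recording."""


class InvalidBandError(PainDecodeError):
    """Unknown or infeasible frequency band."""


class InvalidWindowError(PainDecodeError):
    """Empty or malformed analysis window."""


class ProtocolInfeasibleError(PainDecodeError):
    """Simulation protocol cannot be realized (e.g. overlapping trials)."""


class InvalidCovarianceError(PainDecodeError):
    """Covariance matrix is not symmetric positive semi-definite."""


class SingularCovarianceError(PainDecodeError):
    """Innovation covariance is singular (degenerate observation noise)."""


class MissingChannelError(PainDecodeError):
    """Requested channel label not present in the recording."""


class NoValidChannelError(PainDecodeError):
    """Every channel was rejected by the artifact screen."""


class DegenerateBaselineError(PainDecodeError):
    """Baseline has zero variance; Z-scoring undefined."""


class DegenerateInputError(PainDecodeError):
    """Input data carries no usable variance."""


class InconsistentInputError(PainDecodeError):
    """Inputs that must agree (lengths, keys) do not."""


class InsufficientDataError(PainDecodeError):
    """Too few observations for the requested computation."""


class DegenerateTestError(PainDecodeError):
    """Test statistic undefined (zero-variance differences)."""


class DuplicateRecordError(PainDecodeError):
    """The same (trial, region) key appeared more than once."""


class SchemaError(PainDecodeError):
    """Session file does not conform to the expected layout."""


class InternalConsistencyError(PainDecodeError):
    """An internal guarantee (e.g. EM ascent) was violated."""


@dataclass
class LFPRecording:
    """Continuous multi-channel LFP trace for one region.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz; must be at least 1000 Hz so that the
        300-500 Hz band is resolvable.
    channel_labels : list of str
        One label per row of ``data``.
    region : str
        Anatomical region name (e.g. ``"S1"``, ``"ACC"``).
    t0 : float
        Time of the first sample, in seconds.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    region: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs < MIN_SAMPLING_RATE_HZ:
            raise InvalidSamplingRateError(
                f"fs={self.fs} Hz is below the minimum {MIN_SAMPLING_RATE_HZ} Hz"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise InconsistentInputError(
                "channel_labels length does not match number of data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's trace by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.data[idx]

    def sample_index(self, t: float) -> int:
        """Index of the sample containing time ``t``."""
        return int(round((t - self.t0) * self.fs))

    def copy(self) -> "LFPRecording":
        return LFPRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            region=self.region,
            t0=self.t0,
        )
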