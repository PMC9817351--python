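"""Session file format (HDF5) and pipeline configuration.

Layout (schema version "1")::

    /regions/<name>/lfp      float dataset, (channels, samples), microvolts
                             attrs: fs_hz, channel_labels
    /events/trial_id         int dataset
    /events/modality         string dataset
    /events/stimulus_onset_s float dataset
    /events/withdrawal_s     float dataset (NaN where absent)
    root attrs: schema_version, seed, created

All regions share the time origin (t = 0 at the first sample).
"""
from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import InvalidSamplingRateError, LFPRecording, SchemaError

SCHEMA_VERSION = "1"

EVENT_COLUMNS = ["trial_id", "modality", "stimulus_onset_s", "withdrawal_s"]


def write_session(
    path,
    regions: dict[str, LFPRecording],
    events: pd.DataFrame,
    seed: int = 0,
) -> None:
    """Write recordings and the event table to an HDF5 session file."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["seed"] = int(seed)
        f.attrs["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        reg = f.create_group("regions")
        for name, rec in regions.items():
            g = reg.create_group(name)
            ds = g.create_dataset("lfp", data=rec.data)
            ds.attrs["fs_hz"] = float(rec.fs)
            ds.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
        ev = f.create_group("events")
        ev.create_dataset("trial_id", data=np.asarray(events["trial_id"], dtype=np.int64))
        ev.create_dataset(
            "modality",
            data=np.asarray(events["modality"], dtype=h5py.string_dtype()),
        )
        ev.create_dataset(
            "stimulus_onset_s", data=np.asarray(events["stimulus_onset_s"], dtype=float)
        )
        withdrawal = np.asarray(
            events.get("withdrawal_s", np.full(len(events), np.nan)), dtype=float
        )
        ev.create_dataset("withdrawal_s", data=withdrawal)


def read_session(path) -> tuple[dict[str, LFPRecording], pd.DataFrame]:
    """Read a schema-version-1 session file; round-trips with write_session."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"missing or unsupported schema_version (expected {SCHEMA_VERSION!r})"
            )
        if "regions" not in f:
            raise SchemaError("missing group '/regions'")
        if "events" not in f:
            raise SchemaError("missing group '/events'")
        regions = {}
        for name, g in f["regions"].items():
            if "lfp" not in g:
                raise SchemaError(f"missing dataset '/regions/{name}/lfp'")
            ds = g["lfp"]
            if "fs_hz" not in ds.attrs:
                raise SchemaError(f"missing attribute fs_hz on '/regions/{name}/lfp'")
            fs = float(ds.attrs["fs_hz"])
            if fs < 1000:
                raise InvalidSamplingRateError(
                    f"session region {name!r} sampled at {fs} Hz (< 1000 Hz)"
                )
            labels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in ds.attrs.get("channel_labels", [])
            ]
            regions[name] = LFPRecording(
                data=ds[()], fs=fs, channel_labels=labels, region=name
            )
        ev = f["events"]
        for col in EVENT_COLUMNS:
            if col not in ev:
                raise SchemaError(f"missing dataset '/events/{col}'")
        events = pd.DataFrame(
            {
                "trial_id": ev["trial_id"][()].astype(int),
                "modality": [
                    m.decode() if isinstance(m, bytes) else str(m)
                    for m in ev["modality"][()]
                ],
                "stimulus_onset_s": ev["stimulus_onset_s"][()],
                "withdrawal_s": ev["withdrawal_s"][()],
            }
        )
    return regions, events


@dataclass
class PipelineConfig:
    """End-to-end analysis settings.

    Defaults follow the decoder's standard operating point: the three
    canonical bands in 100 ms bins, a 0.5 s pre-stimulus baseline, a 0.5 s
    mechanical response window (thermal trials run to withdrawal), the
    3.38 confidence-bound threshold at a 95% CI, and automatic SNR-based
    channel selection.
    """

    bands: tuple[str, ...] = ("30-50", "50-100", "300-500")
    bin_ms: float = 100.0
    erp_band: tuple[float, float] = (4.0, 100.0)
    baseline_s: float = 0.5
    response_s: float = 0.5
    threshold: float = 3.38
    ci_level: float = 0.95
    channel_mode: str = "auto"       # "auto" or an explicit channel label
    em_max_iter: int = 500
    em_tol: float = 1e-6
    seed: int = 0
    log_level: str = "INFO"

    @property
    def bin_size(self) -> float:
        return self.bin_ms / 1000.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = list(self.bands)
        d["erp_band"] = list(self.erp_band)
        return d

    def config_hash(self) -> str:
        """Short stable digest of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        if "erp_band" in raw:
            raw["erp_band"] = tuple(raw["erp_band"])
        return cls(**raw)
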