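"""Per-trial latency tables and paired region comparisons.

Latencies from the two regions (S1, ACC) are joined per trial and compared
with a two-tailed paired t-test on the ACC - S1 differences over complete
pairs; results are reported as mean +- SEM, and a direction is declared
only at p < 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DegenerateTestError, DuplicateRecordError, InsufficientDataError

ALPHA = 0.05

_MEASURE_COLUMNS = {"erp": "erp_latency_s", "zpeak": "zpeak_latency_s"}

TABLE_COLUMNS = [
    "trial_id",
    "region",
    "modality",
    "erp_latency_s",
    "zpeak_latency_s",
]


@dataclass
class PairedComparison:
    """Two-tailed paired t-test summary for ACC - S1 latency differences."""

    measure: str
    n_pairs: int
    mean_diff: float
    sem_diff: float
    t_statistic: float
    p_value: float
    direction: str  # "ACC_longer" | "S1_longer" | "none"

    def to_dict(self) -> dict:
        return asdict(self)


def _normalize(results, value_attr: str) -> dict[tuple[int, str], float]:
    """Accept {(trial, region): value-or-result} dicts or record sequences."""
    out: dict[tuple[int, str], float] = {}
    if results is None:
        return out
    if isinstance(results, dict):
        items = results.items()
    else:
        items = []
        seen = set()
        for rec in results:
            key = (rec["trial_id"], rec["region"])
            if key in seen:
                raise DuplicateRecordError(f"duplicate record for {key}")
            seen.add(key)
            items.append((key, rec.get(value_attr)))
    for key, val in items:
        if val is not None and not np.isscalar(val):
            val = getattr(val, value_attr, None)
        out[key] = np.nan if val is None else float(val)
    return out


def build_table(
    erp_results=None,
    detection_results=None,
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join ERP and Z-peak latencies into one row per (trial, region).

    ``erp_results`` maps ``(trial_id, region)`` to a latency, an
    :class:`~paindecode.erp.ERPResult`, or ``None``; ``detection_results``
    likewise with ``peak_latency`` /
    :class:`~paindecode.ssm.DetectionResult`.  Sequences of records with
    ``trial_id``/``region`` keys are also accepted; duplicate keys raise.
    Missing values are preserved as NaN.
    """
    erp = _normalize(erp_results, "latency")
    det = _normalize(detection_results, "peak_latency")
    modality = {}
    if events is not None and len(events):
        modality = dict(zip(events["trial_id"], events["modality"]))

    keys = sorted(set(erp) | set(det))
    rows = [
        {
            "trial_id": t,
            "region": r,
            "modality": modality.get(t, ""),
            "erp_latency_s": erp.get((t, r), np.nan),
            "zpeak_latency_s": det.get((t, r), np.nan),
        }
        for t, r in keys
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def paired_latency_test(
    table: pd.DataFrame,
    measure: str,
    region_a: str = "ACC",
    region_b: str = "S1",
) -> PairedComparison:
    """Two-tailed paired t-test on ``region_a - region_b`` latencies.

    Trials missing either region's latency are dropped (complete-case).
    All-zero differences return the null result (t = 0, p = 1); non-zero
    constant differences have an undefined t statistic and raise
    :class:`DegenerateTestError`.
    """
    if measure not in _MEASURE_COLUMNS:
        raise ValueError(f"measure must be one of {sorted(_MEASURE_COLUMNS)}")
    col = _MEASURE_COLUMNS[measure]
    wide = table.pivot_table(index="trial_id", columns="region", values=col)
    for region in (region_a, region_b):
        if region not in wide.columns:
            raise InsufficientDataError(f"no latencies for region {region!r}")
    wide = wide[[region_a, region_b]].dropna()
    n = len(wide)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, got {n}")
    diffs = (wide[region_a] - wide[region_b]).to_numpy()

    if np.all(diffs == 0):
        return PairedComparison(measure, n, 0.0, 0.0, 0.0, 1.0, "none")
    sd = diffs.std(ddof=1)
    # constant non-zero differences leave only rounding noise in sd
    if sd <= 1e-9 * np.abs(diffs).max():
        raise DegenerateTestError("constant non-zero differences: t undefined")
    t_stat, p = sps.ttest_rel(wide[region_a], wide[region_b])
    mean_diff = float(diffs.mean())
    direction = "none"
    if p < ALPHA:
        direction = f"{region_a}_longer" if mean_diff > 0 else f"{region_b}_longer"
    return PairedComparison(
        measure=measure,
        n_pairs=n,
        mean_diff=mean_diff,
        sem_diff=float(sd / np.sqrt(n)),
        t_statistic=float(t_stat),
        p_value=float(p),
        direction=direction,
    )


def region_summary(table: pd.DataFrame, measure: str) -> dict[str, dict[str, float]]:
    """Per-region mean +- SEM of a latency measure (complete rows only)."""
    col = _MEASURE_COLUMNS[measure]
    out = {}
    for region, grp in table.groupby("region"):
        vals = grp[col].dropna().to_numpy()
        if vals.size:
            out[str(region)] = {
                "n": int(vals.size),
                "mean_s": float(vals.mean()),
                "sem_s": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else 0.0,
            }
    return out
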