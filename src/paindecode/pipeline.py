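"""End-to-end analysis: session file to latency tables and paired tests.

Per region: channel selection, band-amplitude features, an independent
per-trial EM fit of the state-space model, Kalman filtering, baseline
Z-scoring, confidence-bound onset detection and Z-peak latency; plus
single-trial ERP latencies on mechanical trials.  The two regions are
decoded independently and compared trial-by-trial.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .core import PainDecodeError
from .erp import erp_peak_latency, extract_trial
from .features import band_amplitude_features, band_by_name, select_channel
from .session import SCHEMA_VERSION, PipelineConfig, read_session
from .ssm import DetectionConfig, detect_onset, em_fit, kalman_filter, zscore_trajectory
from .stats import build_table, paired_latency_test, region_summary

logger = logging.getLogger("paindecode")


def decode_trial(
    rec,
    event,
    channel: str,
    config: PipelineConfig,
):
    """Decode one trial of one region: features -> EM -> filter -> Z -> detect.

    The model is fitted on the pre-stimulus baseline plus the trial response
    window; the feature window end is snapped to a whole number of bins.
    Returns (DetectionResult, ZScoreSeries, SSMParams).
    """
    stim = float(event["stimulus_onset_s"])
    if event.get("modality") == "thermal" and np.isfinite(event.get("withdrawal_s", np.nan)):
        resp_end = float(event["withdrawal_s"])
    else:
        resp_end = stim + config.response_s
    start = stim - config.baseline_s
    n_bins = int(np.floor((resp_end - start) / config.bin_size + 1e-9))
    end = start + n_bins * config.bin_size

    bands = tuple(band_by_name(b) for b in config.bands)
    feats = band_amplitude_features(
        rec, channel, bands=bands, bin_size=config.bin_size, window=(start, end)
    )
    params, _ = em_fit(feats, max_iter=config.em_max_iter, tol=config.em_tol)
    est = kalman_filter(params, feats)
    det_cfg = DetectionConfig(threshold=config.threshold, ci_level=config.ci_level)
    zs = zscore_trajectory(params, est, baseline_window=(start, stim), config=det_cfg)
    det = detect_onset(zs, stim, det_cfg, response_window=(stim, min(resp_end, end)))
    return det, zs, params


def run_pipeline(
    config: PipelineConfig,
    session_path,
    out_dir,
) -> dict:
    """Run the full analysis on a session file and write outputs to ``out_dir``.

    Outputs: ``latency_table.csv`` (one row per trial x region, with a
    header citing the schema version and config hash), one
    ``comparison_<measure>.json`` per applicable measure, ``channels.json``
    and ``pipeline.log``.  Stage errors are logged with their trial/region
    context and the run continues (partial-results contract).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        return _run(config, session_path, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, session_path, out: Path) -> dict:
    regions, events = read_session(session_path)
    logger.info(
        "session=%s regions=%s trials=%d config_hash=%s",
        session_path,
        sorted(regions),
        len(events),
        config.config_hash(),
    )

    erp_results: dict[tuple[int, str], float | None] = {}
    det_results: dict[tuple[int, str], float | None] = {}
    channels: dict[str, str] = {}

    for name, rec in regions.items():
        if config.channel_mode == "auto":
            channel, report = select_channel(
                rec, events, baseline_s=config.baseline_s, response_s=config.response_s
            )
            logger.info("region=%s selected channel=%s", name, channel)
            logger.debug("region=%s channel report:\n%s", name, report)
        else:
            channel = config.channel_mode
        channels[name] = channel

        for _, event in events.iterrows():
            trial = int(event["trial_id"])
            key = (trial, name)
            try:
                det, _, _ = decode_trial(rec, event, channel, config)
                det_results[key] = det.peak_latency
                logger.info(
                    "trial=%d region=%s stage=decode detected=%s zpeak_latency=%.3f",
                    trial,
                    name,
                    det.detected,
                    det.peak_latency if det.peak_latency is not None else float("nan"),
                )
            except PainDecodeError as exc:
                det_results[key] = None
                logger.warning("trial=%d region=%s stage=decode error=%s", trial, name, exc)

            if event["modality"] == "mechanical":
                try:
                    tw = extract_trial(
                        rec,
                        event,
                        [channel],
                        str(event["modality"]),
                        baseline_s=config.baseline_s,
                        response_s=config.response_s,
                        erp_band=config.erp_band,
                    )
                    res = erp_peak_latency(tw)
                    erp_results[key] = res.latency
                    logger.info(
                        "trial=%d region=%s stage=erp latency=%s n_candidates=%d",
                        trial,
                        name,
                        f"{res.latency:.4f}" if res.latency is not None else "absent",
                        res.n_candidate_peaks,
                    )
                except PainDecodeError as exc:
                    erp_results[key] = None
                    logger.warning("trial=%d region=%s stage=erp error=%s", trial, name, exc)

    table = build_table(erp_results or None, det_results or None, events)
    table_path = out / "latency_table.csv"
    with open(table_path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(f"# config_hash={config.config_hash()}\n")
        table.to_csv(fh, index=False)

    measures = ["zpeak"]
    if (events["modality"] == "mechanical").any():
        measures.insert(0, "erp")
    comparisons = {}
    for measure in measures:
        path = out / f"comparison_{measure}.json"
        try:
            cmp_result = paired_latency_test(table, measure)
            payload = cmp_result.to_dict()
            payload["per_region"] = region_summary(table, measure)
            comparisons[measure] = cmp_result
            logger.info(
                "measure=%s n=%d mean_diff=%.4f t=%.3f p=%.4g direction=%s",
                measure,
                cmp_result.n_pairs,
                cmp_result.mean_diff,
                cmp_result.t_statistic,
                cmp_result.p_value,
                cmp_result.direction,
            )
        except PainDecodeError as exc:
            payload = {"measure": measure, "error": str(exc)}
            logger.warning("measure=%s comparison failed: %s", measure, exc)
        payload["schema_version"] = SCHEMA_VERSION
        payload["config_hash"] = config.config_hash()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    with open(out / "channels.json", "w") as fh:
        json.dump(channels, fh, indent=2)

    return {
        "table": table,
        "comparisons": comparisons,
        "channels": channels,
        "out_dir": str(out),
    }
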