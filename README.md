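# paindecode

Tools for studying *when* cortical pain signals arrive: an unsupervised
state-space decoder of acute pain onset from local field potential (LFP)
band power, a single-trial event-related-potential (ERP) latency estimator,
and a synthetic two-region LFP generator that plants known response
latencies so the whole analysis can be validated end to end.

The package is aimed at systems-neuroscience analyses that compare the
timing of nociceptive responses between the primary somatosensory cortex
(S1, sensory-discriminative) and the anterior cingulate cortex (ACC,
affective), under sharp mechanical (pinprick) or slowly ramping thermal
(Hargreaves) stimulation.

## The model

LFP amplitudes in three pain-relevant bands — low gamma (30–50 Hz), high
gamma (50–100 Hz) and the ultra-high-frequency / spiking-band range
(300–500 Hz) — are averaged in 100 ms bins to form an observation vector
`y_k`.  A scalar latent pain state `z_k` drives all three bands through a
linear-Gaussian state-space model:

    z_k = a z_{k-1} + eps_k,        eps_k ~ N(0, sigma^2),  0 < |a| < 1
    y_k = c z_k + d + v_k,          v_k   ~ N(0, Sigma)

All parameters Theta = {a, c, d, sigma^2, Sigma} are fitted by EM (exact
E-step: Kalman filter + Rauch–Tung–Striebel smoother; closed-form M-step).
The Kalman-filtered posterior mean `z_{k|k}` is standardized against a
0.5 s pre-stimulus baseline,

    Z_k = (z_{k|k} - mean(z_baseline)) / SD(z_baseline),

and pain onset is declared when the 95% confidence bound clears a
threshold: `Z - CI > 3.38` or `Z + CI < -3.38`, with the CI half-width
derived from the posterior variance `Q_{k|k}`.  The *Z-peak latency* of a
trial is the time from stimulus onset to the maximum |Z| inside the
response window.  In parallel, the single-trial *ERP latency* is the time
to the earliest local extremum of the 4–100 Hz-filtered trace that deviates
from the baseline mean by more than 3 baseline SDs (first-peak rule).

Per-trial latencies from the two independently decoded regions are compared
with a two-tailed paired t-test (ACC − S1, alpha = 0.05, mean ± SEM).

## Worked example

Simulate a 96-trial mechanical session with planted latencies
S1 = 150 ms and ACC = 250 ms (30 ms per-trial jitter), run the full
pipeline, and compare regions:

```python
import paindecode as pdz
from paindecode.session import PipelineConfig

proto = pdz.mechanical_protocol(n_trials=96, seed=1)
regions, events, ground_truth = pdz.generate_session(proto)
pdz.write_session("session.h5", regions, events, seed=proto.seed)
result = pdz.run_pipeline(PipelineConfig(), "session.h5", "out/")
for measure, cmp in result["comparisons"].items():
    print(measure, f"n={cmp.n_pairs} mean_diff={cmp.mean_diff*1e3:.1f} ms "
                   f"t={cmp.t_statistic:.2f} p={cmp.p_value:.2g} {cmp.direction}")
```

A representative run prints (seed 1; mean ERP latencies 147.8 ms in S1 and
247.8 ms in ACC):

```
erp n=96 mean_diff=100.0 ms t=17.8 p=2.8e-41 ACC_longer
zpeak n=96 mean_diff=88.5 ms t=8.3 p=4.7e-13 ACC_longer
```

i.e. both the ERP and the decoder's Z-peak latency recover the planted
100 ms S1-lead: nociceptive information reaches S1 before ACC for a sharp
mechanical stimulus.  The same pipeline on a thermal session (equal planted
latencies, withdrawal near 4 s) yields a non-significant Z-peak difference
(e.g. p = 0.51), the expected null for a slowly ramping stimulus.

The same steps are available from the shell:

```bash
paindecode simulate --protocol protocol.yaml --out sim/ --seed 1
paindecode run --session sim/session.h5 --out out/
paindecode compare --table out/latency_table.csv --measure zpeak --out cmp.json
```

## Layout

| module | contents |
| --- | --- |
| `paindecode.synth` | protocols, background LFP, ERP/band-power injection, state-space simulation |
| `paindecode.features` | band-pass filtering, Hilbert envelopes, binned features, channel selection |
| `paindecode.ssm` | Kalman filter, RTS smoother, EM, Z-scoring, onset detection |
| `paindecode.erp` | trial extraction and single-trial ERP peak latency |
| `paindecode.stats` | latency tables and paired region comparisons |
| `paindecode.session` | HDF5 session format and pipeline configuration |
| `paindecode.pipeline` | end-to-end per-trial decoding and reporting |
| `paindecode.cli` | `simulate`, `decode`, `erp`, `compare`, `run` verbs |

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
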