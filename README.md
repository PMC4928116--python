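# fafnet

Analysis pipeline for **frequency-altered feedback (FAF)** experiments:
speakers sustain a vowel while hearing their own voice briefly pitch-shifted
(e.g. +50 or +200 cents), which elicits a rapid compensatory vocal response
and an auditory N1–P2 cortical response. `fafnet` quantifies both, estimates
theta-band functional connectivity between EEG channels with the
synchronization likelihood, and characterizes the resulting brain graphs
with degree-indexed small-world metrics against degree-preserving random
nulls. A paradigm-faithful synthetic-data generator with known ground truth
makes every stage testable end to end, including two-group (patient-like vs
control-like) cohort studies with injected effects.

Intended users: speech-motor-control and clinical-EEG researchers who want a
reproducible, scriptable version of this analysis chain, and methodologists
who need a calibrated testbed for recurrence-based connectivity and graph
metrics.

## The quantities at the core

* **Vocal compensation.** F0 contours are converted to cents,
  `cents = 1200 · log2(F0 / 195.997 Hz)`, epoched −200..+700 ms around each
  shift, and averaged. A response is *valid* when the averaged waveform
  leaves the baseline mean by more than 2 baseline SDs, starting ≥ 60 ms
  after shift onset and lasting ≥ 50 ms; magnitude is the peak deviation
  after the response onset, latency the interpolated first crossing.
* **N1/P2.** EEG is band-passed 1–20 Hz (zero phase), epoched −200..+500 ms,
  artifact-screened (±55 µV against an 80-ms moving average; channels bad
  when flagged in > 20% of segments; files rejected over 10 bad channels),
  re-referenced to the mastoid average, averaged and baseline-corrected.
  N1 is the minimum in 80–180 ms, P2 the maximum in 160–280 ms.
* **Synchronization likelihood (SL).** Signals are delay-embedded,
  `v_i = (x_i, x_{i+L}, …, x_{i+(m−1)L})`; per reference time, cutoff
  distances are set so a fraction `P_ref = 0.01` of candidate times recur.
  SL is the conditional likelihood of *simultaneous* recurrence in both
  signals, symmetrized: `P_ref` for independent signals, 1 for identical
  ones.
* **Small-world metrics.** An SL matrix is binarized by keeping the
  `E = round(K·N/2)` strongest weights for each mean degree `K` (9–14 in
  steps of 0.25), giving clustering `C` and harmonic-mean path length
  `L = n_pairs / Σ 1/l_ij` (finite under disconnection). Against the mean of
  30 double-edge-swap surrogates: `γ = C/C_rand`, `λ = L/L_rand`,
  `σ = γ/λ > 1` indicates small-world organization. Erdős–Rényi references
  `C_rand = K/N`, `L_rand = ln N / ln K` are reported alongside.
* **Group statistics.** Two-way mixed ANOVA (shift magnitude within,
  group between) for vocal responses, Welch t-tests per degree `K` for
  network metrics, Pearson correlations for behavioural/clinical covariates.

## Worked example

One synthetic subject (20 vocalizations × 5 shifts, 32 EEG channels, four
theta coupling blocks at strength 0.6, programmed vocal response 14 cents at
120 ms):

```python
import numpy as np
import fafnet
from fafnet import vocal, erp, sl, graph
from fafnet.config import ParadigmConfig, VocalGroundTruth, EEGGroundTruth, DegreeSweep

cfg = ParadigmConfig(n_vocalizations=20, eeg_channels=32)
vt = VocalGroundTruth(response_magnitude_cents=14.0, response_latency_ms=120.0,
                      jitter_sd_cents=4.0)
blocks = tuple((tuple(range(b, b + 7)), 0.6) for b in (0, 7, 14, 21))
session = fafnet.generate_session(cfg, vt, EEGGroundTruth(theta_blocks=blocks), seed=42)

cents = vocal.hz_to_cents(session.f0_hz)
eps = vocal.epoch_vocal(cents, cfg.f0_sample_rate, session.event_onsets_s,
                        session.event_magnitudes_cents)
for cond, avg in vocal.average_epochs(eps).items():
    r = vocal.detect_vocal_response(avg, eps.times_ms)
    print(f"+{cond:.0f} cents: valid={r.valid}, magnitude={r.magnitude_cents:.1f} cents, "
          f"latency={r.latency_ms:.0f} ms")

epochs, averages = erp.erp_pipeline(session.eeg, cfg.eeg_sample_rate,
                                    session.event_samples_eeg,
                                    session.event_magnitudes_cents,
                                    session.channel_names)
for cond in (50.0, 200.0):
    pk = erp.measure_peak(averages[cond], "P2", "Cz")
    print(f"P2 at Cz (+{cond:.0f} cents): {pk.amplitude_uv:.1f} uV at {pk.latency_ms:.0f} ms")

theta = sl.theta_filter(session.eeg, cfg.eeg_sample_rate)
teps = sl.decimate_epochs(
    erp.segment(theta, cfg.eeg_sample_rate, session.event_samples_eeg,
                session.event_magnitudes_cents, session.channel_names), 250.0)
slm = sl.sl_matrix(teps, exclude=("M1", "M2"))
good = [i for i, n in enumerate(slm.channel_names) if n not in ("M1", "M2")]
table = graph.sweep_degrees(slm.values[np.ix_(good, good)],
                            DegreeSweep(9, 14, 1.0), n_surrogates=10, seed=0)
print(table[["K", "C", "L", "gamma", "lambda", "sigma"]].round(3).to_string(index=False))
```

prints

```
+50 cents: valid=True, magnitude=15.1 cents, latency=134 ms
+200 cents: valid=True, magnitude=15.3 cents, latency=134 ms
P2 at Cz (+50 cents): 6.1 uV at 250 ms
P2 at Cz (+200 cents): 7.8 uV at 231 ms
   K     C     L  gamma  lambda  sigma
 9.0 0.463 1.550  1.575   1.007  1.564
10.0 0.463 1.499  1.382   1.004  1.376
11.0 0.478 1.453  1.335   1.001  1.334
12.0 0.485 1.417  1.205   1.001  1.204
13.0 0.501 1.382  1.146   1.001  1.144
14.0 0.520 1.349  1.096   1.000  1.096
```

The recovered vocal magnitudes (≈15 cents vs 14 programmed, the small excess
being the peak rule's noise bias) and P2 peaks (programmed 4.5/6.0 µV at
256/234 ms plus theta-background noise) land where the generator put them,
and `σ > 1` across all `K` reflects the block-coupled (modular, hence
clustered) theta sources.

The same pipeline is available from the shell:

```bash
fafnet simulate --seed 1 --out session/
fafnet vocal --f0 session/f0.tsv --events session/events.tsv --out results/
fafnet erp --eeg session/eeg.tsv --events session/events.tsv --out results/
fafnet connectivity --eeg session/eeg.tsv --events session/events.tsv --out results/
fafnet network --sl results/sl_50.tsv --seed 1 --out results/
fafnet cohort-study --small --seed 1 --out cohort/
```

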