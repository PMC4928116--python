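# Methods

This note documents the models and procedures implemented in `fafnet`, the
assumptions behind the synthetic-data generator, the numerical choices that
were genuinely open, and the limitations that follow from them.

## Paradigm and synthetic sessions

A session consists of `n_vocalizations` sustained phonations of 5–6 s,
separated by 2–3 s rests. Each vocalization carries
`shifts_per_vocalization` pitch-shift events of 200 ms; the first occurs
500–1000 ms after vocal onset and subsequent ones follow at inter-stimulus
intervals of 700–900 ms. Shift magnitudes (+50/+200 cents by default) are
assigned by shuffling a globally balanced multiset, so per-magnitude trial
counts are exactly equal (100 + 100 with the defaults) while the ordering
within vocalizations is random. Within each vocalization the delays are
redrawn until the last event's full analysis epoch (+700 ms) fits inside the
phonation; configurations whose *minimal* schedule cannot fit raise a
configuration error naming the violated constraint. Event onsets are snapped
to the EEG sample grid so vocal and EEG epochs align exactly. All randomness
flows through one seeded `numpy` generator in a fixed order
(schedule → voice → EEG), so identical seeds give bit-identical sessions.

The study this paradigm emulates published no generative description of its
signals. Everything below the event schedule is therefore a stand-in chosen
for plausibility and testability, not a reconstruction:

* **Voice.** The F0 contour is `baseline_f0 · 2^(c(t)/1200)` where `c(t)` is
  an AR(1) process in the cents domain with stationary SD
  `jitter_sd_cents` (default 5) and correlation time 10 ms, plus, for each
  shift, a raised-cosine excursion (80 ms rise and fall, plateau of one
  shift duration) of the programmed magnitude opposing the shift sign,
  starting at the programmed latency. Unvoiced gaps between vocalizations
  carry F0 = 0. The 10-ms correlation time models cycle-level pitch
  perturbation, which dominates the measured baseline SD of sustained
  phonation; slow vocal wander (hundreds of ms to seconds) is deliberately
  not modelled — see *Limitations*.
* **EEG.** Gaussian white noise per channel (default SD 5 µV), plus, on
  every scalp channel, a two-component event-related template: Gaussian
  deflections at the programmed N1 (negative, width 15 ms) and P2 (positive,
  width 20 ms) latencies, per shift magnitude. Theta-band (3–8 Hz) activity
  is built from unit-variance band-limited noise sources: channels inside a
  coupling block mix a shared source with an independent one as
  `√s·common + √(1−s)·own` (strength `s ∈ [0, 1]`); other scalp channels get
  independent theta. The montage always ends in the mastoid pair M1/M2,
  which carry noise only (no ERP, no theta) so that mastoid re-referencing
  is exact in the noiseless limit. Artifact transients are 300-ms biphasic
  pulses — two opposite-polarity Gaussian lobes (SD 15 ms) — injected at
  chosen (epoch, channel) positions; smooth 300-ms shapes would be tracked
  by the 80-ms moving average and never trip the ±55 µV rule, so sharp lobes
  are required for the rejection machinery to be exercisable at realistic
  amplitudes.

## Vocal response quantification

Cents conversion uses the fixed reference G4 = 195.997 Hz. Epochs span
−200..+700 ms; a trial is excluded when its window leaves the recording,
contains unvoiced samples, or exceeds ±600 cents anywhere (both thresholds
configurable) — a deterministic surrogate for the study's visual screening.
Averaged per condition, the response is detected with the 2-SD rule:
baseline mean and SD come from the averaged waveform's −200..0 ms samples;
threshold crossings (|deviation| > 2 SD) closer than 10 ms are merged; an
excursion is a valid response when it starts ≥ 60 ms post-onset and lasts
≥ 50 ms. Magnitude is the largest |deviation| from the response onset to the
epoch end (the excursion marks the onset; the peak may fall beyond the
crossing run); latency is the linearly interpolated first threshold
crossing. When several excursions qualify, the earliest wins, ties broken
toward the larger magnitude. A perfectly constant waveform yields an
invalid-response result; a constant baseline with post-onset structure is
handled with a tiny SD floor so the threshold stays defined.

Two readings of "baseline variability" are provided.
`baseline_variability(mode="average")` is the temporal SD of the averaged
baseline — the quantity the detection threshold uses; it shrinks roughly as
1/√n with trial count. `mode="trials"` pools the baseline samples of all
kept trials and recovers the per-trial jitter SD itself; this is the index
used when correlating vocal variability with response magnitude across
subjects, since the averaged-baseline SD mostly reflects trial count.

**Bias of the peak rule.** The magnitude estimator takes a maximum over
~600 ms of an averaged waveform whose noise SD is `σ_avg`; its expected
excess is ≈ 2–2.5 `σ_avg`. With 200 trials and 3 cents of jitter that is
≈ 0.5 cents — negligible for 15–30-cent responses but a systematic ~10%
overestimate of a 5-cent response. The parameter-recovery suite therefore
runs at 2 cents of jitter, where recovery is within 10%/20 ms in ≥ 95% of
seeded runs across the whole magnitude grid; at 3 cents the smallest
magnitude fails its relative tolerance for this structural reason.

## ERP pipeline

Fixed order: zero-phase 4th-order Butterworth band-pass 1–20 Hz (forward–
backward, so peak latencies are undistorted) → segmentation −200..+500 ms
(events whose window leaves the recording are dropped and logged) → artifact
detection → channel/file rules → mastoid re-referencing → averaging of
retained epochs → baseline correction → peak measurement.

A channel-in-epoch is flagged when any sample deviates from the channel's
centered 80-ms moving average by more than 55 µV; the moving average uses
edge truncation (shorter effective windows at epoch edges). A channel is bad
when flagged in more than 20% of epochs; an epoch is rejected when any
*non-bad* channel is flagged in it (bad channels no longer veto epochs); a
file is rejected beyond 10 bad channels. The flagged/rejected sets are
exposed as an audit structure instead of the study's manual re-inspection.
Note two consequences of this rule set, both deliberate: a mid-epoch step of
height H produces a residual of only ≈ H/2 (a 100-µV step is *not* flagged
mid-epoch, but is at epoch edges where truncation breaks the symmetry), and
retained-trial fraction is monotone in contamination only below the
bad-channel rescue threshold.

N1 is the signed minimum in 80–180 ms, P2 the signed maximum in 160–280 ms,
at a named electrode; flat stretches resolve to the earliest sample, and bad
electrodes yield missing values rather than errors. No sign constraint is
enforced on measured peaks.

## Synchronization likelihood

Delay embedding `v_i = (x_i, x_{i+L}, …, x_{i+(m−1)L})`. For reference time
`i`, candidates are `j` with `w1 < |i−j| < w2`; per signal, the cutoff
distance is the smallest radius capturing a fraction `P_ref` of candidates
(the ⌈P_ref·n⌉-th smallest Euclidean distance; ties round the fraction up).
The SL accumulates, over reference times, the fraction of X-recurrences that
are simultaneously Y-recurrences, in both directions, and averages the two —
giving 1 for identical signals and `P_ref` (=0.01) for independent ones.
Constant series are rejected as degenerate.

The default embedding for theta at 250 Hz (after anti-aliased FIR decimation
from 1 kHz, configurable off) follows common practice for band-limited EEG:
`L = fs/(3·f_high)` ≈ 10 samples, `m = 1 + ⌈3·f_high/f_low⌉ = 9`,
`w1 = 2·L·(m−1)`, `w2` capped at the series length. For short epochs this
recipe leaves too few candidates at `P_ref = 0.01`; `EmbeddingParams.for_band`
then reduces `m` (and relaxes `w1` to one embedding span) until at least one
reference time has ⌈1/P_ref⌉ candidates. Reference times without enough
candidates are skipped; with very short epochs the achievable recurrence
fraction is ⌈P_ref·n⌉/n > P_ref, so the independence floor sits slightly
above 0.01 — a known small-sample property, irrelevant for within-study
contrasts computed at a fixed epoch length.

`sl_matrix` computes all channel pairs per epoch by precomputing per-channel
recurrence masks and reducing the pairwise step to one matrix product, then
averages SL matrices over retained epochs. Bad or excluded channels (the
mastoid reference pair, in the cohort pipeline) keep NaN rows/columns. The
emulated study's text once mentions thresholding "partial correlation
coefficients"; everything else there and here operates on SL values, and
this package thresholds SL.

## Graphs and small-world metrics

For each mean degree `K` (default 9–14 in 0.25 steps) the binary graph keeps
the `E = round(K·N/2)` largest off-diagonal weights — non-integer `K` is
realizable only as a mean degree via the edge count, which also guarantees
equal edge counts across subjects and groups at each `K`. Ties at the cut
break lexicographically, so graphs are deterministic.

Clustering: `c_i = E_i / (k_i(k_i−1)/2)`, zero for `k_i ≤ 1`; `C` is the
node mean. Path length: harmonic mean of shortest path lengths over all
unordered pairs with `1/∞ = 0`, applied to all graphs (connected or not) for
consistency; an edgeless graph raises. Nulls: 30 surrogates by double-edge
swaps — pick two edges, orient randomly, rewire unless a self-loop or
duplicate would arise — with 10·E accepted swaps per surrogate
operationalizing "swap until randomized" (configurable); degree sequences
are preserved exactly. `γ = C/C_rand`, `λ = L/L_rand`, `σ = γ/λ` use the
empirical surrogate means, since degree-matched nulls are the appropriate
comparison when degree distributions are non-Gaussian; the theoretical
Erdős–Rényi values `K/N` and `ln N/ln K` are reported alongside, and a ring
lattice with matched edge count is available as the ordered reference. A
swap-saturated graph (e.g. complete) returns its surrogates unchanged with a
warning.

## Group statistics and the cohort driver

The two-way mixed ANOVA uses the classical univariate sums of squares
(between-group effect tested against subjects-within-groups; within-subject
effect and interaction against the within-subject residual), requires a
complete within-factor design per subject, and tolerates unequal group
sizes. No sphericity correction is applied: the within factor has two
levels, where sphericity is trivial. Group contrasts of network metrics are
Welch t-tests at every `K`, uncorrected by default to mirror per-K
significance marking, with an optional Benjamini–Hochberg switch.

`cohort_study` simulates a patient-like and a control-like group end to end.
Per subject it draws vocal magnitude (group mean, plus a component
proportional to the subject's jitter SD — inducing the positive
variability–magnitude correlation), response latency, N1/P2 amplitudes (the
patient-like P2 is reduced by a fixed deficit plus a disease-duration slope,
durations 2–20 years), and a theta coupling strength applied to four channel
blocks. It then runs every pipeline and the statistics above, drops subjects
with an invalid vocal response in any condition from the vocal ANOVA
(logging the count), and reports group-difference directions and
significance flags. Defaults mirror the emulated study's scale (28 per
group, full paradigm, 64 channels; vocal group means 16.3 vs 12.2 cents);
`CohortConfig.small()` is a desk-scale preset (5 per group, 6 vocalizations,
32 channels, K ∈ {9..14}, 5 surrogates) with deliberately strong injections,
used to verify that injected effects propagate end to end with the right
signs — it makes no claim about clinical effect sizes, which at realistic
SDs are not direction-stable at this n.

## Numerical choices

* Filters: 4th-order Butterworth SOS, `sosfiltfilt`; decimation via
  zero-phase FIR.
* Peak/latency ties: earliest sample. Binarization ties: lexicographic.
* Vocal latency: linear interpolation between the samples bracketing the
  2-SD crossing.
* Excursion merging: crossings separated by < 10 ms are merged before the
  50-ms duration rule.
* The SL recurrence fraction rounds up to the nearest achievable count.
* Seeds: every public entry point takes a seed or `numpy` Generator;
  subject-level streams in the cohort driver come from `SeedSequence.spawn`.

## Problem sizes used in validation

The test suite validates SL anchors on 2048–4096-sample series (50
independent pairs for the floor), graph oracles on 200 random graphs with
N ≤ 8, degree preservation across 30 surrogates of a 64-node graph, vocal
recovery on 100 sessions per grid point (full 40-vocalization paradigm),
ERP recovery on 100 six-channel sessions (100 epochs per condition, noise
SD 2 µV), test calibration on 2000 null simulations, and effect-direction
propagation on 20 seeded small-preset cohorts.

## Limitations

* Generator realism: white EEG background (no 1/f spectrum, no ocular/EMG
  structure beyond the injected transients), spatially uniform ERP topography
  with gain 0 at the mastoids, theta sources with block-uniform coupling, and
  a single fast AR(1) jitter process for voice. Passing recovery tests shows
  the pipeline is correct under these conditions, not that it is robust to
  everything real data do.
* The 2-SD vocal validity rule is fragile against slow F0 drift: drift
  excursions of the *averaged* contour cross a threshold that shrinks with
  trial count at a rate that does not, producing false early "responses".
  Real contours contain such drift; users should inspect borderline latency
  estimates.
* The peak magnitude rule overestimates small responses by ≈ 2–2.5 averaged
  baseline SDs (max-of-noise bias).
* SL on 700-ms epochs requires a reduced embedding dimension and yields a
  floor slightly above `P_ref`; absolute SL values are not comparable across
  different epoch lengths.
* Downward pitch shifts are supported by the sign conventions but not
  exercised; no source localization, channel interpolation, weighted-graph
  metrics, or three-way electrode ANOVA.
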