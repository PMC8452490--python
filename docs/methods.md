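# Methods

`meapheno` turns per-electrode spike trains from 24-well micro-electrode-array
(MEA) plates — 12 electrodes per well, 10-minute recordings — into a 17-column
per-well parameter table, applies explicit quality-control rules, and runs the
cohort statistics used to compare neuronal-network phenotypes. A synthetic
multiwell generator with full ground truth serves as the test bed. This note
records the models, the tunable parameters and their defaults, the numerical
choices, and what the synthetic validation does and does not show.

## Spike detection (optional front-end)

Raw extracellular traces (10 kHz) are band-limited with a second-order
high-pass Butterworth at 100 Hz and a fourth-order low-pass Butterworth at
3500 Hz, applied zero-phase (forward-backward, `sosfiltfilt`). Zero-phase
filtering avoids latency shifts at the cost of bit-exact equivalence with a
causal acquisition chain; the effective amplitude response is the squared
single-pass magnitude.

Spikes are threshold crossings of |x| at 4.5 noise standard deviations. The
noise SD is estimated robustly as `median(|x|)/0.6745` because the plain SD is
inflated by the spikes themselves. Both polarities are detected; within a
2 ms dead time the sample of largest |x| is kept as the event and its signed
value recorded as the amplitude. The SD estimator and the dead time are
assumptions (configurable), not acquisition-vendor facts.

## Peak-train I/O

Timestamps are float64 seconds from recording start, strictly increasing;
intervals are half-open `[start, end)`. Two dialects:

- `mcs_mat`: MATLAB file with one `ptrain_<row><col>` variable per electrode
  (3×4 grid; electrode *k* → row `(k-1)//4+1`, column `(k-1)%4+1`), each an
  N×2 array of `[sample index at sampling_rate, amplitude in µV]`, plus scalar
  `sampling_rate` and `duration_samples`. Sample indices are integral, so this
  dialect is exact only to one sample (0.1 ms); the writer bumps colliding
  indices by one sample because two events cannot share a sample.
- `portable_hdf5`: `/well/electrode_k/{timestamps,amplitudes}` in seconds/µV
  with recording and metadata attributes; lossless.

A missing electrode reads as an empty train in its grid slot (logged), because
silent electrodes still count in all per-well averages (the all-electrode
rule: restricting analysis to active electrodes inflates every rate
parameter).

## Single-channel bursts

Max-interval ("string") method: a burst is a maximal run of at least
`min_spikes` = 5 spikes whose inter-spike intervals are all ≤ `max_isi` =
100 ms (inclusive at the boundary). Burst start/end are the first/last spike
times. Defaults are the common operating point for multi-unit MEA data and
are configurable per recording; per-run settings are serialized with results
so a settings sweep (suboptimal vs. tuned detection) is reproducible.

Well-level statistics: BR = bursts/min averaged over all 12 electrode slots;
BD and BSR average over every burst in the well; IBI pools per-electrode
consecutive-burst gaps; PRS = percentage of spikes outside every burst.
Undefined quantities (no bursts; a single burst for IBI) are NaN with flags.

## Network bursts

The well-wide spike train is binned at 25 ms. Contiguous bins whose count
exceeds the rate threshold form episodes; each episode is tightened to its
first/last spike; episodes closer than `merge_gap` = 0.3 s are merged; an
episode is a network burst (NB) only if strictly more than 25 % of the 12
channels participate, where a channel participates only if it contributes at
least 3 spikes (a lone stray spike does not make an electrode part of a
network event).

Numerical choices, and why:

- The default rate threshold is an absolute floor of 1.5 spikes/bin
  (60 spikes/s well-wide). A peak-relative term
  (`peak_fraction × peak rate`) is available but off by default: a high
  relative threshold strands the low-rate tail of an NB sub-threshold and
  fragments one burst into several, which inflates NBR and CV_NIBI — the
  exact failure mode that per-recording tuning is meant to avoid.
- `merge_gap` = 0.3 s reattaches tail fragments; it is an order of magnitude
  below any realistic inter-NB interval (seconds to tens of seconds), so it
  cannot bridge distinct NBs.
- The participation inequality is strict (3/12 = 25 % is *not* enough),
  matching the "> 25 %" recommendation.
- For developmental series, `settings_from_latest_div` freezes the threshold
  resolved on the latest-DIV recording and applies it backward.

NBR = NBs/min; NBD = mean NB duration; NIBI = mean end-to-next-start gap;
CV_NIBI = sample SD/mean of those gaps (n−1 denominator). Fewer than two NBs
leaves NIBI/CV_NIBI NaN, flagged.

## Network-burst shape, rise and decay time

Per NB, the well-summed rate is binned at 5 ms from onset over a window
(default 1.5× the longest NB) plus a 0.1 s pre-onset margin, and averaged
over NBs; optional peak normalization. The pre-margin matters because
detection trims an NB's start to its first supra-threshold spike, which
already sits above baseline — without the margin the rise is invisible.

RT is the time from the last upward crossing of 10 % of peak to the (first)
peak bin; DT the time from the (last) peak bin to the downward crossing of
the same level, linearly interpolated. The downward crossing is taken at the
*last* supra-level bin: on a clean unimodal profile this coincides with the
first downward crossing, but it is immune to single noisy bins dipping early
— with a dozen NBs averaged at 5 ms bins, tail bins are Poisson-noisy and a
naive first-crossing rule collapses DT at low firing rates. Flat-topped
profiles use the first/last peak bin for RT/DT and are flagged
`DEGENERATE_PLATEAU`; a peak on the window edge leaves both NaN.

## Connectivity

The cross-correlogram of trains *a*, *b* counts lag differences
`t_b − t_a` in 10 ms bins over ±0.5 s, normalized by `sqrt(N_a·N_b)` so
identical trains score 1 at zero lag, and clipped at 1 so pathological
coincidence multiplicity cannot break the unit bound. C_0 is the zero-lag
value ("synchronization"), C_peak the maximum over lags ("correlation");
C_peak ≥ C_0 by construction. All 66 unordered pairs are evaluated; silent
pairs score 0.

Functional links: each pair is a link iff its C_peak exceeds the
`1 − α` quantile (α = 0.05) of C_peak pooled over surrogate wells built by
dithering every spike with an independent uniform ±0.5 s offset (preserves
rates, destroys fine-timescale correlation). The seed is mandatory; link
weight = mean C_peak over links. These definitions are stated contracts of
this package — the zero-lag/peak split, the dither width and the pooled null
are choices, configurable in `ConnectivitySettings`.

## Quality control and pooling

Inclusion criteria (defaults, values exactly at a threshold are kept):
MFR ≥ 0.1 spikes/s, BR ≥ 0.4 bursts/min, NBR ≥ 1 NB/min, active electrodes
≥ 80 % (active = ≥ 1 spike/min, a configurable assumption), mean NB channel
participation ≥ 25 %, NBs present at DIV 27. These activity criteria describe
healthy *control* networks and are applied to control wells only by default
(`control_only_activity_criteria`): a patient well must not be dropped for
expressing its hypoactive phenotype. Visual culture quality (density,
clumping) cannot be judged from spike data and enters as a curator-provided
`manual_exclude` metadata column. Every exclusion is logged once with
machine-readable reason codes.

Wells are pooled over the stable window DIV 27–35; discarded early-DIV rows
and coating mixtures are warned about. `batch_sufficiency_check` warns below
12 wells or 2 MEA batches per line. A decline of network parameters across
DIVs is flagged (never auto-excluded) by `flag_development_reduction`,
because the quantitative criterion for that exclusion is a curator decision.

"Channels in NB" is interpreted as the mean participation across a well's
NBs (a per-NB reading is also computable from the NB list).

## The 17 parameters

MFR, PRS, BR, BD, BSR, IBI, NBR, NBD, NIBI, CV_NIBI, RT, DT, C_0, C_peak,
link weight, number of connections, and the NB shape peak rate (the maximum
of the averaged shape profile, spikes/s) as the burst-shape summary. The
exact membership of the seventeenth slot is an interpretation; the table is
assembled from named columns, so any subset can be selected per analysis.

## Cohort statistics

- **Stability**: CV% = 100·SD/mean within each line, summarized as mean ± SD
  across lines; parameters above 50 % are flagged variable.
- **PCA**: column-wise Z-scoring then PCA; sign fixed by making each
  component's largest-magnitude loading positive; reconstruction from all
  components is lossless.
- **Batch variance**: per parameter, a one-way linear model with the batch
  factor; R² = SS_between/SS_total; Benjamini-Hochberg adjustment across
  parameters. The "combined" share fits the same one-way model to all
  parameters' Z-scored values stacked into one response — an interpretation
  of "variance explained on all parameters combined"; it equals the mean
  per-parameter R² when batch moves parameters coherently and shrinks toward
  zero when per-parameter batch profiles oppose each other.
- **Group comparisons**: two groups → Mann-Whitney U with Bonferroni across
  the tested parameters; three or more → one-way ANOVA + Tukey when every
  group passes a Kolmogorov-Smirnov normality gate, otherwise Kruskal-Wallis
  with Dunn's post hoc (rank z statistics with tie correction,
  Bonferroni-style adjustment over pairs; written in-package because no
  installed library provides Dunn's test).
- **Burst-shape comparison**: per-bin two-sample t tests on aligned profiles
  with Holm-Sidak family correction across bins.
- **Power**: two-sample noncentral-t approximation (statsmodels
  `TTestIndPower`); `wells_required` returns the smallest integer n reaching
  the target power (d = 1.21, α = 0.05, power = 0.8 → 12 wells/group). The
  t-approximation is also used where the comparison itself is rank-based —
  the standard asymptotic-relative-efficiency shortcut.

## Synthetic multiwell generator

Each well is generated as:

- **NB onsets**: gamma-renewal process, mean interval `60/nb_rate`, CV
  `nb_cv`; intervals are floored at `nb_duration + 0.3 s` so NBs stay
  disjoint.
- **Intra-NB activity**: each channel participates with probability
  `participation`; a participating channel emits
  Poisson(`intra_nb_rate · nb_duration`) spikes whose offsets follow a gamma
  density (shape `1 + rise_tau/decay_tau`, scale `decay_tau`) truncated at
  `nb_duration`. With the preset choice `rise_tau = decay_tau =
  nb_duration/5` this is a shape-2 gamma truncated at five scale lengths:
  right-skewed (fast rise, slow decay) and, importantly, the truncation pins
  the realized and detected burst span to the nominal duration, making
  duration recovery well-defined.
- **Single-channel bursts**: stereotyped 8-spike runs at ~12 ms ISI at
  `channel_burst_rate` per channel, placed away from NB windows and from each
  other across channels — they model *isolated, asynchronous* events, so
  accidental cross-channel coincidences do not masquerade as network events.
- **Background**: independent Poisson spikes per channel; lognormal
  amplitudes with random polarity (mostly negative lobes).

Every spike is attributable to exactly one component in the recorded ground
truth, and identical seeds give bit-identical wells.

Preset operating points (10-minute wells, defaults of `PhenotypeParams`):
the control preset is calibrated so the *pipeline's* estimates land near a
typical healthy operating point — ≈3.5 spikes/s MFR, ≈4.8 bursts/min,
≈3.2 NB/min, NB duration ≈1.28 s, inter-NB CV ≈0.4. The `melas_like` preset
shifts only toward reduced spiking and network bursting, weaker channel
participation, shorter bursts and a larger random-spike share; `ks_like`
only toward fewer but longer network bursts with a slower decay. Directions,
not magnitudes, are the modeled claim.

Cohorts add multiplicative lognormal effects on the rate-generating
parameters (`nb_rate`, `intra_nb_rate`, `background_rate`): one shared
"activity" multiplier per MEA batch and per astrocyte batch
(`batch_effect_sd` = 0.2 log-SD) and one per well (`well_noise_sd` = 0.2).
A single shared multiplier per batch is deliberate: batch quality moves rate
parameters coherently, which is what makes a stacked combined variance share
meaningful; independent per-parameter multipliers would cancel in the
stacked model. Duration- and regularity-type parameters carry no batch
effect by design, so the combined share over all 17 measured parameters is
diluted relative to the rate-derived subset (MFR, BSR, NBR) — batch-recovery
checks therefore compare the measured rate-derived combined share against
the cohort's *realized* generative share computed from the ground-truth rate
parameters.

## What the synthetic validation shows — and does not

Passing tests show that the detectors agree exactly with brute-force
enumeration, that the pipeline recovers known generative rates, durations
and regularity within stated tolerances (NB rate and duration within 10 %,
inter-NB CV within 0.1, over 20 ten-minute wells), that QC reproduces a
designed inclusion pattern exactly, that a ~50 % generative batch share is
recovered within 10 points (and a zero share below 5 %), that the disease
presets separate with Bonferroni-corrected significance and a PCA silhouette
above 0.2 at 12 wells per line, and that the planning module returns
12 wells/group at d = 1.21.

The generator does *not* emulate: electrode-distance-dependent correlation
(the 300 µm geometry), NB propagation and latency structure, reverberating
super-bursts, development over DIV (beyond assigning a DIV label),
non-stationary drift within a recording, or biophysical spike waveforms
beyond a single biphasic template. Agreement on synthetic data therefore
validates the *analysis machinery*, not claims about any particular culture.

## Problem sizes and determinism

The shipped checks use desk-scale sizes chosen to exercise the statistics at
their intended operating points: 20 wells for control recovery, 32 wells ×
4 batches (effect) and 36 wells × 2 batches (null) for batch variance,
3 lines × 12 wells for phenotype discrimination, 300–1000 random trains and
40–100 random pairs for oracle equivalence. All randomness flows from
explicit seeds; `scripts/acceptance.py` derives every sub-seed from its
`--seed` argument and recomputes all reported values at run time.

## Known limitations

- The `mcs_mat` dialect is defined by this package's documented fixture; the
  layout of any particular vendor export must be mapped onto it (a reader
  isolated behind `read_peak_trains` is the single point of adaptation).
- The MELAS-like burst-duration effect is the weakest modeled direction; at
  12 wells/group it reproduces with Bonferroni significance under the default
  conditions but sits near the detection limit, and individual reruns at
  other seeds can miss it — consistent with it being the subtlest printed
  contrast.
- With few batches, the realized between-batch spread is itself a small-
  sample draw; batch-share recovery is therefore assessed against the
  realized generative share, not the asymptotic 50 %.
- Dunn's test uses the normal approximation for pairwise rank statistics;
  at very small group sizes its p-values are approximate.
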