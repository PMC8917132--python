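# Methods

`swrkit` implements the statistical pipeline used to test whether transient
inhibition arriving just before hippocampal sharp-wave ripples (SWRs) sets
the timing of CA1 pyramidal-cell activity during the events. This note
documents the models, the conventions and defaults, what the synthetic
generators do and do not emulate, and the design decisions taken where the
procedure was genuinely open.

## Conventions

Time is seconds (float64) internally; milliseconds appear only in
configuration and display. Sample indices are 0-based; event intervals are
half-open `[onset, offset)`. The SWR *onset* — the leading edge-threshold
crossing of the detection statistic — is `t = 0` for every downstream
alignment. All operations are pure: inputs are never modified, and every
stochastic routine is a deterministic function of its inputs and a seed.

## SWR detection

Two detectors cover the two recording pathways.

**Patch-session detector** (`detect_swr_patch`). The LFP is band-passed
100–250 Hz (Chebyshev type-I, order 4, 1 dB ripple, applied
forward–backward so event timing carries no filter delay). The envelope is
the rectified filtered trace smoothed by an 8-ms moving average; events are
taken where it exceeds `threshold_sd` (default 3) baseline SDs. "Baseline
noise" is estimated robustly (MAD × 1.4826 of the filtered trace) and
re-estimated once with detected events excluded, so the threshold does not
depend on event content. Events closer than 30 ms are merged. A practical
limit of this criterion: a 3-SD envelope threshold crosses partway up a
gradually rising burst, so detected onsets lag true envelope starts by
roughly 10–15 ms for realistic burst shapes.

**Probe detector** (`detect_swr_probe`). The signal is brought to 1250 Hz,
band-passed 130–200 Hz (fourth-order Chebyshev), squared, smoothed (8 ms)
and z-scored. The baseline mean/SD are iteratively re-estimated with
detected events (spans around peaks ≥ `peak_sd`) excluded; sub-peak noise
excursions stay in the baseline so the SD estimate is unbiased. Peaks must
reach `peak_sd` (default 5) SDs; boundaries are the surrounding `edge_sd`
(default 2) crossings — no merge step, so brief noise excursions fall to
the 20-ms duration floor. Durations outside [20, 200] ms are discarded;
events co-detected on an optional noise channel are treated as artifacts.
Both detectors threshold in SD units and are therefore exactly invariant
to amplitude scaling. On synthetic bursts at 10× noise SD the probe
detector reaches 100% recall with ~4–5 ms mean onset error; occasional
short false positives at the duration floor are what the noise-channel
exclusion and the programmatic QC (`swr_qc`: minimum ripple-band power,
maximum line-noise ratio) are for. Sessions entering downstream analyses
must contain at least 30 SWRs (`require_min_events`).

## Intracellular (Vm) measurements

Spikes are detected as the peaks of excursions above −20 mV. For
subthreshold averaging, spikes are truncated: the trace is smoothed with a
1-ms moving average, leading edges are the first samples where the rate of
change exceeds 4 V/s, and each edge is linearly interpolated until the
trace first returns below the edge value. For complex spikes (several
edges within ~30 ms) each edge inside an already-interpolated span is
absorbed by that span — the segment is anchored at its own edge value; the
alternative anchoring (each segment re-anchored at the previous edge's
value) differs only in the rare case that the inter-spike trough sits
above the first edge value. A final guard interpolates any residual
supra-threshold excursion, so the output is guaranteed below −20 mV, and
the whole operation is idempotent.

Per SWR, with baseline `B` = mean Vm over [−2000, −1000) ms before onset:

* **ΔVm_pre** — Vm minimum within [−50, 0) ms is located (ties toward the
  earlier time), Vm is averaged over ±25 ms around it (the window may
  extend past onset; it is not clipped), and `B` is subtracted. Negative
  values mean pre-SWR hyperpolarization. The measure is invariant to
  adding any constant to the trace.
* **Depolarization peak time** — time of the Vm maximum within
  [−20, +120] ms, ties toward the earlier time.
* Events without full [−2000, +120] ms coverage are skipped with a reason
  code rather than padded, avoiding baseline bias at recording edges.

Voltage-clamp currents convert to conductances as
`g(t) = (I(t) − I_base)/(V_hold − E_rev)` with the same baseline window;
pA/mV gives nS directly. Defaults: EPSG at −70 mV holding vs 0 mV
reversal, IPSG at +10 mV vs −90 mV.

**Triplet order test.** For three simultaneously recorded cells, each SWR
with all three measured ranks the cells by depolarization peak time
(position 1 = earliest); the order of their ΔVm_pre values (largest, i.e.
least hyperpolarized, first) is one of six permutations. Observed order
frequencies are compared against a null built by randomly exchanging the
ΔVm_pre values across the three cells within each SWR (default 10,000
draws). Because six correlated frequencies are inspected at once, the
`flag` column marks excursions beyond a *simultaneous* (Bonferroni 0.05/6
per order, two-sided) band of the null — with per-order 95% bands the
probability that some frequency strays outside under exchangeability is
~20%, which would make the flags uninterpretable. The per-order 95% band
is also returned (`lo95`/`hi95`) for display. Percentiles of the discrete
permutation distribution use conservative quantiles (`lower`/`higher`)
and equality counts as inside.

**Pairwise correlations.** Per cell pair, Pearson r of ΔVm_pre and of
depolarization peak times over shared SWRs (two-sided t-test of the
coefficient); across pairs, second-level correlations of the ΔVm_pre r
against the peak-time r and against anatomical pair distance.

## Extracellular quintile/latency analysis

Pre-SWR-firing interneurons are found from peri-event time histograms
(2.5-ms bins, window ±200 ms — the span is a package default; only the bin
width is prescribed): cells whose peak firing time lies more than 1.5 SDs
below the population mean peak time (optionally intersected with the k
most negative). Single-SWR rates use a Gaussian kernel of 15 ms FWHM
(σ ≈ 6.37 ms), unit mass per spike; the pre-SWR rate is the kernel-rate
mean over the 30 ms before onset, computed either on a rate grid
(`smoothed_rate` + `pre_swr_rate`) or in closed form via Gaussian masses
(`pre_swr_rates`), the two agreeing to discretization error.

SWRs are ranked by pre-SWR rate and split into quintiles (Q1 = highest;
stable sort on (rate, index) breaks ties; group sizes differ by ≤ 1).
First-spike latency is measured from onset to the cell's first spike
inside [onset, offset]; rank order is the cell's normalized position among
the SWR's participating pyramidal cells, `(position − 1)/(n − 1)`. Cells
with fewer than 10 spikes over the relevant events are excluded. The
Q1−Q5 mean-latency difference is tested against a null of 500 latency
shuffles across quintile labels (group sizes preserved); significance is
the observed value falling outside the conservative 2.5–97.5 percentile
band. On exchangeable data the empirical flag rate is ~4.8% (nominal 5%);
an injected 10-ms Q1−Q5 gap at 300 SWRs is detected in ~100% of runs.

## Poisson hidden Markov model (sequence structure)

Spikes of N pyramidal cells within one SWR are binned into nonoverlapping
15-ms bins, giving a T×N count sequence. The network occupies one of M
latent states per bin with first-order Markov transitions; within a state,
counts are independent Poisson with state-specific means (`Lambda`, N×M).
Default M = 15; a twofold cross-validation helper (`cv_select_states`) is
provided for choosing M.

Fitting is EM over multiple sequences with exact log-space
forward–backward (batched over equal-length sequences); the training LL is
non-decreasing every iteration to numerical tolerance (1e-8 relative,
asserted in tests). Initialization assigns bins to random states for
`Lambda` (plus 25% jitter), near-uniform transitions with a 0.1
self-transition bias, uniform initial distribution, best of 5 restarts
(tol 1e-6 relative ΔLL, ≤ 500 iterations). Rates are floored at 1e-4
counts/bin. Per-sequence log-likelihoods are normalized by T. The forward
pass is verified against brute-force path enumeration and an independent
library implementation.

**Cross-quintile comparison.** An HMM fitted on one quintile's sequences
is evaluated on the other; the statistic is
`LL(Q_test) − LL(Q_train)` (mean normalized LLs), computed in both
directions. Negative values mean the model fits its own training quintile
better. The control refits after randomly reassigning sequences to groups
(sizes preserved), and the one-sided p-value is the share of shuffles with
a mean difference at or below the observed one.

## Poisson mixture (interneuron ensembles)

Per-SWR spike-count vectors across N interneurons are modeled as draws
from one of M latent ensembles, each with expected-count vector λ_j and
weight π_j. EM with the same floor/restart conventions as the HMM;
responsibilities give soft assignments, argmax gives reported labels.

**Choosing M.** 20-fold cross-validation over M = 2..30: fit on 19 folds,
deviance (−2 × mean per-SWR held-out LL) on the held-out fold, averaged
over folds. CV fits use 2 restarts, tol 1e-4, ≤ 150 iterations — one
restart regularly stuck in local optima at the true M, flattening the
curve's elbow and biasing selection upward. The deviance curve is
summarized by a descending exponential `a·exp(−bM) + c` (least squares,
b > 0) and M* is the grid value maximizing its curvature
`κ = |d″|/(1 + d′²)^{3/2}` — the point just before the plateau. On
strongly separated 3-ensemble data M* lands in {3, 4} essentially always;
the criterion tends to overshoot sharp elbows by about +1 because κ peaks
where the fitted slope is ~1/√2 in the curve's own units (curvature is not
scale-free; normalizing the curve first traded this bias for
under-selection and was not adopted). A non-descending or degenerate curve
falls back to the deviance minimum with a warning.

**Surrogate co-firing test.** With M* fixed, each CV fold compares the
held-out fold's mean per-SWR LL with that of surrogate folds in which
every interneuron's counts are permuted across the fold's SWRs — marginal
rates are preserved exactly, co-firing is destroyed — 50 repeats per fold
(1000 differences total). Positive differences mean the model captures
co-firing beyond marginal rates. Significance: the 50 within-fold repeats
share one fitted model and one test fold, and the 20 fold means share
training data, so a t-test over the pooled 1000 differences is grossly
anti-conservative (~70% of null runs below p = 0.05 empirically). The
default `p` is therefore a one-sample t-test on the 20 per-fold means with
the Nadeau–Bengio variance correction for cross-validated estimates
(1/K → 1/K + n_test/n_train), which is approximately uniform under the
null (KS p ≈ 0.28 over 150 independent-Poisson datasets) while structured
data still yield p ≪ 0.01. The pooled-test p is reported as `p_pooled`
for reference.

**Profiles.** Per-ensemble predicted counts are the λ columns; Z-scored
profiles express each interneuron's λ relative to its across-SWR count
mean/SD. Ensemble–ensemble Pearson correlations are computed in both
spaces: gain-like co-fluctuations around a shared mean profile correlate
strongly in raw space and spread around zero after Z-scoring.

## Synthetic data: what it emulates, and what it does not

All pipeline inputs are generated with known ground truth
(`swrkit.synth`); defaults are the study conditions the analyses assume.

* `gen_lfp`: Gaussian white noise with Hanning-enveloped ripple-band
  bursts (150 Hz, 60–120 ms, peak amplitude `snr`× the noise SD,
  inter-burst gaps ≥ 500 ms). A 1/f background is deliberately absent:
  white noise keeps SD-based thresholds analytic, so detector tests probe
  threshold logic, not spectral whitening.
* `gen_vm`: baseline −60 mV with, per SWR, a hyperpolarizing dip (depth ~
  N(2.0, 0.7²) mV) just before onset and a Gaussian depolarization (8 mV,
  σ 12 ms) whose peak time is `40 ms + coupling × ΔVm_pre` plus 4-ms
  jitter; default coupling −10 ms/mV, i.e. deeper hyperpolarization →
  later peak, the sign structure the measured correlations report. "Depth"
  is defined as the dip's mean over the ±25 ms averaging window (the
  raised-cosine trough is 2× depth; the rectangular dip spans
  [−75, +25] ms), so the expected measured ΔVm_pre equals −depth exactly
  for both shapes. Threshold crossings emit 2-ms triangular spikes to
  +20 mV, exercising the −20 mV detector and the 4 V/s edge logic.
  Onsets must be ≥ 4 s apart so each event owns a clean baseline window.
* `gen_unit_spikes`: interneurons fire Poisson bursts in the 30 ms before
  each SWR with per-SWR Gamma-distributed rates (mean 60 Hz, CV 0.5)
  over a 3-Hz baseline; each pyramidal cell is paired one-to-one with an
  interneuron and fires its first within-SWR spike at
  `25 ms + slope × pre-rate` plus 10-ms jitter, then ~60 Hz for the rest
  of the event. The one-to-one pairing is the simplest structure the
  quintile analysis can detect.
* `gen_hmm_counts` / `gen_mixture_counts`: exact generative twins of the
  two latent-variable models. Default mixture ensembles drive disjoint
  interneuron subsets at an 8:0.75 rate ratio (>10×), the "strong
  separation" regime of the recovery tests.

Passing tests on these data show that the implementations measure what
they claim under the models' own assumptions. They do not show robustness
to non-Poisson spiking, bursting, 1/f and movement artifacts in real LFP,
electrode drift, or misclassified cell types — all properties of real
recordings the generators intentionally omit.

## Problem sizes and numerical choices

Monte-Carlo sizes used by the test-suite and the acceptance script —
1000 calibration runs for the latency shuffle test, 200 datasets for
surrogate-test calibration, 50 datasets for ensemble-number selection,
200 sequences for HMM recovery, 60 runs for triplet band coverage — were
chosen so the full suite completes on a single CPU in well under half an
hour while keeping binomial error on estimated rates a few percent.
Vm examples run at 2–5 kHz sampling (measurement windows are tens of
milliseconds, so nothing is lost relative to the 20-kHz acquisition-rate
default). Tie-breaks are always toward the earlier time or the stable
sort order, so every result is reproducible bit-for-bit from (data, seed).

## Known limitations

* The patch detector's onset lag (above) biases patch-aligned analyses by
  a constant ~10 ms relative to envelope start; probe-aligned analyses do
  not share this.
* Curvature-based ensemble selection is scale-dependent and overshoots
  sharp elbows by ~+1 (above).
* `cross_quintile_hmm_test` refits one HMM pair per shuffle; at the
  default M = 15 and 100 shuffles this is the pipeline's most expensive
  call.
* The rank-order measure is undefined for single-participant SWRs and is
  returned as NaN; downstream averages must use NaN-aware reductions.
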