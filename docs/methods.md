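# Methods

This package reconstructs, end to end, a prediction-horizon analysis of
elevated intracranial-pressure (ICP) events in critically ill children from
minute-resolution bedside-monitor data. Because real pediatric neuro-ICU
recordings are not publicly distributable, the pipeline is driven by a
synthetic cohort generator with exact ground truth; every downstream stage
(artifact QC, segmentation, feature extraction, benchmarking, attribution)
is therefore testable against a known answer. This note documents the
models, the defaults and why, the numerical choices, and what the synthetic
results do and do not say about real data.

## Clinical framing

Eight channels are carried at 1-min resolution: systolic, diastolic and
mean arterial pressure (SBP/DBP/MAP, mmHg), ICP (cm H2O), cerebral
perfusion pressure (CPP, mmHg), EKG-derived heart rate and plethysmographic
pulse rate (bpm), and SpO2 (%). ICP is stored in cm H2O because the
clinical event threshold is 20 cm H2O (~15 mmHg); CPP is computed in mmHg
as `CPP = MAP − 0.7355·ICP`, with 0.7355 mmHg per cm H2O.

* **Case (elevated-ICP event):** ICP ≥ 20 cm H2O sustained for ≥ 10
  consecutive minutes; the onset is the first minute of the run. Events
  within 5 h of a kept event are not independent and are dropped
  (greedy, left to right). Each kept onset anchors a 4-h **case record**
  spanning the 240 minutes before onset, rejected if that span touches any
  other qualifying run or the 60-min washout after a run resolves.
* **Control period:** a 6-h stretch with every minute's ICP < 20 cm H2O;
  its final 4 h form the control record, anchored at the period end so case
  and control records are structurally identical. Quiet stretches are tiled
  greedily from their start. The choice of the *final* 4 h is a design
  decision (the framing only fixes the 6-h quiet requirement); anchoring at
  the period end makes the "time to anchor" axis comparable across labels.
* **Analysis windows:** each 4-h record is tiled by 8 consecutive,
  non-overlapping 30-min windows. Window *w* ends `30·(w−1)` min before the
  anchor — its prediction horizon. Window 2 (the 30–60 min window) carries
  the headline 30-min-horizon results.

Missing (NaN) ICP minutes break event runs — an event must be observed —
but are tolerated inside control stretches; spans with heavy missingness
are removed by QC instead.

## Synthetic cohort generator

Each of the default 22 patients contributes one continuous record built
from ~10 blocks: quiet 6-h control blocks and event blocks (4-h pre-event
span + a 12–25 min supra-threshold ICP run + 60-min washout), with a
per-segment case probability of 1/11. This reproduces the study scale of
roughly 20 case events and 200 control periods (~10:1 imbalance).

**Signal model.** Every channel is
`patient baseline + slow OU + quasi-periodic oscillation + fast OU`,
where OU denotes a mean-reverting Ornstein–Uhlenbeck (AR(1)) component.
Defaults: slow τ = 150 min (hemodynamic drift), oscillation period 8–20 min
(vasomotor-type cyclic variation), fast τ = 8 min. Two properties motivated
this structure over a single AR(1):

1. *Artifact-rule consistency.* The wide-artifact rule compares short-window
   deviations against 2× the whole-record SD. Real records owe much of
   their SD to slow drift, so clean 5-min deviations sit far below the
   threshold. A single fast AR(1) concentrates all variance at short lags
   and false-fires the rule on clean data.
2. *Sample-entropy definedness.* SampEn(m = 2, r = 0.2·SD) on 30-sample
   windows needs recurring patterns; on drifting noise with no cyclic
   component it is undefined (no template matches) on 25–40% of windows.
   With the oscillatory component the undefined rate falls under ~10%,
   matching the qualitative smoothness of minute-averaged clinical vitals.

Pressures are generated structurally — DBP and pulse pressure PP, with
SBP = DBP + PP and MAP pinned strictly between them — so DBP < MAP < SBP
holds by construction; CPP is derived exactly from MAP and ICP.

**Planted prodrome.** Six pre-event signatures are planted over the 240 min
before each onset, ramped linearly toward the event (so expression grows in
windows closer to onset): rising ICP level (+2.8 cm H2O at onset) and ICP
irregularity (extra white noise, SD 0.45), regular triangular heart-rate
swings (amplitude 4.5 bpm — a uniform-marginal cyclic surge that raises
binned entropy; note that with 30 samples in 10 bins *added noise lowers*
binned entropy by creating outlier bins), a common downward drift of all
three arterial pressures (−4.5 mmHg at onset, expressed as a negative DBP
mean-change), shrinkage of SBP fluctuation about its local level (−33% at
onset), and smoothing of MAP (blend weight 0.45, lowering its sample
entropy). A global `magnitude` scales all six; magnitude 0 yields a null
cohort in which case and control pre-anchor data are exchangeable.
Magnitudes were fixed once so that the planted-signal window-2 XGB
benchmark lands near an AUROC of ~0.8 on the default cohort, the regime
the analysis is meant to probe; they are free parameters of the simulator,
not estimates of real effect sizes.

**Artifacts and missingness.** Wide artifacts are 2–5-min excursions of
25–60 mmHg (75% negative — flushes and disconnects point down) applied
coherently to SBP/DBP/MAP/CPP; narrow artifacts are single-minute relative
jumps of 40–80%. Default rates corrupt ≈ 2.8 minutes per 4-h record.
Missingness is injected as contiguous 4–45-min gaps (off-unit transport
blanks all channels; line dysfunction blanks the BP channels), placed off
artifact minutes and event runs so the ground truth stays exact.

## Artifact QC

The two-step pass runs on SBP, where arterial-line artifacts are most
dramatic, and corrects all four BP-linked streams together:

1. **Wide:** a 5-min block slides 1 min at a time, left to right; a value
   deviating from the block's first (already-corrected) datapoint by more
   than 2 record-SDs is flagged and immediately forward-filled, so anchors
   stay at the pre-excursion level and long excursions are removed in full.
2. **Narrow:** any remaining minute-to-minute relative change > 30%
   (against the corrected previous value) is flagged and forward-filled;
   the return from a spike is therefore not itself flagged.

Numerical choices: deviations are two-sided (dropouts are downward); ties
exactly at 2 SD or 30% are *not* flagged (strict "exceeded"); a zero
previous value makes the narrow ratio undefined and the minute is treated
as artifact; NaN minutes are never flagged, never serve as anchors or fill
values. The record SD is a **one-time property of the raw record**,
computed before any correction and carried on the returned mask.
Re-applying the pass with that SD is idempotent; recomputing the SD on
corrected data would shrink the threshold and re-flag legitimate
variation.

Adjudication: a monitoring record with < 4 h of concurrent EKG + ABP + ICP
data is excluded outright; an analysis span is excluded when missing or
artifact-replaced minutes exceed 10% (> 20 min of a 4-h span) in any BP
stream. On the default synthetic cohort the detector recovers ≥ 90% of
injected artifact minutes (in practice ~100%) with ≤ 2% false flags on
clean minutes — the recall mirrors, but is not evidence for, performance
on real artifacts, which are more varied than the two injected classes.

## Features

Eighteen statistics per channel per 30-min window: mean, median, max, min,
quantiles 0.2/0.4/0.6/0.8 (linear interpolation), variance and SD
(population denominator *n*), four aggregated moments of the one-sided FFT
magnitude spectrum, sample entropy, binned entropy, absolute change
(summed |first difference|), and mean change ((last − first)/(n − 1)).

The spectral moments treat `p_k = |F_k| / Σ|F|` over frequency indices
k = 0..n/2 as a distribution and report its variance ("aggregated
variance"), centroid, skew and kurtosis; time-domain skew/kurtosis are
deliberately excluded to keep the count at 18, with the spectral reading
anchored by the prominence of "kurtosis of the FFT" among the informative
ICP features. SampEn uses m = 2, r = 0.2·window-SD, Chebyshev distance,
self-matches excluded (field-standard defaults); binned entropy uses 10
equal-width bins over [min, max] and natural log. Undefined values (SampEn
with no matches, spectral moments of a degenerate spectrum, < 2 non-missing
samples) become NaN markers: median-imputed inside the LR/SVM pipelines,
consumed natively by RF and XGB. NaN samples are dropped before computing
a window's statistics, which slightly distorts the time axis of SampEn and
the FFT on gappy windows; QC bounds such windows at 10% missingness.

## Benchmark

Per window: ten Monte-Carlo 70/30 splits at segment level (train size
`floor(0.7·n)`; stratified by label so every test set contains cases — at
~20 cases an unstratified 30% draw can contain none). A patient-grouped
mode is provided because segment-level splitting lets one patient straddle
train and test. Training controls are randomly undersampled to 1:1 against
cases; test sets keep the natural ~10:1 imbalance. Four families: logistic
regression and RBF-SVM (median-impute + standardize pipelines), random
forest, XGBoost.

Hyperparameters are chosen inside each training subset by a sequential
model-based search (GP surrogate, Matérn 5/2, expected improvement over
random candidates; 8 random initial points) over documented spaces, scored
by stratified 3-fold CV AUROC on the training subset — a single small
held-out split proved too noisy to rank hyperparameters at ~28 training
rows. The default budget is 25 evaluations; a budget of 1 skips the search
and uses the documented per-family defaults. Test rows never enter tuning
or fitting (a leakage guard raises if they do).

Metrics: AUROC, AUPRC (average precision — the no-skill baseline equals
test prevalence, ~0.095 at 10:1), and sensitivity/specificity/PPV/NPV at a
0.5 probability threshold (threshold configurable; 0.5 is a neutral
default). Across-iteration summaries are mean ± 1.96·SE (normal
approximation over the 10 iterations).

## Attribution

Exact TreeSHAP attributions are computed by the gradient-boosted booster
itself; local accuracy (attributions + base = margin) holds to ~1e-6 per
row. Importance is the mean |attribution| over an iteration's test rows;
the top-20 features per (window, iteration) — ties broken lexicographically
so rankings are deterministic — are pooled over the 10 iterations and
counted by source signal (SBP/DBP/MAP grouped as ABP; HR labeled EKG), so
every heatmap column sums to 200. Attribution is restricted to the XGB
bundles; LR coefficient magnitudes are reported separately and never mixed
into the heatmap. Kernel-based attribution for the SVM is out of scope.

## Problem sizes

The shipped drivers and checks run the default cohort (22 patients, ~220
segments), 10 Monte-Carlo iterations per window, and a search budget of 16
evaluations for tuned runs (8 random + 8 GP-guided) — sizes chosen so the
whole analysis re-runs on a laptop-class single core in minutes while
keeping every structural quantity (8 windows, 18 statistics, 200-entry
heatmap columns, ~10:1 imbalance) at study scale.

## What passing tests show — and what they don't

The synthetic cohort demonstrates that the pipeline is *correct* (oracle
equivalence of features and segmentation, exact attribution bookkeeping,
no leakage, null cohorts at chance, monotone response to planted effect
size) and *behaves sensibly* (planted signatures are recovered in the
stated directions; ICP-derived importance grows toward the event; SpO2 —
the one channel with no planted effect — contributes least). It does not
validate clinical performance: the generator's effects are stylized, its
artifact classes are exactly the two the detector targets, channel
cross-correlations are simpler than real physiology, and the synthetic
AUPRC runs higher than a real cohort's at matched AUROC because real
heterogeneity (ages, pathologies, drugs, monitor types) is absent. Known
limitations shared with the framing it reconstructs: minute resolution,
no cross-window trajectory features, segment-level (not patient-level)
default splits, and no modeling of vasoactive or sedative effects.
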