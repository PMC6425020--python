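# Methods

This note documents the models, estimators and numerical choices behind
`megrsa`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic-data experiments do and do not
establish about real recordings.

## The analysis problem

Given epoched multichannel recordings of a subject viewing many exemplars of
a factorial stimulus set (here: 16 face identities × several images,
identities crossing gender × age group × familiarity), the pipeline asks
*when* each stimulus dimension becomes linearly decodable, whether
familiarity enhances those representations, and how the neural
representational geometry relates to behavioral similarity judgments. All
statistics are nonparametric; nothing assumes Gaussian group distributions.

## Preprocessing

Per subject, in this order (each step a pure function):

1. **Baseline correction** — subtract each trial's and channel's mean over
   the pre-stimulus window (default −200…0 ms).
2. **Trial rejection** — flag trials whose peak-to-peak range on any channel
   exceeds a threshold (6000 fT is the conventional magnetometer value;
   the synthetic data needs none). Trials are flagged, never dropped, so
   indices stay stable; invalid trials are excluded from every downstream
   computation, including the PCA fit.
3. **Low-pass smoothing** — zero-phase FIR (windowed-sinc, Hamming, default
   37 taps, applied forward-backward). Zero phase matters because latency is
   the quantity of interest; a causal filter would bias onsets late. The
   filter squares the magnitude response: a 5 Hz component passes with <5%
   attenuation, a 100 Hz component is suppressed >90% (verified against the
   designed response in the tests). Disabling the filter is supported and
   should not change conclusions.
4. **Dimensionality reduction** — PCA fit on the concatenation of all valid
   trials and time points (samples = trials × timepoints, features =
   channels), never per time point; the smallest number of components
   reaching 99.99% cumulative explained variance is kept, and component
   scores are re-baseline-corrected. Order (smooth → reduce) follows the
   conventional processing sequence. On real 306-sensor data this keeps
   ~70 components; on the synthetic 60-channel data with white noise it
   keeps nearly all.

## Pairwise decoding into RDMs

For each unordered pair of conditions and each time point:

* trials of each condition are randomly partitioned into **5 splits**
  (sizes within 1 of each other) and averaged into pseudo-trials
  (sub-averaging raises SNR before classification);
* a **linear soft-margin SVM** (C = 1 on unscaled component scores) is
  trained on 4 pseudo-trials per class and tested on the held-out pair,
  rotating through all 5 splits (leave-one-split-out);
* the procedure repeats with fresh random sub-averagings
  (`n_repetitions`, default 100; desk-scale runs use 3–10) and accuracies
  are averaged.

The result is a symmetric condition × condition RDM per time point with an
undefined (NaN) diagonal; for *n* conditions there are *n(n−1)/2* unique
entries. Averaging the lower triangle gives the image-decoding time course;
training at one time and testing at all others gives the temporal
generalization matrix; training a category classifier on a subset of
identities and testing on held-out identities gives cross-category
decoding, whose chance level is also 50%.

Numerics: the inner problem is an 8-sample dual QP solved by a compiled SMO
loop (working tolerance 1e-6 on the dual variables, ≤60 sweeps; the bias is
the free-support-vector average, or the midpoint of the KKT-feasible
interval when no support vector is free — the libsvm convention). Decisions
agree with a tightly converged reference solve and with libsvm to ~1e-5,
and predicted labels match sklearn's SVC exactly on randomized fixtures; a
straightforward fold-loop re-implementation using sklearn reproduces the
pipeline's accuracies bit-for-bit in the tests. Ties (decision value
exactly 0) predict the negative class, so fully degenerate problems —
identical pseudo-trial sets for both classes — score exactly 0.5 on the
balanced test pair rather than 0; all-constant feature input additionally
warns. Repetition averaging happens in `build_rdm_series`;
`pairwise_decode_timepoint` scores one already-sub-averaged pair, which is
the primitive the repetition loop calls.

## Partial-rank RSA

Category models are binary RDMs (1 between, 0 within category); feature
models use 1 − Pearson *r* between per-condition feature vectors (range
0–2). Because the models are mutually correlated by design (every
between-gender pair is also between-identity), each model's time course is
the **partial Spearman correlation** with the data RDM, partialling all
competing models plus an optional low-level feature confound: vectors are
rank-transformed with average ranks for ties (binary models are heavily
tied; this is the standard convention), ranks are regressed on covariate
ranks with an intercept, and residuals are Pearson-correlated. With no
covariates this is exactly the textbook Spearman coefficient (tested to
1e-12). Rank-deficient covariate sets (e.g. duplicated models) are handled
by least-squares pseudo-inverse rather than an error. If the data vector
lies exactly in the covariate span, the residual is zero and the
correlation is defined as 0 (with a warning): there is no variance left to
share. Constant *input* vectors are an error.

Familiarity-split analyses restrict data and model RDMs to the
familiar-only and unfamiliar-only condition subsets (the familiarity model
is constant within a subset and must be excluded there); per-subject
difference time courses (familiar − unfamiliar) feed the same group
inference against zero. The full-set analyses partial the familiarity model
alongside the others; `include_other_models=False` disables competing-model
partialling where a marginal correlation is wanted.

## Group inference

**Cluster-based sign-permutation test.** Subject time courses are centered
by the chance level (0.5 for accuracies, 0 for correlations). Each
permutation flips whole subject time courses by ±1 and recomputes the group
mean; the identity assignment is always included, guaranteeing p > 0. When
all 2^n sign patterns fit within the permutation budget (n ≤ 9 at the
default 1000) the test enumerates them exhaustively and is exact — the
small-sample case is verified against an independent enumeration oracle.
Per-timepoint cluster-inducing thresholds are the 95th percentile of the
permutation distribution, with the "higher" interpolation convention so the
exact case has no interpolation ambiguity; time points strictly above
threshold are cluster-inducing. The cluster-length criterion is the
smallest run length whose permutation tail probability P(max run ≥ L) is at
most the corrected level — equivalent to requiring a cluster p-value ≤ 0.05
— which keeps the family-wise error controlled despite run lengths being
small discrete integers (an "≥ 95th percentile" rule would not: atoms at
the threshold can push the error rate well above the nominal level). The
empirical family-wise error over 200 null datasets is checked in the
acceptance suite. Testing is one-sided positive by default (decoding above
chance, positive correlations); a two-sided mode thresholds |mean|.

**Latencies.** Onset is the earliest cluster-corrected significant time
point after stimulus onset; peak is the maximum of the group statistic
inside a fixed early window (80–180 ms by default, isolating the first
peak from later offset responses; ties take the earliest time). Bootstrap
CIs resample subjects with replacement, recompute the full cluster test
per resample (permutation thresholds included — a threshold-reuse fast
mode exists and is flagged as an approximation), and take the 2.5th/97.5th
percentiles. Resamples with no significant post-onset point are excluded
from the onset distribution and counted; if more than half fail, the onset
CI is marked unreportable. Latency comparisons use paired draws (the same
resampled subject set evaluates every condition in a draw); the two-sided
p-value counts bootstrap differences on either side of zero, doubles the
smaller tail, and is floored at 2/n_bootstrap. Families of such tests are
corrected with Benjamini–Hochberg FDR at q = 0.05.

A caveat worth knowing: because every bootstrap draw re-runs a test with
5% family-wise error, roughly that fraction of draws contains a spurious
cluster somewhere in the window; when it lands before the true onset it
contaminates the onset distribution's lower tail. The contamination shrinks
as the analyzed window grows relative to the pre-onset stretch (the null
max-run criterion lengthens) and as the data-RDM noise falls (more
condition pairs, more sub-averaging repetitions). This floor — not the
effect size — limits how small onset-difference p-values can get at desk
scale.

## Behavior

Behavioral RDMs are pairwise **squared** on-screen distances between
arranged items; all rank statistics are invariant to uniform coordinate
scaling. The neural–behavior time course is the partial Spearman
correlation per time point, partialling only the low-level feature model.
The **noise ceiling** rank-transforms each subject's RDM vector and
averages correlations with the group mean including the subject (upper
bound; an overestimate) and excluding it (lower bound; an underestimate).
Spearman is used for consistency with the RSA statistic. Note the upper
bound has a floor of 1/√n_subjects even for unrelated subjects — the
self-correlation share — so "both bounds ≈ 0" holds for the lower bound
only.

**Commonality analysis** partitions the squared partial correlation between
neural data and behavior: for model *m*, the coefficient is
r²(drop-m) − r²(full), where "full" partials every model plus the low-level
confound and "drop-m" leaves out *m*. The squared (variance) scale is the
standard commonality definition; a literal r-scale difference is available
via `scale="r"`. The reference time course is the squared partial
correlation given only the low-level confound — the total shared variance
being decomposed. For mutually orthogonal models the coefficients sum to
that total (verified to 1e-10 on exact toys); coefficients can be small or
slightly negative in general, which is inherent to variance partitioning.
The analysis window should be the significant neural–behavior interval, and
a model whose neural signature lies outside that window (the late
familiarity signature) should be excluded.

**1-back performance.** d′ = z(hit) − z(false alarm) with rates clipped
into [1/(2N), 1 − 1/(2N)] to avoid infinite z on perfect subjects; mean RT
over correct target trials; familiarity effects tested with two-sided
Wilcoxon signed-rank across subjects (identical paired vectors return
p = 1 by convention rather than erroring).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes — not
the physics of the recording. Per subject, each stimulus dimension
contributes `amplitude · envelope(t) · pattern(level)`, where the pattern is
a fresh random unit vector per factor level per subject (subjects have
idiosyncratic topographies, mirroring subject-specific component spaces; one
pattern per image for the image component, per identity for identity), and
the envelope rises as a half-Gaussian from onset (exactly zero at onset;
rise σ = (peak − onset)/1.5, wide enough that the signal gains amplitude
soon after onset so detected onsets track nominal ones) to 1 at the peak,
then decays exponentially (τ = 150 ms). Familiar conditions multiply the
gender and identity patterns by a familiarity gain (default 1.5 ≥ 1,
encoding early enhancement); a separate late additive familiarity component
(onset 403 ms) models the late familiarity signature. Trial noise is i.i.d.
Gaussian per trial/channel/timepoint; per-subject amplitude jitter (SD 0.2,
multiplicative) adds between-subject variability.

Defaults encode the study conditions: component onsets/peaks at
image 46/103, age 60/120, gender 72/125, identity 91/125, late familiarity
403/450 ms; 16 identities crossing gender × age × familiarity with equal
cell counts; 28 trials per condition; epochs −200…800 ms. The time step
default is 5 ms (configurable to 1 ms) and amplitudes (0.32/0.27/0.22/0.26/
0.18 in trial-noise units) were calibrated once so the pipeline reproduces
realistic effect sizes — image decoding peaking near ~73% and partial
correlations of a few hundredths to ~0.2. The age amplitude is set slightly
above gender's because the familiarity gain boosts gender (and identity)
but not age; the calibration equalizes the resulting group-level effect
magnitudes.

Behavioral arrangements embed a weighted sum of binary model RDMs into 2-D
by classical (Torgerson) scaling, then jitter positions with Gaussian
noise; negligible eigenvalues are clipped to exactly zero so noiseless
arrangements preserve exact ties. A 2-D embedding necessarily compresses
high-dimensional structure (identity), which is a realistic property of
arrangement tasks. The synthetic 1-back trial log draws hits/false alarms
at fixed rates (0.96/0.005, giving d′ ≈ 4.3) and Gaussian RTs with a
familiarity advantage (454 vs 462 ms).

What passing recovery tests shows: the chain of estimators is unbiased at
chance on null data, controls family-wise error, and recovers injected
latency order, familiarity enhancement and variance attribution at
realistic effect sizes. What it does not show: robustness to structured
MEG noise (1/f spectra, sensor correlations, artifacts), to non-unimodal
envelopes, or to confounds between low-level features and categories —
the generator has none of these by construction.

## Validation experiment sizes

Desk-scale experiment sizes used by the test suite, chosen to keep the
whole suite comfortably runnable on one CPU: null-calibration decoding uses
16 conditions × 25 trials × 30 channels at 5 ms over −100…300 ms with 10
repetitions; family-wise-error calibration uses 200 null datasets of 8
subjects × 150 time points at 200 permutations; the latency-recovery
experiment uses 12 subjects, 48 conditions (16 identities × 3 images — the
48 within-identity pairs keep the identity model's partial correlation
stable), epochs to 400 ms at 5 ms, 3 decoding repetitions, and 1000
bootstrap draws with 1000 permutations each (the study-scale inference
sizes; inference is cheap next to decoding). Three generator seeds are run
for the recovery experiment; all are expected to reproduce the qualitative
pattern (gender and age onsets before identity; familiarity-difference
clusters for gender and identity but not age).

## Known limitations

* The decoder is strictly linear with fixed C = 1; no kernels, scaling or
  hyperparameter search (deliberate: the RDM entries must be comparable
  across pairs and time).
* Partial rank correlation removes *linear* dependence in rank space;
  strongly nonlinear model relationships can leave residual confounding.
* The bootstrap-within-permutation design inherits the onset-tail
  contamination described above; onset CIs at small n should be read with
  that in mind.
* `reject_bad_trials` flags whole trials only — no channel interpolation or
  partial repair.
* The generator's familiarity gain applies to gender and identity patterns;
  an age enhancement, if wanted, must be added explicitly.
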