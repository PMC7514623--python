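# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not establish.

## Problem and pipeline

A subject's degree of motor-fluctuation severity is the categorised average
change in UPDRS-III between medication OFF and ON states: minimal (≤ 5),
mild (5–10], moderate (10–15], severe (> 15), or inconclusive (INC) when
the subject never reaches ON.  The pipeline estimates this category from
two gyroscopes (wrist, ankle) without state annotations, in three stages:
a per-window symptom representation, a per-round-pair *incremental*
representation of how the window distribution changed, and a subject-level
histogram decision.

### Preprocessing

Band-pass FIR, 0.5–15 Hz, windowed-sinc (Hamming) of order `4·fs/band_lo`
(512 at the default fs = 64 Hz), applied forward–backward so both sensor
sites stay phase-aligned.  The taps are mean-shifted to place an exact null
at DC; without it the Hamming stopband leaves a ~2·10⁻³ residual gain at
0 Hz, which squared by the two-pass application still leaks ~4·10⁻⁶ of a
constant input.  Sampling rate is a metadata field (64 Hz default in the
simulator — typical for clinical-grade inertial units, and comfortably
above twice the 15 Hz band edge).  Windows are 5 s with 4 s overlap; rounds
in the decision stage are 180 s.  Recordings shorter than one window (or
one round) produce empty results with a logged warning.

### Symptom features (66 per site)

21 per-axis features × 3 axes + 3 inter-axis cross-correlations.  Fixed
definitions, each pinned to a brute-force oracle in the tests:

* sample entropy: m = 2, r = 0.2·SD, Chebyshev distance over the n−m
  templates shared by both lengths; −ln(A/B); 0 for a constant signal or
  when B = 0; capped at −ln(2/((n−m−1)(n−m))) when A = 0;
* Shannon entropy: 16-bin amplitude histogram, natural log;
* Gini index on |x| via the sorted-rank formula;
* jerk: mean |first difference| × fs;
* spectral quantities from the one-sided periodogram of the mean-removed
  axis, scaled so the bin sum equals the mean square (Parseval); band
  power is the inclusive bin sum over [lo, hi];
* spectral peaks: strict local maxima of the raw periodogram (no
  smoothing), ties broken toward lower frequency; bins below 10⁻¹² of the
  maximum are treated as zero (FFT rounding floor), which is what makes
  "percentage of peaks above 4 Hz" equal 100 % for a pure in-band tone;
* autocorrelation: biased normalised estimate; first peak = first strict
  local maximum at positive lag (amplitude/lag 0 when none exists;
  a constant signal reports amplitude 1 at lag 0);
* cross-correlation: signed value at the lag maximising |ρ|, 0 when an
  axis is constant.

Degenerate (constant) axes therefore never produce NaN.  Two sensors are
fused by concatenation (132 dimensions) by default; a single-site mode
(66 dimensions) is available, and was measurably worse on the synthetic
cohort.

### SOTM clustering

Online competitive learning with threshold `H(r) = H(0)(1 − exp(−r/2N))`
(H(0) = sum of per-feature ranges, N = number of vectors) and learning rate
`α(r) = 0.8·exp(−r/τ_eff)`.  Two readings existed for the printed decay
constant τ = 0.1: taken literally, α(1) ≈ 3.6·10⁻⁵ and the update rule is
inert after the first vector, so the default is τ_eff = τ·N (decay over
one data pass); the literal reading stays available via `literal_tau`.
Note the threshold *grows* with r, so node creation concentrates in the
early presentations; in consequence the free fit's node count is largely
capacity-bound, and the default cap `max_cls = 5` brackets the mean
cluster count (≈ 4.3) reported for wearable symptom-feature rounds of this
kind.  Presentation order is a seeded permutation, reshuffled per epoch,
without replacement.

The fixed-K variant removes the iteration stop, grows until exactly K
nodes exist — with a deterministic safeguard (after a full epoch without a
creation, the vector farthest from its nearest node seeds the next one;
otherwise the growing threshold can stall the growth forever) — and then
completes one convergence pass.  Final cluster definition for both
variants: vectors are re-assigned to the nearest node and each node is
recentred to the mean of its members.  The online positions are
single-pass stochastic estimates whose variance is set by the learning-rate
schedule rather than by cluster size; reporting the members' centroid makes
the model well-defined and presentation-order-insensitive, which matters
because the downstream features are distances between these centroids.
K is selected per cross-validation fold as the half-down-rounded median of
free-fit node counts over the training rounds only.

### Incremental features

Clusters of each round are sorted by descending centroid norm (ties by
creation order), then five blocks are concatenated: within-round pairwise
centroid distances (I, then J), within-cluster spreads
`Σ d(v_n, C_k)/(m_k − 1)` (singletons and empty clusters report 0), and
cross-round distances between rank-matched centroids — `2·C(K,2) + 3K`
non-negative values.  Rank matching (not optimal assignment) follows the
sorted-order notation of the construction; it is cheap and deterministic
but contributes noise when two rounds' cluster structures order
differently.

### Change classifier and decision rule

Random forest: 100 Gini trees, bags of ⌈2n/3⌉ drawn with replacement,
√N features per split, unlimited depth, unweighted classes (optional
`class_weight` in the config).  Prediction is the majority vote over
trees with ties broken toward the higher severity — clinically
conservative.  The out-of-bag error curve and the per-block (grouped) mean
impurity importances are computed from the stored per-tree bags.

The decision rule uses `ratio = (d1+d2+d3)/d0` (+∞ when d0 = 0) with the
0.3/0.2 thresholds; in the fluctuating branch percentages are normalised
by d1+d2+d3.  The alternative normalisation over all four counts is
available via `pseudocode_denominator`, but only the d0-excluding
denominator reproduces all 24 published per-subject percentage rows, so it
is the default.  Percentages are rounded half-up to integers.  Boundary
conventions: ratio = 0.3 → INC, ratio = 0.2 → S = 0; percentage arg-max
ties go to the higher degree.

## Synthetic cohort

The generator emulates only the signal properties the features read out:

* tremor — 4–6 Hz sinusoid, frequency redrawn per 5-s block, amplitude
  40 deg/s × tremor_level on the wrist (ankle damped 50 %), ±20 % block
  envelope, projected on a per-subject, per-site fixed unit direction
  (a strapped sensor's tremor axis does not move between rounds);
* activity background — band-limited (0.5–3 Hz) Gaussian process,
  25 deg/s RMS, scaled by (1 − 0.7·brady_level);
* white noise, 1.5 deg/s SD;
* pseudo-UPDRS = round(5 + 25·tremor_level + 30·brady_level), range 5–60.

A subject's day is a timeline of 3-min rounds (8–12 by default): the first
half at the OFF profile, the rest at the ON profile ("step" schedule; a
"linear" interpolation is available).  Three to four rounds (weighted
toward four, matching an average just under four scored rounds per
subject) carry pseudo-UPDRS scores and form the training pairs; the
severity decision uses *all* timeline pairs, which is what makes the
histogram statistically meaningful — day-long monitoring yields tens of
pairs even though only a handful of rounds are clinically scored.  The
OFF→ON change allocates the score delta half to tremor and half to
bradykinesia through the score weights, so a given UPDRS change produces
the same signal change for every subject.  Per-class score-change targets
are drawn inside the class bands with ≥ 1 point of margin from the
5/10/15 cutoffs, so integer rounding cannot flip a pair's label.  The
default cohort is 24 converting subjects (5/5/5/9 across the four
classes, keeping severe the largest); non-converting (INC) subjects can be
added via `n_inconclusive` — note that a subject with no ON rounds has
only degree-0 pairs and is structurally decided S = 0, so INC recovery is
not expected of the decision rule on this generator.

What the generator does *not* model: distinct activity types (walking,
eating — the window distribution is unimodal per round), dyskinesia, gait
events, sensor artefacts, or score noise.  Passing tests on this cohort
therefore show that the pipeline recovers severity classes when the
symptom-to-signal link is clean and stationary; they do not show
robustness to activity heterogeneity, which on real data is the dominant
confounder for mild changes.

## Evaluation results and limits

Leave-one-subject-out on the default cohort (seed 0, one CPU, ≈ 5.5 min):
pairwise change-degree accuracy 0.786 against a 0.460 majority-class
baseline; subject-level severity accuracy 0.750 (18/24).  All errors are
adjacent-class: mild subjects decided minimal and moderate subjects mild
(or INC).  Two observations bound what is achievable here: (i) the same
incremental vectors classified with subject-mixed cross-validation reach
≈ 0.95 accuracy, against ≈ 0.77 grouped by subject — the representation
carries the class signal, but its absolute scale is subject-specific and
the method has no subject-level normalisation; (ii) the class bands are
only 5 UPDRS points wide, so adjacent classes differ by signal changes
comparable to the clustering noise of two independent SOTM fits.  The mild
class is the weakest, with errors falling into the minimal class — the
same asymmetry reported for real patients.
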