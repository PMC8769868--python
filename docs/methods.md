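# Methods

## Problem

EEG-based person identification classifies a subject from multichannel scalp
recordings. Dense montages (64 electrodes) are uncomfortable and slow to set
up, and many channels are redundant or uninformative for identity. Channel
selection is therefore a combinatorial optimization problem: find a mask
m ∈ {0,1}^d, m ≠ 0, that keeps identification accuracy high while using as
few electrodes as possible.

`eegselect` treats this as a wrapper search. The search state is a continuous
vector per candidate; a sigmoid transfer function turns it into a binary
channel mask; each mask is scored by cross-validated KNN identification on
the channels' autoregressive features; a binary cuckoo search explores the
mask space.

## Feature pipeline

Each recording is band-pass filtered (0.5–50 Hz, 4th-order Butterworth),
notch filtered (60 Hz, Q=30), both applied forward–backward so the output
has zero phase shift, and optionally wavelet-denoised ('db4', level 4, soft
universal threshold estimated by the median absolute deviation of the finest
detail coefficients). Denoising is off by default: it is a preprocessing
option, not part of the method, and the universal threshold is only
appropriate under dense Gaussian-like noise.

Per channel, an AR(p) model x_t = Σ a_j x_{t−j} + e_t is fitted by Burg's
method (Yule–Walker available as an alternative); p ∈ {5, 10, 20} are the
conventional presets. The d·p coefficients of one recording form one row of
a channel-blocked feature table: channel c owns the contiguous columns
[c·p, (c+1)·p), so masking a channel removes exactly its block. Features are
computed per recording by default; a per-subject mean is available as an
aggregation mode, but cross-validation needs several rows per subject, so
per-recording rows are the CV default.

Burg was chosen because it is the standard estimator for short EEG segments
and does not require windowing; its convention here is a_j > 0 for positive
lag-j dependence, and stability (characteristic roots inside the unit
circle) is checked via `ARModel.is_stable`.

## Fitness

A mask m is scored by

    Fit(m) = W1 · acc(m) + W2 · (1 − |m|/d),   W1 = 0.8, W2 = 0.2,

where acc(m) is the fraction of rows correctly identified by k-nearest
neighbours (k = 1, Euclidean distance on raw AR coefficients) under
stratified 10-fold cross-validation with a fixed fold seed. Fit ∈ [0, 1];
at fixed accuracy each extra channel costs W2/d. The channel-count term is
expressed as a *reduction* (1 − |m|/d) so that maximizing Fit favours fewer
channels; expressing it as a raw channel count would reward more channels
and contradict the goal of the selection.

Predictions are pooled across the 10 folds (each row is tested exactly
once), one-vs-rest confusion counts (TA/TR/FA/FR per subject) are
accumulated from the pooled predictions, and all metrics derive from those
counts: per-class accuracy/recall/precision are macro-averaged, the F-score
is the harmonic mean of the macro precision and macro recall, and the
accuracy entering the fitness is the plain multiclass fraction correct.
Pooling rather than averaging per-fold metrics keeps the stored counts and
the reported metrics exactly consistent (the report can be recomputed from
its own counts bit for bit) and avoids small-fold denominator pathologies.
Classes with zero denominators (never predicted, or absent) contribute 0
with a warning.

Cross-validation dominates the cost of any wrapper search, so the evaluator
precomputes one squared-distance matrix per channel block; the distance
matrix of a mask is the sum over its selected blocks. For k = 1 prediction
is a vectorised argmin; for k > 1 scikit-learn's KNN runs on the precomputed
distances. Reports are memoised by mask bit pattern — metaheuristics revisit
masks constantly, and on small d the cache converts a 6000-evaluation run
into at most 2^d − 1 distinct CV computations.

## Optimizer

Binary cuckoo search with N = 30 nests and 100 iterations by default,
abandonment probability p_a = 0.25 and Lévy exponent β = 1.5. Per iteration:

1. *Global walk.* Every nest proposes x' = x + α · L(β) ⊙ (x − x_best);
   the incumbent best proposes x' = x + α · L(β). L(β) is drawn by
   Mantegna's construction (ratio of scaled normals), giving symmetric
   heavy-tailed steps. The proposal is binarized and scored, and replaces a
   uniformly chosen *other* nest only if strictly better (a greedy
   per-index variant is available).
2. *Local walk.* Each coordinate of each nest is displaced, with
   probability p_a, by u · (x_j − x_k) for two other random nests j ≠ k and
   u ~ U(0,1); the perturbed solution replaces its own nest if better.
3. *Elitism.* The best-ever solution is re-inserted over the worst nest if
   both walks lost it, so the best-fitness trace is non-decreasing by
   construction.

Binarization sets bit_c = 1 iff φ < σ(x_c) with φ ~ U(0,1) and
σ(s) = 1/(1+e^(−s)). An all-zero draw is repaired by setting one random
bit: an empty channel set cannot be scored. The published inverted
inequality (bit = 1 iff φ > σ) is available behind
`printed_transfer_rule=True` for compatibility; under it, large positions
produce 0-bits, which contradicts the standard S-shaped transfer
convention, so it is not the default.

**Step scale α = 1.0.** Positions live on the logit scale of the sigmoid,
whose natural unit is 1: moving a coordinate from 0 to ±4 moves its bit
probability from 0.5 to ≈0.98/0.02. The α ≈ 0.01 convention from
continuous cuckoo search assumes steps scaled to the problem's coordinate
range; applied here it yields displacements of order 10⁻³, the walk never
saturates any coordinate, every binarization stays a near-coin-flip, and
the search degenerates into random mask sampling. With α = 1 the Lévy walk
actually drives coordinates to saturation and the population converges
(measured on planted d=16 tables: matched-budget win rate over random
search rises from 15/20 to 20/20, and the number of distinct masks
evaluated per run drops by half).

Positions are initialized uniformly on [−1, 1] and left unbounded
afterwards; the sigmoid absorbs scale, so box constraints would only slow
saturation.

Determinism: one `numpy` generator seeded from the run seed drives
initialization, walks and binarization; identical inputs and seed give
bit-identical results.

## Synthetic data

The generator emulates the shape of a 64-electrode, many-subject,
12-recordings-per-subject identification benchmark with a known planted set
S* of informative channels, providing ground truth that no real dataset
offers.

*Feature-table plant* (fast path): rows are subject-labelled vectors; every
cell carries N(0, noise_sd²) noise; columns of channels in S* additionally
get subject-specific means drawn N(0, σ_μ²) with

    σ_μ = effect_size · noise_sd / √|S*|.

`effect_size` thus measures the *joint* separation of the planted set:
single planted channels are individually weak (at effect_size = 3,
|S*| = 8, d = 32: single-channel accuracy ≈ 0.47, full-S* ≈ 0.99,
all-channels ≈ 0.93), which mirrors real EEG, where identity evidence is
distributed over electrodes, and makes recovering most of S* necessary for
high accuracy. With effect_size = 0 all columns are exchangeable noise and
identification sits at chance = 1/n_subjects.

*Signal plant*: subject identity is encoded in AR coefficients, not
amplitude, so the AR extraction stage is the information bottleneck.
Channels in S* follow subject-specific AR(5) processes built in reflection-
coefficient space — k_s = tanh(k_template + 0.05 · effect_size · δ_s) with
δ_s ~ N(0, I) drawn once per subject and channel; the tanh keeps |k| < 1
and hence the process stable. Each recording perturbs the AR coefficients
with additive N(0, (0.02 · noise_sd)²) noise, projecting back to stability
by shrinking any root to modulus 0.98 (bounded retries). Channels outside
S* share one AR process across all subjects; recordings differ only in
their innovations. Default scale: 160 Hz, 4 s segments — one motor-imagery
trial.

What the plant does *not* model: eye-blink/muscle artifacts, line-noise
bursts, volume-conduction correlations between channels, non-stationarity
within a recording, or session effects. Passing tests on planted data
therefore demonstrate the machinery (feature extraction bottleneck, fitness
trade-off, search behaviour), not performance on real EEG.

## Experiments and statistics

A method is characterised by a batch of independent runs (25 by default)
differing only in seed. Batches are compared with the two-sided Wilcoxon
signed-rank test paired by seed, reported as a Z value under the normal
approximation *without* tie correction (zero differences dropped, average
ranks), matching the classic tabulated convention in which 25 concordant
pairs give |Z| = 4.3724; SciPy's tie-corrected approximation is used as a
cross-check on tie-free data. Significance is declared at p < 0.05.

Method × measure tables are summarised by dense ranks (best = 1, exact ties
share a rank, next distinct value gets the next integer) and their sums;
smaller rank sums are better. Measures follow the EEG_Fit / EEG_ACC /
EEG_Len / EEG_Precision / EEG_Recall / EEG_Fscore naming, with accuracy
displayed ×100 and kept as a fraction internally.

The built-in control is random search at matched budget: it evaluates as
many uniformly random nonempty masks as the optimizer computed uncached CV
evaluations. For small d it can sample without replacement, where a full
budget of 2^d − 1 reproduces exhaustive enumeration exactly — the same
enumeration (`exhaustive_best_mask`, guarded at d ≤ 12, ties broken toward
fewer channels then lexicographically smaller bit tuples) that serves as
the oracle for small-instance tests.

## Problem sizes and tolerances

Verification fixtures are scaled to run on a laptop: oracle-equivalence on
d = 8 tables (10 subjects × 12 recordings, 20 seeds), planted recovery on
d = 32 with |S*| = 8 (20 subjects × 12 recordings, 10 seeds), matched-budget
comparison on d = 16 (20 paired seeds). Monte-Carlo assertions use ≥ 10⁵
draws with 3–4 standard-error tolerances; AR recovery is asserted at
n = 20 000 samples within ±0.05 per coefficient; fitness agreement with the
enumeration oracle is asserted to 10⁻⁹ (the quantities are identical
rationals when the same evaluator cache is shared).

## Known limitations

- The weighted-sum scalarization returns one operating point per run, not a
  Pareto front; W1/W2 encode the accuracy-vs-channel trade-off a priori.
- 1-NN with pooled-fold metrics is sensitive to duplicated or near-duplicate
  recordings; no leakage control beyond fold stratification is applied.
- Burg estimation assumes per-recording stationarity; heavily artifacted
  segments should be cleaned or discarded upstream.
- The comparison suite ships only the cuckoo optimizer and the random-search
  control; other metaheuristics can be plugged in through the optimizer
  callable interface but are not implemented.
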