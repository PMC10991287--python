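# Methods

This note records the modelling choices, defaults and numerical conventions
behind `mlhdpm`, and what the synthetic benchmarks do and do not show.

## Data model and preprocessing

Records follow the 14-column UCI heart-disease dialect: 13 predictors and a
graded outcome `num` ∈ {0..4}, binarized so that 0 means no disease and 1–4
mean disease.  `?` is the only missing marker; an empty field is a format
error.  Missing values are flagged, never zero-filled, and `num` may not be
missing.

**Cohort imputation.**  A patient's cohort is the set of records that agree
with them on at least a quorum (default 0.5) of binned similarity fields —
the age decade (bin width 10 years) and the observed-data quartiles of
cholesterol and resting blood pressure.  The three fields and their binning
operationalize "similar patients"; the quorum, bin width and field list are
configuration.  Missing categorical fields take the cohort mode, continuous
fields the cohort mean, with a global fallback when the cohort has no
observation.  Observed values are never altered.

**Scaling.**  Standard scaling uses the sample SD (n−1 denominator), is fit
on training data only, and its parameters serialize to JSON so the same
transform applies at prediction time.  A constant column is an error rather
than a silent pass-through.

## Feature selection

The GA searches over boolean feature masks.  Fitness is the 3-fold
cross-validated MSE of a ridge regression (α=1) on the binary label over the
masked columns; folds are seeded, so fitness is a pure function of
(mask, data, seed).  Ridge was chosen as the base learner because it is
deterministic, fast enough to score thousands of genomes, and yields
coefficient magnitudes usable for the elimination ranking; the elimination
step standardizes columns first so magnitudes are comparable.  Defaults
follow the printed protocol: 18 generations, population 80, 40 elites
carried + 40 fresh random genomes, crossover probability 0.05 (single-point
for bitmasks), per-bit mutation 0.05.  An all-zero mask receives +inf
fitness rather than raising, so selection discards it naturally.  The
hybrid runs GA first (global search), then RFE within the GA winner's
subset (local refinement); the result is always a subset of the GA subset,
and asking RFE for more features than the GA retained is a configuration
error.

## Signal features

Two printed formulas are kept verbatim behind an `as_printed` mode because
they are dimensionally anomalous: the grid entropy sums P/ln(P) (negative
for every non-degenerate distribution, undefined when a cell equals 1) and
the successive-difference RMS takes the square root of a *signed* sum,
which can be negative.  The pipeline defaults are the standard corrected
forms: Shannon entropy −Σ P·ln(P) (natural log; zero cells contribute 0 by
the limit convention) and RMSSD sqrt(Σ diff²/(M−1)).  Sums over successive
RR differences run over the M−1 valid adjacent pairs.  Zero-valued samples
produce no zero crossing (the sign change is strict), which makes the
crossing rate invariant under positive rescaling.  How signal features join
the tabular predictors is left to the caller: they are exposed as optional
extra columns, not merged automatically.

## USCOM resampling

Steps: (1) under-sample the majority class uniformly without replacement
(default retention 2/3, the imbalance ratio of the protocol this transplants
from; configurable because other cohorts differ — the Cleveland-like
generator default uses retention 1 in the cross-validated benchmark, where
folds are already small); (2) k-means-cluster the minority on standardized
features; (3) split the under-sampled majority and each minority cluster
8:1:1 (test = max(1, round(0.1n)) rows, then validation likewise, train the
remainder, after a seeded shuffle) and merge per role, so each minority
subgroup is represented in every role; clusters with fewer than 3 members go
wholly to train; (4) SMOTE the rarer class of the merged training set until
the counts are exactly equal.

**Elbow rule.**  K is the smallest candidate whose SSE drop relative to the
SSE at the smallest candidate K falls below the threshold (default 0.10).
Normalizing by the initial SSE rather than the previous one is deliberate:
on unstructured data the successive-ratio drops decay like K^(−2/d) and
never cross a fixed threshold, whereas the chosen rule stops as soon as an
added cluster stops explaining a meaningful share of the total scatter.

**SMOTE geometry.**  Each synthetic row is s + u·(nb − s) with u ~ U(0,1)
and nb drawn from the seed row's k nearest minority neighbors (default
k=5, clamped to n−1).  Distances and interpolation run in standardized
space — unscaled Euclidean distance would be dominated by the
large-magnitude columns (cholesterol, blood pressure) — and synthetic rows
map back to the original scale.  Synthetic rows are confined to the
training set by construction and carry `synthetic` provenance.

## Classifier

The network is dense: hidden units compute a = exp(−z²) of their affine
pre-activation z = b + w·x, and the single output unit is linear; the
decision threshold (default 0.5) is applied downstream.  The Gaussian
activation acts as a radial basis on a learned projection — a unit responds
maximally on the hyperplane z = 0 and decays symmetrically — which suits
class boundaries that are bands rather than half-spaces.  Activation applied
to the weighted sum (not to raw inputs) is the only reading under which the
first-layer weights matter.  Weights initialize uniformly on
[−init_scale, +init_scale] (default 0.5), seeded.  Training is per-sample
online backpropagation in a seeded shuffled order per epoch; the error
signal uses the activation derivative −2z·exp(−z²) at each unit's
pre-activation (identically 1 at the linear output).  A non-finite epoch
loss raises a divergence error naming the epoch.

## AEHOM

Minimization convention throughout (fitness = MSE).  Per generation: every
non-best clan member moves p′ = p + c·(p_best − p)·r with a per-dimension
uniform r (c default 0.5); the matriarch (clan best) is re-placed at
l·(clan center) (l default 0.1); the n_worst (default 1) lowest-fitness
members of each clan are re-seeded at P_min + (P_max − P_min)·k with fresh
uniform k per dimension; the best elephants of randomly paired clans
exchange the gene segment [⌊L/3⌋, ⌊L/3⌋+⌊L/2⌋) (children replace each
clan's worst member); and every non-matriarch gene mutates to a fresh
uniform draw with probability 0.05.  Every operator clips to the search
box.  The best-ever position is retained outside the herd, so the reported
history is non-increasing by construction.  Fractional crossover cut points
are floored to integers; the two-point scheme needs L ≥ 6, so in
lower-dimensional searches the crossover operator is skipped and the
remaining operators carry the search.  With l near 0 the matriarch update
contracts toward the origin regardless of data scale; bounds clipping is
the guard, and for zero-centered weight vectors the contraction doubles as
a useful shrinkage step.

**Weight training.**  Herd positions are flattened parameter vectors
(layer-major, weights then biases per layer); fitness is training-set MSE.
A schedule interleaves the herd with backpropagation: every 5 generations
the incumbent best is refined by 1 online epoch and re-injected in place of
the currently worst elephant (keeping the history monotone), and a final
backprop polish (default 40 epochs) runs unconstrained by the search box.
With zero herd generations the procedure reduces exactly to seeded-init
backpropagation.

## Evaluation

Class 1 is positive.  Metrics with a zero denominator are reported as 0 and
listed in an `undefined` flag instead of raising.  Cross-validation is
stratified (the imbalance the pipeline targets would otherwise leave folds
unrepresentative), k defaults to 10, and resampling runs inside each
training fold only — applying SMOTE before splitting would leak
interpolated copies of test points into training.

## Synthetic data

The tabular generator emulates the Cleveland schema: continuous predictors
are Gaussian with realistic marginals (age 54±9 y, resting BP 131±17 mmHg,
cholesterol 246±51 mg/dl, max heart rate 149±23 bpm, ST depression
1.0±1.1), categorical predictors are sampled over their legal supports with
Cleveland-like marginals, labels are allocated to an exact class ratio
(default 164:139), and each informative continuous column's class-1 mean is
shifted by effect_size standardized units.  Missingness is injected
completely at random over predictors only.  The generator reproduces
marginals, the class ratio and the informative shifts — not the real joint
distribution, correlations between predictors, or informative categorical
structure — so passing benchmarks demonstrate the machinery recovers
planted signal under clean conditions, not clinical performance.  RR series
are Gaussian with a positivity margin (mean > 3·SD, residual nonpositive
draws rejected).

## Benchmark problem sizes and defaults

The end-to-end benchmark uses n=500 rows at the 164:139 ratio with **four**
informative features at effect size 2.0.  Four is the separability floor
for the ≥0.95 accuracy bar: with k independent informative features the
between-class Mahalanobis distance is 2√k, giving Bayes accuracies of ≈0.92
(k=2), ≈0.958 (k=3) and ≈0.977 (k=4); only k≥4 leaves usable headroom.  The
pipeline's own GA default is a lighter configuration (6 generations × 24
genomes, 12 elites + 12 randoms) than the selector's printed default
(18 × 80), chosen so that repeated cross-validated runs remain cheap; the
printed configuration remains the `feature_selection` default and is what
the selector benchmark runs.  The network benchmark architecture is one
hidden layer of 6 Gaussian units on the selected features, α=0.05, 40
final backprop epochs, a herd of 2 clans × 8 over [−1, 1].

## Known limitations

* The imputation cohort rule is O(n²) per missing field; adequate at the
  hundreds-of-rows scale it targets.
* The network is a binary classifier with a single linear output; the 0–4
  severity grades are collapsed before training.
* No harmonic estimation: THD inputs (component magnitudes, fundamental
  power) are taken as given, and there is no QRS detection — RR series are
  inputs.
* The elbow rule assumes the SSE curve is computed on enough minority rows
  for k-means to be stable; tiny minorities fall back to small K by
  construction (candidates above n are dropped).
* Multi-cohort merging (Hungary/Switzerland/Long Beach schema variants) is
  out of scope; only the 14-column dialect is read.
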