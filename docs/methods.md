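# Methods

## The model

`qgafs` implements a quantum-inspired genetic algorithm (QGA) for binary
optimization and applies it as a wrapper feature selector for multiclass
image classification on deep features.

### Qubit registers and observation

A candidate solution over `m` binary genes is represented not as a
bitstring but as a *qubit register*: `m` amplitude pairs `(α_i, β_i)` with
the normalization constraint

    α_i² + β_i² = 1,

where `β_i²` is the probability that gene `i` collapses to 1 when the
register is *observed*. A register therefore encodes a full product
distribution over the `2^m` bitstrings. The population consists of
`population_size` registers, one per slot; each generation every register
is observed independently to produce a concrete bitstring, which is scored
by the fitness function.

Amplitudes are stored as reals. The general qubit state allows complex
amplitudes, but the only operator ever applied here — a real 2×2
rotation — never leaves the real plane, so complex storage would add
invariant surface without observable consequence.

### Rotation-gate update

After evaluation, every register is nudged toward the best individual `B`
found so far (elitism: `B` is replaced only by a strictly fitter
individual, so ties keep the earlier one and the best fitness is exactly
non-decreasing). The update applies, gene by gene, the rotation

    [α'; β'] = [cos Δθ, −sin Δθ; sin Δθ, cos Δθ] [α; β]

with a signed angle chosen per gene:

* zero when the observed bit agrees with `B`'s bit;
* magnitude `rotation_magnitude` (default 0.05·π) toward `B`'s bit when
  they disagree and the observed individual is not fitter than `B`;
* no rotation at all for an individual strictly fitter than `B` (it is
  about to become the new `B`).

The angle is clamped so that `β²` stays inside
`[saturation, 1 − saturation]` (default `saturation = 1e-4`). Without the
clamp a gene can collapse to probability exactly 0 or 1 and never
recover; the guard keeps every bitstring reachable, which is standard
practice for this family of algorithms.

Writing a gene as `(cos φ, sin φ)`, the rotation is exactly `φ → φ + Δθ`,
so norm preservation is structural; the run loop nevertheless asserts
`|α² + β² − 1| ≤ 1e-9` for every gene after every generation and aborts
on violation.

### Mutation and termination

With per-gene probability `mutation_rate` (default 0.01) the amplitudes
are swapped, `(α, β) → (β, α)`, inverting the gene's bit probabilities —
the quantum analogue of a NOT gate. This preserves normalization by
construction.

The loop stops at `max_generations` (default 50) or, optionally, after
`stall_patience` consecutive generations without a best-fitness
improvement (disabled by default). A non-finite fitness value aborts the
run with a diagnostic naming the offending bitstring.

### Defaults that the problem does not pin down

Population size 20 and 50 generations are conventional desk-scale values
for this algorithm family; both are plain constructor arguments. The
rotation magnitude 0.05·π is at the small end of the usual fixed-angle
range, favouring stable convergence over speed. All defaults are exposed
in `QGAConfig` / the estimator constructors.

## Wrapper feature selection

Feature subsets of a `n × d` labeled matrix are bitstrings of length `d`
(bit i = keep column i). The fitness of a mask is

    mean stratified k-fold CV accuracy of a multinomial-logistic probe
    on the masked columns  −  λ · (n_selected / d),

with `k = 5` folds and `λ = 0.01` by default. The logistic probe is a
deliberately cheap surrogate for the final model: wrapper selection
re-trains a classifier for every candidate mask, and a convex,
deterministic probe keeps that affordable while ranking masks similarly
to the full head. The sparsity term expresses the goal of reducing the
feature dimensionality; at `λ = 0.01` it separates ties between
equally-accurate masks without overriding real accuracy differences. The
all-zero mask is assigned fitness 0 rather than raising, so the fitness
is total, as the optimizer requires. Fold assignment is stratified and
seeded, making the fitness a deterministic function of (data, mask,
seed); mask scores are memoized within a fit.

`QGAFeatureSelector` implements the scikit-learn selector API (`fit`,
`transform`, `get_support`) and composes with pipelines. The full
experiment driver `run_selection`:

1. splits the data into a stratified 80/20 train/test partition;
2. runs the QGA mask search with the CV fitness *on the training portion
   only*;
3. retrains the softmax head on the selected training columns;
4. evaluates exactly once on the held-out portion.

The held-out split never influences the search — the package's test suite
instruments the single evaluation call to verify this. One experiment
seed fans out into independent sub-seeds for the split, the search and
the head training via `numpy.random.SeedSequence.spawn`, so a single
integer reproduces every number bit-for-bit.

## The classification head

The final model is a single-hidden-layer softmax classifier: dense(128) →
ReLU → inverted dropout (rate 0.5) → softmax, trained with Adam
(learning rate 1e-3), batch size 32, at most 50 epochs, early stopping on
validation loss (patience 5, best weights restored) and reduce-on-plateau
learning-rate decay (factor 0.5, patience 5). A stratified 10% slice of
the training data serves as the validation set for the callbacks; when
the data is too small to stratify, the callbacks watch the training loss
itself. The head is written directly in numpy because the callback
semantics (dropout + plateau decay + best-weight restoration) are part of
its contract; it follows the scikit-learn estimator API.

## Image front end and feature extraction

Images are loaded from a class-per-subdirectory tree (lexicographic class
order), converted to RGB, bilinearly resized to 128×128 and scaled to
[0, 1] (integer inputs divided by 255). Preprocessing is idempotent.
Unreadable files are skipped with a warning and counted; a class with no
readable image is an error.

Feature extraction is a pluggable contract: any deterministic map from a
preprocessed image to a fixed-length vector. The extractor shipped here
is a seeded random projection of the flattened pixels followed by ReLU
rectification (default d = 64). Random projections approximately preserve
pixel-space geometry, so classes separable from raw pixels remain
separable in feature space — exactly the property the selection stage
needs from a backbone. A pretrained convolutional backbone (the intended
production front end) slots into the same contract; the package does not
ship network weights, so everything here runs offline.

## Evaluation metrics

From the C×C confusion matrix (rows = true class) the package computes,
per class via one-vs-rest counts: precision `TP/(TP+FP)`, recall
`TP/(TP+FN)`, and F1 (harmonic mean); and overall: accuracy
(trace/total), Cohen's kappa

    κ = (p₀ − p_e) / (1 − p_e),   p₀ = trace/total,
    p_e = Σ_c row_c·col_c / total²,

and the Matthews correlation coefficient in the covariance (Gorodkin)
form

    MCC = (c·s − Σ_k t_k p_k) / sqrt((s² − Σ_k p_k²)(s² − Σ_k t_k²)),

which reduces exactly to the binary
`(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` at C = 2 (property
tested); a macro-averaged one-vs-rest MCC is exposed as an option. All
ratios return 0 on a zero denominator (degenerate classes), making every
metric total; κ on marginals that force chance agreement 1 returns 1 for
perfect agreement and 0 otherwise. The suite is verified against
independent library implementations to 1e-12 on randomized inputs.

## Synthetic data

`gen_features` draws class-conditional Gaussian matrices: `k` of `d`
columns are informative, the rest pure `N(0, σ²)` noise. For each
informative column, per-class means are drawn iid from
`N(0, (δσ)²/2)`, so the RMS separation between any two class means is
exactly `δ·σ` per column. Defaults (`n=600, d=64, k=8, C=3, δ=2, σ=1`)
give a matrix on which a linear probe on the informative columns scores
≥ 0.9 while the noise columns score at chance — a well-posed
feature-recovery ground truth. Informative column positions are random,
not a prefix. Labels are balanced within ±1 and shuffled.

`gen_images` writes PNG directories of noisy geometric motifs (disc,
ring, cross, blank; up to 4 classes, default 64×64, additive Gaussian
pixel noise σ = 0.05). The motifs are linearly separable from raw
pixels, so the end-to-end pipeline has a known attainable accuracy.
Generation is byte-identical per seed.

What the generators do *not* emulate: real MRI anatomy, intensity bias
fields, correlated deep-feature structure, class imbalance, or label
noise. Passing tests therefore demonstrate the correctness of the
machinery — search, hygiene, metrics, determinism — not clinical
performance on real scans.

## Problem sizes and numerical choices

The test and acceptance workloads use the generator defaults above:
the feature-recovery run searches 64-dimensional mask space with
population 20 for 40 generations (~800 fitness evaluations before
memoization); the exhaustive-equivalence check uses d = 8 (255 masks,
20 independent search seeds against the enumerated optimum); the image
pipeline uses 3 motif classes × 30 images with a d = 32 extractor and a
10-generation search. Fitness ties in the optimizer are broken toward
the first-encountered individual; the stratified CV fold count drops to
the smallest class count when a class is too small for 5 folds, and a
class with fewer than 2 members is an error.

## Known limitations

* The rotation policy uses a single fixed angle magnitude; per-gene
  angle lookup tables from the wider literature are not implemented.
* The fitness probe is a linear classifier; feature subsets whose value
  is only visible to a non-linear model may be under-ranked.
* The random-projection extractor is a geometry-preserving stand-in, not
  a learned representation; with it the pipeline measures machinery, not
  image understanding.
* Multi-objective selection (accuracy vs. subset size as a Pareto front)
  is out of scope; the scalarized λ-penalty is the only trade-off knob.
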