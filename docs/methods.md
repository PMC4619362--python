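# Methods

## Model and objective

A scene observed in modalities mod1..modM is the vertical stack of that
scene's per-modality histograms. Training data is a d×n nonnegative matrix
*V* whose columns are stacked scenes; the learner fits *V* ≈ *W·H* with
*W* (d×k) and *H* (k×n) nonnegative, minimizing the I-divergence
D_I(V‖WH) = Σ (V ln(V/WH) − V + WH) with the 0·ln 0 = 0 convention. The
I-divergence suits sparse, high-dimensional count histograms better than the
Frobenius norm: it is scale-covariant (D_I(cA‖cB) = c·D_I(A‖B)), so a
modality's contribution to the loss is proportional to its total mass —
which is why every modality is first normalized to mean column 1-norm 1.

Fitting alternates the Lee–Seung multiplicative updates

    H ← H ⊛ (Wᵀ(V ⊘ WH)) ⊘ (Wᵀ·1)
    W ← W ⊛ ((V ⊘ WH)Hᵀ) ⊘ (1·Hᵀ)

(H first, then W, per iteration). Both updates preserve nonnegativity and do
not increase the loss; the implementation asserts this up to a 1e-9 relative
slack because the eps floors below perturb exact monotonicity at the level
of floating-point rounding.

**Numerical choices.** Factors initialize entrywise Uniform(eps, 1) from a
seeded generator — a strictly positive start keeps multiplicative updates
live (a zero entry is absorbing). All denominators, and the reconstruction
inside the loss evaluation, are floored at eps = 1e-12. The run stops at
`max_iter` (default 50; ten is usually near convergence) or when the
relative loss change drops below `tol` (default 1e-6). No column
normalization of W is applied during fitting; the W/H scale indeterminacy is
accepted. With identical seed and inputs, fits are bitwise reproducible.

## Partial-modality coding and cross-modal reconstruction

The dictionary splits row-wise into per-modality blocks W_mod (the stacking
order is fixed by the schema and persisted with the model). Coding an
observation over a subset S of modalities solves argmin_h D_I(v_S‖W_S·h) by
iterating only the H update with W_S frozen — the same algorithm, same
floors, seeded start. Held-out observations are always scaled by the
*training* normalization factors; test statistics are never re-estimated.
The expected perception in an unobserved modality is W_target·h. Whether
reconstructions should be rescaled back to raw units before comparison is
ambiguous; comparisons here stay in normalized units.

## Cross-modal recognition protocol

A trial observes a test example in the test modalities and must pick, among
one reference per concept class observed in disjoint reference modalities,
the one sharing its concept. Three comparison modes (internal codes;
reconstruct-into-reference-modality; reconstruct-into-test-modality) cross
five scores (Euclidean, forward/reversed/symmetrized I-divergence, cosine).
Forward orientation means D_I(test-side‖reference-side). Cosine of a zero
vector is defined as 0 with a warning; an infinite I-divergence score is
never chosen unless all candidates are infinite. Ties resolve to the lowest
index. The default is internal + cosine.

The test set is split into stratified folds (default 10, shrunk if a class
is too small); each fold's samples serve as trials while references are
drawn uniformly, seeded, from the remaining folds. Referents are redrawn per
trial by default — averaging over referent choice — with a fixed-per-fold
option. Success rate = correct trials / total trials; a uniform-random
chooser (metric=None) gives the 1/C chance baseline. Per-sample codes and
reconstructions are computed once in batch, so the per-trial cost is an
argmin over C cached scores.

## Representation layer

Sequential signals become additive nonnegative vectors:

- **delayed derivative** x_t − x_{t−d} (velocities for joint angles, Δ/ΔΔ
  streams for acoustic frames; default d = 2 frames — the exact acoustic
  delay is configurable because no canonical value exists);
- **codebooks**: k-means (seeded) over training frames; quantization maps a
  frame to its nearest centroid, ties to the lowest index;
- **lagged co-occurrence histograms (HAC)**: entry (a, b) of a (stream, lag)
  block counts positions with events e_t = a, e_{t+lag} = b; blocks sum to
  L − lag and concatenate in stream-major, lag-minor order, prefixed by
  `extra` reserved zero entries. Total length extra + lags·Σ kᵢ². The
  acoustic reference configuration (three streams, codebooks 150/150/100,
  lags 2 and 5 at a 0.01 s frame period, i.e. 20 ms and 50 ms, extra = 2)
  yields 110002 entries. The two extra entries are kept for dimensional
  fidelity only; they are zero here (their original content is unspecified);
- **angle–velocity histograms**: per degree of freedom, (angle, delayed
  velocity) pairs are quantized by that DOF's 2-D codebook and counted;
  per-DOF histograms concatenate. The default motion instantiation is 9 DOFs
  × 50 cells = 450 dimensions; both counts are configurable since only the
  product is canonical.

Counting makes every representation additive over time partitions up to a
boundary deficit of at most `lag` pairs per cut and stream — the property
that lets NMF treat a sequence as a convex mixture of its parts.

## Localization and representation analysis

**Sliding windows** of width 0.5 s shifted by 0.05 s (defaults) are cut from
a test sequence, featurized with the *training* featurizer (same codebooks
and lags, no per-window renormalization — window mass is informative), coded
into coefficients, and cosine-scored against per-concept references. The
similarity curve of the true concept peaks on windows overlapping the
keyword. A sequence shorter than the window is processed whole, with a
warning; an empty-feature window scores 0.

**Mutual information.** For concept l, X_l indicates label l per sample; each
coefficient is quantized into 10 equal-width bins over its observed range
(equal-frequency optional; the binning is per coefficient). MI(X_l; Y_j) is
the plug-in estimate from empirical joint frequencies, in natural log units
— nats make the deterministic-indicator benchmark come out at
−(0.1 ln 0.1 + 0.9 ln 0.9) ≈ 0.325 for ten uniform classes (base 2 would
give 0.469). A constant coefficient occupies a single bin and carries 0. A
Hungarian assignment on −MI aligns one coefficient per concept; remaining
coefficients follow in descending peak-MI order. k = 15 is the default rank
for MI demonstrations; recognition experiments default to k = 50 with 50
iterations.

## Synthetic data generator

The generator produces the study conditions the learner assumes: each scene
carries **exactly one** concept, expressed in every modality, among
modality-specific distractors. Per modality,

    v = α·prototype_c + (1 − α)·Σ λ_j·distractor_j + noise,  λ ~ Dirichlet(1)

with α = 0.5 and truncated-Gaussian (clip-at-0) noise of level σ (default
0). Prototypes and distractors are sparse (expected 30% nonzero) random
nonnegative vectors scaled to unit 1-norm, resampled until pairwise cosine
< 0.9, seeded. Keeping the distractor mass at (1 − α) holds the mean sample
1-norm constant across σ and D so per-modality normalization cannot mask
generator settings. Defaults are 10 concepts, 5 distractors, 3 modalities of
dimension 40, 500 training samples, uniform classes; `shuffle_associations`
redraws the concept independently per modality — the negative control under
which recognition collapses to 1/C.

Event-level "sentences" are uniform distractor event streams with one
concept-specific n-gram inserted at a recorded span; the bundled
localization corpus pairs whole-sentence HAC vectors (sound) with concept
image histograms, using 200-frame (2 s) sentences and 50-frame (0.5 s)
keywords so the canonical window geometry applies. Truncated Gaussian noise
was chosen over Poisson because histograms are real-valued after
normalization anyway.

**What the generator does not emulate**: acoustic or visual realism,
grammar, correlated distractor–concept co-occurrence (a `confound` would
need real corpus statistics), non-stationary class frequencies, or the
high-dimensional sparsity of real HAC vectors. Passing tests therefore
demonstrate that the algorithmic chain recovers planted cross-situational
structure under its own assumptions, not performance on recorded speech,
motion capture, or images.

## Problem sizes and limitations

Tests and the acceptance script use 10 concepts, ≤ 500 training samples,
rank ≤ 50, 2000 Monte-Carlo trials for the chance baseline, and 100 test
sentences for localization — sizes at which every quantity is stable across
seeds while the whole suite runs in seconds. Known limitations: NMF is
non-convex, so different seeds reach different (equally valid)
factorizations; the W/H scaling is unidentifiable; plug-in MI is biased
upward at small n; the evaluation assumes exactly one concept per scene and
disjoint test/reference modalities; batch learning only — no incremental
updates.
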