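# Methods

This note records the modeling choices behind the package: the encoders
and their exact conventions, the embedding trainer, the selection and
evaluation procedures, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written
down.

## Problem setting

Input objects are 41-nt RNA windows over {A, C, G, U} with a uridine at
the center (signed positions −20…+20, site at 0). Positives are windows
whose central U is 5-methylated; negatives are unmodified uridine
windows. Windows are supplied as FASTA (DNA `T` accepted and mapped to
`U`; any other non-ACGU character is rejected, because none of the
encoders can represent ambiguity codes) or extracted from transcripts
at 1-based positions with a hard boundary rule: a window that would run
off the transcript is an error, never padded.

## Physicochemical encoders

**Kmer.** Counts of each of the 4^k k-mers divided by the number of
k-mer positions L − k + 1, so each block sums to exactly 1. Some
toolkits divide by the sequence length L instead; that convention is
available via `denominator="length"`. The position-count denominator
was chosen as the default because it makes the normalization invariant
exact and matches the windowed (ENAC) variant of the same formula.

**ENAC.** A length-5 window slides 5'→3' with step 1; within each
window the four mononucleotide frequencies are recorded, giving
4·(L − 4) = 148 features at L = 41. Feature names carry the 1-based
window start (`enac_w07_C`), so selection and attribution outputs are
stable, human-readable labels.

**CKSNAP.** For each gap k = 0…5, the 16 ordered pair counts
N_xy (seq[i] = x, seq[i+k+1] = y) divided by the pair-position count
L − (k + 1). Each gap block sums to 1; 96 features total.

**PseDNC.** The 16 dinucleotide frequencies (normalized to sum 1)
extended by λ tier-correlation factors

    θ_j = (1 / (L − 1 − j)) Σ_i Θ(R_i R_{i+1}, R_{i+j} R_{i+j+1}),

with Θ(a, b) the mean squared difference of the six standardized
dinucleotide indices between a and b, and the whole vector divided by
Σf + w Σθ. Defaults λ = 3, w = 0.5. Requirements enforced at the type
level: λ ≤ L − 2, and the property table must be standardized.

The bundled property table is the standard strand-symmetric A-form RNA
base-step parameter set (rise, roll, shift, slide, tilt, twist per
dinucleotide), standardized per index to mean 0 / sd 1 across the 16
dinucleotides before use — the established PseNAC convention, which
makes Θ scale-free and therefore insensitive to each index's physical
units. Users can supply their own 6×16 TSV; it is standardized on load
unless asked not to.

**Fusion order** is CKSNAP, ENAC, Kmer, PseDNC. With the default
hyperparameters (k = 1,2,3 for Kmer, λ = 3) the fused view has
96 + 148 + 84 + 19 = 347 dimensions; no dimension is hard-coded — the
count follows from the configured hyperparameters.

## Skip-gram k-mer embedding

Each window is tiled into L − k + 1 overlapping k-mers; the token lists
form the training corpus. The trainer is skip-gram with negative
sampling implemented directly on numpy arrays:

* fixed symmetric context window w (every token within w positions is a
  context; no random window shrinking, which keeps runs bit-reproducible);
* 5 negative samples per pair from the unigram distribution raised to
  3/4;
* minibatched SGD (batch 1024) over the precomputed pair list with a
  linearly decaying learning rate (0.05 → 0.0005), 50 epochs by default
  — small corpora (vocabulary ≤ 4^k) need many passes;
* all randomness from one `numpy` generator seeded by the caller;
  training is single-threaded, so a fixed seed gives identical vectors.

A window's representation is the unweighted mean of its k-mer vectors
(default dim 100). Out-of-vocabulary k-mers at prediction time are
skipped from the mean; a window with no known k-mer maps to the zero
vector with a logged warning. Embeddings are trained on training
windows only (leakage-safe); `tune_embedding` grid-searches (k, w) with
a caller-supplied CV-accuracy evaluator, preferring smaller k then
smaller w on ties.

## Two-step feature selection

Step 1 ranks the fused physicochemical features by ANOVA F, the
classical F-score ((m⁺−m)² + (m⁻−m)²)/(s⁺² + s⁻²) with ddof-1
variances, or gain importance from LightGBM/XGBoost (seeded,
single-threaded). Constant features score 0 under ANOVA; a
zero-denominator F-score is 0 when class means coincide and +inf when
they differ. Ties keep original column order (stable sort).

Step 2 (IFS) evaluates ranked prefixes of size step, 2·step, …, plus
the full set, each by the mean accuracy of the configured classifier
under a *single* seeded stratified k-fold partition reused for every
prefix — reusing the partition removes fold-resampling noise from the
IFS curve so prefix accuracies are directly comparable. The smallest
prefix attaining the maximum wins (parsimony tie-break). Default step
is 1; the pipeline exposes a coarser step for large feature counts.

Embedding features deliberately bypass IFS: selection operates on the
fused physicochemical view only, and the embedding block is
concatenated afterwards.

## SVM and evaluation

The margin optimization is delegated to libsvm (scikit-learn `SVC`);
this package owns the kernel/C/γ surface. Grid search is exhaustive
over C ∈ {2⁻⁵ … 2¹⁵} and γ ∈ {2⁻¹⁵ … 2³} (powers of 4, the canonical
log grid), every candidate scored on the same seeded stratified k-fold
partition, ties resolved toward smaller C then smaller γ, and the
winner refit on the full training set.

Metrics come from the confusion matrix at the solver's default 0
decision boundary: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc, precision,
F1, and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Undefined-denominator metrics are reported as 0 and flagged rather than
NaN. The ROC curve sweeps the continuous decision score (tied scores
collapse to one operating point) with trapezoidal AUC; no probability
calibration is performed. Cross-validation reports per-fold metrics,
their across-fold means (the conventional k-fold estimate), and
pooled-confusion metrics — both, since either convention is found in
the literature.

## Shapley interpretation

Attributions follow the coalition-weighted marginal-contribution
definition with val(S) = mean model output over a background set with
the features in S fixed to the explained sample (interventional
mean-imputation — the standard model-agnostic reading; the background
is user-supplied, defaulting in the pipeline to a training subsample).
Exact enumeration of all 2^p coalitions is used up to p = 15 (the
desk-scale ceiling); beyond that a seeded permutation sampler estimates
the same quantity and converges to the exact values in n_perm. Exact
mode satisfies efficiency (Σφ + base = f(x)), symmetry and the dummy
axiom to floating precision; the suite checks all three plus agreement
with an independent all-orderings permutation oracle at p = 3. Pipeline
attribution runs on the post-selection feature space (selected
physicochemical + embedding features), and summaries rank by mean |φ|
(top 20 by default).

## Composition analysis

For each (signed position, nucleotide) cell, the per-sequence presence
indicator is compared between classes with a Welch two-sample t-test —
the unequal-variance form matches the two-sample-logo convention — at
uncorrected α = 0.05 (an optional Bonferroni flag divides α by the 4·L
cell count). Degenerate cells where both classes are constant (e.g. U
at position 0, where every window is U by construction) get t = 0,
p = 1 when equal and p = 0 when the constants differ. The exported logo
matrix holds signed −log10 p for significant cells, 0 otherwise.

## Synthetic data

The generator emulates the structure of uridine-centered window sets:
odd length L (default 41), all centers forced to U, uniform ACGU
background, and a consensus motif (default `UUC` at signed positions
0–2, mirroring the enriched consensus around genuine modification
sites) planted into positives with a configurable probability (1.0 for
forced planting; pipeline-level checks use 0.9 to leave class overlap).
Negatives are pure uniform background. It does **not** emulate:
transcript-level composition bias (real flanks are far from uniform),
shared-transcript correlation between positives and negatives,
homology between windows, or multi-position dependency structure beyond
the single planted motif. Consequently, passing tests demonstrate that
the machinery recovers a known planted signal under controlled
conditions — not that any particular accuracy carries over to real
transcriptome data.

A note on attainable accuracy under these conditions: a planted
positional motif is a conjunction of position-specific events, and with
uniform negatives a fraction of the background mimics it by chance
(1/16 of negatives carry U at +1 and C at +2). At 300 windows per class
and planting probability 0.9 the Bayes ceiling is ≈ 0.92, and the full
pipeline's tenfold-CV accuracy lands around 0.87–0.88. Bag-of-k-mer
features alone cannot approach the ceiling at all, because they discard
position — roughly half of uniform negatives contain no UUC anywhere,
capping a 3-mer-only classifier near 0.75. Positional encoders (ENAC)
carry the recoverable signal.

## Problem sizes and numerical choices

Test and validation runs use deliberately compact problem sizes chosen
to exercise every code path with comfortable statistical margins:
200 random windows for encoder-oracle equivalence, 200 samples ×
100 features × 10 seeds for selection recovery, 300 windows per class
for the end-to-end run (IFS step 10, reduced SVM grid), 500 per class
for the type-I null check. Tolerances: encoder/normalization identities
at 1e−9 (they hold to machine precision), Shapley efficiency at 1e−6 in
exact mode. Stable sorts everywhere a ranking can tie; all stochastic
stages take explicit seeds, and the pipeline derives per-stage seeds
from a single run seed recorded in the manifest.

## Known limitations

* The embedding trainer is a compact reference implementation tuned for
  small k-mer vocabularies; it is not optimized for corpora beyond
  ~10⁴ sentences.
* IFS cost grows as (features/step) × folds SVM fits; for the full
  497-dimensional fused view at step 1 expect minutes, not seconds.
* Exact Shapley is limited to 15 features by 2^p enumeration; the
  sampled estimator's error decays as 1/√n_perm.
* The enrichment test is per-cell and uncorrected by default, matching
  the common practice for two-sample logos; treat cell-level
  significance as descriptive unless the Bonferroni flag is on.
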