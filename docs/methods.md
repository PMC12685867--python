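# Methods

This note documents the models and procedures implemented in `bacpred`, the
parameter choices that matter, the numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## Descriptor engine

Every sequence is validated against the 20-letter amino-acid alphabet in the
fixed order **A R N D C Q E G H I L K M F P S T W Y V**.  All feature names
index this order 1-based, so `aac_5` is the cysteine fraction and `aac_11`
the leucine fraction.  The nine families and their conventions:

* **AAC / DC** — residue frequencies (÷L) and adjacent-pair frequencies
  (÷(L−1)), row-major over the alphabet for pairs.
* **PseAAC** (type 1, λ = 10, w = 0.05) — composition augmented with λ
  sequence-correlation factors.  τ_j averages, over positions i, the mean
  squared difference of three standardized scales (hydrophobicity,
  hydrophilicity, side-chain mass; population z-scores over the 20 residues)
  between residues j apart.  Components are f_r/(Σf + wΣτ) and
  w·τ_j/(Σf + wΣτ), so the 30-vector sums to 1.
* **APseAAC** (λ = 10, w = 0.05) — same construction, but the
  hydrophobicity and hydrophilicity scales are tracked *separately*,
  interleaved per lag (2λ = 20 tail components).  The squared-difference
  form is used for both pseudo-composition families: it keeps all
  components non-negative, makes the w → 0 limit collapse exactly onto AAC,
  and gives homopolymers an exactly zero correlation tail — three
  identities the test suite asserts.
* **CTD** — seven properties (hydrophobicity, normalized van der Waals
  volume, polarity, polarizability, charge, secondary structure, solvent
  accessibility), each partitioning the residues into three disjoint
  exhaustive groups per the classic three-group convention.  Composition is
  group frequency; transition counts unordered adjacent inter-group pairs
  ÷(L−1); distribution records the 1-based position (as % of L) of the
  ⌈q·k⌉-th group occurrence for q ∈ {first, 25%, 50%, 75%, 100%}.  An
  absent group contributes zeros.  Property order is fixed so that
  `dist_93` is the 50% quantile of group 1 (buried residues) of solvent
  accessibility.
* **SS** — H/E/C state fractions plus longest-run lengths ÷L.  When no
  external PSIPRED `.ss2` profile is supplied, an internal propensity
  predictor (per-residue helix/strand/coil propensities smoothed with a
  centered window of 5, argmax state) fills in.  This fallback is a
  deliberately simple stand-in whose purpose is keeping the 1,103-feature
  schema computable offline; externally predicted profiles always take
  precedence and fallback usage is recorded in the output metadata.
* **SOCN / QSO** (maxlag 20, w = 0.1) — coupling numbers
  τ_d = Σ_i d(R_i, R_{i+d})² over an amino-acid distance matrix, and the
  quasi-sequence-order normalization combining them with composition.  The
  distance matrix is constructed as the root-mean-square distance in the
  three-dimensional standardized property space (hydrophobicity,
  hydrophilicity, side-chain mass) — the same scales that drive the
  pseudo-composition families.  Distances in physicochemical property space
  are the standard basis for sequence-order descriptors; building the
  matrix from the package's own scales keeps the whole descriptor engine
  self-contained and exactly reproducible.  The matrix is symmetric with a
  zero diagonal, so homopolymer coupling numbers vanish.
* **PSSM transitions** — position scores are squashed with the logistic
  σ(x) = 1/(1+e^(−x)); feature (a,b) is the mean over adjacent positions of
  σ(S_{i,a})·σ(S_{i+1,b}) (the product form, committed).  Without a real
  PSI-BLAST profile, a pseudo-profile built from BLOSUM62 rows of the
  observed residues is used and flagged in metadata.

λ = 10 and maxlag = 20 are pinned by the family dimensionalities
(30 = 20 + λ, 40 = 20 + 2λ, 40 = 20 + 20); the weights 0.05/0.05/0.1 are
the conventional defaults for these descriptor types.  Sequences of length
≤ 20 are rejected with a named error (the sequence-order families are
undefined below the maximum lag); callers who need shorter peptides must
lower `maxlag_so` explicitly.

## Correlation pruning

Greedy keep-first scan in schema order on training rows only: feature j is
dropped iff |r(i,j)| ≥ 0.9 (inclusive) for some already-kept i < j.  The
earlier schema index wins because no principled ordering exists between two
near-duplicate descriptors and schema order is reproducible.  Zero-variance
features have undefined correlation and are dropped and reported
separately.  Correlations within 10⁻¹² of ±1 are snapped to ±1 so exact
duplicates always trigger the inclusive bound despite floating-point
rounding.  The pruned count is data-dependent and is not an invariant.

## CVFS

Stratified splitting uses scikit-learn's stratified k-fold machinery, so
part sizes differ by at most one per class.  Per-run RNG streams are
spawned from the global seed, making runs distinct yet replayable.  The
per-part "top-ranked" cut is *all features with positive gain importance*
in an XGBoost fit — a parameter-free rule requiring no arbitrary k.  The
per-part importance model uses one fixed, documented configuration
(200 trees, depth 5, η = 0.1, single-threaded histogram growth) rather
than a per-part grid search: importance rankings, not tuned accuracy, are
consumed here, and a fixed configuration keeps rankings comparable across
parts and runs.  It is overridable through `CVFSConfig.xgb_params`.
Consensus threshold is ⌈p·e⌉, giving 2/3/4 at e = 5 for p = 0.4/0.6/0.8;
selected sets are therefore nested decreasing in p at a fixed seed.

## HFE

Uniform-width bins over the training [min, max] per feature; bins are
left-closed/right-open with the final bin closed, an interior boundary
value joins the upper bin, constant features occupy one bin, and test-time
values outside the training range clamp to the edge bins.  With uniform
vertex and edge weights, a single non-lazy step of the walk that enters a
bin edge lands on class k with probability n_k/n — the laziness parameter α
cancels from this conditional distribution, so α (default 0.5) only
affects the mixing of the Monte-Carlo oracle, never the scores.  The
ratings are the closed-form one-step reduction of the walk: R1 = n_min/n,
R2 = n_maj/n (minority/majority designated from overall training class
sizes, ties to the positive class), R0 = |n₊ − n₋|/n.  The feature score
S(f) = Σ_b (n_b/N)·R0 is the sample-weighted mean class separation over the
feature's bins: 1 when every bin is pure, 0 when every bin mirrors a 50/50
mixture.  It is invariant to sample duplication and monotone under bin
purification.  A seeded lazy-walk simulator over the full hypergraph serves
as an independent oracle; tests require agreement with the closed form
within three standard errors at 10⁵ steps.  Ranking is by descending score
with ties broken by ascending schema index; the retained budget is
z = round(β·m), half away from zero, which gives 90/181/301 for m = 602 at
β = 15/30/50%.

## Classifier and evaluation

Grid search over max_depth {3,5,7} × learning rate {0.05,0.1,0.3} ×
n_estimators {100,300} × subsample {0.8,1.0}, stratified 5-fold CV on the
training split only, selection by mean CV accuracy with ties resolved to
the smaller model (fewer trees, then shallower).  Training is
single-threaded histogram construction with a fixed seed, so two runs with
the same seed serialize to byte-identical bundles.  The train/test split
uses a per-class floor rule — each class contributes ⌊0.2·n_class⌋ test
samples — so 283/283 yields a 112-sequence test set.

Evaluation thresholds predicted probability at 0.5 and derives accuracy,
MCC, recall, precision and F1 directly from the confusion counts; AUC is
the Mann–Whitney rank statistic with average ranks over ties (0.5 when all
scores tie).  Degenerate denominators return 0 with an explicit warning
flag instead of NaN.

SHAP attribution uses the booster's native exact TreeSHAP
(`pred_contribs`), computed by default on the test split.  Per-feature
importance is mean |SHAP| over samples; family sums aggregate the nine
descriptor families and conserve the grand total exactly.  Booster outputs
are float32, so the local-accuracy identity (base value + row sum = margin)
is asserted at 10⁻⁶ absolute plus 10⁻⁶ relative tolerance — machine
precision at typical margin magnitudes.

## Synthetic benchmark

The generator emits i.i.d. residues per class: uniform 1/20 baseline for
the negative class; the positive class multiplies cysteine by 0.3 and
L/I/V/F by 1.5 and renormalizes (defaults: 283 + 283 sequences, lengths
uniform on [30, 120]).  The planting direction mirrors the biology the
classifier should learn — bacteriocin-like sequences are cysteine-poor with
a hydrophobic core — and, being purely compositional, propagates into every
composition-driven descriptor family, which is what the selection stages
are tested against.  An i.i.d. emission model was chosen over motif
planting because the descriptor families under test are compositional;
motif-sensitive descriptors would need a different generator.

What the synthetic benchmark does *not* emulate: real bacteriocin length
and composition distributions, sequence redundancy structure, genuine
PSI-BLAST profiles or predicted secondary structure (both fall back to
their internal stand-ins), and any correlation structure between residues.
Passing tests demonstrate that the machinery — descriptors, pruning,
selection, training, attribution — recovers a known planted signal; they do
not certify accuracy on real sequence databases.

**Bayes ceiling of the default planting.**  With the default effect sizes,
the exact Bayes classifier (the true per-class log-likelihood ratio, which
upper-bounds every learnable classifier) reaches only ≈ 0.874 accuracy:
the per-residue Kullback–Leibler divergence between the two emission
distributions is ≈ 0.034 nat, too little for reliable separation at
lengths 30–120.  End-to-end checks that expect near-perfect recovery
therefore use the package's high-separability profile
(`HIGH_SEPARABILITY_EFFECT`: cysteine × 0.05, L/I/V/F × 3.0), chosen as the
weakest round-valued planting whose Bayes accuracy exceeds 0.99.  The
default profile remains the benchmark for signal-recovery (ranking and
selection) checks, which do not require a separable classification
problem.

## Problem sizes

Statistical checks run at the generator's default scale (566 sequences,
1,103 features) with 5–10 seeded replicates for recovery and accuracy
properties; exhaustive oracles (all-pairs correlation, purification
enumeration) run on instances of at most 50 features or 8 samples, where
enumeration is exact.  The Monte-Carlo walk oracle uses 10⁵ steps per
edge, giving standard errors near 0.002 on landing frequencies.

## Known limitations

* The PSSM and secondary-structure fallbacks are sequence-derived
  surrogates; predictions for real use should supply PSI-BLAST profiles
  and PSIPRED outputs.
* Binary classification only; multi-class bacteriocin families and
  protein-cluster detection (e.g., tailocins) are out of scope.
* The HFE ratings implement the one-step closed form of the lazy-walk
  conductance idea with uniform weights; weighted or multi-step variants
  are not implemented.
* Class balancing is random down-sampling only.
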