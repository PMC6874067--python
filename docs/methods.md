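# Methods

## Problem and data model

A candidate crotonylation site is a lysine in a protein sequence. The
unit of analysis is the peptide window of length 2ξ+1 centred on that
lysine; the default flank is ξ = 20 (41-mers), the value that performed
best in the literature this design follows (21 and 61 being the usual
alternatives). Windows that overrun a protein terminus are padded with
`X`. Site positions are 1-based in all user-facing I/O (UniProt
convention) and 0-based internally.

Residues are encoded by alphabetical rank of the one-letter code
(`A→1 … Y→20`). The padding symbol `X` is encoded as 0 and is excluded
from every composition/position accumulator, so a boundary window and
an interior window of identical content get identical composition
features. Input tables are screened: rows containing the ambiguity or
non-standard codes B, J, O, U, Z anywhere, or `X` outside the terminal
padding runs, are rejected individually with a logged reason; duplicate
window strings (including the pathological case of the same 41-mer
labelled both positive and negative) are rejected with a warning. An
input yielding zero valid windows is a hard error, never an empty
dataset.

## Feature battery

Eight segments, fixed order, 194 values for a 41-mer (the layout is
versioned as `icrotok-194-v1` and serialized with every trained model;
a version mismatch at prediction time is an error):

1. **Sequence-matrix moments (30).** The SVV is laid row-major into the
   smallest square matrix (side m = ⌈√L⌉; 7×7 for L = 41, the 8
   trailing cells zero). Ten raw, ten central and ten Hahn moments of
   degree r+s ≤ 3 are taken in the fixed index order
   (0,0),(0,1),(0,2),(1,0),(1,1),(2,0),(1,2),(2,1),(0,3),(3,0).
2. **PRIM moments (30)** of the 20×20 position-relative incidence
   matrix: H[i,j] accumulates, over every occurrence of residue j at a
   1-based position p strictly after the first occurrence of residue i,
   the offset p − first(i). Rows of absent residues are zero. This
   reading of "relative positional incidence" is one deliberate choice
   among several defensible ones; it is computable in a single pass and
   has an exact reversal duality with RPRIM.
3. **RPRIM moments (30):** PRIM of the reversed window.
4. **FV (20):** per-residue occurrence counts.
5. **AAPIV (20):** per-residue sums of 1-based occurrence positions.
6. **RAAPIV (20):** AAPIV of the reversed window. For an unpadded
   window of length L the identity μᵢ + μ′ᵢ = occᵢ·(L+1) holds and is
   property-tested.
7. **SVV (41):** the raw encoded window (padding zeros included here).
8. **SVV statistics (3):** mean, population variance and biased
   skewness of the encoded vector; skewness of a constant vector is
   defined as 0.

The total of 194 is a published constraint; the segment itemisation
above is this package's own reconstruction (no itemised layout is
published), so the count is reproduced exactly while the internal
ordering is a versioned convention of this implementation.

## Moment engine numerics

* Raw and central moments use 1-based cell coordinates, with a the row
  index. Central moments are taken about the centroid
  (x̄, ȳ) = (M₁₀/M₀₀, M₀₁/M₀₀); the second factor is (b − ȳ)^s, the
  standard 2-D form. A zero-mass matrix has no centroid; its central
  moments are defined as all-zero with a logged warning (this arises
  only for degenerate all-padding windows).
* Hahn moments project onto the discrete orthogonal Hahn polynomial
  basis on the support {0 … m−1} (0-based, as is standard for discrete
  orthogonal polynomials). The polynomials are evaluated through the
  classical terminating ₃F₂ sum with rising-factorial terms; printed
  variants of this sum in the applied literature are frequently
  corrupted, so the implementation was fixed against the defining
  properties instead: discrete orthogonality under the Hahn weight
  ρ(r) = Γ(u+r+1)Γ(z+M−r)/(Γ(r+1)Γ(M−r)), and exact invertibility of
  the full-order transform. Both are asserted in the test suite (Gram
  matrix = identity to 1e−10 for m ≤ 16; 7×7 round-trip to 1e−8).
* Parameters default to u = z = 0, reducing the basis to the discrete
  Chebyshev (Gram) polynomials — the least-informative choice in the
  absence of a published value — and are configurable. For integer
  u, z the polynomial table and weights are computed in exact rational
  arithmetic (`fractions.Fraction`) and converted to floats only at
  normalisation, so orthonormality holds to machine precision even at
  degree m−1; non-integer parameters fall back to log-gamma float
  evaluation. Degree-3 moments require m ≥ 4 (windows of length ≥ 10);
  smaller matrices are an error rather than a silent truncation.
* PRIM/RPRIM moments are computed on the 20×20 incidence matrix
  directly, without reshaping.

## Classifier

A feed-forward network trained by backpropagation
(`sklearn.neural_network.MLPClassifier` behind the package's estimator
surface): one hidden layer of 100 logistic units, logistic output,
cross-entropy loss, adam with initial learning rate 0.01, at most 2000
epochs, early stopping once the loss improves by < 1e−7 for 50
consecutive epochs. No published architecture exists for this
predictor family, so the default was sized to two requirements: train
in minutes on one CPU at benchmark scale (~900 × 194), and have enough
capacity to interpolate the training set, which the published
self-consistency result (all metrics perfect) implies.

Feature columns span many orders of magnitude (third-order raw moments
of a 20×20 incidence matrix vs. single residue codes), so each column
is standardized to zero mean / unit variance on training rows;
constant columns map to zero. The scaler is part of the fitted model
and is refit inside every cross-validation fold, never on test rows.
Class imbalance (378:500 at benchmark scale) is left untouched by
default, with an optional `class_weight='balanced'` mode that evens
the classes by deterministic minority oversampling (the underlying
optimizer has no per-class loss weights).

With a fixed `random_state`, configuration and data, the whole
fit→predict path is exactly reproducible. Trained models serialize to
a single JSON file embedding config, scaler, weights and the
feature-layout version; scoring is a plain in-package forward pass, so
a loaded model reproduces scores to machine precision.

## Evaluation protocols

Metrics use the miss-count parameterisation (N⁺, N⁻ class totals; N₋⁺
missed positives; N₊⁻ false alarms). Its MCC form is algebraically the
standard TP/TN/FP/FN formula; the equivalence is checked exhaustively
over all confusion 4-tuples with class totals ≤ 20. Degenerate cases
are flagged rather than silently zeroed: an empty class leaves Sn or
Sp (and MCC) undefined; a vanishing MCC denominator reports MCC = 0
with an explicit flag, the common convention.

*Self-consistency* trains and tests on the same data — a resubstitution
upper bound, reported as such. *k-fold cross-validation* uses
stratified shuffled folds (class proportions within one sample per
fold) from a seeded plan; "casual selection" is the published wording,
and stratification was chosen because a 378:500 ratio destabilises
small-fold Sn/Sp under plain random folds. When k exceeds the minority
class (leave-one-out on tiny sets) the plan degrades to a plain
shuffled partition with a notice. The headline numbers are the
unweighted fold-means (NaN-skipping, so single-sample folds with an
empty class do not poison the average); pooled-count metrics are
reported alongside, since the two aggregations can differ.

## Synthetic data: what it emulates, what it does not

The generator emulates the two-class window structure of a Kcr
benchmark: 41-mers centred on K, positives carrying a positional motif
(at each configured offset, the motif residue is drawn with the
enrichment probability; elsewhere background), negatives pure
background. Defaults are the benchmark-scale study conditions chosen
for this package: n⁺ = 378, n⁻ = 500, ξ = 20, motif E/D/A/G at offsets
−2/−1/+1/+2 with enrichment 0.9, uniform background (a SwissProt-like
composition preset is available). Enrichment 1.0 gives rule-separable
classes; enrichment at the background rate gives exchangeable classes
(a permutation null), both of which are tested.

What it does **not** emulate: evolutionary redundancy and homology
clusters (the CD-HIT-style structure of real benchmarks), broad
compositional bias around real Kcr sites, position-dependent background
composition, or correlated multi-residue motifs. Consequently, passing
the synthetic end-to-end tests demonstrates that the feature battery
carries positional signal and that the pipeline is leak-free and
reproducible — it does not certify accuracy on real proteome data.

## Known limitations

* The synthetic motif signal is an *equality* pattern on an ordinal
  code axis ("residue at offset −2 is E"). The descriptor represents it
  faithfully (a hand-written rule on the SVV segment separates the
  classes almost perfectly at enrichment 0.9), but a
  backpropagation network over standardized ordinal codes must carve
  narrow axis-aligned response bumps to exploit it, and at n ≈ 400–900
  samples gradient training recovers that signal only partially:
  cross-validated accuracy on the default synthetic conditions lands in
  the high-80s rather than the high-90s, well above the permutation
  null (~50%, computed alongside every CV acceptance check) but short
  of the published cross-validation regime. Real benchmark data, whose
  class signal is spread over smoother composition features, is the
  setting the published numbers describe; the original benchmark
  windows are not redistributable here, so the dataset-scale checks run
  on the synthetic stand-in and report this gap openly instead of
  tuning the generator until it vanishes.
* Self-consistency at 100% is an interpolation check of model
  capacity, not evidence of generalisation; it is kept because it is
  part of the published evaluation protocol.
* The "21 to 41 dummy values" padding scheme described alongside the
  window formulation is not implemented; a single padding code 0 keeps
  FV/AAPIV/RAAPIV 20-dimensional, which the feature definitions
  require.
* UniProt querying, XML parsing and CD-HIT redundancy reduction (60%
  threshold) are upstream preprocessing, documented but out of scope:
  datasets arrive as files.
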