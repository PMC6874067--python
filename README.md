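# icrotok

Prediction of lysine crotonylation (Kcr) sites in proteins from
position- and composition-relative sequence features.

Crotonylation is a reversible post-translational modification of lysine
side chains with roles in chromatin regulation, metabolism and disease.
Experimental mapping of Kcr sites is expensive, so sequence-based
predictors are used to triage candidate lysines. `icrotok` implements a
pseudo-amino-acid-composition (PseAAC) style predictor: each candidate
site is represented by the 41-residue window centred on the lysine
(flank ξ = 20, terminal positions padded with `X`), the window is
encoded into a fixed 194-dimensional descriptor, and a feed-forward
neural network trained by backpropagation separates crotonylation sites
from non-sites.

## The descriptor

With the window encoded as the site vicinity vector (SVV)
`S = [s₁ … s₄₁]`, `sᵢ ∈ {1..20}` the alphabetical rank of the residue
(`A→1 … Y→20`, padding `X→0`), the descriptor concatenates:

| segment | dim | definition |
|---|---|---|
| sequence-matrix moments | 30 | raw `M_rs = Σ_a Σ_b a^r b^s P[a,b]`, central `I_rs` about the centroid, and discrete orthogonal Hahn moments `h_rs`, all with degree `r+s ≤ 3`, of the 7×7 row-major square layout of the SVV |
| PRIM moments | 30 | the same three families of the 20×20 position-relative incidence matrix `H[i,j] = Σ_{p > first(i)} (p − first(i))` over occurrences `p` of residue `j` |
| RPRIM moments | 30 | same, on the reversed window |
| FV | 20 | residue frequencies `f₁ … f₂₀` |
| AAPIV | 20 | accumulative absolute position incidence `μᵢ = Σ_k p_k` over the 1-based positions of residue `i` |
| RAAPIV | 20 | AAPIV of the reversed window |
| SVV | 41 | the raw encoded window |
| SVV statistics | 3 | mean, variance, skewness of the SVV |

Total: **194 features**. Hahn moments use the classical discrete Hahn
polynomials with parameters `u = z = 0` (discrete Chebyshev), evaluated
in exact rational arithmetic and normalised to an orthonormal basis, so
the full-order transform is exactly invertible.

Evaluation follows the two standard protocols — self-consistency
(resubstitution) and stratified 10-fold cross-validation — scored with
the Chou-style metric set (Sn, Sp, Acc, MCC) in the miss-count
parameterisation `Sn = 1 − N₋⁺/N⁺`, `Sp = 1 − N₊⁻/N⁻`, etc.

## Worked example

Labelled windows come either from a CSV/TSV/XLSX table with
`sequence,label` columns (41-mers, label 1 = Kcr site), from FASTA
proteins plus a site list, or from the built-in synthetic generator:

```bash
$ icrotok synth --n-pos 60 --n-neg 60 --seed 7 --out demo_windows.csv
wrote 120 windows (60+/60-) to demo_windows.csv

$ icrotok featurize --in demo_windows.csv --out demo_features.csv
wrote 120x194 feature matrix to demo_features.csv

$ icrotok selfcheck --features demo_features.csv --seed 7
Acc 100.00%  Sp 100.00%  Sn 100.00%  MCC 1.0000

$ icrotok cv --features demo_features.csv --k 5 --seed 7
fold-mean: Acc 77.50%  Sp 75.00%  Sn 80.00%  MCC 0.5624
```

The self-consistency line shows the default network interpolating its
own training set (an upper-bound check, not a generalisation claim);
the cross-validation line is the honest generalisation estimate for
this small synthetic set, where each fold's scaler and network are
refit on the training folds only. The same objects are available as a
library:

```python
from icrotok import generate, PeptideFeaturizer, CrotonylationClassifier

ds = generate(seed=11)                       # 378+/500- synthetic benchmark
X = PeptideFeaturizer().fit_transform(ds.windows)
clf = CrotonylationClassifier(random_state=1).fit(X, ds.labels)
scores = clf.predict_score(X)                # P(site) per window
```

`CrotonylationClassifier` and `PeptideFeaturizer` follow scikit-learn
estimator conventions and compose with sklearn pipelines and model
selection.

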