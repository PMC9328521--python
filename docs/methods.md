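# Methods

## Model

The data are an order-3 tensor **A** ∈ ℝ^{m×p×n}: *m* subjects, *p*
'omics features, *n* ordered timepoints, fully sampled (every subject
observed at every timepoint, possibly after imputation).  The horizontal
slice A_{i,:,:} is subject *i*'s whole *p*×*n* time-series; the tube
fiber A_{i,j,:} is one feature's trajectory in one subject.

Given an invertible *n*×*n* matrix **M**, the mode-3 product Â = A ×₃ M
applies **M** to every tube fiber.  The ⋆_M product of conforming
tensors is the face-wise matrix product in the hat domain, mapped back
by M⁻¹; under it every real tensor admits the tubal SVD
A = U ⋆_M S ⋆_M Vᵀ with ⋆_M-orthogonal U, V and f-diagonal S, computed
as one economy matrix SVD per hat-domain face.

TCAM centers A to mean-deviation form (MDF: zero mean sample), takes the
tsvdm of the centered tensor, and pools the hat-domain singular values
of **all** faces into one globally sorted ranking vector
r = {(r_{h,1}, r_{h,2})}.  Component (score) h of subject ℓ is the
(ℓ, r_{h,1}) entry of hat face r_{h,2} of (A − Ā) ⋆_M V; its explained
variance fraction is σ̂_h²/Σσ̂².  The same formula applied to a new 1×p×n
trajectory is the out-of-sample extension; for training slices it equals
Û σ̂ (both paths are computed and tested to agree to 1e-10, the read-out
formula being the normative one).

**Assumptions.** Fully sampled grid after imputation; n small relative
to memory (M is dense n×n); real-valued data on a scale where Euclidean
geometry after the chosen normalization is meaningful.  The
factorization itself makes no distributional assumptions — which is why
normalization is delegated to explicit front-ends.

## Choice of M

* `dct2` (default): the **orthonormal** DCT-II.  "Scaled DCT" is
  implemented as the unit-norm-row variant so that ×₃ M is an exact
  isometry; then Frobenius errors in the hat and original domains
  coincide, and the truncation-error identity
  ‖A − A_q‖²_F = Σ_{h>q} σ̂_h² holds exactly.  The DCT decorrelates
  smooth temporal profiles, concentrating slow trajectory variation in
  the leading faces.
* `haar_random`: an orthogonal matrix drawn uniformly (Haar) via QR of a
  Gaussian matrix with the R-diagonal sign fix; the seed is stored in
  the `MTransform` so runs are bitwise reproducible.
* `custom`: any invertible matrix; only orthogonal M gives the isometry
  guarantees, and only real matrices are supported so scores and
  loadings stay real.

## Economy decomposition and ranking

Per face we keep k = min(m, p) singular triplets.  'omics data has
p ≫ m, and the p − m trailing hat-domain singular values are exactly
zero, so the full p×p×n V is never materialized and the ranking vector
spans k·n tuples (the omitted tuples all carry σ̂ = 0 and no score or
loading information).  Ties in the global sort are broken by ascending
diagonal index, then ascending face index (a stable sort over the
row-major (diagonal, face) flattening), making the factor order fully
deterministic.

**Sign convention.** For each hat-domain singular pair, the
largest-magnitude entry of the V̂ column is made positive (ties resolved
to the lowest feature index) and the Û column flips with it.  This makes
two fits of the same tensor bitwise identical across runs.

**Loadings.** Row h of the q×p loadings matrix is the (r_{h,1})-th
hat-domain right singular vector of face r_{h,2}.  Rows therefore have
unit Euclidean norm and rows sharing a face are mutually orthogonal.
(The alternative reading — a row rather than a column of V̂ — would not
be unit-norm nor consistent with the projection formula; we use the
column.)

## Truncation and choosing q

Explicit rank-q truncation zeroes all but the q top-ranked hat
diagonals.  Scores and loadings nest: the rank-q embedding is bitwise
the leading block of the full one, so q can be chosen after the fit
(`choose_q_by_variance` picks the smallest q whose cumulative explained
variance reaches a threshold; `scree_table` supports scree-plot
inspection).  Exhaustive enumeration on small instances confirms that no
other keep-set of q hat diagonals achieves a smaller reconstruction
error, and random pseudo ⋆_M-orthogonal rank-q maps (random orthonormal
hat-face columns with a random keep-set) never capture more score
variance nor distort the mode-1 Gram configuration less — the two
optimality properties that justify running PERMANOVA-style tests on the
scores.

## Normalization front-ends

All front-ends operate per subject or per sample and log their
parameters; replaying the log on raw data reproduces the output bitwise.

* **DFB** (deviation from baseline): subtract each subject's own
  baseline value per feature.  Several baseline timepoints are
  aggregated by their arithmetic mean — the simplest subject-level
  reference.  Baseline slices become exactly 0 and are retained so n
  stays constant across subjects.
* **LFB** (log-fold from baseline): log_b((x + c)/(x_base + c)) with a
  symmetric pseudocount, default c = 1 (counts) and base 2 — the
  standard log-fold-change convention, with both knobs explicit.
* **rclr**: per sample, ln(x) minus the mean ln over that sample's
  nonzero entries; zeros are excluded from the geometric mean and stay 0
  (matched-mask convention), avoiding pseudocount distortion in sparse
  compositions.  A sample with no nonzero feature is an error.
* **filter_features**: minimum nonzero prevalence and minimum overall
  mean; thresholds are required parameters since sensible values are
  dataset-specific.

Missing whole (subject, timepoint) samples can be imputed by zeros, LOCF
(with backward fill at the series start) or per-tube linear
interpolation (clamped at the edges).  Features merely absent from a
present sample are 0, not missing — standard feature-table semantics.
Tensor-completion imputation is out of scope.

## Synthetic data

`generate_longitudinal_tensor` draws
entry = baseline_j + offset_{i,j} + effect_{g(i),t}·1[j ∈ signal] + ε,
with Gaussian subject offsets (sd default 1.0, emulating the large
stable inter-individual differences of real cohorts), Gaussian noise (sd
default 0.1), and per-group temporal effect profiles (default: group g
ramps linearly to slope g, group 0 flat).  Defaults of 2 groups × 10
subjects × 50 features × 6 timepoints mirror a small longitudinal
intervention cohort.  A `counts` mode pushes the continuous value
through exp → Poisson, giving sparse non-negative integers for rclr
testing.  All randomness flows from one seed via numpy generator
spawning.

What the generator does **not** emulate: ecological interactions,
compositional closure, overdispersion beyond log-normal–Poisson,
realistic missingness mechanisms, or measurement batch effects.  Tests
that pass on it certify the algebra and the pipeline plumbing, not
biological discovery performance on real cohorts.

`planted_rank_tensor` builds U ⋆ S ⋆ Vᵀ with exactly q nonzero,
well-separated hat diagonals (values in [1, 2]) at random positions, for
rank-recovery and truncation tests.

## Numerical choices

* Degenerate input: if the centered tensor's total variance falls at or
  below (1e-12·max(‖A‖_F, 1))², `fit` raises instead of returning NaN
  explained-variance fractions; the relative floor absorbs the ~ε
  residue of centering identical slices.
* ⋆_M-orthogonality checks default to tol 1e-8; reconstruction checks to
  1e-10 relative — both comfortably above float64 SVD error for the
  sizes involved.
* `transform` centers internally with the stored Ā; callers always pass
  raw (uncentered) data.
* Out-of-range q, negative singular values, non-finite tensors, unknown
  enum values: immediate `ValueError`s with the offending value named.

## Problem sizes

Unit and property tests run on tensors up to ~10×40×8; exhaustive
truncation-optimality enumerates all C(12, q) keep-sets on 4×5×3
tensors; competitor-map comparisons use 200 random maps × q ∈ {1,2,5} ×
10 tensors of shape 6×8×3; synthetic recovery uses 40 seeds of a
2×8-subject, 30-feature, 5-timepoint cohort.  These sizes make the whole
suite and the acceptance script run in seconds while still covering the
m<p / m=p / m>p regimes and n ∈ {1, 2, 5, 8}.

## Known limitations

* Order-3 tensors only; no higher-order generalization.
* Real orthogonal M only (no DFT/unitary transforms); no data-adaptive
  selection of M.
* No tensor completion: missing data must be imputed (naively) before
  fitting.
* Statistical testing on scores (PERMANOVA, ANOVA, mixed models, FDR)
  is downstream and out of scope; the package only guarantees that the
  score geometry faithfully represents trajectory distances.
* The input formats are tidy long CSV and per-timepoint wide TSV;
  feature tables in other containers should be melted to long form
  first.
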