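# Methods

## Problem and model

The package grades the pathological severity of diabetic nephropathy (DN)
from routine clinical variables, without renal biopsy at prediction time.
Two tasks are supported: binary glomerular grading (Renal Pathology Society
classes I–II "mild" vs III–IV "severe") and 3-class interstitial fibrosis /
tubular atrophy (IFTA) grading (scores 0–1, 2, 3).

The predictive core is a *tabular-to-text-to-vector* pipeline: the record is
serialized into a clinical narrative by deterministic slot filling; two
frozen causal language models embed the narrative; a second-order
co-occurrence head fuses the multi-layer embeddings; and a small MLP is
trained end-to-end with the fusion parameters on the downstream label.  The
language models are pure feature extractors — no fine-tuning, no gradient
into the backbones, no text generation — which keeps the trainable footprint
at the downstream stack (≈46.3 M parameters at full scale: 10 projections
4096→1024 ≈ 42.0 M, the scalar γ, and an MLP head 4196→1024→C ≈ 4.3 M).

Alongside the pipeline, a biomarker-statistics surface covers the
platelet-to-albumin ratio (PAR = PLT[10⁹/L] / ALB[g/L]): empirical ROC,
Youden-index cutoff, 2×2 predictive values, and the unadjusted odds ratio.

## Serialization

The default template renders demographics, renal function, PAR ("Core
Indicator"), and the metabolic/hematologic context in a fixed sentence
order.  Choices the template itself does not determine:

* Hypertension maps to "Comorbid Hypertension"; the normotensive phrase is
  rendered as "Normal Blood Pressure" (a package choice — only the
  hypertensive phrase is dictated by the reference narrative style).
* 24-h proteinuria is stored in g/24 h but serialized in mg (×1000, integer)
  to honor the template's "mg" unit label.
* Numbers are rendered at their stored precision without trailing zeros
  (`"g"` formatting); per-placeholder format specs can override this.
  Serialization is therefore injective across records that differ in any
  serialized field.

Templates are user-overridable via plain-text files; unknown placeholders
are rejected at validation time.

## Embedding extraction

For a narrative of S tokens, a backend with L transformer layers and hidden
width D yields, per layer, an S×D hidden-state sequence.  Because the
backbones are decoder-only (each token attends only to its predecessors),
the final token aggregates the whole context, so the sequence representation
of layer k is the last token's state.  The last K = 5 layers are kept,
giving a K×D stack per backend; "last K layers" excludes the embedding
layer's output and includes the final layer.  The primary backend
additionally provides a token-mean of its final layer (the `v_Q` tail of the
fused vector); mean pooling over tokens of the final layer (rather than over
the K layer vectors) is the adopted reading and is fixed here.

The mock backend derives each token state from a BLAKE2 hash of
(seed, layer, position, token), mapped through a PCG64 generator to a
standard-normal vector.  It is bit-reproducible across processes, needs no
checkpoints or network, and is sensitive to any change in the narrative
text — which is the property the tests rely on.  What it does **not** model:
semantic similarity (two clinically similar narratives get unrelated
embeddings), token interactions, or any medical prior knowledge.  Passing
desk-scale tests therefore demonstrates the correctness and determinism of
the machinery, not the clinical value of LLM features; above-chance CV
metrics on the mock backend arise only from the hash features incidentally
encoding label-correlated text differences.

## Fusion

The 2K = 10 layer vectors (primary's 5 layers ascending, then secondary's 5)
are each compressed by their own affine map + ReLU to 1024 dimensions —
per-vector maps, not shared.  The stack X ∈ R^{10×1024} forms the Gram
matrix C = XXᵀ, capturing second-order interactions across layers and
models.  Fixed conventions where the construction is order-dependent:

* Row order into X: primary-then-secondary, layers ascending.  C is
  equivariant only under simultaneous row permutations, so this is part of
  the model definition.
* C is flattened row-major; all 100 entries are used (not just the upper
  triangle), since the head is defined as 100-dimensional.
* p = 2σ(γ·c_flat) − 1 with γ initialized to 1.0 and trainable
  (sign-unconstrained).  The sigmoid argument is capped at ±36 so p honors
  the strict (−1, 1) bound in float64 even for extreme co-occurrences.

The bounded head is the architectural regularizer; only boundedness is
asserted by tests, not any overfitting claim.

## Classifier and optimization

MLP head: affine(fused→hidden) → ReLU → dropout(p = 0.5, the single
activation layer) → affine(hidden→C).  Default hidden width 1024, which
lands the full-scale stack near the ≈46.5 M reference budget (the computed
total is 46.25 M; the exact decomposition behind the reference figure is not
published, so the ≈0.25 M gap is noted, not resolved).

Loss: weighted label-smoothed cross-entropy.  Class weights
w_c ∝ 1/(N_c + ε) with ε = 1e-8, normalized to unit mean, computed on the
training fold.  Label smoothing α = 0.1.  The implementation is checked
against an explicit per-sample/per-class double loop to 1e-6 and reduces to
plain cross-entropy at α = 0, w ≡ 1.

Optimizer: AdamW (decoupled weight decay 1e-2; biases and γ exempt from
decay, as is conventional), initial lr 1e-4, cosine annealing to 0 over
300 epochs, batch 32.  All of this is hand-written NumPy with manual
backpropagation through the MLP, the scaled sigmoid, the Gram matrix, and
the ReLU projections; gradients are verified against central finite
differences in the test suite.

Augmentation: "noise scaled up to 20 times" is read as up to 20 noisy
copies per real sample, each with zero-mean Gaussian noise of per-feature
sd = noise_scale × the feature's training-fold sd (noise_scale default 0.1).
Both knobs are exposed; copies are regenerated every epoch (real-time
augmentation), in the raw embedding space for the end-to-end model.  The
original batch is always retained.

Determinism: one master seed fans out through a single `numpy.random`
Generator to initialization, per-epoch augmentation noise, shuffling, and
dropout masks, so a fixed seed reproduces the loss history exactly.

## Evaluation protocol

Stratified 5-fold CV (per-fold class counts within one sample of
proportional allocation; every class must have ≥ k members).  Per fold, the
standard scaler, class weights, and augmentation statistics are fitted on
the training folds only; an internal guard recomputes the scaler mean from
the training indices and fails the run on any mismatch.  Metrics: binary
F1/sensitivity on the severe class, specificity on the mild class, AUC from
the severe-class probability; multiclass macro-F1, macro one-vs-rest AUC,
and macro-averaged one-vs-rest sensitivity/specificity (averaged unweighted
over classes present in the fold; a fold missing a rare class averages AUC
over present classes).  Multiclass prediction is the softmax argmax with
ties broken toward the lower class index.  Baselines (same folds,
standard-scaled tabular features): 4-variable clinical logistic regression
(age, eGFR, 24-h proteinuria, PAR), full-feature LR (max 1,000 iterations),
RBF-kernel SVM, 100-tree random forest, XGBoost; hyperparameters beyond
these are the libraries' defaults.

## Biomarker statistics

ROC thresholds are the midpoints between adjacent sorted unique scores plus
∓∞ sentinels; a score ≥ threshold is a positive call.  The trapezoidal area
over the staircase (lexicographic (FPR, sensitivity) traversal so vertical
climbs precede horizontal moves) is asserted equal to the Mann-Whitney rank
statistic to 1e-10 on every call.  The Youden cutoff maximizes
J = sensitivity + specificity − 1; ties favor higher specificity, then the
lower threshold.  Scores inversely related to the outcome (AUC < 0.5) are
negated with a warning.  The odds ratio uses the Haldane-Anscombe +0.5
correction when any cell is zero, with a Wald log-scale CI.  The AUC CI is
a percentile bootstrap over patients with a stated seed — a method choice;
it is not expected to match parametric CIs from other software.

## Synthetic cohort generator

The generator emulates a 195-patient biopsy cohort (39 mild / 156 severe at
default mix; deterministic largest-remainder allocation).  Per stratum and
per lab, distributions are chosen by the shape of the reference summaries:
labs summarized as median (IQR) — skewed — are log-normal with
μ = ln(median) and σ = (ln q3 − ln q1)/(2·z₀.₇₅); labs summarized as
mean ± sd — roughly symmetric — are truncated normals (albumin on
[12, 55] g/L; eGFR on [30, 170], the lower bound being the study's
exclusion threshold).  Severity direction is inherited from the group
summaries: severe strata have stochastically higher PLT, sCr, proteinuria
and (via derivation) PAR, and lower Hb and eGFR.  PAR is always recomputed
from the generated PLT and ALB, never sampled.  Sex and hypertension are
Bernoulli at the group frequencies.

Values the reference summaries do not cover, fixed once as realistic
choices: diabetes duration log-normal with median 10 y, IQR ≈ (5, 16);
glomerular class within strata 1:2 = 0.35:0.65 and 3:4 = 0.55:0.45; IFTA
given stratum (0.30, 0.45, 0.20, 0.05) for mild and (0.02, 0.13, 0.45,
0.40) for severe, which keeps every 3-class label ≥ 5 members at n = 195.
Labs are sampled independently within stratum (no joint distribution is
published); the only built-in correlations are stratum membership and the
derived PAR.  Consequently the generator reproduces marginals and group
contrasts, not the real covariance structure — multivariable results on
synthetic data say nothing about real-cohort adjusted effects.

## Problem sizes and degenerate inputs

Desk-scale runs (tests, acceptance script) use mock backends at D = 32,
L = 8, projection width 128, hidden width 128, 40 epochs and 2 augmentation
copies — the package's chosen profile for fast, deterministic end-to-end
verification; full-scale defaults (D = 4096, 1024/1024, 300 epochs, 20
copies) remain on the estimators.  Degenerate inputs are contracts, not
crashes: empty narrative text, K > L, non-one-hot labels, single-class
training folds, zero 2×2 denominators (flagged `undefined`), and incomplete
CSV rows (rejected with row/column coordinates — complete-case analysis; no
imputation) all raise typed errors or flags.

## Known limitations

* The mock backend validates machinery, not the semantic-feature hypothesis;
  real-checkpoint runs require the optional torch/transformers extra.
* Published cohort-dependent performance values (cross-validated F1/AUC
  tables, the PAR AUC 0.716 / cutoff 7.155, adjusted odds ratios) are not
  reproducible without the private cohort and 8-B checkpoints; the package
  reproduces the in-table 2×2 arithmetic and the protocol, and its CV
  numbers on synthetic cohorts are qualitatively, not numerically,
  comparable.
* Multivariable logistic regression, spline non-linearity tests, DeLong/IDI
  comparisons are deliberately out of scope; established statistics
  packages cover them.
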