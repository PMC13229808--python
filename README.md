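# nephrotext

Non-invasive grading of diabetic-nephropathy (DN) severity from routine
clinical variables, via a fine-tuning-free *tabular-to-text-to-vector*
pipeline, plus the platelet-to-albumin-ratio (PAR) biomarker statistics that
motivate it.

## Who this is for

Clinical-ML researchers working with small biopsy-proven cohorts who want to
(a) study PAR = PLT / ALB as a severity biomarker for DN (ROC, Youden
cutoff, predictive values, odds ratio), and (b) experiment with frozen
large-language-model embeddings as features for tabular clinical prediction
without fine-tuning anything.

## The method

Given a patient record `x_i` (≈22 routine variables) and a pathological
label `y_i` (glomerular class I–IV, binarized to mild I–II vs severe
III–IV; or the IFTA score 0–3, re-binned to 0–1 / 2 / 3):

1. **Serialize** — a slot-filling template `P(·)` maps `x_i` to a clinical
   narrative `T_i = P(x_i)` ("Basic Information: 58 years old Male, …
   Core Indicator: Platelet-to-Albumin Ratio (PAR) is 7.73. …").
2. **Embed** — two frozen causal LMs (a primary and a secondary stream)
   encode `T_i`; the hidden state at the last token of each of the last
   K = 5 layers gives `v^(k) = H^(k)[last]`, so each model yields a K×D
   stack.
3. **Fuse** — the 2K = 10 vectors are compressed by per-vector affine maps,
   `u_j = ReLU(W_j v_j + b_j)` (1024-dim), stacked into `X ∈ R^{10×1024}`,
   and combined through the co-occurrence (Gram) matrix `C = X Xᵀ`.  `C` is
   flattened row-major and squashed, `p = 2·σ(γ·c_flat) − 1 ∈ (−1,1)^100`,
   then concatenated with the primary model's mean-pooled final-layer
   embedding: `f_i = [p, v_Q]` — exactly 100 + 4096 = 4,196 dimensions at
   D = 4096.
4. **Classify** — an MLP head (affine → ReLU → dropout 0.5 → affine) is
   trained end-to-end with the projections and γ under AdamW (lr 1e-4,
   weight decay 1e-2, cosine annealing, 300 epochs, batch 32), Gaussian
   noise augmentation, inverse-frequency class weights `w_c ∝ 1/(N_c + ε)`
   normalized to unit mean, and label smoothing
   `y^LS = (1−α)y + α/C`, α = 0.1:

   `L = −(1/N) Σ_i w_{y_i} Σ_k y^LS_{i,k} log softmax(z_i)_k`

5. **Evaluate** — stratified 5-fold CV with fold-local scaling, reporting
   F1 / AUC / sensitivity / specificity (macro variants for the 3-class
   task), against tabular baselines (clinical 4-variable logistic
   regression, full LR, RBF-SVM, random forest, XGBoost).

No checkpoint is required to use the package: a deterministic mock backend
(hash-derived hidden states) exercises the full pipeline at desk scale, and
a synthetic cohort generator emulates the marginal distributions of a
195-patient biopsy cohort (39 mild / 156 severe).  Real checkpoints plug in
through an optional `transformers` adapter.

## Worked example

```bash
nephrotext generate --n 195 --seed 1 --cohort cohort.csv
nephrotext clinstats --cohort cohort.csv --out out --seed 0 --n-boot 500
```

prints (abridged):

```json
{
  "auc": 0.6851577909270217,
  "optimal_cutoff": 8.815000000000001,
  "metrics": {
    "undefined": [],
    "sensitivity": 0.4807692307692308,
    "specificity": 0.9230769230769231,
    "ppv": 0.9615384615384616,
    "npv": 0.3076923076923077
  },
  "odds_ratio": {
    "odds_ratio": 11.11111111111111,
    "ci_low": 3.2837823874109797,
    "ci_high": 37.59591092173233
  }
}
```

Read: on this synthetic cohort, PAR separates severe from mild glomerular
lesions with moderate discrimination (AUC ≈ 0.69); at the Youden-optimal
cutoff (≈ 8.8), a high PAR is a strong rule-in signal (PPV ≈ 0.96) but a
low PAR does not exclude severe disease (NPV ≈ 0.31) — the same qualitative
picture real biopsy cohorts show.

The fusion pipeline on the mock backend:

```bash
cat > config.yaml <<EOF
cohort_path: cohort.csv
output_dir: out
task: glomerular
seed: 0
proj_dim: 128
train: {hidden_dim: 128, epochs: 40, augment_copies: 2}
EOF
nephrotext run --config config.yaml
```

writes `out/cv_report.json` with per-fold and mean ± sd metrics and
`out/predictions.csv` with per-patient held-out probabilities.

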