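# Methods

## The two-phase model

**Phase 1 — dual-loss autoencoder.** Each grayscale radiograph
`x ∈ [0,1]^{H×W}` is mapped by a convolutional encoder `Q_φ` to a latent
vector `z = Q_φ(x)` of dimension `d` (default 128; the full-scale value
8192 used on real radiographs is supported).  The latent feeds two heads trained jointly:

* a mirrored convolutional decoder `P_θ` under the reconstruction loss
  `L₁ = mean_i ‖x_i − P_θ(Q_φ(x_i))‖² / (H·W)`;
* a three-layer Leaky-ReLU dense classifier `D_ψ` with a single sigmoid
  output, under the binary cross-entropy `L₂` on the severe-periodontitis
  label (severe = generalised Stage III or Stage IV).

The training objective is `L = L₁ + w·L₂` with `w = 1` by default;
reconstruction gradients flow through decoder + encoder and classification
gradients through head + encoder within the same batch.  `w = 0` gives the
plain-autoencoder ablation used to quantify the benefit of the second
loss.  Optimisation is Adam with the two-phase schedule: 10 epochs at
learning rate 1e-4, then 10 refinement epochs at 1e-5, batch size 32.
Sigmoid + binary cross-entropy is used for the head (equivalent to a
two-way softmax for binary labels); the Leaky-ReLU negative slope is 0.01;
the head consumes the full latent vector.

The encoder is a stack of stride-2 3×3 convolutional blocks (channels
8→16→32 by default) flattened into a dense bottleneck; the decoder mirrors
it with nearest-neighbour upsampling + convolution blocks and a sigmoid
output layer.  The bidirectional-ConvLSTM skip stage of the BCDU-style
architecture family is deliberately omitted at desk scale: the testable
mechanism here is the dual loss, not the skip dialect, and a plain
convolutional encoder/decoder keeps the CPU cost of the multi-seed suites
tractable.

All layers, backpropagation and Adam are implemented directly on numpy in
`perifuse.nn` (no deep-learning framework is a dependency of this
package).  Computation is float32; training is bit-reproducible on a
single device because every random draw (init, shuffling, dropout) flows
through explicitly seeded `numpy.random.Generator` objects.

**Phase 2 — three-branch fusion.** The frozen latent vector passes
through branch `N₁` (dense, `d → 32`) and the eight tabular features
through `N₂` (dense, `8 → 32`), so both feature sets enter the
concatenation at equal width — this is what keeps the much larger image
feature set from dominating.  The concatenated vector feeds `N₃`
(64 → 64 → 32 → 1 by default) with ReLU activations
(`u_L = ReLU(W·x + b)`), dropout (rate 0.5) between dense layers and a
sigmoid output.  One binary classifier is trained per ICD-10 chapter:
Adam, learning rate 1e-4, batch size 50, 300 epochs.  Unimodal ablations
drop one branch entirely, leaving everything else unchanged.  Latents are
not fine-tuned in phase 2 (strictly two-phase pipeline).

Both branch inputs are standardized with training-set statistics.  The
tabular z-scoring is required because the eight features mix scales
(income vs stage code); the latent z-scoring is this package's own design
choice — with raw-scale latents the two branches learn at very different
effective rates under the shared 1e-4 learning rate, and the fused model
can fail to use the tabular branch at all.

**Width defaults.** The exact layer tables of the original networks are
unpublished; `N₁`/`N₂` output widths default to 32/32 (equal, honouring
the stated motivation of balancing the feature sets) and the config
rejects widths differing by more than 4×.

## Synthetic cohort

The real cohort (1188 panoramic radiographs + hospital records) is
private, so the package generates cohorts with the statistical structure
the method assumes:

* Hidden severity score `s = √w_img·z_img + √w_tab·z_tab + √(1−w_img−w_tab)·z_res`
  with independent standard-normal factors; default signal weights
  0.5/0.5.  The severe label is `s > τ` with `τ = Φ⁻¹(1 − 0.458)`, so the
  expected severe fraction is the 45.8% split of the reference cohort
  (544 of 1188).  A seven-rung stage ladder (health … Stage IV) is carved
  out of fixed population quantiles of `s`; the top two rungs form the
  severe group.
* **Images** are a schematic tooth-row texture (bright tooth blocks over a
  uniform alveolar-crest band).  In severe subjects the crest band is
  eroded by `lesion_effect·(0.5 + 0.5·Φ(z_img))` — presence encodes the
  label, depth encodes the image-borne risk factor — plus Gaussian pixel
  noise (sd 0.05 by default) and 8-bit PNG quantization.  The lesion mask
  marks exactly the pixels whose expected intensity differs between
  labels; its area fraction (≈ 14% of the image) is the chance baseline
  for Grad-CAM localization.  No anatomical realism is attempted: the
  preserved property is that disease signal is spatially localized, which
  is what saliency must find.
* **Tabular features** (age, gender, income, teeth number, stage code,
  three bone-loss measures) load linearly on the tabular-borne factor
  `z_tab` with clinically signed loadings (e.g. teeth number −0.50, bone
  loss ≈ +0.7); gender is an independent Bernoulli(0.61 female).
  Missingness, when requested, is injected only into the bone-level
  columns, which is where it occurs in practice, and is repaired by mean
  imputation.
* **Chapter labels** follow `logit p = α_c + β·(s_img + s_tab)` with
  `s_img = √w_img·z_img`, `s_tab = √w_tab·z_tab`, `β = 2.5`, and `α_c`
  solved by Gauss–Hermite quadrature + root finding so the marginal
  prevalence matches the configured value.  Chapters are conditionally
  independent given the risk components (no co-occurrence structure is
  modelled).

Because the two modality factors are independent, modality-wise Bayes
AUCs are known: ranking the severe label by a single factor of weight `w`
has AUC given by a two-dimensional Gaussian integral (evaluated to machine
precision by Gauss–Legendre quadrature in `perifuse.theory`; 0.8267 at
`w = 0.5`), while the full score separates the thresholded label perfectly
(AUC 1).  The classical closed form `Φ(d/√2)` for the unconditional
Gaussian-shift model is included as a cross-check of the quadrature
machinery.  These oracles bound what trained models can achieve and are
asserted in the tests.

What the generator does **not** emulate: anatomical content, scanner and
positioning artefacts, site effects, label noise, chapter co-occurrence,
and real covariate distributions.  Passing tests therefore demonstrate
that the pipeline recovers planted, well-specified signal — not clinical
performance.

## Evaluation harness

* AUC is the tie-corrected Mann–Whitney statistic; the ROC curve comes
  from scikit-learn.  Ties get half credit, and midrank placement values
  are used throughout the DeLong machinery.
* The single-AUC confidence interval is the normal interval with the
  DeLong structural-components variance, clipped to [0,1]; a collapsed
  variance (perfect AUC at tiny n) is widened by a `1/(mn)` continuity
  floor and flagged.  The paired two-model comparison is DeLong's
  two-sided z-test with the placement-covariance variance of the AUC
  difference.  Calibration (type-I error 5% ± 1% at n = 200 over 2000
  null replicates) and variance agreement with bootstrap/jackknife
  oracles are asserted in the acceptance suite.
* Splits are severity-stratified 70/30 with stratified ten-fold CV inside
  the training portion.  One global split is drawn up front and reused by
  both phases, so the phase-1 autoencoder never sees test subjects; the
  evaluation entry point raises a hard error on any train/test overlap.
  Class balancing (random downsampling of the majority to the minority
  count) triggers only when the majority exceeds twice the minority
  ("extremely unbalanced"), is applied to the training portion only, and
  never drops a minority subject.
* Per-chapter reports carry threshold metrics (threshold 0.5 by default)
  with mean ± sd over `n_refits` re-trainings from different seeds,
  a row-normalized confusion matrix, the CV AUC distribution, the
  DeLong CI of the test AUC, and fused-vs-unimodal DeLong p-values.
  The F1/precision/recall harmonic identity is checked per refit.

## Interpretability

Grad-CAM targets the last convolutional activation of the encoder
(configurable) with the severity-head logit as the class score; channel
weights are spatially averaged gradients, the map is ReLU-ed, bilinearly
upsampled and min-max normalized.  `localization_score` is the fraction of
heat mass inside the planted lesion mask — the quantitative surrogate for
"the model attends to the periodontal area"; its chance level is the mask
area fraction.  The latent PCA projection uses mean-centred top-2
components with a deterministic sign convention (largest-magnitude loading
positive); the severity silhouette of the 2-D projection is the
quantitative surrogate for "two separated clusters".

## Study conditions and problem sizes

The multi-seed study behind the fusion-superiority, dual-loss and
interpretability claims uses five independent cohorts of n = 400 at
32×32 pixels, latent dimension 64, the default signal weights (0.5/0.5),
lesion effect 0.35, pixel noise 0.05, and chapter IX (the most prevalent,
0.40) as the phase-2 target.  These sizes were fixed as the package's
desk-scale defaults: large enough that the Bayes-AUC ordering of the
generator is resolvable above Monte-Carlo noise, small enough that the
whole suite trains ten autoencoders on one CPU in minutes.  The
end-to-end demo uses 120 subjects and three chapters.

## Numerical choices and degenerate inputs

* Probabilities are clipped at 1e-7 inside the cross-entropy; the
  training path uses the logit-stable form.
* Thresholded predictions with an empty predicted-positive set report
  precision/F1 as undefined rather than zero.
* CV folds whose validation part is single-class are skipped with a
  warning and reported.
* `epochs = 0` returns the freshly initialized model unchanged; an
  all-zero image encodes to a finite latent.
* Image sizes must be divisible by `2^depth` (encoder downsampling);
  PNG round trips are exact to 8-bit quantization, and the subject CSV
  round-trips bit-exactly (floats serialized with `repr`).

## Known limitations

* Synthetic images only; no claim transfers to real radiographs without
  retraining and revalidation.
* The probe saturates (AUC 1.0) at the default lesion strength, so the
  dual-loss comparison at these conditions demonstrates "no degradation"
  rather than a strict gain; weaker-signal configurations separate the
  two objectives more sharply.
* No multiple-testing correction across chapters (none is applied in the
  reference design), no probability calibration, no multi-label joint
  modelling.
* Bit-level reproducibility is guaranteed on a single device; across
  BLAS implementations results agree only to floating-point tolerance.
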