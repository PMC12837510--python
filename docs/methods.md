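# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The continual pretraining model

The pipeline models the clinical situation where unlabeled chest-CT data
arrives in sequential domains — here, the mediastinal and lung window
renderings of the same anatomy — and earlier raw images may not be kept.

**Stage 1: masked autoencoding.** Images are tiled into n patches of size
(V, V); m = round(n·r) patches are masked uniformly at random (round half
up; r = 0.75 by default). The tokenizer (patch embedding plus learnable
positional encodings) and a pre-norm ViT encoder see only the n−m visible
tokens; a lighter decoder receives the encoded visible tokens plus a shared
learnable mask token at each masked position — never the masked pixels —
and predicts the masked patch contents. The loss is the mean squared error
over masked pixels, normalized by m·V²·C. One mask is drawn per mini-batch
iteration and shared across the batch; the encoder's blindness to masked
content is asserted by test (two images differing only on masked patches
encode identically).

A class token is kept in the encoder but excluded from extracted token
features, so the feature matrix of an image has exactly T = n rows. This
keeps the T×T affinity of the ensembling step aligned with the patch grid.

**Stage 2: the latent-replay buffer.** Every first-domain image is encoded
(full, unmasked pass) to a T×E matrix. Clustering operates on token-mean
pooled vectors — pooling exists only for clustering; the stored record is
the full T×E matrix. k-means with k = round(N·α) (seeded k-means++, 10
restarts, Euclidean metric, via scikit-learn) partitions the pooled
vectors; from each cluster the q = round(β/α) members nearest its center
are kept, ties broken by lowest source index. Rounding can make the
per-cluster quotas overshoot or undershoot round(N·β): overshoot drops the
globally farthest selections, undershoot backfills with the globally
nearest unselected members, so the buffer always holds round(N·β) records.
Defaults α = 0.01, β = 0.05. No transformation or compression is applied
to stored features. The privacy contract — the archive contains no
image-shaped arrays — is asserted by test. An `experience` mode stores raw
images instead and is the ablation baseline.

**Stage 3: continual pretraining with feature distillation.** The student
model starts from the stage-1 weights (continual-pretraining convention;
no re-initialization). Each iteration runs, on the same augmented
mini-batch: a masked pass for L_SSL, an unmasked pass for the student
features P_S (the masked pass yields only n−m tokens, and the T×T affinity
needs all T), a replay draw of equal size for the teacher features P_T,
and the distillation loss. The total objective is
L_total = L_SSL + λ_fd·L_FD with λ_fd = 1 by default. With λ_fd = 0 the
loop consumes the identical random stream and reproduces plain sequential
masked autoencoding bit-for-bit — this exact equivalence is a test.

**WKD.** A feature batch is summarized channel-wise by μ (mean) and δ
(population standard deviation, divisor d) over all d = B·T token vectors,
treating tokens as the spatial samples of a feature map and channels
l = E. The loss is γ·‖μ_T − μ_S‖₂ + ‖δ_T − δ_S‖₂ with *unsquared*
Euclidean norms — the implementation follows this form exactly rather than
the squared Gaussian-2-Wasserstein decomposition. Diagonal covariance only;
the Gaussian density itself is never evaluated. γ defaults to 2.0.

**BKE.** Teacher and student token vectors are L2-normalized (ε = 1e−12
guards the division; an exactly zero-norm token raises). Per batch slice,
A[b,i,j] = ⟨p̂ᵀ[b,i], p̂ˢ[b,j]⟩; the normalization is a softmax over j with
self-exclusion, giving Â with zero diagonal, non-negative entries and unit
row sums. The propagation Q⁽ᵗ⁾ = ωÂQ⁽ᵗ⁻¹⁾ + (1−ω)P_T converges (ω < 1,
row-stochastic Â) to Q_T = (1−ω)(I−ωÂ)⁻¹P_T, computed as a batched linear
solve, never an explicit inverse. The propagation matrix is entrywise
non-negative with unit row sums, so ensembled tokens are convex
combinations of teacher tokens; closed form and 60-step iteration agree to
1e−6 by test. ω defaults to 0.5. Teacher quantities (P_T, Â, Q_T) are
constants during optimization; gradients flow only into P_S.

Two readings of the affinity index were possible (token-level T×T within
each batch slice vs batch-level B×B); the token-level reading is
implemented because the stated shape B×T×T and the product ÂP_T
(T×T by T×E) both require it.

**Multi-stage sequences.** For more than two domains, training and buffer
construction alternate and buffers are merged cumulatively, so later
stages replay memory from all earlier domains; per-record stage ids are
preserved.

**Fine-tuning.** The final encoder plus an MLP head is trained end-to-end
with cross-entropy. Token pooling for classification is mean ⊕ smooth-max:
the mean channel carries global context, the log-sum-exp channel
(temperature 0.1) approximates a per-channel max over tokens so that focal
findings — a nodule occupies only a few of the 64 patch tokens — survive
pooling. The pooled vector passes through LayerNorm and one hidden GELU
layer. Mean pooling alone put the head on a long optimization plateau at
this scale because pooled features of a small ViT have little
between-sample variance. The best-validation-accuracy weights are
retained. The retention (forgetting) probe is deliberately lighter: a
frozen-encoder logistic regression on token-mean pooled features, the same
for every checkpoint compared.

## Synthetic phantoms

The generator draws a cartoon axial chest slice in Hounsfield units: air
background (−1000 HU), soft-tissue body ellipse (40 HU), two lung
ellipses (−750 HU), a bone disc (700 HU), with mild geometric jitter and
per-compartment Gaussian noise (sd 10–30 HU). Class 1 adds a solid nodule
(disc, radius 3–6 px, 30 HU — soft-tissue density) inside a lung; class 2
adds a ground-glass opacity (Gaussian profile, peak +300 HU by default)
to the lung parenchyma. Rendering samples one (WL, WW) pair per image
uniformly from clinically standard preset ranges — mediastinal 40±20 /
350±50 HU; lung −625±75 / 1350±350 HU (with a second lung preset
−600±100 / 1300±300 HU) — emulating inter-scan variability of viewing
presets.

What the phantoms reproduce: the physically meaningful domain shift
between window settings (the mediastinal window saturates aerated lung to
black; the lung window resolves it), HU-scale tissue contrast, and lesion
classes whose visibility is window-dependent — the soft-tissue nodule is
conspicuous in the mediastinal window, the ground-glass opacity only in
the lung window. What they do not reproduce: anatomy (no ribs, vessels,
airways), scanner physics (no projection, beam hardening, or
reconstruction-kernel noise texture), 3-D structure, or inter-patient
variability beyond geometric jitter. Passing tests therefore demonstrate
that the pipeline's mechanisms behave as specified under a controlled
domain shift, not that the method attains any particular accuracy on real
chest CT.

## Study conditions and problem sizes

The bundled study (acceptance tests and `scripts/acceptance.py`) uses
200 images per domain, the default tiny encoder (64-px images, patch 8,
embed 64, depth 2, heads 4, decoder 48×1), 30 epochs per pretraining
stage (batch 64 in stage 1, 32 in stage 3, warm-up 4 epochs to peak rate
1.5e−3, cosine decay), α = 0.01, β = 0.05, γ = 2.0, ω = 0.5, λ_fd = 1.
The downstream task is nodule-vs-normal in the mediastinal window — chosen
as the *separable* task because the nodule is a high-contrast focal
finding there — with 100 training and 100 test images, fine-tuned 80
epochs at batch 32, constant rate 3e−3. The retention probe uses 100/100
first-domain images. These sizes keep a full three-seed study within a few
CPU-minutes; a paper-scale ViT-B/224 configuration is constructable
(`MAEConfig.vit_b()`) but not exercised by the tests.

The reference-scale recipe (batch 64/32, warm-up 40 epochs to 1.5e−4,
AdamW 5e−5 for fine-tuning, 300/80 epochs) is preserved in the
`StageConfig` and `finetune` signature defaults; the tiny profile in
`cssl_ct.config.DEFAULTS` overrides epochs, rates and sizes downward for
desk-scale runs. Of the two learning-rate prescriptions, the
warm-up/cosine schedule is assigned to pretraining stages and the flat
rate to fine-tuning.

## Numerical choices

- The tensor engine is float-dtype-following: model weights are float32
  (training path), while float64 inputs produce float64 graphs (oracle and
  test paths). All oracle comparisons run in float64.
- m = round(n·r), k = round(N·α), buffer size round(N·β) all use
  round-half-up.
- Gaussian statistics use the population divisor d, not d−1.
- The affinity softmax is computed without max-shifting (cosine
  similarities are bounded by 1, so overflow is impossible and the
  hand-worked values are exact); the classification smooth-max pooling and
  all classifier softmaxes are max-shifted.
- BKE's linear system is solved per batch slice with a dense LU solve;
  ω < 1 with a row-stochastic matrix guarantees nonsingularity.
- Degenerate inputs raise typed errors: non-positive window width,
  non-finite HU, masks that would leave zero masked or zero visible
  patches, zero-norm tokens, empty buffers, single-class label sets.
- Determinism: every source of randomness is an explicit
  `numpy.random.Generator`; pipelines are bit-reproducible under a fixed
  seed in single-threaded numpy.

## Known limitations

- The retention ordering between the distilled and no-replay arms is not
  statistically resolvable at these problem sizes: the distillation loss
  verifiably anchors the student's first-domain feature distribution (its
  stage-1 moment distance stays an order of magnitude smaller than without
  distillation), but the probe-AUC difference between the arms is within
  seed noise. The corresponding directional acceptance test reports this
  honestly; at these sizes it can fail by a margin smaller than the
  probe's seed-to-seed spread.
- Fine-tuning a small ViT on ~100 images is plateau-prone; the smooth-max
  pooling channel and best-validation snapshotting mitigate but do not
  eliminate per-seed variance.
- One mask per mini-batch (not per image); per-image masks would need a
  batched gather the engine does not currently provide.
- The buffer is rebuilt per stage and merged, never pruned; long
  curricula grow memory linearly.
- No DICOM rescale handling, no VOI-LUT sigmoid windows, no 3-D
  windowing; HU input is 16-bit PNG (+1024 offset) or NIfTI slices.
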