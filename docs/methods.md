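# Methods

## Architecture

Both network variants are generated from one declarative layer plan
(`mm3dunet.network.layer_plan`), which is also the ledger the analytic
complexity engine walks — there is a single source of truth, and the test
suite asserts that the instantiated network's introspected parameter total
equals the analytic total for every configuration tested.

* **Encoder.** `num_levels` (default 4) modules.  Module *i* applies two
  feature-extraction units — the first maps into width `base_channels·2^i`,
  the second preserves it — followed by 2×2×2 max pooling, so each module
  doubles channels and halves all three extents.  Input extents must be
  divisible by `2^num_levels`.
* **Decoder.** The mirror: each module opens with a 2×2×2, stride-2
  transpose convolution that doubles extents and halves channels,
  concatenates the matching encoder skip tensor, and applies two
  feature-recovery units (the first halves the concatenated width — the
  mirror of the encoder's doubling unit — the second preserves it).  A
  final 1×1×1 convolution maps to the segmentation classes and a sigmoid
  produces voxel probabilities.  We use the classical U-Net ordering
  (transpose → concatenate → units); a literal reading of the source
  description ("each module *ends* in a transpose convolution") would put
  the units one level deeper, but the accompanying architecture figure and
  the classical-U-Net skip-concatenation convention both point to the
  ordering implemented here.
* **Units.** In the mobile variant every unit is an inverted-residual CEC
  unit: 1×1×1 expansion to `t·C_in`, depthwise 3×3×3 in the widened space,
  linear 1×1×1 compression; LeakyReLU (slope 0.01) + instance norm
  (ε = 1e-5, learned affine) after the first two stages, nothing after the
  compression (the linear bottleneck); identity skip when `C_in = C_out`.
  In the baseline variant every unit is one standard 3×3×3 convolution +
  LeakyReLU + instance norm.  All convolutions are bias-free; "same" zero
  padding at stride 1.
* **ACT head.** Attached to the deepest *encoder* features (the encoder-end
  reading; a decoder-stage attachment is not implemented).  The depth axis
  is collapsed by averaging ("maps the features to a two-dimensional
  space"), followed by a 2-D 3×3 convolution narrowing to `base_channels`,
  LeakyReLU, 2×2 max pooling, global average pooling, and a linear layer
  (the package's only biased layer) to the two classes.

The model accepts any input whose extents are divisible by
`2^num_levels` — the network is fully convolutional, which lets training
run on 16-slice slabs while evaluation sees whole volumes.

## Cost model

`complexity.count_params` / `count_flops` implement the closed forms:
standard or transpose convolution `C_in·K³·C_out` parameters and
`D·H·W·C_in·K³·C_out` MACs at the *output* extents; separable convolution
`C_in·K³ + C_in·C_out` and `D·H·W·C_in·(K³ + C_out)`.  One MAC counts as
one FLOP; activations, normalisation and pooling contribute no FLOPs —
this is the convention under which the closed-form reduction ratio
`1/C_out + 1/K³` is exact and identical for parameters and FLOPs
(asserted to machine precision).  Parameter totals include instance-norm
affine pairs and the ACT head; rounding (half-up, two decimals, millions/
billions) happens only at report time, with exact integer arithmetic
underneath.

## Fitting the reference configuration — outcome

Published complexity tables for this network family print totals without
the base width and input shape that produced them.  `fit_reference_config`
enumerates base width ∈ {4, 8, 12, 16, 24, 32}, depth ∈ {16, 32}, in-plane
∈ {128, 192, 256} and returns every configuration whose rounded totals
match a requested (params, FLOPs) pair.

For the published baseline row (1.78 M, 115.10 G) the result is **empty**,
and this is provable rather than a search-depth artefact: every term of
the CEC unit's cost is proportional to t, so twice the t = 6 row minus the
t = 12 row recovers the t-independent cost (transposes + final layer) —
about 0.09 M / 12.31 G.  The baseline row would then require the
standard-conv units to cost ≈ 14× (parameters) and ≈ 7× (FLOPs) their
t = 6 CEC replacements, yet per layer the ratio
`27·C_out / (6·(C_in + 27 + C_out))` is bounded by 4.5 for *any* channel
counts.  No width schedule, decoder arrangement or rounding convention can
reach the printed cells simultaneously; they evidently derive from an
unpublished configuration not recoverable from the stated formulas.  The
package therefore reports the fit honestly: `fit-config` prints "no
match" plus the closest member (base width 16, input 32×256×256 → 1.55 M /
65.65 G), and that closest member is the canonical configuration used by
`scripts/acceptance.py`.

## Synthetic phantoms

`io_synth.generate_phantom_volume` draws a smooth background texture
(Gaussian-filtered noise, σ = 6 voxels, ±15 % around unit intensity), adds
1–2 bright ellipsoidal lesions (random radii 4–9 voxels, random
orientation, margin perturbed by a smooth field scaled by 0.2 for
irregular outlines, intensity = background × 2.0) with probability 0.8 per
volume, and Gaussian noise (σ = 0.05).  The mask is the exact lesion
support.  Defaults are the package's desk-scale study conditions: 32
volumes of 32×48×48 (1 mm isotropic), small enough that a 30-epoch CPU run
finishes in minutes.

What the phantoms do **not** model: contrast kinetics (multi-phase
enhancement curves), anatomy (fibroglandular structure, skin, chest wall),
coil inhomogeneity, partial-volume effects at real slice thickness, or
non-mass-like enhancement.  Passing phantom benchmarks therefore
demonstrates that the pipeline *optimises and generalises on geometrically
realistic bright-lesion volumes* — it says nothing quantitative about
clinical DCE-MRI accuracy.

## Training recipe

Z-score intensity normalisation per volume; augmentation with in-plane
rotation uniform in ±15°, horizontal flip with probability 0.5, and ±20 %
global intensity scaling (volume linear, mask nearest-neighbour, scaling
volume-only); uniform random 16- or 32-slice slabs; 8:2 train/test split
by seeded shuffle; Adam with first-moment decay β₁ = 0.95 (the natural
reading of "momentum factor 0.95" for Adam), β₂ = 0.999, decoupled weight
decay 1e-4; one-cycle cosine annealing `lr_t = lr0/2·(1+cos(tπ/T))` with
T = epochs.  A 10 % validation subset is carved from the training split
for curve monitoring.  Full-scale defaults follow the published recipe
(130 epochs, batch 24, lr₀ = 1e-4).

**Desk-scale optimisation settings.**  The benchmark runs in
`tests/test_acceptance.py` train a base-width-4, two-level network for 30
epochs on 32 phantoms — roughly 200 optimizer steps, two orders of
magnitude fewer than the full recipe.  These runs use lr₀ = 1e-2 and batch
size 4, calibrated once with an overfit-one-volume pilot (the 6.5 k-
parameter network reaches IoU > 0.95 on a single phantom within ~40 Adam
steps at this rate); the full-scale 1e-4 rate moves such a small model
only ~2 % of a unit in 200 steps and is an artefact of the large-batch,
many-step regime.  The multi-task weight λ defaults to 1.0 (unstated in
the source recipe); the Dice smoothing constant ε = 1e-6; binarisation
threshold 0.5 with ties counted positive.

## Numerical choices

* float32 tensors throughout; loss accumulation in float64.
* He-style fan-in-scaled Gaussian weight initialisation, seeded through
  `NetworkConfig.seed`; rebuilding from a seed is bitwise reproducible.
* Max-pool gradient ties are broken toward the first maximal voxel per
  window, keeping backward passes deterministic.
* Cross-entropy clamps log-probabilities at 1e-12; softmax is computed
  with max-subtraction; the sigmoid uses the two-branch stable form.
* IoU/DSC are defined as 1.0 when both masks are empty (an option to
  exclude such volumes from averages can be layered on the per-volume
  table that `evaluate_model` returns).
* Volume-wise (not slice-wise) metric aggregation.

## Known limitations

* No GPU path and no batching across volumes inside a single forward pass;
  throughput is a few slabs per second at desk scale.
* The decoder-stage ACT attachment and slice-wise metric aggregation
  mentioned above are not implemented.
* Transpose convolutions are fixed at kernel 2, stride 2; pooling is
  always 2×2×2, so strongly anisotropic volumes must be resampled first.
* The complexity engine covers exactly the layer grammar of
  `layer_plan`; arbitrary user-defined architectures are out of scope.
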