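# Methods

This note records the model as implemented, the numerical and design
choices made where the architecture family leaves them open, what the
synthetic benchmarks do and do not emulate, and known limitations.

## Numerical core

The network runs on a purpose-built reverse-mode autodiff engine over
numpy arrays (`mfda_unet.engine`): a `Tensor` with closure-based
backpropagation, the convolution layouts the architecture needs (dense
and depth-wise, plus a non-overlapping 2×2 stride-2 transposed
convolution), a border-aware 3×3 box filter, bilinear resampling,
layer/instance normalization, stochastic depth, and AdamW. All arithmetic
is float64. That choice makes the package's exact identities (DC
rejection, residual skeletons, checkpoint round-trips) hold to the last
bit and keeps the attention-vs-oracle comparison far inside its 1e-5
relative tolerance, at roughly a 2× speed cost over float32 — acceptable
at the desk scales targeted here. Only two gradient layouts exist for
`conv2d` (groups = 1 and depth-wise); gradients of every primitive are
verified against central finite differences in the test suite.

## Linear attention

The kernel feature map is φ(x) = ELU(x) + 1, computed in the fused form
x + 1 for x > 0 and exp(x) for x ≤ 0, clamped to the smallest normal
double. The naive evaluation (exp(x) − 1) + 1 underflows to exactly 0
for x < −37, which would break the strict-positivity contract of the
implied attention weights; the fused form is positive for every finite
input.

Attention is evaluated strictly in the reassociated order — KᵀV first,
scaled by 1/N, then the query product, then the per-query normalizer
ρᵢ = 1/(Qᵢ·mean_j K_j + ε) with ε = 1e-6 appearing only in that
denominator. Because the 1/N scaling is applied to KᵀV and mirrored in ρ,
ε is effectively compared against the *mean* kernel similarity rather
than the sum. An explicit O(N²) oracle (`naive_attention_oracle`,
guarded at N ≤ 512) exists solely for testing; the analytic multiply-add
model (`attention_macs` vs `naive_attention_macs`) carries the
linear-vs-quadratic complexity claim (ratio 2 vs 4 under doubling of N).

Attention is single-head by default; a `num_heads` hook folds heads into
the batch axis when set. Q/K projections carry biases, as do all linear
and convolutional layers (documented default; affects checkpoints only).

## MELA and the MFDA block

The main-branch depth-wise convolution in the gated dual-branch block is
3×3 (stride 1, padding 1), matching every other sized depth-wise
convolution in the architecture; its size is otherwise unconstrained.
DropPath appears both inside MELA (after its output projection) and
around the FD-MELA mixer and the MLP in the block skeleton, exactly as
the block equations compose; the two draws compound only during training
(evaluation is the identity), and the rate follows a linear schedule over
the eight encoder blocks from 0 to `drop_path_max` (default 0.1).

Frequency decoupling splits channels in half (block widths must be even),
concatenating low-path output first and high-path output second before
the linear fusion — a fixed, documented order. The box average uses
**valid-pixel border handling** and is computed as
x + (Σ valid-neighbour deviations)/count. That formulation makes
spatially constant inputs bit-exact fixed points everywhere, including
borders, so the high-frequency component of a constant is exactly zero.
The reconstruction identity half2 = high + AvgPool(half2) is exact by
construction in its subtraction form (high is the float difference); the
re-added form agrees to ≤ 1 ulp — floating-point addition cannot make
(a−b)+b bit-equal to a in general, and the tests check the constructive
form bit-wise plus the re-added form at 1e-12 relative.

InstanceNorm in the high-frequency branch uses a variance floor of 1e-5
and no learned affine, so constant inputs normalize to exactly zero
(degenerate 1×1 spatial maps are handled by the same floor). The block
MLP uses GELU with expansion ratio 4. Layer normalization acts over the
channel axis of token sequences, with affine parameters initialized to
the identity — which is what makes the zeroed-weight residual-skeleton
identity exact. The `positional_encoding` switch removes both CPE
applications *and* LePE; the two CPE sites (before the MLP, and on the
low path before MELA) use separate weights, as nothing in the block
equations indicates sharing.

## GCSA

Queries derive from the (pre-upsampled) decoder stream, keys and values
from the encoder stream, each LayerNorm-ed separately after flattening.
Q and K pass through φ; V is a plain linear projection (mirroring the
attention core, where V is the unmapped main-branch feature). The gate
MLP has hidden width C (two linear layers with GELU, no expansion
claimed), squashed by a sigmoid. The module output re-enters the decoder
additively on the upsampled feature before the decoder block. ρ/ε
normalization is identical to the encoder attention. Modes: `off`
(network falls back to plain addition), `ungated`, `gate_on_v`,
`gate_on_output` (default).

## Network assembly

The stem is two 3×3 stride-2 conv + channel-LayerNorm + SiLU units (×4),
so four stages give ×32 total reduction — standard for 224/256 inputs.
Within a stage, the two MFDA blocks run before the stride-2 downsampling
convolution. The deepest stage feeds the decoder directly (no extra
bottleneck block). Decoder blocks are inverted residuals (1×1 expand ×4 →
3×3 depth-wise → 1×1 project, SiLU, batch-free channel LayerNorm,
residual). Deep supervision attaches a 1×1 conv head at each of the three
decoder levels with bilinear upsampling of logits to full resolution; the
final head restores full resolution with two further 2×2 transposed
convolutions. Default widths (32, 64, 128, 256) are desk-scale choices;
absolute parameter counts of any particular full-scale instantiation are
not a contract of this package, so only the *direction* of the ablation
family's parameter ordering is asserted (w/o FD > full > GCSA off > conv
baseline). The pure-convolutional baseline uses inverted residuals with
expansion 2 in place of MFDA blocks.

Checkpoints are single `.npz` files keyed by hierarchical layer names
with the model config embedded as JSON, so a checkpoint alone rebuilds
its model; round-trips are bit-identical.

## Losses, schedule, metrics

Hybrid losses weight the pixel term and the smoothed soft-Dice term
0.5/0.5, with Dice smoothing s = 1.0 in numerator and denominator,
averaged over classes and batch. Deep-supervision weights decay
geometrically, 2^-(k+1) with k = 0 nearest full resolution; auxiliary
maps are pre-upsampled so all levels share the full-resolution target.
The optimizer is AdamW (weight decay 0.01, the optimizer's conventional
default) with per-step cosine annealing lr(t) = min_lr +
½(lr−min_lr)(1+cos(πt/T)) from 1e-3 to 1e-5.

Hard predictions threshold sigmoid probabilities at 0.5 (binary) or take
the channel argmax (multi-class). A class absent from both prediction and
target scores 100 % IoU/DSC and is excluded from means; means run over
foreground classes, except binary mIoU, which averages foreground and
background IoU (the common reporting convention under which binary mIoU
values sit below DSC). HD95 extracts boundaries as mask pixels 4-adjacent to
non-mask (the image border counts as outside), pools both directed
distance sets, and takes the 95th percentile; empty masks yield NaN,
excluded from case averages and listed separately.

## Synthetic data

The lesion generator emulates dermoscopy-style binary data: one irregular
blob per image (periodic cubic-spline perturbation of a disc, radius
0.15–0.33 of the canvas, control radii ±25 %), Gaussian-soft boundary
(σ = 1.5 px), lesion/background contrast drawn from (0.25, 0.6),
smooth background texture and 5 % multiplicative speckle, with per-image
foreground fraction held inside (0.05, 0.6) by bounded deterministic
resampling. The organ-phantom generator produces K−1 disjoint elliptical
regions with ordered intensity bands, one ring-shaped (annulus) to mimic
myocardium-like topology. Sample i of seed s derives from
`default_rng([s, i])`, so datasets are reproducible and prefix-stable.
Augmentation is restricted to flips and right-angle rotations so masks
never need interpolation.

What passing the training controls does and does not show: the positive
control (200 lesion samples at 64×64, widths 16/32/64/128, batch 8,
≤ 20 epochs) demonstrates that the full pipeline — generator, losses,
deep supervision, optimizer, schedule, attention and skip modules —
learns a genuinely image-dependent segmentation to held-out DSC ≥ 0.9 on
one CPU in minutes. It does **not** establish performance on real
dermoscopy or CT data, which have far richer texture, artefacts, scale
variation and label noise. The null control (contrast 0, images
statistically independent of masks) is compared against an explicit
chance baseline: because the blob masks share a strong central prior,
the best image-independent predictor (the majority mask of the training
set) already reaches DSC ≈ 0.5–0.7, and the null-trained model must not
meaningfully exceed it — "chance" here is that prior, not zero.

## Problem sizes

Unit and property tests run at token counts up to 256 (oracle guard 512)
and canvases up to 256×256 for shape contracts; training-based checks use
32–64 px canvases, 16–200 samples, and the width family 8/16/32/64 or
16/32/64/128 — sizes chosen so the full suite and the acceptance script
each complete in minutes on a single CPU while still exercising every
code path at multiple scales.

## Known limitations

* No GPU path, no float32 fast path, no multi-processing; throughput is
  sufficient only for desk-scale studies.
* Only stride-2 kernel-2 transposed convolutions (non-overlapping) are
  implemented; overlapping deconvolution variants are out of scope.
* No rotary positional embedding (the frequency-decoupled design
  deliberately omits it), no softmax-attention fallback, no causal
  masking, no 3-D volumetric variant, no pretrained weights.
* HD95 is 2-D with isotropic or anisotropic pixel spacing; surface
  metrics (ASSD, surface Dice) are not provided.
* The synthetic generators model geometry and first-order intensity
  statistics only — no hair/ruler artefacts, no multi-lesion images, no
  partial-volume effects.
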