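# Methods

This note records the model implemented by `osteoseg`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Network

**Encoders.** Four stages; each applies two 3x3 convolutions with LeakyReLU
(slope 0.01) followed by squeeze-and-excitation channel gating, with 2x2
max pooling between stages and dropout p = 0.2 during training. Widths are
`base_channels * {1, 2, 4, 8}` at scales 1, 1/2, 1/4, 1/8 of the input; the
full-scale default is `base_channels = 32` at 512x512, the desk-scale
preset (`small_config()`) is 8 at 64x64. Inputs must be divisible by 16
(four stride-2 stages); inference pads and crops automatically. No
normalization layers are used anywhere.

**Dual-resolution exchange block.** Each route first passes a residual
`F` block (`x + H(H(x))`, the identity at zero initialization), producing
`M_0`; five densely connected `H` steps follow, each concatenating the
whole own-route history plus the other route's previous map resampled
across the octave — a stride-2 convolution downward, a stride-2 transposed
convolution upward (spatial dimensions must match before concatenation,
so the two resampling directions necessarily use different operators).
The output is `O = w*M_5 + M_0` with residual scale `w = 0.4`. Growth
factors default to each route's input width; this makes the concatenation
feeding step n carry exactly `n*g_own + g_other` channels and lets the
residual sum typecheck without projection. If a different growth factor is
configured, a trainable 1x1 projection restores the route width before the
residual sum. With every parameter zero the block is the exact identity on
both routes — the reference point the surrounding topology relies on, and
an invariant the test suite asserts bitwise.

**Fusion subnetwork.** Four layers over four scales. Per layer, every
selected pair of scales runs one exchange block (`all_pairs`: six blocks;
`adjacent`: three, kept for ablation); each scale's candidate outputs are
fused by elementwise mean followed by a trainable 1x1 projection
initialized to the identity. After layer 1 the layer output is added to
the subnet input — once, not per layer. Pairs more than one octave apart
reuse the two-route block unchanged: the finer member is average-pooled to
one octave above the coarser one, and its exchange output is applied at
native resolution as a bilinearly upsampled residual correction
`x + up(O - pool(x))`. The correction form (rather than plain
pool-process-upsample) keeps the zero-initialized subnetwork exactly the
identity, so the identity/doubling invariants hold for every pairing mode;
a finite-difference probe confirms that with all pairs one layer connects
the finest to the coarsest scale, while adjacent pairing needs three.

**Gated shape stream.** A width-16 full-resolution stream seeded from the
first encoder tap. At each of three steps the next (coarser) tap is
injected through a 1x1 projection and bilinear resize, an attention map
`alpha = sigmoid(Conv1x1([S, D]))` is computed against the deep semantic
feature `D` (the fused coarsest scale, bilinearly resampled), and the
stream updates as `S <- F(S * alpha)`. The stream's features concatenated
with the Sobel gradient magnitude of the raw image feed a 1x1 head
producing edge logits; they are also fused (an `F` block on the
concatenation) with the final decoder output before the mask head. Which
features play `S_0` and `D` is not forced by the architecture; the finest
tap and the fused coarsest scale pair the most local evidence with the
most semantic, and the choice is configurable in code. Edge supervision
uses the morphological gradient (3x3 dilation minus erosion) of the
reference mask — the standard construction when only region masks exist.
Disabling the stream (`shape_flow_enabled=False`) removes only the edge
output; the segmentation path is unchanged.

**Decoders.** Four blocks, each doubling resolution from a 1/16 bottleneck
(a stride-2 convolution on the fused coarsest scale) back to full
resolution. Skip inputs are the fusion outputs passed through per-scale
`F` blocks, not raw encoder taps. Each block concatenates two branches:
(i) spatial/channel attention `(SE + 1)(x) ⊙ M` — read as the residual
gating `x*gates + x` under a replicated single-channel sigmoid mask, which
keeps the operator well-typed; and (ii) an additive attention gate whose
coefficients `sigmoid(Conv1x1(phi(skip) + psi(P)))` are computed at the
coarse resolution and upsampled *bilinearly* — a learned transposed
convolution there could leave (0,1), and strict (0,1) coefficients are an
invariant we assert; the feature path `T(P)` remains a learned transposed
convolution. Two `H` convolutions produce the block output.

## Training

Loss = Dice + BCE + 0.5 * edge-BCE on logits. Dice targets the evaluation
metric directly, BCE conditions the early diffuse phase, and the edge term
gives the shape stream a training signal; the weights are configurable.
Adam with lr 1e-4, 200 epochs and batch 8 at full scale. Model selection
keeps the epoch with the best validation mean DSC. Masks predicted at
inference threshold the sigmoid at 0.5. Convolutions are He-initialized
with the LeakyReLU gain, biases zero, from a generator seeded by the model
config; training, phantom generation and batch order are all seeded, so
runs are exactly reproducible on a fixed backend.

Metrics: IoU, DSC, precision, recall, F1 and accuracy from pooled per-pixel
confusion counts. Per-image means and pooled-count versions are both
emitted (reported segmentation scores may follow either convention). When
both masks are empty the overlap metrics report 1; any other 0/0 ratio
reports 0.

## Numerical backend

The network runs on a reverse-mode automatic-differentiation engine over
NumPy arrays (`osteoseg.nn`): convolution and transposed convolution as
im2col GEMMs (float32 parameters by default; all operators preserve the
caller's dtype, so float64 verification paths stay exact), pooling,
bilinear resizing as explicit row-stochastic interpolation matrices,
dropout, and a numerically stable BCE-with-logits. Stride-2 convolution
uses ceiling division and its transpose doubles exactly, so down/up round
trips preserve power-of-two sizes. Every operator is verified against
direct-loop reference implementations and central finite differences in
the test suite. Max-pool gradients split ties evenly, matching the finite
difference subgradient.

## Synthetic phantoms

`PhantomSpec` generates grayscale slices: a smoothed random low-frequency
background in [0.15, 0.45] with bright elliptical bone bands (capped at
0.7), one or two tumors per slice — ellipses (eccentricity 0.6-1.0) whose
boundary radius is perturbed by a random order-2..5 Fourier series with
amplitude 0.3 — at +0.35 contrast, plus Gaussian noise sigma = 0.05
(contrast-to-noise about 7), clipped to [0, 1]. Masks are the exact
noiseless geometry. Defaults are 64x64 slices grouped five per synthetic
patient. Sample i is a pure function of (seed, i).

Phantoms exercise every pipeline contract — multiscale structure, ambiguous
noisy boundaries, patient grouping — but are far easier than clinical MRI:
tumors are the only consistently bright compact objects, there is no
intensity non-uniformity, motion, partial volume, or inter-scanner
variation, and the noise is Gaussian rather than Rician. Passing the
phantom-recovery study shows the implementation can learn and localize the
geometry it models; it says nothing about clinical accuracy.

## Desk-scale experiments

Problem sizes were chosen so the full study runs in minutes on one CPU
core: the recovery study trains `base_channels = 8` on 64x64 phantoms
(160 train / 40 validation) for at most 300 Adam steps at batch 2 with a
2-layer adjacent-pairing fusion graph, and the overfitting probe runs 200
steps on one fixed 4-sample 32x32 batch. At these scales the full-scale
learning rate of 1e-4 would barely move the weights within the step
budget; the desk-scale runs use 2e-3. The full-scale defaults (four
all-pairs fusion layers, base 32, lr 1e-4, 200 epochs) remain the
package's configured defaults.

## Known limitations

* 2-D slices only; no 3-D context, DICOM metadata, or scanner
  harmonization.
* The NumPy backend is single-device and eager; it is sized for the
  desk-scale studies above, not for 512x512 training runs.
* The published description of the architecture leaves several quantities
  open (channel widths, growth factors, the fusion operator joining
  same-scale candidates, the shape stream's exact tap wiring); the choices
  made here are documented above and in the code, and alternatives are
  configurable where they are plausible.
* Augmentation is the fixed x4 set (rotation, transposition, flip); no
  elastic or intensity augmentation.
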