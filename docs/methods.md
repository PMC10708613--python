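# Methods

This note documents the models, conventions and design choices behind
`cptseg`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the tests do and do not
establish.

## Model family

All three network variants share one skeleton operating on 2D grayscale
slices:

1. **Hybrid CNN encoder.** A 7×7 stride-2 root convolution (width 64),
   3×3 stride-2 max-pool, then three stages of pre-activation residual
   bottlenecks (units 3/4/10, mid widths 32/64/128, output widths
   128/256/512), reaching 1/16 resolution. GroupNorm is used
   throughout (see *Normalization* below). The root and first two
   stage outputs are kept as skip features at 1/2, 1/4 and 1/8 scale.
2. **Patch/position embedding.** A 1×1 convolution maps the 512-channel
   1/16-scale features to d = 768 tokens; a learned position embedding
   on a fixed 14×14 reference grid is bilinearly resized to the actual
   token grid, so the parameter total is independent of input size
   (224/320/512 all build the same weights).
3. **Transformer stack.** One of:
   * `serial` — L standard pre-norm ViT-Base layers
     (d 768, 12 heads, MLP 3072): `x + MHSA(LN(x))`, then `+ MLP(LN(·))`;
   * `parallel_vit` — L layers of B branches,
     `x' = x + Σ_b MHSA_b(LN_b(x))`, `out = x' + Σ_b MLP_b(LN_b(x'))`;
   * `cpt` — L cross-parallel layers (below).
   A final LayerNorm closes the stack.
4. **CUP decoder.** A 3×3 convolution (768→256) on the re-gridded
   tokens, then four upsample(×2, bilinear)+concat(skip)+two-3×3-conv
   stages with channels 256/160/48/32 and skips 256/128/64/none, and a
   3×3 head to the class logits. Softmax/argmax produce per-pixel
   probabilities/labels.

### The cross-parallel layer

Each branch normalizes the shared input once and projects it to Q/K/V
(one LN per branch, three d×d linear maps). A stack of `n_dd ∈ {0,1,2}`
Dendrite-Net layers refines each projection: `DD(x) = (Wx)∘x + Wx`,
a Hadamard gate whose linear output is also added back so suppressed
features are not lost; one shared d×d weight per projection per DD
layer, applied sequentially when `n_dd = 2` (more layers saturate the
gating, hence the cap). Fusion adds the branches' Q̂/K̂/V̂ into the left
branch, with fresh LayerNorms on the fused Q and K (the fused V is a
plain sum); the right branch's Q̂/K̂ get their own norms and its V̂
stays raw. The left attention is ordinary multi-head self-attention on
the fused triplet; the right attention uses `V'_r = V̂_r + O_left`, so
the left result steers what the right branch propagates. Both
attentions have independent output projections and dropout after
softmax and after the projection. The layer ends with
`z_out = GELU(LN(z + O_left + O_right))` — no feed-forward MLP and no
residual around the activation block (a flag can add one; ablation
variants replace it with 1–2 parallel residual MLP blocks).

Head mechanics: the Q/K/V projections double as the per-head maps —
the d channels are split into h = 12 disjoint subspaces of width
d_k = 64, attended independently, concatenated, projected. This is the
standard implementation equivalence of the textbook per-head-matrix
formulation and is what the parameter budgets require.

The cross pattern is defined for exactly two branches. Wider
parallelism is provided as ⌈B/2⌉ independent cross-pairs (plus one
plain self-attention branch when B is odd) whose outputs are summed;
this generalization is non-canonical and excluded from the
reproduction targets (published totals for the 3×4 C-PT arrangement do
not follow from any construction we could reconstruct).

## Accounting and the calibrated convention

`count_parameters` enumerates trainable scalars exactly;
`count_flops` traces one forward pass and tallies multiply-accumulates
(MACs) by category (conv, linear, attention matmul, Hadamard). A
`ConventionFlags` record makes every reporting choice explicit: count
biases? count norm affines? which divisor for "M"/"G"? include the
attention score/weighting products and Hadamard gates? one FLOP per
MAC or two?

`calibrate_convention` recovers the convention behind a set of printed
figures from their **inter-row deltas** (row pairs differing only in
transformer depth/DD/MLP counts), which cancel whatever fixed backbone
the totals include. Deltas below 1.0 printed unit are skipped — at two
printed decimals they are rounding noise. On the published tables of
this family the calibration is unambiguous: the "M" columns divide raw
counts by 2²⁰ (every printed delta matches binary millions to print
precision and is ~4.8% off in decimal millions), and the FLOPs columns
divide by 10⁹ but count only parametrized-layer MACs — the signature
of hook-based profilers, which never see the N×N attention products
(0.059 G per ViT-B layer at N = 196). The calibrated default therefore
excludes attention matmuls; a flag includes them.

The published absolute totals imply a far lighter CNN/decoder than the
commonly distributed truncation of this lineage (~8.2 M parameters and
~8.1 GMACs at 224 for everything outside the transformer stack). Since
the original truncation is not reported, the default encoder/decoder
widths above were solved once against those two budget figures and
frozen; the reconstruction reproduces all eighteen published totals to
≤0.3% and is the package's definition of the family. Ratio claims
(the ~29%/~21.4% reductions) are insensitive to this choice because
both networks share the backbone.

## Metrics

Evaluation follows the multi-organ CT protocol: slices are segmented
independently, stacked per case, and each foreground class scored in
3D. DSC = 2|A∩B|/(|A|+|B|) (defined as 1 when both masks are empty).
HD95 is the symmetric 95th-percentile surface distance in mm,
`max(d95(A→B), d95(B→A))` over full foreground voxel sets (boundary
extraction and the non-standard `d95(A→B)+d95(B→A)` combination are
flags), computed with a KD-tree under anisotropic voxel spacing; it is
undefined (NaN, excluded from averages) when either mask is empty.
Accuracy/F1/sensitivity/precision come from the voxel confusion
counts, with zero-denominator ratios reported as 0. Classes absent
from a case's reference are excluded for that case; averages are over
cases, then over foreground classes.

## Synthetic phantoms

Phantom cases emulate the *structure* of the abdominal protocol —
cases of stacked slices, labels 0–8, anisotropic 1×1×3 mm voxels,
per-case organ inventories — with eight 3D ellipsoids (fixed
fractional-coordinate priors, per-case jittered centers/axes, painted
in class order with first-painted-wins so organs never overlap) on a
darker background, piecewise-constant intensities plus Gaussian noise
(σ = 0.03 by default; σ = 0 gives exactly piecewise-constant images).
Generation is bitwise deterministic given (seed, case index); the
default split is 60/40 by case, mirroring the 18/12 protocol ratio.
What passing tests on phantoms shows: the pipeline is wired correctly
end to end and can fit structured data. What they do not show:
performance on real CT — no CT physics, no soft-tissue ambiguity, no
inter-case anatomical variability.

## Training

SGD with lr 0.01, momentum 0.9, weight decay 1e-4, on
0.5·cross-entropy + 0.5·soft-Dice (the lineage's convention; weights
configurable), with random ±20° rotation and flips. The full
published recipe (batch 24, 14k iterations) is provided;
tests and examples use the desk-scale profile (batch 4, ≤500
iterations, reduced widths: hidden 96, 6 heads, 64² inputs) so the
whole suite runs in minutes on one CPU. The learnability check —
a reduced-width C-PT model reaching training DSC ≥ 0.95 on an 8-slice
phantom within 500 iterations — passes at ~0.98.

## Numerical choices

* Float64 throughout; oracle-equivalence tests assert 1e-6 agreement.
* GELU is the exact erf form (not the tanh approximation).
* LayerNorm ε = 1e-6 (configurable); GroupNorm ε = 1e-5.
* Dropout 0.1 after softmax and after attention projections (the
  ViT-Base convention; the source architecture retains dropout but
  states no rate), 0 in evaluation and in the desk profile.
* Initialization: truncated normal (std 0.02, exact ±2σ rejection) for
  linear/DD/embedding weights, He-normal for convolutions, zeros for
  biases, ones/zeros for norms; fully determined by the build seed.
* Linear and DD layers carry biases by default (the calibration
  confirms the published counts include them).
* **Normalization choice:** GroupNorm is used in the decoder where the
  lineage uses BatchNorm, trading a tiny behavioural difference for
  state-free evaluation-mode determinism (no running statistics);
  parameter counts are identical.
* Degenerate inputs: empty masks (see Metrics), zero-variance rows in
  LayerNorm resolved by ε, `N = 1` token sequences exercise the
  softmax-of-a-scalar path.

## The autodiff engine

The package is self-contained on numpy: all networks run on a small
tape-based reverse-mode engine (`cptseg.engine`), which keeps the
whole stack inspectable end to end and free of framework state.
It provides ~20 differentiable primitives (including
im2col convolution, max-pool, bilinear resize), checked against
central finite differences in the test suite. Backward closures
capture arrays rather than output tensors, keeping graphs acyclic so
memory is reclaimed by reference counting. A shape-only tracing mode
executes forwards without the matmul/conv arithmetic for near-free MAC
accounting of zero-initialized models. Evaluation-mode forwards are
bitwise reproducible; training is deterministic given the build and
data seeds on a fixed BLAS.

## Known limitations

* Desk-scale training only; no pretrained backbone weights, so
  absolute segmentation accuracy on real data is out of scope.
* B > 2 cross-parallelism is a documented, non-canonical extension.
* The engine is single-threaded numpy; it is not a performance
  baseline.
* Phantom realism is structural, not anatomical (see above).
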