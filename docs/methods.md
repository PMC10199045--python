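# Methods

This note documents the models, numerical choices and limitations behind
`bmkfo`. It is the package's own account of its science; every empirical
number mentioned here is one the test suite or `scripts/acceptance.py`
computes at run time.

## Problem setting

A 1-way k-shot segmentation episode consists of k labeled support pairs
(image, binary mask) and one query pair, all drawn from the same "class" of
compact organ-like shapes. The learner may adapt on the support pair(s) and
is scored on the query. The package studies two ingredients for this setting:
a meta-optimizer that learns how to take adaptation steps, and a
shape-aware training objective based on the average Hausdorff distance.

## Kronecker-factored gradient preconditioning

For each parameter tensor, flattened to a matrix G ∈ R^{m×n} (convolution
kernels to (out, in·kh·kw), biases to (m, 1)), the meta-optimizer U_ξ holds
a pair of small square factors L ∈ R^{m×m}, R ∈ R^{n×n} and transforms
gradients as G ↦ L·G·R. Under column-major vectorisation this is the action
of the mn×mn matrix Rᵀ ⊗ L, so the map is full-rank whenever L and R are,
its span contains the identity (L = I, R = I recovers plain gradient
descent — the initialization used everywhere), and it costs m² + n²
parameters instead of (mn)². The full Kronecker product is materialised
only inside tests, as the oracle for the vec-identity
vec(L G R) = (Rᵀ ⊗ L) vec(G).

One factor pair is allocated per parameter tensor. Biases are uniformly
treated as (m, 1) matrices with a 1×1 right factor; the smallest tensor in
the default model (the 2-logit bias) then carries 2×2 + 1 = 5 optimizer
parameters, so no further special-casing of tiny tensors is needed.

## MAML and the bidirectional step

The MAML baseline takes `inner_steps` gradient steps of size α on the
support loss and descends the query loss at the adapted parameters with meta
step size β, differentiating through the inner steps (second order) or
treating the adapted parameters as leaves (first order, selectable by flag).

The bidirectional step (BM-KFO) processes each task in two phases:

1. **meta-train**: θ' = θ − β ∂L_support/∂θ and ξ' = ξ − β ∂L_support/∂ξ.
   The support loss at raw θ does not depend on ξ, so the ξ-gradient is
   defined through a probe update θ̃ = θ − α U_ξ(∇_θ L_support) and the
   derivative of L_support(θ̃) with respect to ξ. This is the only
   well-defined route by which a loss value depends on the optimizer
   parameters, and it mirrors the learned-optimizer objective that U_ξ is
   trained to minimise.
2. **meta-test**: θ* = θ' − α U_{ξ'}(∇_{θ'} L_support(θ')). The step size α
   multiplies the preconditioned gradient so that identity factors recover
   an exact gradient-descent step (verified to 1e-10 in the tests).

The query loss at θ* is differentiated with respect to the outer (θ, ξ) —
through both phases when `second_order` is set — and the outer parameters
step with size β (plain SGD by default, Adam selectable), averaged over the
task batch. Both phases consume the support set; only the outer update sees
the query labels, so no query information leaks into adaptation. With ξ
frozen at identity, the θ-trajectory of one bidirectional step is exactly a
two-inner-step MAML trajectory, which the tests exploit as an equivalence
oracle.

Step-size defaults are α = 0.01 and β = 0.001 with a ×0.98 multiplicative
decay every 1000 outer iterations. Non-finite losses abort with the phase
name (meta-train / meta-test / outer) rather than propagating NaNs.

## Hausdorff losses

Point sets are pixel coordinates under one of three grid metrics
(Manhattan/L1, Euclidean/L2, Chebyshev/L∞; Chebyshev is the default because
it measures a step in any of the eight grid directions equally). The
directed Hausdorff distance is max-min; the symmetric form takes the max of
both directions and is dominated by single outliers; the average Hausdorff
distance (AHD) averages per-point minimum distances over both directions
(the 1/X, 1/Y prefactors are cardinalities) and is robust to outliers —
both behaviours are demonstrated quantitatively in the tests.

Masks can be reduced to point sets in `foreground` mode (all labeled
pixels, the default) or `boundary` mode (foreground pixels with a
background 4-neighbour, image border counting as background). Foreground
mode is the default because it leaves no corner case for masks that fill
the image, and because either reading satisfies the "distance between truth
and prediction from both perspectives" idea; the boundary variant remains
selectable.

The exact set AHD is not differentiable in predicted probabilities (it
involves an argmin over a thresholded set), so training uses a surrogate:

    L = ( ⟨p, D_gt⟩ / Σp  +  ⟨g, D_pred⟩ / Σg ) / 2

where D_gt is the distance transform of the ground-truth set, D_pred the
distance transform of the prediction thresholded at 0.5, p the probability
grid and g the truth grid. Gradients flow through p in the first term only;
the reverse term is a constant per evaluation. On a binary prediction the
surrogate equals the exact foreground-mode AHD (tested to 1e-9). Distance
transforms are exact under all three metrics (Euclidean EDT, taxicab and
chessboard chamfer transforms). Degenerate cases: a prediction with zero
mass returns a large constant (1e3) with zero gradient and logs a warning;
ground truths with empty foreground contribute cross-entropy only, since
the set distance is undefined on empty sets.

Cross-entropy is the mean per-pixel negative log-likelihood with a
probability floor of 1e-7 (the log is undefined at zero). The combined
objective is the weighted sum w_ce·L_CE + w_ahd·L_AHD with default weights
(1, 1). When the AHD term is used for *training*, it is additionally scaled
by 1/grid-side: raw AHD is measured in pixels and would otherwise dwarf the
cross-entropy term on a 64×64 grid; evaluation always reports the raw,
unscaled exact-set AHD. Pixel spacing is unit and isotropic throughout;
distances are in pixels.

## Evaluation metrics

Precision TP/(TP+FP), recall TP/(TP+FN), Dice 2TP/(2TP+FP+FN); Dice is the
harmonic mean of precision and recall, an identity the tests verify
exhaustively. Degenerate conventions: if truth and prediction are both
empty all three are 1; if exactly one is empty all three are 0. Reports
carry per-episode rows and arithmetic-mean aggregates; the printed table
shows rates as percentages with two decimals and a trailing Mean column.
The per-episode AHD column is NaN when either mask is empty and is excluded
from the aggregate mean.

## Synthetic episodes

The generator emulates the structure of abdominal-MRI few-shot data at desk
scale, not its anatomy:

* **shapes** — a class is a family of radial-harmonic-perturbed ellipses
  (r(φ) = r₀(1 + Σ aₖ cos(kφ + φₖ))); four default families differ in size,
  elongation and boundary texture. Masks are rejection-sampled until they
  are a single 4-connected component with foreground fraction in
  [0.02, 0.4]. With zero perturbation the rasterized area matches πab to
  within 2%.
* **intensities** — foreground/background Gaussian intensity models
  (defaults 0.75/0.25, sd 0.03), additive noise (sd 0.05), and a smooth
  multiplicative bias field (random quadratic polynomial, ±30%, unit mean)
  mimicking MRI coil inhomogeneity; images are clipped to [0, 1].
* **distractors** — 0–2 blobs from other classes are painted into the
  background sharing the foreground intensity, emulating organs of similar
  brightness; an intensity threshold alone cannot reject them, which is
  what makes the support mask informative.
* **splits** — `setting1` lets test-class shapes appear as training-image
  distractors; `setting2` removes them entirely, and an audit pass checks
  the recorded class usage of every training episode rather than assuming
  hygiene.
* **pseudo-labels** — superpixel-style partitions come from seeded region
  growing with priority (intensity difference to the seed pixel, Euclidean
  distance, insertion order); on a constant image this reduces to the
  Voronoi partition of the seeds. This stands in, at toy scale, for the
  superpixel machinery used by self-supervised few-shot pipelines; exact
  SLIC-style superpixels are out of scope because the meta-optimizer, not
  the superpixel algorithm, is the object of study.

Grids default to 64×64 (a desk-scale stand-in for 224×224 clinical
slices), episodes to 1-way 1-shot. Everything is driven by explicit seeded
generators; a (seed, config) pair reproduces datasets byte-for-byte, which
the CLI tests check at the byte level. What passing tests on this generator
do *not* show: robustness to real MRI artifacts (motion, partial volume,
anisotropic spacing), to multi-organ context, or to annotation noise.

## Segmentation model

A deliberately tiny conditioned CNN (≈10k parameters, well under the 50k
cap): the input stacks (query image, support image, support mask) as
channels, three stride-1 convolutions at full/half/quarter resolution with
ReLU and average pooling, two ×2 upsampling stages, and a head convolution
that sees the upsampled features concatenated with the raw input (restoring
full-resolution detail). Initialization is seeded fan-in-scaled Gaussian;
biases start at zero. The network exists to exercise the meta-optimizer —
which is model-agnostic and is smoke-tested on a second, differently-shaped
spec — not to compete with pretrained backbones.

All tensor arithmetic runs on a small float64 reverse-mode tape
(`bmkfo.autodiff`) whose backward rules are themselves tape operations, so
second-order meta-gradients are exact rather than approximated; convolution
is im2col gathering plus matrix multiplication, with scatter-add adjoints.

## Study conditions and numerical choices

The headline experiment (`fast_adaptation_study`, also what
`scripts/acceptance.py` runs) uses: 200 meta-training episodes (64×64,
high-contrast regime), 40 held-out test episodes of an unseen class under
`setting2`, 5 adaptation steps at evaluation. Training makes three passes
over the 200 episodes with the first-order variant and an Adam outer loop
(α = 0.1, β = 0.002) — first-order because the first-order approximation
is the standard efficiency trade-off for CPU-scale meta-learning, three
passes because single-pass training leaves the CE-only variant short of
convergence (empty predictions on a handful of test episodes, which makes
its AHD column unrepresentative). Two models are trained from the same
seeded initialization — CE-only and CE+AHD — and compared against the
identically-adapted random initialization.

Tolerances: the Kronecker vec-identity and gradient-descent recovery hold
to 1e-10; MAML closed forms to 1e-8; surrogate/exact AHD equivalence to
1e-9; set distances match brute force to 1e-12. Checkpoints serialize to
sorted-key JSON so save→load→save is byte-identical; datasets use raw
`.npy` plus JSON manifests for the same reason.

## Known limitations

* The exact per-iteration mixture of Hausdorff variants used by published
  GPU-scale pipelines is underdetermined; this package fixes one coherent
  choice (training on the AHD surrogate, evaluating exact set AHD) and
  keeps the classical max-form HD available.
* The ξ-gradient in the meta-train phase is defined through a probe update;
  other constructions (e.g. differentiating a multi-step unrolled inner
  loop) are possible and would change the learned factors.
* The generator's distractors share intensity but not texture with the
  target; real confusable organs are harder.
* Single-process determinism only; parallel episode evaluation is safe only
  where aggregation is order-independent.
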