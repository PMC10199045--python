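# bmkfo

Few-shot binary segmentation with a **bidirectional meta-Kronecker factored
optimizer (BM-KFO)** and **average-Hausdorff-distance (AHD) losses**, built
and tested end-to-end on synthetic organ-like episodes.

Medical image segmentation rarely has the labeled data that supervised
training assumes: patient data is scarce, private, and expensive to
annotate. Few-shot learners instead adapt to a new structure from a handful
of labeled *support* examples and are scored on a held-out *query*. This
package implements, as a reusable library with a CLI, two ingredients for
that setting:

* **BM-KFO** — an optimization-based meta-learner in the MAML family that
  trains the model parameters θ *and* optimizer parameters ξ jointly. The
  meta-optimizer U_ξ transforms each gradient matrix G ∈ ℝ^{m×n} with
  learned Kronecker factors, U_ξ(G) = L·G·R ≙ (Rᵀ⊗L)vec(G), using m²+n²
  parameters per tensor instead of (mn)²; identity factors recover plain
  gradient descent. Each task runs a *meta-train* phase
  (θ′ = θ − β ∂L_sup/∂θ, ξ′ = ξ − β ∂L_sup/∂ξ) and a *meta-test* phase
  (θ\* = θ′ − α U_{ξ′}(∇_{θ′} L_sup)), and the query loss at θ\* updates the
  outer (θ, ξ) — second-order by default, with a first-order flag.
* **AHD loss** — a shape-aware objective. With point sets X (prediction)
  and Y (truth), AHD(X,Y) = (meanₓ min_y d(x,y) + mean_y minₓ d(x,y))/2
  under Manhattan, Euclidean or Chebyshev grid metrics (Chebyshev default).
  Unlike the classical Hausdorff max–min distance it is robust to outliers;
  unlike cross-entropy it scores the whole shape rather than the overlap.
  Training uses an exact-on-binary differentiable surrogate built from
  distance transforms; the total objective is L_CE + L_AHD.

Segmentation quality is reported as precision TP/(TP+FP), recall
TP/(TP+FN), Dice 2TP/(2TP+FP+FN) (the harmonic mean of the former two) and
exact set AHD. Since desk-scale CPU experiments cannot reproduce
GPU-benchmark numbers on clinical MRI, the package ships a seeded synthetic
episode generator (organ-like blobs, MRI-style bias fields and noise,
confusable distractor blobs, superpixel-style pseudo-labels, and the
strict/lenient class-split regimes) and validates every component against
independent oracles. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from bmkfo.hausdorff_losses import ahd, hd_loss, mask_to_pointset
from bmkfo.metrics import confusion, dice, precision, recall

gt = np.zeros((8, 8), dtype=np.uint8); gt[2:6, 2:6] = 1
pred = np.zeros((8, 8), dtype=np.uint8); pred[3:7, 3:7] = 1   # shifted by 1
X, Y = mask_to_pointset(pred), mask_to_pointset(gt)
c = confusion(pred, gt)
print(f"dice={dice(c):.4f} precision={precision(c):.4f} recall={recall(c):.4f}")
print(f"ahd={ahd(X, Y, 'chebyshev'):.4f}  hd={hd_loss(X, Y, 'chebyshev'):.4f}")
```

prints

```
dice=0.5625 precision=0.5625 recall=0.5625
ahd=0.4375  hd=1.0000
```

— the two 4×4 squares overlap in 9 of 16 pixels (Dice 18/32 = 0.5625), the
worst-matched pixel of either set is 1 Chebyshev step from the other set
(HD 1), and the *average* mismatch is under half a pixel (AHD 0.4375),
illustrating why AHD tracks overall shape agreement rather than worst-case
or overlap-only measures.

The CLI drives full experiments (configuration in YAML; every output
directory gets the resolved config echoed next to it, and rerunning any
command with the same config and seed reproduces outputs byte-for-byte):

```
bmkfo simulate --config cfg.yaml --seed 1 --out data/   # episodes + audit
bmkfo train    --config cfg.yaml --seed 1 --out run/ --data data/
bmkfo evaluate --config cfg.yaml --seed 1 --out eval/ --data data/ \
               --checkpoint run/checkpoint.json
bmkfo verify                                            # built-in oracles
```

`bmkfo verify` runs the oracle suites and prints:

```
AHD brute-force oracle              60 cases  PASS
Kronecker vec-oracle                16 cases  PASS
gradient-descent recovery            1 cases  PASS
Dice/precision/recall identities    25 cases  PASS
all checks passed
```

## Layout

| module | contents |
| --- | --- |
| `bmkfo.kron_linalg` | Kronecker product, factored maps L·G·R, identity factors |
| `bmkfo.hausdorff_losses` | exact HD/AHD, distance transforms, surrogate, CE, total loss |
| `bmkfo.metrics` | confusion counts, precision/recall/Dice, metric reports |
| `bmkfo.meta_optim` | MAML, Meta-KFO, BM-KFO steps, checkpoints |
| `bmkfo.synth_tasks` | episode generator, splits, superpixel pseudo-labels |
| `bmkfo.seg_model` | conditioned segmentation CNN on the autodiff tape |
| `bmkfo.autodiff` | float64 reverse-mode tape with double-backward |
| `bmkfo.experiments` | training/evaluation loops, fast-adaptation study |
| `bmkfo.cli_runner` | the `bmkfo` command-line interface |
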