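# Methods

## The model

`topofit` trains image-segmentation networks whose outputs are constrained
to have a prescribed topology.  The object of study is a probability map
`S = f(X; w)` over a 2D or 3D grid, with `S_ij ∈ [0, 1]` the predicted
probability that pixel `(i, j)` belongs to the segmented object.

### Super-level-set cubical filtration

Each pixel is identified with its closed unit cube, and for a threshold
`p` the super-level set `B(p)` is the union of cubes with value `≥ p`.
As `p` falls from 1 to 0 these sets grow, and persistent homology records
each topological feature — connected component (dimension 0), loop
(dimension 1), enclosed cavity (dimension 2) — as a bar `(b, d)`: the
feature exists for thresholds `d < p ≤ b`.  Because unions of *closed*
cubes are used, diagonally adjacent pixels are connected (8-connectivity
in 2D, 26 in 3D), and every lower-dimensional face enters the filtration
with the maximum over its cofacing pixels.

The component that survives to `p = 0` never dies; its bar is truncated at
filtration value 0.  Since `B(0)` is the full grid (contractible), this is
the only essential class — the implementation asserts this invariant.

Persistence is computed by standard boundary-matrix reduction over GF(2)
in filtration order, on the full cubical complex ("doubled grid"
representation).  Cells are ordered by value (descending), then dimension
(ascending, so faces precede cofaces within value ties), then
lexicographic index.  The last key fixes all tie-breaks, making barcodes
and critical cells bit-reproducible.

Every bar endpoint equals the value of one specific pixel (its *critical
cell*); for a cell whose value is attained by several pixels, the
lexicographically smallest pixel is responsible.  This is what makes the
barcode differentiable: for generic fields (all values distinct), the map
from a critical pixel's value to the bar endpoint is locally the identity.

### The Betti-prior loss

Given desired Betti numbers `β*_k`, bars of dimension `k` are ranked by
descending length and the loss is

    L_k = Σ_{ℓ=1..β*_k} (1 − |b−d|²)  +  Σ_{ℓ>β*_k} |b−d|²,
    L_topo = Σ_k w_k · L_k.

`L_topo = 0` exactly when there are precisely `β*_k` bars of full length 1
per dimension and no others.  A wanted bar that does not exist contributes
its maximal penalty 1.  The gradient lives on the critical pixels:
`∓2(b−d)` at the birth/death cells of a wanted bar, signs flipped for an
unwanted bar; the essential bar's death is the constant 0 and receives no
gradient.  Optional per-dimension weights and "ignore windows" (rank
ranges excluded from both sums) generalise the loss; both default off.

Two subtleties worth knowing:

* At the loss minimum the gradient is *not* zero — the minimum sits on the
  boundary of `[0,1]^V` (birth cells are pushed towards 1, death cells
  towards 0) and clamping absorbs the residual gradient.
* At exact value ties, and at exact bar-length ties (where ranks swap),
  the loss is non-smooth; the gradient routed through the tie-broken
  critical cells is a valid subgradient and is used as-is.  Finite-
  difference checks therefore use generic (distinct-valued) fields.

### Betti-number oracles

`betti_at_threshold` computes Betti numbers of a thresholded field with no
persistence involved, along two independent routes:

* `gf2` — ranks of the GF(2) boundary matrices of the closed cubical set
  (dense bitmask elimination; guarded to ≤ 20 000 cells);
* `fast` — β0 by connected-component labelling with vertex adjacency, χ by
  cell counting, and in 3D β2 as the number of bounded 6-connected
  components of the complement (Alexander duality), with β1 = β0 + β2 − χ.

`auto` uses `gf2` for small 3D inputs and `fast` otherwise (e.g. for 16³
phantom verification, where dense elimination would be slow).  The routes
are cross-checked against each other and against bar counts of the
persistence barcode in the test suite.  A third, fully independent oracle
(`reference_barcode_bruteforce`) re-derives whole barcodes by dense
reduction with its own cell enumeration, and is the ground truth for the
persistence tests.

## Training frameworks

* **Supervised**: soft Dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)`, ε = 1e−6
  (MSE in denoising mode), adaptive-moment descent (Adam), validation
  every `val_interval` epochs, early stop after `patience` non-improving
  evaluations, best-validation weights returned.
* **Semi-supervised**: alternating steps — one labelled batch
  backpropagates the Dice loss, one unlabelled batch backpropagates
  `λ ×` the batch-mean topological loss with per-item priors.  Averaging
  over the unlabelled batch keeps λ's meaning independent of batch size.
  With `λ = 0` the unlabelled stream is skipped entirely; because
  labelled and unlabelled batch sampling use separate seeded streams,
  that run is bit-identical to continued supervised training.
* **Post-processing**: per test item, the trained weights are cloned and
  `mean((S − S0)²) + λ·L_topo(S)` is minimised for a fixed step budget,
  where `S0` is the frozen prediction of the original network — the
  minimal change to the output that corrects its topology.  The weights
  with the best objective seen are returned; the original predictor is
  never modified.

Barcodes are recomputed at every optimisation step: critical pixels
migrate as `S` changes, so cached gradients would be stale.

### The predictor

A compact U-net (2D and 3D): per level two 3^d convolutions + ReLU, 2×
average-pool down, nearest-neighbour up, skip concatenation, 1-voxel
convolution + sigmoid head.  Channel counts double with depth from
`base_channels`.  Forward and backward passes are explicit numpy code; the
backward pass is verified against finite differences in the test suite.
Initialisation is seeded (He normal), so identical seeds give identical
networks.

### Hyperparameters

| parameter | default | role |
|---|---|---|
| λ (post-processing / semi-supervised) | 0.01 | weight of the topological loss |
| lr (supervised) | 1e−3 | Adam step size |
| lr (semi-supervised phase) | 3e−4 | gentler, see below |
| postproc_lr / steps | 3e−4 / 250 | adaptation budget per item |
| val_interval / patience | problem-dependent | early stopping |
| threshold for topological correctness | 0.5 | evaluation convention |

Adam normalises per-parameter step sizes, so even a small λ·gradient can
move weights by ~lr each step; at lr 1e−2 the adaptation phase collapsed
predictions to a constant (after which all gradients vanish through the
saturated sigmoid).  The post-processing and semi-supervised phases
therefore run at 3e−4.  All values are config-overridable.

## Synthetic data

The generator emulates two things:

* **Fourier line-removal corruption**: zero-fill `m` random rows and `m`
  random columns of the centred 2D spectrum (optionally excluding a
  centred band of `preserve_centre` lines), invert, take the magnitude
  (the deletions break conjugate symmetry, so the inverse is complex),
  min-max rescale.  This produces spatially correlated blurring/aliasing
  artefacts of the kind that arise when acquisition happens in the
  frequency domain.  Mean corruption error grows monotonically with `m`.
* **Phantoms of known topology**: disk (1,0), ring (1,1), two-loop (1,2),
  ball (1,0,0), shell (1,0,1), solid torus (1,1,0).  Geometry (centre,
  scale) is randomly perturbed per sample; the Betti label of every
  generated mask is verified against the Betti oracle at construction, so
  a mislabelled sample is impossible by construction.

### Reference study conditions

The package's reference experiments use thin ring annuli (thickness
≈ 0.09·n, ±10 % centre offset, ±15 % scale, 0.1 additive jitter) on 32×32
grids, a depth-2 U-net with 8 base channels, and heavy corruption:
m = 18/32 lines (post-processing study, 10 labelled items) and m = 16/32
(semi-supervised study, 5 labelled + 20 unlabelled), centre 4 lines
preserved.  These sizes were chosen so that a full 5-seed study runs on a
single CPU core in minutes while the supervised baseline still commits
topological errors (broken rings, spurious components) on a substantial
fraction of test items — the regime the topological prior addresses.
Thick, geometrically regular rings make the baseline topologically
perfect and the studies vacuous.

What the phantoms do **not** emulate: anatomical shape statistics and
appearance, intensity inhomogeneity, speckle or scanner noise models,
class imbalance beyond the thin-ring geometry, multi-structure scenes.
Passing these studies shows that the loss and both frameworks do what
they claim on images whose topology is the dominant difficulty; it does
not certify performance on any clinical data distribution.

## Numerical choices and degenerate inputs

* Fields must be finite and in [0, 1]; `normalize01` maps a constant
  array to all zeros (and hence "remove every Fourier line" yields the
  zero image).
* Zero-length bars are dropped — they contribute nothing to any loss term.
* An all-zero field has an empty barcode; a prior then costs exactly the
  number of wanted bars.
* Dice between two empty masks is defined as 1.
* The brute-force barcode oracle refuses fields with more than 500 pixels;
  the GF(2) Betti route refuses complexes over 20 000 cells.
* Complexity: building the complex is Θ(2^d V) cells with ≤ 2d facets
  each; reduction is worst-case cubic but near-linear on these inputs
  (a 32×32 barcode takes ~10 ms, a 16³ volume ~1 s).

## Known limitations

* The loss is a subgradient at value/length ties; optimisation across a
  tie can chatter (not observed to matter in practice).
* Persistence is exact but unoptimised Python/numpy; real-time 3D use
  would need a compiled reduction or downsampled maps.
* Binary (single-channel) segmentation only; multi-class topology and
  boundary topology are out of scope.
* With more than one large spurious component, the loss cannot know which
  to keep — the basin of attraction is large but not global.
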