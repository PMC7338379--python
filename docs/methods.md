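# Methods

## Problem setting

Hanging-drop spheroids respond to cytotoxic drugs with a visible phenotype:
apoptosis inside the spheroid disturbs cell–cell cohesion, shifting a round,
sharp-edged, high-contrast cell mass towards a fragmented, blurred, irregular
one. Because single spheroids yield too few cells for biochemical viability
assays, viability ground truth comes from flow cytometry of *pools* of
equally treated spheroids (single-marker Annexin-V gating), and the
pool-level live fraction labels every image from that pool. The package
implements this full readout as software: image synthesis, cytometry
simulation, labelling, CNN training/evaluation, and classical morphometry.

No public image corpus exists for this assay, so the package ships a
first-class synthetic data generator; all quantitative claims in the test
suite are claims about this generator's distribution, not about any
particular laboratory's micrographs.

## Image simulator

Each micrograph is a 400×320 single-channel float raster in [0, 1], dark
background (0.08) and bright cell mass, rendered as a pure function of a
`SimulationConfig` (bit-identical per seed). The stress phenotype is
parameterized by a single **fragmentation** axis f ∈ [0, 1]:

* the projected cell area π·r² (base radius: 22% of the smaller image
  dimension by default, ±8% jitter) is split among 1 + round(f·(n_max−1))
  blobs with Dirichlet(5) weights, displaced by up to ~1.8·r·f;
* blob boundaries are low-order harmonic perturbations of a disc whose
  amplitude grows with f (irregularity 0.05 + 0.5·f);
* the whole frame is blurred with Gaussian sigma = `edge_softness` + 2.5·f.
  Coupling blur to fragmentation is a deliberate modelling choice: cohesion
  loss and edge-contrast loss are the same phenotype, and the coupling makes
  boundary edge contrast *monotonically* decreasing in f, which the test
  suite verifies in expectation over 20 seeds per point;
* foreground intensity falls linearly from 0.85 to 0.60 across f (a loose,
  apoptotic mass scatters less light than a dense one);
* debris speckle (small dim discs, expected count = `debris_density` ·
  pixels/1000) surrounds the mass, plus Gaussian texture noise (sd 0.02) and
  a quadratic radial vignette (strength 0.15) emulating the droplet optics.

Per-class morphology ranges are non-overlapping on fragmentation by default
— unaffected (0.00–0.12), mildly affected (0.32–0.52), affected (0.72–0.95)
— with matched edge-softness and debris ranges. `class_margin` < 1 widens
the ranges symmetrically towards a harder benchmark. The defaults guarantee
the classes carry signal a classical threshold can find (the baseline
requirement below), so a CNN failure would indicate a training defect, not
an unlearnable dataset.

What the simulator does **not** model: physical optics (PSF, defocus),
fluorescence channels, cell-scale texture, plate artefacts, illumination
gradients beyond the radial vignette, or inter-cell-line morphology
differences. Passing tests therefore demonstrate that the pipeline recovers
a phenotype of this qualitative structure; they do not certify performance
on any real microscope's output.

## Cytometry simulation and labelling

Event intensities are a two-component log-normal mixture: live events with
median 100 a.u., apoptotic events with median 10,000 a.u., shared log-scale
σ = 0.4 (natural log). These values give component overlap ≪ binomial noise
at the default gate, the geometric midpoint √(live_mu·dead_mu) = 1,000 a.u.
— halfway between the medians on the log scale, which is where a cytometrist
would put a single gate between well-separated populations. The gated live
fraction is the share of events below the gate.

Labels: > 0.80 unaffected; [0.40, 0.60] mildly affected; < 0.40 affected.
These three bands leave (0.60, 0.80] uncovered; values there (and exactly
0.80) map to `unlabeled` and are excluded from training rather than
inventing a fourth trained class. The boundary conventions — strict at 0.80
and 0.40, closed at 0.40/0.60 — make the three stated inequalities
non-overlapping and total.

Dataset assembly pools 80 spheroid images per simulated cytometry run
(20,000 events each); the gated label annotates all images of the pool.
Ground-truth live fractions are drawn a small margin inside each label band
(e.g. mildly affected from [0.42, 0.58]) so binomial gating noise cannot
flip a pool across a boundary; with 20,000 events the gating standard error
is ≈ 0.003, an order of magnitude below the margin.

## Network and training

The classifier is declared as a `ModelSpec` — conv3×3(32)/ReLU/pool2×2,
conv3×3(64)/ReLU/pool, conv3×3(64)/ReLU/pool, conv3×3(128)/ReLU/pool,
flatten, dense(128)/ReLU/dropout, dense(3)/softmax — with valid padding,
stride 1, and floor division on odd pooled extents. Shape inference and
parameter counting are pure functions of the spec: at 400×320×1 the flatten
width is 23·18·128 = 52,992 and the total parameter count 6,913,091, with
the dense(128) layer holding 98% of them.

The trainable instance is a compact numpy engine (`spheroscreen.nn`):
im2col-style convolutions via strided views, analytic backpropagation,
inverted dropout, softmax/cross-entropy head, Adam (lr 1e-3, β = 0.9/0.999).
Weight initialization is Glorot-uniform from per-layer seeded streams, so a
run is bit-reproducible given its seed. Gradients are validated against
float64 central finite differences along random parameter directions
(relative tolerance 1e-5). Arithmetic is float32.

Open hyperparameters were fixed as: dropout 0.5 after the dense layer
("high" regularization for a ~7M-parameter model on ~10³ images), Adam as
the standard adaptive optimizer, batch size 16, categorical cross-entropy as
the loss implied by the softmax head.

Augmentation (training folds only; validation/test always clean) draws per
image: rotation ± 40°, shear ± 0.2 rad, zoom in [0.8, 1.2], horizontal flip
with probability 0.5; conventional ranges for this transform family since
only the transform *names* are fixed by the protocol. Resampling is bilinear
with nearest-edge fill — constant-fill corners would imitate the affected
phenotype and leak label information. The `rescale` factor defaults to 1.0
because in-memory images are already on [0, 1]; the PNG loader performs the
1/255 (or 1/65535) conversion, which is the same operation at a different
seam.

## Evaluation protocol

A stratified 80/20 hold-out is drawn first; the 80% pool is split into five
stratified folds (stratification is the variance-reducing choice for
balanced 400-per-class data). One fresh model trains per fold; per-epoch
train/validation accuracies are averaged across folds; the best model —
highest final-epoch validation accuracy, lowest fold index on ties — is
evaluated once on the untouched test set. At the nominal 1,200-image scale
this yields 960/240 hold-out and 768/192 folds. Metrics are the per-class
precision, recall, F1 = 2·p·r/(p+r) and the 3×3 confusion matrix; the
implementation is cross-checked in tests against both a brute-force counting
oracle and scikit-learn's reference routines.

## Morphometry

Segmentation is Otsu thresholding with removal of sub-9-pixel objects
(optional morphological closing and largest-component keep). Features:
foreground area; equivalent radius r_eq = √(area/π); ball-model volume
(4/3)·π·r_eq³ in arbitrary units — the only volume consistent with a single
projection of a ball-shaped spheroid, with no pixel calibration assumed;
boundary edge contrast as the mean Sobel gradient magnitude over perimeter
pixels (mask minus its erosion); connected-component count; and solidity
(area / convex-hull area). A blank image returns a flagged empty feature set
rather than raising.

`EdgeContrastBaseline` is a depth-2 decision tree over (edge contrast,
component count) — operationally two learned thresholds on the dominant
feature. Its required ≥ 0.80 accuracy on default classes guards against a
simulator whose classes only a deep model could separate.

## Problem sizes and profiles

Two named profiles ship with the package. `full` is the nominal protocol:
400×320 images, 400 per class, 50 epochs — a multi-hour single-CPU run,
available through the CLI for complete experiments. `smoke` (64×64 images,
60 per class, 10 epochs, ~1–2 min) is the scale at which the automated test
suite exercises the end-to-end training claim; the acceptance threshold
there is averaged validation accuracy ≥ 0.80 (observed ≈ 0.95 at seed 1).
The architecture checks, split protocol, metric identities, gating recovery
(1,000 simulated pools of 2,000 events) and morphometry closed forms are all
desk-scale and run at full fidelity. Dataset-protocol counts are verified at
the nominal 1,200-image scale.

## Known limitations

* The synthetic phenotype is low-dimensional by design; real spheroid
  micrographs vary along axes (texture, illumination, cell line, focus) the
  generator does not model, so reported accuracies do not transfer to real
  data.
* The image↔pool assignment in a real screen is a laboratory bookkeeping
  step; the simulator assigns pools by generation order.
* Single-marker gating only: no compensation, doublet discrimination or
  multi-channel panels.
* The numpy engine targets correctness and reproducibility over speed; the
  full-scale 50-epoch protocol is practical but slow on one CPU.
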