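# Methods

## The segmentation problem

Radiotherapy planning for non-small-cell lung cancer requires contours for
six thoracic organs at risk (OARs) on axial CT: left lung, right lung,
heart, spinal cord, trachea, and esophagus. Five of these are large or
anatomically fixed and segment well with a single full-slice network. The
esophagus does not: it is small (a few hundred mm² per slice), has soft
tissue contrast comparable to the image noise, and its luminal air filling
varies between patients and along the organ. `thorseg` implements a
two-step, coarse-to-fine strategy built around that asymmetry:

1. **Stage 1** — a dense U-shaped network segments the five
   easier organs on full slices (6-class output including background).
2. **Localization** — the per-slice centre of gravity of the *predicted*
   trachea, shifted 5 mm toward the image left and 5 mm up, centres a
   64×64-pixel crop. The shift leaves room for the esophagus, which lies
   posterior to the trachea and drifts toward the image left below the
   carina. Slices with no predicted trachea chain from the previous
   slice's centre, stepped 1 mm further left per slice.
3. **Stage 2** — a residual attention network segments the esophagus
   (binary sigmoid output) inside the crop.
4. **Paste-back** — stage-2 foreground becomes esophagus wherever stage 1
   assigned background; every other stage-1 organ label wins conflicts and
   is left bitwise unchanged. The esophagus in the final volume comes
   exclusively from stage 2.

A plain U-Net trained on the same 7-class task serves as the comparison
baseline, and a 7-class variant of stage 1 (esophagus as an extra class)
serves as the one-step ablation.

## Preprocessing

CT volumes in HU are window/levelled with the mediastinal soft-tissue
window (width 400 HU, level 40 HU), mapping
`[level − width/2, level + width/2] → [0, 255]` with clipping, then scaled
to `[0, 1]` as network input. Windowed intensities are kept as reals;
quantisation to 8 bits happens only on PNG export, avoiding double
rounding. Expert per-organ masks merge into one exclusive integer label
field with fixed overlap precedence `trachea > cord > esophagus > heart >
lungs`; the thin air column must stay stable against the adjacent
esophagus, which networks otherwise confuse.

## The cascaded attention block

Stage 2 is built from residual blocks whose main path (two 3×3
convolutions) is gated by *spatial attention followed by channel
attention*:

* **Spatial gate.** The C×H×W map is channel-wise max-pooled and
  mean-pooled into two 1×H×W maps, stacked, convolved with one k×k kernel
  (default 7, configurable), and squashed by a sigmoid; the resulting
  per-position probability multiplies every channel.
* **Channel gate.** The spatially gated map is globally max- and
  mean-pooled over H×W into two C-vectors; both pass the *same* 1-D
  convolution of adaptive kernel size `K = log2(C)` — rounded half-up,
  floored at 1 — are summed and squashed; the per-channel probability
  multiplies every position. The growing K gives wider channel receptive
  fields as depth increases without a fully connected bottleneck.

Both attention convolutions use edge-replicate padding so that a constant
input produces a constant gate (zero padding would break this symmetry at
borders). The block output is main path plus shortcut; identity blocks use
the raw input (in/out widths must match, and a zeroed main path makes the
block an exact identity), convolution blocks a 1×1 convolution. Encoders
alternate convolution and identity attention blocks with stride-2
downsampling; decoders alternate nearest-neighbour-upsample+conv with
identity blocks; encoder/decoder levels are joined by channel
concatenation, and a 1×1 convolution emits logits. Since no normalisation
layers are used, exact residual identities hold and the trainability of
small configurations rests on He initialisation plus Adam.

## Stage-1 dense U-net

The stage-1 encoder keeps the dense-connectivity mechanism: each encoder
stage is a dense block of L 3×3 layers with growth rate g whose outputs
are concatenated in series (output width `in + L·g`), linked by
transition layers (2×2 stride-2 convolutions with channel compression θ).
Exact layer counts are configuration, not constants; the defaults are 4
stages, 4 layers per block, g = 12, θ = 0.5. A stride-2 stem moves the
dense blocks to half resolution — the standard DenseNet entry — which is
also what keeps full-slice CPU training tractable; a light full-resolution
side feature (3×3 convolution) provides the topmost skip so logits return
at input size.

## Training

Loss is an equal mix of voxel cross-entropy (binary cross-entropy for
stage 2) and soft Dice over foreground classes; optimiser Adam, default
learning rate 1e-3, seeded shuffling, best-validation-epoch weights kept.
Validation scores are mean foreground Dice of argmax (threshold-0.5)
predictions. Everything is float32 numpy on the CPU; with one BLAS
thread, reruns with the same config and seed are bit-identical. These
choices (loss, optimiser, schedule, batch construction) were genuinely
open and are all exposed in `TrainConfig`/`NetworkConfig`.

Stage-2 training crops are centred on the *label* trachea centroid (the
predicted one is used only at inference), shifted 5 mm left/up, then
jittered by a random displacement with magnitude uniform on 0–4 mm and
uniform direction — emulating stage-1 localisation error, whose scale
matches the average surface distance of first-stage esophagus output.
Crops that miss the esophagus re-centre by the same 1 mm leftward
fallback stepping. The 0.5 decision threshold on the stage-2 sigmoid and
the leftward fallback direction are package choices exposed in
`CropSpec`; "left" is consistent with the esophagus drifting left of the
trachea below the carina.

## Geometric evaluation

DSC, HD95 and ASD are computed in 3D per patient with anisotropic voxel
spacing (one value per organ per patient), not slice-wise 2D — the
standard benchmark convention, and material at 5 mm slice thickness. The
surface of a mask is its set of foreground voxels with a face-adjacent
(6-connected) background or out-of-volume neighbour; distances are
centre-to-centre Euclidean mm. Conventions the literature leaves open are
fixed and exposed as options:

* HD95 combines directions as the **max of the two directed 95th
  percentiles** (a pooled variant is available);
* percentile interpolation is **linear**, so the HD95 of two single voxels
  equals their exact distance;
* empty masks yield missing distance values, never 0; an organ empty in
  both volumes scores DSC 1, in exactly one DSC 0.

The fast path uses a Euclidean distance transform; tests verify it against
an independent O(n²) all-pairs oracle to 1e-9 mm. Cohort summaries report
per-organ mean ± sd over non-missing values, and model comparisons use the
paired Wilcoxon signed-rank test (exact null for n ≤ 25 without ties,
normal approximation otherwise; all-zero differences report p = 1 by
convention).

## The synthetic phantom

Clinical CT with expert contours is private, so the package ships a
seeded, parametric thoracic phantom that reproduces the *topology and
contrast statistics* the method depends on — not patient anatomy. Each
phantom is an axial stack of analytic ellipses with per-slice centre
jitter (sd 0.7 mm): soft-tissue body (40 HU) in air, lateral lungs
(−750 HU) clipped to a chest-wall ellipse, a central-anterior heart
(70 HU, mildly contrast-enhanced), a posterior vertebral ring (700 HU)
enclosing the cord (45 HU), an air trachea (−950 HU), and an esophagus
adjacent to and posterior of the trachea. Per patient the generator
samples trachea radius (6–9 mm), esophagus radius (3.5–6 mm),
trachea–esophagus gap (2–6 mm), luminal air fraction (0–0.8, lumen
−950 HU) and a leftward drift rate (0.6–1.2 mm/slice below the carina,
capped at 15 mm); Gaussian noise (sd 15 HU) is added last. The esophageal
wall is set to 55 HU — about one noise standard deviation above the
surrounding mediastinum — so that an air-free esophagus is genuinely
low-contrast yet not pixel-identical to its surroundings, which would be
unlearnable in principle; mild wall enhancement is realistic for
contrast-injected acquisitions. An anatomical contract checker validates
every invariant (single connected component per organ per slice, lungs
lateral, trachea anterior of cord, esophagus strictly left of the trachea
below the carina, bounded trachea–esophagus gap) on 100 % of generated
samples under the default configuration.

What the phantom does **not** emulate: organ texture, tumours, partial
volume effects, breathing deformation, inter-observer contouring noise,
and the trachea's bifurcation into bronchi. Passing phantom benchmarks
therefore demonstrates that the pipeline's mechanics (localisation,
attention, paste-back, metrics) work and that the two-step design helps
under class imbalance and low contrast — not clinical-grade accuracy.

## Numerical engine

No GPU framework is used: the networks run on a compact reverse-mode
automatic-differentiation engine over float32 numpy arrays
(`thorseg.nn.autograd`). Convolutions lower to im2col + BLAS matmul with
explicit backward passes (including edge-padding gradient folding);
losses are fused, numerically stable implementations (log-sum-exp
softmax cross-entropy, logit-space BCE). Finite-difference tests check
every operation's gradient.

## Scaled-down benchmark conditions

The end-to-end experiment keeps the clinical study's cohort structure —
39 training, 8 validation, 12 test patients, split by patient — at a grid
the CPU engine trains in minutes: 128² slices at 3 mm pixels, 6 slices of
5 mm per patient, carina at slice 2, small network configurations
(stage-1 dense U-net: 3 stages, 2 layers/block, growth 8, stem 12;
stage 2 and baseline: widths 8/16/32), 3 epochs, batch 4 — three epochs
being the least budget at which stage 1 reliably converges on the trachea
across seeds, without which the localizer (and with it the comparison)
degenerates for reasons unrelated to the claim. At this scale
the esophagus is 2–4 px across — mirroring, in pixels, the smallness that
motivates the two-step design. The benchmark's claim is directional, not
absolute: two-step esophagus test DSC exceeds the one-step 7-class
ablation and is at least the baseline U-Net's. In runs to date the margin
is large (the baseline usually fails to predict the esophagus class at
all within this budget — exactly the class-imbalance failure the second
stage exists to fix, and the one-step ablation fails at most seeds) while
the two-step pipeline reaches an esophagus DSC around 0.67–0.71 with
trachea DSC ≈ 0.92–0.94.

## Known limitations

* 2D slice-wise networks; no 3D convolutions or inter-slice context
  beyond the fallback chaining.
* The numpy engine is single-threaded and CPU-bound; it is built for
  tests and phantom-scale experiments, not clinical volumes.
* Phantom realism limits are listed above; no dosimetric evaluation
  (treatment planning is out of scope).
* DICOM / DICOM-RT are not read or written; NIfTI (and read-only PNG
  stacks) are the only formats.
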