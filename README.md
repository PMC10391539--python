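# thorseg

Two-step, coarse-to-fine segmentation of thoracic organs at risk (OARs) on
CT for lung-cancer radiotherapy planning, with a dedicated residual
attention network for the esophagus.

Contouring the six thoracic OARs — left lung, right lung, heart, spinal
cord, trachea, esophagus — is routine but slow, and the esophagus is the
consistent weak spot of one-pass segmentation networks: it is small, has
near-noise soft-tissue contrast, and its luminal air filling varies. This
package implements the two-step strategy that splits the task by organ
character:

1. a **dense U-shaped network** (dense-block encoder, U-shaped
   decoder with long skips) segments the five large/fixed organs on full
   slices;
2. the per-slice **centre of gravity of the predicted trachea**, shifted
   5 mm left and 5 mm up, localises a 64×64 crop (the esophagus lies just
   posterior-left of the trachea, drifting further left below the carina;
   trachea-free slices chain from the previous slice's centre, 1 mm
   further left per slice);
3. a **residual attention network** — residual blocks whose main path is
   gated by spatial attention (channel-wise max+mean pooling → k×k conv →
   sigmoid) then channel attention (global max+mean pooling → shared 1-D
   conv of adaptive size K = log₂C → sigmoid) — segments the esophagus
   inside the crop;
4. the crop prediction is **pasted back**: stage-2 foreground becomes
   esophagus only where stage 1 saw background; all other organ labels are
   untouched.

Evaluation uses the field's standard geometric triple, computed in 3D
with anisotropic voxel spacing:

* **DSC** = 2|A∩B| / (|A|+|B|),
* **HD95** — max over directions of the 95th-percentile directed surface
  distance (mm),
* **ASD** — symmetric mean nearest-surface distance (mm),

with surfaces defined by 6-connectivity and distances centre-to-centre,
plus paired Wilcoxon signed-rank model comparisons. Because clinical data
with expert contours is private, the package ships a seeded parametric
thoracic phantom generator (lungs, heart, vertebra+cord, trachea,
variably air-filled esophagus) so every stage is trainable and testable
end-to-end. The networks run on a compact numpy automatic-differentiation
engine included in the package — no GPU framework required.

## Worked example

Run the full experiment — generate a seeded 39/8/12 phantom cohort, train
the two-step pipeline plus the one-step ablation and the baseline U-Net,
and evaluate the 12 test patients:

```python
from thorseg import run_phantom_benchmark

out = run_phantom_benchmark(seed=1)
print("two-step esophagus DSC:", round(out["two_step_esophagus_dsc"], 3))
print("one-step esophagus DSC:", round(out["one_step_esophagus_dsc"], 3))
print("baseline U-Net esophagus DSC:", round(out["baseline_unet_esophagus_dsc"], 3))
print(out["reports"]["two_step"].summary.round(3))
```

which prints (seed 1; a few CPU-minutes):

```
two-step esophagus DSC: 0.706
one-step esophagus DSC: 0.64
baseline U-Net esophagus DSC: 0.0
```

followed by the per-organ mean ± sd table of the two-step model (trachea
DSC ≈ 0.92 in this run). Read: the trachea — high contrast, fixed
position — is segmented well by stage 1, which is what makes it a
reliable localization anchor; the esophagus, which the one-pass baseline
misses entirely at this scale and class imbalance, reaches a usable DSC
through the localized second stage. The directional gap between the
two-step pipeline and both one-pass alternatives is the design's claim,
and it holds across seeds.

A thin CLI mirrors the library:

```bash
thorseg phantom-generate --out data --seed 1
thorseg train-stage1 --data data --out stage1.npz --seed 1
thorseg build-crops  --data data --out crops.npz --seed 1
thorseg train-stage2 --data data --out stage2.npz --seed 1
thorseg infer --ct data/test/p047/ct.nii.gz --stage1 stage1.npz --stage2 stage2.npz --out pred.nii.gz
thorseg evaluate --pred preds/ --gt data/test --out metrics.csv
```

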