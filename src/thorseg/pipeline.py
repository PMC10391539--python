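"""End-to-end orchestration of the two-step segmentation workflow.

Stage 1 trains a dense U-net on full axial slices for background + five
organs (left lung, right lung, heart, cord, trachea). Stage 2 builds 64×64
crops around jittered label-trachea centroids and trains the residual
attention network to segment the esophagus inside them. Two-step inference
runs stage 1, localises per-slice crops from the *predicted* trachea
centroid (falling back layer by layer when a slice has none), runs stage 2
in the crops, and pastes the esophagus back without touching any other
organ label. Cohort evaluation reports per-organ mean ± sd of DSC/HD95/ASD
and paired Wilcoxon signed-rank comparisons between two models.

Training is fully seeded and single-threaded numpy, so reruns with the same
config and seed are bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .crop import (CropSpec, centroid, extract_crop, fallback_center,
                   inference_center, paste_esophagus, training_center)
from .errors import ConfigError, ValidationError
from .metrics import evaluate_patient
from .networks import (NetworkConfig, build_baseline_unet, build_dense_unet,
                       build_residual_attention_net)
from .nn.autograd import Tensor, sigmoid_bce, softmax, softmax_cross_entropy
from .nn.layers import Adam
from .phantom import PhantomConfig, generate_patient
from .preprocess import WindowConfig, apply_window, to_unit_interval
from .volume_io import CTVolume, LabelVolume, read_labelmap, read_volume

logger = logging.getLogger("thorseg")

__all__ = [
    "TrainConfig", "PatientRecord", "CohortReport", "load_cohort", "cohort_from_samples",
    "network_input", "train_stage1", "build_stage2_dataset", "train_stage2",
    "infer_two_step", "evaluate_cohort", "compare_models", "run_phantom_benchmark",
]

STAGE1_ORGANS = ("left_lung", "right_lung", "heart", "cord", "trachea")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by all training entry points."""

    epochs: int = 2
    batch_size: int = 4
    lr: float = 1e-3
    dice_weight: float = 0.5  # loss = dice_weight*(1-softDice) + (1-dice_weight)*CE
    seed: int = 0
    device: str = "cpu"  # hint only; execution is numpy on the CPU

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


@dataclass
class PatientRecord:
    patient_id: str
    ct: CTVolume
    labels: LabelVolume


@dataclass
class CohortReport:
    """Per-patient metric records plus per-organ mean ± sd summary."""

    records: pd.DataFrame  # columns: patient_id, organ, dsc, hd95_mm, asd_mm
    summary: pd.DataFrame  # index organ, columns (metric, mean|sd|n)

    def organ_mean(self, organ: str, metric: str = "dsc") -> float:
        return float(self.summary.loc[organ, (metric, "mean")])


def load_cohort(root) -> dict[str, list[PatientRecord]]:
    """Load a dataset directory laid out by :func:`thorseg.phantom.write_cohort`.

    Asserts split integrity: a patient id may appear in exactly one split.
    """
    import os

    cohort: dict[str, list[PatientRecord]] = {}
    seen: dict[str, str] = {}
    for split in sorted(os.listdir(root)):
        sdir = os.path.join(root, split)
        if not os.path.isdir(sdir):
            continue
        cohort[split] = []
        for pid in sorted(os.listdir(sdir)):
            if pid in seen:
                raise ValidationError(f"patient {pid} appears in splits {seen[pid]} and {split}")
            seen[pid] = split
            pdir = os.path.join(sdir, pid)
            cohort[split].append(PatientRecord(
                patient_id=pid,
                ct=read_volume(os.path.join(pdir, "ct.nii.gz")),
                labels=read_labelmap(os.path.join(pdir, "labels.nii.gz")),
            ))
    return cohort


def cohort_from_samples(samples, prefix: str = "p") -> list[PatientRecord]:
    return [PatientRecord(f"{prefix}{i:03d}", s.ct, s.labels) for i, s in enumerate(samples)]


def network_input(ct: CTVolume, window: WindowConfig = WindowConfig()) -> np.ndarray:
    """Window/level a HU volume and scale to [0, 1]: the canonical network
    input, shaped (n_slices, 1, H, W) float32."""
    u = to_unit_interval(apply_window(ct, window), window.out_max)
    return u.voxels[:, None].astype(np.float32)


# ---------------------------------------------------------------------------
# Losses and the shared training loop
# ---------------------------------------------------------------------------

def _soft_dice_loss(probs: Tensor, onehot: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - mean foreground soft Dice. ``probs``/(N,C,H,W) vs one-hot target."""
    fg = probs[:, 1:] if probs.shape[1] > 1 else probs
    oh = onehot[:, 1:] if onehot.shape[1] > 1 else onehot
    t = Tensor(oh.astype(np.float32))
    inter = (fg * t).sum(axis=(0, 2, 3))
    denom = fg.sum(axis=(0, 2, 3)) + t.sum(axis=(0, 2, 3))
    return 1.0 - ((inter * 2.0 + eps) / (denom + eps)).mean()


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    oh = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    np.put_along_axis(oh, labels[:, None], 1.0, axis=1)
    return oh


def _multiclass_loss(logits: Tensor, labels: np.ndarray, w: float) -> Tensor:
    ce = softmax_cross_entropy(logits, labels)
    dice = _soft_dice_loss(softmax(logits, axis=1), _onehot(labels, logits.shape[1]))
    return dice * w + ce * (1.0 - w)


def _binary_loss(logits: Tensor, target: np.ndarray, w: float) -> Tensor:
    bce = sigmoid_bce(logits, target)
    dice = _soft_dice_loss(logits.sigmoid(), target)
    return dice * w + bce * (1.0 - w)


def _mean_fg_dsc_multiclass(model, xs: np.ndarray, ys: np.ndarray, n_classes: int,
                            batch: int = 4) -> float:
    """Mean foreground Dice of argmax predictions over a slice set."""
    from .metrics import dsc as _dsc

    preds = predict_logits(model, xs, batch).argmax(axis=1)
    vals = [
        _dsc(preds == c, ys == c)
        for c in range(1, n_classes) if (ys == c).any() or (preds == c).any()
    ]
    return float(np.mean(vals)) if vals else 1.0


def predict_logits(model, xs: np.ndarray, batch: int = 4) -> np.ndarray:
    outs = [model(Tensor(xs[i:i + batch])).data for i in range(0, len(xs), batch)]
    return np.concatenate(outs, axis=0)


def _fit(model, xs, ys, val_fn, cfg: TrainConfig, loss_fn):
    """Seeded epoch loop; keeps the best-validation weights. Returns history."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = [{"epoch": 0, "val_dsc": val_fn(model)}]
    best = (history[0]["val_dsc"], model.state_dict())
    n = len(xs)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            model.zero_grad()
            loss = loss_fn(model(Tensor(xs[idx])), ys[idx])
            if not np.isfinite(loss.data):
                raise ArithmeticError(f"non-finite loss at epoch {epoch} step {i}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dsc": val_fn(model)}
        history.append(entry)
        logger.info("epoch %d: loss %.4f val_dsc %.4f", epoch, entry["train_loss"], entry["val_dsc"])
        if entry["val_dsc"] >= best[0]:
            best = (entry["val_dsc"], model.state_dict())
    model.load_state_dict(best[1])
    return history


def _slice_arrays(patients: list[PatientRecord], n_classes: int):
    """Stack all slices of a patient list into (X, Y); esophagus labels are
    dropped to background when the class count excludes them."""
    xs = np.concatenate([network_input(p.ct) for p in patients], axis=0)
    ys = np.concatenate([p.labels.labels for p in patients], axis=0).astype(np.int64)
    ys = ys.copy()
    ys[ys >= n_classes] = 0
    return xs, ys


def train_stage1(cohort: dict, net_cfg: NetworkConfig, cfg: TrainConfig,
                 architecture: str = "dense_unet"):
    """Train a full-slice multi-class segmenter (stage 1 or the U-Net
    baseline). Returns ``(model, history)``; the model carries the weights
    of the best validation epoch."""
    if "train" not in cohort or not cohort["train"]:
        raise ValidationError("cohort has no training patients")
    if "val" not in cohort or not cohort["val"]:
        raise ConfigError("cohort has no validation split")
    builder = {"dense_unet": build_dense_unet, "baseline_unet": build_baseline_unet}[architecture]
    model = builder(net_cfg)
    nc = net_cfg.n_classes
    xs, ys = _slice_arrays(cohort["train"], nc)
    xv, yv = _slice_arrays(cohort["val"], nc)
    if len(xv) > 24:  # evenly thinned validation subset keeps epochs cheap
        step = int(np.ceil(len(xv) / 24))
        xv, yv = xv[::step], yv[::step]
    history = _fit(
        model, xs, ys,
        val_fn=lambda m: _mean_fg_dsc_multiclass(m, xv, yv, nc),
        cfg=cfg,
        loss_fn=lambda logits, labels: _multiclass_loss(logits, labels, cfg.dice_weight),
    )
    return model, history


# ---------------------------------------------------------------------------
# Stage-2 crop dataset
# ---------------------------------------------------------------------------

@dataclass
class CropDataset:
    x: np.ndarray  # (n, 1, s, s) unit-interval image crops
    y: np.ndarray  # (n, 1, s, s) binary esophagus masks
    meta: list  # (patient_id, CropRegion)
    skipped: list = field(default_factory=list)


def _crop_contains(mask2d, center, spec) -> bool:
    crop, _ = extract_crop(mask2d, center, spec)
    return bool(crop.any())


def build_stage2_dataset(patients: list[PatientRecord], spec: CropSpec,
                         seed: int = 0, max_fallback_steps: int = 64) -> CropDataset:
    """Cut jittered 64×64 training crops around label trachea centroids.

    Slices with an empty trachea mask chain from the previous slice's
    anchor; crops that miss the esophagus label are re-centred by the same
    1 mm fallback stepping. Slices with neither an anchor nor an esophagus
    are skipped and logged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    xs, ys, meta, skipped = [], [], [], []
    for p in patients:
        vol = network_input(p.ct)
        trachea = p.labels.mask("trachea")
        esoph = p.labels.mask("esophagus")
        dy, dx = p.ct.spacing[1:]
        anchor = None
        for z in range(p.ct.shape[0]):
            if trachea[z].any():
                anchor = centroid(trachea[z])
            elif anchor is not None:
                anchor = fallback_center(anchor, (dy, dx), spec)
            else:
                skipped.append((p.patient_id, z, "no trachea and no previous anchor"))
                logger.warning("skip %s slice %d: no trachea anchor", p.patient_id, z)
                continue
            if not esoph[z].any():
                skipped.append((p.patient_id, z, "slice has no esophagus"))
                continue
            center = training_center(anchor, (dy, dx), spec, rng)
            for _ in range(max_fallback_steps):
                if _crop_contains(esoph[z], center, spec):
                    break
                center = fallback_center(center, (dy, dx), spec)
            else:
                skipped.append((p.patient_id, z, "fallback never reached the esophagus"))
                continue
            xc, region = extract_crop(vol[z, 0], center, spec, slice_index=z)
            yc, _ = extract_crop(esoph[z].astype(np.float32), center, spec, slice_index=z)
            xs.append(xc)
            ys.append(yc)
            meta.append((p.patient_id, region))
    if not xs:
        raise ValidationError("no crops could be extracted")
    return CropDataset(
        x=np.stack(xs)[:, None].astype(np.float32),
        y=np.stack(ys)[:, None].astype(np.float32),
        meta=meta, skipped=skipped,
    )


def train_stage2(train_ds: CropDataset, val_ds: CropDataset,
                 net_cfg: NetworkConfig, cfg: TrainConfig):
    """Train the residual attention network (binary esophagus) on crops."""
    from .metrics import dsc as _dsc

    if net_cfg.n_classes != 1:
        raise ConfigError("stage 2 is binary: n_classes must be 1 (sigmoid output)")
    model = build_residual_attention_net(net_cfg)

    def val_fn(m, thr=0.5):
        pred = predict_logits(m, val_ds.x, batch=8)[:, 0] > 0.0  # sigmoid>0.5 <=> logit>0
        return _dsc(pred, val_ds.y[:, 0] > 0.5)

    history = _fit(model, train_ds.x, train_ds.y, val_fn, cfg,
                   loss_fn=lambda logits, target: _binary_loss(logits, target, cfg.dice_weight))
    return model, history


# ---------------------------------------------------------------------------
# Two-step inference
# ---------------------------------------------------------------------------

def infer_two_step(ct: CTVolume, stage1_model, stage2_model,
                   spec: CropSpec = CropSpec(), threshold: float = 0.5,
                   label_table=None) -> LabelVolume:
    """Full two-step inference on one CT volume.

    Stage-1 argmax labels every slice (exact ties go to the lowest class
    index); the predicted trachea drives per-slice crop centres, chaining
    the 1 mm fallback through trachea-free slices; stage-2 sigmoid output is
    thresholded and pasted back as the esophagus. If no slice has a
    predicted trachea the esophagus stays empty and a warning is issued.
    """
    from .volume_io import DEFAULT_LABEL_TABLE

    label_table = dict(label_table or DEFAULT_LABEL_TABLE)
    xs = network_input(ct)
    logits = predict_logits(stage1_model, xs)
    stage1 = logits.argmax(axis=1).astype(np.int16)  # first maximum wins ties
    lv = LabelVolume(stage1, spacing=ct.spacing, label_table=label_table)
    trachea_code = label_table["trachea"]
    dy, dx = ct.spacing[1:]

    if not (stage1 == trachea_code).any():
        warnings.warn("no trachea predicted in any slice; esophagus left empty")
        return paste_esophagus(lv, [])

    crops = []
    anchor = None
    for z in range(ct.shape[0]):
        tmask = stage1[z] == trachea_code
        if tmask.any():
            anchor = centroid(tmask)
        elif anchor is not None:
            anchor = fallback_center(anchor, (dy, dx), spec)
        else:
            continue  # leading slices before the first trachea prediction
        center = inference_center(anchor, (dy, dx), spec)
        xc, region = extract_crop(xs[z, 0], center, spec, slice_index=z)
        crops.append((xc, region))
    from scipy.special import expit

    probs_in = np.stack([c for c, _ in crops])[:, None]
    logit2 = predict_logits(stage2_model, probs_in, batch=8)
    preds = expit(logit2[:, 0]) >= threshold
    return paste_esophagus(lv, [(preds[i], crops[i][1]) for i in range(len(crops))])


# ---------------------------------------------------------------------------
# Cohort evaluation and model comparison
# ---------------------------------------------------------------------------

def evaluate_cohort(preds: list[LabelVolume], gts: list[LabelVolume],
                    patient_ids: list[str], organs=None) -> CohortReport:
    rows = []
    for pred, gt, pid in zip(preds, gts, patient_ids):
        for rec in evaluate_patient(pred, gt, organs=organs, patient_id=pid):
            rows.append({"patient_id": rec.patient_id, "organ": rec.organ,
                         "dsc": rec.dsc, "hd95_mm": rec.hd95, "asd_mm": rec.asd})
    records = pd.DataFrame(rows)
    summary = records.groupby("organ")[["dsc", "hd95_mm", "asd_mm"]].agg(["mean", "std", "count"])
    summary.columns = pd.MultiIndex.from_tuples(
        [(m, {"std": "sd", "count": "n"}.get(s, s)) for m, s in summary.columns])
    return CohortReport(records=records, summary=summary)


def compare_models(report_a: CohortReport, report_b: CohortReport) -> pd.DataFrame:
    """Paired per-organ, per-metric Wilcoxon signed-rank comparison.

    Pairs with a missing value on either side are dropped; if every paired
    difference is zero the p-value is 1 by convention. The exact null
    distribution is used for n ≤ 25 (no ties/zeros), normal approximation
    otherwise.
    """
    a, b = report_a.records, report_b.records
    if sorted(a.patient_id.unique()) != sorted(b.patient_id.unique()):
        raise ValidationError("reports cover different patients")
    key = ["patient_id", "organ"]
    merged = a.set_index(key).join(b.set_index(key), lsuffix="_a", rsuffix="_b")
    rows = []
    for organ, grp in merged.groupby("organ"):
        for metric in ("dsc", "hd95_mm", "asd_mm"):
            va, vb = grp[f"{metric}_a"].to_numpy(), grp[f"{metric}_b"].to_numpy()
            ok = np.isfinite(va) & np.isfinite(vb)
            va, vb = va[ok], vb[ok]
            if len(va) == 0:
                p = float("nan")
            elif np.all(va == vb):
                p = 1.0
            else:
                method = "exact" if len(va) <= 25 else "approx"
                try:
                    p = float(stats.wilcoxon(va, vb, method=method).pvalue)
                except ValueError:
                    p = float(stats.wilcoxon(va, vb, method="approx").pvalue)
            rows.append({"organ": organ, "metric": metric, "n": int(len(va)),
                         "mean_a": float(np.mean(va)) if len(va) else float("nan"),
                         "mean_b": float(np.mean(vb)) if len(vb) else float("nan"),
                         "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scaled-down end-to-end phantom benchmark
# ---------------------------------------------------------------------------

#: Phantom conditions for the desk-scale benchmark: the clinical cohort's
#: 39/8/12 patient split at reduced grid size (128² at 3 mm pixels, 6 slices
#: of 5 mm) so three architectures train in CPU-minutes.
BENCH_PHANTOM = PhantomConfig(image_size=128, n_slices=6, spacing=(5.0, 3.0, 3.0),
                              carina_slice=2)
BENCH_SPLITS = {"train": 39, "val": 8, "test": 12}
BENCH_STAGE1 = NetworkConfig(n_classes=6, dense_stages=3, growth_rate=8,
                             dense_layers_per_block=2, stem_width=12)
BENCH_UNET = NetworkConfig(n_classes=7, widths=(8, 16, 32))
BENCH_STAGE2 = NetworkConfig(n_classes=1, widths=(8, 16, 32))
BENCH_TRAIN = TrainConfig(epochs=3, batch_size=4, lr=1e-3)


def run_phantom_benchmark(seed: int, phantom_cfg: PhantomConfig = BENCH_PHANTOM,
                          splits: dict = None, crop_spec: CropSpec = CropSpec(),
                          train_cfg: TrainConfig = BENCH_TRAIN) -> dict:
    """Train two-step, one-step (7-class stage 1) and baseline U-Net models
    on one seeded phantom cohort and return test esophagus DSC for each,
    plus the stage-1 organ summary. All randomness derives from ``seed``."""
    splits = dict(splits or BENCH_SPLITS)
    base = replace(phantom_cfg, seed=seed)
    n_total = sum(splits.values())
    samples = [generate_patient(base, i) for i in range(n_total)]
    recs = cohort_from_samples(samples)
    cohort, i = {}, 0
    for split, count in splits.items():
        cohort[split] = recs[i:i + count]
        i += count
    tcfg = replace(train_cfg, seed=seed)

    # two-step: 6-class stage 1 + residual attention stage 2
    stage1, h1 = train_stage1(cohort, replace(BENCH_STAGE1, seed=seed), tcfg)
    train_crops = build_stage2_dataset(cohort["train"], crop_spec, seed=seed)
    val_crops = build_stage2_dataset(cohort["val"], crop_spec, seed=seed + 1)
    stage2, h2 = train_stage2(train_crops, val_crops, replace(BENCH_STAGE2, seed=seed), tcfg)

    # ablation: one-step 7-class stage 1 (esophagus as an extra class)
    one_step, h1b = train_stage1(cohort, replace(BENCH_STAGE1, n_classes=7, seed=seed), tcfg)
    # baseline: plain U-Net, all organs in one pass
    unet, h3 = train_stage1(cohort, replace(BENCH_UNET, seed=seed), tcfg,
                            architecture="baseline_unet")

    gts = [p.labels for p in cohort["test"]]
    ids = [p.patient_id for p in cohort["test"]]
    two_step_preds, one_step_preds, unet_preds = [], [], []
    for p in cohort["test"]:
        two_step_preds.append(infer_two_step(p.ct, stage1, stage2, crop_spec))
        for model, sink in ((one_step, one_step_preds), (unet, unet_preds)):
            lab = predict_logits(model, network_input(p.ct)).argmax(axis=1).astype(np.int16)
            sink.append(LabelVolume(lab, spacing=p.ct.spacing,
                                    label_table=dict(p.labels.label_table)))
    rep_two = evaluate_cohort(two_step_preds, gts, ids)
    rep_one = evaluate_cohort(one_step_preds, gts, ids)
    rep_unet = evaluate_cohort(unet_preds, gts, ids)
    return {
        "two_step_esophagus_dsc": rep_two.organ_mean("esophagus"),
        "one_step_esophagus_dsc": rep_one.organ_mean("esophagus"),
        "baseline_unet_esophagus_dsc": rep_unet.organ_mean("esophagus"),
        "reports": {"two_step": rep_two, "one_step": rep_one, "baseline_unet": rep_unet},
        "history": {"stage1": h1, "stage2": h2, "one_step": h1b, "baseline_unet": h3},
        "comparison": compare_models(rep_two, rep_unet),
    }
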