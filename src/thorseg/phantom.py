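"""Seeded parametric thoracic CT phantoms with ground-truth organ labels.

Each phantom is an axial stack that reproduces the topology and contrast
statistics a thoracic-OAR segmenter relies on, not patient-realistic
anatomy: a soft-tissue body ellipse in air, two lateral lung fields, a
central-anterior heart, a posterior vertebral ring enclosing the spinal
cord, an air-filled trachea in the mediastinum, and a small esophagus
adjacent to the trachea that drifts toward the image left below the carina
and whose lumen is air-filled over a sampled fraction of its cross-section.

Organs are analytic ellipses/annuli with per-slice centre jitter. All HU
means are configuration, not constants, so tests can stress low-contrast
regimes. Row/column image convention: rows grow posteriorly (downward),
patient left is image right; "drifts left" therefore means decreasing
column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GenerationError
from .preprocess import assemble_labels
from .volume_io import CTVolume, LabelVolume, DEFAULT_LABEL_TABLE, write_volume, write_labelmap

__all__ = ["PhantomConfig", "PhantomSample", "generate_patient", "generate_cohort",
           "write_cohort", "validate_sample"]

#: Default mean HU per structure (standard tissue ranges; esophageal wall is
#: mildly contrast-enhanced, ~1 noise-sd above mediastinal soft tissue).
DEFAULT_HU = {
    "air": -1000.0,
    "body": 40.0,
    "lung": -750.0,
    "bone": 700.0,
    "cord": 45.0,
    "heart": 70.0,
    "trachea_lumen": -950.0,
    "esophagus_wall": 55.0,
    "esophagus_lumen": -950.0,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Sampling ranges and grid geometry for one phantom cohort.

    Ranges are (low, high) tuples sampled once per patient; point values are
    expressed as degenerate ranges. ``carina_slice`` is the slice index below
    which the esophagus starts drifting left.
    """

    image_size: int = 256
    n_slices: int = 24
    spacing: tuple[float, float, float] = (5.0, 1.5, 1.5)
    carina_slice: int = 8
    trachea_radius_mm: tuple[float, float] = (6.0, 9.0)
    esophagus_radius_mm: tuple[float, float] = (3.5, 6.0)
    esophagus_air_fraction: tuple[float, float] = (0.0, 0.8)
    esophagus_trachea_gap_mm: tuple[float, float] = (2.0, 6.0)
    esophagus_drift_mm_per_slice: tuple[float, float] = (0.6, 1.2)
    esophagus_drift_cap_mm: float = 15.0
    slice_jitter_sd_mm: float = 0.7
    noise_sd_hu: float = 15.0
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.carina_slice < self.n_slices):
            raise GenerationError("carina_slice must lie inside the slice range")
        for name in ("trachea_radius_mm", "esophagus_radius_mm", "esophagus_air_fraction",
                     "esophagus_trachea_gap_mm", "esophagus_drift_mm_per_slice"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise GenerationError(f"{name} range inverted: ({lo}, {hi})")


@dataclass
class PhantomSample:
    """One synthetic patient: CT in HU, exclusive labels, and the sampled
    ground-truth geometry (per-patient scalars + per-slice centres)."""

    ct: CTVolume
    labels: LabelVolume
    truth_params: dict


def _sample(rng, lohi):
    lo, hi = lohi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _ellipse(grid_r, grid_c, center, semi) -> np.ndarray:
    """Boolean ellipse mask on a (rows, cols) pixel grid; centre/semi in px."""
    return ((grid_r - center[0]) / semi[0]) ** 2 + ((grid_c - center[1]) / semi[1]) ** 2 <= 1.0


def _largest_cc(mask2d: np.ndarray) -> np.ndarray:
    """Largest 4-connected component of a 2D mask (empty stays empty)."""
    lab, n = ndimage.label(mask2d, structure=ndimage.generate_binary_structure(2, 1))
    if n <= 1:
        return mask2d
    sizes = ndimage.sum_labels(mask2d, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def generate_patient(cfg: PhantomConfig, patient_seed: int) -> PhantomSample:
    """Deterministically generate one phantom from ``(cfg, patient_seed)``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(patient_seed)]))
    S, Z = cfg.image_size, cfg.n_slices
    dz, dy, dx = cfg.spacing
    px = np.array([dy, dx])  # mm per pixel, (row, col)

    # per-patient geometry, in pixels unless noted
    jit = lambda mm: rng.normal(0.0, mm, 2) / px  # noqa: E731 — mm-scaled (row,col) jitter
    body_c = np.array([0.52 * S, 0.50 * S]) + jit(2.0)
    body_s = np.array([0.40 * S, 0.44 * S]) * rng.uniform(0.94, 1.03, 2)
    lung_s = np.array([0.26 * S, 0.155 * S]) * rng.uniform(0.92, 1.05, 2)
    lung_row = 0.48 * S + jit(2.0)[0]
    lung_dc = 0.22 * S * rng.uniform(0.95, 1.05)
    heart_c = np.array([0.40 * S, 0.60 * S]) + jit(2.5)
    heart_s = np.array([0.13 * S, 0.13 * S]) * rng.uniform(0.9, 1.1, 2)
    ring_c = np.array([0.74 * S, 0.50 * S]) + jit(1.5)
    ring_r_out, ring_r_in = 14.0, 7.0  # mm
    cord_r = 4.5  # mm
    trach_c0 = np.array([0.58 * S, 0.50 * S]) + jit(1.5)
    r_t = _sample(rng, cfg.trachea_radius_mm)
    r_e = _sample(rng, cfg.esophagus_radius_mm)
    gap = _sample(rng, cfg.esophagus_trachea_gap_mm)
    air_frac = _sample(rng, cfg.esophagus_air_fraction)
    drift_rate = _sample(rng, cfg.esophagus_drift_mm_per_slice)

    grid_r, grid_c = np.mgrid[0:S, 0:S].astype(np.float64)
    organs = ("left_lung", "right_lung", "heart", "cord", "trachea", "esophagus")
    masks = {k: np.zeros((Z, S, S), dtype=bool) for k in organs}
    ct = np.full((Z, S, S), cfg.hu["air"], dtype=np.float32)
    centers = {"trachea": [], "esophagus": []}

    for z in range(Z):
        sj = lambda mm=cfg.slice_jitter_sd_mm: rng.normal(0.0, mm, 2) / px  # noqa: E731

        bc = body_c + sj(0.3)
        body = _ellipse(grid_r, grid_c, bc, body_s)
        # chest wall: organs are clipped to an inner ellipse 6 mm inside the body
        inner = _ellipse(grid_r, grid_c, bc, body_s - 6.0 / px)
        # patient left = image right (larger columns)
        llung = _ellipse(grid_r, grid_c, [lung_row, 0.5 * S + lung_dc] + sj(), lung_s) & inner
        rlung = _ellipse(grid_r, grid_c, [lung_row, 0.5 * S - lung_dc] + sj(), lung_s) & inner
        heart = _ellipse(grid_r, grid_c, heart_c + sj(), heart_s) & inner
        # cardiac notch: heart claims the overlap; slivers the bite detaches
        # revert to mediastinal soft tissue via largest-component selection
        llung = _largest_cc(llung & ~heart)
        rlung = _largest_cc(rlung & ~heart)
        rc = ring_c + sj(0.4)
        ring = _ellipse(grid_r, grid_c, rc, np.array([ring_r_out] * 2) / px)
        canal = _ellipse(grid_r, grid_c, rc, np.array([ring_r_in] * 2) / px)
        cord = _ellipse(grid_r, grid_c, rc + sj(0.4), np.array([cord_r] * 2) / px)
        bone = ring & ~canal
        cord &= canal

        tc = trach_c0 + sj()
        trachea = _ellipse(grid_r, grid_c, tc, np.array([r_t] * 2) / px)
        drift = 0.0 if z < cfg.carina_slice else min(
            drift_rate * (z - cfg.carina_slice + 1), cfg.esophagus_drift_cap_mm)
        ec = tc + np.array([(r_t + gap + r_e) / dy, -drift / dx]) + sj(0.4)
        esoph = _ellipse(grid_r, grid_c, ec, np.array([r_e] * 2) / px)
        r_lumen = r_e * np.sqrt(air_frac)
        lumen = _ellipse(grid_r, grid_c, ec, np.array([max(r_lumen, 1e-6)] * 2) / px) \
            if r_lumen > 0 else np.zeros_like(esoph)

        for m in (llung, rlung, heart, bone, cord, trachea, esoph):
            if not (m <= body).all():
                raise GenerationError(f"slice {z}: an organ leaves the body outline")
        if (trachea & esoph).any() or ((trachea | esoph) & (llung | rlung | ring | heart)).any():
            raise GenerationError(f"slice {z}: mediastinal air-column placement collides with a neighbour")

        img = ct[z]
        img[body] = cfg.hu["body"]
        img[llung | rlung] = cfg.hu["lung"]
        img[bone] = cfg.hu["bone"]
        img[cord] = cfg.hu["cord"]
        img[heart] = cfg.hu["heart"]
        img[trachea] = cfg.hu["trachea_lumen"]
        img[esoph] = cfg.hu["esophagus_wall"]
        img[lumen & esoph] = cfg.hu["esophagus_lumen"]

        masks["left_lung"][z], masks["right_lung"][z] = llung, rlung
        masks["heart"][z], masks["cord"][z] = heart, cord
        masks["trachea"][z], masks["esophagus"][z] = trachea, esoph
        centers["trachea"].append(tc.tolist())
        centers["esophagus"].append(ec.tolist())

    if cfg.noise_sd_hu > 0:
        ct += rng.normal(0.0, cfg.noise_sd_hu, ct.shape).astype(np.float32)

    labels = assemble_labels(masks, DEFAULT_LABEL_TABLE, spacing=cfg.spacing)
    truth = {
        "trachea_radius_mm": r_t, "esophagus_radius_mm": r_e,
        "esophagus_trachea_gap_mm": gap, "esophagus_air_fraction": air_frac,
        "esophagus_drift_mm_per_slice": drift_rate, "centers_px": centers,
        "patient_seed": int(patient_seed),
    }
    return PhantomSample(ct=CTVolume(ct, spacing=cfg.spacing, intensity_space="HU"),
                         labels=labels, truth_params=truth)


def generate_cohort(cfg: PhantomConfig, n_patients: int, seed: int) -> list[PhantomSample]:
    """Generate ``n_patients`` phantoms; patient seeds derive from ``seed``."""
    if n_patients < 1:
        raise GenerationError("n_patients must be >= 1")
    base = replace(cfg, seed=seed)
    return [generate_patient(base, i) for i in range(n_patients)]


def write_cohort(cfg: PhantomConfig, splits: dict[str, int], seed: int, out_dir) -> dict[str, list[str]]:
    """Generate and lay out a dataset directory with disjoint splits.

    Layout: ``<out_dir>/<split>/<patient_id>/{ct.nii.gz, labels.nii.gz}``.
    Patient ids are globally unique, so no patient appears in two splits.
    Returns the patient ids per split.
    """
    import os

    base = replace(cfg, seed=seed)
    ids: dict[str, list[str]] = {}
    i = 0
    for split, count in splits.items():
        ids[split] = []
        for _ in range(count):
            sample = generate_patient(base, i)
            pid = f"p{i:03d}"
            pdir = os.path.join(os.fspath(out_dir), split, pid)
            os.makedirs(pdir, exist_ok=True)
            write_volume(sample.ct, os.path.join(pdir, "ct.nii.gz"))
            write_labelmap(sample.labels, os.path.join(pdir, "labels.nii.gz"))
            ids[split].append(pid)
            i += 1
    return ids


# ---------------------------------------------------------------------------
# Anatomical contract checker
# ---------------------------------------------------------------------------

_STRUCT_2D = ndimage.generate_binary_structure(2, 1)


def validate_sample(sample: PhantomSample, cfg: Optional[PhantomConfig] = None) -> list[str]:
    """Check the anatomical contract; return a list of violations (empty = ok).

    Checks: mutual exclusivity (guaranteed by the integer label field, so
    checked as per-organ mask presence), one connected component per organ
    per slice, lungs lateral of the midline, trachea anterior of the cord,
    esophagus adjacent to the trachea and strictly left of it below the
    carina.
    """
    cfg = cfg or PhantomConfig()
    lv = sample.labels
    S = lv.shape[1]
    problems: list[str] = []
    table = lv.label_table

    for organ in table:
        m = lv.mask(organ)
        for z in range(lv.shape[0]):
            if m[z].any():
                n = ndimage.label(m[z], structure=_STRUCT_2D)[1]
                if n != 1:
                    problems.append(f"{organ} slice {z}: {n} connected components")

    def centroid_col(mask2d):
        return float(np.argwhere(mask2d)[:, 1].mean())

    def centroid_row(mask2d):
        return float(np.argwhere(mask2d)[:, 0].mean())

    for z in range(lv.shape[0]):
        ll, rl = lv.mask("left_lung")[z], lv.mask("right_lung")[z]
        tr, es = lv.mask("trachea")[z], lv.mask("esophagus")[z]
        cd = lv.mask("cord")[z]
        if not (ll.any() and rl.any() and tr.any() and es.any() and cd.any()):
            problems.append(f"slice {z}: an expected organ is absent")
            continue
        if not (centroid_col(rl) < 0.5 * S < centroid_col(ll)):
            problems.append(f"slice {z}: lungs not lateral of midline")
        if not centroid_row(tr) < centroid_row(cd):
            problems.append(f"slice {z}: trachea not anterior of cord")
        if (tr & es).any():
            problems.append(f"slice {z}: trachea and esophagus overlap")
        if z >= cfg.carina_slice and not centroid_col(es) < centroid_col(tr):
            problems.append(f"slice {z}: esophagus not left of trachea below carina")
        # adjacency: edge-to-edge gap bounded by sampled gap + lateral drift
        dt = ndimage.distance_transform_edt(~tr, sampling=cfg.spacing[1:])
        edge_gap = float(dt[es].min())
        if not 0.0 < edge_gap <= cfg.esophagus_trachea_gap_mm[1] + cfg.esophagus_drift_cap_mm:
            problems.append(f"slice {z}: esophagus-trachea gap {edge_gap:.1f} mm out of contract")
    return problems
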