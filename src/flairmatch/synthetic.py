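"""Synthetic DWI/FLAIR phantom cohorts and synthetic raters.

The clinical imaging this method was developed for cannot be shared, so the
package ships a phantom generator that reproduces the *statistical* structure
the classifier exploits, not anatomy:

* coregistered DWI/FLAIR pairs on one voxel grid;
* an acute lesion always conspicuous on DWI (contrast well above noise);
* FLAIR lesion conspicuity rising monotonically with time since onset via a
  sigmoid contrast curve centred at the 4.5 h treatment boundary — so the
  label boundary is exactly where rating is hardest, as in the clinic;
* confounders: leukoaraiosis-like periventricular FLAIR hyperintensity
  (independent of onset time), old FLAIR-bright/DWI-silent lesions, and small
  focal susceptibility-like DWI artifacts;
* an unlabeled cohort with shifted characteristics (a fraction lesion-free, a
  fraction with lesions in a different through-plane band, unknown onset
  time) for autoencoder pre-training;
* synthetic rater tables with configurable sensitivity, specificity and
  indeterminable rate, the indeterminables biased toward low-contrast cases.

Everything is reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for a phantom cohort.

    Defaults target the desk-scale grid 64x64x32 (square in-plane, divisible
    by 2^5 so exact network invariance holds end to end).  The acute-class
    fraction defaults to the labeled clinical cohort's prevalence of
    onset-to-MRI <= 4.5 h (43.35 %).
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    n_labeled: int = 60
    n_unlabeled: int = 40
    p_acute: float = 0.4335            # P(time <= 4.5 h) among labeled patients
    t_range: tuple[float, float] = (0.5, 24.0)  # hours
    t_mid: float = 4.5                 # sigmoid midpoint of FLAIR conspicuity (h)
    slope: float = 2.0                 # sigmoid scale (h)
    dwi_contrast: float = 1.2
    flair_contrast: float = 1.0
    lesion_radius_xy: tuple[float, float] = (5.0, 10.0)   # voxels
    lesion_radius_z: tuple[float, float] = (2.5, 5.0)
    leukoaraiosis_rate: float = 0.3
    old_lesion_rate: float = 0.2
    artifact_rate: float = 0.2
    frac_lesion_free: float = 0.4      # unlabeled cohort
    frac_shifted: float = 0.25         # unlabeled cohort, lesion in shifted z-band
    noise_std: float = 0.15
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_acute", "leukoaraiosis_rate", "old_lesion_rate",
                     "artifact_rate", "frac_lesion_free", "frac_shifted"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.t_mid <= 0:
            raise ValueError("t_mid must be positive")
        hi_xy = self.lesion_radius_xy[1]
        hi_z = self.lesion_radius_z[1]
        if 2 * hi_xy >= min(self.shape[:2]) or 2 * hi_z >= self.shape[2]:
            raise ValueError("lesion radii do not fit inside the grid")


@dataclass
class SyntheticCohort:
    """In-memory phantom cohort: volumes, truth, and the cohort table."""

    volumes: np.ndarray              # (N, 2, X, Y, Z) float32; channel 0 DWI, 1 FLAIR
    lesion_masks: np.ndarray         # (N, X, Y, Z) bool, acute lesion only
    table: pd.DataFrame              # patient_id, time_to_mri_h, label, cohort, ...
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def labeled_index(self) -> np.ndarray:
        return np.flatnonzero(self.table["cohort"].to_numpy() == "labeled")

    @property
    def labels(self) -> np.ndarray:
        idx = self.labeled_index
        return self.table["label"].to_numpy()[idx].astype(int)

    @property
    def labeled_volumes(self) -> np.ndarray:
        return self.volumes[self.labeled_index]


def flair_lesion_contrast(t_hours: float, cfg: PhantomConfig) -> float:
    """Expected FLAIR lesion contrast at onset-to-scan time ``t`` (monotone
    increasing sigmoid; the DWI-FLAIR mismatch signal in reverse)."""
    return float(cfg.flair_contrast * expit((t_hours - cfg.t_mid) / cfg.slope))


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _background(rng: np.random.Generator, shape) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed random-field parenchyma plus a ventricle-like central
    structure (dark on DWI, bright on FLAIR)."""
    base = gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=3.0)
    base *= 1.0 / max(base.std(), 1e-6)
    cx, cy, cz = (s / 2 for s in shape)
    vent = _ellipsoid_mask(shape, (cx, cy, cz),
                           (shape[0] / 8, shape[1] / 5, shape[2] / 4)).astype(float)
    vent = gaussian_filter(vent, sigma=1.0)
    dwi = 0.3 * base - 0.8 * vent
    flair = 0.3 * base + 0.8 * vent
    return dwi, flair


def _soft_lesion(shape, rng, z_band: tuple[float, float], cfg: PhantomConfig):
    rx = rng.uniform(*cfg.lesion_radius_xy)
    ry = rng.uniform(*cfg.lesion_radius_xy)
    rz = rng.uniform(*cfg.lesion_radius_z)
    cx = rng.uniform(rx + 1, shape[0] - rx - 1)
    cy = rng.uniform(ry + 1, shape[1] - ry - 1)
    lo = max(rz + 0.5, z_band[0] * shape[2])
    hi = min(shape[2] - rz - 0.5, z_band[1] * shape[2])
    cz = rng.uniform(lo, max(hi, lo + 1e-6))
    hard = _ellipsoid_mask(shape, (cx, cy, cz), (rx, ry, rz))
    soft = gaussian_filter(hard.astype(float), sigma=0.8)
    return hard, soft


def _confounders(rng, shape, dwi, flair, cfg: PhantomConfig) -> dict[str, bool]:
    flags = {}
    flags["leukoaraiosis"] = bool(rng.random() < cfg.leukoaraiosis_rate)
    if flags["leukoaraiosis"]:
        # blobby rim of FLAIR hyperintensity around the ventricle region
        cx, cy, cz = (s / 2 for s in shape)
        outer = _ellipsoid_mask(shape, (cx, cy, cz),
                                (shape[0] / 5.5, shape[1] / 3.8, shape[2] / 3.2))
        inner = _ellipsoid_mask(shape, (cx, cy, cz),
                                (shape[0] / 8, shape[1] / 5, shape[2] / 4))
        rim = (outer & ~inner).astype(float)
        rim *= gaussian_filter(rng.random(shape), 2.0) > 0.5
        flair += 0.6 * gaussian_filter(rim, sigma=1.0)
    flags["old_lesion"] = bool(rng.random() < cfg.old_lesion_rate)
    if flags["old_lesion"]:
        _, soft = _soft_lesion(shape, rng, (0.1, 0.9), cfg)
        flair += 0.8 * soft     # FLAIR-bright, DWI-silent: not an acute lesion
    flags["artifact"] = bool(rng.random() < cfg.artifact_rate)
    if flags["artifact"]:
        c = tuple(rng.uniform(3, s - 3) for s in shape)
        spot = gaussian_filter(_ellipsoid_mask(shape, c, (2.0, 2.0, 1.5)).astype(float), 0.8)
        dwi += 2.0 * spot       # susceptibility-like focal DWI hyperintensity
    return flags


def generate_cohort(cfg: PhantomConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate the labeled + unlabeled phantom cohort.

    With ``out_dir`` set, writes per-patient NIfTI volumes (DWI, FLAIR, acute
    lesion mask) plus ``cohort.csv`` in the layout the preprocessing module
    consumes; otherwise everything stays in memory.
    """
    shape = tuple(cfg.shape)
    n = cfg.n_labeled + cfg.n_unlabeled
    ss = np.random.SeedSequence(cfg.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    patient_rngs = [np.random.default_rng(s) for s in ss.spawn(n + 1)[1:]]

    volumes = np.empty((n, 2, *shape), dtype=np.float32)
    masks = np.zeros((n, *shape), dtype=bool)
    rows = []
    for i in range(n):
        rng = patient_rngs[i]
        labeled = i < cfg.n_labeled
        dwi, flair = _background(rng, shape)
        t = np.nan
        contrast = 0.0
        has_lesion = True
        z_band = (0.25, 0.75)
        if labeled:
            acute = rng.random() < cfg.p_acute
            t = rng.uniform(cfg.t_range[0], cfg.t_mid) if acute \
                else rng.uniform(cfg.t_mid, cfg.t_range[1])
        else:
            u = rng.random()
            if u < cfg.frac_lesion_free:
                has_lesion = False
            elif u < cfg.frac_lesion_free + cfg.frac_shifted:
                z_band = (0.0, 0.2) if rng.random() < 0.5 else (0.8, 1.0)
            # hidden onset time drives FLAIR conspicuity but is not recorded
            t_hidden = rng.uniform(*cfg.t_range)
        if has_lesion:
            t_eff = t if labeled else t_hidden
            hard, soft = _soft_lesion(shape, rng, z_band, cfg)
            contrast = flair_lesion_contrast(t_eff, cfg)
            dwi += cfg.dwi_contrast * soft
            flair += contrast * soft
            masks[i] = hard
        flags = _confounders(rng, shape, dwi, flair, cfg)
        dwi += rng.normal(0.0, cfg.noise_std, size=shape)
        flair += rng.normal(0.0, cfg.noise_std, size=shape)
        volumes[i, 0] = dwi
        volumes[i, 1] = flair
        rows.append({
            "patient_id": f"p{i:04d}",
            "time_to_mri_h": round(t, 4) if np.isfinite(t) else np.nan,
            "label": int(t <= cfg.t_mid) if np.isfinite(t) else pd.NA,
            "cohort": "labeled" if labeled else "unlabeled",
            "has_lesion": has_lesion,
            "flair_lesion_contrast": round(contrast, 6),
            **flags,
        })
    table = pd.DataFrame(rows)
    _ = master  # reserved for cohort-level draws

    cohort = SyntheticCohort(volumes=volumes, lesion_masks=masks, table=table, config=cfg)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(cohort.config.spacing) + [1.0])
    dwi_paths, flair_paths, mask_paths = [], [], []
    for i, pid in enumerate(cohort.table["patient_id"]):
        for suffix, arr, paths in (
            ("dwi", cohort.volumes[i, 0], dwi_paths),
            ("flair", cohort.volumes[i, 1], flair_paths),
            ("lesion", cohort.lesion_masks[i].astype(np.uint8), mask_paths),
        ):
            p = out_dir / f"{pid}_{suffix}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(arr), affine), p)
            paths.append(str(p))
    table = cohort.table.copy()
    table["dwi_path"] = dwi_paths
    table["flair_path"] = flair_paths
    table["lesion_mask_path"] = mask_paths
    table.to_csv(out_dir / "cohort.csv", index=False)
    cohort.table = table


@dataclass(frozen=True)
class RaterModel:
    """A synthetic human rater for the mismatch task."""

    sensitivity: float = 0.62
    specificity: float = 0.78
    indeterminable_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "indeterminable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


RATING_CATEGORIES = ("mismatch", "no_mismatch", "indeterminable")


def generate_raters(labels: np.ndarray, flair_contrasts: np.ndarray,
                    model: RaterModel, patient_ids=None,
                    rater_id: str = "rater1") -> pd.DataFrame:
    """Simulate one rater's categorical calls against the true labels.

    A fraction ``indeterminable_rate`` of patients (sampled with weight
    inversely related to FLAIR lesion contrast, i.e. the genuinely ambiguous
    cases) is rated indeterminable; the rest are rated mismatch/no-mismatch
    with the configured sensitivity and specificity.
    """
    labels = np.asarray(labels).astype(int)
    contrasts = np.asarray(flair_contrasts, dtype=float)
    n = labels.size
    if contrasts.size != n:
        raise ValueError("labels and flair_contrasts must align")
    if patient_ids is None:
        patient_ids = [f"p{i:04d}" for i in range(n)]
    rng = np.random.default_rng(model.seed)

    k = int(round(model.indeterminable_rate * n))
    indet = np.zeros(n, dtype=bool)
    if k > 0:
        w = 1.0 / (0.05 + np.abs(contrasts))
        w /= w.sum()
        indet[rng.choice(n, size=k, replace=False, p=w)] = True

    u = rng.random(n)
    rating = np.where(labels == 1,
                      np.where(u < model.sensitivity, "mismatch", "no_mismatch"),
                      np.where(u < model.specificity, "no_mismatch", "mismatch"))
    rating = np.where(indet, "indeterminable", rating)
    return pd.DataFrame({"patient_id": patient_ids, "rater_id": rater_id,
                         "rating": rating})
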