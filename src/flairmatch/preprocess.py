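"""NIfTI IO, coregistration/resampling, grid resizing, and intensity
standardization.

The pipeline mirrors minimal clinical post-processing: images stay "raw" (no
skull stripping or bias correction); FLAIR is resampled onto the DWI grid;
both are resized to a common working grid (192x192x50 at clinical scale);
voxel intensities are standardized to zero mean, unit variance using
statistics of the *training set only*, which are then applied unchanged to
validation and test data (no leakage by construction: ``apply_standardizer``
takes explicit stats).

Standardization is per modality channel by default — DWI and FLAIR live on
different intensity scales and a joint z-score would let one modality
dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates, zoom


@dataclass
class VolumePair:
    """Coregistered DWI+FLAIR arrays with grid metadata."""

    dwi: np.ndarray
    flair: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""
    dwi_affine: np.ndarray | None = None
    flair_affine: np.ndarray | None = None

    @property
    def stacked(self) -> np.ndarray:
        """(2, X, Y, Z) float32 network input (DWI channel 0, FLAIR 1)."""
        return np.stack([self.dwi, self.flair]).astype(np.float32)


@dataclass(frozen=True)
class StandardizationStats:
    """Per-channel mean/std fitted on the training set."""

    mean: np.ndarray  # (2,)
    std: np.ndarray   # (2,)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std) <= 0):
            raise ValueError("standard deviation must be positive")


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"unreadable NIfTI header: {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, spacing


def load_pair(dwi_path, flair_path, patient_id: str = "") -> VolumePair:
    """Load a DWI/FLAIR pair; grids may differ (resampling is a later stage)."""
    dwi, dwi_aff, spacing = _load_nifti(dwi_path)
    flair, flair_aff, _ = _load_nifti(flair_path)
    return VolumePair(dwi=dwi, flair=flair, spacing=spacing,
                      patient_id=patient_id, dwi_affine=dwi_aff, flair_affine=flair_aff)


def coregister_resample(pair: VolumePair, backend: str = "identity") -> VolumePair:
    """Bring FLAIR onto the DWI voxel grid.

    ``identity`` asserts the grids already match (synthetic phantoms are
    generated coregistered).  ``rigid-resample`` maps DWI voxel coordinates
    through both NIfTI affines and trilinearly interpolates FLAIR — a
    resampling backend, not a registration optimizer; deformable registration
    is deliberately out of scope and pluggable.
    """
    if backend == "identity":
        if pair.dwi.shape != pair.flair.shape:
            raise ValueError(
                f"identity backend requires matching grids, got DWI {pair.dwi.shape} "
                f"vs FLAIR {pair.flair.shape}")
        return pair
    if backend != "rigid-resample":
        raise ValueError(f"unknown backend {backend!r}")
    if pair.dwi_affine is None or pair.flair_affine is None:
        raise ValueError("rigid-resample requires affines from load_pair")
    # FLAIR voxel coords of every DWI voxel: inv(A_flair) @ A_dwi @ ijk
    shape = pair.dwi.shape
    ijk = np.indices(shape, dtype=np.float64).reshape(3, -1)
    ijk1 = np.vstack([ijk, np.ones((1, ijk.shape[1]))])
    m = np.linalg.inv(pair.flair_affine) @ pair.dwi_affine
    src = (m @ ijk1)[:3]
    flair = map_coordinates(pair.flair.astype(np.float64), src, order=1,
                            mode="constant", cval=0.0).reshape(shape)
    return replace(pair, flair=flair.astype(np.float32),
                   flair_affine=pair.dwi_affine.copy())


def resize_to_grid(pair: VolumePair, target: tuple[int, int, int] = (192, 192, 50)) -> VolumePair:
    """Trilinearly resize both channels to the working grid."""
    if pair.dwi.shape != pair.flair.shape:
        raise ValueError("resize expects a coregistered pair (matching grids)")
    if tuple(pair.dwi.shape) == tuple(target):
        return pair
    factors = [t / s for t, s in zip(target, pair.dwi.shape)]
    dwi = zoom(pair.dwi, factors, order=1)
    flair = zoom(pair.flair, factors, order=1)
    spacing = tuple(sp / f for sp, f in zip(pair.spacing, factors))
    return replace(pair, dwi=dwi.astype(np.float32), flair=flair.astype(np.float32),
                   spacing=spacing)


def fit_standardizer(pairs, per_channel: bool = True) -> StandardizationStats:
    """Fit per-channel (default) or joint mean/std on training pairs only."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one training pair")
    stacks = np.stack([p.stacked if isinstance(p, VolumePair) else np.asarray(p)
                       for p in pairs])  # (N, 2, X, Y, Z)
    if per_channel:
        mean = stacks.mean(axis=(0, 2, 3, 4))
        std = stacks.std(axis=(0, 2, 3, 4))
    else:
        mean = np.full(2, stacks.mean())
        std = np.full(2, stacks.std())
    if np.any(std <= 1e-12):
        raise ValueError("zero-variance training data; cannot standardize")
    return StandardizationStats(mean=mean.astype(np.float64), std=std.astype(np.float64))


def apply_standardizer(pair, stats: StandardizationStats):
    """Standardize with explicit (training) stats; works on a
    :class:`VolumePair` or an ``(N, 2, X, Y, Z)`` array."""
    if isinstance(pair, VolumePair):
        return replace(pair,
                       dwi=((pair.dwi - stats.mean[0]) / stats.std[0]).astype(np.float32),
                       flair=((pair.flair - stats.mean[1]) / stats.std[1]).astype(np.float32))
    arr = np.asarray(pair, dtype=np.float32)
    return ((arr - stats.mean.reshape(1, 2, 1, 1, 1))
            / stats.std.reshape(1, 2, 1, 1, 1)).astype(np.float32)


class VolumeStandardizer:
    """sklearn-style transformer over ``(N, 2, X, Y, Z)`` arrays.

    ``fit`` learns training-set statistics; ``transform`` applies them to any
    split, so validation/test data never influence the scaling.
    """

    def __init__(self, per_channel: bool = True):
        self.per_channel = per_channel

    def fit(self, X, y=None):
        self.stats_ = fit_standardizer(list(np.asarray(X)), per_channel=self.per_channel)
        return self

    def transform(self, X):
        if not hasattr(self, "stats_"):
            raise RuntimeError("VolumeStandardizer is not fitted")
        return apply_standardizer(np.asarray(X), self.stats_)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"per_channel": self.per_channel}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def load_cohort_csv(csv_path, backend: str = "identity",
                    target: tuple[int, int, int] | None = None):
    """Read a cohort table (patient_id, dwi_path, flair_path, time_to_mri_h,
    cohort) and return (volumes, table) with all pairs coregistered and on a
    common grid."""
    import pandas as pd

    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    required = {"patient_id", "dwi_path", "flair_path", "cohort"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    vols = []
    for row in table.itertuples():
        pair = load_pair(row.dwi_path, row.flair_path, patient_id=str(row.patient_id))
        pair = coregister_resample(pair, backend=backend)
        if target is not None:
            pair = resize_to_grid(pair, target)
        vols.append(pair.stacked)
    return np.stack(vols), table
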