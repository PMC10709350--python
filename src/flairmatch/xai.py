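"""SmoothGrad saliency volumes, universal-threshold heatmaps, and an
automated localization score.

SmoothGrad averages the absolute input-gradient of the model's output over
noise-perturbed copies of the input.  The gradient is taken at the
pre-sigmoid logit, not the probability, so saliency does not vanish for
confidently classified cases.  Noise is Gaussian with standard deviation
``sigma`` times the input intensity range, following common practice.

Heatmaps are per-channel max-normalized to [0, 1] before a single universal
threshold is applied, so masks are comparable across patients.  Localization
against a known lesion mask is quantified as lesion coverage and Dice, with a
"well-localized" flag when the saliency mask covers more than half of the
lesion on the DWI channel and on the same region in the FLAIR channel — an
automated surrogate for visual heatmap rating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SaliencyVolume:
    """Non-negative per-channel attribution map with its smoothing settings."""

    values: np.ndarray          # (2, X, Y, Z), >= 0
    n: int
    sigma: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("saliency values must be non-negative")


def _input_gradient(net, x: np.ndarray) -> np.ndarray:
    """d logit / d input for a single input (1, 2, X, Y, Z)."""
    from .model import AERegNet

    if isinstance(net, AERegNet):
        logit, recon = net.forward(x, train=False)
        g = net.backward(np.ones(1, dtype=np.float32),
                         np.zeros_like(recon))
    else:
        net.forward(x, train=False)
        g = net.backward(np.ones(1, dtype=np.float32))
    if not np.all(np.isfinite(g)):
        raise RuntimeError("non-finite input gradients; check weights and input scaling")
    return g[0]


def smoothgrad(net, pair: np.ndarray, n: int = 25, sigma: float = 0.1,
               seed: int = 0) -> SaliencyVolume:
    """SmoothGrad attribution of the classification logit.

    ``pair`` is a 2-channel volume (2, X, Y, Z).  ``sigma`` scales the
    Gaussian noise by the input intensity range; ``sigma=0, n=1`` reduces
    exactly to the plain absolute gradient.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1 gradient samples")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = np.asarray(pair, dtype=np.float32)[None]
    if sigma == 0.0:
        acc = np.abs(_input_gradient(net, x))
        for _ in range(n - 1):
            acc += np.abs(_input_gradient(net, x))
    else:
        rng = np.random.default_rng(seed)
        noise_std = sigma * float(x.max() - x.min())
        acc = np.zeros_like(x[0])
        for _ in range(n):
            xn = x + rng.normal(0.0, noise_std, size=x.shape).astype(np.float32)
            acc += np.abs(_input_gradient(net, xn))
    return SaliencyVolume(values=acc / n, n=n, sigma=sigma)


def threshold_heatmap(sal: SaliencyVolume | np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask: per-channel max-normalized saliency >= threshold.

    The same ("universal") threshold is meant to be reused across patients.
    """
    v = sal.values if isinstance(sal, SaliencyVolume) else np.asarray(sal)
    peak = v.reshape(v.shape[0], -1).max(axis=1)
    peak = np.where(peak > 0, peak, 1.0)
    norm = v / peak[:, None, None, None]
    return norm >= threshold


@dataclass(frozen=True)
class LocalizationReport:
    """Lesion coverage and Dice of the saliency mask, per input channel."""

    coverage_dwi: float
    coverage_flair: float
    dice_dwi: float
    dice_flair: float
    well_localized: bool


def _coverage_dice(mask: np.ndarray, lesion: np.ndarray) -> tuple[float, float]:
    inter = np.count_nonzero(mask & lesion)
    nl = np.count_nonzero(lesion)
    nm = np.count_nonzero(mask)
    coverage = inter / nl if nl else float("nan")
    dice = 2.0 * inter / (nl + nm) if (nl + nm) else float("nan")
    return coverage, dice


def localization_score(mask_dwi: np.ndarray, mask_flair: np.ndarray,
                       lesion_mask: np.ndarray,
                       min_coverage: float = 0.5) -> LocalizationReport:
    """Score how well thresholded saliency covers the true lesion.

    ``well_localized`` requires coverage > ``min_coverage`` on the DWI channel
    and on the same lesion region in the FLAIR channel.
    """
    if mask_dwi.shape != lesion_mask.shape or mask_flair.shape != lesion_mask.shape:
        raise ValueError("masks must share one grid")
    cov_d, dice_d = _coverage_dice(mask_dwi.astype(bool), lesion_mask.astype(bool))
    cov_f, dice_f = _coverage_dice(mask_flair.astype(bool), lesion_mask.astype(bool))
    return LocalizationReport(
        coverage_dwi=cov_d, coverage_flair=cov_f,
        dice_dwi=dice_d, dice_flair=dice_f,
        well_localized=bool(cov_d > min_coverage and cov_f > min_coverage),
    )


def save_saliency_nifti(sal: SaliencyVolume, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write the 2-channel saliency volume as two NIfTI files
    (``*_dwi.nii.gz``, ``*_flair.nii.gz``) aligned to the input grid."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    base = str(path)
    for c, name in enumerate(("dwi", "flair")):
        nib.save(nib.Nifti1Image(sal.values[c].astype(np.float32), affine),
                 f"{base}_{name}.nii.gz")
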