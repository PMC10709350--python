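"""Low-level 3D correlation with "same" zero padding, plus its gradients.

The implementation extracts sliding windows (a strided view, no copy) and
contracts them against the kernel with ``np.tensordot`` so the inner loop is a
single BLAS matrix multiply.  Kernels must have odd extents so the rotation
center and the padding are well defined — a requirement the equivariant layers
rely on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _check_kernel(shape: tuple[int, int, int]) -> None:
    if any(k % 2 == 0 for k in shape):
        raise ValueError(
            f"kernel extents must be odd for 'same' padding and a defined "
            f"rotation center, got {shape}"
        )


def _pad_same(x: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    px, py, pz = (k // 2 for k in kshape)
    return np.pad(x, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))


def _windows(x: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    """(N, C, X, Y, Z, kx, ky, kz) view of the zero-padded input."""
    xp = _pad_same(x, kshape)
    return sliding_window_view(xp, kshape, axis=(2, 3, 4))


def correlate3d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlate ``x (N,Ci,X,Y,Z)`` with ``w (Co,Ci,kx,ky,kz)``."""
    _check_kernel(w.shape[2:])
    win = _windows(x, w.shape[2:])
    # contract over (Ci, kx, ky, kz) -> (N, X, Y, Z, Co)
    y = np.tensordot(win, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def correlate3d_grad_w(x: np.ndarray, gy: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    """Gradient of ``correlate3d`` w.r.t. the kernel."""
    win = _windows(x, kshape)
    # dw[o,c,i,j,k] = sum_{n,xyz} gy[n,o,xyz] * win[n,c,xyz,ijk]
    return np.tensordot(gy, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))


def correlate3d_grad_x(gy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of ``correlate3d`` w.r.t. the input.

    For odd kernels with "same" padding this is a correlation of the output
    gradient with the spatially flipped, channel-transposed kernel.
    """
    w_t = np.ascontiguousarray(np.flip(w, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
    return correlate3d(gy, w_t)
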