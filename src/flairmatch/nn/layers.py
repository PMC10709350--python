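"""Neural-network layers with explicit forward/backward passes.

Everything runs in float32 NumPy.  Layers cache what their backward pass
needs; ``Sequential`` chains them and exposes a flat, dot-separated parameter
namespace (``stage1.conv.w``) used for checkpoints and encoder transfer.

The equivariant layers (:class:`LiftingConv3d`, :class:`GroupConv3d`) realize
D4h group convolutions: base kernels are stored once and expanded at forward
time by applying each group element's voxel permutation (plus, for group
layers, the matching permutation of the input-orientation axis).  Because the
expansion is an exact permutation, layer equivariance holds to floating-point
accuracy, and the parameter count equals that of a plain convolution on the
unfolded channels.
"""

from __future__ import annotations

import numpy as np

from ..groups import ORDER, CayleyTable, act_on_volume, build_group
from .functional import (
    _check_kernel,
    correlate3d,
    correlate3d_grad_w,
    correlate3d_grad_x,
)


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict[str, Parameter]:
        return {}

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    """Plain 3D convolution ("same" padding, odd kernel)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int, int] = (3, 3, 3),
                 bias: bool = True, rng: np.random.Generator | None = None):
        _check_kernel(tuple(kernel_size))
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = tuple(kernel_size)
        fan_in = in_channels * int(np.prod(kernel_size))
        self.w = Parameter(_he_init(rng, (out_channels, in_channels, *kernel_size), fan_in))
        self.b = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._x: np.ndarray | None = None

    def parameters(self):
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def forward(self, x, train=False):
        self._x = x
        y = correlate3d(x, self.w.value)
        if self.b is not None:
            y += self.b.value[None, :, None, None, None]
        return y

    def backward(self, gy):
        self.w.grad += correlate3d_grad_w(self._x, gy, self.kernel_size)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        return correlate3d_grad_x(gy, self.w.value)


def _spatial_perm_indices(table: CayleyTable, kernel_size: tuple[int, int, int]) -> np.ndarray:
    """(16, K) gather indices: act_on_volume(g, u).flat = u.flat[idx[g]]."""
    K = int(np.prod(kernel_size))
    base = np.arange(K).reshape(kernel_size)
    return np.stack([
        np.ascontiguousarray(act_on_volume(g, base)).ravel() for g in range(ORDER)
    ]).astype(np.intp)


class LiftingConv3d(Module):
    """First equivariant layer: scalar channels -> 16 orientation channels.

    One base kernel per (out, in) channel pair; orientation channel ``g`` is
    the correlation with the kernel transformed by ``g``.  Bias is shared
    across orientations (anything else breaks equivariance).
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int, int] = (3, 3, 3),
                 bias: bool = True, table: CayleyTable | None = None,
                 rng: np.random.Generator | None = None):
        kernel_size = tuple(kernel_size)
        _check_kernel(kernel_size)
        if kernel_size[0] != kernel_size[1]:
            raise ValueError("kernel in-plane extent must be square for exact rotation")
        rng = rng or np.random.default_rng()
        self.table = table or build_group()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * int(np.prod(kernel_size))
        self.w = Parameter(_he_init(rng, (out_channels, in_channels, *kernel_size), fan_in))
        self.b = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._sp = _spatial_perm_indices(self.table, kernel_size)
        self._sp_inv = np.argsort(self._sp, axis=1)
        self._x: np.ndarray | None = None

    def parameters(self):
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def _expand(self) -> np.ndarray:
        co, ci = self.out_channels, self.in_channels
        K = int(np.prod(self.kernel_size))
        wf = self.w.value.reshape(co, ci, K)
        wexp = wf[:, :, self._sp]                    # (co, ci, 16, K)
        return np.ascontiguousarray(wexp.transpose(0, 2, 1, 3)).reshape(
            co * ORDER, ci, *self.kernel_size)

    def _fold(self, gexp: np.ndarray) -> np.ndarray:
        co, ci = self.out_channels, self.in_channels
        K = int(np.prod(self.kernel_size))
        g = gexp.reshape(co, ORDER, ci, K)
        out = np.zeros((co, ci, K), dtype=np.float32)
        for o in range(ORDER):
            out += g[:, o][:, :, self._sp_inv[o]]
        return out.reshape(self.w.value.shape)

    def forward(self, x, train=False):
        self._x = x
        self._wexp = self._expand()
        y = correlate3d(x, self._wexp)
        if self.b is not None:
            b = np.repeat(self.b.value, ORDER)
            y += b[None, :, None, None, None]
        return y

    def backward(self, gy):
        gexp = correlate3d_grad_w(self._x, gy, self.kernel_size)
        self.w.grad += self._fold(gexp)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3, 4)).reshape(self.out_channels, ORDER).sum(axis=1)
        return correlate3d_grad_x(gy, self._wexp)


class GroupConv3d(Module):
    """Equivariant layer on orientation-indexed features.

    Input/output layout folds orientation into channels: ``(N, C*16, X, Y, Z)``
    with channel index ``c*16 + o``.  For output orientation ``g`` the base
    kernel is spatially transformed by ``g`` and its input-orientation axis is
    permuted by ``h -> g^-1 h`` (the group correlation).
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int, int] = (3, 3, 3),
                 bias: bool = True, table: CayleyTable | None = None,
                 rng: np.random.Generator | None = None):
        kernel_size = tuple(kernel_size)
        _check_kernel(kernel_size)
        if kernel_size[0] != kernel_size[1]:
            raise ValueError("kernel in-plane extent must be square for exact rotation")
        rng = rng or np.random.default_rng()
        self.table = table or build_group()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * ORDER * int(np.prod(kernel_size))
        self.w = Parameter(
            _he_init(rng, (out_channels, in_channels, ORDER, *kernel_size), fan_in))
        self.b = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._sp = _spatial_perm_indices(self.table, kernel_size)
        self._sp_inv = np.argsort(self._sp, axis=1)
        # orientation gather: oi[g, h] = index of g^-1 * h
        t = self.table
        self._oi = t.compose[t.inverse][:, :].astype(np.intp)
        self._oi_inv = np.argsort(self._oi, axis=1)
        self._x: np.ndarray | None = None

    def parameters(self):
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def _expand(self) -> np.ndarray:
        co, ci = self.out_channels, self.in_channels
        K = int(np.prod(self.kernel_size))
        wf = self.w.value.reshape(co, ci, ORDER, K)
        # (co, ci, g, h, K): base kernel at orientation g^-1 h, spatially moved by g
        wexp = wf[:, :, self._oi[:, :, None], self._sp[:, None, :]]
        wexp = np.ascontiguousarray(wexp.transpose(0, 2, 1, 3, 4))
        return wexp.reshape(co * ORDER, ci * ORDER, *self.kernel_size)

    def _fold(self, gexp: np.ndarray) -> np.ndarray:
        co, ci = self.out_channels, self.in_channels
        K = int(np.prod(self.kernel_size))
        g = gexp.reshape(co, ORDER, ci, ORDER, K)
        out = np.zeros((co, ci, ORDER, K), dtype=np.float32)
        for o in range(ORDER):
            out += g[:, o][:, :, self._oi_inv[o]][:, :, :, self._sp_inv[o]]
        return out.reshape(self.w.value.shape)

    def forward(self, x, train=False):
        if x.shape[1] != self.in_channels * ORDER:
            raise ValueError(
                f"expected {self.in_channels * ORDER} channels "
                f"({self.in_channels} features x {ORDER} orientations), got {x.shape[1]}")
        self._x = x
        self._wexp = self._expand()
        y = correlate3d(x, self._wexp)
        if self.b is not None:
            b = np.repeat(self.b.value, ORDER)
            y += b[None, :, None, None, None]
        return y

    def backward(self, gy):
        gexp = correlate3d_grad_w(self._x, gy, self.kernel_size)
        self.w.grad += self._fold(gexp)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3, 4)).reshape(self.out_channels, ORDER).sum(axis=1)
        return correlate3d_grad_x(gy, self._wexp)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Module):
    """max(x, slope*x); the small negative-side slope keeps gradient flowing
    through units that start (or fall) below threshold."""

    def __init__(self, slope: float = 0.1):
        self.slope = float(slope)

    def forward(self, x, train=False):
        self._scale = np.where(x > 0, np.float32(1.0), np.float32(self.slope))
        return x * self._scale

    def backward(self, gy):
        return gy * self._scale


class MaxPool3d(Module):
    """2x2x2 max pooling, stride 2; odd trailing voxels are floor-cropped."""

    def forward(self, x, train=False):
        n, c, X, Y, Z = x.shape
        if min(X, Y, Z) < 2:
            raise ValueError(f"spatial dims too small to pool: {(X, Y, Z)}")
        self._in_shape = x.shape
        xc = x[:, :, : X - X % 2, : Y - Y % 2, : Z - Z % 2]
        self._crop_shape = xc.shape
        xr = xc.reshape(n, c, xc.shape[2] // 2, 2, xc.shape[3] // 2, 2, xc.shape[4] // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        # distribute gradient equally among tied maxima
        mask = xr == y[:, :, :, None, :, None, :, None]
        self._mask = mask
        self._count = mask.sum(axis=(3, 5, 7))
        return y

    def backward(self, gy):
        g = (gy / self._count)[:, :, :, None, :, None, :, None] * self._mask
        gx = np.zeros(self._in_shape, dtype=np.float32)
        cx, cy, cz = self._crop_shape[2:]
        gx[:, :, :cx, :cy, :cz] = g.reshape(self._crop_shape)
        return gx


class AvgPool3d(Module):
    """Block average pooling by an integer factor per axis (used to bring the
    working grid down before the first convolution; block averaging commutes
    with all D4h actions when the dims divide, so equivariance is preserved)."""

    def __init__(self, factor: tuple[int, int, int]):
        self.factor = tuple(int(f) for f in factor)

    def forward(self, x, train=False):
        n, c, X, Y, Z = x.shape
        fx, fy, fz = self.factor
        if X % fx or Y % fy or Z % fz:
            raise ValueError(f"spatial dims {(X, Y, Z)} not divisible by pool factor {self.factor}")
        self._in_shape = x.shape
        xr = x.reshape(n, c, X // fx, fx, Y // fy, fy, Z // fz, fz)
        return xr.mean(axis=(3, 5, 7))

    def backward(self, gy):
        fx, fy, fz = self.factor
        scale = 1.0 / (fx * fy * fz)
        g = np.broadcast_to(
            (gy * scale)[:, :, :, None, :, None, :, None],
            gy.shape[:2] + (gy.shape[2], fx, gy.shape[3], fy, gy.shape[4], fz),
        )
        return np.ascontiguousarray(g).reshape(self._in_shape)


class OrientationPool(Module):
    """Reduce the 16 orientation channels to one per feature (max or mean).

    After this layer features transform as plain volumes: pooling over the
    whole orientation axis is invariant to the orientation permutation, so
    ``pool(act_on_oriented(g, f)) == act_on_volume(g, pool(f))`` exactly.
    """

    def __init__(self, mode: str = "max"):
        if mode not in ("max", "mean"):
            raise ValueError(f"mode must be 'max' or 'mean', got {mode!r}")
        self.mode = mode

    def forward(self, x, train=False):
        n, ctot = x.shape[:2]
        if ctot % ORDER:
            raise ValueError(f"channel count {ctot} is not a multiple of {ORDER}")
        xr = x.reshape(n, ctot // ORDER, ORDER, *x.shape[2:])
        self._in_shape = x.shape
        if self.mode == "max":
            y = xr.max(axis=2)
            mask = xr == y[:, :, None]
            self._mask = mask
            self._count = mask.sum(axis=2)
            return y
        return xr.mean(axis=2)

    def backward(self, gy):
        n, c = gy.shape[:2]
        if self.mode == "max":
            g = (gy / self._count)[:, :, None] * self._mask
        else:
            g = np.broadcast_to((gy / ORDER)[:, :, None],
                                (n, c, ORDER, *gy.shape[2:]))
        return np.ascontiguousarray(g).reshape(self._in_shape)


class GlobalAvgPool(Module):
    """Average over all spatial positions: (N, C, X, Y, Z) -> (N, C)."""

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gy):
        n, c, X, Y, Z = self._in_shape
        g = gy[:, :, None, None, None] / (X * Y * Z)
        return np.broadcast_to(g, self._in_shape).astype(np.float32).copy()


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Parameter(_he_init(rng, (out_features, in_features), in_features))
        self.b = Parameter(np.zeros(out_features, dtype=np.float32))

    def parameters(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gy):
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value


class Dropout(Module):
    """Inverted dropout; active only when ``train=True`` and a RNG is set."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without an RNG")
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class Upsample3d(Module):
    """Nearest-neighbour upsampling by an integer factor per axis."""

    def __init__(self, factor: tuple[int, int, int] | int = 2):
        if isinstance(factor, int):
            factor = (factor, factor, factor)
        self.factor = tuple(int(f) for f in factor)

    def forward(self, x, train=False):
        self._in_shape = x.shape
        fx, fy, fz = self.factor
        return x.repeat(fx, axis=2).repeat(fy, axis=3).repeat(fz, axis=4)

    def backward(self, gy):
        n, c, X, Y, Z = self._in_shape
        fx, fy, fz = self.factor
        return gy.reshape(n, c, X, fx, Y, fy, Z, fz).sum(axis=(3, 5, 7))


class CropPad(Module):
    """Crop or zero-pad trailing spatial voxels to an exact target shape."""

    def __init__(self, target: tuple[int, int, int]):
        self.target = tuple(int(t) for t in target)

    def forward(self, x, train=False):
        self._in_shape = x.shape
        n, c = x.shape[:2]
        out = np.zeros((n, c, *self.target), dtype=np.float32)
        sx, sy, sz = (min(a, b) for a, b in zip(x.shape[2:], self.target))
        out[:, :, :sx, :sy, :sz] = x[:, :, :sx, :sy, :sz]
        return out

    def backward(self, gy):
        gx = np.zeros(self._in_shape, dtype=np.float32)
        sx, sy, sz = (min(a, b) for a, b in zip(self._in_shape[2:], self.target))
        gx[:, :, :sx, :sy, :sz] = gy[:, :, :sx, :sy, :sz]
        return gx


class Sequential(Module):
    """A named chain of modules with a flat dotted parameter namespace."""

    def __init__(self, steps: list[tuple[str, Module]]):
        names = [n for n, _ in steps]
        if len(set(names)) != len(names):
            raise ValueError("duplicate step names")
        self.steps = list(steps)

    def forward(self, x, train=False):
        for _, m in self.steps:
            x = m.forward(x, train=train)
        return x

    def backward(self, gy):
        for _, m in reversed(self.steps):
            gy = m.backward(gy)
        return gy

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, m in self.steps:
            for pname, p in m.parameters().items():
                out[f"{name}.{pname}"] = p
        return out

    def __getitem__(self, name: str) -> Module:
        for n, m in self.steps:
            if n == name:
                return m
        raise KeyError(name)

    def modules(self):
        """Depth-first iteration over all leaf modules."""
        for _, m in self.steps:
            if isinstance(m, Sequential):
                yield from m.modules()
            else:
                yield m
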