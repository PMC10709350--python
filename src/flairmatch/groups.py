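"""The D4h point group realized as voxel-grid transforms.

Axial brain MRI is acquired as a stack of thin slices: the in-plane grid is
square and (statistically) symmetric under quarter-turn rotations and
mirroring, while the through-plane axis only supports a flip.  The symmetry
group generated by {90-degree in-plane rotation, in-plane mirror,
through-plane flip} is D4h, of order 16.  Equivariant convolution layers need
this group in three concrete forms:

* as abstract elements with a composition table (:func:`build_group`),
* as an action on scalar volumes (:func:`act_on_volume`),
* as an action on orientation-indexed feature maps (:func:`act_on_oriented`).

Conventions (fixed so serialized models are portable):

* volumes are indexed ``(x, y, z)``; rotations and the mirror act in the
  ``(x, y)`` plane, the flip acts on ``z``;
* an element is ``(r, m, z)`` with canonical index ``r + 4*m + 8*z``;
* ``compose(g, h)`` means "apply ``h`` first, then ``g``" (function
  composition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: order of the D4h group
ORDER = 16


@dataclass(frozen=True)
class GroupElement:
    """One D4h symmetry: ``r`` in-plane quarter turns, optional in-plane
    mirror ``m``, optional through-plane flip ``z``."""

    r: int
    m: int
    z: int

    def __post_init__(self) -> None:
        if self.r not in (0, 1, 2, 3):
            raise ValueError(f"quarter-turn count must be in 0..3, got {self.r}")
        if self.m not in (0, 1) or self.z not in (0, 1):
            raise ValueError("mirror and flip bits must be 0 or 1")

    @property
    def index(self) -> int:
        """Canonical index in [0, 16): ``r + 4*m + 8*z``."""
        return self.r + 4 * self.m + 8 * self.z

    @classmethod
    def from_index(cls, index: int) -> "GroupElement":
        if not 0 <= index < ORDER:
            raise ValueError(f"index must be in [0, {ORDER}), got {index}")
        return cls(r=index % 4, m=(index // 4) % 2, z=index // 8)


IDENTITY = GroupElement(0, 0, 0)
ELEMENTS: tuple[GroupElement, ...] = tuple(GroupElement.from_index(i) for i in range(ORDER))


def _as_element(g) -> GroupElement:
    if isinstance(g, GroupElement):
        return g
    if isinstance(g, (int, np.integer)):
        return GroupElement.from_index(int(g))
    raise TypeError(f"expected GroupElement or index, got {type(g).__name__}")


def act_on_volume(g, v: np.ndarray, axes: tuple[int, int, int] = (-3, -2, -1)) -> np.ndarray:
    """Apply a D4h element to a volume (a pure voxel permutation).

    ``axes`` names the (x, y, z) axes of ``v``; leading axes (batch, channel)
    are untouched.  The in-plane dims must be square so that quarter turns map
    the grid onto itself.  Returns a (possibly non-contiguous) view-like array.
    """
    g = _as_element(g)
    v = np.asarray(v)
    ax, ay, az = (a % v.ndim for a in axes)
    if v.shape[ax] != v.shape[ay]:
        raise ValueError(
            "in-plane dimensions must be square for quarter-turn rotations, "
            f"got {v.shape[ax]}x{v.shape[ay]}"
        )
    if g.z:
        v = np.flip(v, axis=az)
    if g.m:
        v = np.flip(v, axis=ax)
    if g.r:
        v = np.rot90(v, k=g.r, axes=(ax, ay))
    return v


@dataclass(frozen=True)
class CayleyTable:
    """Composition and inversion tables for the 16 D4h elements.

    ``compose[g, h]`` is the index of "h first, then g"; ``inverse[g]`` the
    index of g's inverse.  Built once by :func:`build_group` and shared.
    """

    compose: np.ndarray  # (16, 16) int
    inverse: np.ndarray  # (16,) int

    def compose_elements(self, g, h) -> GroupElement:
        return ELEMENTS[self.compose[_as_element(g).index, _as_element(h).index]]

    def inverse_element(self, g) -> GroupElement:
        return ELEMENTS[self.inverse[_as_element(g).index]]

    def to_json(self) -> str:
        return json.dumps(
            {"group": "D4h", "order": ORDER,
             "compose": self.compose.tolist(), "inverse": self.inverse.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "CayleyTable":
        obj = json.loads(text)
        table = cls(
            compose=np.asarray(obj["compose"], dtype=np.intp),
            inverse=np.asarray(obj["inverse"], dtype=np.intp),
        )
        table.validate()
        return table

    def validate(self) -> None:
        """Check the full set of group axioms (exhaustive, cheap at order 16)."""
        c = self.compose
        if c.shape != (ORDER, ORDER):
            raise ValueError("compose table must be 16x16")
        ident = IDENTITY.index
        for i in range(ORDER):
            if sorted(c[i]) != list(range(ORDER)) or sorted(c[:, i]) != list(range(ORDER)):
                raise ValueError("compose table is not a Latin square")
            if c[i, self.inverse[i]] != ident or c[self.inverse[i], i] != ident:
                raise ValueError("inverse table inconsistent with compose table")
        # associativity over all 16^3 triples, vectorized:
        # c[c][g,h,k] = (g*h)*k and c[:, c][g,h,k] = g*(h*k)
        if not np.array_equal(c[c], c[:, c]):
            raise ValueError("composition is not associative")


def _reference_grid() -> np.ndarray:
    # Smallest grid on which the action is faithful: square in-plane, two
    # slices, all entries distinct.
    return np.arange(3 * 3 * 2, dtype=np.int64).reshape(3, 3, 2)


@lru_cache(maxsize=1)
def build_group() -> CayleyTable:
    """Construct the D4h Cayley table by composing the concrete voxel actions.

    The table is derived, not hardcoded: each element's permutation of a
    reference grid is computed, pairwise compositions are matched back to
    elements, and the group axioms are verified.
    """
    ref = _reference_grid()
    perms = [act_on_volume(g, ref).ravel() for g in ELEMENTS]
    keys = {p.tobytes(): i for i, p in enumerate(perms)}
    if len(keys) != ORDER:
        raise AssertionError("D4h action is not faithful on the reference grid")

    compose = np.empty((ORDER, ORDER), dtype=np.intp)
    for i, gi in enumerate(ELEMENTS):
        for j, gj in enumerate(ELEMENTS):
            prod = act_on_volume(gi, act_on_volume(gj, ref)).ravel()
            compose[i, j] = keys[prod.tobytes()]

    inverse = np.empty(ORDER, dtype=np.intp)
    ident = IDENTITY.index
    for i in range(ORDER):
        (inv,) = np.nonzero(compose[i] == ident)[0]
        inverse[i] = inv

    table = CayleyTable(compose=compose, inverse=inverse)
    table.validate()
    return table


def act_on_oriented(
    g,
    f: np.ndarray,
    table: CayleyTable | None = None,
    orientation_axis: int = -4,
    axes: tuple[int, int, int] = (-3, -2, -1),
) -> np.ndarray:
    """Apply a D4h element to an orientation-indexed feature map.

    ``f`` carries an orientation axis of length 16 next to the spatial axes
    (default layout ``(..., orientation, x, y, z)``).  The action transforms
    every orientation channel spatially by ``g`` and permutes the orientation
    axis by ``h -> g*h``, i.e. ``out[g*h] = act_on_volume(g, f[h])``.  This is
    the regular representation under which lifting and group convolutions are
    equivariant.
    """
    g = _as_element(g)
    f = np.asarray(f)
    oax = orientation_axis % f.ndim
    if f.shape[oax] != ORDER:
        raise ValueError(
            f"orientation axis must have length {ORDER}, got {f.shape[oax]}"
        )
    if table is None:
        table = build_group()
    out = act_on_volume(g, f, axes=axes)
    # out[k] should hold a_g(f[g^-1 * k])
    perm = table.compose[table.inverse[g.index], :]
    return np.take(out, perm, axis=oax)
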