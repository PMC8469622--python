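"""Discretized truncated-cube nanoparticles and their assemblies.

A magnetite nanocube with rounded corners is modelled as the intersection of
a cube of side ``l`` with a sphere of diameter ``d = l (1 + sqrt(3)) / 2``
(the mean of the side and the space diagonal).  Particles are rasterized on a
regular grid of hexahedral cells of edge ``ds``; a cell is magnetic iff its
center lies inside the cube-sphere intersection.  Assemblies (3x3x3 clusters,
linear chains) are unions of translated copies of the single-particle mask.

All lengths are in nanometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRUNCATION_RATIO",
    "NanocubeShape",
    "AssemblySpec",
    "DiscretizedGeometry",
    "InvalidGeometryError",
    "ResolutionError",
    "InvalidAssemblyError",
    "build_truncated_cube",
    "build_assembly",
    "ds_for_size",
]

#: Ratio d / l between the truncation-sphere diameter and the cube side.
TRUNCATION_RATIO = (1.0 + np.sqrt(3.0)) / 2.0

#: Cell-size range (nm) used for the default resolution rule.
DS_RANGE = (1.25, 4.1)


class InvalidGeometryError(ValueError):
    """Nonsensical particle geometry (nonpositive side or cell size)."""


class ResolutionError(ValueError):
    """Grid too coarse to resolve the particle (l / ds < 4)."""


class InvalidAssemblyError(ValueError):
    """Assembly specification that would make particles overlap."""


def ds_for_size(l: float) -> float:
    """Default cell edge for a particle of side ``l``: l/16 clamped to [1.25, 4.1] nm."""
    return float(np.clip(l / 16.0, *DS_RANGE))


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidGeometryError("orientation must be a 3x3 rotation matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-10
    ):
        raise InvalidGeometryError("orientation must be a proper rotation")
    return R


@dataclass(frozen=True)
class NanocubeShape:
    """Truncated cube: side ``l`` (nm) and an optional crystal->lab rotation.

    The truncation-sphere diameter is forced to ``d = l (1 + sqrt(3)) / 2``.
    The rotation maps crystal <100> axes to lab axes; by convention it is
    applied to the field protocol rather than to the rasterized mask (the two
    are equivalent for loop observables).
    """

    l: float
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if self.l <= 0:
            raise InvalidGeometryError(f"cube side must be positive, got {self.l}")
        _check_rotation(self.orientation)

    @property
    def d(self) -> float:
        """Truncation-sphere diameter (nm)."""
        return self.l * TRUNCATION_RATIO


@dataclass(frozen=True)
class AssemblySpec:
    """Particle arrangement: a single particle, a 3x3x3 cluster or an n-chain.

    ``d_gap`` is the nominal face-to-face distance (nm) between neighbouring
    particles; the realized gap is rounded so the center spacing is an integer
    number of cells, and is recorded on the built geometry.
    """

    kind: str = "single"
    n: int | None = None
    d_gap: float = 0.0
    axis: int = 0  # chain direction (0=x, 1=y, 2=z)

    def __post_init__(self):
        if self.kind not in ("single", "cluster", "chain"):
            raise InvalidAssemblyError(f"unknown assembly kind {self.kind!r}")
        if self.d_gap < 0:
            raise InvalidAssemblyError("face-to-face distance must be >= 0")
        n = self.n
        if self.kind == "single":
            n = 1
        elif self.kind == "cluster":
            if n is None:
                n = 27
            if n != 27:
                raise InvalidAssemblyError("cluster is a 3x3x3 grid of 27 particles")
        elif self.kind == "chain":
            if n is None:
                n = 8
            if n < 2:
                raise InvalidAssemblyError("chain needs at least 2 particles")
        object.__setattr__(self, "n", n)


@dataclass
class DiscretizedGeometry:
    """Occupancy mask of one or more particles on a regular hexahedral grid.

    Attributes
    ----------
    ds : cell edge (nm).
    mask : bool array (nx, ny, nz), True where the cell is magnetic.
    origin : lab-frame coordinate (nm) of the center of cell (0, 0, 0).
    particle_id : int array, -1 outside particles, particle index inside.
    shape_spec : the generating NanocubeShape.
    realized_gap : face-to-face distance actually realized on the grid (nm),
        None for a single particle.
    """

    ds: float
    mask: np.ndarray
    origin: np.ndarray
    particle_id: np.ndarray
    shape_spec: NanocubeShape | None = None
    realized_gap: float | None = None

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """Total magnetic volume (nm^3)."""
        return self.n_cells * self.ds**3

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def cell_centers(self, occupied_only: bool = True) -> np.ndarray:
        """Lab-frame cell-center coordinates (nm), computed on demand."""
        idx = np.argwhere(self.mask) if occupied_only else np.argwhere(
            np.ones_like(self.mask)
        )
        return self.origin + idx * self.ds

    def meta(self) -> dict:
        out = {
            "ds_nm": self.ds,
            "grid": list(self.grid_shape),
            "n_cells": self.n_cells,
            "volume_nm3": self.volume,
        }
        if self.shape_spec is not None:
            out["l_nm"] = self.shape_spec.l
            out["d_nm"] = self.shape_spec.d
        if self.realized_gap is not None:
            out["realized_gap_nm"] = self.realized_gap
        return out

    def to_json(self) -> str:
        return json.dumps(self.meta(), indent=2)


def _single_mask(l: float, ds: float) -> np.ndarray:
    """Rasterize cube(l) ∩ sphere(d) on an n^3 grid centred on the particle."""
    n = int(round(l / ds))
    # cell centers at (i + 0.5 - n/2) * ds, i = 0..n-1
    c = (np.arange(n) + 0.5 - n / 2.0) * ds
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    r2 = x * x + y * y + z * z
    d = l * TRUNCATION_RATIO
    inside_cube = (np.abs(x) <= l / 2) & (np.abs(y) <= l / 2) & (np.abs(z) <= l / 2)
    return inside_cube & (r2 <= (d / 2) ** 2)


def build_truncated_cube(
    l: float, ds: float | None = None, orientation: np.ndarray | None = None
) -> DiscretizedGeometry:
    """Build a single truncated-cube particle.

    Parameters
    ----------
    l : cube side (nm).
    ds : cell edge (nm); defaults to ``ds_for_size(l)``.
    orientation : optional proper rotation (crystal -> lab).
    """
    if l <= 0:
        raise InvalidGeometryError(f"cube side must be positive, got {l}")
    if ds is None:
        ds = ds_for_size(l)
    if ds <= 0:
        raise InvalidGeometryError(f"cell size must be positive, got {ds}")
    if l / ds < 4:
        raise ResolutionError(f"l/ds = {l / ds:.2f} < 4: grid too coarse")
    shape = NanocubeShape(l, orientation if orientation is not None else np.eye(3))
    mask = _single_mask(l, ds)
    n = mask.shape[0]
    origin = np.full(3, (0.5 - n / 2.0) * ds)
    pid = np.where(mask, 0, -1)
    return DiscretizedGeometry(ds=ds, mask=mask, origin=origin, particle_id=pid,
                               shape_spec=shape)


def build_assembly(
    shape: NanocubeShape, spec: AssemblySpec, ds: float | None = None
) -> DiscretizedGeometry:
    """Build a particle assembly as a union of translated single-particle masks.

    The nominal center-to-center spacing ``l + d_gap`` is rounded to the
    nearest integer number of cells; the realized face-to-face gap is recorded
    in ``realized_gap``.  Raises :class:`InvalidAssemblyError` if rounding
    would make particles overlap.
    """
    if ds is None:
        ds = ds_for_size(shape.l)
    single = build_truncated_cube(shape.l, ds, shape.orientation)
    if spec.kind == "single":
        return single

    m = single.mask
    n1 = m.shape[0]
    spacing_cells = int(round((shape.l + spec.d_gap) / ds))
    if spacing_cells < n1:
        raise InvalidAssemblyError(
            f"center spacing {spacing_cells * ds:.2f} nm < particle size: overlap"
        )
    realized_gap = spacing_cells * ds - shape.l

    if spec.kind == "cluster":
        reps = (3, 3, 3)
    else:  # chain
        reps = tuple(spec.n if a == spec.axis else 1 for a in range(3))

    full_shape = tuple(n1 + (r - 1) * spacing_cells for r in reps)
    mask = np.zeros(full_shape, dtype=bool)
    pid = np.full(full_shape, -1, dtype=int)
    k = 0
    for i in range(reps[0]):
        for j in range(reps[1]):
            for kk in range(reps[2]):
                sl = tuple(
                    slice(t * spacing_cells, t * spacing_cells + n1)
                    for t in (i, j, kk)
                )
                mask[sl] |= m
                pid[sl][m] = k
                k += 1
    origin = np.array(
        [(0.5 - s / 2.0) * ds for s in full_shape]
    )
    return DiscretizedGeometry(ds=ds, mask=mask, origin=origin, particle_id=pid,
                               shape_spec=shape, realized_gap=realized_gap)
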