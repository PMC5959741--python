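"""Cylindrical simulation space: site classification, point sampling, thinning.

The dosage form is a cylinder of radius ``R`` and axial extent ``H`` embedded
in a conceptual cubic lattice of unit cuboids.  The cross-section is split
into three regions: the *interior* (where drug molecules live), the *leak*
shell of unit thickness just inside the surface (molecules reaching it are
released), and the *restricted* outside.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np

from .errors import EmptyCloudError, GeometryError, PackingError

__all__ = [
    "INTERIOR",
    "LEAK",
    "RESTRICTED",
    "LatticeCylinder",
    "ParticleCloud",
    "classify_site",
    "sample_cylinder_points",
    "min_pairwise_buffer",
    "current_radius",
]

INTERIOR = "interior"
LEAK = "leak"
RESTRICTED = "restricted"

#: shell width in lattice units; the leak region is [(R-1)^2, R^2] radially
LEAK_THICKNESS = 1.0


@dataclasses.dataclass(frozen=True)
class LatticeCylinder:
    """Geometry of the dosage form.

    Parameters
    ----------
    R : float
        Current radius in lattice units.  Shrinks as the simulation proceeds.
    R0 : float
        Initial radius.  ``0 < R <= R0``.
    H : float
        Axial extent in lattice units.  Constant over a simulation: release
        happens only through the side surface.
    leak_thickness : float
        Width of the leak shell.  Fixed at 1 (one cuboid side).
    """

    R: float
    R0: float
    H: float
    leak_thickness: float = LEAK_THICKNESS

    def __post_init__(self):
        if not (0 < self.R <= self.R0):
            raise GeometryError(f"need 0 < R <= R0, got R={self.R}, R0={self.R0}")
        if self.H <= 0:
            raise GeometryError(f"axial extent must be positive, got H={self.H}")
        if self.leak_thickness != LEAK_THICKNESS:
            raise GeometryError("leak shell thickness is fixed at 1 lattice unit")

    def shrunk(self, new_R: float) -> "LatticeCylinder":
        return dataclasses.replace(self, R=new_R)


class ParticleCloud:
    """Positions of the drug molecules remaining in the matrix.

    Thin wrapper around an ``(n, 3)`` float array of ``(x, y, z)`` coordinates
    in lattice units.
    """

    __slots__ = ("points",)

    def __init__(self, points: Iterable | np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected an (n, 3) array, got shape {pts.shape}")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    def radial(self) -> np.ndarray:
        """Distance of each point from the vertical symmetry axis."""
        return np.hypot(self.points[:, 0], self.points[:, 1])

    def subset(self, mask_or_index) -> "ParticleCloud":
        return ParticleCloud(self.points[mask_or_index])

    def __eq__(self, other) -> bool:
        return isinstance(other, ParticleCloud) and np.array_equal(
            self.points, other.points
        )

    def __repr__(self) -> str:
        return f"ParticleCloud(n={self.n})"


def classify_site(x: float, y: float, R: float) -> str:
    """Classify a cross-section position as interior, leak, or restricted.

    The three regions partition the plane: interior is ``x^2+y^2 < (R-1)^2``,
    the leak shell is ``(R-1)^2 <= x^2+y^2 <= R^2``, and everything beyond
    ``R^2`` is restricted.

    Raises
    ------
    GeometryError
        If ``R <= 1`` (the leak shell would swallow the whole cylinder).
    """
    if R <= 1.0:
        raise GeometryError(f"radius must exceed the shell width 1, got R={R}")
    rho2 = x * x + y * y
    if rho2 < (R - 1.0) ** 2:
        return INTERIOR
    if rho2 <= R * R:
        return LEAK
    return RESTRICTED


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _raw_cylinder_points(
    n: int, R: float, H: float, sampler_mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` interior points: random angle, random radius < R-1, random z."""
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    u = rng.random(n)
    if sampler_mode == "paper":
        # uniform radius, as in the published generator (density ~ 1/r)
        r = u * (R - 1.0)
    elif sampler_mode == "volume_uniform":
        r = (R - 1.0) * np.sqrt(u)
    else:
        raise ValueError(f"unknown sampler_mode {sampler_mode!r}")
    z = rng.uniform(0.0, H, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _thin_indices(pts: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Greedy thinning: keep a random point, drop everything within d, repeat.

    Returns the sorted indices of the survivors.
    """
    n = len(pts)
    if n == 0 or d <= 0:
        return np.arange(n)
    d2 = d * d
    alive = np.ones(n, dtype=bool)
    kept = np.zeros(n, dtype=bool)
    while True:
        candidates = np.flatnonzero(alive & ~kept)
        if candidates.size == 0:
            break
        i = candidates[rng.integers(candidates.size)]
        kept[i] = True
        diff = pts[candidates] - pts[i]
        close = np.einsum("ij,ij->i", diff, diff) < d2
        victims = candidates[close]
        alive[victims[victims != i]] = False
    return np.flatnonzero(kept)


def min_pairwise_buffer(
    points: ParticleCloud, d: float, seed=None
) -> ParticleCloud:
    """Thin a cloud so that no two surviving points are closer than ``d``.

    Iterates: pick a random survivor, delete every other point within
    distance ``d`` of it, and repeat on the remainder.  The output is a
    subset of the input (original order preserved); with ``d = 0`` the input
    is returned unchanged.
    """
    if d < 0:
        raise ValueError(f"minimum distance must be non-negative, got {d}")
    rng = _as_rng(seed)
    idx = _thin_indices(points.points, d, rng)
    return points.subset(idx)


#: how many times the sample-and-thin cycle is retried before giving up
MAX_PACKING_ATTEMPTS = 100


def sample_cylinder_points(
    n: int,
    R: float,
    H: float,
    d: float = 0.0,
    sampler_mode: str = "paper",
    seed=None,
    max_attempts: int = MAX_PACKING_ATTEMPTS,
) -> ParticleCloud:
    """Generate ``n`` random points in the cylinder interior.

    Points satisfy ``x^2 + y^2 <= (R-1)^2`` and ``0 <= z <= H``.  With
    ``sampler_mode="paper"`` the radius is drawn uniformly (matching the
    published generator, which concentrates density near the axis);
    ``"volume_uniform"`` draws ``r = (R-1) * sqrt(u)`` for true uniformity
    over the volume.

    If ``d > 0`` the sample is thinned so all pairwise distances are at
    least ``d``; the sample-and-thin cycle is re-run (growing the candidate
    pool) until exactly ``n`` survivors can be returned or ``max_attempts``
    is exhausted, in which case :class:`PackingError` reports the best
    achieved count.
    """
    if n < 0:
        raise ValueError(f"point count must be non-negative, got {n}")
    if n == 0:
        return ParticleCloud(np.empty((0, 3)))
    if R <= 1.0:
        raise GeometryError(f"radius must exceed the shell width 1, got R={R}")
    if H <= 0:
        raise GeometryError(f"axial extent must be positive, got H={H}")
    if d >= 2 * R:
        raise ValueError(f"minimum distance d={d} is infeasible for radius {R}")
    rng = _as_rng(seed)

    if d <= 0:
        return ParticleCloud(_raw_cylinder_points(n, R, H, sampler_mode, rng))

    pool_n = n
    best = 0
    for attempt in range(1, max_attempts + 1):
        pts = _raw_cylinder_points(pool_n, R, H, sampler_mode, rng)
        surviving = _thin_indices(pts, d, rng)
        if surviving.size >= n:
            chosen = rng.choice(surviving.size, size=n, replace=False)
            return ParticleCloud(pts[np.sort(surviving[chosen])])
        best = max(best, int(surviving.size))
        pool_n = int(pool_n * 1.5) + 1
    raise PackingError(requested=n, achieved=best, attempts=max_attempts)


def current_radius(cloud: ParticleCloud) -> float:
    """Distance of the farthest point from the vertical symmetry axis."""
    if cloud.n == 0:
        raise EmptyCloudError("cannot compute the radius of an empty cloud")
    return float(cloud.radial().max())
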