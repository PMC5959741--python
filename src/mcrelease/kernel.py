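"""Monte Carlo release kernels and micro-step (MCS) time models.

Two kernels produce release trajectories:

* ``shell`` — the published heuristic: at each step every molecule in the
  leak shell is removed and the radius shrinks by one lattice unit.
* ``walk`` — the textbook description: molecules perform a single-occupancy
  random walk on the integer lattice and are released on reaching the shell.

The simulation clock advances by a Monte Carlo Micro-Step whose functional
form encodes the physical release mechanism: ``1/N(t)`` for diffusion,
an exponential waiting time ``|ln u| / lambda`` for polymer erosion, or a
hybrid combination of both.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np

from .errors import ConfigError, CurveError, ShellExhaustedError
from .lattice import LatticeCylinder, ParticleCloud, sample_cylinder_points

__all__ = [
    "MCSModel",
    "SimulationConfig",
    "ReleaseCurve",
    "WalkState",
    "mcs_diffusion",
    "mcs_erosion",
    "mcs_hybrid",
    "remove_leak_shell",
    "quantize_cloud",
    "random_walk_step",
    "simulate_release",
    "fraction_released",
]

log = logging.getLogger(__name__)

MODES = ("diffusion", "erosion", "hybrid")
FORMS = ("constant", "1/k", "k")
KERNELS = ("shell", "walk")


def _coeff(form: str, const: float, k: int) -> float:
    if form == "constant":
        return const
    if form == "1/k":
        return 1.0 / k
    if form == "k":
        return float(k)
    raise ConfigError(f"unknown coefficient form {form!r}")


@dataclasses.dataclass(frozen=True)
class MCSModel:
    """Time-increment rule for one Monte Carlo event.

    ``mode`` selects which fields are read:

    * ``diffusion`` — MCS = 1/N(t); no parameters.
    * ``erosion`` — MCS = |ln u| / lambda_, u ~ U(0,1).
    * ``hybrid`` — MCS = A(k) * (1/lambda1) * N^(-nu) + B(k) * (1/lambda2) * |ln u|,
      where A(k)/B(k) follow ``A_form``/``B_form`` ("constant" uses the
      constants ``A``/``B``; "1/k" and "k" are step-indexed).
    """

    mode: str = "diffusion"
    nu: float = 1.0
    lambda_: Optional[float] = None
    lambda1: Optional[float] = None
    lambda2: Optional[float] = None
    A_form: str = "constant"
    A: float = 1.0
    B_form: str = "constant"
    B: float = 1.0
    noise_family: str = "exponential"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"unknown MCS mode {self.mode!r}")
        if self.A_form not in FORMS or self.B_form not in FORMS:
            raise ConfigError(
                f"coefficient forms must be one of {FORMS}, "
                f"got A_form={self.A_form!r}, B_form={self.B_form!r}"
            )
        if self.noise_family != "exponential":
            raise ConfigError(f"unsupported noise family {self.noise_family!r}")
        if self.mode == "erosion":
            if self.lambda_ is None or self.lambda_ <= 0:
                raise ConfigError("erosion mode needs lambda_ > 0")
        if self.mode == "hybrid":
            a_dead = self.A_form == "constant" and self.A == 0.0
            b_dead = self.B_form == "constant" and self.B == 0.0
            if not a_dead and (self.lambda1 is None or self.lambda1 <= 0):
                raise ConfigError("hybrid mode needs lambda1 > 0")
            if not b_dead and (self.lambda2 is None or self.lambda2 <= 0):
                raise ConfigError("hybrid mode needs lambda2 > 0")

    def a_coeff(self, k: int) -> float:
        return _coeff(self.A_form, self.A, k)

    def b_coeff(self, k: int) -> float:
        return _coeff(self.B_form, self.B, k)


def mcs_diffusion(N: int) -> float:
    """Diffusion micro-step: the reciprocal of the remaining count."""
    if N <= 0:
        raise ValueError(f"remaining count must be positive, got N={N}")
    return 1.0 / N


def mcs_erosion(lambda_: float, u: float) -> float:
    """Erosion micro-step: exponential waiting time ``|ln u| / lambda_``."""
    if lambda_ <= 0:
        raise ValueError(f"erosion rate must be positive, got lambda={lambda_}")
    if not (0.0 < u <= 1.0):
        raise ValueError(f"uniform draw must lie in (0, 1], got u={u}")
    return (1.0 / lambda_) * abs(math.log(u))


def mcs_hybrid(N: int, k: int, model: MCSModel, u: float) -> float:
    """Hybrid micro-step: deterministic N-dependent term plus noise term.

    ``A(k) * (1/lambda1) * N**(-nu) + B(k) * (1/lambda2) * |ln u|``.
    Reduces exactly to :func:`mcs_diffusion` when the B term vanishes with
    ``A = 1, nu = 1, lambda1 = 1``, and to :func:`mcs_erosion` when the A
    term vanishes with ``B = 1, lambda2 = lambda_``.
    """
    if N <= 0:
        raise ValueError(f"remaining count must be positive, got N={N}")
    if k <= 0:
        raise ValueError(f"step index must be positive, got k={k}")
    det, sto = _hybrid_parts(model, N, k, u)
    return det + sto


def _hybrid_parts(model: MCSModel, N: int, k: int, u: Optional[float]):
    a = model.a_coeff(k)
    b = model.b_coeff(k)
    det = 0.0
    if a != 0.0:
        lam1 = model.lambda1 if model.lambda1 is not None else 1.0
        det = a * (1.0 / lam1) * float(N) ** (-model.nu)
    sto = 0.0
    if b != 0.0:
        if u is None:
            raise ValueError("noise term active but no uniform draw supplied")
        if not (0.0 < u <= 1.0):
            raise ValueError(f"uniform draw must lie in (0, 1], got u={u}")
        sto = b * (1.0 / model.lambda2) * abs(math.log(u))
    return det, sto


def remove_leak_shell(cloud: ParticleCloud, R: float):
    """Remove every molecule in the leak shell and shrink the radius by one.

    Returns ``(remaining_cloud, removed_count, R - 1)``.  Raises
    :class:`ShellExhaustedError` when ``R <= 1`` (no shell remains, the
    simulation must stop).
    """
    if R <= 1.0:
        raise ShellExhaustedError(f"radius {R} leaves no leak shell")
    rho2 = np.einsum("ij,ij->i", cloud.points[:, :2], cloud.points[:, :2])
    in_shell = ((R - 1.0) ** 2 <= rho2) & (rho2 <= R * R)
    removed = int(in_shell.sum())
    return cloud.subset(~in_shell), removed, R - 1.0


# ---------------------------------------------------------------------------
# release curve


@dataclasses.dataclass
class ReleaseCurve:
    """A (t, N(t)) trajectory from a simulation or loaded from file.

    ``N`` holds remaining amounts by default; after
    :func:`fraction_released` (or when loading fractional data) it holds
    the released fraction and ``meta["kind"] == "fraction"``.
    """

    t: np.ndarray
    N: np.ndarray
    n0: float
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.t.shape != self.N.shape or self.t.ndim != 1:
            raise CurveError(
                f"time and value arrays must be equal-length vectors, "
                f"got {self.t.shape} and {self.N.shape}"
            )
        if self.t.size and np.any(np.diff(self.t) <= 0):
            row = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise CurveError(f"times must be strictly increasing (index {row})")

    @property
    def kind(self) -> str:
        return self.meta.get("kind", "remaining")

    @property
    def n_points(self) -> int:
        return self.t.size

    def check_monotone(self) -> None:
        """Assert the remaining amount never increases (simulator contract)."""
        if self.kind == "remaining" and np.any(np.diff(self.N) > 0):
            raise CurveError("remaining amount increased along the curve")
        if self.kind == "fraction" and np.any(np.diff(self.N) < 0):
            raise CurveError("released fraction decreased along the curve")

    def fraction_values(self) -> np.ndarray:
        if self.kind == "fraction":
            return self.N
        if self.n0 <= 0:
            raise ValueError("fractional release needs n0 > 0")
        return 1.0 - self.N / self.n0


def fraction_released(curve: ReleaseCurve) -> ReleaseCurve:
    """Convert a remaining-amount curve to fractional release ``1 - N/n0``."""
    if curve.n0 <= 0:
        raise ValueError(f"fractional release needs n0 > 0, got {curve.n0}")
    if curve.kind == "fraction":
        return curve
    meta = dict(curve.meta, kind="fraction")
    return ReleaseCurve(t=curve.t.copy(), N=1.0 - curve.N / curve.n0,
                        n0=curve.n0, meta=meta)


# ---------------------------------------------------------------------------
# simulation config


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one release simulation."""

    n0: int
    R0: float
    H: float
    d: float = 0.0
    sampler_mode: str = "paper"
    kernel: str = "shell"
    mcs: MCSModel = dataclasses.field(default_factory=MCSModel)
    max_steps: int = 1_000_000
    seed: Optional[int] = None
    per_molecule: bool = False

    def __post_init__(self):
        if self.n0 <= 0:
            raise ConfigError(f"initial count must be positive, got n0={self.n0}")
        if self.R0 <= 1.0:
            raise ConfigError(f"radius must exceed 1, got R0={self.R0}")
        if self.H <= 0:
            raise ConfigError(f"axial extent must be positive, got H={self.H}")
        if self.d < 0 or self.d >= 2 * self.R0:
            raise ConfigError(f"minimum distance d={self.d} infeasible for R0={self.R0}")
        if self.kernel not in KERNELS:
            raise ConfigError(f"unknown kernel {self.kernel!r}")
        if self.max_steps <= 0:
            raise ConfigError(f"max_steps must be positive, got {self.max_steps}")
        if self.sampler_mode not in ("paper", "volume_uniform"):
            raise ConfigError(f"unknown sampler_mode {self.sampler_mode!r}")

    @property
    def geometry(self) -> LatticeCylinder:
        return LatticeCylinder(R=self.R0, R0=self.R0, H=self.H)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# micro-step drawing shared by both kernels


class _StepClock:
    """Draws micro-steps for a model, tracking component times and resamples."""

    def __init__(self, model: MCSModel, rng: np.random.Generator):
        self.model = model
        self.rng = rng
        self.det_time = 0.0
        self.sto_time = 0.0
        self.resampled = 0

    def _draw_u(self) -> float:
        # u = 0 gives an infinite step, u = 1 a zero step; both are resampled
        while True:
            u = float(self.rng.random())
            if 0.0 < u < 1.0:
                return u
            self.resampled += 1
            log.debug("resampled degenerate uniform draw u=%s", u)

    def step(self, N: int, k: int) -> float:
        """One micro-step at remaining count N (floored at 1) and step index k."""
        model = self.model
        n_eff = max(N, 1)
        if model.mode == "diffusion":
            det, sto = 1.0 / n_eff, 0.0
        elif model.mode == "erosion":
            det, sto = 0.0, (1.0 / model.lambda_) * abs(math.log(self._draw_u()))
        else:
            b = model.b_coeff(k)
            u = self._draw_u() if b != 0.0 else None
            det, sto = _hybrid_parts(model, n_eff, k, u)
        self.det_time += det
        self.sto_time += sto
        return det + sto


# ---------------------------------------------------------------------------
# shell kernel


def _simulate_shell(config: SimulationConfig, rng: np.random.Generator) -> ReleaseCurve:
    cloud = sample_cylinder_points(
        config.n0, config.R0, config.H, config.d, config.sampler_mode, seed=rng
    )
    clock = _StepClock(config.mcs, rng)
    R = float(config.R0)
    t = 0.0
    times = [0.0]
    counts = [cloud.n]
    k = 0
    stop = "max_steps"
    while k < config.max_steps:
        if cloud.n == 0:
            stop = "exhausted"
            break
        if R <= 1.0:
            stop = "R_floor"
            break
        k += 1
        n_pre = cloud.n
        cloud, removed, R = remove_leak_shell(cloud, R)
        if config.per_molecule and removed > 0:
            # one micro-step per removed molecule, at the count after each removal
            for j in range(removed):
                t += clock.step(n_pre - 1 - j, k)
        else:
            t += clock.step(cloud.n, k)
        times.append(t)
        counts.append(cloud.n)
    else:
        stop = "max_steps"
    if cloud.n == 0:
        stop = "exhausted"
    elif R <= 1.0:
        stop = "R_floor"
    meta = {
        "kernel": "shell",
        "stop": stop,
        "steps": k,
        "escaped": config.n0 - cloud.n,
        "det_time": clock.det_time,
        "sto_time": clock.sto_time,
        "resampled_u": clock.resampled,
        "final_R": R,
        "seed": config.seed,
    }
    return ReleaseCurve(np.array(times), np.array(counts, dtype=float),
                        n0=float(config.n0), meta=meta)


# ---------------------------------------------------------------------------
# random-walk kernel

_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)

MOVED = "moved"
REJECTED = "rejected"
ESCAPED = "escaped"


@dataclasses.dataclass
class WalkState:
    """Integer-lattice positions with single-occupancy bookkeeping."""

    positions: np.ndarray  # (n, 3) int
    occupied: dict  # (x, y, z) -> row index
    R: float
    H: float

    @property
    def n(self) -> int:
        return self.positions.shape[0]


def _neighbour_offsets(max_radius: int = 6) -> np.ndarray:
    span = np.arange(-max_radius, max_radius + 1)
    grid = np.stack(np.meshgrid(span, span, span, indexing="ij"), axis=-1).reshape(-1, 3)
    order = np.argsort(np.einsum("ij,ij->i", grid, grid), kind="stable")
    return grid[order]


_OFFSETS = _neighbour_offsets()


def quantize_cloud(cloud: ParticleCloud, R: float, H: float) -> WalkState:
    """Round a continuous cloud onto the integer lattice, one molecule per site.

    Collisions (and roundings that land outside the interior) are resolved to
    the nearest free interior site.
    """
    inner2 = (R - 1.0) ** 2
    occupied: dict = {}
    positions = np.empty((cloud.n, 3), dtype=int)
    z_max = int(math.floor(H))
    for i, p in enumerate(np.rint(cloud.points).astype(int)):
        placed = False
        for off in _OFFSETS:
            q = p + off
            if q[0] * q[0] + q[1] * q[1] >= inner2:
                continue
            if not (0 <= q[2] <= z_max):
                continue
            key = (int(q[0]), int(q[1]), int(q[2]))
            if key in occupied:
                continue
            occupied[key] = i
            positions[i] = q
            placed = True
            break
        if not placed:
            raise ConfigError(
                "lattice too crowded: could not place all molecules on "
                "distinct interior sites"
            )
    return WalkState(positions=positions, occupied=occupied, R=R, H=H)


def random_walk_step(state: WalkState, rng: np.random.Generator) -> str:
    """Attempt one random-walk move; returns 'moved', 'rejected' or 'escaped'.

    A molecule and one of its six von-Neumann neighbour sites are drawn
    uniformly.  Moves into occupied, restricted, or out-of-range axial sites
    are rejected; a molecule stepping onto a leak site is removed and counted
    as released.
    """
    i = int(rng.integers(state.n))
    direction = _DIRS[int(rng.integers(6))]
    old = state.positions[i]
    new = old + direction
    if not (0 <= new[2] <= math.floor(state.H)):
        return REJECTED
    rho2 = int(new[0]) ** 2 + int(new[1]) ** 2
    if rho2 > state.R * state.R:
        return REJECTED
    if rho2 >= (state.R - 1.0) ** 2:
        # leak site: release the molecule (swap-delete its row)
        del state.occupied[(int(old[0]), int(old[1]), int(old[2]))]
        last = state.n - 1
        if i != last:
            moved_site = tuple(int(v) for v in state.positions[last])
            state.positions[i] = state.positions[last]
            state.occupied[moved_site] = i
        state.positions = state.positions[:last]
        return ESCAPED
    key = (int(new[0]), int(new[1]), int(new[2]))
    if key in state.occupied:
        return REJECTED
    del state.occupied[(int(old[0]), int(old[1]), int(old[2]))]
    state.occupied[key] = i
    state.positions[i] = new
    return MOVED


def _simulate_walk(config: SimulationConfig, rng: np.random.Generator) -> ReleaseCurve:
    cloud = sample_cylinder_points(
        config.n0, config.R0, config.H, config.d, config.sampler_mode, seed=rng
    )
    state = quantize_cloud(cloud, config.R0, config.H)
    clock = _StepClock(config.mcs, rng)
    t = 0.0
    times = [0.0]
    counts = [state.n]
    k = 0
    stop = "max_steps"
    while k < config.max_steps:
        if state.n == 0:
            stop = "exhausted"
            break
        k += 1
        t += clock.step(state.n, k)
        event = random_walk_step(state, rng)
        if event == ESCAPED:
            times.append(t)
            counts.append(state.n)
    if state.n == 0:
        stop = "exhausted"
    meta = {
        "kernel": "walk",
        "stop": stop,
        "steps": k,
        "escaped": config.n0 - state.n,
        "det_time": clock.det_time,
        "sto_time": clock.sto_time,
        "resampled_u": clock.resampled,
        "final_R": config.R0,
        "seed": config.seed,
    }
    return ReleaseCurve(np.array(times), np.array(counts, dtype=float),
                        n0=float(config.n0), meta=meta)


def simulate_release(config: SimulationConfig) -> ReleaseCurve:
    """Run one seeded release simulation and return its trajectory.

    Shell kernel: per step, every molecule in the leak shell is removed, the
    radius shrinks by one, and the clock advances by one micro-step evaluated
    at the post-removal count (or one per removed molecule when
    ``per_molecule`` is set).  Walk kernel: one micro-step per attempted
    move; the trajectory records each escape.  Stops when no molecules
    remain, the radius reaches the shell width (shell kernel), or
    ``max_steps`` is hit.
    """
    rng = np.random.default_rng(config.seed)
    if config.kernel == "shell":
        curve = _simulate_shell(config, rng)
    else:
        curve = _simulate_walk(config, rng)
    curve.check_monotone()
    return curve
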