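"""Genetic-algorithm inference of hybrid micro-step parameters.

Given an observed release curve, the hybrid micro-step parameters
(exponent nu, rates lambda1/lambda2, optionally the coefficient forms and a
time-scale factor) are estimated by minimizing the sum of squared
deviations between the observed curve and the mean of a small simulation
ensemble run under each candidate parameter set.

The balance between the deterministic and stochastic terms of the
recovered micro-step identifies the dominant release mechanism:
diffusion-generated data yield a small stochastic-time share, erosion-
generated data a large one.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .errors import ExtrapolationError, InferenceError
from .fitting import spawn_seeds
from .kernel import FORMS, MCSModel, ReleaseCurve, SimulationConfig, simulate_release

__all__ = [
    "GAConfig",
    "InferenceResult",
    "objective_ssq",
    "ensemble_mean_curve",
    "infer_mcs",
    "stochastic_time_share",
]

DEFAULT_BOUNDS = {
    "nu": (0.2, 2.0),
    "log_lambda1": (math.log(1e-2), math.log(1e2)),
    "log_lambda2": (math.log(5e-2), math.log(1e4)),
}


@dataclasses.dataclass
class GAConfig:
    """Hyperparameters and search space of the genetic algorithm."""

    population_size: int = 40
    generations: int = 60
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    tournament_size: int = 3
    elitism: int = 1
    mutation_sigma: float = 0.15  # fraction of each gene's range
    bounds: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    infer_forms: bool = False
    infer_time_scale: bool = False
    time_scale_bounds: tuple = (math.log(1e-3), math.log(1e3))
    profile_time_scale: bool = True
    ensemble_size_per_candidate: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")
        if self.ensemble_size_per_candidate < 1:
            raise ValueError("ensemble_size_per_candidate must be >= 1")


# ---------------------------------------------------------------------------
# genome <-> model


@dataclasses.dataclass(frozen=True)
class _Gene:
    name: str
    lo: float
    hi: float
    integer: bool = False


def _gene_spec(ga: GAConfig) -> list:
    genes = [_Gene(n, lo, hi) for n, (lo, hi) in ga.bounds.items()]
    if ga.infer_forms:
        genes.append(_Gene("a_form", 0, len(FORMS) - 1, integer=True))
        genes.append(_Gene("b_form", 0, len(FORMS) - 1, integer=True))
    if ga.infer_time_scale:
        genes.append(_Gene("log_time_scale", *ga.time_scale_bounds))
    return genes


def decode_genome(genome, genes, template: MCSModel):
    """Map a genome vector to (MCSModel, time_scale, readable params dict)."""
    vals = dict(zip((g.name for g in genes), genome))
    params = {
        "nu": float(vals.get("nu", template.nu)),
        "lambda1": float(np.exp(vals["log_lambda1"])) if "log_lambda1" in vals
        else template.lambda1,
        "lambda2": float(np.exp(vals["log_lambda2"])) if "log_lambda2" in vals
        else template.lambda2,
    }
    a_form = FORMS[int(round(vals["a_form"]))] if "a_form" in vals else template.A_form
    b_form = FORMS[int(round(vals["b_form"]))] if "b_form" in vals else template.B_form
    model = MCSModel(
        mode="hybrid", nu=params["nu"], lambda1=params["lambda1"],
        lambda2=params["lambda2"], A_form=a_form, A=template.A,
        B_form=b_form, B=template.B,
    )
    time_scale = float(np.exp(vals.get("log_time_scale", 0.0)))
    params.update({"A_form": a_form, "B_form": b_form, "time_scale": time_scale})
    return model, time_scale, params


# ---------------------------------------------------------------------------
# objective

_GRID_POINTS = 256


def _mean_on_grid(curves, time_scale: float):
    t_max = max(c.t[-1] for c in curves) * time_scale
    grid = np.linspace(0.0, t_max, _GRID_POINTS)
    stack = np.empty((len(curves), grid.size))
    for i, c in enumerate(curves):
        # beyond a finished run the remaining count stays at its final value
        stack[i] = np.interp(grid, c.t * time_scale, c.N)
    return grid, stack.mean(axis=0)


def ensemble_mean_curve(
    sim_config: SimulationConfig, m_runs: int, seed=None, time_scale: float = 1.0
) -> ReleaseCurve:
    """Average of ``m_runs`` seeded simulations on a common time grid."""
    seeds = spawn_seeds(seed, m_runs)
    curves = [simulate_release(sim_config.replace(seed=s)) for s in seeds]
    grid, mean_N = _mean_on_grid(curves, time_scale)
    truncated = any(c.meta.get("stop") == "max_steps" for c in curves)
    meta = {"kind": "remaining", "m_runs": m_runs, "seed": seed,
            "time_scale": time_scale, "truncated": truncated}
    return ReleaseCurve(t=grid, N=mean_N, n0=float(sim_config.n0), meta=meta)


def objective_ssq(
    observed: ReleaseCurve,
    candidate: MCSModel,
    sim_config: SimulationConfig,
    m_runs: int,
    seed=None,
    time_scale: float = 1.0,
    on_fraction: Optional[bool] = None,
) -> float:
    """Sum of squared deviations between observed and ensemble-mean curves.

    The candidate micro-step model is simulated ``m_runs`` times, the runs
    are averaged on a common grid, the mean is linearly interpolated at the
    observed time points (after multiplying simulated times by
    ``time_scale``), and the squared deviations are summed.  If the
    observed times extend beyond a simulation truncated by ``max_steps``,
    an :class:`ExtrapolationError` is raised; runs that finished naturally
    are extended flat (release is over).
    """
    if observed.n_points < 3:
        raise ValueError("observed curve needs >= 3 points")
    if m_runs < 1:
        raise ValueError("m_runs must be >= 1")
    mean = ensemble_mean_curve(
        sim_config.replace(mcs=candidate), m_runs, seed=seed, time_scale=time_scale
    )
    if mean.meta["truncated"] and observed.t[-1] > mean.t[-1]:
        raise ExtrapolationError(
            f"observed times reach {observed.t[-1]:.4g} but a truncated "
            f"simulation only covers {mean.t[-1]:.4g}"
        )
    yhat = np.interp(observed.t, mean.t, mean.N)
    if on_fraction is None:
        on_fraction = observed.kind == "fraction"
    if on_fraction:
        obs_vals = observed.fraction_values()
        yhat = 1.0 - yhat / mean.n0
    else:
        obs_vals = observed.N
    return float(np.sum((obs_vals - yhat) ** 2))


def _profiled_objective(
    observed: ReleaseCurve,
    candidate: MCSModel,
    sim_config: SimulationConfig,
    m_runs: int,
    seed=None,
    on_fraction: Optional[bool] = None,
):
    """SSQ minimized over a global time-scale factor, plus the best factor.

    Both micro-step rates enter times as ``1/lambda``, so multiplying all
    simulated times by ``s`` is exactly equivalent to dividing lambda1 and
    lambda2 by ``s``.  Profiling ``s`` on the already-simulated mean curve
    therefore searches the (log lambda1, log lambda2) diagonal for free,
    which conditions the GA landscape; the recovered rates are corrected
    by the profiled factor afterwards.
    """
    mean = ensemble_mean_curve(sim_config.replace(mcs=candidate), m_runs, seed=seed)
    if on_fraction is None:
        on_fraction = observed.kind == "fraction"
    if on_fraction:
        obs_vals = observed.fraction_values()
        ref = 1.0 - mean.N / mean.n0
    else:
        obs_vals = observed.N
        ref = mean.N

    def ssq_at(s: float) -> float:
        if mean.meta["truncated"] and observed.t[-1] > s * mean.t[-1]:
            return math.inf
        return float(np.sum((obs_vals - np.interp(observed.t, s * mean.t, ref)) ** 2))

    scales = np.geomspace(0.05, 20.0, 81)
    vals = [ssq_at(s) for s in scales]
    i = int(np.argmin(vals))
    # golden-section refinement in log-space around the grid minimum
    lo = math.log(scales[max(i - 1, 0)])
    hi = math.log(scales[min(i + 1, len(scales) - 1)])
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d_ = b - phi * (b - a), a + phi * (b - a)
    fc, fd = ssq_at(math.exp(c)), ssq_at(math.exp(d_))
    for _ in range(25):
        if fc < fd:
            b, d_, fd = d_, c, fc
            c = b - phi * (b - a)
            fc = ssq_at(math.exp(c))
        else:
            a, c, fc = c, d_, fd
            d_ = a + phi * (b - a)
            fd = ssq_at(math.exp(d_))
    s_best = math.exp((a + b) / 2.0)
    best = ssq_at(s_best)
    if vals[i] < best:
        best, s_best = vals[i], float(scales[i])
    return best, s_best


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclasses.dataclass
class InferenceResult:
    """Best hybrid micro-step parameters found by the GA."""

    best_params: dict
    best_objective: float
    generation_trace: list
    evaluations: int
    seed: int
    best_eval_seed: int
    best_genome: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tournament(rng, scores, k: int) -> int:
    picks = rng.integers(len(scores), size=k)
    return int(picks[np.argmin(scores[picks])])


def infer_mcs(
    observed: ReleaseCurve,
    ga: GAConfig,
    sim_config: SimulationConfig,
    on_fraction: Optional[bool] = None,
) -> InferenceResult:
    """Seeded generational GA over hybrid micro-step parameters.

    Tournament selection, blend crossover, bounded Gaussian mutation, and
    elitism of one.  All candidates are evaluated with common random numbers
    (one fixed evaluation seed for the whole run), which makes the objective
    a deterministic function of the genome: candidates are comparable, the
    elite keeps its score, and the generation trace is non-increasing.
    """
    genes = _gene_spec(ga)
    template = sim_config.mcs if sim_config.mcs.mode == "hybrid" else MCSModel(
        mode="hybrid", nu=1.0, lambda1=1.0, lambda2=1.0,
        A_form="1/k", B_form="k",
    )
    rng = np.random.default_rng(ga.seed)
    lo = np.array([g.lo for g in genes])
    hi = np.array([g.hi for g in genes])
    is_int = np.array([g.integer for g in genes])

    def clip(genome):
        g = np.clip(genome, lo, hi)
        g[is_int] = np.rint(g[is_int])
        return g

    pop = lo + rng.random((ga.population_size, len(genes))) * (hi - lo)
    pop = np.array([clip(g) for g in pop])

    best_obj = math.inf
    best_genome = None
    best_params: dict = {}
    best_eval_seed = -1
    trace = []
    evaluations = 0

    eval_seed = int(
        np.random.SeedSequence([int(ga.seed) & 0xFFFFFFFF, 7919])
        .generate_state(1, np.uint64)[0]
    )
    for gen in range(ga.generations + 1):
        scores = np.empty(ga.population_size)
        for i, genome in enumerate(pop):
            model, time_scale, params = decode_genome(genome, genes, template)
            try:
                if ga.profile_time_scale:
                    scores[i], s_best = _profiled_objective(
                        observed, model, sim_config,
                        m_runs=ga.ensemble_size_per_candidate,
                        seed=eval_seed, on_fraction=on_fraction,
                    )
                    # times scaled by s correspond to rates divided by s
                    params = dict(params)
                    if params.get("lambda1") is not None:
                        params["lambda1"] /= s_best
                    if params.get("lambda2") is not None:
                        params["lambda2"] /= s_best
                    params["time_scale"] = s_best
                else:
                    scores[i] = objective_ssq(
                        observed, model, sim_config,
                        m_runs=ga.ensemble_size_per_candidate,
                        seed=eval_seed, time_scale=time_scale,
                        on_fraction=on_fraction,
                    )
            except (ExtrapolationError, ValueError, OverflowError):
                scores[i] = math.inf
            evaluations += 1
            if scores[i] < best_obj:
                best_obj = float(scores[i])
                best_genome = genome.copy()
                best_params = params
                best_eval_seed = eval_seed
        if not np.any(np.isfinite(scores)):
            raise InferenceError("every candidate in a generation failed to simulate")
        trace.append(best_obj)
        if gen == ga.generations:
            break

        # next generation: elite first, then tournament + BLX-0.5 + mutation.
        # Mutation width anneals so late generations refine the valley floor.
        sigma = ga.mutation_sigma * (hi - lo) * 0.96 ** gen
        children = [best_genome.copy() for _ in range(ga.elitism)]
        while len(children) < ga.population_size:
            p1 = pop[_tournament(rng, scores, ga.tournament_size)]
            p2 = pop[_tournament(rng, scores, ga.tournament_size)]
            if rng.random() < ga.crossover_rate:
                alpha = rng.uniform(-0.5, 1.5, len(genes))
                child = alpha * p1 + (1.0 - alpha) * p2
            else:
                child = p1.copy()
            mutate = rng.random(len(genes)) < ga.mutation_rate
            noise = rng.normal(0.0, sigma)
            child = np.where(mutate, child + noise, child)
            children.append(clip(child))
        pop = np.array(children)

    return InferenceResult(
        best_params=best_params,
        best_objective=best_obj,
        generation_trace=trace,
        evaluations=evaluations,
        seed=int(ga.seed),
        best_eval_seed=best_eval_seed,
        best_genome=list(map(float, best_genome)),
    )


def stochastic_time_share(
    model: MCSModel, sim_config: SimulationConfig, m_runs: int = 10, seed=None
) -> float:
    """Fraction of total simulated time contributed by the noise term.

    Near zero for diffusion-dominated micro-steps, near one for
    erosion-dominated ones — the discrimination statistic behind the
    mechanism-identification claim.
    """
    seeds = spawn_seeds(seed, m_runs)
    det = sto = 0.0
    for s in seeds:
        curve = simulate_release(sim_config.replace(mcs=model, seed=s))
        det += curve.meta["det_time"]
        sto += curve.meta["sto_time"]
    total = det + sto
    if total == 0.0:
        return 0.0
    return sto / total
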