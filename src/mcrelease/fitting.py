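"""Release-model regressions and ensemble summaries.

Three models are fitted to (t, N(t)) release curves:

* Weibull (stretched exponential) ``N(t) = a * exp(-b * t**c)`` by bounded
  nonlinear least squares — the natural fit for diffusion-dominated release;
* linear ``N(t) = a + b * t`` by ordinary least squares — the natural fit
  for erosion-dominated release;
* Higuchi ``released(t) = kH * sqrt(t)`` through the origin.

Each fit reports R-style diagnostics: estimate, standard error, t value,
two-sided p-value, residual standard error on its degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .errors import FitInputError
from .kernel import ReleaseCurve, SimulationConfig, simulate_release

__all__ = [
    "FitResult",
    "EnsembleSummary",
    "fit_weibull",
    "fit_linear",
    "fit_higuchi",
    "run_ensemble",
    "make_synthetic_curve",
]

log = logging.getLogger(__name__)

MODELS = ("weibull", "linear", "higuchi")


@dataclasses.dataclass
class FitResult:
    """Parameter estimates and diagnostics of one release-model regression."""

    model: str
    estimates: dict
    std_errors: dict
    t_values: dict
    p_values: dict
    residual_std_error: float
    degrees_of_freedom: int
    log_likelihood: float
    converged: bool
    n_points: int
    r_squared: Optional[float] = None
    f_statistic_p: Optional[float] = None
    message: str = ""

    def summary(self) -> str:
        """Aligned text table in the style of R's coefficient summary."""
        lines = [
            f"Model: {self.model}   converged: {self.converged}",
            f"{'Parameter':<10}{'Estimate':>14}{'Std. Error':>14}"
            f"{'t value':>12}{'Pr(>|t|)':>14}",
        ]
        for name in self.estimates:
            lines.append(
                f"{name:<10}{self.estimates[name]:>14.5g}"
                f"{self.std_errors[name]:>14.5g}"
                f"{self.t_values[name]:>12.4g}{self.p_values[name]:>14.4g}"
            )
        lines.append(
            f"Residual standard error: {self.residual_std_error:.6g} on "
            f"{self.degrees_of_freedom} degrees of freedom"
        )
        if self.r_squared is not None:
            lines.append(f"R-squared: {self.r_squared:.6g}")
        if self.f_statistic_p is not None:
            lines.append(f"F-statistic p-value: {self.f_statistic_p:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _gaussian_loglik(rss: float, n: int) -> float:
    if rss <= 0 or n == 0:
        return float("inf")
    return -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)


def _diag_tables(names, est, se, dof):
    tvals = {n: (e / s if s > 0 else np.nan) for n, e, s in zip(names, est, se)}
    pvals = {
        n: (2.0 * scipy.stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan)
        for n, t in tvals.items()
    }
    return dict(zip(names, est)), dict(zip(names, se)), tvals, pvals


def _weibull(t, a, b, c):
    return a * np.exp(-b * np.power(t, c))


def fit_weibull(curve: ReleaseCurve, init: Optional[Sequence[float]] = None) -> FitResult:
    """Bounded nonlinear least squares of ``N(t) = a * exp(-b * t**c)``.

    Exact-zero times are dropped (``t**c`` is singular there for c < 0).
    Non-convergence after a restart grid over the shape exponent yields
    ``converged=False`` rather than an exception.
    """
    keep = curve.t > 0
    if not keep.all():
        log.warning("dropping %d exact-zero time point(s) for Weibull fit",
                    int((~keep).sum()))
    t = curve.t[keep]
    y = curve.N[keep]
    if t.size < 4:
        raise FitInputError(f"Weibull fit needs >= 4 positive-time points, got {t.size}")
    names = ("a", "b", "c")
    dof = t.size - 3
    if np.ptp(y) == 0.0:
        # flat curve: b -> 0 leaves the shape exponent unidentifiable
        nan = {n: np.nan for n in names}
        return FitResult("weibull", {"a": float(y[0]), "b": 0.0, "c": np.nan},
                         dict(nan), dict(nan), dict(nan), 0.0, dof, np.inf,
                         converged=False, n_points=t.size,
                         message="constant curve: shape exponent unidentifiable")

    y_scale = float(np.max(np.abs(y))) or 1.0
    a_hi = 10.0 * y_scale
    bounds = ([1e-12, 1e-12, -np.inf], [a_hi, np.inf, np.inf])

    starts = []
    if init is not None:
        starts.append(tuple(init))
    a0 = min(max(float(y[0]), 1e-6), a_hi)
    mid = t.size // 2
    for c0 in (0.7, 0.3, 0.5, 1.0):
        ratio = y[mid] / a0
        b0 = -np.log(ratio) / t[mid] ** c0 if 0 < ratio < 1 else 1.0
        starts.append((a0, max(b0, 1e-6), c0))

    best = None
    for p0 in starts:
        try:
            popt, pcov = scipy.optimize.curve_fit(
                _weibull, t, y, p0=np.clip(p0, bounds[0], bounds[1]),
                bounds=bounds, method="trf", maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _weibull(t, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    if best is None:
        nan = {n: np.nan for n in names}
        return FitResult("weibull", nan, dict(nan), dict(nan), dict(nan),
                         np.nan, dof, np.nan, converged=False,
                         n_points=t.size, message="no optimizer start converged")
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov))
    converged = bool(np.all(np.isfinite(se)))
    est, ses, tvals, pvals = _diag_tables(names, popt, se, dof)
    return FitResult(
        model="weibull", estimates=est, std_errors=ses, t_values=tvals,
        p_values=pvals,
        residual_std_error=float(np.sqrt(rss / dof)) if dof > 0 else np.nan,
        degrees_of_freedom=dof, log_likelihood=_gaussian_loglik(rss, t.size),
        converged=converged, n_points=t.size,
        message="" if converged else "singular covariance: estimates unreliable",
    )


def fit_linear(curve: ReleaseCurve) -> FitResult:
    """Ordinary least squares of ``N(t) = a + b*t`` with full diagnostics."""
    if curve.n_points < 3:
        raise FitInputError(f"linear fit needs >= 3 points, got {curve.n_points}")
    res = sm.OLS(curve.N, sm.add_constant(curve.t)).fit()
    names = ("a", "b")
    est, ses, tvals, pvals = _diag_tables(
        names, res.params, res.bse, int(res.df_resid)
    )
    return FitResult(
        model="linear", estimates=est, std_errors=ses, t_values=tvals,
        p_values=pvals, residual_std_error=float(np.sqrt(res.scale)),
        degrees_of_freedom=int(res.df_resid),
        log_likelihood=float(res.llf), converged=True,
        n_points=curve.n_points, r_squared=float(res.rsquared),
        f_statistic_p=float(res.f_pvalue),
    )


def fit_higuchi(curve: ReleaseCurve, on_fraction: bool = False) -> FitResult:
    """Least squares of released amount (or fraction) = kH * sqrt(t), no intercept."""
    if np.any(curve.t < 0):
        raise FitInputError("Higuchi fit requires non-negative times")
    if curve.n_points < 2:
        raise FitInputError(f"Higuchi fit needs >= 2 points, got {curve.n_points}")
    if curve.kind == "fraction":
        y = curve.N
    elif on_fraction:
        y = curve.fraction_values()
    else:
        y = curve.n0 - curve.N
    x = np.sqrt(curve.t)
    res = sm.OLS(y, x).fit()
    dof = int(res.df_resid)
    est, ses, tvals, pvals = _diag_tables(("kH",), res.params, res.bse, dof)
    rss = float(np.sum(res.resid**2))
    return FitResult(
        model="higuchi", estimates=est, std_errors=ses, t_values=tvals,
        p_values=pvals, residual_std_error=float(np.sqrt(res.scale)),
        degrees_of_freedom=dof, log_likelihood=_gaussian_loglik(rss, curve.n_points),
        converged=True, n_points=curve.n_points,
        r_squared=float(res.rsquared),
    )


_FITTERS = {"weibull": fit_weibull, "linear": fit_linear, "higuchi": fit_higuchi}


def fit_model(curve: ReleaseCurve, model: str, **kw) -> FitResult:
    """Dispatch to the named model's fitting routine."""
    if model not in _FITTERS:
        raise FitInputError(f"unknown model {model!r}; choose from {MODELS}")
    return _FITTERS[model](curve, **kw)


# ---------------------------------------------------------------------------
# ensembles


@dataclasses.dataclass
class EnsembleSummary:
    """Fitted-parameter distributions over replicate simulations."""

    model: str
    n_runs: int
    n_converged: int
    samples: dict  # parameter -> np.ndarray over converged runs
    p_value_samples: dict
    seeds: list

    @property
    def means(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.samples.items()}

    @property
    def sds(self) -> dict:
        return {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for k, v in self.samples.items()}

    @property
    def quartiles(self) -> dict:
        return {k: tuple(np.percentile(v, [25, 50, 75])) for k, v in self.samples.items()}

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{k}": v for k, v in self.samples.items()}
        cols.update({f"p_{k}": v for k, v in self.p_value_samples.items()})
        return pd.DataFrame(cols)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_runs": self.n_runs,
            "n_converged": self.n_converged,
            "means": self.means,
            "sds": self.sds,
            "quartiles": {k: list(v) for k, v in self.quartiles.items()},
        }


def spawn_seeds(seed, n: int) -> list:
    """Deterministic per-run sub-seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, np.uint64)[0]) for child in ss.spawn(n)]


def run_ensemble(
    config: SimulationConfig, n_runs: int, model: str, seed=None
) -> EnsembleSummary:
    """Run replicate simulations, fit each, and pool the parameter samples.

    Non-converged fits are counted and excluded from the summaries.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    if model not in _FITTERS:
        raise FitInputError(f"unknown model {model!r}; choose from {MODELS}")
    seeds = spawn_seeds(seed, n_runs)
    rows: list[FitResult] = []
    for s in seeds:
        curve = simulate_release(config.replace(seed=s))
        rows.append(_FITTERS[model](curve))
    converged = [r for r in rows if r.converged]
    if converged:
        names = list(converged[0].estimates)
        samples = {n: np.array([r.estimates[n] for r in converged]) for n in names}
        pvals = {n: np.array([r.p_values[n] for r in converged]) for n in names}
    else:
        samples, pvals = {}, {}
    return EnsembleSummary(
        model=model, n_runs=n_runs, n_converged=len(converged),
        samples=samples, p_value_samples=pvals, seeds=seeds,
    )


# ---------------------------------------------------------------------------
# synthetic curves

_PARAM_KEYS = {
    "weibull": {"a", "b", "c"},
    "linear": {"a", "b"},
    "higuchi": {"kH", "n0"},
}


def make_synthetic_curve(
    model: str, params: dict, times, noise_sd: float = 0.0, seed=None
) -> ReleaseCurve:
    """Evaluate a release model on a time grid and add Gaussian noise.

    For ``higuchi`` the curve is stored as remaining amount
    ``n0 - kH * sqrt(t)`` so all three models share the (t, N) convention.
    """
    if model not in _PARAM_KEYS:
        raise FitInputError(f"unknown model {model!r}; choose from {MODELS}")
    missing = _PARAM_KEYS[model] - set(params)
    if missing:
        raise FitInputError(f"missing parameter(s) {sorted(missing)} for {model}")
    if noise_sd < 0:
        raise FitInputError(f"noise_sd must be non-negative, got {noise_sd}")
    t = np.asarray(times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise FitInputError("times must be strictly increasing")
    if model == "weibull":
        if params["a"] <= 0 or params["b"] <= 0:
            raise FitInputError("Weibull needs a > 0 and b > 0")
        if params["c"] < 0 and np.any(t == 0):
            raise FitInputError("t = 0 is singular for a negative shape exponent")
        values = _weibull(t, params["a"], params["b"], params["c"])
        n0 = float(params["a"])
    elif model == "linear":
        values = params["a"] + params["b"] * t
        n0 = float(params["a"])
    else:
        if np.any(t < 0):
            raise FitInputError("Higuchi needs non-negative times")
        values = params["n0"] - params["kH"] * np.sqrt(t)
        n0 = float(params["n0"])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=t.shape)
    meta = {"kind": "remaining", "model": model, "params": dict(params),
            "noise_sd": noise_sd, "seed": seed, "synthetic": True}
    return ReleaseCurve(t=t, N=values, n0=n0, meta=meta)
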