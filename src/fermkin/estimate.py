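"""Parameter estimation for the batch kinetic model.

Fits (mu_max, C_Xm, m_S, alpha, beta) to an observed
:class:`~fermkin.model.TimeCourse` by bounded weighted least squares,
with the stoichiometric yield Y_XS held fixed (0.45 g/g by default).
The three state equations are fit jointly: the objective is the sum
over variables of squared residuals, each variable normalized by its
observed range so that glucose (~40 g/L) and DHA (~2.5 g/L) carry
comparable weight.

The optimizer is trust-region-reflective least squares
(:func:`scipy.optimize.least_squares`) restarted from a fixed-seed
Latin-hypercube set of starting points; the best final objective wins,
ties broken by start order, so the whole fit is deterministic for a
given configuration.

Goodness of fit is reported per variable with the statistic

    R² = SSM / (SSM + SSE),
    SSM = Σ(C_cal − C̄_exp)²,  SSE = Σ(C_cal − C_exp)²,

which is bounded in [0, 1] by construction and equals 1 exactly at a
perfect fit.  Note this is *not* the classical coefficient of
determination (the model deviations, not the data deviations, appear
in the numerator).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import (
    CultureState,
    KineticParameters,
    TimeCourse,
    analytic_trajectory,
    logistic_biomass_integral,
    logistic_closed_form,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "MixedGrowthShares",
    "fit_parameters",
    "r_squared",
    "mixed_growth_partition",
]

_FREE = ("mu_max", "C_Xm", "m_S", "alpha", "beta")

#: Default box constraints, generous relative to the fitted strain values.
DEFAULT_BOUNDS = {
    "mu_max": (1e-6, 5.0),   # 1/d
    "C_Xm": (1e-6, 60.0),    # g/L
    "m_S": (0.0, 0.5),       # g/g d
    "alpha": (0.0, 1.0),     # g/g
    "beta": (0.0, 0.5),      # g/g d
}


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one bounded least-squares fit.

    ``bounds``/``guesses`` entries override the defaults per parameter;
    a missing guess is filled from the data (carrying capacity from the
    biomass maximum).  ``weight_mode`` is ``"range"`` (divide each
    variable's residuals by its observed range; default) or ``"none"``.
    ``multistart_count`` Latin-hypercube starts are drawn with
    ``multistart_seed``; the data-driven guess is always tried first.
    """

    bounds: dict = field(default_factory=dict)
    guesses: dict = field(default_factory=dict)
    fix_Y_XS: bool = True
    Y_XS_value: float = 0.45
    weight_mode: str = "range"
    multistart_count: int = 8
    multistart_seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_mode not in ("range", "none"):
            raise ValueError("weight_mode must be 'range' or 'none'")
        if self.multistart_count < 0:
            raise ValueError("multistart_count must be >= 0")
        for name, (lo, hi) in self.resolved_bounds().items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lower < upper")
        for name, g in self.guesses.items():
            lo, hi = self.resolved_bounds()[name]
            if not lo <= g <= hi:
                raise ValueError(f"guess for {name} ({g}) outside bounds [{lo}, {hi}]")

    def resolved_bounds(self) -> dict:
        b = dict(DEFAULT_BOUNDS)
        b.update(self.bounds)
        return b


@dataclass
class FitResult:
    """Outcome of :func:`fit_parameters`."""

    params: KineticParameters
    r2_X: float
    r2_S: float
    r2_P: float
    residuals: np.ndarray       # observed − predicted, one entry per observation
    converged: bool
    objective_value: float      # final weighted sum of squares
    n_obs: int
    objective_trace: np.ndarray  # accepted (improving) objective values, in order
    start_objectives: np.ndarray  # final objective of every multistart

    @property
    def r2_min(self) -> float:
        """The blanket fit quality: the worst of the three per-variable values."""
        return min(self.r2_X, self.r2_S, self.r2_P)


@dataclass(frozen=True)
class MixedGrowthShares:
    """Partition of total product formed into Luedeking–Piret terms."""

    growth_associated: float      # fraction from the alpha·mu·C_X term
    non_growth_associated: float  # fraction from the beta·C_X term
    alpha_dominant: bool          # alpha > beta, the qualitative criterion


def r_squared(predicted, observed) -> float:
    """Goodness-of-fit statistic SSM/(SSM+SSE) in [0, 1] (see module docs)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be nonempty and equal-length")
    ssm = float(np.sum((predicted - observed.mean()) ** 2))
    sse = float(np.sum((predicted - observed) ** 2))
    if ssm + sse == 0.0:
        return 1.0  # constant data predicted exactly
    return ssm / (ssm + sse)


def _initial_state(data: TimeCourse) -> CultureState:
    """First-observation initial state (replicate means at the earliest time)."""
    m = data.replicate_means()
    return CultureState(max(m.X[0], 1e-9), max(m.S[0], 0.0), max(m.P[0], 0.0))


def _predict(theta: np.ndarray, y_xs: float, initial: CultureState, times: np.ndarray):
    p = KineticParameters(
        mu_max=theta[0], C_Xm=theta[1], Y_XS=y_xs, m_S=theta[2], alpha=theta[3], beta=theta[4]
    )
    return analytic_trajectory(initial, p, times)


def fit_parameters(data: TimeCourse, config: FitConfig | None = None) -> FitResult:
    """Jointly fit the five free kinetic parameters to a time course.

    Requires at least 6 distinct sampling times with every variable
    observed at 4 or more of them.  All individual observations
    (replicates included) enter the objective.  Deterministic for a
    fixed configuration.  If no start converges the best candidate is
    still returned with ``converged=False``.
    """
    config = config or FitConfig()
    if data.n_times < 6:
        raise ValueError(f"need >= 6 distinct sampling times, got {data.n_times}")
    for name, arr in (("biomass", data.X), ("glucose", data.S), ("product", data.P)):
        n_ok = np.unique(data.times[~np.isnan(arr)]).size
        if n_ok < 4:
            raise ValueError(f"{name} must be observed at >= 4 times, got {n_ok}")

    y_xs = config.Y_XS_value
    if not config.fix_Y_XS:
        raise NotImplementedError(
            "estimating Y_XS is not supported; fix it at the stoichiometric value"
        )
    initial = _initial_state(data)

    obs = {"X": data.X, "S": data.S, "P": data.P}
    masks = {k: ~np.isnan(v) for k, v in obs.items()}
    if config.weight_mode == "range":
        weights = {}
        for k, v in obs.items():
            rng_v = np.nanmax(v) - np.nanmin(v)
            weights[k] = rng_v if rng_v > 0 else max(np.nanmax(np.abs(v)), 1.0)
    else:
        weights = {k: 1.0 for k in obs}

    trace: list[float] = []

    def residual_vector(theta: np.ndarray) -> np.ndarray:
        X, S, P = _predict(theta, y_xs, initial, data.times)
        parts = [
            (pred[masks[k]] - obs[k][masks[k]]) / weights[k]
            for k, pred in (("X", X), ("S", S), ("P", P))
        ]
        r = np.concatenate(parts)
        cost = float(r @ r)
        if not trace or cost < trace[-1]:
            trace.append(cost)
        return r

    bounds = config.resolved_bounds()
    lo = np.array([bounds[n][0] for n in _FREE])
    hi = np.array([bounds[n][1] for n in _FREE])

    # data-driven first start, then the Latin-hypercube multistart set
    guess = {
        "mu_max": 1.0,
        "C_Xm": float(np.clip(1.05 * np.nanmax(data.X), lo[1], hi[1])),
        "m_S": 0.01,
        "alpha": 0.05,
        "beta": 0.01,
    }
    guess.update(config.guesses)
    starts = [np.array([guess[n] for n in _FREE])]
    if config.multistart_count:
        sampler = qmc.LatinHypercube(d=len(_FREE), seed=config.multistart_seed)
        unit = sampler.random(config.multistart_count)
        starts.extend(qmc.scale(unit, lo, hi))

    best = None
    start_objectives = []
    for x0 in starts:
        sol = least_squares(residual_vector, x0, bounds=(lo, hi), method="trf", x_scale="jac")
        start_objectives.append(float(sol.cost * 2))  # scipy cost = 0.5 * sum(r^2)
        if best is None or sol.cost < best.cost:  # strict: ties keep the earlier start
            best = sol

    theta = best.x
    params = KineticParameters(
        mu_max=float(theta[0]),
        C_Xm=float(theta[1]),
        Y_XS=y_xs,
        m_S=float(theta[2]),
        alpha=float(theta[3]),
        beta=float(theta[4]),
    )
    X, S, P = _predict(theta, y_xs, initial, data.times)
    r2 = {
        k: r_squared(pred[masks[k]], obs[k][masks[k]])
        for k, pred in (("X", X), ("S", S), ("P", P))
    }
    observed_minus_pred = np.concatenate(
        [obs[k][masks[k]] - pred[masks[k]] for k, pred in (("X", X), ("S", S), ("P", P))]
    )
    return FitResult(
        params=params,
        r2_X=r2["X"],
        r2_S=r2["S"],
        r2_P=r2["P"],
        residuals=observed_minus_pred,
        converged=bool(best.status > 0),
        objective_value=float(best.cost * 2),
        n_obs=int(sum(m.sum() for m in masks.values())),
        objective_trace=np.array(trace),
        start_objectives=np.array(start_objectives),
    )


def mixed_growth_partition(result: FitResult, trajectory: TimeCourse) -> MixedGrowthShares:
    """Split total product formed over a trajectory into its two sources.

    Integrates the growth-associated rate alpha·mu·C_X (which equals
    alpha·dC_X/dt, hence alpha·ΔC_X in closed form) and the
    non-growth-associated rate beta·C_X over [t_first, t_last] of the
    trajectory, using the fitted parameters and the trajectory's
    initial biomass.  Shares sum to 1 whenever any product is formed.
    """
    p = result.params
    means = trajectory.replicate_means()
    x0 = float(means.X[0])
    span = float(means.times[-1] - means.times[0])
    dx = logistic_closed_form(span, x0, p) - x0
    integral = logistic_biomass_integral(span, x0, p)
    growth = p.alpha * dx
    non_growth = p.beta * integral
    total = growth + non_growth
    if total <= 0:
        return MixedGrowthShares(0.0, 0.0, p.alpha > p.beta)
    return MixedGrowthShares(growth / total, non_growth / total, p.alpha > p.beta)
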