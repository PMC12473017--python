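"""Kinetic model of batch DHA fermentation.

The model couples three state variables, all in g/L:

* ``C_X`` — biomass dry cell weight (DCW),
* ``C_S`` — residual glucose,
* ``C_P`` — DHA titer,

through three ordinary differential equations (time in days):

.. math::

    \\frac{dC_X}{dt} &= \\mu C_X, \\qquad
        \\mu = \\mu_{max}\\left(1 - \\frac{C_X}{C_{Xm}}\\right) \\\\
    \\frac{dC_S}{dt} &= -\\frac{1}{Y_{X/S}}\\frac{dC_X}{dt} - m_S C_X \\\\
    \\frac{dC_P}{dt} &= (\\alpha\\mu + \\beta) C_X

Growth is logistic (density-limited by the carrying capacity ``C_Xm``,
not substrate-limited), glucose is consumed stoichiometrically for
growth plus a maintenance drain ``m_S``, and product formation follows
the Luedeking–Piret law with a growth-associated coefficient ``alpha``
and a non-growth-associated coefficient ``beta``.

Because biomass growth is decoupled from the other two states, the
whole system has a closed-form solution (`logistic_closed_form`,
`logistic_biomass_integral`, `analytic_trajectory`) which serves both
as the oracle for the numerical integrator and as a fast exact
predictor for parameter estimation.

Substrate exhaustion convention: the published equations let ``C_S``
go negative once glucose runs out (growth saturates through ``C_Xm``
only).  We clamp: ``dC_S/dt`` is forced to 0 once ``C_S`` reaches 0;
the growth and product equations are untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KineticParameters",
    "CultureState",
    "TimeCourse",
    "specific_growth_rate",
    "model_rhs",
    "logistic_closed_form",
    "logistic_biomass_integral",
    "analytic_trajectory",
]


@dataclass(frozen=True)
class KineticParameters:
    """The six constants of the batch kinetic model.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate, 1/day.  Must be > 0.
    C_Xm : float
        Carrying-capacity (maximum) biomass concentration, g/L.  > 0.
    Y_XS : float
        Stoichiometric biomass yield on glucose, g/g, in (0, 1].
        Fixed at 0.45 g/g for *A. limacinum* on glucose (from the
        elemental biomass formula); held constant during fitting by
        default.
    m_S : float
        Maintenance coefficient, g glucose/(g DCW · day).  >= 0.
    alpha : float
        Growth-associated product coefficient, g product/g DCW.  >= 0.
    beta : float
        Non-growth-associated product coefficient,
        g product/(g DCW · day).  >= 0.
    """

    mu_max: float
    C_Xm: float
    Y_XS: float = 0.45
    m_S: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not self.C_Xm > 0:
            raise ValueError(f"C_Xm must be > 0, got {self.C_Xm}")
        if not 0 < self.Y_XS <= 1:
            raise ValueError(f"Y_XS must be in (0, 1], got {self.Y_XS}")
        for name in ("m_S", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class CultureState:
    """Instantaneous culture composition (all g/L, all non-negative)."""

    C_X: float  # biomass dry cell weight
    C_S: float  # glucose
    C_P: float  # DHA

    def __post_init__(self) -> None:
        for name in ("C_X", "C_S", "C_P"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.C_X, self.C_S, self.C_P], dtype=float)


@dataclass
class TimeCourse:
    """A sampled fermentation trajectory, possibly with replicates.

    One entry per observation.  ``times`` are in days and must be
    strictly increasing *within each replicate*; observations are kept
    sorted by (time, replicate).  Missing observations are NaN.
    """

    times: np.ndarray
    X: np.ndarray
    S: np.ndarray
    P: np.ndarray
    replicate: np.ndarray = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        n = self.times.size
        if self.replicate is None:
            self.replicate = np.zeros(n, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        for name in ("X", "S", "P", "replicate"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have the same length as times ({n})")
        if n == 0:
            raise ValueError("TimeCourse must contain at least one observation")
        if self.times[0] < 0:
            raise ValueError("times must be >= 0")
        order = np.lexsort((self.replicate, self.times))
        for name in ("times", "X", "S", "P", "replicate"):
            setattr(self, name, getattr(self, name)[order])
        for r in np.unique(self.replicate):
            t_r = self.times[self.replicate == r]
            if np.any(np.diff(t_r) <= 0):
                raise ValueError(f"times must be strictly increasing within replicate {r}")
        for name in ("X", "S", "P"):
            v = getattr(self, name)
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError(f"{name} contains negative concentrations")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_times(self) -> int:
        return np.unique(self.times).size

    def state_at(self, i: int) -> CultureState:
        return CultureState(self.X[i], self.S[i], self.P[i])

    def replicate_means(self) -> "TimeCourse":
        """Average replicates at each sampling time (NaN-aware)."""
        t_unique = np.unique(self.times)
        cols = []
        for arr in (self.X, self.S, self.P):
            cols.append(
                np.array(
                    [
                        np.nanmean(arr[self.times == t])
                        if np.any(~np.isnan(arr[self.times == t]))
                        else np.nan
                        for t in t_unique
                    ]
                )
            )
        return TimeCourse(t_unique, cols[0], cols[1], cols[2], label=self.label)


def specific_growth_rate(C_X, params: KineticParameters):
    """Instantaneous specific growth rate µ = µ_max·(1 − C_X/C_Xm), 1/day.

    Affine-decreasing in biomass: µ(0) = µ_max, µ(C_Xm) = 0.  Negative
    above the carrying capacity (overshoot self-corrects; no clamp).
    """
    C_X = np.asarray(C_X, dtype=float)
    if np.any(C_X < 0):
        raise ValueError("C_X must be >= 0")
    mu = params.mu_max * (1.0 - C_X / params.C_Xm)
    return float(mu) if mu.ndim == 0 else mu


def model_rhs(state, params: KineticParameters):
    """Right-hand side (dC_X/dt, dC_S/dt, dC_P/dt) in g/(L·day).

    Accepts a `CultureState` or any length-3 sequence (C_X, C_S, C_P).
    The system is autonomous.  When glucose is exhausted (C_S <= 0 and
    the raw consumption rate is negative) dC_S/dt is clamped to 0.
    """
    if isinstance(state, CultureState):
        C_X, C_S, _ = state.C_X, state.C_S, state.C_P
    else:
        C_X, C_S, _ = float(state[0]), float(state[1]), float(state[2])
    mu = params.mu_max * (1.0 - C_X / params.C_Xm)
    dX = mu * C_X
    dS = -dX / params.Y_XS - params.m_S * C_X
    if C_S <= 0.0 and dS < 0.0:
        dS = 0.0
    dP = (params.alpha * mu + params.beta) * C_X
    return (dX, dS, dP)


def logistic_closed_form(t, C_X0: float, params: KineticParameters):
    """Exact logistic biomass C_X(t) from inoculum C_X0 (g/L).

    C_X(t) = C_Xm / (1 + ((C_Xm − C_X0)/C_X0)·e^{−µ_max t}); written in
    decaying-exponential form so large t cannot overflow.  Valid for
    any C_X0 > 0 (including above C_Xm, where the trajectory relaxes
    back down to the carrying capacity).
    """
    if C_X0 <= 0:
        raise ValueError(f"C_X0 must be > 0, got {C_X0}")
    t = np.asarray(t, dtype=float)
    a = (params.C_Xm - C_X0) / C_X0
    x = params.C_Xm / (1.0 + a * np.exp(-params.mu_max * t))
    return float(x) if x.ndim == 0 else x


def logistic_biomass_integral(t, C_X0: float, params: KineticParameters):
    """Cumulative biomass-time integral ∫₀ᵗ C_X(τ) dτ in g·day/L.

    Closed form for the logistic solution:
    (C_Xm/µ_max)·[µ_max t + ln((C_X0 + (C_Xm−C_X0)e^{−µ_max t})/C_Xm)],
    used for exact substrate and product balances.
    """
    if C_X0 <= 0:
        raise ValueError(f"C_X0 must be > 0, got {C_X0}")
    t = np.asarray(t, dtype=float)
    mu, cm = params.mu_max, params.C_Xm
    val = (cm / mu) * (mu * t + np.log((C_X0 + (cm - C_X0) * np.exp(-mu * t)) / cm))
    return float(val) if val.ndim == 0 else val


def analytic_trajectory(
    initial: CultureState, params: KineticParameters, times
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact model solution (C_X, C_S, C_P) on a time grid.

    Uses the logistic closed form and its time integral:

    * C_S(t) = C_S0 − (C_X(t) − C_X0)/Y_XS − m_S·∫C_X,
      clamped to 0 from the first sampled time at which the raw
      balance crosses zero (once exhausted, glucose stays at 0);
    * C_P(t) = C_P0 + α·(C_X(t) − C_X0) + β·∫C_X.

    Exact for the clamped system as long as the raw substrate balance
    is monotone between samples (always true for C_X0 < C_Xm).
    """
    times = np.asarray(times, dtype=float)
    X = logistic_closed_form(times, initial.C_X, params)
    I = logistic_biomass_integral(times, initial.C_X, params)
    dX = X - initial.C_X
    S_raw = initial.C_S - dX / params.Y_XS - params.m_S * I
    exhausted = np.maximum.accumulate(S_raw <= 0.0)
    S = np.where(exhausted, 0.0, S_raw)
    P = initial.C_P + params.alpha * dX + params.beta * I
    return np.atleast_1d(X), np.atleast_1d(S), np.atleast_1d(P)
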