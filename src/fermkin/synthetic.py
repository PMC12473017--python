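"""Synthetic shake-flask time courses.

Stands in for measured 5-day shake-flask data: simulates the noise-free
model trajectory for a named scenario and overlays independent Gaussian
measurement noise per variable, truncated at zero.  The three built-in
scenarios carry the fitted parameter columns for the native,
acid-tolerant (BBF001) and acid/temperature-tolerant (BBF002) strains
of *Aurantiochytrium limacinum* grown at pH 4.5 and 30 °C.

Noise model: for each variable the standard deviation at an observation
is ``max(CV · value, floor)`` — multiplicative assay error with an
absolute floor.  CV defaults of 5 % mirror typical DCW / HPLC / GC
precision; the true measurement error of the original assays is not
recoverable, so these are documented assumptions, not estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import CultureState, KineticParameters, TimeCourse
from .simulate import SimulationSpec, simulate

__all__ = ["NoiseSpec", "Scenario", "SCENARIO_NAMES", "builtin_scenario", "generate"]

#: Fitted parameter columns (mu_max 1/d, C_Xm g/L, Y_XS g/g, m_S g/g d,
#: alpha g/g, beta g/g d) for the three strains at pH 4.5, 30 degC.
_TABLE = {
    "native": KineticParameters(1.568, 12.934, 0.45, 0.005, 0.100, 0.001),
    "BBF001": KineticParameters(1.585, 17.866, 0.45, 0.024, 0.033, 0.029),
    "BBF002": KineticParameters(1.617, 19.891, 0.45, 0.033, 0.055, 0.020),
}
SCENARIO_NAMES = tuple(_TABLE)

#: Default initial state: 40 g/L glucose from the production medium;
#: biomass/product carryover of a 10 % (v/v) inoculum (not published,
#: config-exposed everywhere it is used).
DEFAULT_INITIAL = CultureState(C_X=0.6, C_S=40.0, C_P=0.02)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description for one generated data set.

    ``cv_*`` are per-variable coefficients of variation (dimensionless),
    ``floor_sd_*`` absolute noise floors in g/L.  One root ``seed``
    feeds three per-variable child streams derived deterministically,
    so identical seeds give bit-identical tables.
    """

    cv_X: float = 0.05
    cv_S: float = 0.05
    cv_P: float = 0.05
    floor_sd_X: float = 0.0
    floor_sd_S: float = 0.0
    floor_sd_P: float = 0.0
    seed: int = 0
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("cv_X", "cv_S", "cv_P", "floor_sd_X", "floor_sd_S", "floor_sd_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """A named (parameters, initial state, sampling grid) triple."""

    name: str
    params: KineticParameters
    initial: CultureState = DEFAULT_INITIAL
    sample_times: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = self.sample_times
        if t is None:
            t = np.arange(0.0, 6.0)  # daily sampling over the 5-day cultivation
        object.__setattr__(self, "sample_times", np.asarray(t, dtype=float))

    def replace(self, **changes) -> "Scenario":
        return replace(self, **changes)


def builtin_scenario(name: str) -> Scenario:
    """Return a built-in strain scenario (``native``, ``BBF001``, ``BBF002``)."""
    try:
        params = _TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose one of {', '.join(SCENARIO_NAMES)}"
        ) from None
    return Scenario(name=name, params=params)


def generate(scenario: Scenario, noise: NoiseSpec) -> TimeCourse:
    """Simulate the scenario and overlay replicated measurement noise.

    Each variable gets independent Gaussian noise with standard
    deviation ``max(CV · value, floor)``, truncated at 0.  Replicate
    indices are recorded per observation.  With all CVs and floors at
    zero and a single replicate the output equals the noise-free
    trajectory exactly.
    """
    clean = simulate(
        SimulationSpec(scenario.initial, scenario.params, scenario.sample_times),
        label=scenario.name,
    )
    n_t, n_r = len(clean), noise.replicates
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(noise.seed).spawn(3)]

    times = np.repeat(clean.times, n_r)
    reps = np.tile(np.arange(n_r), n_t)
    noisy = []
    specs = [
        (clean.X, noise.cv_X, noise.floor_sd_X),
        (clean.S, noise.cv_S, noise.floor_sd_S),
        (clean.P, noise.cv_P, noise.floor_sd_P),
    ]
    for rng, (values, cv, floor) in zip(streams, specs):
        sd = np.maximum(cv * values, floor)  # per-time SD, shared by replicates
        draws = values[:, None] + sd[:, None] * rng.standard_normal((n_t, n_r))
        noisy.append(np.maximum(draws, 0.0).ravel())

    return TimeCourse(times, *noisy, replicate=reps, label=scenario.name)
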