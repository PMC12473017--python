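"""Endpoint kinetic descriptors of a fermentation run.

Over a window (t1, t2) taken from the sampled grid — by convention from
inoculation to the time of maximum product titer — the panel comprises

* volumetric rates, g/(L·d):
  Q_X = ΔC_X/Δt (biomass), Q_S = −ΔC_S/Δt (glucose consumption),
  Q_P = ΔC_P/Δt (product);
* the specific growth rate µ = Q_X / mean(C_X,1, C_X,2), 1/d;
* observed yields, g/g: Y_X/S = ΔC_X/(−ΔC_S), Y_P/S = ΔC_P/(−ΔC_S).

These are finite-difference endpoint quantities, computed from sampled
values only (no interpolation: requesting an off-grid time is an
error).  Replicates are averaged per time point before differencing;
per-replicate panels are available for spread reporting.  When no
glucose is consumed over the window the yields are undefined (NaN);
the rates are still returned.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import TimeCourse

__all__ = ["DescriptorPanel", "compute_descriptors", "per_replicate_panels", "pick_window"]


@dataclass(frozen=True)
class DescriptorPanel:
    """The endpoint rate/yield panel over a window (units in field names)."""

    Q_X: float       # biomass production rate, g/(L d)
    Q_S: float       # glucose consumption rate, g/(L d)
    Q_P: float       # product (DHA) production rate, g/(L d)
    mu: float        # specific growth rate, 1/d
    Y_XS_obs: float  # observed biomass yield, g/g (NaN if no consumption)
    Y_PS_obs: float  # observed product yield, g/g (NaN if no consumption)
    window: tuple    # (t1, t2), days

    def as_dict(self) -> dict:
        return {
            "Q_X": self.Q_X,
            "Q_S": self.Q_S,
            "Q_P": self.Q_P,
            "mu": self.mu,
            "Y_XS_obs": self.Y_XS_obs,
            "Y_PS_obs": self.Y_PS_obs,
            "t1": self.window[0],
            "t2": self.window[1],
        }


def pick_window(data: TimeCourse) -> tuple[float, float]:
    """Default window: first sampled time to the time of maximum product.

    Ties in the product maximum resolve to the earliest such time, so a
    flat product trace gives a zero-length window starting and ending
    at the first sample.
    """
    m = data.replicate_means()
    t2 = float(m.times[int(np.nanargmax(m.P))])
    return float(m.times[0]), t2


def _index_of(times: np.ndarray, t: float, what: str) -> int:
    hit = np.flatnonzero(np.isclose(times, t, rtol=0, atol=1e-9))
    if hit.size == 0:
        nearest = times[np.argsort(np.abs(times - t))[:2]]
        raise ValueError(
            f"{what} = {t:g} d is not a sampled time; nearest available: "
            + ", ".join(f"{v:g}" for v in sorted(nearest))
        )
    return int(hit[0])


def _panel(times, X, S, P, t1: float, t2: float) -> DescriptorPanel:
    i1, i2 = _index_of(times, t1, "t1"), _index_of(times, t2, "t2")
    if not t2 > t1:
        raise ValueError(f"window must have t2 > t1, got ({t1}, {t2})")
    dt = times[i2] - times[i1]
    dX, dS, dP = X[i2] - X[i1], S[i2] - S[i1], P[i2] - P[i1]
    q_x, q_s, q_p = dX / dt, -dS / dt, dP / dt
    mu = q_x / ((X[i1] + X[i2]) / 2.0)
    if -dS > 0:
        y_xs, y_ps = dX / -dS, dP / -dS
    else:
        y_xs = y_ps = math.nan
    return DescriptorPanel(q_x, q_s, q_p, mu, y_xs, y_ps, (float(t1), float(t2)))


def compute_descriptors(
    data: TimeCourse, t1: float | None = None, t2: float | None = None
) -> DescriptorPanel:
    """Compute the endpoint panel on replicate-mean values.

    ``t1``/``t2`` default to :func:`pick_window`.  Both must be sampled
    times of the trajectory.
    """
    if t1 is None or t2 is None:
        auto = pick_window(data)
        t1 = auto[0] if t1 is None else t1
        t2 = auto[1] if t2 is None else t2
    m = data.replicate_means()
    return _panel(m.times, m.X, m.S, m.P, t1, t2)


def per_replicate_panels(
    data: TimeCourse, t1: float | None = None, t2: float | None = None
) -> dict[int, DescriptorPanel]:
    """One panel per replicate, for mean-with-SD style reporting."""
    if t1 is None or t2 is None:
        auto = pick_window(data)
        t1 = auto[0] if t1 is None else t1
        t2 = auto[1] if t2 is None else t2
    out = {}
    for r in np.unique(data.replicate):
        sel = data.replicate == r
        out[int(r)] = _panel(data.times[sel], data.X[sel], data.S[sel], data.P[sel], t1, t2)
    return out
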