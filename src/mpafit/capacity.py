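"""Carrying-capacity estimates and recovery-time summaries.

The capacity of a selected saturating fit is its asymptote K; a Ricker
fit yields its peak instead; linear/exponential fits yield an explicit
"no finite capacity" record.  When the early, well-enforced part of a
series grows exponentially while the whole period saturates, the
exponential trend can be projected to the study's end horizon to bound
what the capacity might have been without the mid-series disturbance
(``exponential_projection``); such values are labelled as projections,
never as asymptotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy.optimize import brentq

from .fitting import GrowthFit, SelectionResult
from .models import GrowthModelSpec, asymptote, evaluate

__all__ = [
    "CapacityEstimate",
    "capacity_from_fit",
    "exponential_projection",
    "time_to_fraction",
]

#: Default fraction of the asymptote defining "time to carrying capacity".
CAPACITY_FRACTION = 0.95

#: Default projection horizon: the full 23-year study span (t = 23).
DEFAULT_HORIZON = 23.0

SATURATING_FAMILIES = ("logistic", "asymptotic", "von_bertalanffy", "gompertz")


@dataclass(frozen=True)
class CapacityEstimate:
    """Carrying capacity (or peak / projection) for one analysis cell."""

    descriptor: str
    variable: str
    period: str
    method: str  # asymptote | peak | exponential_projection | none
    value: float | None
    time_to_95pct: float | None
    provenance: GrowthModelSpec | None

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "variable": self.variable,
            "period": self.period,
            "method": self.method,
            "value": self.value,
            "time_to_95pct": self.time_to_95pct,
            "family": self.provenance.family if self.provenance else None,
            "params": dict(self.provenance.params) if self.provenance else None,
        }


def capacity_from_fit(
    selection: SelectionResult | GrowthFit,
    descriptor: str = "",
    variable: str = "",
    period: str = "",
    fraction: float = CAPACITY_FRACTION,
) -> CapacityEstimate:
    """Capacity estimate implied by a selected fit.

    Saturating families map their asymptote K to ``method='asymptote'``
    with the time to reach ``fraction`` of K; Ricker maps its analytic
    peak to ``method='peak'``; unbounded families yield an explicit
    record with ``method='none'`` and no value.
    """
    fitted = selection.selected if isinstance(selection, SelectionResult) else selection
    if not fitted.converged or fitted.spec is None:
        raise ValueError("selected fit did not converge")
    asym = asymptote(fitted.spec)
    if asym.kind == "carrying_capacity":
        try:
            t95 = time_to_fraction(fitted.spec, fraction)
        except ValueError:
            t95 = None
        return CapacityEstimate(
            descriptor, variable, period, "asymptote", asym.value, t95, fitted.spec
        )
    if asym.kind == "peak":
        return CapacityEstimate(
            descriptor, variable, period, "peak", asym.value, None, fitted.spec
        )
    if asym.kind == "constant":
        return CapacityEstimate(
            descriptor, variable, period, "constant", asym.value, None, fitted.spec
        )
    return CapacityEstimate(
        descriptor, variable, period, "none", None, None, fitted.spec
    )


def exponential_projection(
    first_period_fit: GrowthFit,
    t_end: float = DEFAULT_HORIZON,
    descriptor: str = "",
    variable: str = "",
) -> CapacityEstimate:
    """Project a first-period exponential trend to the study horizon.

    value = a * exp(b * t_end).  Requires a converged exponential fit
    with positive growth rate b; the result is an interpretation of what
    the series could have reached, flagged by its method label.
    """
    if first_period_fit.spec is None or first_period_fit.family != "exponential":
        raise ValueError("projection requires an exponential fit")
    if not first_period_fit.converged:
        raise ValueError("projection requires a converged fit")
    a = first_period_fit.spec.params["a"]
    b = first_period_fit.spec.params["b"]
    if b <= 0:
        raise ValueError(f"no growth to project (b = {b})")
    return CapacityEstimate(
        descriptor,
        variable,
        "first",
        "exponential_projection",
        a * math.exp(b * t_end),
        None,
        first_period_fit.spec,
    )


def time_to_fraction(spec: GrowthModelSpec, fraction: float) -> float:
    """Smallest t >= 0 with y(t) >= fraction * K for a saturating curve.

    Closed form for logistic and asymptotic, numerical root-finding
    (tolerance 1e-6 years) for von Bertalanffy and Gompertz.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if spec.family not in SATURATING_FAMILIES:
        raise ValueError(f"{spec.family} does not saturate")
    p: Mapping[str, float] = spec.params
    K = p["K"]

    if spec.family == "logistic":
        N0, r = p["N0"], p["r"]
        if r <= 0 or not 0 < N0 < K:
            raise ValueError("logistic must be growing (0 < N0 < K, r > 0)")
        if fraction <= N0 / K:
            return 0.0
        return math.log(((K - N0) / N0) * (fraction / (1.0 - fraction))) / r

    if spec.family == "asymptotic":
        N0, r = p["N0"], p["r"]
        if r <= 0 or N0 >= K:
            raise ValueError("asymptotic must be growing (N0 < K, r > 0)")
        if fraction * K <= N0:
            return 0.0
        return math.log((K - N0) / (K * (1.0 - fraction))) / r

    # von Bertalanffy / Gompertz: bisection on y(t) - fraction*K
    target = fraction * K

    def g(t: float) -> float:
        return float(evaluate(spec, [t])[0]) - target

    if g(0.0) >= 0:
        return 0.0
    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("curve does not reach the target fraction")
    return float(brentq(g, 0.0, hi, xtol=1e-6))
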