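"""The seven population-growth curve families.

Each family is an evaluable parametric curve y(t) with asymptote
semantics used to derive carrying capacities:

========================  =======================================  ==========
family                    equation                                 parameters
========================  =======================================  ==========
linear                    y = a + m*t                              a, m
exponential               y = a * exp(b*t)                         a, b
von_bertalanffy           y = K * (1 - exp(-r*(t - t0)))           K, r, t0
logistic                  y = K / (1 + ((K - N0)/N0) * exp(-r*t))  K, N0, r
asymptotic                y = K + (N0 - K) * exp(-r*t)             K, N0, r
gompertz                  y = K * exp(b * exp(r*t))                K, b, r
ricker                    y = N0 + (a*t) * exp(-b*t)               N0, a, b
========================  =======================================  ==========

The saturating families (von Bertalanffy, logistic, asymptotic, and
Gompertz with r < 0) approach the carrying capacity K; Ricker reaches a
peak N0 + (a/b)/e at t = 1/b; linear and exponential growth is
unbounded.  Gompertz only saturates at K when r < 0 (then exp(r*t) -> 0
and y -> K), which is the sign convention enforced at fitting time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "FAMILIES",
    "GrowthModelSpec",
    "Asymptote",
    "evaluate",
    "asymptote",
    "initial_guess",
]


def _linear(t, a, m):
    return a + m * t


def _exponential(t, a, b):
    return a * np.exp(b * t)


def _von_bertalanffy(t, K, r, t0):
    return K * (1.0 - np.exp(-r * (t - t0)))


def _logistic(t, K, N0, r):
    if N0 == 0:
        raise ValueError("logistic requires N0 != 0 (division by zero)")
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def _asymptotic(t, K, N0, r):
    return K + (N0 - K) * np.exp(-r * t)


def _gompertz(t, K, b, r):
    return K * np.exp(b * np.exp(r * t))


def _ricker(t, N0, a, b):
    return N0 + (a * t) * np.exp(-b * t)


# analytic jacobians (d y / d theta), column order = param order


def _linear_jac(t, a, m):
    return np.column_stack([np.ones_like(t), t])


def _exponential_jac(t, a, b):
    e = np.exp(b * t)
    return np.column_stack([e, a * t * e])


def _von_bertalanffy_jac(t, K, r, t0):
    e = np.exp(-r * (t - t0))
    return np.column_stack([1.0 - e, K * (t - t0) * e, -K * r * e])


def _logistic_jac(t, K, N0, r):
    e = np.exp(-r * t)
    C = (K - N0) / N0
    D = 1.0 + C * e
    return np.column_stack(
        [
            1.0 / D - K * e / (N0 * D**2),
            K**2 * e / (N0**2 * D**2),
            K * C * t * e / D**2,
        ]
    )


def _asymptotic_jac(t, K, N0, r):
    e = np.exp(-r * t)
    return np.column_stack([1.0 - e, e, (K - N0) * t * e])


def _gompertz_jac(t, K, b, r):
    E = np.exp(r * t)
    y = K * np.exp(b * E)
    return np.column_stack([np.exp(b * E), y * E, y * b * E * t])


def _ricker_jac(t, N0, a, b):
    e = np.exp(-b * t)
    return np.column_stack([np.ones_like(t), t * e, -a * t**2 * e])


@dataclass(frozen=True)
class ModelFamily:
    name: str
    param_names: tuple[str, ...]
    fn: Callable[..., np.ndarray]
    #: analytic jacobian d y / d theta, shape (n_times, n_params)
    jac: Callable[..., np.ndarray]
    #: box constraints used during fitting, keyed by parameter name
    lower: Mapping[str, float]
    upper: Mapping[str, float]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


_EPS = 1e-8

#: Fitted yearly rates are boxed to |rate| <= 3 per year: e**3 ~ 20-fold
#: change per year already far exceeds any plausible fish-assemblage
#: dynamic, and the bound keeps the exponentials float-safe and the
#: least-squares surface smooth.
_RATE_MAX = 3.0

FAMILIES: dict[str, ModelFamily] = {
    f.name: f
    for f in (
        ModelFamily("linear", ("a", "m"), _linear, _linear_jac, {}, {}),
        ModelFamily("exponential", ("a", "b"), _exponential, _exponential_jac,
                    {"b": -_RATE_MAX}, {"b": _RATE_MAX}),
        ModelFamily("von_bertalanffy", ("K", "r", "t0"), _von_bertalanffy,
                    _von_bertalanffy_jac,
                    {"r": -_RATE_MAX}, {"r": _RATE_MAX}),
        ModelFamily(
            "logistic", ("K", "N0", "r"), _logistic, _logistic_jac,
            {"K": _EPS, "N0": _EPS, "r": -_RATE_MAX}, {"r": _RATE_MAX},
        ),
        ModelFamily("asymptotic", ("K", "N0", "r"), _asymptotic,
                    _asymptotic_jac,
                    {"r": -_RATE_MAX}, {"r": _RATE_MAX}),
        # r < 0 so that y -> K as t -> inf (saturating sign convention)
        ModelFamily("gompertz", ("K", "b", "r"), _gompertz, _gompertz_jac,
                    {"K": _EPS, "b": -50.0, "r": -_RATE_MAX},
                    {"b": 50.0, "r": -_EPS}),
        ModelFamily("ricker", ("N0", "a", "b"), _ricker, _ricker_jac,
                    {"b": -_RATE_MAX}, {"b": _RATE_MAX}),
    )
}


@dataclass(frozen=True)
class GrowthModelSpec:
    """A growth-model family with a concrete parameter vector."""

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        fam = FAMILIES.get(self.family)
        if fam is None:
            raise ValueError(
                f"unknown family {self.family!r}; known: {sorted(FAMILIES)}"
            )
        missing = set(fam.param_names) - set(self.params)
        extra = set(self.params) - set(fam.param_names)
        if missing or extra:
            raise ValueError(
                f"{self.family} expects parameters {fam.param_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )

    @property
    def n_params(self) -> int:
        return FAMILIES[self.family].n_params

    def param_vector(self) -> np.ndarray:
        fam = FAMILIES[self.family]
        return np.array([self.params[p] for p in fam.param_names], dtype=float)


def evaluate(spec: GrowthModelSpec, t: Sequence[float] | np.ndarray) -> np.ndarray:
    """Evaluate the family's curve at times ``t``."""
    fam = FAMILIES[spec.family]
    t = np.asarray(t, dtype=float)
    return np.asarray(fam.fn(t, *(spec.params[p] for p in fam.param_names)))


@dataclass(frozen=True)
class Asymptote:
    """Long-run level of a growth curve.

    ``kind`` is one of carrying_capacity (saturating approach to K),
    peak (Ricker interior maximum), unbounded, or constant.  ``t_at``
    is the time of the peak for Ricker, None otherwise.
    """

    value: float | None
    kind: str
    t_at: float | None = None


def asymptote(spec: GrowthModelSpec) -> Asymptote:
    """Long-run level implied by the fitted parameters.

    For the K-parameterised saturating families the value is the K
    parameter itself (meaningful when the fitted growth rate is
    positive, i.e. the series actually approaches K).
    """
    p = spec.params
    fam = spec.family
    if fam in ("logistic", "asymptotic", "von_bertalanffy"):
        return Asymptote(float(p["K"]), "carrying_capacity")
    if fam == "gompertz":
        if p["r"] < 0:
            return Asymptote(float(p["K"]), "carrying_capacity")
        warnings.warn(
            "gompertz with r >= 0 does not saturate; reporting unbounded",
            stacklevel=2,
        )
        return Asymptote(None, "unbounded")
    if fam == "ricker":
        a, b, N0 = p["a"], p["b"], p["N0"]
        if a == 0:
            return Asymptote(float(N0), "constant")
        if b <= 0:
            return Asymptote(None, "unbounded")
        if a < 0:
            # dips below N0 and returns to it; supremum is the start value
            return Asymptote(float(N0), "peak", t_at=0.0)
        return Asymptote(float(N0 + (a / b) * math.exp(-1.0)), "peak", t_at=1.0 / b)
    if fam == "exponential":
        a, b = p["a"], p["b"]
        if b == 0:
            return Asymptote(float(a), "constant")
        if b < 0:
            return Asymptote(0.0, "constant")
        return Asymptote(None, "unbounded")
    if fam == "linear":
        if p["m"] == 0:
            return Asymptote(float(p["a"]), "constant")
        return Asymptote(None, "unbounded")
    raise ValueError(f"unknown family {fam!r}")


#: Documented constants used when data-driven guesses are unavailable
#: (e.g. log-based guesses on non-positive values).
_FALLBACK_RATE = {"exponential": 0.1, "von_bertalanffy": 0.3,
                  "logistic": 0.5, "asymptotic": 0.3, "gompertz": -0.3}


def _ols_slope_intercept(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def initial_guess(
    family: str, t: Sequence[float], y: Sequence[float]
) -> dict[str, float]:
    """Data-driven start values for nonlinear fitting.

    Raises ValueError when a family needs a positive level (logistic,
    gompertz) and the series has none.
    """
    fam = FAMILIES[family]
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < fam.n_params + 1:
        raise ValueError(
            f"need at least {fam.n_params + 1} points to seed a "
            f"{family} fit, got {len(t)}"
        )

    ymax = float(y.max())
    K0 = 1.05 * ymax
    pos = y > 0
    first_pos = float(y[pos][0]) if pos.any() else None

    if family == "linear":
        m0, a0 = _ols_slope_intercept(t, y)
        return {"a": a0, "m": m0}

    if family == "exponential":
        if pos.sum() >= 2:
            b0, loga0 = _ols_slope_intercept(t[pos], np.log(y[pos]))
            return {"a": math.exp(loga0), "b": b0}
        return {"a": first_pos if first_pos else 1.0,
                "b": _FALLBACK_RATE["exponential"]}

    if family == "von_bertalanffy":
        inside = (y > 0) & (y < K0)
        if inside.sum() >= 2:
            slope, _ = _ols_slope_intercept(t[inside], np.log(1.0 - y[inside] / K0))
            r0 = -slope if slope < 0 else _FALLBACK_RATE["von_bertalanffy"]
        else:
            r0 = _FALLBACK_RATE["von_bertalanffy"]
        return {"K": K0 if K0 > 0 else 1.0, "r": r0, "t0": 0.0}

    if family == "logistic":
        if first_pos is None:
            raise ValueError("logistic guess needs a positive value (N0 > 0)")
        inside = (y > 0) & (y < K0)
        if inside.sum() >= 2:
            slope, _ = _ols_slope_intercept(
                t[inside], np.log(y[inside] / (K0 - y[inside]))
            )
            r0 = slope if slope != 0 else _FALLBACK_RATE["logistic"]
        else:
            r0 = _FALLBACK_RATE["logistic"]
        return {"K": K0, "N0": first_pos, "r": r0}

    if family == "asymptotic":
        return {"K": K0 if K0 != 0 else 1.0, "N0": float(y[0]),
                "r": _FALLBACK_RATE["asymptotic"]}

    if family == "gompertz":
        if first_pos is None or K0 <= 0:
            raise ValueError("gompertz guess needs a positive value")
        b0 = math.log(min(first_pos / K0, 1.0 - 1e-6))
        return {"K": K0, "b": b0, "r": _FALLBACK_RATE["gompertz"]}

    if family == "ricker":
        if len(t) >= 2 and t[1] != t[0]:
            a0 = float((y[1] - y[0]) / (t[1] - t[0]))
        else:
            a0 = 0.1
        t_at_max = float(t[int(np.argmax(y))])
        b0 = 1.0 / t_at_max if t_at_max > 0 else 1.0
        return {"N0": float(y[0]), "a": a0 if a0 != 0 else 0.1, "b": b0}

    raise ValueError(f"unknown family {family!r}")
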