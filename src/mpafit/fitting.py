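"""Nonlinear least-squares fitting of growth curves and AICc selection.

Each candidate family is fitted to a yearly-mean series by minimising
the residual sum of squares with a multi-start trust-region solver
(data-driven initial guess plus seeded, jittered restarts).  Candidate
fits are ranked by AICc in its least-squares form

    AICc = n*ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),

with k counting the curve parameters plus the error variance.  Models
within 2 AICc units of the best are treated as equivalently supported,
and among those the fit with the greatest nonlinear R^2
(R^2 = 1 - RSS/SStot) is selected; remaining ties go to the lower AICc,
then to the fewer-parameter model.

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and compose
with sklearn tooling; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import FAMILIES, GrowthModelSpec, evaluate, initial_guess

__all__ = [
    "GrowthFit",
    "SelectionResult",
    "FitConfig",
    "GrowthCurveRegressor",
    "GrowthModelSelector",
    "fit",
    "fit_all",
    "aicc",
    "r_squared",
    "select",
    "InsufficientDataError",
]

#: Fits whose AICc differs from the best by no more than this are
#: considered equivalently supported.
AICC_EQUIVALENCE_DELTA = 2.0


class InsufficientDataError(ValueError):
    """Too few points to fit a family (need n >= n_params + 2)."""


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike criterion, least-squares form.

    ``k`` must already include the error-variance parameter.  A perfect
    fit (rss = 0) returns ``-inf`` so it ranks first.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n - k - 1 < 1:
        raise ValueError(
            f"AICc undefined for n={n}, k={k} (need n - k - 1 >= 1)"
        )
    if rss == 0:
        return float("-inf")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def r_squared(rss: float, sstot: float) -> float | None:
    """Nonlinear R^2 = 1 - RSS/SStot; None when SStot is 0 (undefined)."""
    if rss < 0 or sstot < 0:
        raise ValueError("sums of squares must be non-negative")
    if sstot == 0:
        return None
    return 1.0 - rss / sstot


@dataclass(frozen=True)
class GrowthFit:
    """One fitted growth model and its selection statistics."""

    spec: GrowthModelSpec | None
    rss: float
    n: int
    k: int  # parameters counted in AICc (curve params + error variance)
    aicc: float
    r2: float | None
    converged: bool
    n_restarts_used: int = 0
    status: str = "ok"  # ok | insufficient_data | failed
    perfect_fit: bool = False

    @property
    def family(self) -> str | None:
        return self.spec.family if self.spec is not None else None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.spec.params) if self.spec else None,
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "aicc": self.aicc,
            "r2": self.r2,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "status": self.status,
            "perfect_fit": self.perfect_fit,
        }


@dataclass(frozen=True)
class SelectionResult:
    """Ranked fits with the supported model under the AICc + R^2 rule."""

    fits: tuple[GrowthFit, ...]  # rankable fits sorted by AICc
    selected: GrowthFit
    equivalent_set: tuple[GrowthFit, ...]
    selection_rule_applied: str  # lowest_aicc | tiebreak_r2
    excluded: tuple[GrowthFit, ...] = ()  # non-converged / insufficient data

    def to_dict(self) -> dict:
        best = self.fits[0].aicc

        def delta(a: float) -> float:
            return 0.0 if a == best else a - best  # -inf best handled

        return {
            "selected_family": self.selected.family,
            "selection_rule_applied": self.selection_rule_applied,
            "fits": [
                {**f.to_dict(), "delta_aicc": delta(f.aicc)} for f in self.fits
            ],
            "equivalent_families": [f.family for f in self.equivalent_set],
            "excluded": [f.to_dict() for f in self.excluded],
        }


@dataclass(frozen=True)
class FitConfig:
    """Options controlling the nonlinear fits."""

    n_restarts: int = 20
    jitter: float = 0.5
    seed: int | None = None
    weighted: bool = False  # inverse-variance weighting by SE (off: the
    # analysis fits unweighted yearly means)
    max_nfev: int | None = None


def _as_time_vector(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2:
        if t.shape[1] != 1:
            raise ValueError("expected a single time feature")
        t = t[:, 0]
    elif t.ndim != 1:
        raise ValueError("time input must be 1-D or a single column")
    return t


class GrowthCurveRegressor(RegressorMixin, BaseEstimator):
    """Fit one growth-curve family to (time, response) data.

    Parameters
    ----------
    family : str
        One of the seven registered families.
    n_restarts : int
        Maximum number of jittered restarts after the data-driven guess.
    jitter : float
        Relative scale of the multiplicative jitter applied to start values.
    random_state : int or None
        Seed for the restart generator.
    max_nfev : int or None
        Cap on function evaluations per solver run.
    restart_patience : int
        Stop restarting after this many consecutive restarts without a
        meaningful RSS improvement (relative 1e-6); ``n_restarts`` stays
        the hard cap.
    """

    def __init__(
        self,
        family: str = "logistic",
        n_restarts: int = 20,
        jitter: float = 0.5,
        random_state: int | None = None,
        max_nfev: int | None = None,
        restart_patience: int = 5,
    ):
        self.family = family
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.random_state = random_state
        self.max_nfev = max_nfev
        self.restart_patience = restart_patience

    # -- internals ---------------------------------------------------

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        fam = FAMILIES[self.family]
        lo = np.array([fam.lower.get(p, -np.inf) for p in fam.param_names])
        hi = np.array([fam.upper.get(p, np.inf) for p in fam.param_names])
        return lo, hi

    def _residual_fn(self, t: np.ndarray, y: np.ndarray, sw: np.ndarray):
        fam = FAMILIES[self.family]
        root_w = np.sqrt(sw)

        def resid(theta: np.ndarray) -> np.ndarray:
            with np.errstate(over="ignore", invalid="ignore"):
                pred = fam.fn(t, *theta)
            r = (pred - y) * root_w
            return np.nan_to_num(r, nan=1e8, posinf=1e8, neginf=-1e8)

        def jac(theta: np.ndarray) -> np.ndarray:
            with np.errstate(over="ignore", invalid="ignore"):
                J = fam.jac(t, *theta) * root_w[:, None]
            return np.nan_to_num(J, nan=0.0, posinf=1e8, neginf=-1e8)

        return resid, jac

    def _start_points(
        self, t: np.ndarray, y: np.ndarray, lo: np.ndarray, hi: np.ndarray
    ) -> Iterable[np.ndarray]:
        fam = FAMILIES[self.family]
        try:
            guess = initial_guess(self.family, t, y)
            theta0 = np.array([guess[p] for p in fam.param_names])
        except ValueError:
            theta0 = np.ones(fam.n_params)
        rng = np.random.default_rng(self.random_state)
        yield np.clip(theta0, lo + 1e-10, hi - 1e-10)
        scale = np.maximum(np.abs(theta0), 1.0)
        for i in range(self.n_restarts):
            z = rng.standard_normal(fam.n_params)
            if i % 2 == 0:  # local jitter around the data-driven guess
                theta = np.where(
                    theta0 != 0,
                    theta0 * (1.0 + self.jitter * z),
                    self.jitter * z,
                )
            else:  # global exploration, covers sign flips of theta0
                theta = scale * z * (1.0 + self.jitter)
            yield np.clip(theta, lo + 1e-10, hi - 1e-10)

    # -- sklearn API --------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        fam = FAMILIES.get(self.family)
        if fam is None:
            raise ValueError(f"unknown family {self.family!r}")
        t = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("time and response lengths differ")
        n = len(y)
        k = fam.n_params + 1  # + error variance
        if n < fam.n_params + 2:
            raise InsufficientDataError(
                f"{self.family}: need at least {fam.n_params + 2} points "
                f"for AICc, got {n}"
            )
        sw = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        lo, hi = self._bounds()
        resid, jac = self._residual_fn(t, y, sw)
        max_nfev = self.max_nfev if self.max_nfev is not None else 100

        best_theta, best_rss = None, np.inf
        any_success = False
        used = 0
        stale = 0
        for i, theta0 in enumerate(self._start_points(t, y, lo, hi)):
            try:
                with np.errstate(over="ignore", invalid="ignore"):
                    res = least_squares(
                        resid,
                        theta0,
                        jac=jac,
                        bounds=(lo, hi),
                        method="trf",
                        x_scale="jac",
                        max_nfev=max_nfev,
                    )
            except (ValueError, FloatingPointError):
                continue
            if not np.all(np.isfinite(res.x)) or not np.isfinite(res.cost):
                continue
            # status 0 (iteration budget) still yields a valid candidate
            # point; only solver-converged runs mark the fit as converged
            any_success = any_success or res.success
            rss = float(np.sum(resid(res.x) ** 2))
            if rss < best_rss * (1.0 - 1e-6):
                best_theta, best_rss = res.x, rss
                used = i
                stale = 0
            else:
                stale += 1
                if best_theta is not None and stale >= self.restart_patience:
                    break
        mean_w = float(np.average(y, weights=sw))
        sstot = float(np.sum(sw * (y - mean_w) ** 2))

        self.n_features_in_ = 1
        self.n_ = n
        self.k_ = k
        self.sstot_ = sstot
        self.n_restarts_used_ = used
        if best_theta is None:
            self.converged_ = False
            self.spec_ = None
            self.params_ = None
            self.rss_ = float("inf")
            self.aicc_ = float("inf")
            self.r2_ = None
            self.perfect_fit_ = False
            return self

        self.converged_ = True
        self.solver_success_ = any_success  # False: best point hit the
        # iteration budget on every restart (flat-ridge geometries)
        params = dict(zip(fam.param_names, (float(v) for v in best_theta)))
        self.spec_ = GrowthModelSpec(self.family, params)
        self.params_ = params
        perfect = best_rss <= max(1e-300, 1e-12 * sstot)
        self.rss_ = 0.0 if perfect else best_rss
        self.perfect_fit_ = perfect
        # with n = n_params + 2 the AICc small-sample correction is
        # undefined (denominator 0); the fit stands but cannot be ranked
        # by AICc and selection falls back to R^2
        self.aicc_ = aicc(self.rss_, n, k) if n - k - 1 >= 1 else float("nan")
        if sstot == 0:  # constant response: R^2 undefined
            self.r2_ = None
        else:
            self.r2_ = 1.0 if perfect else r_squared(best_rss, sstot)
        return self

    def predict(self, X):
        check_is_fitted(self, "spec_")
        if self.spec_ is None:
            raise ValueError("no converged fit available")
        return evaluate(self.spec_, _as_time_vector(X))

    def result_(self) -> GrowthFit:
        """Fitted state as an immutable :class:`GrowthFit` record."""
        check_is_fitted(self, "converged_")
        return GrowthFit(
            spec=self.spec_,
            rss=self.rss_,
            n=self.n_,
            k=self.k_,
            aicc=self.aicc_,
            r2=self.r2_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            status="ok" if self.converged_ else "failed",
            perfect_fit=self.perfect_fit_,
        )


def _r2_key(f: GrowthFit) -> float:
    return f.r2 if f.r2 is not None else float("-inf")


def select(fits: Sequence[GrowthFit]) -> SelectionResult:
    """Apply the AICc + equivalence + greatest-R^2 selection rule.

    Only converged fits with defined AICc are ranked; the rest are
    carried in ``excluded``.  Invariant to input ordering.
    """
    converged = [f for f in fits if f.converged and f.status == "ok"]
    rankable = [f for f in converged if not math.isnan(f.aicc)]
    excluded = tuple(
        f
        for f in fits
        if not (f.converged and f.status == "ok") or math.isnan(f.aicc)
    )
    if not converged:
        raise ValueError("no converged fit to select from")
    if not rankable:
        # series too short for the AICc correction (n = k + 1 for every
        # candidate): rank by R^2 alone
        ranked = sorted(
            converged,
            key=lambda f: (-_r2_key(f), f.k, f.rss, f.family or ""),
        )
        return SelectionResult(
            fits=tuple(ranked),
            selected=ranked[0],
            equivalent_set=tuple(ranked),
            selection_rule_applied="greatest_r2_only",
            excluded=tuple(
                f for f in fits if id(f) not in {id(c) for c in converged}
            ),
        )
    ranked = sorted(rankable, key=lambda f: (f.aicc, f.k, f.family or ""))
    best = ranked[0]
    if math.isinf(best.aicc):  # perfect fits win outright
        equivalent = [f for f in ranked if math.isinf(f.aicc)]
    else:
        equivalent = [
            f for f in ranked if f.aicc - best.aicc <= AICC_EQUIVALENCE_DELTA
        ]
    # greatest R^2; ties -> lower AICc -> fewer parameters -> name
    chosen = sorted(
        equivalent,
        key=lambda f: (-_r2_key(f), f.aicc, f.k, f.family or ""),
    )[0]
    rule = "lowest_aicc" if chosen is best else "tiebreak_r2"
    return SelectionResult(
        fits=tuple(ranked),
        selected=chosen,
        equivalent_set=tuple(equivalent),
        selection_rule_applied=rule,
        excluded=excluded,
    )


class GrowthModelSelector(RegressorMixin, BaseEstimator):
    """Fit every candidate family and select the supported model.

    ``predict`` evaluates the selected model.  Fitted attributes:
    ``fits_`` (ranked), ``selected_``, ``equivalent_set_``,
    ``selection_`` (the full :class:`SelectionResult`).
    """

    def __init__(
        self,
        families: tuple[str, ...] | None = None,
        n_restarts: int = 20,
        jitter: float = 0.5,
        random_state: int | None = None,
        max_nfev: int | None = None,
    ):
        self.families = families
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.random_state = random_state
        self.max_nfev = max_nfev

    def fit(self, X, y, sample_weight=None):
        families = tuple(self.families) if self.families else tuple(FAMILIES)
        seeds = np.random.SeedSequence(self.random_state).spawn(len(families))
        results: list[GrowthFit] = []
        for fam_name, ss in zip(families, seeds):
            reg = GrowthCurveRegressor(
                family=fam_name,
                n_restarts=self.n_restarts,
                jitter=self.jitter,
                random_state=int(ss.generate_state(1)[0] % (2**31)),
                max_nfev=self.max_nfev,
            )
            try:
                reg.fit(X, y, sample_weight=sample_weight)
                results.append(reg.result_())
            except InsufficientDataError:
                fam = FAMILIES[fam_name]
                results.append(
                    GrowthFit(
                        spec=GrowthModelSpec(
                            fam_name, {p: float("nan") for p in fam.param_names}
                        ),
                        rss=float("nan"),
                        n=len(np.asarray(y)),
                        k=fam.n_params + 1,
                        aicc=float("nan"),
                        r2=None,
                        converged=False,
                        status="insufficient_data",
                    )
                )
        self.selection_ = select(results)
        self.fits_ = self.selection_.fits
        self.selected_ = self.selection_.selected
        self.equivalent_set_ = self.selection_.equivalent_set
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "selected_")
        return evaluate(self.selected_.spec, _as_time_vector(X))


# -- functional wrappers ----------------------------------------------


def fit(
    family: str,
    t: Sequence[float],
    y: Sequence[float],
    config: FitConfig = FitConfig(),
    se: Sequence[float] | None = None,
) -> GrowthFit:
    """Fit one family to a series; insufficient data yields a structured
    non-converged result instead of an exception."""
    fam = FAMILIES[family]
    sample_weight = None
    if config.weighted and se is not None:
        se = np.asarray(se, dtype=float)
        sample_weight = 1.0 / np.clip(se, max(se[se > 0].min(), 1e-12), None) ** 2
    reg = GrowthCurveRegressor(
        family=family,
        n_restarts=config.n_restarts,
        jitter=config.jitter,
        random_state=config.seed,
        max_nfev=config.max_nfev,
    )
    try:
        reg.fit(np.asarray(t, dtype=float), y, sample_weight=sample_weight)
    except InsufficientDataError:
        return GrowthFit(
            spec=GrowthModelSpec(family, {p: float("nan") for p in fam.param_names}),
            rss=float("nan"),
            n=len(np.asarray(y)),
            k=fam.n_params + 1,
            aicc=float("nan"),
            r2=None,
            converged=False,
            status="insufficient_data",
        )
    return reg.result_()


def fit_all(
    t: Sequence[float],
    y: Sequence[float],
    config: FitConfig = FitConfig(),
    families: Sequence[str] | None = None,
    se: Sequence[float] | None = None,
) -> SelectionResult:
    """Fit all families and select the supported model."""
    sel = GrowthModelSelector(
        families=tuple(families) if families else None,
        n_restarts=config.n_restarts,
        jitter=config.jitter,
        random_state=config.seed,
        max_nfev=config.max_nfev,
    )
    sample_weight = None
    if config.weighted and se is not None:
        se = np.asarray(se, dtype=float)
        sample_weight = 1.0 / np.clip(se, max(se[se > 0].min(), 1e-12), None) ** 2
    sel.fit(np.asarray(t, dtype=float), y, sample_weight=sample_weight)
    return sel.selection_
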