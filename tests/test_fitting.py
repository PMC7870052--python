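"""Nonlinear fitting, AICc and the selection rule."""

import math

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from mpafit.fitting import (
    FitConfig,
    GrowthCurveRegressor,
    GrowthFit,
    GrowthModelSelector,
    InsufficientDataError,
    aicc,
    fit,
    fit_all,
    r_squared,
    select,
)
from mpafit.models import GrowthModelSpec, evaluate

# ---------------------------------------------------------------- aicc


def test_aicc_hand_arithmetic():
    # rss = n*e so the log term is exactly 1: 19 + 6 + 24/15 = 26.6
    n, k = 19, 3
    assert aicc(n * math.e, n, k) == pytest.approx(19 + 6 + 24 / 15, rel=1e-12)
    assert aicc(n * math.e, n, k) == pytest.approx(26.6, rel=1e-12)


def test_aicc_doubling_identity():
    base = aicc(10.0, 19, 4)
    assert aicc(20.0, 19, 4) - base == pytest.approx(19 * math.log(2), rel=1e-12)


def test_aicc_edge_cases():
    assert aicc(0.0, 19, 3) == float("-inf")
    with pytest.raises(ValueError):
        aicc(1.0, 4, 4)  # n - k - 1 < 1
    with pytest.raises(ValueError):
        aicc(-1.0, 19, 3)


def test_r_squared():
    assert r_squared(0.0, 50.0) == 1.0
    assert r_squared(50.0, 50.0) == 0.0
    assert r_squared(25.0, 100.0) == 0.75
    assert r_squared(1.0, 0.0) is None
    with pytest.raises(ValueError):
        r_squared(-1.0, 1.0)


# ---------------------------------------------------------------- select


def _mk(family, aicc_val, r2, converged=True, status="ok", k=4):
    params = {p: 1.0 for p in
              {"linear": ("a", "m"), "exponential": ("a", "b"),
               "logistic": ("K", "N0", "r"),
               "asymptotic": ("K", "N0", "r")}[family]}
    return GrowthFit(
        spec=GrowthModelSpec(family, params),
        rss=1.0, n=19, k=k, aicc=aicc_val, r2=r2,
        converged=converged, status=status,
    )


def test_select_lowest_aicc():
    res = select([_mk("linear", 10.0, 0.9), _mk("exponential", 13.0, 0.95)])
    assert res.selected.family == "linear"
    assert res.selection_rule_applied == "lowest_aicc"
    assert [f.family for f in res.equivalent_set] == ["linear"]


def test_select_tiebreak_r2():
    res = select([_mk("linear", 10.0, 0.60), _mk("exponential", 11.5, 0.70)])
    assert res.selected.family == "exponential"
    assert res.selection_rule_applied == "tiebreak_r2"
    assert {f.family for f in res.equivalent_set} == {"linear", "exponential"}


def test_select_r2_tie_broken_by_lower_aicc():
    res = select([_mk("linear", 10.0, 0.70), _mk("exponential", 11.9, 0.70)])
    assert res.selected.family == "linear"
    assert res.selection_rule_applied == "lowest_aicc"


def test_select_invariant_to_ordering():
    fits = [_mk("linear", 10.0, 0.60), _mk("exponential", 11.5, 0.70),
            _mk("logistic", 30.0, 0.99), _mk("asymptotic", 11.0, 0.65)]
    results = [select(order) for order in (fits, fits[::-1],
                                           fits[2:] + fits[:2])]
    assert len({r.selected.family for r in results}) == 1
    assert len({tuple(f.family for f in r.fits) for r in results}) == 1


def test_select_excludes_non_converged():
    bad = _mk("logistic", float("nan"), None, converged=False, status="failed")
    res = select([_mk("linear", 10.0, 0.9), bad])
    assert res.selected.family == "linear"
    assert [f.family for f in res.excluded] == ["logistic"]
    with pytest.raises(ValueError):
        select([bad])


def test_select_invariants():
    res = select([_mk("linear", 10.0, 0.60), _mk("exponential", 11.5, 0.70),
                  _mk("asymptotic", 11.0, 0.65)])
    assert res.selected in res.equivalent_set
    best_r2 = max(f.r2 for f in res.equivalent_set)
    assert res.selected.r2 == best_r2


def test_select_r2_only_fallback():
    # every candidate has undefined AICc (n = k + 1): rank by R^2 alone
    fits = [
        GrowthFit(spec=GrowthModelSpec("linear", {"a": 1, "m": 1}),
                  rss=2.0, n=4, k=3, aicc=float("nan"), r2=0.8, converged=True),
        GrowthFit(spec=GrowthModelSpec("logistic", {"K": 1, "N0": 1, "r": 1}),
                  rss=1.0, n=4, k=4, aicc=float("nan"), r2=0.9, converged=True),
    ]
    res = select(fits)
    assert res.selection_rule_applied == "greatest_r2_only"
    assert res.selected.family == "logistic"


# ---------------------------------------------------------------- fitting


def test_noiseless_logistic_recovery():
    t = np.arange(1, 20, dtype=float)
    y = evaluate(GrowthModelSpec("logistic", {"K": 100, "N0": 10, "r": 0.5}), t)
    res = fit("logistic", t, y, FitConfig(seed=0))
    assert res.converged
    assert res.spec.params["K"] == pytest.approx(100, rel=1e-3)
    assert res.rss < 1e-10
    assert res.perfect_fit
    assert res.aicc == float("-inf")
    assert res.r2 == 1.0


def test_constant_series_linear():
    t = np.arange(1, 8, dtype=float)
    res = fit("linear", t, np.full(7, 7.0), FitConfig(seed=0))
    assert res.spec.params["a"] == pytest.approx(7, abs=1e-6)
    assert res.spec.params["m"] == pytest.approx(0, abs=1e-8)
    assert res.rss == 0.0
    assert res.r2 is None  # sstot = 0: undefined


def test_insufficient_data_structured():
    res = fit("logistic", [1, 2, 3], [1, 2, 3], FitConfig(seed=0))
    assert not res.converged
    assert res.status == "insufficient_data"
    with pytest.raises(InsufficientDataError):
        GrowthCurveRegressor(family="logistic").fit([1, 2, 3], [1, 2, 3])


def test_vb_asymptotic_rss_equivalence():
    rng = np.random.default_rng(11)
    t = np.arange(1, 20, dtype=float)
    mu = evaluate(GrowthModelSpec("asymptotic", {"K": 80, "N0": 5, "r": 0.25}), t)
    y = mu * np.exp(0.05 * rng.standard_normal(len(t)))
    vb = fit("von_bertalanffy", t, y, FitConfig(seed=1))
    asym = fit("asymptotic", t, y, FitConfig(seed=1))
    assert vb.converged and asym.converged
    assert vb.rss == pytest.approx(asym.rss, rel=1e-8)


def test_grid_search_oracle():
    # exponential fit beats (or matches within 1%) a brute-force RSS grid
    rng = np.random.default_rng(5)
    for trial in range(30):
        t = np.arange(1, 11, dtype=float)
        a_true = rng.uniform(1, 10)
        b_true = rng.uniform(-0.3, 0.3)
        y = a_true * np.exp(b_true * t) * np.exp(
            0.1 * rng.standard_normal(len(t))
        )
        res = fit("exponential", t, y, FitConfig(seed=trial))
        a_grid = np.linspace(0.2 * a_true, 3 * a_true, 60)
        b_grid = np.linspace(-0.6, 0.6, 60)
        pred = a_grid[:, None, None] * np.exp(b_grid[None, :, None] * t)
        grid_best = float(((pred - y) ** 2).sum(axis=2).min())
        assert res.rss <= grid_best * 1.01


def test_fit_all_selects_logistic_on_clean_data():
    t = np.arange(1, 20, dtype=float)
    rng = np.random.default_rng(4)
    mu = evaluate(GrowthModelSpec("logistic", {"K": 100, "N0": 10, "r": 0.5}), t)
    y = mu * np.exp(0.05 * rng.standard_normal(len(t)))
    sel = fit_all(t, y, FitConfig(seed=4))
    families = {f.family for f in sel.equivalent_set} | {sel.selected.family}
    assert "logistic" in families


def test_selector_deterministic():
    t = np.arange(1, 20, dtype=float)
    rng = np.random.default_rng(9)
    y = 10 * np.exp(0.1 * t) * np.exp(0.05 * rng.standard_normal(len(t)))
    s1 = fit_all(t, y, FitConfig(seed=123))
    s2 = fit_all(t, y, FitConfig(seed=123))
    assert s1.to_dict() == s2.to_dict()


def test_sklearn_conventions():
    reg = GrowthCurveRegressor(family="exponential", random_state=0)
    assert reg.get_params()["family"] == "exponential"
    reg2 = clone(reg).set_params(family="linear")
    assert reg2.get_params()["family"] == "linear"
    with pytest.raises(NotFittedError):
        reg.predict([[1.0]])
    t = np.arange(1, 10, dtype=float)
    y = 2 * np.exp(0.2 * t)
    reg.fit(t.reshape(-1, 1), y)
    pred = reg.predict(t.reshape(-1, 1))
    assert np.allclose(pred, y, rtol=1e-6)
    assert reg.score(t.reshape(-1, 1), y) > 0.999

    sel = GrowthModelSelector(random_state=0).fit(t, y)
    assert sel.selected_.family == "exponential"
    assert np.allclose(sel.predict(t), y, rtol=1e-4)


def test_weighted_fit_option():
    t = np.arange(1, 12, dtype=float)
    y = 3 + 2 * t
    y_noisy = y.copy()
    y_noisy[-1] += 30  # outlier with huge SE
    se = np.ones(len(t))
    se[-1] = 100.0
    unweighted = fit("linear", t, y_noisy, FitConfig(seed=0))
    weighted = fit("linear", t, y_noisy, FitConfig(seed=0, weighted=True), se=se)
    assert abs(weighted.spec.params["m"] - 2) < abs(
        unweighted.spec.params["m"] - 2
    )
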