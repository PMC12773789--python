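"""Balancing weights: GPS density ratio, entropy balancing, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import NonlinearConstraint, minimize

from econunpred.balancing import (
    CONFOUNDER_COLUMNS,
    BalanceResult,
    constrained_balance_weights,
    effective_sample_size,
    encode_confounders,
    gps_weights,
    select_method,
    weighted_correlation,
)
from econunpred.simulate import simulate_linear_confounding


def test_encoding_is_fifteen_columns_with_reference_dropped():
    raw = pd.DataFrame(
        {
            "family_id": ["a", "b"],
            "education": ["assoc_degree", "postgrad"],
            "income_fpl": ["fpl_200_400", "fpl_le_200"],
            "race_ethnicity": ["asian", "white"],
            "child_age": [2.0, 4.0],
            "child_disability": ["no", "yes"],
            "child_health": [3.0, 4.5],
        }
    )
    enc = encode_confounders(raw)
    cols = [c for c in enc.columns if c != "family_id"]
    assert cols == list(CONFOUNDER_COLUMNS)
    assert len(cols) == 15
    # reference-level row encodes to all-zero dummies
    a = enc.set_index("family_id").loc["a"]
    assert a[[c for c in cols if c.startswith(("education", "income", "race"))]].sum() == 0


def test_ess_hand_formula():
    assert effective_sample_size([1.0, 1.0, 2.0]) == pytest.approx(16 / 6)
    assert effective_sample_size(np.ones(50)) == pytest.approx(50)


def test_weighted_correlation_two_routes_agree(rng):
    x, y = rng.normal(size=(2, 200))
    w = rng.uniform(0.2, 3.0, 200)
    direct = weighted_correlation(x, y, w)
    # independent route: weighted regression slope on weighted-standardized data
    mx, my = np.average(x, weights=w), np.average(y, weights=w)
    sx = np.sqrt(np.average((x - mx) ** 2, weights=w))
    sy = np.sqrt(np.average((y - my) ** 2, weights=w))
    slope = np.sum(w * (x - mx) / sx * (y - my) / sy) / np.sum(w * ((x - mx) / sx) ** 2)
    assert direct == pytest.approx(slope, abs=1e-10)


def test_independent_exposure_gives_unit_gps_weights(rng):
    """With exposure independent of the confounders the density ratio is
    1 in the population; estimated weights sit near 1 (tail deviations
    reflect the estimated conditional mean) and the ESS stays near n."""
    d = simulate_linear_confounding(2000, rng, r2=0.3)
    exposure = rng.normal(size=2000)  # independent of X
    res = gps_weights(exposure, d["X"])
    assert np.median(np.abs(res.weights - 1.0)) < 0.1
    assert res.ess > 0.97 * 2000


def test_exactly_balanced_data_gives_uniform_entropy_weights(rng):
    """Uniform weights are feasible (hence entropy-optimal) when the
    sample cross-moments are exactly zero; construct such data by
    residualizing every confounder on the exposure."""
    n = 400
    exposure = rng.normal(size=n)
    X = rng.normal(size=(n, 5))
    ec = exposure - exposure.mean()
    for j in range(X.shape[1]):
        xc = X[:, j] - X[:, j].mean()
        X[:, j] = xc - ec * (ec @ xc) / (ec @ ec)  # sample cov with e is 0
    res = constrained_balance_weights(exposure, pd.DataFrame(X, columns=[f"x{j}" for j in range(5)]))
    p = res.weights / res.weights.sum()
    kl = float(np.sum(p * np.log(p * len(p))))
    assert kl < 1e-6


def test_entropy_balancing_zeroes_weighted_correlations():
    for seed in (0, 1, 2):
        d = simulate_linear_confounding(500, seed)
        res = constrained_balance_weights(d["exposure"], d["X"])
        assert res.max_abs_post_corr <= 0.01
        assert res.pre_corr.abs().max() > 0.1  # there was imbalance to remove
        assert np.all(res.weights > 0)
        assert res.ess <= 500


def test_entropy_dual_matches_generic_constrained_solver(rng):
    """Primal objective from the dual solution agrees with SLSQP on the
    explicit constrained problem (small instances, few confounders)."""
    for seed in range(3):
        r = np.random.default_rng(seed)
        n = 50
        z = r.normal(size=n)
        X = pd.DataFrame({f"x{j}": 0.5 * z + r.normal(0, 0.8, n) for j in range(3)})
        e = 0.5 * z + r.normal(0, 0.8, n)
        res = constrained_balance_weights(e, X)
        obj_dual = float(np.sum(res.weights * np.log(res.weights)))

        Xv = X.to_numpy()

        def constraints(w):
            out = [w.sum() - n, np.average(e, weights=w) - e.mean()]
            for j in range(Xv.shape[1]):
                out.append(np.average(Xv[:, j], weights=w) - Xv[:, j].mean())
                out.append(np.average((e - e.mean()) * (Xv[:, j] - Xv[:, j].mean()), weights=w))
            return np.array(out)

        sol = minimize(
            lambda w: np.sum(w * np.log(np.maximum(w, 1e-12))),
            np.ones(n),
            jac=lambda w: np.log(np.maximum(w, 1e-12)) + 1,
            constraints=[NonlinearConstraint(constraints, 0, 0)],
            bounds=[(1e-10, None)] * n,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        assert sol.success
        assert obj_dual == pytest.approx(float(sol.fun), abs=1e-6)


def test_gps_overlap_violation_errors(rng):
    X = pd.DataFrame({"x": rng.normal(size=100)})
    e = 2.0 * X["x"].to_numpy()  # conditionally deterministic
    with pytest.raises(ValueError, match="residual variance"):
        gps_weights(e, X)


def _result(n_balanced, max_abs, ess, method="m"):
    return BalanceResult(
        weights=np.ones(4), method=method,
        pre_corr=pd.Series(dtype=float), post_corr=pd.Series(dtype=float),
        n_balanced=n_balanced, max_abs_post_corr=max_abs, ess=ess,
    )


def test_select_method_rules():
    a = _result(15, 0.05, 90, "a")
    assert select_method([a]) is a
    b = _result(14, 0.02, 120, "b")
    assert select_method([a, b]) is a  # more balanced wins
    c = _result(15, 0.09, 100, "c")
    assert select_method([a, c]) is a  # tie on count: smaller max |r|
    d = _result(15, 0.05, 110, "d")
    assert select_method([a, d]) is d  # tie again: larger ESS


def test_ess_decreases_with_confounding_strength():
    ess_weak = np.mean([gps_weights(*_xy(s, 0.1)).ess for s in range(5)])
    ess_strong = np.mean([gps_weights(*_xy(s, 0.5)).ess for s in range(5)])
    assert ess_strong < ess_weak


def _xy(seed, r2):
    d = simulate_linear_confounding(500, seed, r2=r2)
    return d["exposure"], d["X"]


def test_null_confounding_preserves_correlation_distribution(rng):
    """Exposure independent of X: pre-weighting correlations are pure
    sampling noise and weighting only moves them within that noise."""
    n = 1000
    d = simulate_linear_confounding(n, rng)
    exposure = rng.normal(size=n)  # independent of X
    for fn in (gps_weights, constrained_balance_weights):
        res = fn(exposure, d["X"])
        assert np.abs(res.post_corr - res.pre_corr).max() < 4.0 / np.sqrt(n)
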