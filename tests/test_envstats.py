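"""Unpredictability statistics: CV, penalized segmentation, noise color."""

import math

import numpy as np
import pytest

from econunpred import envstats
from econunpred.envstats import (
    coefficient_of_variation,
    detect_changepoints,
    detrend_values,
    noise_color,
    segment_optimal,
    transform_noise,
)
from econunpred.ingest import MonthlySeries
from econunpred.simulate import colored_noise

# ---------------------------------------------------------------- CV


def test_cv_constant_series_is_zero():
    assert coefficient_of_variation(np.full(20, 3.0)) == 0.0


def test_cv_alternating_series_matches_direct_formula():
    vals = np.array([1.0, 7.0] * 8)
    # independent arithmetic: mean 4, sample sd sqrt(16*9/15)
    expected = math.sqrt(16 * 9 / 15) / 4.0
    assert coefficient_of_variation(vals) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.7745966692414834, abs=1e-12)


@pytest.mark.parametrize("c", [0.5, 2.0, 17.3])
def test_cv_scale_invariance(c, rng):
    x = rng.uniform(1.0, 7.0, 30)
    assert coefficient_of_variation(c * x) == pytest.approx(coefficient_of_variation(x), rel=1e-12)


def test_cv_needs_two_points():
    with pytest.raises(ValueError):
        coefficient_of_variation(np.array([2.0]))


# ------------------------------------------------- segmentation oracle


def test_constant_series_has_no_changepoints():
    for kind in ("mean", "variance"):
        seg = segment_optimal(np.full(20, 2.0), kind=kind, penalty=1.0)
        assert seg.changepoints == []


def test_single_mean_jump_found_by_dp_and_single_split_search():
    rng = np.random.default_rng(5)
    y = np.concatenate([rng.normal(1, 0.2, 10), rng.normal(6, 0.2, 10)])
    seg = segment_optimal(y, kind="mean", penalty_rule="bic")
    assert seg.changepoints == [10]
    # exhaustive single-split oracle: position 10 must be the argmin
    from econunpred.envstats import _SegmentCost

    c = _SegmentCost(y, "mean")
    costs = {s: c.cost(0, s) + c.cost(s, 20) for s in range(1, 20)}
    assert min(costs, key=costs.get) == 10


def test_single_variance_jump_found():
    rng = np.random.default_rng(6)
    y = np.concatenate([rng.normal(0, 0.1, 12), rng.normal(0, 2.0, 12)])
    seg = segment_optimal(y, kind="variance")
    assert seg.changepoints == [12]


def test_total_cost_consistent_with_segments():
    rng = np.random.default_rng(7)
    y = np.concatenate([rng.normal(0, 1, 15), rng.normal(4, 1, 15)])
    for kind in ("mean", "variance"):
        seg = segment_optimal(y, kind=kind)
        from econunpred.envstats import _SegmentCost

        c = _SegmentCost(y, kind)
        bounds = [0] + seg.changepoints + [len(y)]
        recomputed = sum(c.cost(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        recomputed += seg.penalty * len(seg.changepoints)
        assert seg.total_cost == pytest.approx(recomputed, abs=1e-9)


def _random_series(rng):
    n = int(rng.integers(8, 51))
    y = rng.normal(0, 1, n)
    for _ in range(int(rng.integers(0, 3))):
        pos = int(rng.integers(1, n))
        y[pos:] += rng.normal(0, 3)
    if rng.uniform() < 0.5:
        pos = int(rng.integers(1, n))
        y[pos:] *= rng.uniform(1.5, 3.0)
    return y


@pytest.mark.parametrize("kind", ["mean", "variance"])
@pytest.mark.parametrize("penalty_rule", ["mbic", "bic"])
def test_pelt_equals_exhaustive_dp(kind, penalty_rule):
    rng = np.random.default_rng(42)
    for _ in range(40):
        y = _random_series(rng)
        a = segment_optimal(y, kind=kind, penalty_rule=penalty_rule)
        b = detect_changepoints(y, kind=kind, penalty_rule=penalty_rule)
        assert a.changepoints == b.changepoints
        assert a.total_cost == pytest.approx(b.total_cost, abs=1e-8)


def test_changepoint_count_invariant_to_constant_shift(rng):
    y = _random_series(rng)
    for kind in ("mean", "variance"):
        a = detect_changepoints(y, kind=kind)
        b = detect_changepoints(y + 100.0, kind=kind)
        assert a.changepoints == b.changepoints


# ---------------------------------------------------------- detrending


def test_detrend_removes_linear_ramp():
    resid = detrend_values(np.linspace(0, 5, 48))
    assert np.max(np.abs(resid)) < 1e-8


def test_detrend_removes_annual_harmonic():
    moy = (np.arange(48)) % 12 + 1
    x = 2.0 + 1.5 * np.sin(2 * np.pi * moy / 12.0)
    resid = detrend_values(x, first_month_of_year=1)
    assert np.max(np.abs(resid)) < 1e-8


def test_variance_detrending_equalizes_halves(rng):
    n = 512
    scale = np.linspace(1.0, 2.0, n)  # variance doubling over time
    x = rng.normal(0, 1, n) * scale
    resid = detrend_values(x)
    v1 = resid[: n // 2].var()
    v2 = resid[n // 2 :].var()
    assert abs(v1 - v2) / max(v1, v2) < 0.15


def test_internal_gap_interpolation_and_flag():
    months = [f"2020-{m:02d}" for m in range(1, 13) if m != 6]
    s = MonthlySeries("f", months, np.arange(len(months), dtype=float))
    resid, flagged = envstats.detrend_for_noise(s)
    assert resid.size == 12  # regular grid restored
    assert not flagged  # 1/12 interpolated, under the 20% flag threshold


# ---------------------------------------------------------- noise color


@pytest.mark.parametrize("beta", [0.0, 2.0])
def test_noise_color_recovers_synthesized_exponent(beta):
    errs = [
        abs(noise_color(colored_noise(1024, beta, np.random.default_rng(s))) - beta)
        for s in range(25)
    ]
    assert np.mean(errs) < 0.2


@pytest.mark.parametrize("beta,expected", [(-0.5, -0.5), (1.2, -1.2), (0.0, 0.0)])
def test_negabs_transform(beta, expected):
    assert transform_noise(beta, "negabs") == pytest.approx(expected)


def test_transform_alternatives():
    assert transform_noise(0.7, "neg") == pytest.approx(-0.7)
    assert transform_noise(0.7, "shift") == pytest.approx(1.3)


def test_noise_unpred_nonpositive_and_zero_only_at_white(rng):
    for beta in (-1.0, 0.0, 0.5, 2.0):
        t = transform_noise(beta)
        assert t <= 0
        assert (t == 0) == (beta == 0)


def test_noise_color_needs_enough_points():
    with pytest.raises(ValueError):
        noise_color(np.ones(5))


# ---------------------------------------------------------- full record


def test_compute_env_stats_record(small_cohort):
    from econunpred import ingest

    _, tables, _ = small_cohort
    series, _ = ingest.build_series(tables["responses"])
    eligible, _ = ingest.filter_eligible(series)
    rec = envstats.compute_env_stats(eligible[0])
    assert rec.cv >= 0
    assert rec.n_cpt_mean >= 0 and rec.n_cpt_var >= 0
    assert np.isfinite(rec.noise_beta)
    assert rec.noise_unpred == pytest.approx(-abs(rec.noise_beta))
    assert 1.0 <= rec.severity <= 7.0
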