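"""Scale scoring, Cronbach's alpha, correlations, group summaries."""

import numpy as np
import pandas as pd
import pytest

from econunpred.descriptives import (
    cronbach_alpha,
    group_summaries,
    pairwise_correlations,
    score_scales,
)
from econunpred.simulate import SimConfig, simulate_cohort


def test_alpha_identical_items_is_one(rng):
    x = rng.normal(size=200)
    assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)


def test_alpha_independent_items_near_zero(rng):
    X = rng.normal(size=(5000, 6))
    assert abs(cronbach_alpha(X)) < 0.05


def test_alpha_small_matrix_matches_direct_formula():
    X = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [3.0, 5.0, 4.0], [4.0, 4.0, 6.0]])
    k = 3
    expected = k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / X.sum(axis=1).var(ddof=1))
    assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)


def test_alpha_invariant_to_item_shift(rng):
    X = rng.normal(size=(100, 4))
    assert cronbach_alpha(X + 10.0) == pytest.approx(cronbach_alpha(X), abs=1e-10)


def test_alpha_zero_total_variance_errors():
    X = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
    with pytest.raises(ValueError):
        cronbach_alpha(X)


def test_scale_scores_in_range(small_cohort):
    _, tables, _ = small_cohort
    scores, alphas = score_scales(tables["scales"])
    assert scores["routines_mean"].between(1, 4).all()
    assert scores["quic_sum"].between(0, 18).all()
    assert 0 < alphas["routines"] <= 1


def test_correlation_identity_and_sign(rng):
    x = rng.normal(size=100)
    df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=100)})
    r, n = pairwise_correlations(df)
    assert r.loc["a", "a"] == pytest.approx(1.0)
    assert r.loc["a", "b"] == pytest.approx(-1.0)
    assert np.allclose(r.to_numpy(), r.to_numpy().T, equal_nan=True)
    assert (n == 100).all().all()


def test_constant_column_reports_missing_cell(rng):
    df = pd.DataFrame({"a": rng.normal(size=50), "b": np.full(50, 2.0)})
    r, _ = pairwise_correlations(df)
    assert np.isnan(r.loc["a", "b"])


def test_complete_case_correlation_matrix_is_psd(rng):
    X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
    r, _ = pairwise_correlations(pd.DataFrame(X))
    assert np.linalg.eigvalsh(r.to_numpy()).min() > -1e-10


def test_planted_latent_correlation_recovered():
    """Severity and instability latent drivers planted at correlation 0.5."""
    cfg = SimConfig(n_families=1000, months_total=18, min_months=10,
                    severity_latent_rho=1.0, instability_latent_rho=0.5, seed=77)
    _, truth = simulate_cohort(cfg)
    z = np.array([f["z_latent"] for f in truth.families.values()])
    u = np.array([f["instability"] for f in truth.families.values()])
    assert abs(np.corrcoef(z, u)[0, 1] - 0.5) < 0.1


def test_single_group_summary_equals_cohort_mean(rng):
    vals = pd.DataFrame({"family_id": [f"F{i}" for i in range(40)], "cv": rng.uniform(0, 1, 40)})
    demo = pd.DataFrame({"family_id": vals["family_id"], "income_fpl": ["fpl_le_200"] * 40})
    g = group_summaries(vals, demo, "income_fpl")
    assert len(g) == 1
    assert g["mean"].iloc[0] == pytest.approx(vals["cv"].mean())
    assert g["n"].iloc[0] == 40


def test_ci_width_scales_inverse_sqrt_n(rng):
    # same values, one group with n and one with 4n: CI width halves
    x = rng.normal(size=100)
    vals = pd.DataFrame(
        {"family_id": [f"F{i}" for i in range(500)], "v": np.concatenate([x, np.tile(x, 4)])}
    )
    demo = pd.DataFrame(
        {"family_id": vals["family_id"], "g": ["small"] * 100 + ["big"] * 400}
    )
    g = group_summaries(vals, demo, "g").set_index("group")
    w_small = g.loc["small", "ci_hi"] - g.loc["small", "ci_lo"]
    w_big = g.loc["big", "ci_hi"] - g.loc["big", "ci_lo"]
    assert w_small / w_big == pytest.approx(2.0, rel=0.10)


def test_low_income_group_shows_higher_hardship_statistics():
    """Planted SES confounding: the <=200% FPL group should exceed the
    >=400% group on severity and CV in most seeds."""
    from econunpred import envstats, ingest

    wins_sev = wins_cv = total = 0
    for seed in range(8):
        cfg = SimConfig(n_families=150, seed=400 + seed)
        tables, _ = simulate_cohort(cfg)
        series, _ = ingest.build_series(tables["responses"])
        eligible, _ = ingest.filter_eligible(series)
        st = envstats.env_stats_table(eligible)
        g = group_summaries(
            st[["family_id", "severity", "cv"]], tables["confounders"], "income_fpl"
        ).set_index(["statistic", "group"])
        wins_sev += g.loc[("severity", "fpl_le_200"), "mean"] > g.loc[("severity", "fpl_ge_400"), "mean"]
        wins_cv += g.loc[("cv", "fpl_le_200"), "mean"] > g.loc[("cv", "fpl_ge_400"), "mean"]
        total += 1
    assert wins_sev >= 7
    assert wins_cv >= 6


def test_tiny_group_is_flagged(rng):
    vals = pd.DataFrame({"family_id": ["a", "b", "c"], "v": [1.0, 2.0, 3.0]})
    demo = pd.DataFrame({"family_id": ["a", "b", "c"], "g": ["x", "x", "y"]})
    g = group_summaries(vals, demo, "g").set_index("group")
    assert bool(g.loc["y", "small_group"])
    assert np.isnan(g.loc["y", "sd"])
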