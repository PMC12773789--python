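"""Synthetic longitudinal hardship cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 321 families answering a six-item monthly hardship checklist for
15-36 months between 2020 and 2023, with

* a piecewise-constant mean path (planted level shifts),
* a piecewise-constant variance path (planted spread shifts),
* an annual seasonal harmonic,
* additive 1/f^beta colored noise (spectral amplitudes proportional to
  f^(-beta/2), uniform random phases),
* socioeconomic confounding: a latent SES-adversity factor drives both
  the hardship exposures and the sociodemographic confounders,
* a child self-regulation outcome that is linear in true hardship
  severity, true instability, and the encoded confounders,
* five-item family-routines and 18-item binary QUIC questionnaires with
  weak loadings on the instability latent.

Every planted quantity is recorded in a ground-truth object so parameter
recovery is testable end to end.  The same config and seed always produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balancing import CONFOUNDER_COLUMNS, encode_confounders
from .ingest import ITEM_COLUMNS, MonthlySeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "colored_noise",
    "simulate_hardship_series",
    "simulate_cohort",
    "simulate_linear_confounding",
]

# direction each category pushes the SES-adversity latent (sampling utilities)
_EDU_ADVERSITY = {
    "less_than_hs": 1.2, "hs_ged": 0.6, "some_college": 0.3,
    "assoc_degree": 0.1, "bachelor": -0.5, "postgrad": -1.0,
}
_INC_ADVERSITY = {"fpl_le_200": 1.0, "fpl_200_400": 0.0, "fpl_ge_400": -1.0}
_RACE_ADVERSITY = {
    "black": 0.5, "latinx": 0.4, "multiracial": 0.1,
    "other": 0.0, "asian": -0.1, "white": -0.3,
}

_DEFAULT_GROUP_PROBS = {
    "education": {
        "less_than_hs": 0.08, "hs_ged": 0.22, "some_college": 0.22,
        "assoc_degree": 0.10, "bachelor": 0.22, "postgrad": 0.16,
    },
    "income_fpl": {"fpl_le_200": 0.40, "fpl_200_400": 0.30, "fpl_ge_400": 0.30},
    "race_ethnicity": {
        "black": 0.13, "latinx": 0.20, "white": 0.55,
        "asian": 0.05, "multiracial": 0.04, "other": 0.03,
    },
}

# outcome-model coefficients per encoded confounder column (length 15);
# nonzero on the SES-marker dummies so ignoring them biases a naive fit
_DEFAULT_CONFOUNDER_EFFECTS = {
    "education_bachelor": -0.10, "education_hs_ged": 0.15, "education_less_than_hs": 0.25,
    "education_postgrad": -0.20, "education_some_college": 0.10,
    "income_fpl_fpl_ge_400": -0.25, "income_fpl_fpl_le_200": 0.25,
    "race_ethnicity_black": 0.10, "race_ethnicity_latinx": 0.08,
    "race_ethnicity_multiracial": 0.05, "race_ethnicity_other": 0.0,
    "race_ethnicity_white": -0.05,
    "child_disability_yes": 0.30, "child_age": 0.05, "child_health": -0.10,
}


def _default_confounder_effects() -> np.ndarray:
    return np.array([_DEFAULT_CONFOUNDER_EFFECTS[c] for c in CONFOUNDER_COLUMNS])


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the target design: 321 families, a 36-month window
    with at least 15 observed months each, hardship on the 1-7 scale
    after the +1 transform, a 125-family outcome subsample, and planted
    outcome effects on the scale of the reported raw slopes (severity
    0.36, unpredictability 0.21 outcome units per exposure unit).
    """

    n_families: int = 321
    months_total: int = 36
    min_months: int = 15
    missing_rate: float = 0.22
    group_probs: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_GROUP_PROBS.items()})
    segment_rate: float = 1.0
    var_segment_rate: float = 0.7
    seasonal_amplitude: float = 0.3
    noise_beta_range: tuple = (0.0, 2.0)
    noise_scale: float = 0.5
    confounding_strength: float = 0.8
    severity_latent_rho: float = 0.6
    instability_latent_rho: float = 0.5
    effect_severity: float = 0.36
    effect_unpredictability: float = 0.21
    confounder_effects: np.ndarray = field(default_factory=_default_confounder_effects)
    outcome_intercept: float = -0.6
    outcome_noise_sd: float = 0.8
    n_outcome: int = 125
    responses_per_month: int = 1
    missing_mechanism: str = "mcar"  # or "mar": drop prob rises with hardship
    scale_loading: float = 0.45
    enforce_eligibility: bool = True
    start_month: str = "2020-04"
    seed: int = 0

    def validate(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if not (2 <= self.min_months <= self.months_total):
            raise ValueError("need 2 <= min_months <= months_total")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be a probability below 1")
        if self.outcome_noise_sd <= 0:
            raise ValueError("outcome_noise_sd must be positive")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")
        if len(self.confounder_effects) != len(CONFOUNDER_COLUMNS):
            raise ValueError(f"confounder_effects must have length {len(CONFOUNDER_COLUMNS)}")
        for var, probs in self.group_probs.items():
            vals = np.array(list(probs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1.0) > 1e-8:
                raise ValueError(f"group probabilities for {var!r} must lie in [0,1] and sum to 1")


@dataclass
class GroundTruth:
    """Every planted simulator quantity, keyed for recovery tests."""

    seed: int
    effect_severity: float
    effect_unpredictability: float
    confounder_effects: list
    families: dict = field(default_factory=dict)
    n_eligible: int = 0
    outcome_family_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def colored_noise(n: int, beta: float, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """1/f^beta noise via spectral synthesis.

    Fourier amplitudes proportional to f^(-beta/2) with i.i.d. uniform
    phases, inverse-transformed and rescaled to sample sd ``scale``.
    beta=0 gives (phase-randomized) white noise, beta=2 a red random
    drift, beta<0 fast but regular alternation.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:  # Nyquist coefficient must be real
        spec[-1] = amp[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd > 0:
        x = x / sd * scale
    return x


def _month_labels(start: str, n: int) -> list[str]:
    y0, m0 = (int(p) for p in start.split("-"))
    base = y0 * 12 + m0 - 1
    return [f"{(base + k) // 12:04d}-{(base + k) % 12 + 1:02d}" for k in range(n)]


def _plant_boundaries(n_cpts: int, n: int, rng: np.random.Generator, min_gap: int = 3) -> list[int]:
    """Strictly increasing interior segment-start indices with spacing."""
    bounds: list[int] = []
    candidates = list(range(min_gap, n - min_gap + 1))
    for _ in range(n_cpts):
        ok = [c for c in candidates if all(abs(c - b) >= min_gap for b in bounds)]
        if not ok:
            break
        bounds.append(int(rng.choice(ok)))
    return sorted(bounds)


def _piecewise(n: int, boundaries: list[int], values: list[float]) -> np.ndarray:
    out = np.empty(n)
    edges = [0] + list(boundaries) + [n]
    for v, (a, b) in zip(values, zip(edges[:-1], edges[1:])):
        out[a:b] = v
    return out


def simulate_hardship_series(
    config: SimConfig,
    latent: float,
    rng: np.random.Generator,
    instability: float = 0.0,
) -> tuple[MonthlySeries, dict]:
    """One family's monthly hardship series plus its planted ground truth.

    ``latent`` sets the family's base hardship level (0-6 pre-transform
    units); ``instability`` (standard-normal scale) inflates changepoint
    rates and noise level and whitens the noise color.  The continuous
    latent path (levels + season + colored noise) is rounded, clipped to
    0-6, and +1-transformed, mirroring the bounded sum-score instrument.

    Returns the observed :class:`MonthlySeries` (after missingness) and a
    per-family truth dict including the full-window planted integers.
    """
    if not np.isfinite(latent):
        raise ValueError("family latent must be finite")
    n = config.months_total
    rate_mult = float(np.exp(0.9 * instability))
    base = float(np.clip(latent, 0.0, 2.5))

    # hardship unfolds as episodes: stretches of elevated need on a low
    # baseline, entered and left abruptly -- each episode contributes a
    # pair of mean-path boundaries; episode frequency scales with the
    # instability latent, episode height with the severity latent
    n_episodes = rng.poisson(config.segment_rate * rate_mult)
    mean_path = np.full(n, base)
    mean_bounds: list[int] = []
    for _ in range(n_episodes):
        start = int(rng.integers(1, n - 2))
        duration = int(3 + rng.geometric(0.35))
        stop = min(start + duration, n)
        height = rng.uniform(1.2, 2.8) * (0.7 + 0.4 * max(latent, 0.2))
        mean_path[start:stop] += height
        mean_bounds.extend([start, stop] if stop < n else [start])
    mean_path = np.clip(mean_path, 0.0, 6.0)
    mean_bounds = sorted(set(mean_bounds))
    edges = [0] + mean_bounds + [n]
    levels = [float(mean_path[a]) for a in edges[:-1]]

    # noise level tracks the current hardship level (families at the zero
    # floor barely fluctuate) and the instability latent
    base_sd = max(config.noise_scale * np.exp(0.4 * instability), 0.08)
    sd_path = base_sd * (0.5 + 0.25 * np.sqrt(mean_path))

    # planted variance regimes multiply the spread over a stretch
    n_var_cpts = rng.poisson(config.var_segment_rate * rate_mult)
    var_bounds = _plant_boundaries(n_var_cpts, n, rng)
    sd_scales = [1.0] + [float(rng.uniform(1.6, 3.0)) if i % 2 == 0 else 1.0 for i in range(len(var_bounds))]
    sd_path = sd_path * _piecewise(n, var_bounds, sd_scales)

    lo, hi = config.noise_beta_range
    beta = float(np.clip(0.8 - 0.5 * instability + rng.normal(0.0, 0.2), lo, hi))
    noise = colored_noise(n, beta, rng, scale=1.0) * sd_path

    phase = rng.uniform(0.0, 12.0)
    m0 = int(config.start_month.split("-")[1])
    moy = (m0 - 1 + np.arange(n)) % 12 + 1
    seasonal = config.seasonal_amplitude * np.cos(2.0 * np.pi * (moy - phase) / 12.0)

    y_int = np.clip(np.round(mean_path + seasonal + noise), 0, 6).astype(int)

    # missingness (per-family rate; MAR option raises drop prob with hardship)
    fam_rate = rng.uniform(0.0, 2.0 * config.missing_rate)
    observed = None
    for attempt in range(25):
        p_drop = np.full(n, fam_rate)
        if config.missing_mechanism == "mar":
            p_drop = np.clip(fam_rate + 0.15 * (y_int / 6.0 - 0.5), 0.0, 0.9)
        mask = rng.uniform(size=n) >= p_drop
        if not config.enforce_eligibility or mask.sum() >= config.min_months:
            observed = mask
            break
    if observed is None:
        raise RuntimeError("could not retain min_months observed months after bounded retries")

    labels = _month_labels(config.start_month, n)
    obs_idx = np.flatnonzero(observed)
    series = MonthlySeries(
        family_id="",
        months=[labels[i] for i in obs_idx],
        values=y_int[obs_idx].astype(float) + 1.0,
    )
    span = np.arange(obs_idx[0], obs_idx[-1] + 1)
    series.gap_months = [labels[i] for i in span if not observed[i]]

    truth = {
        "mean_boundaries": [int(b) for b in mean_bounds],
        "mean_levels": levels,
        "var_boundaries": [int(b) for b in var_bounds],
        "var_scales": sd_scales,
        "noise_beta": beta,
        "base_noise_sd": base_sd,
        "instability": float(instability),
        "severity_true": float(np.clip(mean_path, 0, 6).mean() + 1.0),
        "monthly_sums": [int(v) for v in y_int],
        "observed_mask": [bool(b) for b in observed],
        "n_observed": int(observed.sum()),
    }
    return series, truth


def _sample_category(probs: dict, scores: dict, z: float, strength: float, rng) -> str:
    cats = sorted(probs)
    util = np.array([np.log(max(probs[c], 1e-12)) + strength * z * scores.get(c, 0.0) for c in cats])
    p = np.exp(util - util.max())
    p /= p.sum()
    return str(rng.choice(cats, p=p))


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> tuple[dict, GroundTruth]:
    """Full synthetic cohort: responses, confounders, outcome, scales.

    Returns ``(tables, truth)`` where ``tables`` maps artifact names
    (``responses``, ``confounders``, ``outcome``, ``scales``) to tidy
    DataFrames keyed by family id, and ``truth`` holds every planted
    parameter.  Same config + seed gives identical tables.
    """
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss))

    fam_ids = [f"F{i:04d}" for i in range(config.n_families)]
    truth = GroundTruth(
        seed=config.seed,
        effect_severity=config.effect_severity,
        effect_unpredictability=config.effect_unpredictability,
        confounder_effects=[float(v) for v in config.confounder_effects],
    )

    resp_rows, conf_rows, scale_rows = [], [], []
    severities_true, instabilities = {}, {}

    for fid in fam_ids:
        z = rng.normal()
        rho_s, rho_u = config.severity_latent_rho, config.instability_latent_rho
        sev_mix = rho_s * z + np.sqrt(1 - rho_s**2) * rng.normal()
        u = rho_u * z + np.sqrt(1 - rho_u**2) * rng.normal()
        base_level = float(np.clip(np.exp(-1.1 + 0.9 * sev_mix) - 0.1, 0.0, 2.5))

        series, fam_truth = simulate_hardship_series(config, base_level, rng, instability=u)
        series.family_id = fid
        fam_truth["z_latent"] = float(z)
        truth.families[fid] = fam_truth
        severities_true[fid] = fam_truth["severity_true"]
        instabilities[fid] = float(u)

        # survey responses: item subset of size == planted monthly sum
        for month, value in zip(series.months, series.values):
            s = int(round(value - 1.0))
            for _ in range(config.responses_per_month):
                day = int(rng.integers(2, 28))
                chosen = rng.choice(6, size=s, replace=False) if s > 0 else np.array([], dtype=int)
                row = {"family_id": fid, "date": f"{month}-{day:02d}"}
                for j, col in enumerate(ITEM_COLUMNS):
                    row[col] = int(j in chosen)
                resp_rows.append(row)

        strength = config.confounding_strength
        conf_rows.append(
            {
                "family_id": fid,
                "education": _sample_category(config.group_probs["education"], _EDU_ADVERSITY, z, strength, rng),
                "income_fpl": _sample_category(config.group_probs["income_fpl"], _INC_ADVERSITY, z, strength, rng),
                "race_ethnicity": _sample_category(config.group_probs["race_ethnicity"], _RACE_ADVERSITY, z, strength, rng),
                "child_age": float(np.round(rng.uniform(0.5, 5.5), 2)),
                "child_disability": "yes" if rng.uniform() < 1 / (1 + np.exp(2.2 - 0.3 * z)) else "no",
                "child_health": float(np.round(np.clip(rng.normal(3.5 - 0.25 * z, 0.8), 1.0, 5.0), 2)),
            }
        )

        # questionnaire scales: weak loadings on the instability latent
        lam = config.scale_loading
        f_rout = -(0.5 * u + 0.3 * z) + rng.normal(0.0, 0.8)
        for admin in range(1, 4):
            for item in range(1, 6):
                v = int(np.clip(np.round(3.3 + lam * f_rout + rng.normal(0.0, 0.5)), 1, 4))
                scale_rows.append(
                    {"family_id": fid, "scale": "routines", "administration": admin, "item": item, "value": v}
                )
        f_q = 0.6 * u + 0.3 * z + rng.normal(0.0, 0.7)
        for item in range(1, 19):
            d = -0.8 + 1.6 * (item - 1) / 17.0  # fixed item-difficulty spread
            p = 1 / (1 + np.exp(-(-2.6 + 2.0 * lam * f_q + d)))
            scale_rows.append(
                {"family_id": fid, "scale": "quic", "administration": 1, "item": item,
                 "value": int(rng.uniform() < p)}
            )

    confounders = pd.DataFrame(conf_rows)
    n_out = min(config.n_outcome, config.n_families)
    out_ids = sorted(rng.choice(fam_ids, size=n_out, replace=False).tolist())
    truth.outcome_family_ids = out_ids

    X = encode_confounders(confounders.set_index("family_id")).loc[out_ids]
    gamma = np.asarray(config.confounder_effects, dtype=float)
    sev = np.array([severities_true[f] for f in out_ids])
    unp = np.array([instabilities[f] for f in out_ids])
    outcome_vals = (
        config.outcome_intercept
        + config.effect_severity * sev
        + config.effect_unpredictability * unp
        + X.to_numpy() @ gamma
        + rng.normal(0.0, config.outcome_noise_sd, n_out)
    )
    outcome = pd.DataFrame({"family_id": out_ids, "self_regulation": np.round(outcome_vals, 6)})

    truth.n_eligible = sum(
        1 for f in fam_ids if truth.families[f]["n_observed"] >= config.min_months
    )

    tables = {
        "responses": pd.DataFrame(resp_rows),
        "confounders": confounders,
        "outcome": outcome,
        "scales": pd.DataFrame(scale_rows),
    }
    return tables, truth


# ---------------------------------------------------------------------------
# planted linear-confounding scenarios (estimator calibration)


def _calibration_design(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """15-column full-rank confounder matrix sharing a scalar latent.

    Nine continuous columns and six moderate-prevalence binaries, all
    correlated with one latent factor.  Moderate prevalences keep every
    dummy cell populated, so this design measures estimator calibration;
    near-empty categorical cells (a distinct failure mode, where exact
    balance can be infeasible outright) arise in the cohort simulator's
    realistic sociodemographic design instead.
    """
    z = rng.normal(size=n)
    cols = {}
    loadings = (0.3, 0.5, 0.7, 0.4, 0.6, 0.35, 0.55, 0.45, 0.65)
    for j, lam in enumerate(loadings):
        cols[f"x_cont{j + 1}"] = lam * z + rng.normal(0.0, np.sqrt(1 - lam**2), n)
    prevalences = (0.5, 0.4, 0.3, 0.25, 0.2, 0.15)
    from scipy import stats as _st

    for j, p in enumerate(prevalences):
        lat = 0.5 * z + rng.normal(0.0, np.sqrt(0.75), n)
        cols[f"x_bin{j + 1}"] = (lat > _st.norm.ppf(1 - p)).astype(float)
    return pd.DataFrame(cols)


def simulate_linear_confounding(
    n: int,
    rng: np.random.Generator | int,
    r2: float = 0.3,
    effect: float = 0.36,
    confounder_outcome_scale: float = 0.8,
    outcome_noise_sd: float = 0.8,
    second_effect: float | None = None,
    exposure_corr: float = 0.5,
) -> dict:
    """Planted linear-confounding scenario for weighting calibration.

    The exposure is a linear function of the 15 encoded confounders
    (population R-squared ``r2``) plus independent noise, scaled to unit
    variance; the outcome is ``effect * exposure`` plus a confounder
    signal colinear with the confounding direction (naive OLS bias is
    then ``confounder_outcome_scale * r2``) plus Gaussian noise.

    With ``second_effect`` set, two exposures sharing the confounding
    direction are produced with correlation ``exposure_corr``; separate
    marginal models then face both confounding and leakage through the
    co-exposure, mirroring the correlated severity/unpredictability pair.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    X = _calibration_design(n, rng)
    Xv = X.to_numpy()
    gamma = np.array([0.6, -0.4, 0.5, 0.9, -0.8, 0.5, -0.7, 0.8, 0.4, 0.3, 0.2, 0.1, -0.3, 0.25, -0.35])
    p = (Xv - Xv.mean(axis=0)) @ gamma
    p_sd = p.std(ddof=1)
    if p_sd <= 0:
        raise ValueError("degenerate confounder design")
    p = p / p_sd * np.sqrt(r2)

    out = {"X": X, "truth": {"effect": effect, "r2": r2,
                             "naive_bias": confounder_outcome_scale * r2}}
    if second_effect is None:
        exposure = p + rng.normal(0.0, np.sqrt(1.0 - r2), n)
        y = effect * exposure + confounder_outcome_scale * p + rng.normal(0.0, outcome_noise_sd, n)
        out["exposure"] = exposure
        out["outcome"] = y
        return out

    resid_var = 1.0 - r2
    cov_u = exposure_corr - r2
    if not (-resid_var < cov_u <= resid_var):
        raise ValueError("exposure_corr incompatible with r2")
    cov = np.array([[resid_var, cov_u], [cov_u, resid_var]])
    U = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    e1, e2 = p + U[:, 0], p + U[:, 1]
    y = (
        effect * e1 + second_effect * e2 + confounder_outcome_scale * p
        + rng.normal(0.0, outcome_noise_sd, n)
    )
    out.update(exposure=e1, exposure2=e2, outcome=y)
    out["truth"]["second_effect"] = second_effect
    return out
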