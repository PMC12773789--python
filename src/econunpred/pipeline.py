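"""End-to-end pipeline: simulate -> ingest -> statistics -> PCA ->
descriptives -> balancing -> effects, with checksummed artifacts.

All randomness flows from one root seed.  Rerunning with the same config
and seed reproduces byte-identical artifacts; ``run_report.json`` records
a sha256 checksum for every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import balancing, descriptives, dimensions, effects, envstats, ingest
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("econunpred")

EXPOSURES = ("severity", "composite", "cv", "n_cpt_mean", "n_cpt_var", "noise_unpred")


@dataclass
class RunConfig:
    outdir: str = "econunpred_run"
    sim: SimConfig = field(default_factory=SimConfig)
    min_months: int = 15
    penalty_rule: str = "mbic"
    noise_transform: str = "negabs"
    pca_k: int = 2
    balance_methods: tuple = ("gps", "ebal")
    seed: int = 0

    def validate(self) -> None:
        sim = dataclasses.replace(self.sim, seed=self.seed, min_months=self.min_months)
        sim.validate()
        if self.penalty_rule not in ("mbic", "bic"):
            raise ValueError("penalty_rule must be 'mbic' or 'bic'")
        if self.noise_transform not in ("negabs", "neg", "shift"):
            raise ValueError("noise_transform must be one of negabs/neg/shift")
        if self.pca_k < 1 or self.pca_k > 4:
            raise ValueError("pca_k must be between 1 and 4")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the consolidated run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _write_csv(df, path)
        artifacts[name] = _checksum(path)

    def save_json(name: str, obj) -> None:
        path = outdir / name
        _write_json(obj, path)
        artifacts[name] = _checksum(path)

    # --- simulate -----------------------------------------------------
    log.info("stage: simulate (n_families=%d)", config.sim.n_families)
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed, min_months=config.min_months)
    tables, truth = simulate_cohort(sim_cfg)
    for name in ("responses", "confounders", "outcome", "scales"):
        save_csv(f"{name}.csv", tables[name])
    save_json("ground_truth.json", truth.to_dict())

    # --- ingest & eligibility ----------------------------------------
    log.info("stage: ingest")
    series, ingest_report = ingest.build_series(tables["responses"])
    eligible, elig_report = ingest.filter_eligible(series, min_months=config.min_months)
    if not eligible:
        raise RuntimeError("no eligible families after the minimum-months filter")
    save_csv("monthly_series.csv", ingest.series_to_frame(eligible))
    sev = ingest.severity_table(eligible)
    save_csv("severity.csv", sev)

    # --- unpredictability statistics ---------------------------------
    log.info("stage: envstats (%d eligible families)", len(eligible))
    stats = envstats.env_stats_table(
        eligible, penalty_rule=config.penalty_rule, noise_transform=config.noise_transform
    )
    save_csv("envstats.csv", stats)

    # --- PCA & composite ---------------------------------------------
    log.info("stage: dimensions")
    model = dimensions.fit_pca(stats, k=config.pca_k)
    composite = dimensions.composite_index(model)
    save_json("pca_model.json", model.to_dict())
    save_csv("composite.csv", composite)

    # --- descriptives -------------------------------------------------
    log.info("stage: descriptives")
    scale_scores, alphas = descriptives.score_scales(tables["scales"])
    merged = (
        stats.loc[:, ["family_id", "cv", "n_cpt_mean", "n_cpt_var", "noise_unpred", "severity"]]
        .merge(composite, on="family_id")
        .merge(scale_scores, on="family_id", how="left")
    )
    corr, corr_n = descriptives.pairwise_correlations(merged.drop(columns=["family_id"]))
    group_tables = []
    for gvar in ("education", "income_fpl", "race_ethnicity"):
        group_tables.append(
            descriptives.group_summaries(
                merged.loc[:, ["family_id", "cv", "n_cpt_mean", "n_cpt_var", "noise_unpred", "composite"]],
                tables["confounders"],
                gvar,
            )
        )
    groups = pd.concat(group_tables, ignore_index=True)
    save_csv("group_summaries.csv", groups)
    save_json(
        "descriptives_report.json",
        {
            "cronbach_alpha": {k: round(v, 6) for k, v in alphas.items()},
            "correlations": {c: {r: (None if pd.isna(corr.loc[r, c]) else round(float(corr.loc[r, c]), 6)) for r in corr.index} for c in corr.columns},
            "correlation_n": {c: {r: int(corr_n.loc[r, c]) for r in corr_n.index} for c in corr_n.columns},
            "severity_composite_r": (
                None if pd.isna(corr.loc["severity", "composite"]) else round(float(corr.loc["severity", "composite"]), 6)
            ),
        },
    )

    # --- balancing & effects -----------------------------------------
    log.info("stage: balancing + effects")
    analysis = merged.merge(tables["outcome"], on="family_id", how="inner")
    X = balancing.encode_confounders(tables["confounders"]).merge(
        analysis[["family_id"]], on="family_id", how="right"
    )
    Xmat = X.drop(columns=["family_id"])
    exposures = analysis.loc[:, list(EXPOSURES)]
    effects_table, balance_results = effects.effect_suite(
        analysis["self_regulation"].to_numpy(),
        exposures,
        Xmat,
        methods=config.balance_methods,
    )
    save_csv("effects_table.csv", effects_table)

    balance_report = {}
    for exp_name, res in balance_results.items():
        save_csv(
            f"weights_{exp_name}.csv",
            pd.DataFrame({"family_id": analysis["family_id"], "weight": res.weights}),
        )
        save_csv(
            f"balance_table_{exp_name}.csv",
            pd.DataFrame(
                {
                    "confounder": res.pre_corr.index,
                    "pre_corr": res.pre_corr.values,
                    "post_corr": res.post_corr.values,
                }
            ),
        )
        balance_report[exp_name] = {
            "method": res.method,
            "n_balanced": res.n_balanced,
            "max_abs_post_corr": round(res.max_abs_post_corr, 6),
            "ess": round(res.ess, 3),
            "n": int(res.n),
        }
    save_json("balance_report.json", balance_report)
    save_json(
        "effects_report.json",
        {
            "effects": effects_table.to_dict(orient="records"),
            "n_analysis": int(len(analysis)),
        },
    )

    report = {
        "seed": config.seed,
        "config": {
            "n_families": config.sim.n_families,
            "months_total": config.sim.months_total,
            "min_months": config.min_months,
            "penalty_rule": config.penalty_rule,
            "noise_transform": config.noise_transform,
            "pca_k": config.pca_k,
            "balance_methods": list(config.balance_methods),
        },
        "ingest": ingest_report,
        "eligibility": elig_report,
        "n_eligible_planted": truth.n_eligible,
        "pca_variance_explained": [round(float(v), 6) for v in model.variance_explained],
        "artifacts": artifacts,
    }
    save_json("run_report.json", {k: v for k, v in report.items() if k != "artifacts"} | {"artifacts": artifacts})
    report["outdir"] = str(outdir)
    return report
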