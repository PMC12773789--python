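"""Weighted regression of the child outcome on each hardship exposure.

One weighted least-squares model per exposure (intercept + exposure),
with the balancing weights doing the confounder adjustment.  Standard
errors are heteroskedasticity-robust (HC3 sandwich), confidence
intervals are normal-approximation 95%, and the standardized slope is
B * sd(exposure) / sd(outcome) with unweighted sample sds so effects on
different exposure scales are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .balancing import balance_all_methods, effective_sample_size

__all__ = ["EffectEstimate", "weighted_effect", "effect_suite"]


@dataclass
class EffectEstimate:
    exposure: str
    B: float
    beta_std: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n: int
    ess: float
    weights_method: str

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "B": self.B,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "beta_std": self.beta_std,
            "p_value": self.p_value,
            "n": self.n,
            "ess": self.ess,
            "weights_method": self.weights_method,
        }


def weighted_effect(
    outcome,
    exposure,
    weights=None,
    name: str = "exposure",
    weights_method: str = "none",
) -> EffectEstimate:
    """Weighted least squares of outcome on one exposure with HC3 errors.

    With uniform weights this reduces exactly to OLS.  Degenerate designs
    (zero exposure variance, mismatched lengths, non-positive weights)
    raise rather than returning garbage.
    """
    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if not (y.size == e.size == w.size):
        raise ValueError("outcome, exposure and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    sd_e = e.std(ddof=1)
    sd_y = y.std(ddof=1)
    if sd_e <= 0:
        raise ValueError("exposure has zero variance")
    X = sm.add_constant(e)
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC3")
    B = float(res.params[1])
    se = float(res.bse[1])
    return EffectEstimate(
        exposure=name,
        B=B,
        beta_std=float(B * sd_e / sd_y) if sd_y > 0 else float("nan"),
        ci_lo=B - 1.96 * se,
        ci_hi=B + 1.96 * se,
        p_value=float(res.pvalues[1]),
        n=int(y.size),
        ess=effective_sample_size(w),
        weights_method=weights_method,
    )


def effect_suite(
    outcome,
    exposures: pd.DataFrame,
    confounders: pd.DataFrame,
    methods=("gps", "ebal"),
) -> tuple[pd.DataFrame, dict]:
    """One balanced weighted model per exposure column.

    Each exposure gets its own balancing weights (best method selected by
    balance diagnostics); rows are ordered by |standardized slope|.  An
    exposure whose balancing fails is reported flagged with no estimate
    while the others proceed.

    Returns ``(effects table, balance results per exposure)``.
    """
    y = np.asarray(outcome, dtype=float)
    rows = []
    balances = {}
    for col in exposures.columns:
        e = exposures[col].to_numpy(dtype=float)
        try:
            best, _ = balance_all_methods(e, confounders, methods=methods)
        except (RuntimeError, ValueError) as exc:
            rows.append({"exposure": col, "B": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                         "beta_std": np.nan, "p_value": np.nan, "n": y.size,
                         "ess": np.nan, "weights_method": f"failed: {exc}"})
            continue
        balances[col] = best
        est = weighted_effect(y, e, best.weights, name=col, weights_method=best.method)
        rows.append(est.as_row())
    table = pd.DataFrame(rows)
    order = table["beta_std"].abs().fillna(-np.inf).sort_values(ascending=False).index
    return table.loc[order].reset_index(drop=True), balances
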