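"""Questionnaire scoring, internal consistency, correlations, group summaries.

Non-inferential descriptives: Cronbach's alpha for the questionnaire
scales, pairwise-complete Pearson correlations among the unpredictability
indices, scales and composite, and per-group mean/sd/CI tables for
sociodemographic comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cronbach_alpha",
    "score_scales",
    "pairwise_correlations",
    "group_summaries",
]


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / total variance).

    ``items`` is a respondents x items matrix with complete rows; sample
    variances (n-1).  Undefined when the total score has zero variance.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    if not np.all(np.isfinite(X)):
        raise ValueError("item matrix must be complete")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def score_scales(scales: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-family scale scores from the tidy long scales table.

    Family routines (five 1-4 items, possibly several administrations)
    are averaged within family across items and administrations; QUIC
    (18 binary items, single administration) is summed.  Returns the
    per-family score table and a dict of Cronbach's alphas computed on
    family-level item means (routines) / the item matrix (QUIC).
    """
    out = {}
    alphas = {}
    rout = scales.loc[scales["scale"] == "routines"]
    if not rout.empty:
        fam_item = rout.pivot_table(index="family_id", columns="item", values="value", aggfunc="mean")
        out["routines_mean"] = fam_item.mean(axis=1)
        complete = fam_item.dropna()
        if len(complete) >= 3:
            alphas["routines"] = cronbach_alpha(complete.to_numpy())
    quic = scales.loc[scales["scale"] == "quic"]
    if not quic.empty:
        fam_item = quic.pivot_table(index="family_id", columns="item", values="value", aggfunc="first")
        out["quic_sum"] = fam_item.sum(axis=1, min_count=1)
        complete = fam_item.dropna()
        if len(complete) >= 3:
            alphas["quic"] = cronbach_alpha(complete.to_numpy())
    scores = pd.DataFrame(out)
    scores.index.name = "family_id"
    return scores.reset_index(), alphas


def pairwise_correlations(df: pd.DataFrame, min_periods: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix with per-cell n.

    Constant columns yield missing cells.  Returns ``(r, n)`` matrices.
    """
    numeric = df.select_dtypes(include=[np.number])
    r = numeric.corr(method="pearson", min_periods=min_periods)
    notna = numeric.notna().astype(int)
    n = pd.DataFrame(notna.T.to_numpy() @ notna.to_numpy(), index=r.index, columns=r.columns)
    return r, n


def group_summaries(values: pd.DataFrame, demographics: pd.DataFrame, group_var: str) -> pd.DataFrame:
    """Per-group mean, sd, n and normal 95% CI for each numeric column.

    CI = mean +/- 1.96 * sd / sqrt(n); groups with n < 2 have sd and CI
    omitted and are flagged.  Descriptive only — no inferential tests.
    """
    merged = values.merge(demographics[["family_id", group_var]], on="family_id", how="inner")
    rows = []
    for stat in values.select_dtypes(include=[np.number]).columns:
        for grp, sub in merged.groupby(group_var, sort=True):
            x = sub[stat].dropna().to_numpy(dtype=float)
            n = x.size
            mean = float(x.mean()) if n else float("nan")
            if n >= 2:
                sd = float(x.std(ddof=1))
                half = 1.96 * sd / np.sqrt(n)
                lo, hi, flag = mean - half, mean + half, False
            else:
                sd, lo, hi, flag = float("nan"), float("nan"), float("nan"), True
            rows.append(
                {"group_var": group_var, "group": grp, "statistic": stat,
                 "mean": mean, "sd": sd, "n": n, "ci_lo": lo, "ci_hi": hi, "small_group": flag}
            )
    return pd.DataFrame(rows)
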