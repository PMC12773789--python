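"""Balancing weights for continuous exposures against 15 confounders.

Two weighting families are implemented for each continuous exposure
(hardship severity, the composite unpredictability index, or any single
index):

* **GPS density-ratio weights** — stabilized inverse-probability weights
  for a continuous exposure: the marginal normal density of the exposure
  over its conditional normal density given the confounders (linear
  model), normalized to mean one.
* **Entropy balancing** — weights of minimal Kullback-Leibler divergence
  from uniform subject to exact moment constraints: every confounder
  keeps its unweighted mean, the exposure keeps its mean, and every
  exposure-confounder cross moment (hence weighted covariance and
  weighted Pearson correlation) is driven to zero.  Solved through the
  convex dual with a quasi-Newton iteration.

Balance is diagnosed with weighted Pearson correlations between exposure
and each confounder; |r| <= 0.10 counts as balanced.  Method selection
maximizes the balanced count, breaking ties by smaller worst |r| and
then by larger effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EDUCATION_LEVELS",
    "INCOME_LEVELS",
    "RACE_LEVELS",
    "CONFOUNDER_COLUMNS",
    "encode_confounders",
    "BalanceResult",
    "weighted_correlation",
    "effective_sample_size",
    "gps_weights",
    "constrained_balance_weights",
    "select_method",
    "balance_all_methods",
]

BALANCE_THRESHOLD = 0.10

# fixed category vocabularies; alphabetical first level is the dummy reference
EDUCATION_LEVELS = ("assoc_degree", "bachelor", "hs_ged", "less_than_hs", "postgrad", "some_college")
INCOME_LEVELS = ("fpl_200_400", "fpl_ge_400", "fpl_le_200")
RACE_LEVELS = ("asian", "black", "latinx", "multiracial", "other", "white")

#: the 15-column encoded design: 13 dummies + child age + child health
CONFOUNDER_COLUMNS = (
    [f"education_{l}" for l in EDUCATION_LEVELS[1:]]
    + [f"income_fpl_{l}" for l in INCOME_LEVELS[1:]]
    + [f"race_ethnicity_{l}" for l in RACE_LEVELS[1:]]
    + ["child_disability_yes", "child_age", "child_health"]
)


def encode_confounders(confounders: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the raw confounder table to the fixed 15-column design.

    Categoricals (education, income band, race/ethnicity, disability) use
    the full level vocabularies with the alphabetical first level dropped
    as reference; child age and child health pass through continuous.
    """
    out = pd.DataFrame(index=confounders.index)
    for var, levels in (
        ("education", EDUCATION_LEVELS),
        ("income_fpl", INCOME_LEVELS),
        ("race_ethnicity", RACE_LEVELS),
    ):
        for level in levels[1:]:
            out[f"{var}_{level}"] = (confounders[var] == level).astype(float)
    out["child_disability_yes"] = (confounders["child_disability"] == "yes").astype(float)
    out["child_age"] = confounders["child_age"].astype(float)
    out["child_health"] = confounders["child_health"].astype(float)
    if "family_id" in confounders.columns:
        out.insert(0, "family_id", confounders["family_id"])
    return out


@dataclass
class BalanceResult:
    weights: np.ndarray
    method: str
    pre_corr: pd.Series
    post_corr: pd.Series
    n_balanced: int
    max_abs_post_corr: float
    ess: float

    @property
    def n(self) -> int:
        return self.weights.size


def weighted_correlation(x, y, w) -> float:
    """Pearson correlation under observation weights (weighted moments)."""
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    wm_x = np.average(x, weights=w)
    wm_y = np.average(y, weights=w)
    cov = np.average((x - wm_x) * (y - wm_y), weights=w)
    vx = np.average((x - wm_x) ** 2, weights=w)
    vy = np.average((y - wm_y) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def effective_sample_size(w) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c != "family_id"]
        return X.loc[:, cols].to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _diagnostics(exposure, Xm, cols, w, method) -> BalanceResult:
    ones = np.ones_like(w)
    pre = pd.Series({c: weighted_correlation(exposure, Xm[:, j], ones) for j, c in enumerate(cols)})
    post = pd.Series({c: weighted_correlation(exposure, Xm[:, j], w) for j, c in enumerate(cols)})
    finite = post.dropna().abs()
    return BalanceResult(
        weights=w,
        method=method,
        pre_corr=pre,
        post_corr=post,
        n_balanced=int((finite <= BALANCE_THRESHOLD).sum()),
        max_abs_post_corr=float(finite.max()) if len(finite) else float("nan"),
        ess=effective_sample_size(w),
    )


def gps_weights(exposure, X, truncate_percentile: float | None = None) -> BalanceResult:
    """Stabilized generalized-propensity-score density-ratio weights.

    Numerator: normal density of the exposure under its marginal mean and
    variance.  Denominator: normal density under the OLS conditional mean
    given the confounders with the residual variance.  Weights are
    normalized to mean one; optional upper truncation at a percentile.
    """
    e = np.asarray(exposure, dtype=float)
    Xm, cols = _as_matrix(X)
    n, p = Xm.shape
    if n <= p + 2:
        raise ValueError(f"need n > {p + 2} observations for {p} confounders")
    if e.std(ddof=1) <= 0:
        raise ValueError("exposure has zero variance")
    fit = sm.OLS(e, sm.add_constant(Xm)).fit()
    resid_var = float(fit.scale)
    if resid_var <= 1e-10 * e.var(ddof=1):
        raise ValueError("near-zero residual variance: exposure is conditionally deterministic")
    num = stats.norm.pdf(e, loc=e.mean(), scale=e.std(ddof=1))
    den = stats.norm.pdf(e, loc=fit.fittedvalues, scale=np.sqrt(resid_var))
    w = num / den
    if truncate_percentile is not None:
        w = np.minimum(w, np.percentile(w, truncate_percentile))
    w = w / w.mean()
    return _diagnostics(e, Xm, cols, w, "gps")


def constrained_balance_weights(
    exposure,
    X,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BalanceResult:
    """Entropy balancing for a continuous exposure.

    Minimizes sum(w log w) subject to sum(w)=n, weighted confounder means
    equal to their unweighted means, weighted exposure mean preserved,
    and zero weighted exposure-confounder covariance.  The dual is the
    unconstrained convex problem min log(sum exp(theta' c_i)) over the
    centered constraint functions c_i, solved by BFGS; convergence is
    declared when the largest standardized constraint violation falls
    below ``tol``.
    """
    e = np.asarray(exposure, dtype=float)
    Xm, cols = _as_matrix(X)
    n = e.size
    if e.std(ddof=1) <= 0:
        raise ValueError("exposure has zero variance")

    Xc = Xm - Xm.mean(axis=0)
    ec = e - e.mean()
    cross = ec[:, None] * Xc  # cross-moment target is exactly zero
    C = np.column_stack([Xc, ec, cross])
    scale = C.std(axis=0, ddof=0)
    scale[scale <= 0] = 1.0
    Cs = C / scale
    m = Cs.shape[1]

    def dual_value(theta):
        a = Cs @ theta
        amax = a.max()
        return float(amax + np.log(np.exp(a - amax).sum())), a

    # damped Newton on the convex dual; the Hessian is the weighted
    # covariance of the constraint functions (m x m, m ~ 31)
    theta = np.zeros(m)
    val, a = dual_value(theta)
    for _ in range(max_iter):
        z = np.exp(a - a.max())
        w_prob = z / z.sum()
        grad = Cs.T @ w_prob
        if np.abs(grad).max() < tol:
            break
        H = (Cs * w_prob[:, None]).T @ Cs - np.outer(grad, grad)
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        slope = float(grad @ step)
        alpha = 1.0
        for _ in range(60):  # Armijo backtracking
            new_val, new_a = dual_value(theta - alpha * step)
            if new_val <= val - 1e-4 * alpha * slope:
                break
            alpha *= 0.5
        else:
            break  # no descent direction makes progress
        theta = theta - alpha * step
        val, a = new_val, new_a
        if np.linalg.norm(theta) > 1e8:  # dual diverging: primal infeasible
            break

    z = np.exp(a - a.max())
    w = z / z.mean()  # sum w = n

    violation = np.abs((Cs * w[:, None]).mean(axis=0))
    worst = float(violation.max())
    if worst > tol:
        j = int(violation.argmax())
        name = cols[j] if j < len(cols) else ("exposure_mean" if j == len(cols) else f"cross:{cols[j - len(cols) - 1]}")
        raise RuntimeError(
            f"entropy balancing did not converge (worst standardized violation "
            f"{worst:.2e} on constraint {name!r})"
        )
    return _diagnostics(e, Xm, cols, w, "ebal")


def select_method(results: list[BalanceResult]) -> BalanceResult:
    """Pick the best-balancing candidate.

    Most confounders balanced (|weighted r| <= 0.10) wins; ties go to the
    smaller worst |r|, then to the larger effective sample size.
    """
    if not results:
        raise ValueError("no candidate balance results")
    return max(results, key=lambda r: (r.n_balanced, -r.max_abs_post_corr, r.ess))


def balance_all_methods(exposure, X, methods=("gps", "ebal")) -> tuple[BalanceResult, list[BalanceResult]]:
    """Run the requested weighting methods and select the best balance.

    A method that fails (infeasible constraints, overlap violation) is
    dropped from the candidate set rather than aborting the run.
    """
    candidates: list[BalanceResult] = []
    errors: dict[str, str] = {}
    for method in methods:
        try:
            if method == "gps":
                candidates.append(gps_weights(exposure, X))
            elif method == "ebal":
                candidates.append(constrained_balance_weights(exposure, X))
            else:
                raise ValueError(f"unknown balancing method {method!r}")
        except (RuntimeError, ValueError) as exc:  # keep going with the rest
            errors[method] = str(exc)
    if not candidates:
        raise RuntimeError(f"all balancing methods failed: {errors}")
    return select_method(candidates), candidates
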