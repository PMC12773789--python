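"""PCA of the four unpredictability indices and the weighted composite.

The four indices are z-scored (sample sd) and the correlation matrix
eigendecomposed.  Components are sorted by descending eigenvalue and
sign-fixed so each component's loading on the variance-changepoint count
is non-negative.  The composite unpredictability index is the weighted
average of the retained component scores, weights proportional to each
component's variance-explained share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envstats import FEATURES

__all__ = ["ComponentModel", "fit_pca", "composite_index"]

_SIGN_FEATURE = "n_cpt_var"


@dataclass
class ComponentModel:
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # p x p unit-norm eigenvectors, columns = components
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # proportions, all p components, sums to 1
    scores: pd.DataFrame          # per-family scores for retained components
    k: int

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "k": self.k,
            "sign_convention": f"loading on {_SIGN_FEATURE} non-negative",
        }


def fit_pca(env_stats: pd.DataFrame, features=FEATURES, k: int = 2) -> ComponentModel:
    """Correlation-matrix PCA of the unpredictability indices.

    Requires at least 5 families and nonzero variance in every feature.
    Scores are the z-scored data projected on the unit-norm eigenvectors.
    """
    features = list(features)
    if len(env_stats) < 5:
        raise ValueError("PCA needs at least 5 families")
    X = env_stats.loc[:, features].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(features, sds):
        if sd <= 0:
            raise ValueError(f"feature {name!r} has zero variance")
    Z = (X - means) / sds
    R = (Z.T @ Z) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    sign_row = features.index(_SIGN_FEATURE) if _SIGN_FEATURE in features else 0
    for j in range(evecs.shape[1]):
        if evecs[sign_row, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Z @ evecs[:, :k]
    score_df = pd.DataFrame(
        scores, columns=[f"pc{j + 1}" for j in range(k)], index=env_stats.index
    )
    if "family_id" in env_stats.columns:
        score_df.insert(0, "family_id", env_stats["family_id"].values)
    return ComponentModel(
        feature_names=features,
        means=means,
        sds=sds,
        loadings=evecs,
        eigenvalues=evals,
        variance_explained=evals / evals.sum(),
        scores=score_df,
        k=int(k),
    )


def composite_index(model: ComponentModel) -> pd.DataFrame:
    """Weighted average of retained component scores.

    Weights are the variance-explained proportions of the retained
    components, normalized to sum to one, so with the two-component
    default the composite is (ve1*pc1 + ve2*pc2) / (ve1 + ve2).
    """
    if model.k < 1:
        raise ValueError("need at least one retained component")
    ve = model.variance_explained[: model.k]
    w = ve / ve.sum()
    score_cols = [f"pc{j + 1}" for j in range(model.k)]
    comp = model.scores.loc[:, score_cols].to_numpy() @ w
    out = pd.DataFrame({"composite": comp}, index=model.scores.index)
    if "family_id" in model.scores.columns:
        out.insert(0, "family_id", model.scores["family_id"].values)
    return out
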