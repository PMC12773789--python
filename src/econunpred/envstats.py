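"""Per-family environmental unpredictability statistics.

Four indices summarize the unpredictability of a family's monthly economic
hardship series (1-7 scale):

* **coefficient of variation** — sample sd / mean; scale-free amount of
  fluctuation around the family's own hardship level,
* **changepoints in mean** and **changepoints in variance** — counts of
  penalized-likelihood shifts in level and in spread, detected with PELT
  (Pruned Exact Linear Time) and verifiable against an exhaustive
  dynamic-programming segmenter,
* **noise color** — the spectral exponent beta of what remains after
  removing a linear trend, an annual harmonic, and a linear trend in
  spread; beta near 0 is white (maximally random), beta near 2 is red
  (slow, predictable drift), negative beta is fast but regular
  alternation.  The index reported downstream is a monotone transform of
  beta for which higher = more unpredictable.

Changepoint detection operates on the observed monthly values only (gaps
are not imputed); spectral estimation requires a regular grid, so the
noise stage linearly interpolates internal gaps first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import MonthlySeries

__all__ = [
    "Segmentation",
    "EnvStatsRecord",
    "coefficient_of_variation",
    "segment_optimal",
    "detect_changepoints",
    "penalty_value",
    "detrend_for_noise",
    "noise_color",
    "transform_noise",
    "compute_env_stats",
    "FEATURES",
]

#: feature order used throughout (PCA, reports)
FEATURES = ("cv", "n_cpt_mean", "n_cpt_var", "noise_unpred")

_TIE_TOL = 1e-9
_VAR_FLOOR = 1e-12


@dataclass
class Segmentation:
    """Result of a penalized segmentation of one series.

    ``changepoints`` are the 1-based indices of the last point of each
    segment except the final one (the convention of the R ``changepoint``
    family of tools), so a series split after its 10th point has
    ``changepoints == [10]``.
    """

    changepoints: list[int]
    segment_params: list[float]
    total_cost: float
    penalty: float
    kind: str
    n: int

    @property
    def n_changepoints(self) -> int:
        return len(self.changepoints)


@dataclass
class EnvStatsRecord:
    family_id: str
    cv: float
    n_cpt_mean: int
    n_cpt_var: int
    noise_beta: float
    noise_unpred: float
    n_months: int
    severity: float
    interpolation_flag: bool = False
    segmentation_mean: Segmentation | None = field(default=None, repr=False)
    segmentation_var: Segmentation | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# coefficient of variation


def coefficient_of_variation(series: MonthlySeries | np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    The +1 transform applied at ingest guarantees a strictly positive
    mean, which is what makes this ratio well defined for families who
    reported no hardship in most months.
    """
    values = np.asarray(series.values if isinstance(series, MonthlySeries) else series, dtype=float)
    if values.size < 2:
        raise ValueError("coefficient of variation needs at least 2 observations")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation undefined for non-positive mean")
    return float(values.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# segment costs


class _SegmentCost:
    """Precomputed per-segment cost C(s, t) over y[s:t] (0-based slices).

    kind='mean'   : SSE about the segment mean, scaled by a robust global
                    variance (squared scaled MAD), plus n_s*log(sigma2_g).
                    The robust scale avoids the changepoints themselves
                    inflating the variance estimate and masking detection.
    kind='variance': n_s*(log(sigma2_s) + 1) with deviations taken about
                    the global series mean.
    """

    def __init__(self, y: np.ndarray, kind: str):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("segmentation input contains non-finite values")
        self.n = y.size
        self.kind = kind
        if kind == "mean":
            self.min_seglen = 1
            # robust noise scale from successive differences: immune to the
            # level shifts being sought; fall back to plain MAD, then the
            # sample sd, for heavily quantized or short series
            sig2 = 0.0
            if self.n >= 2:
                sig2 = (1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)) ** 2
            if sig2 <= _VAR_FLOOR:
                sig2 = (1.4826 * np.median(np.abs(y - np.median(y)))) ** 2
            if sig2 <= _VAR_FLOOR:
                sig2 = max(float(y.var()), _VAR_FLOOR)
            self.sig2_global = sig2
            self._log_sig2 = math.log(sig2)
            self._s1 = np.concatenate(([0.0], np.cumsum(y)))
            self._s2 = np.concatenate(([0.0], np.cumsum(y * y)))
        elif kind == "variance":
            self.min_seglen = 2
            d = (y - y.mean()) ** 2
            self._d1 = np.concatenate(([0.0], np.cumsum(d)))
            self._y1 = np.concatenate(([0.0], np.cumsum(y)))
        else:
            raise ValueError(f"unknown segmentation kind: {kind!r}")

    def cost(self, s: int, t: int) -> float:
        m = t - s
        if self.kind == "mean":
            sse = self._s2[t] - self._s2[s] - (self._s1[t] - self._s1[s]) ** 2 / m
            return sse / self.sig2_global + m * self._log_sig2
        sig2 = max((self._d1[t] - self._d1[s]) / m, _VAR_FLOOR)
        return m * (math.log(sig2) + 1.0)

    def param(self, s: int, t: int) -> float:
        m = t - s
        if self.kind == "mean":
            return float((self._s1[t] - self._s1[s]) / m)
        return float(max((self._d1[t] - self._d1[s]) / m, 0.0))


def penalty_value(rule: str, n: int) -> float:
    """Penalty charged per changepoint.

    ``mbic``: 3*log(n), the default; ``bic``: 2*log(n) (one segment
    parameter plus one changepoint location per extra segment).
    """
    if n < 2:
        raise ValueError("penalty undefined for n < 2")
    if rule == "mbic":
        return 3.0 * math.log(n)
    if rule == "bic":
        return 2.0 * math.log(n)
    raise ValueError(f"unknown penalty rule: {rule!r}")


def _better(cost_a, k_a, s_a, cost_b, k_b, s_b) -> bool:
    """Candidate ordering: lower cost; ties -> fewer changepoints, then
    earliest last-changepoint.  Shared by the DP oracle and PELT so the
    two return bit-identical segmentations."""
    if cost_a < cost_b - _TIE_TOL:
        return True
    if cost_a > cost_b + _TIE_TOL:
        return False
    return (k_a, s_a) < (k_b, s_b)


def _backtrack(prev: list[int], n: int) -> list[int]:
    cpts: list[int] = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cpts.append(s)
        t = s
    cpts.reverse()
    return cpts


def _finalize(y, cost_obj: _SegmentCost, cpts: list[int], total: float, penalty: float) -> Segmentation:
    bounds = [0] + cpts + [cost_obj.n]
    params = [cost_obj.param(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    return Segmentation(
        changepoints=cpts,
        segment_params=params,
        total_cost=float(total),
        penalty=float(penalty),
        kind=cost_obj.kind,
        n=cost_obj.n,
    )


def segment_optimal(
    values,
    kind: str = "mean",
    penalty: float | None = None,
    penalty_rule: str = "mbic",
    min_seglen: int | None = None,
) -> Segmentation:
    """Globally optimal penalized segmentation by exhaustive O(n^2) DP.

    This is the reference implementation that :func:`detect_changepoints`
    (PELT) is required to reproduce exactly; it considers every admissible
    last-changepoint position at every endpoint.
    """
    y = np.asarray(values, dtype=float)
    c = _SegmentCost(y, kind)
    msl = c.min_seglen if min_seglen is None else max(min_seglen, c.min_seglen)
    n = c.n
    if n < msl:
        raise ValueError(f"series of length {n} shorter than min segment length {msl}")
    pen = penalty_value(penalty_rule, n) if penalty is None else float(penalty)

    F = [math.inf] * (n + 1)
    K = [0] * (n + 1)
    prev = [0] * (n + 1)
    F[0] = -pen
    for t in range(msl, n + 1):
        best_cost, best_k, best_s = math.inf, 0, -1
        for s in range(0, t - msl + 1):
            if s != 0 and s < msl:
                continue
            if F[s] == math.inf:
                continue
            cand = F[s] + c.cost(s, t) + pen
            k = K[s] + (1 if s > 0 else 0)
            if best_s < 0 or _better(cand, k, s, best_cost, best_k, best_s):
                best_cost, best_k, best_s = cand, k, s
        F[t], K[t], prev[t] = best_cost, best_k, best_s
    return _finalize(y, c, _backtrack(prev, n), F[n], pen)


def detect_changepoints(
    values,
    kind: str = "mean",
    penalty: float | None = None,
    penalty_rule: str = "mbic",
    min_seglen: int | None = None,
) -> Segmentation:
    """PELT: pruned exact search for the optimal penalized segmentation.

    Identical cost function, penalty, and tie-breaking to
    :func:`segment_optimal`; candidate last-changepoints that can no
    longer participate in an optimal solution are pruned, giving
    near-linear expected time.  The pruning inequality keeps a small
    tolerance margin so cost ties survive to be broken the same way the
    oracle breaks them.
    """
    y = np.asarray(values, dtype=float)
    c = _SegmentCost(y, kind)
    msl = c.min_seglen if min_seglen is None else max(min_seglen, c.min_seglen)
    n = c.n
    if n < msl:
        raise ValueError(f"series of length {n} shorter than min segment length {msl}")
    pen = penalty_value(penalty_rule, n) if penalty is None else float(penalty)

    F = [math.inf] * (n + 1)
    K = [0] * (n + 1)
    prev = [0] * (n + 1)
    F[0] = -pen
    cand_set: list[int] = [0]
    for t in range(msl, n + 1):
        best_cost, best_k, best_s = math.inf, 0, -1
        usable = [s for s in cand_set if t - s >= msl]
        for s in usable:
            cand = F[s] + c.cost(s, t) + pen
            k = K[s] + (1 if s > 0 else 0)
            if best_s < 0 or _better(cand, k, s, best_cost, best_k, best_s):
                best_cost, best_k, best_s = cand, k, s
        F[t], K[t], prev[t] = best_cost, best_k, best_s
        # prune: s stays only while it could still start the final segment
        # of an optimal segmentation (margin keeps exact ties alive)
        cand_set = [
            s for s in cand_set if t - s < msl or F[s] + c.cost(s, t) <= F[t] + _TIE_TOL
        ]
        if t >= msl:  # t is admissible as a future last-changepoint
            cand_set.append(t)
    return _finalize(y, c, _backtrack(prev, n), F[n], pen)


# ---------------------------------------------------------------------------
# noise color


def _design_matrix(t: np.ndarray, month_of_year: np.ndarray) -> np.ndarray:
    ang = 2.0 * math.pi * month_of_year / 12.0
    return np.column_stack([np.ones_like(t), t, np.sin(ang), np.cos(ang)])


def detrend_for_noise(series: MonthlySeries) -> tuple[np.ndarray, bool]:
    """Residual series on a regular monthly grid, systematic structure removed.

    Steps: (a) internal gaps filled by linear interpolation onto the
    regular monthly grid; (b) OLS removal of intercept, linear trend and
    one annual harmonic pair; (c) variance detrending — |residual| is
    regressed on time and each residual divided by the fitted value
    (floored at 0.1 x median |residual| to avoid blow-ups near a zero
    crossing of the fit).

    Returns ``(residuals, flagged)`` where ``flagged`` is True when more
    than 20% of grid months were interpolated.
    """
    idx = np.asarray(series.month_index, dtype=float)
    vals = np.asarray(series.values, dtype=float)
    grid = np.arange(idx[0], idx[-1] + 1)
    filled = np.interp(grid, idx, vals)
    n_interp = grid.size - idx.size
    flagged = grid.size > 0 and n_interp / grid.size > 0.20

    moy = (series.first_month_of_year - 1 + (grid - grid[0]).astype(int)) % 12 + 1
    t = grid - grid[0]
    X = _design_matrix(t, moy.astype(float))
    beta, *_ = np.linalg.lstsq(X, filled, rcond=None)
    resid = filled - X @ beta

    absr = np.abs(resid)
    scale_ref = max(1.0, float(np.max(np.abs(filled))))
    if np.max(absr) < 1e-10 * scale_ref:
        return resid, flagged  # numerically zero residuals: nothing to scale
    Xv = np.column_stack([np.ones_like(t), t])
    bv, *_ = np.linalg.lstsq(Xv, absr, rcond=None)
    fitted = Xv @ bv
    floor = 0.1 * np.median(absr)
    if floor <= 0:
        floor = 0.1 * float(np.mean(absr))
    resid = resid / np.maximum(fitted, floor)
    return resid, flagged


def detrend_values(values, first_month_of_year: int = 1) -> np.ndarray:
    """Detrend a gap-free array directly (helper for calibration work)."""
    values = np.asarray(values, dtype=float)
    ms = MonthlySeries.from_regular(values, first_month_of_year=first_month_of_year)
    resid, _ = detrend_for_noise(ms)
    return resid


def noise_color(residuals) -> float:
    """Spectral exponent beta from the log-log periodogram slope.

    Periodogram ordinates at Fourier frequencies f_j = j/n,
    j = 1..floor((n-1)/2); beta is minus the least-squares slope of
    log power on log frequency.  Zero-power ordinates are dropped.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n < 8:
        raise ValueError("noise color needs at least 8 residual points")
    spec = np.fft.rfft(r)
    j = np.arange(1, (n - 1) // 2 + 1)
    power = np.abs(spec[j]) ** 2 / n
    freq = j / n
    keep = power > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable periodogram ordinates")
    lx = np.log(freq[keep])
    ly = np.log(power[keep])
    slope = np.polyfit(lx, ly, 1)[0]
    return float(-slope)


def transform_noise(beta: float, rule: str = "negabs") -> float:
    """Map the raw spectral exponent to an unpredictability score.

    ``negabs`` (default): -|beta| — distance from white noise, negated so
    that higher values mean more unpredictable; white noise (beta=0) is
    the maximally unpredictable color and scores 0, while both red
    (beta=2) and blue (beta=-1) structure score negative.  Alternatives:
    ``neg`` (-beta) and ``shift`` (2-beta) order colors by slowness
    instead and are kept for sensitivity analyses.
    """
    if rule == "negabs":
        return -abs(beta)
    if rule == "neg":
        return -beta
    if rule == "shift":
        return 2.0 - beta
    raise ValueError(f"unknown noise transform: {rule!r}")


# ---------------------------------------------------------------------------
# per-family driver


def compute_env_stats(
    series: MonthlySeries,
    penalty_rule: str = "mbic",
    noise_transform: str = "negabs",
    keep_segmentations: bool = False,
) -> EnvStatsRecord:
    """All four unpredictability indices plus severity for one family."""
    vals = np.asarray(series.values, dtype=float)
    cv = coefficient_of_variation(vals)
    seg_mean = detect_changepoints(vals, kind="mean", penalty_rule=penalty_rule)
    seg_var = detect_changepoints(vals, kind="variance", penalty_rule=penalty_rule)
    resid, flagged = detrend_for_noise(series)
    beta = noise_color(resid)
    return EnvStatsRecord(
        family_id=series.family_id,
        cv=cv,
        n_cpt_mean=seg_mean.n_changepoints,
        n_cpt_var=seg_var.n_changepoints,
        noise_beta=beta,
        noise_unpred=transform_noise(beta, noise_transform),
        n_months=int(vals.size),
        severity=float(vals.mean()),
        interpolation_flag=flagged,
        segmentation_mean=seg_mean if keep_segmentations else None,
        segmentation_var=seg_var if keep_segmentations else None,
    )


def env_stats_table(
    series_list: list[MonthlySeries],
    penalty_rule: str = "mbic",
    noise_transform: str = "negabs",
) -> pd.DataFrame:
    """Tidy per-family table of the indices (one row per eligible family)."""
    rows = []
    for s in series_list:
        rec = compute_env_stats(s, penalty_rule=penalty_rule, noise_transform=noise_transform)
        rows.append(
            {
                "family_id": rec.family_id,
                "cv": rec.cv,
                "n_cpt_mean": rec.n_cpt_mean,
                "n_cpt_var": rec.n_cpt_var,
                "noise_beta": rec.noise_beta,
                "noise_unpred": rec.noise_unpred,
                "n_months": rec.n_months,
                "severity": rec.severity,
                "interpolation_flag": rec.interpolation_flag,
            }
        )
    return pd.DataFrame(rows)
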