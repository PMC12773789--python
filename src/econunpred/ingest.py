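"""From raw survey responses to per-family monthly hardship series.

Each survey response carries six binary "hard to pay for" items (food,
housing, utilities, healthcare, childcare, socioemotional well-being).
Scoring sums the items (0-6); responses are bucketed by calendar month;
multiple responses within a month are averaged; and 1 is added to every
monthly score so the series lives on 1-7 with a strictly positive mean
(required by the coefficient of variation).  Families contributing at
least ``min_months`` observed months (15 by default) are eligible for the
unpredictability statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_COLUMNS",
    "MonthlySeries",
    "score_responses",
    "monthly_aggregate",
    "build_series",
    "filter_eligible",
    "severity",
    "severity_table",
]

ITEM_COLUMNS = (
    "item_food",
    "item_housing",
    "item_utilities",
    "item_healthcare",
    "item_childcare",
    "item_wellbeing",
)


@dataclass
class MonthlySeries:
    """One family's ordered monthly hardship values on the 1-7 scale.

    ``months`` holds the observed calendar months as "YYYY-MM" strings in
    strictly increasing order; unobserved months between the first and
    last observation are *gaps*, retained as gaps (``gap_months``) rather
    than imputed.  ``month_index`` gives each observed month's integer
    offset in months since year 0, so differences are calendar-month
    distances.
    """

    family_id: str
    months: list[str]
    values: np.ndarray
    gap_months: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.months) != self.values.size:
            raise ValueError("months and values length mismatch")
        idx = self.month_index
        if np.any(np.diff(idx) <= 0):
            raise ValueError("months must be strictly increasing")

    @property
    def n_months(self) -> int:
        return int(self.values.size)

    @property
    def month_index(self) -> np.ndarray:
        out = np.empty(len(self.months), dtype=int)
        for i, m in enumerate(self.months):
            y, mo = m.split("-")
            out[i] = int(y) * 12 + int(mo) - 1
        return out

    @property
    def first_month_of_year(self) -> int:
        return int(self.months[0].split("-")[1])

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean mask over the regular grid from first to last observed
        month: True where the month was NOT observed."""
        idx = self.month_index
        span = np.arange(idx[0], idx[-1] + 1)
        return ~np.isin(span, idx)

    @classmethod
    def from_regular(
        cls, values, family_id: str = "f", start: str = "2020-04", first_month_of_year: int | None = None
    ) -> "MonthlySeries":
        """Build a gap-free series from an array (test/calibration helper)."""
        values = np.asarray(values, dtype=float)
        if first_month_of_year is not None:
            start = f"2001-{first_month_of_year:02d}"
        y0, m0 = (int(p) for p in start.split("-"))
        base = y0 * 12 + m0 - 1
        months = [f"{(base + k) // 12:04d}-{(base + k) % 12 + 1:02d}" for k in range(values.size)]
        return cls(family_id=family_id, months=months, values=values)


def score_responses(responses: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Sum the six binary items per response (0-6 scale).

    Responses with any missing or out-of-range item are dropped rather
    than prorated — a partial sum would read as lower hardship — and the
    dropped count is returned for the eligibility report.
    """
    missing = [c for c in ITEM_COLUMNS if c not in responses.columns]
    if missing:
        raise ValueError(f"responses table lacks item columns: {missing}")
    items = responses.loc[:, list(ITEM_COLUMNS)]
    valid_vals = items.isin([0, 1]).all(axis=1) & items.notna().all(axis=1)
    n_dropped = int((~valid_vals).sum())
    kept = responses.loc[valid_vals].copy()
    kept["sum_score"] = items.loc[valid_vals].sum(axis=1).astype(float)
    return kept, n_dropped


def monthly_aggregate(scored: pd.DataFrame, family_id: str) -> MonthlySeries:
    """Calendar-month aggregation with the +1 transform for one family.

    Within a month the mean of available sum scores is taken; months are
    sorted; intervening unobserved months are recorded as gaps.
    """
    sub = scored.loc[scored["family_id"] == family_id]
    if sub.empty:
        raise ValueError(f"no scored responses for family {family_id!r}")
    month = pd.to_datetime(sub["date"]).dt.strftime("%Y-%m")
    agg = sub.groupby(month.values)["sum_score"].mean().sort_index()
    months = list(agg.index)
    values = agg.to_numpy(dtype=float) + 1.0
    series = MonthlySeries(family_id=str(family_id), months=months, values=values)
    idx = series.month_index
    span = np.arange(idx[0], idx[-1] + 1)
    gaps = sorted(set(span) - set(idx))
    series.gap_months = [f"{g // 12:04d}-{g % 12 + 1:02d}" for g in gaps]
    return series


def build_series(responses: pd.DataFrame) -> tuple[list[MonthlySeries], dict]:
    """Score and aggregate every family in a long responses table."""
    scored, n_dropped = score_responses(responses)
    series = [monthly_aggregate(scored, fid) for fid in sorted(scored["family_id"].unique())]
    return series, {"n_responses": int(len(responses)), "n_dropped_responses": n_dropped}


def filter_eligible(
    series_list: list[MonthlySeries], min_months: int = 15
) -> tuple[list[MonthlySeries], dict]:
    """Retain families with at least ``min_months`` observed months.

    Eligibility counts observed months, not the first-to-last span.
    """
    if min_months < 2:
        raise ValueError("min_months must be at least 2")
    eligible = [s for s in series_list if s.n_months >= min_months]
    report = {
        "min_months": int(min_months),
        "n_total": len(series_list),
        "n_eligible": len(eligible),
        "n_excluded": len(series_list) - len(eligible),
    }
    return eligible, report


def severity(series: MonthlySeries) -> float:
    """Time-mean hardship across observed months (gaps ignored), 1-7 scale."""
    return float(np.asarray(series.values, dtype=float).mean())


def severity_table(series_list: list[MonthlySeries]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [s.family_id for s in series_list],
            "severity": [severity(s) for s in series_list],
            "n_months": [s.n_months for s in series_list],
        }
    )


def frame_to_series(df: pd.DataFrame) -> list[MonthlySeries]:
    """Rebuild :class:`MonthlySeries` objects from the tidy long form."""
    out = []
    for fid, sub in df.groupby("family_id", sort=True):
        obs = sub.loc[sub["is_gap"] == 0].sort_values("month")
        s = MonthlySeries(
            family_id=str(fid),
            months=list(obs["month"]),
            values=obs["value"].to_numpy(dtype=float),
        )
        s.gap_months = sorted(sub.loc[sub["is_gap"] == 1, "month"])
        out.append(s)
    return out


def series_to_frame(series_list: list[MonthlySeries]) -> pd.DataFrame:
    """Long tidy form (family_id, month, value, is_gap) for monthly_series.csv."""
    rows = []
    for s in series_list:
        for m, v in zip(s.months, s.values):
            rows.append({"family_id": s.family_id, "month": m, "value": float(v), "is_gap": 0})
        for g in s.gap_months:
            rows.append({"family_id": s.family_id, "month": g, "value": float("nan"), "is_gap": 1})
    df = pd.DataFrame(rows)
    return df.sort_values(["family_id", "month"], kind="mergesort").reset_index(drop=True)
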