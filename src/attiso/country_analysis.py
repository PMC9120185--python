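"""Country-level predictive analysis of attitude-isolation.

Links per-country attitude-isolation to subsequent changes in vaccination
coverage (measles second dose, two consecutive years) and in the fraction
of strongly distrusting respondents, with partial correlations controlling
for wealth and country-level vaccine trust (the proportion of strongly
positive vaccine answers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attitude_network import attitude_isolation
from .survey_core import SurveyDataset, UndefinedResultError

__all__ = [
    "CountryTable",
    "vcp_trust",
    "increment",
    "partial_correlation",
    "dedupe_earliest",
    "build_country_table",
    "predictive_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class CountryTable:
    """One row per country: isolation, coverage and distrust for two years,
    wealth, and the trust proportion."""

    table: pd.DataFrame  # indexed by country code

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate countries in table")


def vcp_trust(data: SurveyDataset, country: str, per_respondent: bool = False) -> float:
    """Country-level trust: proportion of strongly positive vaccine answers.

    Default is the answer-level proportion (strong-trust answers among all
    vaccine answers given); ``per_respondent=True`` instead gives the
    proportion of respondents answering strong trust on all three items.
    """
    sub = data.restrict(country)
    vax_ids = [it.item_id for it in sub.vaccine_items]
    codes = sub.codes(vax_ids).dropna()
    if codes.empty:
        raise UndefinedResultError(f"no complete vaccine respondents in {country!r}")
    if per_respondent:
        return float((codes == 5).all(axis=1).mean())
    return float((codes.to_numpy() == 5).mean())


def increment(y1: float, y2: float) -> float:
    """Year-over-year change, later minus earlier."""
    if pd.isna(y1) or pd.isna(y2):
        raise ValueError("increment requires both years")
    return float(y2 - y1)


def partial_correlation(
    x, y, controls: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out the controls.

    Both variables are residualized on the controls (with an intercept) by
    least squares; with no controls this is the plain Pearson correlation.
    The p-value uses a t test with n - 2 - k degrees of freedom for k
    controls.  Rank-deficient controls raise, naming the offending columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "shape") and np.size(controls) == 0):
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    names = list(controls.columns) if isinstance(controls, pd.DataFrame) else None
    z = np.asarray(controls, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, k = z.shape
    if n != len(x) or n != len(y):
        raise ValueError("x, y and controls differ in length")
    if n < 3 + k:
        raise ValueError(f"need at least {3 + k} observations for {k} controls")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        labels = names if names is not None else [f"control_{i}" for i in range(k)]
        raise ValueError(f"collinear controls: {labels}")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    t = r * np.sqrt(dof / max(1e-300, 1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), dof))
    return r, p


def dedupe_earliest(
    rows: pd.DataFrame,
    country_col: str = "country",
    year_col: str = "year",
    date_col: str = "date",
) -> pd.DataFrame:
    """Keep the earliest-dated row per country-year.

    Ties keep the first row in input order, with a warning.
    """
    df = rows.copy()
    df["_date"] = pd.to_datetime(df[date_col])
    df["_order"] = np.arange(len(df))
    picked = []
    for (_, _), grp in df.groupby([country_col, year_col], sort=False):
        best = grp["_date"].min()
        hits = grp[grp["_date"] == best]
        if len(hits) > 1:
            warnings.warn(
                f"tied dates for {grp[country_col].iloc[0]}/{grp[year_col].iloc[0]}; "
                "keeping the first in input order"
            )
        picked.append(hits.sort_values("_order").index[0])
    return rows.loc[sorted(picked, key=lambda i: df.loc[i, "_order"])].reset_index(drop=True)


def build_country_table(
    isolation: pd.DataFrame,
    coverage: pd.DataFrame,
    distrust: pd.DataFrame,
    wealth: pd.DataFrame,
) -> CountryTable:
    """Inner-join the four per-country sources on the country code.

    Expected columns: isolation(country, isolation[, vcp_trust]),
    coverage(country, coverage_y1, coverage_y2),
    distrust(country, distrust_y1, distrust_y2), wealth(country, wealth).
    A country absent from any source is dropped (logged).
    """
    frames = {"isolation": isolation, "coverage": coverage, "distrust": distrust, "wealth": wealth}
    merged = None
    for name, df in frames.items():
        if "country" not in df.columns:
            raise ValueError(f"{name} table lacks a 'country' column")
        df = df.set_index("country")
        merged = df if merged is None else merged.join(df, how="inner")
    all_countries = set().union(*(set(df["country"]) for df in frames.values()))
    dropped = sorted(all_countries - set(merged.index))
    if dropped:
        logger.info("countries absent from some source dropped: %s", dropped)
    return CountryTable(merged)


def predictive_analysis(table: CountryTable) -> dict:
    """The headline country-level correlations.

    Returns isolation vs. coverage increment (plain and partial,
    controlling wealth and trust) and isolation vs. distrust increment.
    """
    df = table.table
    cov_inc = df["coverage_y2"] - df["coverage_y1"]
    dis_inc = df["distrust_y2"] - df["distrust_y1"]
    out = {}
    r, p = partial_correlation(df["isolation"], cov_inc)
    out["coverage_increment"] = {"r": r, "p": p, "n": len(df)}
    controls = df[[c for c in ("wealth", "vcp_trust") if c in df.columns]]
    r, p = partial_correlation(df["isolation"], cov_inc, controls)
    out["coverage_increment_partial"] = {
        "r": r,
        "p": p,
        "n": len(df),
        "controls": list(controls.columns),
    }
    r, p = partial_correlation(df["isolation"], dis_inc)
    out["distrust_increment"] = {"r": r, "p": p, "n": len(df)}
    return out
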