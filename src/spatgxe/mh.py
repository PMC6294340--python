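"""Age-stratified Mantel–Haenszel risk ratios per locale.

The model-free overall risk map: each locale's cumulative risk is compared
against the rest of the sample ("national average" comparator — every
locale is small relative to the country, so outside-the-locale counts
approximate national counts), pooling age strata with the Mantel–Haenszel
estimator. Counts may be inverse-probability weighted so that case-cohort
tallies estimate population tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["StratumCounts", "LocaleRR", "build_strata", "mantel_haenszel_rr", "mh_risk_table"]


@dataclass(frozen=True)
class StratumCounts:
    """Weighted 2x2 margin for one locale in one age stratum.

    a/n1: (weighted) cases/total inside the locale; c/n0: outside.
    """

    stratum: str
    a: float
    n1: float
    c: float
    n0: float

    def __post_init__(self):
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n0):
            raise ValueError(f"inconsistent stratum counts: {self}")


@dataclass(frozen=True)
class LocaleRR:
    locale_id: int
    rr: float  # NaN when undefined
    ci_low: float
    ci_high: float
    n_strata_used: int


def _age_bands(ages: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(ages / width) * width
    return np.array([f"[{a:g},{a + width:g})" for a in lo])


def build_strata(
    subjects: pd.DataFrame,
    assignment: pd.Series,
    age_breaks: float | list[float] = 5.0,
    weighted: bool = True,
    age_col: str = "event_age",
    case_col: str = "case",
    weight_col: str = "weight",
) -> dict[int, list[StratumCounts]]:
    """Per-locale, per-age-band weighted case/total counts inside vs outside.

    ``age_breaks`` is either a band width in years (default 5-year bands of
    age at study end) or an explicit list of cut points. With
    ``weighted=False`` all weights are 1 (raw case-cohort counts).
    """
    ages = subjects[age_col].to_numpy(dtype=float)
    if np.isscalar(age_breaks):
        bands = _age_bands(ages, float(age_breaks))
    else:
        cut = pd.cut(ages, bins=list(age_breaks), right=False)
        bands = cut.astype(str)
    case = subjects[case_col].to_numpy(dtype=float)
    if weighted and weight_col in subjects.columns:
        w = subjects[weight_col].to_numpy(dtype=float)
    else:
        w = np.ones(len(subjects))
    loc = np.asarray(assignment)

    df = pd.DataFrame({"locale": loc, "band": bands, "wcase": w * case, "w": w})
    by_band = df.groupby("band")[["wcase", "w"]].sum()
    by_loc_band = df.groupby(["locale", "band"])[["wcase", "w"]].sum()

    out: dict[int, list[StratumCounts]] = {}
    for locale_id in np.unique(loc):
        rows = []
        sub = by_loc_band.loc[locale_id]
        for band, r in sub.iterrows():
            tot = by_band.loc[band]
            a, n1 = float(r["wcase"]), float(r["w"])
            c, n0 = float(tot["wcase"] - a), float(tot["w"] - n1)
            if n1 <= 0 or n0 <= 0:
                logger.debug("locale %s stratum %s empty on one side; dropped", locale_id, band)
                continue
            rows.append(StratumCounts(str(band), a, n1, c, n0))
        out[int(locale_id)] = rows
    return out


def mantel_haenszel_rr(strata: list[StratumCounts], alpha: float = 0.05) -> LocaleRR:
    """Mantel–Haenszel risk ratio pooled over strata, with a
    Greenland–Robins variance 95% CI.

    RR_MH = [sum_s a_s n0_s / N_s] / [sum_s c_s n1_s / N_s].  Strata with a
    zero inside or outside total are dropped (no continuity correction); if
    the denominator is zero the RR is undefined and returned as NaN.
    """
    used = [s for s in strata if s.n1 > 0 and s.n0 > 0]
    if not used:
        raise ValueError("no informative stratum (need n1 > 0 and n0 > 0)")
    N = np.array([s.n1 + s.n0 for s in used])
    a = np.array([s.a for s in used])
    c = np.array([s.c for s in used])
    n1 = np.array([s.n1 for s in used])
    n0 = np.array([s.n0 for s in used])
    R = float(np.sum(a * n0 / N))
    S = float(np.sum(c * n1 / N))
    if S <= 0:
        logger.warning("MH denominator zero (no outside cases); RR undefined")
        return LocaleRR(-1, float("nan"), float("nan"), float("nan"), len(used))
    rr = R / S
    if R <= 0:
        return LocaleRR(-1, 0.0, 0.0, float("nan"), len(used))
    # Greenland–Robins variance for stratified risk ratios
    var = float(np.sum(((a + c) * n1 * n0 - a * c * N) / N**2)) / (R * S)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(max(var, 0.0))
    return LocaleRR(
        -1, rr, float(rr * np.exp(-z * se)), float(rr * np.exp(z * se)), len(used)
    )


def mh_risk_table(
    subjects: pd.DataFrame,
    assignment: pd.Series,
    age_breaks: float | list[float] = 5.0,
    weighted: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """MH risk ratio per locale vs the rest of the sample.

    Returns a DataFrame with columns locale_id, rr, ci_low, ci_high,
    n_strata_used, suitable for TSV export or for merging into the locale
    GeoJSON as choropleth properties.
    """
    strata = build_strata(subjects, assignment, age_breaks, weighted, **kwargs)
    rows = []
    for locale_id in sorted(strata):
        try:
            res = mantel_haenszel_rr(strata[locale_id])
        except ValueError:
            res = LocaleRR(locale_id, float("nan"), float("nan"), float("nan"), 0)
        rows.append(
            {
                "locale_id": locale_id,
                "rr": res.rr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_strata_used": res.n_strata_used,
            }
        )
    return pd.DataFrame(rows)
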