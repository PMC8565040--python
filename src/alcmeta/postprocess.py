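"""Posterior draws to reportable tables.

Every derived quantity — aggregated prevalence, mean consumption among
drinkers, survey coverage, drinking-category shares — is computed within
each posterior draw and only then summarised as the 50th (point), 2.5th and
97.5th (credible bounds) percentiles, so the credible intervals of secondary
statistics are exact functionals of the joint posterior rather than
combinations of marginal summaries.

Output tables:

* ``trend_table``    — per year x sex (and total): prevalence of drinkers and
  mean consumption among drinkers (grams/day);
* ``coverage_table`` — per survey: overall coverage; per sex x age group:
  relative coverage (the sex-age deviation, geometric mean one);
* ``category_report`` — per year x sex: proportions of light / intermediate /
  heavy drinkers, their mean consumptions and shares of total volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gammadist import CategoryThresholds, category_shares, category_volume_shares

__all__ = ["PosteriorSummary", "summarize", "population_aggregate",
           "trend_table", "coverage_table", "category_report",
           "DEFAULT_THRESHOLDS"]

#: light-upper / heavy-lower cut-points in grams/day per sex (male, female)
DEFAULT_THRESHOLDS = (CategoryThresholds(24.0, 60.0),
                      CategoryThresholds(12.0, 40.0))


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior median with the 95% credible bounds."""

    point: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo <= self.point <= self.hi):
            raise ValueError("summary must satisfy lo <= point <= hi")


def summarize(draws) -> PosteriorSummary:
    """50th / 2.5th / 97.5th percentiles of a vector of posterior draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarise an empty draw vector")
    lo, point, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return PosteriorSummary(point=float(point), lo=float(lo), hi=float(hi))


def population_aggregate(mu_draws, p_draws, pop, axes=(1, 3)):
    """Aggregate cell draws to population level, draw by draw.

    ``mu_draws`` and ``p_draws`` have shape (n_draws, 2, Y, A); ``pop``
    (2, Y, A).  Aggregation over the given cell axes (default: sexes and age
    groups, keeping years) uses population weights for prevalence and
    drinker mass ``p * pop`` for the mean among drinkers:

        P_agg = sum(p * pop) / sum(pop)
        C_agg = sum(mu * p * pop) / sum(p * pop)

    Returns ``(P_agg, C_agg)`` with the aggregated axes removed (the draw
    axis stays first).  A zero aggregate drinker mass yields NaN.
    """
    mu = np.asarray(mu_draws)
    p = np.asarray(p_draws)
    popb = np.broadcast_to(pop, p.shape)
    ax = tuple(a for a in axes)
    pw = (p * popb).sum(axis=ax)
    P = pw / popb.sum(axis=ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(pw > 0, (mu * p * popb).sum(axis=ax) / pw, np.nan)
    return P, C


def _summary_cols(draw_vec, prefix):
    lo, point, hi = np.percentile(np.asarray(draw_vec).ravel(), [2.5, 50.0, 97.5])
    return {f"{prefix}": float(point), f"{prefix}_lo": float(lo),
            f"{prefix}_hi": float(hi)}


def trend_table(draws, by_age: bool = False) -> pd.DataFrame:
    """Yearly prevalence and mean-consumption trends, per sex and total."""
    m = draws.model
    inp = m.inputs
    mu, p, _ = draws.surface_draws()
    rows = []
    sexes = {1: "male", 2: "female"}
    for g in (1, 2):
        if by_age:
            for a in range(inp.n_ages):
                for yi, year in enumerate(inp.years):
                    rows.append(dict(year=int(year), sex=sexes[g],
                                     age_group=a + 1,
                                     **_summary_cols(p[:, g - 1, yi, a], "prevalence"),
                                     **_summary_cols(mu[:, g - 1, yi, a], "consumption")))
        else:
            P, C = population_aggregate(mu[:, [g - 1]], p[:, [g - 1]],
                                        inp.pop[[g - 1]])
            for yi, year in enumerate(inp.years):
                rows.append(dict(year=int(year), sex=sexes[g], age_group="all",
                                 **_summary_cols(P[:, yi], "prevalence"),
                                 **_summary_cols(C[:, yi], "consumption")))
    if not by_age:
        P, C = population_aggregate(mu, p, inp.pop)
        for yi, year in enumerate(inp.years):
            rows.append(dict(year=int(year), sex="all", age_group="all",
                             **_summary_cols(P[:, yi], "prevalence"),
                             **_summary_cols(C[:, yi], "consumption")))
    return pd.DataFrame(rows)


def coverage_table(draws) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-survey overall coverage and per-(sex, age) relative coverage."""
    m = draws.model
    cprime, cdev = draws.coverage_draws()
    rows = []
    for j, sid in enumerate(m.inputs.survey_ids):
        s = summarize(cprime[:, j])
        rows.append(dict(survey_id=sid, coverage=s.point, coverage_lo=s.lo,
                         coverage_hi=s.hi))
    surveys = pd.DataFrame(rows)
    rows = []
    for g in (1, 2):
        for a in range(m.inputs.n_ages):
            s = summarize(cdev[:, g - 1, a])
            rows.append(dict(sex=g, age_group=a + 1, relative_coverage=s.point,
                             relative_coverage_lo=s.lo,
                             relative_coverage_hi=s.hi))
    relative = pd.DataFrame(rows)
    return surveys, relative


def category_report(draws, thresholds=DEFAULT_THRESHOLDS,
                    by_age: bool = False) -> pd.DataFrame:
    """Light/intermediate/heavy shares, means and volume shares per draw.

    Population aggregation over age groups weights each cell's category
    quantities by its drinker mass ``p * pop``; the per-category means are
    volume-weighted accordingly.
    """
    m = draws.model
    inp = m.inputs
    mu, p, alpha = draws.surface_draws()
    beta = alpha / mu
    n = mu.shape[0]
    cats = ("light", "intermediate", "heavy")
    rows = []
    sexes = {1: "male", 2: "female"}
    for g in (1, 2):
        thr = thresholds[g - 1]
        a_g = alpha[:, g - 1]
        b_g = beta[:, g - 1]
        mu_g = mu[:, g - 1]
        shares = np.stack(category_shares((a_g, b_g), thr))        # (3,n,Y,A)
        vols, means = category_volume_shares((a_g, b_g), thr)
        vols = np.stack(vols)
        if by_age:
            it = [(a + 1, shares[..., a], vols[..., a], mu_g[..., a],
                   p[:, g - 1, :, a], inp.pop[g - 1, :, a])
                  for a in range(inp.n_ages)]
        else:
            # aggregate over ages within each draw: drinker-mass weights
            w = p[:, g - 1] * inp.pop[g - 1]                       # (n,Y,A)
            wsum = w.sum(axis=-1)
            sh_agg = (shares * w).sum(axis=-1) / wsum
            # volume weights: total volume per cell mu*p*pop
            vw = mu_g * w
            vol_agg = (vols * vw).sum(axis=-1) / vw.sum(axis=-1)
            it = [("all", sh_agg, vol_agg,
                   (mu_g * w).sum(axis=-1) / wsum, None, None)]
        for age, sh, vol, mean_all, _, _ in it:
            for yi, year in enumerate(inp.years):
                row = dict(year=int(year), sex=sexes[g], age_group=age)
                for k, cat in enumerate(cats):
                    s = summarize(sh[k][:, yi])
                    row[f"p_{cat}"] = s.point
                    row[f"p_{cat}_lo"] = s.lo
                    row[f"p_{cat}_hi"] = s.hi
                    sv = summarize(vol[k][:, yi])
                    row[f"volume_{cat}"] = sv.point
                    row[f"volume_{cat}_lo"] = sv.lo
                    row[f"volume_{cat}_hi"] = sv.hi
                    with np.errstate(invalid="ignore", divide="ignore"):
                        mean_cat = np.where(sh[k][:, yi] > 0,
                                            mean_all[:, yi] * vol[k][:, yi]
                                            / sh[k][:, yi], np.nan)
                    row[f"mean_{cat}"] = float(np.nanmedian(mean_cat))
                rows.append(row)
    return pd.DataFrame(rows)
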