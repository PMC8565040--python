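"""Collapse survey microdata into the model's aggregated inputs.

From individual records (drinker flag, consumption interval, sampling weight,
cluster id) this module produces, per survey x sex x age group:

* prevalence of current drinkers ``pp`` with a cluster-robust (sandwich)
  linearised standard error ``pse`` of the weighted ratio estimator;
* consumption tuples ``{lc, uc, pc, ne}``: the weighted share ``pc`` of
  drinkers in each distinct consumption interval, with an effective sample
  size ``ne`` obtained by redistributing the pooled sample across surveys
  with quality-effects weighting (precision weights 1/pse^2 modulated by a
  1-20 risk-of-bias score).

Sampling weights are first recalibrated so that they sum to a consistent set
of population totals within each sex x age stratum (post-stratification).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurveyMeta",
    "recalibrate_weights",
    "estimate_prevalence",
    "tabulate_consumption",
    "effective_sample_size",
    "aggregate_surveys",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurveyMeta:
    """Survey-level metadata consumed by the aggregation step."""

    survey_id: str
    year: int
    bias_score: int  # 1-20, higher = lower risk of bias
    has_quantity: bool = True

    def __post_init__(self):
        if not 1 <= self.bias_score <= 20:
            raise ValueError("bias_score must be in 1..20")


def recalibrate_weights(weights, strata, population_totals) -> np.ndarray:
    """Post-stratify weights to a consistent set of population totals.

    Within each stratum the adjusted weights sum exactly to the stratum's
    population total while within-stratum weight ratios are preserved.
    ``population_totals`` maps stratum label -> positive total.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    strata = np.asarray(strata)
    out = np.empty_like(w)
    for label in np.unique(strata):
        m = strata == label
        key = label.item() if hasattr(label, "item") else label
        if key not in population_totals:
            raise ValueError(f"no population total for stratum {key!r}")
        total = population_totals[key]
        s = w[m].sum()
        if s <= 0:
            raise ValueError(f"stratum {key!r} has zero total weight")
        out[m] = w[m] * (total / s)
    return out


def estimate_prevalence(drinker_flags, weights, cluster_ids):
    """Weighted prevalence and its cluster-robust linearised SE.

    The point estimate is the ratio estimator  pp = sum(w*y)/sum(w).  The
    variance linearises the ratio and sums the influence contributions within
    primary sampling units (clusters), with the with-replacement n/(n-1)
    factor; with independent records and equal weights this reduces to the
    simple-random-sampling binomial SE sqrt(p(1-p)/(n-1)).
    """
    y = np.asarray(drinker_flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    cl = np.asarray(cluster_ids)
    clusters = np.unique(cl)
    if clusters.size < 2:
        raise ValueError("at least 2 clusters are required for a variance estimate")
    W = w.sum()
    pp = float((w * y).sum() / W)
    # influence values of the ratio estimator
    z = w * (y - pp) / W
    totals = np.array([z[cl == c].sum() for c in clusters])
    nc = clusters.size
    var = nc / (nc - 1) * float((totals**2).sum())
    return pp, math.sqrt(max(var, 0.0))


def tabulate_consumption(intervals, weights):
    """Weighted shares of drinkers across distinct consumption intervals.

    ``intervals`` is a sequence of (lc, uc) pairs (uc may be inf); returns a
    list of (lc, uc, pc) sorted by lc with pc summing to 1.
    """
    w = np.asarray(weights, dtype=float)
    if len(intervals) == 0:
        raise ValueError("empty cell")
    if len(intervals) != w.size:
        raise ValueError("intervals and weights must align")
    tally: dict[tuple, float] = {}
    for (lc, uc), wi in zip(intervals, w):
        key = (float(lc), float(uc))
        tally[key] = tally.get(key, 0.0) + float(wi)
    total = sum(tally.values())
    out = [(lc, uc, wt / total) for (lc, uc), wt in sorted(tally.items())]
    return out


def effective_sample_size(pse, bias_score, raw_n):
    """Quality-effects redistribution of the pooled sample across surveys.

    For the surveys contributing to one sex-age cell, precision weights
    w_s = 1/pse_s^2 are split into a quality-retained part q_s*w_s
    (q_s = bias_score_s/20) and a forfeited part (1-q_s)*w_s which is
    reallocated across surveys proportionally to their precision weights.
    The pooled raw sample of the cell is then distributed proportionally to
    the adjusted weights, so that sum(ne) == sum(raw_n) exactly.
    """
    pse = np.asarray(pse, dtype=float)
    q = np.asarray(bias_score, dtype=float) / 20.0
    n = np.asarray(raw_n, dtype=float)
    if np.any(np.isnan(q)):
        raise ValueError("missing bias score")
    if np.any(pse <= 0):
        raise ValueError("pse must be positive")
    if np.any((q <= 0) | (q > 1)):
        raise ValueError("bias scores must be in 1..20")
    w = 1.0 / pse**2
    forfeited = ((1.0 - q) * w).sum()
    w_star = q * w + (w / w.sum()) * forfeited
    ne = n.sum() * w_star / w_star.sum()
    return ne


def _cell_iter(df):
    for (g, a), sub in df.groupby(["sex", "age_group"], sort=True):
        yield int(g), int(a), sub


def aggregate_surveys(
    microdata: dict,
    meta: dict,
    population_totals=None,
    ne_mode: str = "per_cell",
):
    """End-to-end aggregation of per-survey microdata.

    ``microdata`` maps survey_id -> DataFrame with columns sex, age_group,
    cluster, weight, drinker, and (for drinkers in quantity surveys) lc, uc.
    ``meta`` maps survey_id -> :class:`SurveyMeta`.  Returns
    ``(prevalence_df, consumption_df)`` in the model-fitting contract:
    columns (survey_id, sex, age_group, pp, pse) and
    (survey_id, sex, age_group, k, lc, uc, pc, ne).

    ``ne_mode`` selects whether quality-effects sample sizes are computed
    within each sex-age cell across surveys (``per_cell``, default) or once
    per survey from its pooled precision (``per_survey``).
    """
    if ne_mode not in ("per_cell", "per_survey"):
        raise ValueError("ne_mode must be 'per_cell' or 'per_survey'")
    prev_rows = []
    cons_rows = []
    raw_sizes = {}  # (survey, g, a) -> drinker count
    for sid, df in microdata.items():
        m = meta[sid]
        w = df["weight"].to_numpy(dtype=float)
        if population_totals is not None:
            strata = list(zip(df["sex"].to_numpy(), df["age_group"].to_numpy()))
            w = recalibrate_weights(w, np.array([f"{g}:{a}" for g, a in strata]),
                                    {f"{g}:{a}": t for (g, a), t in population_totals.items()})
        df = df.assign(weight=w)
        for g, a, sub in _cell_iter(df):
            pp, pse = estimate_prevalence(
                sub["drinker"].to_numpy(), sub["weight"].to_numpy(), sub["cluster"].to_numpy()
            )
            # zero/one cells give pse = 0; keep them out of the normal
            # likelihood by flooring at a small value
            prev_rows.append(dict(survey_id=sid, sex=g, age_group=a,
                                  pp=pp, pse=max(pse, 1e-6)))
            if not m.has_quantity:
                continue
            drk = sub[sub["drinker"] == 1]
            if len(drk) == 0:
                log.warning("survey %s cell (%d,%d): no drinkers, cell omitted", sid, g, a)
                continue
            tuples = tabulate_consumption(
                list(zip(drk["lc"], drk["uc"])), drk["weight"].to_numpy()
            )
            raw_sizes[(sid, g, a)] = len(drk)
            for k, (lc, uc, pc) in enumerate(tuples, start=1):
                cons_rows.append(dict(survey_id=sid, sex=g, age_group=a, k=k,
                                      lc=lc, uc=uc, pc=pc, pse=pse))
    prevalence = pd.DataFrame(prev_rows)
    if not cons_rows:
        return prevalence, pd.DataFrame(
            columns=["survey_id", "sex", "age_group", "k", "lc", "uc", "pc", "ne"]
        )
    cons = pd.DataFrame(cons_rows)

    # attach effective sample sizes
    bias = {sid: meta[sid].bias_score for sid in microdata}
    ne_map = {}
    if ne_mode == "per_cell":
        cells = cons[["sex", "age_group"]].drop_duplicates().itertuples(index=False)
        for g, a in cells:
            sub = cons[(cons.sex == g) & (cons.age_group == a)]
            sids = sub["survey_id"].unique()
            pse = [float(sub[sub.survey_id == s]["pse"].iloc[0]) for s in sids]
            n = [raw_sizes[(s, g, a)] for s in sids]
            ne = effective_sample_size(pse, [bias[s] for s in sids], n)
            for s, v in zip(sids, ne):
                ne_map[(s, g, a)] = v
    else:
        sids = sorted({s for (s, _, _) in raw_sizes})
        pooled_pse = []
        pooled_n = []
        for s in sids:
            sub = cons[cons.survey_id == s]
            pooled_pse.append(float(np.sqrt((sub.groupby(["sex", "age_group"])["pse"]
                                             .first() ** 2).mean())))
            pooled_n.append(sum(v for (ss, _, _), v in raw_sizes.items() if ss == s))
        ne_tot = effective_sample_size(pooled_pse, [bias[s] for s in sids], pooled_n)
        for s, tot in zip(sids, ne_tot):
            n_s = sum(v for (ss, _, _), v in raw_sizes.items() if ss == s)
            for (ss, g, a), v in raw_sizes.items():
                if ss == s:
                    ne_map[(s, g, a)] = tot * v / n_s
    cons["ne"] = [ne_map[(r.survey_id, r.sex, r.age_group)] for r in cons.itertuples()]
    cons = cons.drop(columns=["pse"])
    return prevalence, cons
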