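"""Synthetic survey, population and APC data with known ground truth.

The generator draws data exactly from the model family fitted by
:mod:`alcmeta.model` (up to interval censoring), so that posterior-recovery
failures on synthetic bundles point to implementation bugs rather than model
misspecification:

* truth surfaces for prevalence (logit scale) and mean consumption among
  drinkers (log scale) are bilinear in standardised year and age — a strict
  subspace of every tensor-product spline basis of dimension >= 2;
* individual consumption among drinkers is Gamma with sex-specific shape;
* each survey reports consumption multiplied by its coverage
  c'_s * c''_{g,a} (under-reporting), then censored through its instrument:
  either a frequency-quantity category partition or a rounded weekly drink
  count;
* the APC series is the population-weighted truth total divided by (1 - w)
  plus optional noise, so the noiseless series back-transforms exactly.

Cluster structure: records fall in equal-size clusters whose drinking
propensity carries a small mean-preserving perturbation, so cluster-robust
standard errors differ measurably from the SRS formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .aggregate import SurveyMeta, aggregate_surveys
from .intervals import (
    GRAMS_PER_DRINK,
    FrequencyQuantityResponse,
    instrument_partition,
    weekly_count_to_interval,
)
from .model import R_SHAPE, ModelInputs

__all__ = ["SurveySpec", "TruthSpec", "Truth", "SyntheticBundle",
           "default_instrument", "generate_truth", "simulate_survey",
           "compute_apc", "make_bundle"]


def default_instrument():
    """Default frequency-quantity category grid.

    Frequencies {1-3/month, 1-2/week, 3-4/week, 5-7/week} crossed with
    quantities {1-2, 3-4, 5-6, 7+ standard drinks}; loosely typical of
    frequency-quantity questionnaires.
    """
    freqs = [(1, 3, 30.0), (1, 2, 7.0), (3, 4, 7.0), (5, 7, 7.0)]
    qtys = [(1, 2), (3, 4), (5, 6), (7, math.inf)]
    return [
        FrequencyQuantityResponse(fl, fh, ql, qh, period)
        for (fl, fh, period) in freqs
        for (ql, qh) in qtys
    ]


@dataclass(frozen=True)
class SurveySpec:
    """Roster entry: one synthetic survey."""

    survey_id: str
    year: int
    n: int
    bias_score: int
    coverage: float               # true overall coverage c'_s
    instrument: str = "fq"        # "fq" | "weekly" | "prevalence_only"

    def __post_init__(self):
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.instrument not in ("fq", "weekly", "prevalence_only"):
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if self.n <= 0:
            raise ValueError("n must be positive")


def _default_surveys(years):
    years = list(years)
    return (
        SurveySpec("SYN-A", years[0], 2000, 16, 0.70, "fq"),
        SurveySpec("SYN-B", years[len(years) // 2], 2000, 12, 0.50, "weekly"),
        SurveySpec("SYN-C", years[-1], 2000, 14, 0.30, "fq"),
    )


@dataclass
class TruthSpec:
    """Generating conditions for one synthetic study.

    Defaults give the scaled recovery fixture: 5 years x 2 sexes x 3 age
    groups, three consumption surveys of n = 2,000 with true coverages
    0.70 / 0.50 / 0.30, wastage w = 0.2 and sex-specific Gamma shapes at the
    informative-prior locations.  Bilinear surface coefficients are on the
    link scales over year/age standardised to [-1/2, 1/2].
    """

    years: tuple = tuple(range(2008, 2013))
    ages: tuple = (20.0, 40.0, 60.0)
    # (intercept, year slope, age slope, interaction) per sex [male, female]
    logit_p_coef: tuple = ((0.1, 0.25, -0.5, 0.2), (-1.45, 0.35, -0.7, 0.1))
    # mean surfaces are kept low enough that the 95th percentile of every
    # cell's Gamma stays below the 150 g/day soft cap (q95 ~ 3.4-3.5 mu at
    # the default shapes), so the truth lies in the model family's support
    log_mu_coef: tuple = ((math.log(32.0), -0.2, -0.25, 0.1),
                          (math.log(20.0), -0.1, -0.15, 0.05))
    alpha: tuple = R_SHAPE
    surveys: tuple = None
    cdev_log: tuple = (0.02, -0.01, -0.04, -0.05, 0.03, 0.05)  # row-major (sex, age)
    w: float = 0.2
    apc_noise_sd: float = 0.15    # g/day per capita
    sex_share: tuple = (0.49, 0.51)
    age_share: tuple = (0.40, 0.35, 0.25)
    n_clusters: int = 25
    cluster_sd: float = 0.02      # mean-preserving perturbation of p per cluster
    weight_sd: float = 0.2        # lognormal sd of raw sampling weights
    grams_per_drink: float = GRAMS_PER_DRINK

    def __post_init__(self):
        if self.surveys is None:
            self.surveys = _default_surveys(self.years)
        A = len(self.ages)
        if len(self.cdev_log) != 2 * A:
            raise ValueError("cdev_log must have one entry per sex-age cell")
        if abs(sum(self.cdev_log)) > 1e-9:
            raise ValueError("cdev_log must sum to zero (geometric mean 1)")
        if not 0 <= self.w < 1:
            raise ValueError("w must be in [0, 1)")
        for s in self.surveys:
            if s.year not in self.years:
                raise ValueError(f"survey {s.survey_id} year outside the year range")
        if abs(sum(self.sex_share) - 1) > 1e-9 or abs(sum(self.age_share) - 1) > 1e-9:
            raise ValueError("population shares must sum to 1")


@dataclass
class Truth:
    """Ground-truth record embedded in every bundle for test assertions."""

    spec: TruthSpec
    mu: np.ndarray      # (2, Y, A) grams/day
    p: np.ndarray       # (2, Y, A)
    alpha: np.ndarray   # (2, Y, A)
    cdev: np.ndarray    # (2, A)
    pop: np.ndarray     # (2, Y, A) proportions
    apc_true: np.ndarray  # noiseless (1-w)-corrected series, g/day

    @property
    def cprime(self):
        return {s.survey_id: s.coverage for s in self.spec.surveys}


def _std_axis(values):
    v = np.asarray(values, dtype=float)
    span = max(v.max() - v.min(), 1.0)
    return (v - v.min()) / span - 0.5


def generate_truth(spec: TruthSpec, seed: int = 0) -> Truth:
    """Evaluate the truth surfaces on the (year, age) grid.

    Deterministic given the spec (the seed only matters downstream); with the
    default spec the male surfaces dominate the female ones everywhere.
    """
    years = np.asarray(spec.years)
    ys = _std_axis(years)
    as_ = _std_axis(spec.ages)
    Y, A = ys.size, as_.size
    mu = np.empty((2, Y, A))
    p = np.empty((2, Y, A))
    for g in range(2):
        c0, cy, ca, cya = spec.logit_p_coef[g]
        eta_p = c0 + cy * ys[:, None] + ca * as_[None, :] + cya * ys[:, None] * as_[None, :]
        d0, dy, da, dya = spec.log_mu_coef[g]
        eta_m = d0 + dy * ys[:, None] + da * as_[None, :] + dya * ys[:, None] * as_[None, :]
        p[g] = 1.0 / (1.0 + np.exp(-eta_p))
        mu[g] = np.exp(eta_m)
    alpha = np.broadcast_to(np.asarray(spec.alpha)[:, None, None], (2, Y, A)).copy()
    cdev = np.exp(np.asarray(spec.cdev_log, dtype=float).reshape(2, A))
    pop = (np.asarray(spec.sex_share)[:, None, None]
           * np.asarray(spec.age_share)[None, None, :]
           * np.ones((2, Y, A)))
    apc_true = np.einsum("gya,gya->y", mu * p, pop)
    return Truth(spec=spec, mu=mu, p=p, alpha=alpha, cdev=cdev, pop=pop,
                 apc_true=apc_true)


def _bin_fq(x, partition):
    """Index of the partition interval containing reported value x."""
    # partition is sorted, disjoint, covers [0, inf)
    for iv in partition:
        if iv.lc <= x < iv.uc or (math.isinf(iv.uc) and x >= iv.lc):
            return iv
    return partition[-1]


def simulate_survey(truth: Truth, svy: SurveySpec, seed: int) -> pd.DataFrame:
    """Microdata for one survey: drinking status, censored report, weights.

    Columns: sex (1/2), age_group (1..A), cluster, weight, drinker, lc, uc
    (NaN for non-drinkers and for prevalence-only instruments).
    """
    spec = truth.spec
    import zlib

    sid_code = zlib.crc32(svy.survey_id.encode()) % 2**31
    rng = np.random.default_rng(np.random.SeedSequence([seed, sid_code]))
    yi = list(spec.years).index(svy.year)
    partition = instrument_partition(default_instrument(), spec.grams_per_drink)
    rows = []
    for g in range(2):
        for a in range(len(spec.ages)):
            share = spec.sex_share[g] * spec.age_share[a]
            n_cell = max(int(round(svy.n * share)), 30)
            p_cell = truth.p[g, yi, a]
            mu_cell = truth.mu[g, yi, a]
            al = truth.alpha[g, yi, a]
            cov = svy.coverage * truth.cdev[g, a]
            clusters = rng.integers(0, spec.n_clusters, size=n_cell)
            # mean-preserving cluster perturbation of the drinking propensity
            if p_cell <= 0.0:
                p_clust = np.zeros(spec.n_clusters)
            else:
                p_clust = np.clip(
                    p_cell + rng.normal(0.0, spec.cluster_sd,
                                        size=spec.n_clusters),
                    0.005, 0.995,
                )
            drinker = (rng.random(n_cell) < p_clust[clusters]).astype(int)
            weight = np.exp(rng.normal(0.0, spec.weight_sd, size=n_cell))
            x_true = rng.gamma(shape=al, scale=mu_cell / al, size=n_cell)
            reported = x_true * cov
            lc = np.full(n_cell, np.nan)
            uc = np.full(n_cell, np.nan)
            if svy.instrument == "fq":
                for i in np.nonzero(drinker)[0]:
                    iv = _bin_fq(reported[i], partition)
                    lc[i], uc[i] = iv.lc, iv.uc
            elif svy.instrument == "weekly":
                for i in np.nonzero(drinker)[0]:
                    count = int(round(reported[i] * 7.0 / spec.grams_per_drink))
                    if count == 0:
                        # "less than one drink last week": left-censored
                        lc[i], uc[i] = 0.0, spec.grams_per_drink / 7.0
                    else:
                        iv = weekly_count_to_interval(count, spec.grams_per_drink)
                        lc[i], uc[i] = iv.lc, iv.uc
            cell = pd.DataFrame(dict(
                sex=g + 1, age_group=a + 1,
                cluster=[f"{g+1}-{a+1}-{c}" for c in clusters],
                weight=weight, drinker=drinker, lc=lc, uc=uc,
            ))
            rows.append(cell)
    return pd.concat(rows, ignore_index=True)


def compute_apc(truth: Truth, w: float = None, noise_sd: float = None,
                seed: int = 0) -> pd.DataFrame:
    """Yearly APC series (grams/day per capita) consistent with the truth.

    apc_y = [sum mu*pop*p] / (1 - w) + noise; with zero noise the series
    back-transforms to the truth total exactly.  ``apcse`` is the noise sd.
    """
    spec = truth.spec
    if w is None:
        w = spec.w
    if noise_sd is None:
        noise_sd = spec.apc_noise_sd
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    apc = truth.apc_true / (1.0 - w)
    if noise_sd > 0:
        apc = np.maximum(apc + rng.normal(0.0, noise_sd, size=apc.size), 1e-6)
    return pd.DataFrame(dict(year=list(spec.years), apc=apc,
                             apcse=np.full(apc.size, noise_sd),
                             units="g_per_day"))


@dataclass
class SyntheticBundle:
    """Complete synthetic inputs plus the embedded truth record."""

    truth: Truth
    microdata: dict               # survey_id -> DataFrame
    meta: dict                    # survey_id -> SurveyMeta
    population: pd.DataFrame      # year, sex, age_group, proportion
    apc: pd.DataFrame             # year, apc, apcse, units

    def aggregate(self, ne_mode: str = "per_cell"):
        """Run survey aggregation, returning (prevalence, consumption) tables."""
        return aggregate_surveys(self.microdata, self.meta, ne_mode=ne_mode)

    def model_inputs(self, w: float = None, ne_mode: str = "per_cell") -> ModelInputs:
        spec = self.truth.spec
        prev, cons = self.aggregate(ne_mode=ne_mode)
        return ModelInputs(
            years=np.asarray(spec.years),
            ages=np.asarray(spec.ages),
            prevalence=prev,
            consumption=cons,
            pop=self.truth.pop,
            apc=self.apc["apc"].to_numpy(),
            apcse=np.maximum(self.apc["apcse"].to_numpy(), 1e-3),
            survey_year={m.survey_id: m.year for m in self.meta.values()},
        )

    def write(self, outdir):
        """Emit the tabular contract (CSV) plus a truth sidecar (JSON)."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(out / "population.csv", index=False)
        self.apc.to_csv(out / "apc.csv", index=False)
        meta_rows = [dict(survey_id=m.survey_id, year=m.year,
                          bias_score=m.bias_score, has_quantity=m.has_quantity)
                     for m in self.meta.values()]
        pd.DataFrame(meta_rows).to_csv(out / "surveys.csv", index=False)
        for sid, df in self.microdata.items():
            df.to_csv(out / f"microdata_{sid}.csv", index=False)
        truth = dict(
            spec={k: v for k, v in asdict(self.truth.spec).items()
                  if k != "surveys"},
            surveys=[asdict(s) for s in self.truth.spec.surveys],
            mu=self.truth.mu.tolist(), p=self.truth.p.tolist(),
            alpha=self.truth.alpha.tolist(), cdev=self.truth.cdev.tolist(),
            apc_true=self.truth.apc_true.tolist(),
        )
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def make_bundle(spec: TruthSpec = None, seed: int = 0) -> SyntheticBundle:
    """Generate a complete synthetic study: truth, microdata, population, APC."""
    if spec is None:
        spec = TruthSpec()
    truth = generate_truth(spec, seed)
    microdata = {}
    meta = {}
    for svy in spec.surveys:
        microdata[svy.survey_id] = simulate_survey(truth, svy, seed)
        meta[svy.survey_id] = SurveyMeta(
            survey_id=svy.survey_id, year=svy.year, bias_score=svy.bias_score,
            has_quantity=svy.instrument != "prevalence_only",
        )
    pop_rows = []
    for yi, year in enumerate(spec.years):
        for g in range(2):
            for a in range(len(spec.ages)):
                pop_rows.append(dict(year=year, sex=g + 1, age_group=a + 1,
                                     proportion=truth.pop[g, yi, a]))
    population = pd.DataFrame(pop_rows)
    apc = compute_apc(truth, seed=seed)
    return SyntheticBundle(truth=truth, microdata=microdata, meta=meta,
                           population=population, apc=apc)
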