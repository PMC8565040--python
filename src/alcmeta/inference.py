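"""Posterior sampling, convergence diagnostics and model checking.

``fit`` runs several NUTS chains on the joint posterior and returns the
retained draws together with derived-quantity accessors (surfaces, coverages,
Gamma parameters per cell).  ``diagnose`` computes split-R-hat, bulk ESS and
the Monte-Carlo standard error of the mean per parameter (via arviz) and
checks them against configurable thresholds.  ``posterior_predictive_cdf``
compares the censored observed consumption distribution of one survey with
the model's predictive cumulative curves, and ``standardized_residuals``
checks prevalence residuals against their assumed normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .model import Model, ModelConfig, ModelInputs
from .sampler import nuts

__all__ = ["SamplerConfig", "PosteriorDraws", "Diagnostics", "fit", "diagnose",
           "posterior_predictive_cdf", "standardized_residuals"]


@dataclass(frozen=True)
class SamplerConfig:
    """Chain count, length and warmup protocol.

    The ``paper`` preset mirrors the full-scale protocol (11 chains of
    10,000 with 60% warmup); the ``test`` preset is the scaled default used
    throughout the test suite.
    """

    n_chains: int = 11
    n_iterations: int = 10_000
    warmup_fraction: float = 0.60
    seed: int = 1
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")

    @classmethod
    def preset(cls, name: str, seed: int = 1) -> "SamplerConfig":
        if name == "paper":
            return cls(n_chains=11, n_iterations=10_000, warmup_fraction=0.6,
                       seed=seed)
        if name == "test":
            return cls(n_chains=4, n_iterations=2_000, warmup_fraction=0.6,
                       seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class PosteriorDraws:
    """Retained draws from all chains plus derived-quantity views."""

    theta: np.ndarray            # (chains, kept, dim)
    logpost: np.ndarray          # (chains, kept)
    model: Model
    config: SamplerConfig
    divergences: int = 0
    step_sizes: tuple = ()

    @property
    def n_draws(self):
        return self.theta.shape[0] * self.theta.shape[1]

    def flat(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def _split_flat(self):
        return self.model._split(self.flat().T)

    def surface_draws(self):
        """(mu, p, alpha) arrays of shape (n_draws, 2, Y, A)."""
        m = self.model
        th = self.flat()
        parts = {}
        i = 0
        for k in ("sC", "sP", "u", "v", "t"):
            n = m._sizes[k]
            parts[k] = th[:, i:i + n]
            i += n
        sC = parts["sC"].reshape((-1,) + m.shapes["sC"])
        sP = parts["sP"].reshape((-1,) + m.shapes["sP"])
        eta_c = np.einsum("yi,ngij,aj->ngya", m._By_c, sC, m._Ba_c)
        eta_p = np.einsum("yi,ngij,aj->ngya", m._By_p, sP, m._Ba_p)
        mu = np.exp(eta_c)
        p = 1.0 / (1.0 + np.exp(-eta_p))
        alpha = np.exp(parts["t"]).reshape((-1,) + m.shapes["t"])
        return mu, p, alpha

    def coverage_draws(self):
        """(cprime, cdev) of shapes (n_draws, S) and (n_draws, 2, A)."""
        m = self.model
        th = self.flat()
        i0 = m._sizes["sC"] + m._sizes["sP"]
        u = th[:, i0:i0 + m._sizes["u"]]
        v = th[:, i0 + m._sizes["u"]:i0 + m._sizes["u"] + m._sizes["v"]]
        v_full = np.concatenate([v, -v.sum(axis=1, keepdims=True)], axis=1)
        cprime = 1.0 / (1.0 + np.exp(-u))
        cdev = np.exp(v_full).reshape(-1, 2, m.inputs.n_ages)
        return cprime, cdev

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior={"theta": self.theta})


@dataclass
class Diagnostics:
    """Per-parameter convergence summary with pass/fail verdicts."""

    table: pd.DataFrame          # rhat, ess, mcse, sd per parameter
    divergences: int
    rhat_threshold: float
    mcse_sd_ratio_threshold: float

    @property
    def max_rhat(self):
        return float(np.nanmax(self.table["rhat"]))

    @property
    def min_ess(self):
        return float(np.nanmin(self.table["ess"]))

    @property
    def max_mcse_ratio(self):
        return float(np.nanmax(self.table["mcse_sd_ratio"]))

    @property
    def passed(self) -> bool:
        return (self.max_rhat < self.rhat_threshold
                and self.max_mcse_ratio < self.mcse_sd_ratio_threshold)

    def report(self) -> dict:
        return dict(max_rhat=self.max_rhat, min_ess=self.min_ess,
                    max_mcse_sd_ratio=self.max_mcse_ratio,
                    divergences=self.divergences, passed=bool(self.passed))


def fit(inputs: ModelInputs, config: SamplerConfig,
        model_config: ModelConfig = None, model: Model = None) -> PosteriorDraws:
    """Sample the joint posterior with NUTS; reproducible given the seed."""
    if model is None:
        model = Model(inputs, model_config or ModelConfig())
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains + 1)
    # shared preparation: data-informed start, posterior mode, Laplace metric
    prep_rng = np.random.default_rng(chain_seeds[-1])
    theta_map = model.map_estimate(model.initial_point(prep_rng, jitter=0.0))
    inv_mass0 = model.laplace_inv_mass(theta_map)
    L0 = np.linalg.cholesky(inv_mass0)
    draws, lps, steps = [], [], []
    total_div = 0
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta0 = None
        for scale in (1.0, 0.3, 0.1, 0.03, 0.0):
            cand = theta_map + scale * (L0 @ rng.standard_normal(model.n_params))
            ll, _ = model.logpost_and_grad(cand)
            if np.isfinite(ll):
                theta0 = cand
                break
        if theta0 is None:
            raise RuntimeError(
                "initialisation failed: joint log-posterior non-finite even at "
                "the posterior mode (check consumption tuples and APC inputs)"
            )
        res = nuts(model.logpost_and_grad, theta0, config.n_iterations,
                   config.warmup_fraction, rng,
                   target_accept=config.target_accept,
                   max_treedepth=config.max_treedepth,
                   inv_mass0=inv_mass0)
        draws.append(res.draws)
        lps.append(res.logpost)
        steps.append(res.step_size)
        total_div += res.divergences
    return PosteriorDraws(theta=np.asarray(draws), logpost=np.asarray(lps),
                          model=model, config=config, divergences=total_div,
                          step_sizes=tuple(steps))


def diagnose(draws: PosteriorDraws, rhat_threshold: float = 1.05,
             mcse_sd_ratio_threshold: float = 0.05) -> Diagnostics:
    """Split-R-hat, bulk ESS and MCSE-of-mean per parameter (via arviz)."""
    import arviz as az

    theta = draws.theta
    if theta.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    idata = draws.to_arviz()
    rhat = np.asarray(az.rhat(idata)["theta"])
    ess = np.asarray(az.ess(idata)["theta"])
    mcse = np.asarray(az.mcse(idata)["theta"])
    flat = draws.flat()
    sd = flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, mcse / sd, np.nan)
    table = pd.DataFrame(dict(rhat=rhat, ess=ess, mcse=mcse, sd=sd,
                              mcse_sd_ratio=ratio))
    return Diagnostics(table=table, divergences=draws.divergences,
                       rhat_threshold=rhat_threshold,
                       mcse_sd_ratio_threshold=mcse_sd_ratio_threshold)


def posterior_predictive_cdf(draws: PosteriorDraws, survey_id: str,
                             n_curves: int = 100, n_grid: int = 50,
                             rng: np.random.Generator = None,
                             tuples: pd.DataFrame = None) -> dict:
    """Predictive CDF band vs the censored observed distribution of a survey.

    The observed tuples of the survey (pooled across sex-age cells with
    effective-sample-size weights) define a lower/upper step-function
    envelope: mass known to lie below x versus mass possibly below x, the gap
    being the interval-censoring uncertainty.  ``n_curves`` posterior draws
    give predictive CDFs of *reported* consumption (rate beta / coverage).
    Returns grid, envelope, band and the fraction of grid points where the
    envelope intersects the band.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m = draws.model
    inp = m.inputs
    if tuples is not None:
        sub = tuples  # observed-data stand-in, e.g. replicated data
    else:
        cons = inp.consumption
        sub = cons[cons.survey_id == survey_id]
    if len(sub) == 0:
        raise ValueError(f"survey {survey_id!r} has no consumption tuples "
                         "(prevalence-only surveys are skipped)")
    yr = inp.survey_year[survey_id]
    yi = int(np.nonzero(inp.years == yr)[0][0])
    si = inp.survey_ids.index(survey_id)

    cells = sub.groupby(["sex", "age_group"])
    cell_keys = list(cells.groups)
    ne_w = np.array([cells.get_group(k)["ne"].iloc[0] for k in cell_keys])
    ne_w = ne_w / ne_w.sum()

    finite_uc = sub.uc[np.isfinite(sub.uc)]
    xmax = float(finite_uc.max() if len(finite_uc) else sub.lc.max()) * 1.2
    grid = np.linspace(0.0, max(xmax, 1.0), n_grid)

    env_lo = np.zeros(n_grid)
    env_hi = np.zeros(n_grid)
    for w, k in zip(ne_w, cell_keys):
        cell = cells.get_group(k)
        for lc, uc, pc in zip(cell.lc, cell.uc, cell.pc):
            env_lo += w * pc * (grid >= uc)
            env_hi += w * pc * (grid >= lc)

    mu, p, alpha = draws.surface_draws()
    cprime, cdev = draws.coverage_draws()
    n_total = mu.shape[0]
    take = rng.choice(n_total, size=min(n_curves, n_total), replace=False)
    curves = np.empty((take.size, n_grid))
    for j, d in enumerate(take):
        F = np.zeros(n_grid)
        for w, (g, a) in zip(ne_w, cell_keys):
            gi, ai = int(g) - 1, int(a) - 1
            al = alpha[d, gi, yi, ai]
            rate = al / mu[d, gi, yi, ai] / (cprime[d, si] * cdev[d, gi, ai])
            F += w * special.gammainc(al, rate * grid)
        curves[j] = F
    band_lo = curves.min(axis=0)
    band_hi = curves.max(axis=0)
    overlap = (env_lo <= band_hi + 1e-12) & (band_lo <= env_hi + 1e-12)
    return dict(grid=grid, env_lo=env_lo, env_hi=env_hi, band_lo=band_lo,
                band_hi=band_hi, curves=curves,
                coverage=float(overlap.mean()))


def standardized_residuals(draws: PosteriorDraws) -> dict:
    """Prevalence residuals (pp - median p)/pse and a QQ summary vs N(0,1)."""
    m = draws.model
    inp = m.inputs
    _, p, _ = draws.surface_draws()
    pm = np.median(p[:, m._p_g, m._p_y, m._p_a], axis=0)
    resid = (m._p_pp - pm) / m._p_pse
    ks = stats.kstest(resid, "norm")
    q = np.sort(resid)
    theo = stats.norm.ppf((np.arange(q.size) + 0.5) / q.size)
    table = inp.prevalence.copy()
    table["fitted_p"] = pm
    table["residual"] = resid
    return dict(residuals=resid, table=table, ks_stat=float(ks.statistic),
                ks_pvalue=float(ks.pvalue),
                qq_max_dev=float(np.max(np.abs(q - theo))))
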