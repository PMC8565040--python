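"""Gamma-distribution mathematics for daily alcohol consumption among drinkers.

Individual average daily consumption (grams of pure ethanol per day) among
current drinkers is modelled as Gamma(alpha, beta) with shape ``alpha`` and
rate ``beta``.  The moment parameterisation used throughout is

    alpha = (mu / sd)**2,        beta = alpha / mu,

so that the mean is ``alpha/beta = mu`` and the variance ``alpha/beta**2 =
sd**2``.  Survey under-reporting enters through the scaling property of the
Gamma family: if true consumption is Gamma(alpha, beta), consumption reported
with multiplicative coverage ``c`` is Gamma(alpha, beta/c).

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "GammaConsumption",
    "CategoryThresholds",
    "from_moments",
    "interval_probability",
    "interval_log_probability",
    "quantile",
    "category_shares",
    "category_volume_shares",
]

#: sentinel returned for the mean of a category with zero probability mass
UNDEFINED_MEAN = np.nan


@dataclass(frozen=True)
class GammaConsumption:
    """Shape/rate parameters of one year-sex-age consumption distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.all(np.asarray(self.alpha) > 0) and np.all(np.asarray(self.beta) > 0)):
            raise ValueError("GammaConsumption requires alpha > 0 and beta > 0")

    @property
    def mu(self):
        """Mean daily consumption in grams/day."""
        return np.asarray(self.alpha) / np.asarray(self.beta)

    @property
    def sd(self):
        """Standard deviation of daily consumption in grams/day."""
        return np.sqrt(np.asarray(self.alpha)) / np.asarray(self.beta)


@dataclass(frozen=True)
class CategoryThresholds:
    """Light/heavy cut-points (grams/day) for one sex.

    Drinkers with mean daily consumption below ``light_upper`` are light
    drinkers, above ``heavy_lower`` heavy drinkers, and intermediate in
    between.  Defaults elsewhere follow the 12/40 g (female) and 24/60 g
    (male) convention.
    """

    light_upper: float
    heavy_lower: float

    def __post_init__(self) -> None:
        if not 0 < self.light_upper < self.heavy_lower:
            raise ValueError("thresholds must satisfy 0 < light_upper < heavy_lower")


def from_moments(mu, sd) -> GammaConsumption:
    """Convert (mean, sd) in grams/day to shape/rate parameters."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mu <= 0) or np.any(sd <= 0):
        raise ValueError("from_moments requires mu > 0 and sd > 0")
    alpha = (mu / sd) ** 2
    return GammaConsumption(alpha=alpha if alpha.ndim else float(alpha),
                            beta=(alpha / mu) if alpha.ndim else float(alpha / mu))


def _resolve(g) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(g, GammaConsumption):
        return np.asarray(g.alpha, dtype=float), np.asarray(g.beta, dtype=float)
    alpha, beta = g
    return np.asarray(alpha, dtype=float), np.asarray(beta, dtype=float)


def interval_probability(lc, uc, g, coverage=1.0):
    """Probability that *reported* consumption falls in [lc, uc].

    Under coverage ``c`` the reported consumption is Gamma(alpha, beta/c).
    Degenerate intervals (uc == lc) return the *density* at the point, which
    is how exact reports (weekly drink counts) enter the likelihood.  An
    infinite ``uc`` uses the survival function.
    """
    alpha, beta = _resolve(g)
    lc = np.asarray(lc, dtype=float)
    uc = np.asarray(uc, dtype=float)
    c = np.asarray(coverage, dtype=float)
    if np.any(lc < 0):
        raise ValueError("interval lower bound must be non-negative")
    if np.any(uc < lc):
        raise ValueError("interval upper bound must be >= lower bound")
    if np.any(c <= 0):
        raise ValueError("coverage must be positive")

    rate = beta / c
    scalar = all(np.ndim(v) == 0 for v in (lc, uc, alpha, rate))
    lc_b, uc_b, alpha_b, rate_b = map(
        np.atleast_1d, np.broadcast_arrays(lc, uc, alpha, rate)
    )

    degen = uc_b == lc_b
    zl = rate_b * lc_b
    zu = rate_b * np.where(np.isinf(uc_b), 1.0, uc_b)  # placeholder where inf

    # interval case: difference of regularised incomplete gamma functions,
    # switching to the survival complement when both bounds sit in the tail
    lower = special.gammainc(alpha_b, zl)
    upper = np.where(np.isinf(uc_b), 1.0, special.gammainc(alpha_b, zu))
    p = upper - lower
    tail = ~degen & ~np.isinf(uc_b) & (lower > 0.5)
    if np.any(tail):
        p[tail] = special.gammaincc(alpha_b[tail], zl[tail]) - special.gammaincc(
            alpha_b[tail], zu[tail]
        )
    out = np.clip(p, 0.0, 1.0)

    if np.any(degen):
        # density of Gamma(alpha, rate) at the point
        x = lc_b[degen]
        out[degen] = stats.gamma.pdf(x, a=alpha_b[degen], scale=1.0 / rate_b[degen])
    return float(out[0]) if scalar else out


def interval_log_probability(lc, uc, g, coverage=1.0):
    """Log of :func:`interval_probability`, stable for tiny tail masses."""
    alpha, beta = _resolve(g)
    lc = np.asarray(lc, dtype=float)
    uc = np.asarray(uc, dtype=float)
    c = np.asarray(coverage, dtype=float)
    rate = beta / c
    scalar = all(np.ndim(v) == 0 for v in (lc, uc, alpha, rate))
    lc_b, uc_b, alpha_b, rate_b = map(
        np.atleast_1d, np.broadcast_arrays(lc, uc, alpha, rate)
    )
    out = np.empty(lc_b.shape, dtype=float)

    degen = uc_b == lc_b
    if np.any(degen):
        out[degen] = stats.gamma.logpdf(
            lc_b[degen], a=alpha_b[degen], scale=1.0 / rate_b[degen]
        )
    idx = ~degen
    if np.any(idx):
        p = interval_probability(lc_b[idx], uc_b[idx], (alpha_b[idx], rate_b[idx]), 1.0)
        with np.errstate(divide="ignore"):
            out[idx] = np.log(np.maximum(np.asarray(p), 1e-300))
    return float(out[0]) if scalar else out


def quantile(p, g):
    """Inverse CDF (grams/day) of the consumption distribution."""
    alpha, beta = _resolve(g)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("quantile requires 0 < p < 1")
    q = special.gammaincinv(alpha, p) / beta
    return q if q.ndim else float(q)


def cdf(x, g, coverage=1.0):
    """CDF of reported consumption (rate beta/coverage) at ``x`` grams/day."""
    alpha, beta = _resolve(g)
    return special.gammainc(alpha, (beta / np.asarray(coverage)) * np.asarray(x))


def category_shares(g, thr: CategoryThresholds):
    """Proportions of light / intermediate / heavy drinkers.

    Returns the probability mass below ``thr.light_upper``, between the two
    thresholds, and above ``thr.heavy_lower``; the three sum to one.
    """
    alpha, beta = _resolve(g)
    f_light = special.gammainc(alpha, beta * thr.light_upper)
    f_heavy = special.gammainc(alpha, beta * thr.heavy_lower)
    p_light = f_light
    p_int = f_heavy - f_light
    p_heavy = special.gammaincc(alpha, beta * thr.heavy_lower)
    return p_light, p_int, p_heavy


def _partial_mean(t, alpha, beta):
    # int_0^t x f(x; alpha, beta) dx = mu * CDF(t; alpha+1, beta)
    mu = alpha / beta
    return mu * special.gammainc(alpha + 1.0, beta * t)


def category_volume_shares(g, thr: CategoryThresholds):
    """Share of total volume drunk by each category, and per-category means.

    The volume share of a category is (1/mu) * int_cat x f(x) dx, computed via
    the partial-moment identity int_0^t x f(x; a, b) dx = mu * F(t; a+1, b).
    Returns ``(v_light, v_int, v_heavy), (m_light, m_int, m_heavy)`` where a
    category with zero probability gets a NaN mean.
    """
    alpha, beta = _resolve(g)
    mu = alpha / beta
    pm_light = _partial_mean(thr.light_upper, alpha, beta)
    pm_heavy = _partial_mean(thr.heavy_lower, alpha, beta)
    v_light = pm_light / mu
    v_int = (pm_heavy - pm_light) / mu
    v_heavy = 1.0 - pm_heavy / mu
    p_light, p_int, p_heavy = category_shares(g, thr)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_light = np.where(p_light > 0, mu * v_light / p_light, UNDEFINED_MEAN)
        m_int = np.where(p_int > 0, mu * v_int / p_int, UNDEFINED_MEAN)
        m_heavy = np.where(p_heavy > 0, mu * v_heavy / p_heavy, UNDEFINED_MEAN)
    return (v_light, v_int, v_heavy), (m_light, m_int, m_heavy)
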