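"""Joint posterior of the triangulation model.

The model couples three data sources in one likelihood:

* interval-censored consumption tuples per survey x sex x age cell, each
  contributing its Gamma interval probability under the survey's coverage,
  weighted by ``pc * ne`` (a multinomial-style pseudo-likelihood in which the
  effective sample size acts as a sample size);
* survey prevalence estimates, normally distributed around the model
  prevalence surface with their design-based standard errors;
* the yearly per-capita consumption series (APC), which constrains the
  population total  sum_{g,a} mu * pop * p  to (1 - w) * apc each year,
  where w is the wastage fraction.

Coverage decomposes as c_{s,g,a} = c'_s * c''_{g,a}: one overall factor per
survey times sex-age deviations shared by all surveys and constant in time,
with the deviations constrained to geometric mean one for identifiability.
The Gamma shape alpha carries an informative normal prior per sex (truncated
positive via a log parameterisation), and an informative one-sided prior
keeps the 95th percentile of every consumption distribution from exceeding a
soft cap (150 g/day by default).

Everything is parameterised unconstrained so gradient-based samplers can run
on the raw vector; :meth:`Model.logpost_and_grad` returns the joint log
posterior and its exact gradient (the only internally numerical piece is the
derivative of the regularised incomplete gamma function with respect to its
shape argument, evaluated by a high-accuracy central difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "ETHANOL_G_PER_L", "DAYS_PER_YEAR", "R_SHAPE", "RS_SHAPE",
    "ModelConfig", "ModelInputs", "ModelParameters", "Model",
    "apc_litres_to_grams_per_day",
    "consumption_loglik", "prevalence_loglik", "apc_constraint_logdensity",
    "shape_prior_logdensity", "softcap_logdensity", "joint_logposterior",
]

#: density of pure ethanol, grams per litre
ETHANOL_G_PER_L = 789.24
DAYS_PER_YEAR = 365.25

#: shape-prior locations per sex (male, female): (mu/sd)^-2 ratios
R_SHAPE = (1.171 ** -2, 1.258 ** -2)
#: shape-prior scales per sex (male, female)
RS_SHAPE = (0.028, 0.036)

_LN2PI = float(np.log(2.0 * np.pi))


def apc_litres_to_grams_per_day(apc_litres):
    """Convert litres of pure ethanol per capita per year to grams/day."""
    return np.asarray(apc_litres, dtype=float) * ETHANOL_G_PER_L / DAYS_PER_YEAR


@dataclass(frozen=True)
class ModelConfig:
    """Tunable constants of the joint model."""

    w: float = 0.2                # wastage fraction of APC
    cap: float = 150.0            # soft cap on the 95th percentile, g/day
    cap_scale: float = 5.0        # scale of the one-sided cap penalty, g/day
    coef_sd: float = 3.0          # prior sd of spline coefficients
    cprime_logit_loc: float = 0.0  # prior location of logit c'_s
    cprime_logit_sd: float = 1.5  # prior sd of logit c'_s (broad on (0,1))
    cdev_sd: float = 0.025        # prior sd of log coverage deviations
    dc1: int = 4
    dc2: int = 4
    dp1: int = 4
    dp2: int = 4

    def __post_init__(self):
        if not 0 <= self.w < 1:
            raise ValueError("wastage fraction w must be in [0, 1)")
        if self.cap <= 0 or self.cap_scale <= 0:
            raise ValueError("cap and cap_scale must be positive")


@dataclass
class ModelInputs:
    """Aggregated data consumed by the model.

    ``prevalence`` and ``consumption`` follow the tabular contract of
    :func:`alcmeta.aggregate.aggregate_surveys`; ``pop`` has shape
    (2, n_years, n_ages) and sums to one within each year; ``apc`` and
    ``apcse`` are in grams of ethanol per capita per day.
    """

    years: np.ndarray          # modelled calendar years, ascending
    ages: np.ndarray           # representative age-group midpoints
    prevalence: "pd.DataFrame"
    consumption: "pd.DataFrame"
    pop: np.ndarray            # (2, Y, A) population proportions
    apc: np.ndarray            # (Y,) grams/day per capita
    apcse: np.ndarray          # (Y,) grams/day
    survey_year: dict          # survey_id -> calendar year
    survey_ids: list = field(default=None)  # fit order of surveys

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)
        self.pop = np.asarray(self.pop, dtype=float)
        self.apc = np.asarray(self.apc, dtype=float)
        self.apcse = np.asarray(self.apcse, dtype=float)
        Y, A = self.years.size, self.ages.size
        if self.pop.shape != (2, Y, A):
            raise ValueError(f"pop must have shape (2, {Y}, {A})")
        if not np.allclose(self.pop.sum(axis=(0, 2)), 1.0, atol=1e-6):
            raise ValueError("population proportions must sum to 1 within each year")
        if self.apc.shape != (Y,) or self.apcse.shape != (Y,):
            raise ValueError("apc/apcse must have one value per modelled year")
        if np.any(self.apcse <= 0):
            raise ValueError("apcse must be positive")
        for sid, yr in self.survey_year.items():
            if yr not in self.years:
                raise ValueError(f"survey {sid!r} year {yr} outside the modelled range")
        if self.survey_ids is None:
            self.survey_ids = sorted(self.survey_year)
        cons = self.consumption
        if len(cons):
            bad = (cons.uc == cons.lc) & (cons.lc <= 0)
            if bad.any():
                raise ValueError("degenerate consumption tuples at zero are invalid")
            sums = cons.groupby(["survey_id", "sex", "age_group"])["pc"].sum()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("pc must sum to 1 within each (survey, sex, age) cell")

    @property
    def n_years(self):
        return self.years.size

    @property
    def n_ages(self):
        return self.ages.size

    @property
    def n_surveys(self):
        return len(self.survey_ids)


@dataclass
class ModelParameters:
    """Structured view of one point in parameter space."""

    sC: np.ndarray      # (2, dc1, dc2) mean-surface coefficients
    sP: np.ndarray      # (2, dp1, dp2) prevalence-surface coefficients
    cprime: np.ndarray  # (S,) overall survey coverages in (0, 1]
    cdev: np.ndarray    # (2, A) coverage deviations, geometric mean 1
    alpha: np.ndarray   # (2, Y, A) Gamma shapes

    def __post_init__(self):
        if np.any(self.cprime <= 0) or np.any(self.cprime > 1):
            raise ValueError("cprime must lie in (0, 1]")
        if np.any(self.cdev <= 0):
            raise ValueError("cdev must be positive")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _interval_terms(alpha, rho, lc, uc, degen, want_grad=True):
    """Per-tuple log interval probability and its (alpha, rho) derivatives."""
    logp = np.empty_like(rho)
    dlda = np.empty_like(rho) if want_grad else None
    dldr = np.empty_like(rho) if want_grad else None

    d = degen
    if np.any(d):
        x = lc[d]
        a, r = alpha[d], rho[d]
        logp[d] = a * np.log(r) - special.gammaln(a) + (a - 1.0) * np.log(x) - r * x
        if want_grad:
            dlda[d] = np.log(r) - special.digamma(a) + np.log(x)
            dldr[d] = a / r - x

    nd = ~d
    if np.any(nd):
        a, r = alpha[nd], rho[nd]
        l_, u_ = lc[nd], uc[nd]
        P = _prob(a, r, l_, u_)
        Pc = np.maximum(P, 1e-300)
        logp[nd] = np.log(Pc)
        if want_grad:
            # dP/drho = u f(r u) - l f(r l) with f the standard-gamma density
            term_u = np.where(np.isinf(u_), 0.0, u_ * _std_pdf(a, r * np.where(np.isinf(u_), 1.0, u_)))
            term_l = np.where(l_ > 0, l_ * _std_pdf(a, r * np.maximum(l_, 1e-300)), 0.0)
            dP_drho = term_u - term_l
            # dP/dalpha: high-accuracy central difference on the shape
            h = 6e-6 * np.maximum(a, 1e-2)
            dP_da = (_prob(a + h, r, l_, u_) - _prob(a - h, r, l_, u_)) / (2.0 * h)
            dlda[nd] = dP_da / Pc
            dldr[nd] = dP_drho / Pc
    return logp, dlda, dldr


def _prob(a, r, l_, u_):
    zl = r * l_
    lower = special.gammainc(a, zl)
    finite = ~np.isinf(u_)
    upper = np.ones_like(zl)
    upper[finite] = special.gammainc(a[finite], r[finite] * u_[finite])
    P = upper - lower
    tail = finite & (lower > 0.5)
    if np.any(tail):
        P[tail] = special.gammaincc(a[tail], zl[tail]) - special.gammaincc(
            a[tail], (r * u_)[tail]
        )
    return np.maximum(P, 0.0)


def _std_pdf(a, z):
    z = np.maximum(z, 1e-300)
    return np.exp((a - 1.0) * np.log(z) - z - special.gammaln(a))


class Model:
    """The assembled joint posterior on an unconstrained parameter vector.

    Parameter packing order: mean-surface coefficients, prevalence-surface
    coefficients, logit overall coverages, free log coverage deviations
    (the last sex-age cell is minus the sum of the others, enforcing the
    geometric-mean-one normalisation), log Gamma shapes.
    """

    def __init__(self, inputs: ModelInputs, config: ModelConfig = ModelConfig()):
        self.inputs = inputs
        self.config = config
        Y, A, S = inputs.n_years, inputs.n_ages, inputs.n_surveys
        from .splines import build_basis

        self.basis_year_c = build_basis(inputs.years, config.dc1)
        self.basis_age_c = build_basis(inputs.ages, config.dc2)
        self.basis_year_p = build_basis(inputs.years, config.dp1)
        self.basis_age_p = build_basis(inputs.ages, config.dp2)
        self._By_c = self.basis_year_c.matrix
        self._Ba_c = self.basis_age_c.matrix
        self._By_p = self.basis_year_p.matrix
        self._Ba_p = self.basis_age_p.matrix

        self.shapes = dict(
            sC=(2, config.dc1, config.dc2),
            sP=(2, config.dp1, config.dp2),
            u=(S,),
            v=(2 * A - 1,),
            t=(2, Y, A),
        )
        self._sizes = {k: int(np.prod(s)) for k, s in self.shapes.items()}
        self.n_params = sum(self._sizes.values())

        yr_index = {int(y): i for i, y in enumerate(inputs.years)}
        sid_index = {s: i for i, s in enumerate(inputs.survey_ids)}

        cons = inputs.consumption
        self._has_cons = len(cons) > 0
        if self._has_cons:
            for sid in cons["survey_id"].unique():
                if sid not in sid_index:
                    raise ValueError(f"consumption tuple references unknown survey {sid!r}")
            self._c_s = cons["survey_id"].map(sid_index).to_numpy()
            self._c_g = cons["sex"].to_numpy(dtype=int) - 1
            self._c_a = cons["age_group"].to_numpy(dtype=int) - 1
            self._c_y = np.array([yr_index[inputs.survey_year[s]]
                                  for s in cons["survey_id"]])
            self._c_lc = cons["lc"].to_numpy(dtype=float)
            self._c_uc = cons["uc"].to_numpy(dtype=float)
            self._c_w = (cons["pc"] * cons["ne"]).to_numpy(dtype=float)
            self._c_degen = self._c_uc == self._c_lc
            if np.any((self._c_g < 0) | (self._c_g > 1)):
                raise ValueError("sex codes must be 1 or 2")
            if np.any((self._c_a < 0) | (self._c_a >= A)):
                raise ValueError("consumption tuple references unknown age group")
            # static split into degenerate / interval tuples for the fast path
            dg = np.nonzero(self._c_degen)[0]
            nd = np.nonzero(~self._c_degen)[0]
            self._dg = dict(
                g=self._c_g[dg], y=self._c_y[dg], a=self._c_a[dg],
                s=self._c_s[dg], x=self._c_lc[dg], w=self._c_w[dg],
                logx=np.log(self._c_lc[dg]),
            )
            fin = np.isfinite(self._c_uc[nd])
            lcpos = self._c_lc[nd] > 0
            self._nd = dict(
                g=self._c_g[nd], y=self._c_y[nd], a=self._c_a[nd],
                s=self._c_s[nd], lc=self._c_lc[nd], uc=self._c_uc[nd],
                w=self._c_w[nd], fin=np.nonzero(fin)[0],
                lcpos=np.nonzero(lcpos)[0],
                uc_fin=self._c_uc[nd][fin], lc_pos=self._c_lc[nd][lcpos],
            )

        prev = inputs.prevalence
        self._has_prev = len(prev) > 0
        if self._has_prev:
            self._p_g = prev["sex"].to_numpy(dtype=int) - 1
            self._p_a = prev["age_group"].to_numpy(dtype=int) - 1
            self._p_y = np.array([yr_index[inputs.survey_year[s]]
                                  for s in prev["survey_id"]])
            self._p_pp = prev["pp"].to_numpy(dtype=float)
            self._p_pse = prev["pse"].to_numpy(dtype=float)
            if np.any(self._p_pse <= 0):
                raise ValueError("pse must be positive")

    # ---- packing ---------------------------------------------------------
    def pack(self, params: ModelParameters) -> np.ndarray:
        A = self.inputs.n_ages
        v_full = np.log(params.cdev).ravel()
        if not np.isclose(v_full.sum(), 0.0, atol=1e-8):
            raise ValueError("cdev must have geometric mean 1")
        u = np.log(params.cprime) - np.log1p(-np.minimum(params.cprime, 1 - 1e-12))
        return np.concatenate([
            params.sC.ravel(), params.sP.ravel(), u, v_full[:-1],
            np.log(params.alpha).ravel(),
        ])

    def unpack(self, theta: np.ndarray) -> ModelParameters:
        parts = self._split(theta)
        v_full = np.append(parts["v"], -parts["v"].sum())
        A = self.inputs.n_ages
        return ModelParameters(
            sC=parts["sC"].reshape(self.shapes["sC"]),
            sP=parts["sP"].reshape(self.shapes["sP"]),
            cprime=_sigmoid(parts["u"]),
            cdev=np.exp(v_full).reshape(2, A),
            alpha=np.exp(parts["t"]).reshape(self.shapes["t"]),
        )

    def _split(self, theta):
        out = {}
        i = 0
        for k in ("sC", "sP", "u", "v", "t"):
            n = self._sizes[k]
            out[k] = np.asarray(theta[i:i + n])
            i += n
        return out

    # ---- derived surfaces ------------------------------------------------
    def surfaces(self, theta):
        """(mu, p, alpha) arrays of shape (2, Y, A) at a parameter point."""
        parts = self._split(theta)
        sC = parts["sC"].reshape(self.shapes["sC"])
        sP = parts["sP"].reshape(self.shapes["sP"])
        eta_c = np.einsum("yi,gij,aj->gya", self._By_c, sC, self._Ba_c)
        eta_p = np.einsum("yi,gij,aj->gya", self._By_p, sP, self._Ba_p)
        mu = np.exp(eta_c)
        p = _sigmoid(eta_p)
        alpha = np.exp(parts["t"]).reshape(self.shapes["t"])
        return mu, p, alpha

    def coverages(self, theta):
        """(cprime (S,), cdev (2, A)) at a parameter point."""
        parts = self._split(theta)
        v_full = np.append(parts["v"], -parts["v"].sum())
        return _sigmoid(parts["u"]), np.exp(v_full).reshape(2, self.inputs.n_ages)

    # ---- joint log posterior and gradient --------------------------------
    def logpost_and_grad(self, theta):
        cfg = self.config
        inp = self.inputs
        Y, A, S = inp.n_years, inp.n_ages, inp.n_surveys
        parts = self._split(theta)
        sC = parts["sC"].reshape(self.shapes["sC"])
        sP = parts["sP"].reshape(self.shapes["sP"])
        u = parts["u"]
        v = parts["v"]
        t = parts["t"].reshape(self.shapes["t"])

        eta_c = np.einsum("yi,gij,aj->gya", self._By_c, sC, self._Ba_c)
        eta_p = np.einsum("yi,gij,aj->gya", self._By_p, sP, self._Ba_p)
        if not (np.all(np.isfinite(eta_c)) and np.all(np.isfinite(eta_p))):
            return -np.inf, np.zeros_like(theta)
        mu = np.exp(np.clip(eta_c, -300, 300))
        p = _sigmoid(eta_p)
        alpha = np.exp(np.clip(t, -300, 300))
        beta = alpha / mu
        cp = _sigmoid(u)
        v_full = np.append(v, -v.sum())
        cdev = np.exp(v_full).reshape(2, A)

        ll = 0.0
        g_eta_c = np.zeros_like(eta_c)
        g_eta_p = np.zeros_like(eta_p)
        g_t = np.zeros_like(t)
        g_u = np.zeros_like(u)
        g_vfull = np.zeros((2, A))

        # consumption likelihood (fast path over the static tuple split)
        if self._has_cons:
            ok = True
            for blk in (self._dg, self._nd):
                if blk["g"].size == 0:
                    continue
                ig, iy, ia, isv = blk["g"], blk["y"], blk["a"], blk["s"]
                a_t = alpha[ig, iy, ia]
                cov = cp[isv] * cdev[ig, ia]
                with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                    rho = beta[ig, iy, ia] / cov
                    if not np.all(np.isfinite(rho)):
                        ok = False
                        break
                    if blk is self._dg:
                        x = blk["x"]
                        logrho = np.log(rho)
                        logp = (a_t * logrho - special.gammaln(a_t)
                                + (a_t - 1.0) * blk["logx"] - rho * x)
                        dlda = logrho - special.digamma(a_t) + blk["logx"]
                        dldr = a_t / rho - x
                    else:
                        logp, dlda, dldr = self._nd_terms(a_t, rho)
                if logp is None or not np.all(np.isfinite(logp)):
                    ok = False
                    break
                w = blk["w"]
                ll += float((w * logp).sum())
                # chain rule: rho = alpha / (mu * cov)
                g_alpha_dir = w * (dlda * a_t + dldr * rho)   # wrt t = log alpha
                g_logmu = -w * dldr * rho                      # wrt log mu
                np.add.at(g_t, (ig, iy, ia), g_alpha_dir)
                np.add.at(g_eta_c, (ig, iy, ia), g_logmu)
                np.add.at(g_u, isv, g_logmu * (1.0 - cp[isv]))
                np.add.at(g_vfull, (ig, ia), g_logmu)
            if not ok:
                return -np.inf, np.zeros_like(theta)

        # prevalence likelihood
        if self._has_prev:
            pm = p[self._p_g, self._p_y, self._p_a]
            resid = (self._p_pp - pm) / self._p_pse
            ll += float((-0.5 * resid**2 - np.log(self._p_pse)
                         - 0.5 * _LN2PI).sum())
            dd = resid / self._p_pse * pm * (1.0 - pm)
            np.add.at(g_eta_p, (self._p_g, self._p_y, self._p_a), dd)

        # APC constraint
        T = np.einsum("gya,gya->y", mu * p, inp.pop)
        rz = (T - (1.0 - cfg.w) * inp.apc) / inp.apcse
        ll += float((-0.5 * rz**2 - np.log(inp.apcse) - 0.5 * _LN2PI).sum())
        gT = -rz / inp.apcse  # d ll / d T_y
        g_eta_c += gT[None, :, None] * mu * p * inp.pop
        g_eta_p += gT[None, :, None] * mu * inp.pop * p * (1.0 - p)

        # shape prior (truncated normal via log parameterisation + Jacobian)
        r = np.array(R_SHAPE)[:, None, None]
        rs = np.array(RS_SHAPE)[:, None, None]
        ll += float((-0.5 * ((alpha - r) / rs) ** 2 - np.log(rs)
                     - 0.5 * _LN2PI + t).sum())
        g_t += -(alpha - r) / rs**2 * alpha + 1.0

        # soft cap on the 95th percentile
        z95 = special.gammaincinv(alpha, 0.95)
        q95 = z95 * mu / alpha
        excess = q95 - cfg.cap
        over = excess > 0
        if np.any(over):
            ll += float((-0.5 * (excess[over] / cfg.cap_scale) ** 2).sum())
            gq = -excess / cfg.cap_scale**2
            # dq95/dlogmu = q95 ; dz*/dalpha = -(dP/da at z*)/f(z*)
            g_eta_c += np.where(over, gq * q95, 0.0)
            h = 6e-6 * np.maximum(alpha, 1e-2)
            dPda = (special.gammainc(alpha + h, z95)
                    - special.gammainc(alpha - h, z95)) / (2.0 * h)
            dzda = -dPda / _std_pdf(alpha, z95)
            dq_dt = mu * (dzda * alpha - z95) / alpha  # times alpha for t scale
            g_t += np.where(over, gq * dq_dt, 0.0)

        # priors: spline coefficients, overall coverage, coverage deviations
        ll += float((-0.5 * (sC / cfg.coef_sd) ** 2).sum()
                    + (-0.5 * (sP / cfg.coef_sd) ** 2).sum())
        g_sC = -sC / cfg.coef_sd**2
        g_sP = -sP / cfg.coef_sd**2

        du = (u - cfg.cprime_logit_loc) / cfg.cprime_logit_sd
        ll += float((-0.5 * du**2).sum())
        g_u += -du / cfg.cprime_logit_sd

        ll += float((-0.5 * (v_full / cfg.cdev_sd) ** 2).sum())
        g_vfull += (-v_full / cfg.cdev_sd**2).reshape(2, A)

        # back-propagate surface gradients into coefficients
        g_sC += np.einsum("yi,gya,aj->gij", self._By_c, g_eta_c, self._Ba_c)
        g_sP += np.einsum("yi,gya,aj->gij", self._By_p, g_eta_p, self._Ba_p)
        gv_flat = g_vfull.ravel()
        g_v = gv_flat[:-1] - gv_flat[-1]

        grad = np.concatenate([g_sC.ravel(), g_sP.ravel(), g_u, g_v, g_t.ravel()])
        if not (np.isfinite(ll) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros_like(theta)
        return ll, grad

    def logpost(self, theta):
        return self.logpost_and_grad(theta)[0]

    def _nd_terms(self, a, rho):
        """Batched log interval probabilities and derivatives (interval tuples).

        Evaluates the regularised incomplete gamma at (a, a+h, a-h) in single
        ufunc calls; the a-derivative is the central difference, exact in the
        other arguments.
        """
        nd = self._nd
        n = a.size
        lc, uc = nd["lc"], nd["uc"]
        fin, lcpos = nd["fin"], nd["lcpos"]
        zl = rho * lc
        h = 6e-6 * np.maximum(a, 1e-2)
        A3 = np.concatenate([a, a + h, a - h])
        ZL3 = np.tile(zl, 3)
        FL3 = special.gammainc(A3, ZL3).reshape(3, n)
        FU3 = np.ones((3, n))
        if fin.size:
            zu_f = rho[fin] * nd["uc_fin"]
            Af = np.concatenate([a[fin], (a + h)[fin], (a - h)[fin]])
            FU3[:, fin] = special.gammainc(Af, np.tile(zu_f, 3)).reshape(3, -1)
        P3 = FU3 - FL3
        # survival-side recomputation only where the difference form loses the
        # mass entirely (both bounds far in the upper tail); rare by design
        tail = np.nonzero((P3[0] < 1e-9) & np.isfinite(uc))[0]
        if tail.size:
            zt_u = rho[tail] * uc[tail]
            At = np.stack([a[tail], (a + h)[tail], (a - h)[tail]])
            P3[:, tail] = (special.gammaincc(At, np.broadcast_to(rho[tail] * lc[tail], At.shape))
                           - special.gammaincc(At, np.broadcast_to(zt_u, At.shape)))
        P = np.maximum(P3[0], 1e-300)
        logp = np.log(P)
        dPda = (P3[1] - P3[2]) / (2.0 * h)
        dPdr = np.zeros(n)
        if fin.size:
            zf = rho[fin] * nd["uc_fin"]
            dPdr[fin] = nd["uc_fin"] * np.exp(
                (a[fin] - 1.0) * np.log(zf) - zf - special.gammaln(a[fin])
            )
        if lcpos.size:
            zp = rho[lcpos] * nd["lc_pos"]
            dPdr[lcpos] -= nd["lc_pos"] * np.exp(
                (a[lcpos] - 1.0) * np.log(zp) - zp - special.gammaln(a[lcpos])
            )
        return logp, dPda / P, dPdr / P

    # ---- initialisation --------------------------------------------------
    def initial_point(self, rng: np.random.Generator, jitter: float = 0.05):
        """Data-informed starting point with bounded jitter.

        The constant directions of both surfaces are set from crude weighted
        summaries (overall prevalence; APC-implied mean consumption) and the
        coverages from the ratio of observed survey means to the APC-implied
        mean; random directions get small jitter so chains are dispersed but
        the APC coupling stays finite.
        """
        inp = self.inputs
        theta = np.zeros(self.n_params)
        parts_idx = {}
        i = 0
        for k in ("sC", "sP", "u", "v", "t"):
            parts_idx[k] = (i, i + self._sizes[k])
            i += self._sizes[k]

        pbar = float(np.clip(inp.prevalence["pp"].mean(), 0.02, 0.98)) \
            if self._has_prev else 0.3
        apc_bar = float(np.mean((1.0 - self.config.w) * inp.apc))
        mu_bar = max(apc_bar / pbar, 1.0)

        sC = np.zeros(self.shapes["sC"])
        sC[:, 0, 0] = np.log(mu_bar)
        sP = np.zeros(self.shapes["sP"])
        sP[:, 0, 0] = np.log(pbar / (1.0 - pbar))

        u = np.zeros(self.shapes["u"])
        if self._has_cons:
            cons = self.inputs.consumption
            for j, sid in enumerate(inp.survey_ids):
                sub = cons[cons.survey_id == sid]
                if len(sub) == 0:
                    continue
                mid = np.where(np.isinf(sub.uc), sub.lc * 1.5 + 10.0,
                               0.5 * (sub.lc + sub.uc))
                obs_mean = float((sub.pc * mid).sum() / max(sub.pc.sum(), 1e-12))
                c0 = float(np.clip(obs_mean / mu_bar, 0.05, 0.95))
                u[j] = np.log(c0 / (1.0 - c0))

        t = np.log(np.array(R_SHAPE))[:, None, None] * np.ones(self.shapes["t"])

        theta[slice(*parts_idx["sC"])] = sC.ravel()
        theta[slice(*parts_idx["sP"])] = sP.ravel()
        theta[slice(*parts_idx["u"])] = u
        theta[slice(*parts_idx["t"])] = t.ravel()
        theta += jitter * rng.standard_normal(self.n_params)
        return theta

    def map_estimate(self, theta0, maxiter: int = 2000):
        """Posterior mode from a starting point (L-BFGS on the exact gradient)."""
        from scipy.optimize import minimize

        def negfg(t):
            ll, g = self.logpost_and_grad(t)
            return -ll, -g

        res = minimize(negfg, theta0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=maxiter))
        return res.x

    def laplace_inv_mass(self, theta, h: float = 1e-4) -> np.ndarray:
        """Dense Gaussian-approximation covariance at a mode.

        Central finite differences of the exact gradient give the Hessian;
        eigenvalues are floored so the result is positive definite even when
        the point is not exactly a mode.  Used to seed the sampler's metric.
        """
        n = self.n_params
        H = np.empty((n, n))
        e = np.zeros(n)
        for i in range(n):
            e[i] = h
            _, g1 = self.logpost_and_grad(theta + e)
            _, g2 = self.logpost_and_grad(theta - e)
            e[i] = 0.0
            H[i] = (g1 - g2) / (2.0 * h)
        H = 0.5 * (H + H.T)
        evals, evecs = np.linalg.eigh(-H)  # negative Hessian ~ precision
        evals = np.maximum(evals, 1e-6 * max(evals.max(), 1.0))
        cov = (evecs / evals) @ evecs.T
        return 0.5 * (cov + cov.T)

    def estimate_inv_mass(self, theta, h: float = 1e-4) -> np.ndarray:
        """Crude per-parameter posterior variances from the diagonal Hessian.

        Used to precondition the sampler's initial mass matrix; the warmup
        windows refine it from actual draws.  Curvature is measured by a
        central difference of the gradient at ``theta``.
        """
        var = np.empty(self.n_params)
        e = np.zeros(self.n_params)
        for i in range(self.n_params):
            e[i] = h
            _, g1 = self.logpost_and_grad(theta + e)
            _, g2 = self.logpost_and_grad(theta - e)
            e[i] = 0.0
            curv = -(g1[i] - g2[i]) / (2.0 * h)
            var[i] = 1.0 / curv if curv > 1e-8 else 1.0
        return np.clip(var, 1e-8, 10.0)


# ---- component log-density functions --------------------------------------

def consumption_loglik(model: Model, params: ModelParameters) -> float:
    """Weighted interval-censored Gamma log likelihood of the tuples."""
    if not model._has_cons:
        return 0.0
    mu, p, alpha = _mp(model, params)
    ig, iy, ia, isv = model._c_g, model._c_y, model._c_a, model._c_s
    cov = params.cprime[isv] * params.cdev[ig, ia]
    rho = (alpha / mu)[ig, iy, ia] / cov
    logp, _, _ = _interval_terms(alpha[ig, iy, ia], rho, model._c_lc,
                                 model._c_uc, model._c_degen, want_grad=False)
    return float((model._c_w * logp).sum())


def prevalence_loglik(model: Model, params: ModelParameters) -> float:
    """Normal log likelihood of observed prevalences around the surface."""
    if not model._has_prev:
        return 0.0
    _, p, _ = _mp(model, params)
    pm = p[model._p_g, model._p_y, model._p_a]
    z = (model._p_pp - pm) / model._p_pse
    return float((-0.5 * z**2 - np.log(model._p_pse) - 0.5 * _LN2PI).sum())


def apc_constraint_logdensity(model: Model, params: ModelParameters) -> float:
    """Per-year normal constraint tying the population total to (1-w) APC."""
    mu, p, _ = _mp(model, params)
    T = np.einsum("gya,gya->y", mu * p, model.inputs.pop)
    z = (T - (1.0 - model.config.w) * model.inputs.apc) / model.inputs.apcse
    with np.errstate(over="ignore"):
        return float((-0.5 * z**2 - np.log(model.inputs.apcse)
                      - 0.5 * _LN2PI).sum())


def shape_prior_logdensity(model: Model, params: ModelParameters) -> float:
    """Informative sex-specific normal prior on the Gamma shape (log param)."""
    alpha = params.alpha
    r = np.array(R_SHAPE)[:, None, None]
    rs = np.array(RS_SHAPE)[:, None, None]
    return float((-0.5 * ((alpha - r) / rs) ** 2 - np.log(rs) - 0.5 * _LN2PI
                  + np.log(alpha)).sum())


def softcap_logdensity(model: Model, params: ModelParameters) -> float:
    """One-sided penalty on 95th percentiles exceeding the soft cap."""
    mu, _, alpha = _mp(model, params)
    q95 = special.gammaincinv(alpha, 0.95) * mu / alpha
    excess = np.maximum(q95 - model.config.cap, 0.0)
    with np.errstate(over="ignore"):
        return float((-0.5 * (excess / model.config.cap_scale) ** 2).sum())


def _prior_logdensity(model: Model, params: ModelParameters) -> float:
    cfg = model.config
    u = np.log(params.cprime) - np.log1p(-np.minimum(params.cprime, 1 - 1e-12))
    v_full = np.log(params.cdev).ravel()
    return float((-0.5 * (params.sC / cfg.coef_sd) ** 2).sum()
                 + (-0.5 * (params.sP / cfg.coef_sd) ** 2).sum()
                 + (-0.5 * ((u - cfg.cprime_logit_loc) / cfg.cprime_logit_sd) ** 2).sum()
                 + (-0.5 * (v_full / cfg.cdev_sd) ** 2).sum())


def joint_logposterior(model: Model, params: ModelParameters) -> float:
    """Sum of all likelihood, constraint and prior components."""
    components = {
        "consumption": consumption_loglik(model, params),
        "prevalence": prevalence_loglik(model, params),
        "apc": apc_constraint_logdensity(model, params),
        "shape_prior": shape_prior_logdensity(model, params),
        "softcap": softcap_logdensity(model, params),
        "priors": _prior_logdensity(model, params),
    }
    for name, val in components.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite log-posterior component: {name}")
    return sum(components.values())


def _mp(model: Model, params: ModelParameters):
    eta_c = np.einsum("yi,gij,aj->gya", model._By_c, params.sC, model._Ba_c)
    eta_p = np.einsum("yi,gij,aj->gya", model._By_p, params.sP, model._Ba_p)
    return np.exp(eta_c), _sigmoid(eta_p), params.alpha
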