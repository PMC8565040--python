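"""No-U-Turn sampler with dual-averaging step-size and mass-matrix adaptation.

A self-contained gradient-based Hamiltonian Monte Carlo implementation in the
style of Stan's defaults: the doubling binary-tree trajectory with slice
sampling over the trajectory (Hoffman & Gelman's algorithm), dual averaging
of the step size towards a target acceptance statistic during warmup, and a
windowed estimate of the inverse mass matrix — diagonal in early windows,
dense (full posterior covariance, regularised) once windows are long enough
to support it.  The dense metric matters here: the joint posterior couples
surface coefficients, coverages and shapes along narrow ridges that a
diagonal metric cannot absorb.  Everything is driven by a
``numpy.random.Generator`` so runs are exactly reproducible given a seed.

The target is supplied as a callable ``logpost_and_grad(theta) -> (float,
ndarray)`` returning ``-inf`` (with any gradient) outside the support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "nuts"]

_MAX_DELTA = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsResult:
    draws: np.ndarray        # (n_kept, dim)
    logpost: np.ndarray      # (n_kept,)
    divergences: int
    step_size: float
    inv_mass: np.ndarray
    accept_mean: float
    treedepth_mean: float


class _Metric:
    """Diagonal or dense inverse-mass metric with cached factorisations."""

    def __init__(self, inv_mass):
        inv_mass = np.asarray(inv_mass, dtype=float)
        self.dense = inv_mass.ndim == 2
        self.inv_mass = inv_mass
        if self.dense:
            # inv_mass = Sigma = L L^T ; momentum ~ N(0, Sigma^{-1}) = L^{-T} z
            self._L = np.linalg.cholesky(inv_mass)
        else:
            self._sqrt = np.sqrt(inv_mass)

    def velocity(self, p):
        return self.inv_mass @ p if self.dense else self.inv_mass * p

    def kinetic(self, p):
        return 0.5 * float(np.dot(p, self.velocity(p)))

    def sample_momentum(self, rng):
        z = rng.standard_normal(self.inv_mass.shape[-1])
        if self.dense:
            from scipy.linalg import solve_triangular

            return solve_triangular(self._L, z, lower=True, trans="T")
        return z / self._sqrt


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "ll_prop", "g_prop", "n", "s", "alpha", "n_alpha", "div")


def _leapfrog(x, p, g, eps, target, metric):
    p1 = p + 0.5 * eps * g
    x1 = x + eps * metric.velocity(p1)
    ll1, g1 = target(x1)
    p1 = p1 + 0.5 * eps * g1
    return x1, p1, g1, ll1


def _no_uturn(x_minus, x_plus, p_minus, p_plus, metric):
    dx = x_plus - x_minus
    return (np.dot(dx, metric.velocity(p_minus)) >= 0) and (
        np.dot(dx, metric.velocity(p_plus)) >= 0
    )


def _build_tree(x, p, g, logu, direction, depth, eps, H0, target, metric, rng):
    t = _Tree()
    if depth == 0:
        x1, p1, g1, ll1 = _leapfrog(x, p, g, direction * eps, target, metric)
        H = ll1 - metric.kinetic(p1) if np.isfinite(ll1) else -np.inf
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.ll_prop = ll1
        t.n = 1 if logu <= H else 0
        t.s = 1 if (H - logu) > -_MAX_DELTA else 0
        t.div = 1 - t.s
        t.alpha = min(1.0, float(np.exp(min(H - H0, 0.0)))) if np.isfinite(H) else 0.0
        t.n_alpha = 1
        return t

    left = _build_tree(x, p, g, logu, direction, depth - 1, eps, H0, target,
                       metric, rng)
    t.x_minus, t.p_minus, t.g_minus = left.x_minus, left.p_minus, left.g_minus
    t.x_plus, t.p_plus, t.g_plus = left.x_plus, left.p_plus, left.g_plus
    t.x_prop, t.ll_prop, t.g_prop = left.x_prop, left.ll_prop, left.g_prop
    t.n, t.s, t.alpha, t.n_alpha = left.n, left.s, left.alpha, left.n_alpha
    t.div = left.div
    if left.s == 1:
        if direction == -1:
            right = _build_tree(left.x_minus, left.p_minus, left.g_minus, logu,
                                direction, depth - 1, eps, H0, target, metric, rng)
            t.x_minus, t.p_minus, t.g_minus = right.x_minus, right.p_minus, right.g_minus
        else:
            right = _build_tree(left.x_plus, left.p_plus, left.g_plus, logu,
                                direction, depth - 1, eps, H0, target, metric, rng)
            t.x_plus, t.p_plus, t.g_plus = right.x_plus, right.p_plus, right.g_plus
        total = left.n + right.n
        if total > 0 and rng.random() < right.n / total:
            t.x_prop, t.ll_prop, t.g_prop = right.x_prop, right.ll_prop, right.g_prop
        t.alpha = left.alpha + right.alpha
        t.n_alpha = left.n_alpha + right.n_alpha
        t.n = total
        t.div = max(left.div, right.div)
        t.s = right.s * int(_no_uturn(t.x_minus, t.x_plus, t.p_minus, t.p_plus,
                                      metric))
    return t


def _find_initial_step(x, ll, g, target, metric, rng):
    eps = 1.0
    p = metric.sample_momentum(rng)
    H0 = ll - metric.kinetic(p)
    _, p1, _, ll1 = _leapfrog(x, p, g, eps, target, metric)
    H1 = ll1 - metric.kinetic(p1) if np.isfinite(ll1) else -np.inf
    direction = 1 if (H1 - H0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, _, ll1 = _leapfrog(x, p, g, eps, target, metric)
        H1 = ll1 - metric.kinetic(p1) if np.isfinite(ll1) else -np.inf
        if direction == 1 and (H1 - H0) <= np.log(0.5):
            break
        if direction == -1 and (H1 - H0) > np.log(0.5):
            break
    return max(eps, 1e-8)


def _adapt_metric(buf, prev_inv_mass, dense_threshold: int = 2):
    """Regularised (co)variance of the window draws.

    A dense metric is kept dense: the window covariance is shrunk towards the
    full previous metric, with shrinkage weight n / (n + dim + 5) so short
    windows (sample covariance rank-deficient) lean on the previous estimate.
    A diagonal metric stays diagonal until a window holds at least
    ``dense_threshold * dim`` draws, then upgrades to dense.
    """
    buf = np.asarray(buf)
    n, dim = buf.shape
    if n < 2:
        return prev_inv_mass
    prev_dense = prev_inv_mass.ndim == 2
    if prev_dense or n >= dense_threshold * dim:
        prev_full = (prev_inv_mass if prev_dense
                     else np.diag(np.asarray(prev_inv_mass)))
        w = n / (n + dim + 5.0)
        reg = w * np.cov(buf.T) + (1 - w) * prev_full
        reg += 1e-10 * np.eye(dim)
        try:
            np.linalg.cholesky(reg)
            return reg
        except np.linalg.LinAlgError:
            pass
    prev_diag = np.diag(prev_inv_mass) if prev_dense else prev_inv_mass
    w = n / (n + 5.0)
    var = buf.var(axis=0, ddof=1)
    return np.maximum(w * var + (1 - w) * prev_diag, 1e-10)


def nuts(
    target,
    theta0: np.ndarray,
    n_iterations: int,
    warmup_fraction: float = 0.6,
    rng: np.random.Generator | None = None,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    inv_mass0: np.ndarray | None = None,
) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws.

    ``n_iterations`` counts all iterations; the first
    ``warmup_fraction * n_iterations`` adapt the step size (dual averaging)
    and the mass matrix (expanding windows) and are discarded.  ``inv_mass0``
    seeds the metric with per-parameter variance guesses.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(theta0, dtype=float).copy()
    ll, g = target(x)
    if not np.isfinite(ll):
        raise ValueError("initial point has non-finite log posterior")
    dim = x.size
    n_warm = int(round(warmup_fraction * n_iterations))
    metric = _Metric(np.ones(dim) if inv_mass0 is None
                     else np.asarray(inv_mass0, float))

    eps = _find_initial_step(x, ll, g, target, metric, rng)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, H_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75
    m_da = 0  # dual-averaging step counter, restarted with each metric reset

    # mass-adaptation windows within warmup (Stan-like 15% / windows / 10%)
    w_start = int(0.15 * n_warm)
    w_end = int(0.90 * n_warm)
    window_bounds = []
    wsize = 25
    pos = w_start
    while pos < w_end:
        nxt = min(pos + wsize, w_end)
        if w_end - nxt < wsize:
            nxt = w_end
        window_bounds.append(nxt)
        pos = nxt
        wsize *= 2
    window_buf = []

    kept = np.empty((n_iterations - n_warm, dim))
    kept_ll = np.empty(n_iterations - n_warm)
    divergences = 0
    accepts, depths = [], []

    for it in range(n_iterations):
        p0 = metric.sample_momentum(rng)
        H0 = ll - metric.kinetic(p0)
        logu = H0 + np.log(rng.random())
        x_minus = x_plus = x
        p_minus = p_plus = p0
        g_minus = g_plus = g
        x_new, ll_new, g_new = x, ll, g
        n_tot, s, depth = 1, 1, 0
        alpha_sum, n_alpha = 0.0, 0
        divergent = 0
        while s == 1 and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(x_minus, p_minus, g_minus, logu, -1, depth, eps,
                                H0, target, metric, rng)
                x_minus, p_minus, g_minus = t.x_minus, t.p_minus, t.g_minus
            else:
                t = _build_tree(x_plus, p_plus, g_plus, logu, 1, depth, eps,
                                H0, target, metric, rng)
                x_plus, p_plus, g_plus = t.x_plus, t.p_plus, t.g_plus
            if t.s == 1 and rng.random() < min(1.0, t.n / n_tot):
                x_new, ll_new, g_new = t.x_prop, t.ll_prop, t.g_prop
            n_tot += t.n
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            divergent = max(divergent, t.div)
            s = t.s * int(_no_uturn(x_minus, x_plus, p_minus, p_plus, metric))
            depth += 1
        if divergent and it >= n_warm:
            divergences += 1
        x, ll, g = x_new, ll_new, g_new
        accept_stat = alpha_sum / max(n_alpha, 1)
        accepts.append(accept_stat)
        depths.append(depth)

        if it < n_warm:
            # dual averaging towards the target acceptance statistic
            m_da += 1
            H_bar = (1 - 1 / (m_da + t0_da)) * H_bar + (
                target_accept - accept_stat
            ) / (m_da + t0_da)
            log_eps = mu_da - np.sqrt(m_da) / gamma_da * H_bar
            eta = m_da**-kappa_da
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_start <= it < w_end:
                window_buf.append(x.copy())
                if (it + 1) in window_bounds:
                    metric = _Metric(_adapt_metric(np.asarray(window_buf),
                                                   metric.inv_mass))
                    window_buf = []
                    # re-initialise step-size search under the new metric
                    eps = _find_initial_step(x, ll, g, target, metric, rng)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, H_bar = 0.0, 0.0
                    m_da = 0
            if it == n_warm - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            kept[it - n_warm] = x
            kept_ll[it - n_warm] = ll

    return NutsResult(
        draws=kept,
        logpost=kept_ll,
        divergences=divergences,
        step_size=eps,
        inv_mass=metric.inv_mass,
        accept_mean=float(np.mean(accepts[n_warm:])) if n_iterations > n_warm
        else float("nan"),
        treedepth_mean=float(np.mean(depths[n_warm:])) if n_iterations > n_warm
        else float("nan"),
    )
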