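"""Year x age smooth surfaces for mean consumption and drinker prevalence.

Both surfaces are tensor-product generalised additive models: the log of the
mean consumption among drinkers and the logit of the prevalence of drinkers
are double sums  sum_i sum_j s_{g,i,j} Psi_i(year) Phi_j(age)  over one-
dimensional smooth bases on the year and age axes, with separate coefficient
tensors per sex.  The links guarantee mu > 0 and p in (0, 1) by construction.

The one-dimensional bases are low-rank thin-plate regression splines: the
radial basis |x - k|^3 on the distinct axis values, constrained orthogonal to
the {1, x} polynomial null space and eigen-truncated to the requested
dimension, with the null space itself prepended.  Dimension 2 therefore
reduces to exactly {constant, linear}.  Axes are internally rescaled to
[0, 1] for conditioning; all public values are on natural scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BasisSpec", "Basis1D", "SplineSurface", "build_basis",
           "eval_mean", "eval_prevalence"]


@dataclass(frozen=True)
class BasisSpec:
    """Axis values and basis dimensions for the two surfaces."""

    years: tuple
    ages: tuple
    dc1: int = 4  # mean surface, year axis
    dc2: int = 4  # mean surface, age axis
    dp1: int = 4  # prevalence surface, year axis
    dp2: int = 4  # prevalence surface, age axis

    def __post_init__(self):
        for name in ("dc1", "dc2", "dp1", "dp2"):
            d = getattr(self, name)
            n = len(set(self.years if name.endswith("1") else self.ages))
            if d < 2:
                raise ValueError(f"{name} must be >= 2")
            if d > n:
                raise ValueError(f"{name}={d} exceeds the {n} distinct axis values")


class Basis1D:
    """A one-dimensional thin-plate regression spline basis.

    Evaluable at arbitrary points; ``matrix`` is the design matrix at the
    construction points.  Deterministic: the same axis values and dimension
    always produce the identical basis.
    """

    def __init__(self, axis_values, dim: int):
        x = np.asarray(axis_values, dtype=float)
        knots = np.unique(x)
        if dim < 2:
            raise ValueError("basis dimension must be >= 2")
        if dim > knots.size:
            raise ValueError(
                f"basis dimension {dim} exceeds {knots.size} distinct axis values"
            )
        self.dim = dim
        self._lo = knots[0]
        self._span = max(knots[-1] - knots[0], 1.0)
        ks = self._scale(knots)
        self._knots = ks

        if dim > 2:
            # radial-basis block constrained orthogonal to the {1, x} null
            # space, then eigen-truncated to the dim-2 leading directions
            C = np.abs(ks[:, None] - ks[None, :]) ** 3
            T = np.column_stack([np.ones_like(ks), ks])
            q, _ = np.linalg.qr(T, mode="complete")
            Z = q[:, 2:]
            S = Z.T @ C @ Z
            S = 0.5 * (S + S.T)
            evals, evecs = np.linalg.eigh(S)
            order = np.argsort(-np.abs(evals))[: dim - 2]
            W = Z @ evecs[:, order]
            # fixed sign convention for determinism
            for j in range(W.shape[1]):
                k = np.argmax(np.abs(W[:, j]))
                if W[k, j] < 0:
                    W[:, j] = -W[:, j]
            self._weights = W
            # normalise each smooth column to unit RMS on the knots
            raw = C @ W
            self._colscale = 1.0 / np.sqrt(np.mean(raw**2, axis=0))
        else:
            self._weights = np.zeros((knots.size, 0))
            self._colscale = np.zeros(0)

        self.matrix = self.evaluate(knots)

    def _scale(self, x):
        return (np.asarray(x, dtype=float) - self._lo) / self._span

    def evaluate(self, x) -> np.ndarray:
        """Design matrix (len(x), dim) at arbitrary axis values."""
        xs = np.atleast_1d(self._scale(x))
        cols = [np.ones_like(xs), xs]
        if self.dim > 2:
            R = np.abs(xs[:, None] - self._knots[None, :]) ** 3
            cols.append((R @ self._weights) * self._colscale)
            return np.column_stack(cols)
        return np.column_stack(cols)


def build_basis(axis_values, dim: int) -> Basis1D:
    """Construct the 1-D smooth basis on the given axis values."""
    return Basis1D(axis_values, dim)


@dataclass
class SplineSurface:
    """Tensor-product surface: coefficients per (sex, year-basis, age-basis)."""

    coef: np.ndarray  # (n_sex, dim_year, dim_age)
    year_basis: Basis1D
    age_basis: Basis1D
    link: str = "log"  # "log" (mean) or "logit" (prevalence)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        expected = (self.coef.shape[0], self.year_basis.dim, self.age_basis.dim)
        if self.coef.shape != expected:
            raise ValueError(f"coefficient tensor shape {self.coef.shape} != {expected}")
        if self.link not in ("log", "logit"):
            raise ValueError("link must be 'log' or 'logit'")

    def linear_predictor(self, year, age, sex: int) -> np.ndarray:
        """eta(year, age) for one sex (0-based index), broadcasting grids."""
        By = self.year_basis.evaluate(np.atleast_1d(year))
        Ba = self.age_basis.evaluate(np.atleast_1d(age))
        return By @ self.coef[sex] @ Ba.T

    def grid(self) -> np.ndarray:
        """Surface values on the construction grid, shape (sex, year, age)."""
        By = self.year_basis.matrix
        Ba = self.age_basis.matrix
        eta = np.einsum("yi,gij,aj->gya", By, self.coef, Ba)
        return _apply_link(eta, self.link)


def _apply_link(eta, link):
    if link == "log":
        return np.exp(eta)
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    return np.clip(p, 1e-15, 1.0 - 1e-15)


def eval_mean(year, age, surface: SplineSurface, sex: int = 0):
    """Mean consumption mu(year, age) in grams/day; always positive."""
    if surface.link != "log":
        raise ValueError("eval_mean requires a log-link surface")
    out = np.exp(surface.linear_predictor(year, age, sex))
    return float(out[0, 0]) if out.size == 1 else out


def eval_prevalence(year, age, surface: SplineSurface, sex: int = 0):
    """Prevalence of drinkers p(year, age); strictly inside (0, 1)."""
    if surface.link != "logit":
        raise ValueError("eval_prevalence requires a logit-link surface")
    out = _apply_link(surface.linear_predictor(year, age, sex), "logit")
    return float(out[0, 0]) if out.size == 1 else out
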