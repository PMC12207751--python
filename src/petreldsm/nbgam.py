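"""Negative-binomial additive models with penalized regression splines.

This is the statistical engine behind the density surface models in this
package.  Counts ``y_i`` (storm-petrels per grid cell and survey pass) are
modelled on the log scale,

    y_i ~ NB(mu_i, theta),   log mu_i = offset_i + X_i beta,

where the offset is the log of the surveyed area, and the linear predictor
is built from an intercept plus a collection of terms:

* univariate penalized thin-plate regression splines (eigen-truncated
  radial bases, Wood-style) with a *double* shrinkage penalty: one
  smoothing parameter on the wiggliness penalty and a second on its null
  space, so a term can be shrunk entirely out of the model;
* a bivariate thin-plate spline of the spatial coordinates;
* factor-smooth interactions (one centred smooth per factor level, e.g.
  sea state by survey altitude);
* i.i.d. Gaussian random effects (ridge-penalized indicator columns);
* parametric factor and linear terms.

Smoothing parameters are selected by a working-model REML criterion
evaluated inside a performance-iteration loop (penalized IRLS for beta,
then Laplace/REML on the Gaussian working model for the log smoothing
parameters, repeated until both stabilise).  The negative-binomial size
parameter theta is profiled out by golden-section search on the exact NB
log-likelihood between IRLS passes.  A complexity-inflation factor gamma
(default 1.2) divides the data-information term of the criterion, which
favours smoother fits exactly as an inflated degrees-of-freedom cost
would.

Every smooth is subject to a sum-to-zero constraint over the training
rows (columns are centred), so smooth terms carry no intercept and a
basis of rank k contributes k - 1 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh, null_space
from scipy.spatial.distance import cdist
from scipy.special import gammaln, xlogy
from scipy.stats import chi2


class ModelError(RuntimeError):
    """Raised for specification or convergence failures."""


# ---------------------------------------------------------------------------
# term specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Smooth1D:
    """Univariate thin-plate regression spline, max basis rank ``k``."""

    var: str
    k: int = 5
    shrinkage: bool = True

    @property
    def label(self) -> str:
        return f"s({self.var})"


@dataclass(frozen=True)
class Smooth2D:
    """Bivariate (spatial) thin-plate regression spline."""

    xvar: str
    yvar: str
    k: int = 30
    shrinkage: bool = True

    @property
    def label(self) -> str:
        return f"s({self.xvar},{self.yvar})"


@dataclass(frozen=True)
class FactorSmooth:
    """One centred smooth of ``var`` per level of the factor ``by``."""

    var: str
    by: str
    k: int = 5

    @property
    def label(self) -> str:
        return f"s({self.var},by={self.by})"


@dataclass(frozen=True)
class RandomEffect:
    """i.i.d. Gaussian random effect of a factor (ridge-penalized dummies)."""

    var: str

    @property
    def label(self) -> str:
        return f"re({self.var})"


@dataclass(frozen=True)
class Factor:
    """Parametric factor (treatment-coded; ``ref`` names the reference level,
    defaulting to the first in sort order)."""

    var: str
    ref: object = None

    @property
    def label(self) -> str:
        return f"factor({self.var})"


@dataclass(frozen=True)
class Linear:
    """Parametric linear term."""

    var: str

    @property
    def label(self) -> str:
        return f"lin({self.var})"


TermSpec = Smooth1D | Smooth2D | FactorSmooth | RandomEffect | Factor | Linear

_TERM_KINDS = {"Smooth1D": Smooth1D, "Smooth2D": Smooth2D,
               "FactorSmooth": FactorSmooth, "RandomEffect": RandomEffect,
               "Factor": Factor, "Linear": Linear}


def term_to_dict(spec: TermSpec) -> dict:
    """JSON-serialisable description of a term specification."""
    d = {"kind": type(spec).__name__}
    d.update(spec.__dict__)
    return d


def term_from_dict(d: dict) -> TermSpec:
    d = dict(d)
    return _TERM_KINDS[d.pop("kind")](**d)


# ---------------------------------------------------------------------------
# thin-plate regression spline basis
# ---------------------------------------------------------------------------


def _tps_eta(r: np.ndarray, d: int) -> np.ndarray:
    """Thin-plate radial basis function for m=2 (penalized 2nd derivatives)."""
    if d == 1:
        return r**3 / 12.0
    # d == 2: r^2 log r, with eta(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r * r * np.log(r) / (8.0 * np.pi)
    return np.where(r > 0, out, 0.0)


def _poly_null(x: np.ndarray) -> np.ndarray:
    """Polynomial null-space basis (degree < 2): [1, x] or [1, x, y]."""
    n = x.shape[0]
    return np.column_stack([np.ones(n), x])


class _TPRS:
    """Eigen-truncated thin-plate regression spline in 1 or 2 dimensions.

    The full radial basis at (a deterministic subset of) the unique
    covariate values is truncated to the ``k`` leading eigenvectors of the
    penalty-defining matrix E; the polynomial-orthogonality constraint is
    absorbed so that the wiggliness penalty becomes a small dense matrix on
    the radial part while the polynomial part (minus the intercept) spans
    the penalty null space.
    """

    def __init__(self, x: np.ndarray, k: int, max_knots: int = 200):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] < x.shape[1]:  # accept (n, d) or (d, n)
            x = x.T
        self.d = x.shape[1]
        self.mean = x.mean(axis=0)
        self.scale = x.std(axis=0)
        self.scale[self.scale == 0] = 1.0
        xs = (x - self.mean) / self.scale

        knots = np.unique(xs, axis=0)
        if knots.shape[0] <= k:
            raise ModelError(
                f"basis rank k={k} needs more than k distinct covariate values "
                f"(got {knots.shape[0]}); reduce k"
            )
        if knots.shape[0] > max_knots:
            # deterministic thinning: evenly spaced ranks of the sorted uniques
            order = np.lexsort(knots.T[::-1])
            idx = np.linspace(0, knots.shape[0] - 1, max_knots).round().astype(int)
            knots = knots[order][idx]
        self.knots = knots

        E = _tps_eta(cdist(knots, knots), self.d)
        T = _poly_null(knots)  # (nk, M), M = d + 1
        w, U = eigh(E)
        order = np.argsort(np.abs(w))[::-1][:k]
        Uk, Dk = U[:, order], w[order]
        Z = null_space(T.T @ Uk)  # (k, k - M)
        if Z.shape[1] == 0:
            raise ModelError("degenerate spline basis: constraint removes all columns")
        self.P = Uk @ Z  # maps radial features -> design columns
        S1 = Z.T @ (Uk * Dk).T @ Uk @ Z
        self.S1 = 0.5 * (S1 + S1.T)
        self.n_radial = self.P.shape[1]
        self.n_poly = self.d  # polynomial columns kept (intercept dropped)
        self.ncols = self.n_radial + self.n_poly

    def columns(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.d:
            x = x.T
        xs = (x - self.mean) / self.scale
        Ecols = _tps_eta(cdist(xs, self.knots), self.d) @ self.P
        return np.column_stack([Ecols, xs])


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------


@dataclass
class Penalty:
    """One quadratic penalty acting on a column slice of the design matrix.

    ``S`` is the penalty matrix in term-local coordinates; ``rank`` and
    ``logdet_const`` (sum of log positive eigenvalues) let the REML
    criterion evaluate log|sum_j lambda_j S_j|+ in closed form, because
    penalties are constructed mutually orthogonal within a term and terms
    occupy disjoint columns.
    """

    term: str
    sl: slice
    S: np.ndarray
    rank: int
    logdet_const: float


def _split_penalty(S_full: np.ndarray, term: str, sl: slice, shrinkage: bool) -> list[Penalty]:
    """Split a (possibly rank-deficient) penalty into a clean positive part
    and, when shrinkage is requested, an orthogonal null-space penalty."""
    q = S_full.shape[0]
    w, V = eigh(0.5 * (S_full + S_full.T))
    tol = max(np.max(np.abs(w)), 1.0) * 1e-10
    pos = w > tol
    pens: list[Penalty] = []
    if pos.any():
        Vp, wp = V[:, pos], w[pos]
        # normalize so smoothing parameters are on a comparable scale
        scale = wp.max()
        wp = wp / scale
        S1 = (Vp * wp) @ Vp.T
        pens.append(Penalty(term, sl, S1, int(pos.sum()), float(np.sum(np.log(wp)))))
    if shrinkage and (~pos).any():
        V0 = V[:, ~pos]
        S2 = V0 @ V0.T
        pens.append(Penalty(term, sl, 0.5 * (S2 + S2.T), q - int(pos.sum()), 0.0))
    return pens


# ---------------------------------------------------------------------------
# built terms and design assembly
# ---------------------------------------------------------------------------


@dataclass
class BuiltTerm:
    spec: TermSpec
    label: str
    sl: slice
    means: np.ndarray  # training column means (sum-to-zero centring)
    maker: Callable[[pd.DataFrame], np.ndarray]
    penalized: bool
    support: dict[str, tuple[float, float]] = field(default_factory=dict)
    levels: dict[str, list] = field(default_factory=dict)

    def columns(self, data: pd.DataFrame) -> np.ndarray:
        return self.maker(data) - self.means


def _factor_codes(values: pd.Series, levels: list) -> np.ndarray:
    lut = {lv: i for i, lv in enumerate(levels)}
    unknown = set(values.unique()) - set(levels)
    if unknown:
        raise ModelError(f"unknown factor level(s) {sorted(map(str, unknown))}")
    return values.map(lut).to_numpy()


def _build_term(spec: TermSpec, data: pd.DataFrame, start: int) -> tuple[BuiltTerm, list[Penalty], np.ndarray]:
    """Build one term's training columns, penalties and metadata."""
    if isinstance(spec, Smooth1D):
        x = data[spec.var].to_numpy(dtype=float)
        basis = _TPRS(x[:, None], spec.k)
        raw = basis.columns(x[:, None])
        sl = slice(start, start + raw.shape[1])
        S_full = np.zeros((raw.shape[1], raw.shape[1]))
        S_full[: basis.n_radial, : basis.n_radial] = basis.S1
        pens = _split_penalty(S_full, spec.label, sl, spec.shrinkage)
        bt = BuiltTerm(spec, spec.label, sl, raw.mean(axis=0),
                       lambda d, b=basis, v=spec.var: b.columns(d[v].to_numpy(dtype=float)[:, None]),
                       True, {spec.var: (x.min(), x.max())})
        return bt, pens, raw - raw.mean(axis=0)

    if isinstance(spec, Smooth2D):
        xy = data[[spec.xvar, spec.yvar]].to_numpy(dtype=float)
        basis = _TPRS(xy, spec.k, max_knots=300)
        raw = basis.columns(xy)
        sl = slice(start, start + raw.shape[1])
        S_full = np.zeros((raw.shape[1], raw.shape[1]))
        S_full[: basis.n_radial, : basis.n_radial] = basis.S1
        pens = _split_penalty(S_full, spec.label, sl, spec.shrinkage)
        bt = BuiltTerm(spec, spec.label, sl, raw.mean(axis=0),
                       lambda d, b=basis, u=spec.xvar, v=spec.yvar:
                           b.columns(d[[u, v]].to_numpy(dtype=float)),
                       True,
                       {spec.xvar: (xy[:, 0].min(), xy[:, 0].max()),
                        spec.yvar: (xy[:, 1].min(), xy[:, 1].max())})
        return bt, pens, raw - raw.mean(axis=0)

    if isinstance(spec, FactorSmooth):
        x = data[spec.var].to_numpy(dtype=float)
        levels = sorted(data[spec.by].unique().tolist())
        if len(levels) < 2:
            raise ModelError(f"factor-smooth by={spec.by!r} needs >= 2 levels")
        k = min(spec.k, np.unique(x).size - 1)
        if k < 3:
            raise ModelError(f"too few distinct {spec.var!r} values for a factor smooth")
        basis = _TPRS(x[:, None], k)
        B = basis.columns(x[:, None])
        q = B.shape[1]
        blocks, pens, means = [], [], []
        for j, lv in enumerate(levels):
            ind = (data[spec.by] == lv).to_numpy(dtype=float)
            Xl = B * ind[:, None]
            sub = slice(start + j * q, start + (j + 1) * q)
            S_full = np.zeros((q, q))
            S_full[: basis.n_radial, : basis.n_radial] = basis.S1
            for p in _split_penalty(S_full, f"{spec.label}[{lv}]", sub, True):
                pens.append(p)
            means.append(Xl.mean(axis=0))
            blocks.append(Xl - Xl.mean(axis=0))
        sl = slice(start, start + len(levels) * q)

        def maker(d, b=basis, v=spec.var, by=spec.by, lvs=levels):
            Bn = b.columns(d[v].to_numpy(dtype=float)[:, None])
            _factor_codes(d[by], lvs)  # validate levels
            return np.column_stack([Bn * (d[by] == lv).to_numpy(dtype=float)[:, None] for lv in lvs])

        bt = BuiltTerm(spec, spec.label, sl, np.concatenate(means), maker, True,
                       {spec.var: (x.min(), x.max())}, {spec.by: levels})
        return bt, pens, np.column_stack(blocks)

    if isinstance(spec, RandomEffect):
        levels = sorted(data[spec.var].unique().tolist())
        codes = _factor_codes(data[spec.var], levels)
        raw = np.eye(len(levels))[codes]
        sl = slice(start, start + len(levels))
        pens = [Penalty(spec.label, sl, np.eye(len(levels)), len(levels), 0.0)]

        def maker(d, v=spec.var, lvs=levels):
            return np.eye(len(lvs))[_factor_codes(d[v], lvs)]

        bt = BuiltTerm(spec, spec.label, sl, np.zeros(len(levels)), maker, True,
                       levels={spec.var: levels})
        return bt, pens, raw

    if isinstance(spec, Factor):
        levels = sorted(data[spec.var].unique().tolist())
        if spec.ref is not None and spec.ref in levels:
            levels = [spec.ref] + [l for l in levels if l != spec.ref]
        if len(levels) < 2:
            raise ModelError(f"factor {spec.var!r} has a single level")
        codes = _factor_codes(data[spec.var], levels)
        raw = np.eye(len(levels))[codes][:, 1:]  # drop reference level
        sl = slice(start, start + raw.shape[1])

        def maker(d, v=spec.var, lvs=levels):
            return np.eye(len(lvs))[_factor_codes(d[v], lvs)][:, 1:]

        bt = BuiltTerm(spec, spec.label, sl, np.zeros(raw.shape[1]), maker, False,
                       levels={spec.var: levels})
        return bt, [], raw

    if isinstance(spec, Linear):
        x = data[spec.var].to_numpy(dtype=float)
        raw = x[:, None]
        sl = slice(start, start + 1)
        bt = BuiltTerm(spec, spec.label, sl, np.zeros(1),
                       lambda d, v=spec.var: d[v].to_numpy(dtype=float)[:, None],
                       False, {spec.var: (x.min(), x.max())})
        return bt, [], raw

    raise ModelError(f"unknown term specification {spec!r}")


def build_design(terms: Sequence[TermSpec], data: pd.DataFrame):
    """Assemble the full design matrix (intercept first) and penalty list."""
    n = len(data)
    cols = [np.ones((n, 1))]
    built: list[BuiltTerm] = []
    pens: list[Penalty] = []
    start = 1
    for spec in terms:
        bt, tp, X_t = _build_term(spec, data, start)
        built.append(bt)
        pens.extend(tp)
        cols.append(X_t)
        start += X_t.shape[1]
    return np.column_stack(cols), built, pens


def design_matrix(built: Sequence[BuiltTerm], data: pd.DataFrame) -> np.ndarray:
    n = len(data)
    cols = [np.ones((n, 1))]
    for bt in built:
        cols.append(bt.columns(data))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# negative binomial family
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Exact NB2 log-likelihood, Var(y) = mu + mu^2/theta."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or theta <= 0:
        raise ValueError("nb_loglik requires mu > 0 and theta > 0")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("nb_loglik requires non-negative integer y")
    if not np.isfinite(theta):
        return float(np.sum(xlogy(y, mu) - mu - gammaln(y + 1)))
    # log1p forms avoid cancellation when theta >> mu (the Poisson limit)
    return float(np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        - theta * np.log1p(mu / theta) + y * np.log(mu / (theta + mu))
    ))


def nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    if not np.isfinite(theta):  # Poisson limit
        return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))
    # log1p form avoids cancellation when theta >> y, mu
    return float(2.0 * np.sum(
        xlogy(y, y / mu) - (y + theta) * np.log1p((y - mu) / (mu + theta))
    ))


def _golden_min(f: Callable[[float], float], a: float, b: float,
                tol: float = 1e-4, maxit: int = 80) -> float:
    """Plain golden-section minimizer on [a, b]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(maxit):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _assemble_S(pens: Sequence[Penalty], rho: np.ndarray, p: int) -> np.ndarray:
    S = np.zeros((p, p))
    for pen, r in zip(pens, rho):
        S[pen.sl, pen.sl] += np.exp(r) * pen.S
    return S


def _logdet_S(pens: Sequence[Penalty], rho: np.ndarray) -> float:
    return float(sum(pen.rank * r + pen.logdet_const for pen, r in zip(pens, rho)))


def _chol_solve(A: np.ndarray, b: np.ndarray):
    """Cholesky solve with escalating ridge fallback; returns (x, logdet)."""
    p = A.shape[0]
    base = np.trace(A) / p
    for eps in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            cf = cho_factor(A + eps * base * np.eye(p), lower=True)
            x = cho_solve(cf, b)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return x, logdet, cf
        except np.linalg.LinAlgError:
            continue
    raise ModelError("design + penalty matrix is numerically singular")


def _pirls(X, y, offset, pens, rho, theta, beta=None, tol=1e-10, maxit=200):
    """Penalized IRLS for fixed smoothing parameters and theta."""
    n, p = X.shape
    S = _assemble_S(pens, rho, p)
    if beta is None:
        mu = (y + np.mean(y)) / 2.0 + 1e-3
        eta = np.log(mu)
    else:
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
    dev = nb_deviance(y, mu, theta)
    pen_dev = dev + (0.0 if beta is None else float(beta @ S @ beta))
    for it in range(maxit):
        w = mu / (1.0 + mu / theta) if np.isfinite(theta) else mu
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + S
        beta_new, _, _ = _chol_solve(A, XtW @ z)
        # step halving on the penalized deviance
        step = 1.0
        for _ in range(30):
            b_try = beta_new if beta is None else beta + step * (beta_new - beta)
            eta_try = np.clip(X @ b_try + offset, -30, 30)
            mu_try = np.exp(eta_try)
            pd_try = nb_deviance(y, mu_try, theta) + float(b_try @ S @ b_try)
            if np.isfinite(pd_try) and (beta is None
                                        or pd_try <= pen_dev + 1e-11 * (abs(pen_dev) + 1.0)):
                break
            step *= 0.5
        bchange = np.inf if beta is None else float(np.max(np.abs(b_try - beta)))
        beta, eta, mu = b_try, eta_try, mu_try
        change = abs(pen_dev - pd_try) / (abs(pd_try) + 0.1)
        pen_dev = pd_try
        if change < tol and bchange < 1e-8 * (1.0 + np.max(np.abs(beta))) and it > 0:
            break
    else:
        warnings.warn("penalized IRLS reached the iteration cap", RuntimeWarning)
    return beta, mu, eta


def _criterion(rho, XtWX, XtWz, ztWz, pens, gamma, p):
    """Working-model REML smoothness-selection criterion."""
    S = _assemble_S(pens, rho, p)
    A = XtWX / gamma + S
    try:
        beta, logdetA, cf = _chol_solve(A, XtWz / gamma)
    except ModelError:
        return 1e12
    Dw = ztWz / gamma - 2.0 * beta @ XtWz / gamma + beta @ (XtWX / gamma) @ beta
    pen = float(beta @ S @ beta)
    return 0.5 * (Dw + pen) + 0.5 * logdetA - 0.5 * _logdet_S(pens, rho)


def _criterion_gcv(rho, XtWX, XtWz, ztWz, pens, gamma, p, n):
    S = _assemble_S(pens, rho, p)
    A = XtWX + S
    try:
        beta, _, cf = _chol_solve(A, XtWz)
    except ModelError:
        return 1e12
    Dw = ztWz - 2.0 * beta @ XtWz + beta @ XtWX @ beta
    edf = float(np.trace(cho_solve(cf, XtWX)))
    denom = max(n - gamma * edf, 1.0)
    return n * Dw / denom**2


@dataclass
class FittedDSM:
    """A fitted density surface model."""

    terms: list[BuiltTerm]
    beta: np.ndarray
    Vb: np.ndarray              # Bayesian posterior covariance of beta
    theta: float
    rho: np.ndarray             # log smoothing parameters
    penalties: list[Penalty]
    edf: dict[str, float]
    edf_total: float
    loglik: float
    aic: float
    deviance: float
    null_deviance: float
    deviance_explained: float
    term_table: pd.DataFrame
    converged: bool
    n_obs: int
    gamma: float
    fitted: np.ndarray
    offset_name: str | None = None

    # ------------------------------------------------------------------
    def linear_predictor(self, newdata: pd.DataFrame, offset) -> np.ndarray:
        X = design_matrix(self.terms, newdata)
        return X @ self.beta + np.asarray(offset, dtype=float)

    def predict(self, newdata: pd.DataFrame, offset, se: bool = False,
                allow_extrapolation: bool = False):
        """Expected counts (and link-scale SEs) for new rows.

        ``offset`` is the value added to the linear predictor, i.e. the log
        of the area the prediction refers to.
        """
        for bt in self.terms:
            for var, (lo, hi) in bt.support.items():
                v = newdata[var].to_numpy(dtype=float)
                span = max(hi - lo, 1e-12)
                if v.min() < lo - 1e-9 * span or v.max() > hi + 1e-9 * span:
                    if not allow_extrapolation:
                        raise ModelError(
                            f"prediction covariate {var!r} outside the training "
                            f"support [{lo:.6g}, {hi:.6g}]; pass "
                            "allow_extrapolation=True to override"
                        )
        X = design_matrix(self.terms, newdata)
        offset = np.broadcast_to(np.asarray(offset, dtype=float), (len(newdata),))
        eta = X @ self.beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        if not se:
            return mu
        se_link = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.Vb, X), 0.0))
        return mu, se_link

    def term_effect(self, label: str, newdata: pd.DataFrame) -> np.ndarray:
        """Centred partial effect of one term on the link scale."""
        for bt in self.terms:
            if bt.label == label:
                return bt.columns(newdata) @ self.beta[bt.sl]
        raise KeyError(label)


def fit_nbgam(
    data: pd.DataFrame,
    terms: Sequence[TermSpec],
    y: str | np.ndarray,
    offset: str | np.ndarray | float = 0.0,
    family: str = "nb",
    theta: float | None = None,
    gamma: float = 1.2,
    method: str = "reml",
    max_outer: int = 8,
    rho_init: np.ndarray | None = None,
    optimizer_maxiter: int = 100,
    rho_tol: float = 0.02,
    fix_smoothing: bool = False,
    theta_init: float = 1.0,
) -> FittedDSM:
    """Fit the negative-binomial additive model.

    Parameters
    ----------
    offset
        Linear-predictor offset (log surveyed area), a column name, array
        or scalar.  Rows must have strictly positive effort for the offset
        to be finite.
    theta
        NB size parameter.  ``None`` (default) profiles it out by
        golden-section search; a float fixes it; ``family="poisson"``
        drops it entirely.
    gamma
        Complexity-inflation factor of the smoothness selection criterion
        (1.2 favours simpler curves than plain REML/GCV).
    """
    yv = data[y].to_numpy(dtype=float) if isinstance(y, str) else np.asarray(y, dtype=float)
    if np.any(yv < 0):
        raise ModelError("negative counts")
    if isinstance(offset, str):
        off = data[offset].to_numpy(dtype=float)
        off_name = offset
    else:
        off = np.broadcast_to(np.asarray(offset, dtype=float), yv.shape).copy()
        off_name = None
    if not np.all(np.isfinite(off)):
        raise ModelError("non-finite offset (zero effort area?)")

    X, built, pens = build_design(terms, data)
    n, p = X.shape
    for c in range(p):
        if not np.all(np.isfinite(X[:, c])):
            raise ModelError("non-finite covariate values in the design matrix")

    if family == "poisson":
        th = np.inf
        estimate_theta = False
    elif theta is not None:
        th = float(theta)
        estimate_theta = False
    else:
        th = float(theta_init)
        estimate_theta = True

    m = len(pens)
    rho = np.zeros(m) if rho_init is None else np.array(rho_init, dtype=float)
    beta = None
    converged = False
    for outer in range(max_outer):
        beta, mu, eta = _pirls(X, yv, off, pens, rho, th, beta)
        th_new = th
        if estimate_theta:
            lt = _golden_min(lambda t: -nb_loglik(yv, mu, np.exp(t)), np.log(0.02), np.log(5e7))
            th_new = float(np.exp(lt))
        if m == 0 or fix_smoothing:
            if not estimate_theta or abs(np.log(th_new) - np.log(th)) < 1e-3:
                th = th_new
                converged = True
                break
            th = th_new
            continue
        w = mu / (1.0 + mu / th_new) if np.isfinite(th_new) else mu
        z = (eta - off) + (yv - mu) / mu
        XtW = X.T * w
        XtWX = XtW @ X
        XtWz = XtW @ z
        ztWz = float(w @ z**2)
        if method == "gcv":
            fun = lambda r: _criterion_gcv(r, XtWX, XtWz, ztWz, pens, gamma, p, n)
        else:
            fun = lambda r: _criterion(r, XtWX, XtWz, ztWz, pens, gamma, p)
        res = optimize.minimize(
            fun, rho, method="L-BFGS-B", bounds=[(-15.0, 15.0)] * m,
            options={"maxiter": optimizer_maxiter, "ftol": 1e-10},
        )
        rho_new = res.x
        moved = np.max(np.abs(rho_new - rho)) if m else 0.0
        th_moved = abs(np.log(th_new) - np.log(th)) if estimate_theta else 0.0
        rho, th = rho_new, th_new
        if moved < rho_tol and th_moved < 1e-2 and outer > 0:
            converged = True
            break
    beta, mu, eta = _pirls(X, yv, off, pens, rho, th, beta)

    # final inference quantities (gamma does not enter the posterior)
    w = mu / (1.0 + mu / th) if np.isfinite(th) else mu
    XtWX = (X.T * w) @ X
    S = _assemble_S(pens, rho, p)
    _, _, cf = _chol_solve(XtWX + S, np.zeros(p))
    Vb = cho_solve(cf, np.eye(p))
    F = Vb @ XtWX
    edf_diag = np.diag(F)
    edf = {"(intercept)": float(edf_diag[0])}
    for bt in built:
        edf[bt.label] = float(np.sum(edf_diag[bt.sl]))
    edf_total = float(np.sum(edf_diag))

    ll = nb_loglik(yv, mu, th)
    dev = nb_deviance(yv, mu, th)
    null_dev = _null_deviance(yv, off, th)
    dev_expl = 1.0 - dev / null_dev if null_dev > 0 else 0.0

    rows = []
    for bt in built:
        b_t = beta[bt.sl]
        V_t = Vb[bt.sl, bt.sl]
        r = max(1, int(round(edf[bt.label]))) if bt.penalized else (bt.sl.stop - bt.sl.start)
        Vinv = np.linalg.pinv(V_t, rcond=1e-10)
        stat = float(b_t @ Vinv @ b_t)
        # test df floored at 1: a shrunk term must not look significant
        # just because a chi-square with near-zero df piles mass at 0
        df = max(edf[bt.label], 1.0) if bt.penalized else float(r)
        rows.append({"term": bt.label, "edf": edf[bt.label],
                     "chi_sq": stat, "p_value": float(chi2.sf(stat, df))})
    term_table = pd.DataFrame(rows)

    return FittedDSM(
        terms=built, beta=beta, Vb=Vb, theta=th, rho=rho, penalties=pens,
        edf=edf, edf_total=edf_total, loglik=ll,
        aic=-2.0 * ll + 2.0 * edf_total, deviance=dev, null_deviance=null_dev,
        deviance_explained=dev_expl, term_table=term_table, converged=converged,
        n_obs=n, gamma=gamma, fitted=mu, offset_name=off_name,
    )


def refit_nbgam(base: FittedDSM, data: pd.DataFrame,
                y: str | np.ndarray = "count",
                offset: str | np.ndarray | float = 0.0,
                reestimate_smoothing: bool = True,
                optimizer_maxiter: int = 15, max_outer: int = 1) -> FittedDSM:
    """Refit a fitted model's structure to new rows (bootstrap/validation).

    The spline bases, centring constraints and penalty structure are part
    of the model and are reused as-is; coefficients are re-estimated, the
    smoothing parameters are re-optimised from the base fit's values
    (unless ``reestimate_smoothing`` is False) and theta is held at the
    base fit's estimate.  Inference extras (p-values, null deviance) are
    not recomputed — the result carries what prediction needs.
    """
    yv = data[y].to_numpy(dtype=float) if isinstance(y, str) else np.asarray(y, dtype=float)
    off = (data[offset].to_numpy(dtype=float) if isinstance(offset, str)
           else np.broadcast_to(np.asarray(offset, dtype=float), yv.shape).copy())
    X = design_matrix(base.terms, data)
    pens = base.penalties
    rho = base.rho.copy()
    th = base.theta
    beta = base.beta.copy()
    if reestimate_smoothing and len(pens):
        beta, mu, eta = _pirls(X, yv, off, pens, rho, th, beta)
        w = mu / (1.0 + mu / th) if np.isfinite(th) else mu
        z = (eta - off) + (yv - mu) / mu
        XtW = X.T * w
        XtWX, XtWz, ztWz = XtW @ X, XtW @ z, float(w @ z**2)
        for _ in range(max(max_outer - 1, 0) + 1):
            res = optimize.minimize(
                lambda r: _criterion(r, XtWX, XtWz, ztWz, pens, base.gamma,
                                     X.shape[1]),
                rho, method="L-BFGS-B", bounds=[(-15.0, 15.0)] * len(pens),
                options={"maxiter": optimizer_maxiter, "ftol": 1e-9})
            rho = res.x
            break
    beta, mu, eta = _pirls(X, yv, off, pens, rho, th, beta)
    fit = FittedDSM(
        terms=base.terms, beta=beta, Vb=base.Vb, theta=th, rho=rho,
        penalties=pens, edf={}, edf_total=float("nan"),
        loglik=nb_loglik(yv, mu, th), aic=float("nan"),
        deviance=nb_deviance(yv, mu, th), null_deviance=float("nan"),
        deviance_explained=float("nan"), term_table=pd.DataFrame(),
        converged=True, n_obs=X.shape[0], gamma=base.gamma, fitted=mu)
    return fit


def _null_deviance(y: np.ndarray, off: np.ndarray, theta: float) -> float:
    """Deviance of the intercept-only model with the same offset and theta."""
    X0 = np.ones((y.size, 1))
    beta, mu, _ = _pirls(X0, y, off, [], np.zeros(0), theta, None)
    return nb_deviance(y, mu, theta)
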