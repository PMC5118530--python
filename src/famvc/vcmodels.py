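"""Maximum-likelihood variance-components engine.

Fits the multivariate-normal model

    y ~ N(X beta, sigma^2 * V),   V = sum_c f_c * K_c + (1 - sum_c f_c) * I

where the ``K_c`` are PSD relationship matrices (e.g. 2*Phi, 2*E) and the
variance fractions ``f_c`` live on the simplex. ``beta`` and ``sigma^2`` are
profiled out analytically, so the optimization is over the fractions only:

* one random component: a 1-D profile over the genetic fraction using a
  single eigendecomposition of K (cached across fits against the same K);
* two random components: a profile over the mixing weight ``w`` between the
  components, where ``(1-w) K_1 + w K_2`` is eigendecomposed per candidate
  weight (cached, so repeated fits against the same pair of matrices reuse
  the whole grid).

Boundary solutions (fraction 0 or 1) are legitimate fit results, not errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular
from scipy.stats import chi2

from ._cache import array_key, eigh_cached
from .errors import DomainError, EstimationError, ModelError

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_W_GRID_DEFAULT = 51
_H_GRID_DEFAULT = 41


@dataclass
class VarianceModel:
    """Response, fixed-effect design and random-effect structure of one fit.

    ``components`` holds the n x n PSD matrices multiplying each variance
    fraction (on the 2x-kinship scale); the residual identity component is
    implicit. All arrays must share one complete-case row index.
    """

    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    components: list[np.ndarray] = field(repr=False)
    names: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ModelError("design and response sizes differ")
        for K in self.components:
            if K.shape != (n, n):
                raise ModelError("component dimension does not match response")
        if not np.isfinite(self.y).all() or not np.isfinite(self.X).all():
            raise ModelError("response/design contain non-finite values")
        if self.y.std() <= 0:
            raise ModelError("response has zero variance")
        if n <= self.X.shape[1] + len(self.components):
            raise ModelError("too few observations for the requested model")


@dataclass
class VCFit:
    """Result of a maximum-likelihood variance-components fit."""

    fractions: tuple[float, ...]  # one per random component
    e2: float
    sigma2: float
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    names: tuple[str, ...] = ()
    fraction_se: tuple[float, ...] | None = None
    boundary: bool = False

    @property
    def h2(self) -> float:
        """Total genetic fraction (sum over random components)."""
        return float(sum(self.fractions))


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


# --------------------------------------------------------------------------
# profiled Gaussian likelihood in an eigenbasis
# --------------------------------------------------------------------------


def _profile_ll(h: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Log-likelihood at genetic fraction ``h`` with beta, sigma^2 profiled.

    ``d`` are eigenvalues of the (possibly mixed) genetic component; ``yt``
    and ``Xt`` are the response/design rotated into its eigenbasis.
    Returns (loglik, beta, sigma2, XtWX) or (-inf, None, None, None) when the
    implied covariance is singular.
    """
    n = yt.shape[0]
    v = h * d + (1.0 - h)
    if v.min() <= 1e-12:
        return -np.inf, None, None, None
    w = 1.0 / v
    Xw = Xt * w[:, None]
    G = Xt.T @ Xw
    b = Xt.T @ (w * yt)
    try:
        beta = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(G, b, rcond=None)[0]
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    if rss <= 0:
        return -np.inf, None, None, None
    sigma2 = rss / n
    ll = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + float(np.sum(np.log(v))) + n)
    return ll, beta, sigma2, G


def _optimize_h(d, yt, Xt, grid_size=_H_GRID_DEFAULT, coarse_only=False):
    """Grid-then-Brent maximization of the 1-D profile likelihood over [0, 1]."""
    hs = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([_profile_ll(h, d, yt, Xt)[0] for h in hs])
    i = int(np.argmax(lls))
    if coarse_only:
        return float(hs[i]), float(lls[i])
    lo = hs[max(i - 1, 0)]
    hi = hs[min(i + 1, grid_size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: -_profile_ll(h, d, yt, Xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if np.isfinite(res.fun) and -res.fun > lls[i]:
            return float(res.x), float(-res.fun)
    return float(hs[i]), float(lls[i])


def _finalize(h, d, U, y, X, names, fractions, n, converged=True):
    yt = U.T @ y
    Xt = U.T @ X
    ll, beta, sigma2, G = _profile_ll(h, d, yt, Xt)
    if beta is None:
        raise EstimationError("degenerate likelihood at the optimum")
    try:
        cov_beta = sigma2 * np.linalg.inv(G)
    except np.linalg.LinAlgError:
        # rank-deficient design: SEs from the pseudo-inverse (flagged by
        # the caller where it matters)
        cov_beta = sigma2 * np.linalg.pinv(G)
    beta_se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    boundary = any(f <= 1e-9 or f >= 1 - 1e-9 for f in fractions) or h >= 1 - 1e-9
    return VCFit(
        fractions=tuple(float(f) for f in fractions),
        e2=float(1.0 - sum(fractions)),
        sigma2=float(sigma2),
        beta=beta,
        beta_se=beta_se,
        loglik=float(ll),
        converged=converged,
        n_used=n,
        names=tuple(names),
        boundary=boundary,
    )


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


def fit_ml(
    model: VarianceModel,
    *,
    se_fractions: bool = False,
    w_grid: int = _W_GRID_DEFAULT,
    refine_w: bool = True,
) -> VCFit:
    """Maximize the Gaussian likelihood over the variance-fraction simplex.

    ``w_grid`` and ``refine_w`` control the two-component mixing-weight
    search: a fixed grid (whose eigendecompositions are cached per component
    pair) optionally followed by a local bounded refinement. Mass
    simulations can pass ``refine_w=False`` for speed at a negligible
    likelihood cost.
    """
    y, X = model.y, model.X
    n = y.shape[0]
    names = model.names or [f"K{i+1}" for i in range(len(model.components))]

    if len(model.components) == 0:
        d = np.zeros(n)
        U = np.eye(n)
        return _finalize(0.0, d, U, y, X, names, (), n)

    if len(model.components) == 1:
        K = model.components[0]
        d, U = eigh_cached(K)
        if d[0] < -1e-8 * max(1.0, abs(d[-1])):
            raise ModelError("random component is not positive semi-definite")
        yt, Xt = U.T @ y, U.T @ X
        h, _ = _optimize_h(d, yt, Xt)
        fit = _finalize(h, d, U, y, X, names, (h,), n)
        if se_fractions:
            fit.fraction_se = _fraction_se(model, fit.fractions)
        return fit

    if len(model.components) == 2:
        fit = _fit_two(model, names, w_grid=w_grid, refine_w=refine_w)
        if se_fractions:
            fit.fraction_se = _fraction_se(model, fit.fractions)
        return fit

    raise ModelError("at most two random components are supported")


def _fit_two(model: VarianceModel, names, *, w_grid: int, refine_w: bool) -> VCFit:
    y, X = model.y, model.X
    n = y.shape[0]
    K1, K2 = model.components
    key1, key2 = array_key(K1), array_key(K2)

    def decompose(w: float):
        key = ("mix", key1, key2, round(float(w), 12))
        return eigh_cached(lambda: (1.0 - w) * K1 + w * K2, key=key)

    # scan the mixing weight with a coarse inner grid, then polish at the
    # winning weight; the w grid itself bounds the weight resolution anyway
    best = (-np.inf, 0.0, 0.0)  # ll, w, h
    ws = np.linspace(0.0, 1.0, w_grid)
    for w in ws:
        d, U = decompose(w)
        h, ll = _optimize_h(d, U.T @ y, U.T @ X, grid_size=17, coarse_only=True)
        if ll > best[0]:
            best = (ll, float(w), h)

    _, w_best, _ = best
    d, U = decompose(w_best)
    h_best, ll_best = _optimize_h(d, U.T @ y, U.T @ X)
    if refine_w and 0.0 < w_best < 1.0 and h_best > 1e-9:
        step = 1.0 / (w_grid - 1)

        def neg(w):
            d, U = decompose(w)
            _, ll = _optimize_h(d, U.T @ y, U.T @ X)
            return -ll

        res = optimize.minimize_scalar(
            neg,
            bounds=(max(0.0, w_best - step), min(1.0, w_best + step)),
            method="bounded",
            options={"xatol": 1e-4, "maxiter": 12},
        )
        if np.isfinite(res.fun) and -res.fun > ll_best:
            w_best = float(res.x)
            d, U = decompose(w_best)
            h_best, ll_best = _optimize_h(d, U.T @ y, U.T @ X)

    d, U = decompose(w_best)
    f1 = (1.0 - w_best) * h_best
    f2 = w_best * h_best
    return _finalize(h_best, d, U, y, X, names, (f1, f2), n)


def profile_loglik(model: VarianceModel, fractions) -> float:
    """Log-likelihood at fixed variance fractions (beta, sigma^2 profiled).

    Direct dense evaluation via Cholesky; independent of the eigenbasis fast
    path used by :func:`fit_ml`, which makes it a convenient cross-check.
    """
    fractions = [float(f) for f in np.atleast_1d(fractions)]
    if len(fractions) != len(model.components):
        raise ModelError("one fraction per random component required")
    if any(f < 0 for f in fractions) or sum(fractions) > 1.0 + 1e-12:
        raise DomainError("fractions must be non-negative and sum to <= 1")
    y, X = model.y, model.X
    n = y.shape[0]
    V = (1.0 - sum(fractions)) * np.eye(n)
    for f, K in zip(fractions, model.components):
        V = V + f * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    ys = solve_triangular(L, y, lower=True)
    Xs = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ beta
    rss = float(r @ r)
    if rss <= 0:
        return -np.inf
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)


def _fraction_se(model: VarianceModel, fractions) -> tuple[float, ...]:
    """SEs of the variance fractions from the numerically observed information.

    Uses central differences where the estimate is interior and one-sided
    differences at a boundary (the latter is flagged by ``VCFit.boundary``).
    Returns NaN where the curvature is not negative definite.
    """
    theta = np.array(fractions, dtype=float)
    k = len(theta)
    eps = 1e-4

    def f(t):
        t = np.clip(t, 0.0, None)
        if t.sum() > 1.0 - 1e-9:
            t = t * (1.0 - 1e-9) / t.sum()
        return profile_loglik(model, t)

    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            si = 1.0 if theta[i] + 2 * eps <= 1.0 else -1.0
            sj = 1.0 if theta[j] + 2 * eps <= 1.0 else -1.0
            if i == j:
                H[i, i] = (f(theta + 2 * si * ei) - 2 * f(theta + si * ei) + f0) / eps**2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + si * ei + sj * ej)
                    - f(theta + si * ei)
                    - f(theta + sj * ej)
                    + f0
                ) / (si * sj * eps**2)
    try:
        cov = np.linalg.inv(-H)
        se = tuple(
            float(np.sqrt(c)) if c > 0 else float("nan") for c in np.diag(cov)
        )
    except np.linalg.LinAlgError:
        se = tuple(float("nan") for _ in range(k))
    return se


def lrt(fit_full: VCFit, fit_null: VCFit, df: int = 1) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*(l_full - l_null) vs chi2_df."""
    if df < 1:
        raise DomainError("df must be >= 1")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-5:
        raise EstimationError(
            f"full model log-likelihood below null by {-stat/2:.3g}; "
            "nesting violated or fit did not converge"
        )
    stat = max(stat, 0.0)
    return LRTResult(stat=stat, df=df, p=float(chi2.sf(stat, df)))


def mixture_p(lrt_stat: float) -> float:
    """p-value under the 1/2:1/2 mixture of chi2_1 and a point mass at zero.

    The point mass carries the event at the boundary: a statistic of exactly
    zero returns p = 1.
    """
    if lrt_stat < 0:
        raise DomainError("likelihood-ratio statistic must be non-negative")
    if lrt_stat == 0:
        return 1.0
    return float(0.5 * chi2.sf(lrt_stat, 1))
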