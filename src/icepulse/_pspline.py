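"""Penalized cubic-spline smooth with a Gaussian random intercept per group.

This is the mixed-model representation of a penalized regression spline: a
B-spline basis with a second-order difference penalty is split into its
penalty null space (constant + linear trend, kept as fixed effects) and range
space (treated as i.i.d. Gaussian random coefficients), so the smoothing
parameter is a variance ratio estimated by marginal ML or REML together with
the group (individual) random-intercept variance.  The whole model is

    y = X beta + Z_s b + Z_g u + e,
    b ~ N(0, sigma_s^2 I),  u ~ N(0, sigma_g^2 I),  e ~ N(0, sigma^2 I),

with X spanning the unpenalized polynomial part of the smooth.  Only two
variance ratios are optimized (Nelder-Mead on the profiled likelihood); the
random-effect dimension is small, so everything is dense linear algebra via
the Woodbury identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize


def bspline_design(x: np.ndarray, lo: float, hi: float, n_basis: int,
                   order: int = 4) -> np.ndarray:
    """Clamped uniform B-spline design matrix (order 4 = cubic)."""
    degree = order - 1
    if n_basis < order:
        raise ValueError("n_basis must be >= spline order")
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    xc = np.clip(np.asarray(x, float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _penalty_split(n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-split of the 2nd-difference penalty into null and range spaces.

    Returns (U0, U1s): U0 spans the 2-dim null space; U1s = U+ diag(1/sqrt(lam))
    maps i.i.d. random coefficients onto the penalized directions.
    """
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    S = D.T @ D
    lam, U = np.linalg.eigh(S)
    null = lam < 1e-10 * lam.max()
    U0 = U[:, null]
    U1 = U[:, ~null]
    return U0, U1 / np.sqrt(lam[~null])


@dataclass
class PSplineFit:
    x_range: tuple[float, float]
    n_basis: int
    order: int
    beta: np.ndarray            # fixed coefficients (penalty null space)
    b_spline: np.ndarray        # penalized spline coefficients (BLUPs)
    group_effects: dict         # group -> predicted random intercept
    sigma2: float               # residual variance
    gamma_s: float              # spline variance ratio sigma_s^2 / sigma^2
    gamma_g: float              # group variance ratio sigma_g^2 / sigma^2
    loglik: float               # maximized marginal log-likelihood (ML or REML)
    aic: float
    edf: float                  # effective degrees of freedom of the smooth
    method: str
    cov: np.ndarray             # posterior covariance of (beta, b_spline)
    _U0: np.ndarray = None
    _U1s: np.ndarray = None

    def predict(self, x: np.ndarray, se: bool = False):
        """Population-level fitted curve (random intercepts at zero)."""
        B = bspline_design(x, *self.x_range, self.n_basis, self.order)
        C = np.hstack([B @ self._U0, B @ self._U1s])
        fit = C @ np.concatenate([self.beta, self.b_spline])
        if not se:
            return fit
        var = np.einsum("ij,jk,ik->i", C, self.cov, C)
        return fit, np.sqrt(np.maximum(var, 0.0))


def fit_pspline_mixed(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_basis: int = 10,
    order: int = 4,
    method: str = "ml",
) -> PSplineFit:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    n = len(y)
    if len(x) != n or len(groups) != n:
        raise ValueError("x, y, groups must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("covariate has no variation (rank-deficient design)")
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")

    lo, hi = float(x.min()), float(x.max())
    # a basis larger than the number of distinct covariate values is singular
    n_basis = max(order, min(n_basis, len(np.unique(x))))
    B = bspline_design(x, lo, hi, n_basis, order)
    U0, U1s = _penalty_split(n_basis)
    X = B @ U0
    Zs = B @ U1s
    glabels, gidx = np.unique(groups, return_inverse=True)
    Zg = np.zeros((n, len(glabels)))
    Zg[np.arange(n), gidx] = 1.0
    Z = np.hstack([Zs, Zg])
    qs, qg = Zs.shape[1], Zg.shape[1]
    p = X.shape[1]

    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y

    def profile(theta):
        """Profiled -2 log-likelihood at log variance ratios theta."""
        gs, gg = np.exp(theta)
        g = np.concatenate([np.full(qs, gs), np.full(qg, gg)])
        # Woodbury: V0^-1 = I - Z A^-1 Z^T with A = G^-1 + Z^T Z
        A = ZtZ + np.diag(1.0 / g)
        cho = np.linalg.cholesky(A)

        def vinv_quad(Mt_a, Mt_b, ab):
            # a^T V0^-1 b given Z^T a, Z^T b and a^T b
            wa = np.linalg.solve(cho, Mt_a)
            wb = np.linalg.solve(cho, Mt_b)
            return ab - wa.T @ wb

        XtVX = vinv_quad(ZtX, ZtX, XtX)
        XtVy = vinv_quad(ZtX, Zty, Xty)
        ytVy = vinv_quad(Zty, Zty, yty)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = float(ytVy - XtVy @ beta)
        rss = max(rss, 1e-12)
        # log|V0| = log|A| + log|G|
        logdetV = 2 * np.log(np.diag(cho)).sum() + np.log(g).sum()
        if method == "ml":
            s2 = rss / n
            nll2 = n * np.log(2 * np.pi * s2) + logdetV + n
        else:
            s2 = rss / (n - p)
            sign, logdetX = np.linalg.slogdet(XtVX)
            nll2 = (n - p) * np.log(2 * np.pi * s2) + logdetV + logdetX + (n - p)
        return nll2, beta, s2

    res = minimize(lambda t: profile(t)[0], x0=np.zeros(2),
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    nll2, beta, s2 = profile(res.x)
    gs, gg = np.exp(res.x)

    # BLUPs and posterior covariance via the penalized normal equations
    g = np.concatenate([np.full(qs, gs), np.full(qg, gg)])
    C = np.hstack([X, Z])
    pen = np.concatenate([np.zeros(p), 1.0 / g])
    M = C.T @ C + np.diag(pen)
    Minv = np.linalg.inv(M)
    coef = Minv @ (C.T @ y)
    beta_hat = coef[:p]
    b_spline = coef[p:p + qs]
    u = coef[p + qs:]
    cov_full = s2 * Minv
    keep = np.arange(p + qs)
    cov = cov_full[np.ix_(keep, keep)]

    edf = float(np.trace(Minv @ (C.T @ C)))
    # parameters counted for AIC: fixed effects + 3 variance components
    aic = nll2 + 2 * (p + 3)

    return PSplineFit(
        x_range=(lo, hi), n_basis=n_basis, order=order,
        beta=beta_hat, b_spline=b_spline,
        group_effects=dict(zip(glabels.tolist(), u.tolist())),
        sigma2=s2, gamma_s=gs, gamma_g=gg,
        loglik=-0.5 * nll2, aic=aic, edf=edf, method=method,
        cov=cov, _U0=U0, _U1s=U1s,
    )
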