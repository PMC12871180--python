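"""Geographically weighted regression and global baselines.

GWR fits the spatially varying linear model

    y_i = beta0(u_i, v_i) + sum_k beta_k(u_i, v_i) x_ik + eps_i

by solving, at each observation location, the kernel-weighted least-squares
problem

    beta_hat(u, v) = (X' W(u, v) X)^{-1} X' W(u, v) y,

where W(u, v) is diagonal with entries from a Gaussian or bisquare kernel
of the Euclidean distance to (u, v), scaled by a bandwidth b. Model
complexity is summarised by the hat-matrix trace tr(S) (effective number
of parameters), and bandwidth is chosen by minimising the small-sample
corrected AICc. Global OLS and ridge fits use the same AICc convention
(tr(S) = p for OLS) so information criteria are comparable across models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .errors import DegenerateInputError, LocalSingularityError, ValidationError

_GOLDEN = (math.sqrt(5) - 1) / 2
_RANK_TOL = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus bandwidth b (pixels) governing W(u, v)."""

    family: str = "gaussian"
    bandwidth: float = 100.0

    def __post_init__(self):
        if self.family not in ("gaussian", "bisquare"):
            raise ValidationError("kernel family must be 'gaussian' or 'bisquare'")
        if not self.bandwidth > 0:
            raise ValidationError("bandwidth must be > 0")


@dataclass
class ObservationTable:
    """Response, design matrix (intercept first column) and coordinates."""

    y: np.ndarray
    X: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.X.shape
        if self.y.size != n or self.coords.shape != (n, 2):
            raise ValidationError("inconsistent y/X/coords shapes")
        if n <= p:
            raise ValidationError("need n > p observations")
        if not (
            np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.X))
            and np.all(np.isfinite(self.coords))
        ):
            raise ValidationError("NaN or infinite entries in observation table")

    @classmethod
    def from_arrays(cls, y, predictors, coords) -> "ObservationTable":
        """Build a table with an intercept column prepended to predictors."""
        P = np.asarray(predictors, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        X = np.column_stack([np.ones(len(P)), P])
        return cls(y=y, X=X, coords=coords)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class GwrFit:
    betas: np.ndarray  # n x p, beta_hat at each observation location
    fitted: np.ndarray
    residuals: np.ndarray
    hat_trace: float
    sigma2_hat: float
    aicc: float
    local_r2: np.ndarray
    kernel: KernelSpec


@dataclass
class GlobalFit:
    betas: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    aicc: float
    model: str
    hat_trace: float


@dataclass
class BandwidthResult:
    bandwidth: float
    aicc: float
    at_boundary: bool
    bounds: tuple[float, float]


def kernel_weight(d, spec: KernelSpec) -> np.ndarray:
    """Kernel weight(s) in [0, 1] for distance(s) d.

    gaussian: exp(-d^2 / (2 b^2)); bisquare: (1 - (d/b)^2)^2 for d < b,
    exactly 0 at and beyond the bandwidth (compact support).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be nonnegative")
    b = spec.bandwidth
    if spec.family == "gaussian":
        w = np.exp(-(d**2) / (2 * b**2))
    else:
        w = np.where(d < b, (1 - (d / b) ** 2) ** 2, 0.0)
    return w


def weight_matrix(
    coords: np.ndarray, target: tuple[float, float], spec: KernelSpec
) -> np.ndarray:
    """Diagonal of W(u, v): kernel weights of every observation at target."""
    coords = np.asarray(coords, dtype=float)
    d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    return kernel_weight(d, spec)


def _solve_local(X: np.ndarray, y: np.ndarray, w: np.ndarray, index: int):
    """Solve the weighted normal equations at one location.

    Returns (beta, XtWX_inv). Raises LocalSingularityError when the
    weighted design is rank deficient (relative SVD tolerance 1e-10);
    near-singular fits raise rather than being silently regularized.
    """
    Xw = X * w[:, None]
    A = X.T @ Xw
    U, s, Vt = np.linalg.svd(A)
    if s[0] <= 0 or s[-1] / s[0] < _RANK_TOL:
        raise LocalSingularityError(index)
    A_inv = (Vt.T / s) @ U.T
    beta = A_inv @ (Xw.T @ y)
    return beta, A_inv


def local_fit(
    table: ObservationTable, target_index: int, spec: KernelSpec
) -> tuple[np.ndarray, float, float]:
    """Weighted least squares centred on observation ``target_index``.

    Returns (beta_row, hat_ii, fitted_i) where hat_ii is this location's
    leverage S_ii, the building block of tr(S).
    """
    w = weight_matrix(table.coords, tuple(table.coords[target_index]), spec)
    beta, A_inv = _solve_local(table.X, table.y, w, target_index)
    x_i = table.X[target_index]
    hat_ii = float(w[target_index] * x_i @ A_inv @ x_i)
    fitted_i = float(x_i @ beta)
    return beta, hat_ii, fitted_i


def aicc(n: int, rss: float, hat_trace: float) -> float:
    """Small-sample corrected AIC for a fit with effective parameters tr(S).

    AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S),
    sigma_hat = sqrt(rss / n). Requires n > tr(S) + 2.
    """
    if n - 2 - hat_trace <= 0:
        raise ValidationError(
            f"AICc undefined: n={n} <= tr(S)+2={hat_trace + 2:.2f} (saturated fit)"
        )
    sigma = math.sqrt(rss / n)
    if sigma <= 0:
        return -math.inf
    return (
        2 * n * math.log(sigma)
        + n * math.log(2 * math.pi)
        + n * (n + hat_trace) / (n - 2 - hat_trace)
    )


def fit_gwr(table: ObservationTable, spec: KernelSpec) -> GwrFit:
    """Fit GWR at every observation location.

    Accumulates the hat-matrix trace leverage-by-leverage (no n x n matrix
    is materialised; memory stays linear in n). Local R^2 uses the locally
    weighted residual and total sums of squares about the locally weighted
    mean.
    """
    n, p = table.n, table.p
    betas = np.empty((n, p))
    fitted = np.empty(n)
    local_r2 = np.empty(n)
    hat_trace = 0.0
    du = table.coords[:, 0][:, None] - table.coords[:, 0][None, :]
    dv = table.coords[:, 1][:, None] - table.coords[:, 1][None, :]
    D = np.hypot(du, dv)
    for i in range(n):
        w = kernel_weight(D[i], spec)
        beta, A_inv = _solve_local(table.X, table.y, w, i)
        betas[i] = beta
        x_i = table.X[i]
        hat_trace += float(w[i] * x_i @ A_inv @ x_i)
        fitted[i] = float(x_i @ beta)
        yhat_local = table.X @ beta
        wsum = w.sum()
        ybar_w = float(w @ table.y) / wsum
        tss_w = float(w @ (table.y - ybar_w) ** 2)
        rss_w = float(w @ (table.y - yhat_local) ** 2)
        local_r2[i] = 1.0 - rss_w / tss_w if tss_w > 0 else np.nan
    residuals = table.y - fitted
    rss = float(residuals @ residuals)
    denom = n - hat_trace
    sigma2 = rss / denom if denom > 0 else np.nan
    return GwrFit(
        betas=betas,
        fitted=fitted,
        residuals=residuals,
        hat_trace=hat_trace,
        sigma2_hat=sigma2,
        aicc=aicc(n, rss, hat_trace),
        local_r2=local_r2,
        kernel=spec,
    )


def fit_ols(table: ObservationTable) -> GlobalFit:
    """Ordinary least squares with the GWR-comparable AICc (tr S = p)."""
    X, y = table.X, table.y
    rank = np.linalg.matrix_rank(X)
    if rank < table.p:
        raise ValidationError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    residuals = y - fitted
    rss = float(residuals @ residuals)
    return GlobalFit(
        betas=beta,
        fitted=fitted,
        residuals=residuals,
        aicc=aicc(table.n, rss, float(table.p)),
        model="ols",
        hat_trace=float(table.p),
    )


def fit_ridge(table: ObservationTable, lam: float = 1.0) -> GlobalFit:
    """Ridge baseline: L2 penalty on z-scored predictors, intercept free.

    Effective parameters for AICc are the ridge hat-matrix trace plus one
    for the unpenalized intercept.
    """
    if lam < 0:
        raise ValidationError("ridge penalty must be >= 0")
    P = table.X[:, 1:]
    mu, sd = P.mean(axis=0), P.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (P - mu) / sd
    model = Ridge(alpha=lam, fit_intercept=True)
    model.fit(Z, table.y)
    fitted = model.predict(Z)
    residuals = table.y - fitted
    # Coefficients back on the original predictor scale, intercept adjusted.
    slopes = model.coef_ / sd
    intercept = model.intercept_ - float(slopes @ mu)
    betas = np.concatenate([[intercept], slopes])
    # tr of Z (Z'Z + lam I)^-1 Z' on centred predictors, +1 for intercept.
    Zc = Z - Z.mean(axis=0)
    G = Zc.T @ Zc + lam * np.eye(Zc.shape[1])
    hat_trace = float(np.trace(np.linalg.solve(G, Zc.T @ Zc))) + 1.0
    rss = float(residuals @ residuals)
    return GlobalFit(
        betas=betas,
        fitted=fitted,
        residuals=residuals,
        aicc=aicc(table.n, rss, hat_trace),
        model=f"ridge({lam})",
        hat_trace=hat_trace,
    )


def model_metrics(y: np.ndarray, fitted: np.ndarray) -> dict[str, float]:
    """In-sample R^2, MAE and MSE of a fit."""
    y = np.asarray(y, dtype=float).ravel()
    fitted = np.asarray(fitted, dtype=float).ravel()
    if y.size != fitted.size or y.size < 2:
        raise ValidationError("need two equal-length vectors")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise DegenerateInputError("zero-variance response")
    resid = y - fitted
    return {
        "r2": 1.0 - float(resid @ resid) / tss,
        "mae": float(np.abs(resid).mean()),
        "mse": float((resid**2).mean()),
    }


def default_bandwidth_bounds(coords: np.ndarray) -> tuple[float, float]:
    """(b_min, b_max) = (1.5 x median NN distance, spot diameter)."""
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    d_nn, _ = cKDTree(coords).query(coords, k=2)
    b_min = 1.5 * float(np.median(d_nn[:, 1]))
    span = coords.max(axis=0) - coords.min(axis=0)
    b_max = float(np.hypot(*span))
    return b_min, max(b_max, b_min * 2)


def select_bandwidth(
    table: ObservationTable,
    family: str = "gaussian",
    b_min: float | None = None,
    b_max: float | None = None,
    tol: float = 1e-2,
) -> BandwidthResult:
    """Golden-section AICc minimisation over [b_min, b_max].

    Bandwidths at which every local fit is singular score +inf. The result
    carries an ``at_boundary`` flag when the minimiser lands (within tol)
    on either bound — common on spatially near-homogeneous data, where the
    selector runs to the global-model limit, or on very sharp fields,
    where it hits the floor.
    """
    if b_min is None or b_max is None:
        lo, hi = default_bandwidth_bounds(table.coords)
        b_min = lo if b_min is None else b_min
        b_max = hi if b_max is None else b_max
    if not b_min > 0 or b_max < b_min:
        raise ValidationError("need 0 < b_min <= b_max")

    def score(b: float) -> float:
        try:
            return fit_gwr(table, KernelSpec(family, b)).aicc
        except LocalSingularityError:
            return math.inf
        except ValidationError:
            return math.inf

    if b_max == b_min:
        s = score(b_min)
        if math.isinf(s):
            raise ValidationError("singular fit at the only candidate bandwidth")
        return BandwidthResult(b_min, s, True, (b_min, b_max))

    a, b = b_min, b_max
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = score(c), score(d)
    while b - a > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = score(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = score(d)
    b_star = (a + b) / 2
    s_star = score(b_star)
    # Compare against the bounds themselves: golden section never samples
    # them, yet the optimum may sit there.
    for bound in (b_min, b_max):
        s_bound = score(bound)
        if s_bound < s_star:
            b_star, s_star = bound, s_bound
    if math.isinf(s_star):
        raise ValidationError("all candidate bandwidths produced singular fits")
    at_boundary = (b_star - b_min <= 2 * tol) or (b_max - b_star <= 2 * tol)
    return BandwidthResult(float(b_star), float(s_star), at_boundary, (b_min, b_max))


def residual_autocorrelation(
    residuals: np.ndarray, graph, marker: str = "", n_perm: int = 999, seed: int = 0
):
    """Moran/Geary diagnostics of fit residuals on the cell graph."""
    from .spatial import autocorrelation

    return autocorrelation(residuals, graph, marker=marker, n_perm=n_perm, seed=seed)
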