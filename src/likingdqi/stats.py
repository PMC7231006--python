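"""Numerical primitives: ridge regression, penalty selection, exploratory
factor analysis with varimax rotation, principal components, and normality
testing.

These are small, closed-form implementations with explicit contracts so the
index builders and the risk-score builder can freeze fitted objects and
re-apply them to held-out subjects without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import lilliefors

from .errors import ConstantColumnError, ConvergenceError, RankDeficiencyError

__all__ = [
    "RidgeSpec",
    "RidgeFit",
    "fit_ridge",
    "select_lambda",
    "default_lambda_grid",
    "FactorModel",
    "factor_varimax",
    "PCResult",
    "pca_first",
    "ks_normality",
    "kfold_indices",
]


# --------------------------------------------------------------------------
# Ridge regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RidgeSpec:
    """Configuration of a penalized linear fit.

    ``lam`` is the L2 penalty strength (>= 0).  ``penalized`` optionally
    masks which predictors receive the penalty (the intercept never does).
    With ``standardize`` set, predictors are centered and scaled to unit SD
    before fitting and coefficients are reported on that standardized scale.
    """

    lam: float = 1.0
    penalized: tuple[bool, ...] | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class RidgeFit:
    """Frozen ridge solution: coefficients plus the training scaling needed
    to score new subjects."""

    coef: np.ndarray
    intercept: float
    lam: float
    standardize: bool
    x_mean: np.ndarray
    x_scale: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def predict(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.intercept + Z @ self.coef

    def coef_series(self) -> pd.Series:
        names = self.feature_names or tuple(
            f"x{i}" for i in range(self.coef.size)
        )
        return pd.Series(self.coef, index=list(names))


def fit_ridge(X, y, spec: RidgeSpec = RidgeSpec()) -> RidgeFit:
    """Minimize ||y - b0 - X b||^2 + lam * ||b_penalized||^2 in closed form.

    The intercept is never penalized; with centered predictors it equals
    mean(y).  At lam = 0 a rank-deficient design raises
    :class:`RankDeficiencyError` (any positive lam succeeds).
    """
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need n > 1 observations")
    mask = (
        np.ones(p, dtype=bool)
        if spec.penalized is None
        else np.asarray(spec.penalized, dtype=bool)
    )
    if mask.size != p:
        raise ValueError("penalized mask length != number of predictors")

    x_mean = X.mean(axis=0)
    if spec.standardize:
        x_scale = X.std(axis=0, ddof=1)
        if np.any(x_scale[mask] <= 0):
            bad = [i for i in np.where(mask & (x_scale <= 0))[0]]
            raise ValueError(f"constant penalized predictor(s) at columns {bad}")
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
    else:
        x_scale = np.ones(p)

    Z = (X - x_mean) / x_scale
    yc = y - y.mean()
    A = Z.T @ Z + spec.lam * np.diag(mask.astype(float))
    if spec.lam == 0:
        if np.linalg.matrix_rank(Z, tol=1e-10 * max(n, p)) < p:
            raise RankDeficiencyError(
                "design is rank-deficient at lambda = 0; use lambda > 0"
            )
    coef = np.linalg.solve(A, Z.T @ yc)
    return RidgeFit(
        coef=coef,
        intercept=float(y.mean()),
        lam=float(spec.lam),
        standardize=spec.standardize,
        x_mean=x_mean,
        x_scale=x_scale,
        feature_names=names,
    )


def default_lambda_grid(num: int = 50) -> np.ndarray:
    """Log-spaced penalty grid spanning effectively-OLS to effectively-null
    fits on standardized predictors."""
    return np.logspace(-3, 3, num)


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def select_lambda(
    X,
    y,
    grid=None,
    k_folds: int = 5,
    seed: int = 0,
    spec: RidgeSpec = RidgeSpec(),
) -> float:
    """Pick the penalty minimizing mean held-out squared prediction error.

    Ties (within machine precision) break toward the larger penalty, i.e.
    toward the more parsimonious fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if n < 2 * k_folds:
        raise ValueError(f"need n >= 2*k_folds = {2 * k_folds}, got {n}")

    folds = kfold_indices(n, k_folds, seed)
    sse = np.zeros(grid.size)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        for j, lam in enumerate(grid):
            fit = fit_ridge(X[train], y[train], replace(spec, lam=float(lam)))
            resid = y[test_idx] - fit.predict(X[test_idx])
            sse[j] += float(resid @ resid)
    best = sse.min()
    # tie-break toward larger lambda
    candidates = np.where(sse <= best * (1 + 1e-12))[0]
    return float(grid[candidates[np.argmax(grid[candidates])]])


# --------------------------------------------------------------------------
# Factor analysis with varimax rotation
# --------------------------------------------------------------------------

def _varimax(loadings: np.ndarray, max_iter: int = 1000, tol: float = 1e-9):
    """Kaiser-normalized varimax rotation by pairwise planar rotations.

    Each sweep rotates every factor pair by its closed-form
    criterion-maximizing angle; sweeps repeat until the largest rotation
    angle falls below ``tol``.  Returns the rotated loadings and the
    accumulated orthogonal rotation matrix.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)
    h = np.sqrt((L ** 2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    Ln = L / h[:, None]
    R = np.eye(k)
    W = Ln.copy()
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = W[:, i], W[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (u @ v) - 2.0 * u.sum() * v.sum() / p
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                W[:, [i, j]] = W[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        if max_angle < tol:
            break
    else:
        raise ConvergenceError(
            f"varimax did not converge in {max_iter} sweeps "
            f"(last max angle {max_angle:.2e})")
    return W * h[:, None], R


@dataclass(frozen=True)
class FactorModel:
    """Exploratory factor solution on a correlation matrix.

    Holds the rotated loadings, the orthogonal rotation, per-factor explained
    variance, subject factor scores, and the training standardization plus
    score weights needed to compute factor scores of new subjects by the
    regression (Thomson) method.
    """

    loadings: pd.DataFrame            # items x factors
    rotation: np.ndarray              # orthogonal k x k
    factor_scores: pd.DataFrame       # subjects x factors (training data)
    variance_explained: np.ndarray    # fraction of total item variance
    mean_: np.ndarray = field(repr=False, default=None)
    scale_: np.ndarray = field(repr=False, default=None)
    score_weights: np.ndarray = field(repr=False, default=None)  # R^-1 Lambda

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def score(self, X) -> pd.DataFrame:
        """Factor scores of new subjects through the frozen training model."""
        idx = X.index if isinstance(X, pd.DataFrame) else None
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        S = Z @ self.score_weights
        return pd.DataFrame(S, index=idx, columns=self.loadings.columns)


def factor_varimax(X, n_factors: int, max_iter: int = 5000) -> FactorModel:
    """Extract ``n_factors`` from the correlation matrix and varimax-rotate.

    Extraction is by principal components of the correlation matrix (the
    standard deterministic choice for exploratory use).  Factors are ordered
    by post-rotation explained variance, and each factor's sign is fixed so
    its largest-magnitude loading is positive.  Factor scores use the
    regression (Thomson) method, ``Z R^-1 Lambda``.
    """
    cols = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"v{i}" for i in range(np.shape(X)[1])]
    )
    idx = X.index if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (0 < n_factors < min(p, n)):
        raise ValueError(f"n_factors must be in (0, min(items, subjects)) = (0, {min(p, n)})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [cols[i] for i in np.where(sd <= 0)[0]]
        raise ConstantColumnError(f"constant column(s): {bad}")
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1][:n_factors]
    L = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0, None))
    L_rot, rot = _varimax(L, max_iter=max_iter)

    # order factors by explained variance after rotation; fix signs
    ss = (L_rot ** 2).sum(axis=0)
    col_order = np.argsort(ss)[::-1]
    L_rot = L_rot[:, col_order]
    rot = rot[:, col_order]
    ss = ss[col_order]
    signs = np.sign(L_rot[np.abs(L_rot).argmax(axis=0), np.arange(n_factors)])
    signs = np.where(signs == 0, 1.0, signs)
    L_rot = L_rot * signs
    rot = rot * signs

    weights = np.linalg.solve(R, L_rot)
    scores = Z @ weights
    factor_names = [f"F{i + 1}" for i in range(n_factors)]
    return FactorModel(
        loadings=pd.DataFrame(L_rot, index=cols, columns=factor_names),
        rotation=rot,
        factor_scores=pd.DataFrame(scores, index=idx, columns=factor_names),
        variance_explained=ss / p,
        mean_=mean,
        scale_=sd,
        score_weights=weights,
    )


# --------------------------------------------------------------------------
# Principal components
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCResult:
    """Principal components of the correlation matrix of standardized data."""

    component_loadings: pd.DataFrame   # variables x components (unit-norm)
    scores: pd.DataFrame               # subjects x components
    explained_fraction: np.ndarray     # non-increasing, sums to <= 1
    mean_: np.ndarray = field(repr=False, default=None)
    scale_: np.ndarray = field(repr=False, default=None)


def pca_first(X) -> PCResult:
    """Eigen-decomposition of the correlation matrix of standardized inputs."""
    cols = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"v{i}" for i in range(np.shape(X)[1])]
    )
    idx = X.index if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [cols[i] for i in np.where(sd <= 0)[0]]
        raise ConstantColumnError(f"constant column(s): {bad}")
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    comp_names = [f"PC{i + 1}" for i in range(len(cols))]
    return PCResult(
        component_loadings=pd.DataFrame(eigvec, index=cols, columns=comp_names),
        scores=pd.DataFrame(Z @ eigvec, index=idx, columns=comp_names),
        explained_fraction=eigval / eigval.sum(),
        mean_=mean,
        scale_=sd,
    )


# --------------------------------------------------------------------------
# Normality testing
# --------------------------------------------------------------------------

def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of normality with parameters
    estimated from the data (Lilliefors correction).

    Plain KS with estimated mean/SD is anticonservative; the Lilliefors
    critical values account for the estimation.  Returns (D, p).  D is
    invariant to affine rescaling of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8 for the normality test")
    d, p = lilliefors(x, dist="norm")
    return float(d), float(p)
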