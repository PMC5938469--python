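"""Distance-band spatial weights, Moran's I, and ML SAR spatial-error models.

The regression model is y* = X beta + u with u = lambda W u + eps,
eps ~ N(0, sigma^2 I): an ordinary linear model plus a spatially dependent
error term governed by the weights matrix W and parameter lambda. Estimation
is maximum likelihood with the log-determinant of (I - lambda W) evaluated
exactly from the eigenvalues of W, profiling the likelihood over lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "SARFit",
    "EliminationTrace",
    "build_weights",
    "morans_i",
    "fit_sar_error",
    "lr_test",
    "backward_eliminate",
    "select_neighborhood",
]


@dataclass
class SpatialWeights:
    """Distance-band neighbor weights.

    Units i, j are neighbors iff 0 < d(i, j) <= threshold_km. Rows of the
    row-standardized matrix sum to 1; units with no neighbors get a zero row
    and are flagged in ``isolated``.
    """

    n: int
    threshold_km: float
    style: str  # "row_standardized" | "binary"
    adjacency: np.ndarray  # symmetric boolean (n, n)
    isolated: np.ndarray  # boolean (n,)
    _w: np.ndarray | None = field(default=None, repr=False)
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def matrix(self) -> np.ndarray:
        if self._w is None:
            b = self.adjacency.astype(float)
            if self.style == "binary":
                self._w = b
            else:
                deg = b.sum(axis=1)
                deg[deg == 0] = 1.0
                self._w = b / deg[:, None]
        return self._w

    @property
    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (row-standardized W is similar to a
        symmetric matrix, so its spectrum is real)."""
        if self._eigs is None:
            if self.style == "row_standardized":
                b = self.adjacency.astype(float)
                deg = b.sum(axis=1)
                deg[deg == 0] = 1.0
                s = b / np.sqrt(np.outer(deg, deg))
                self._eigs = linalg.eigvalsh(s)
            else:
                ev = linalg.eigvals(self.matrix)
                if np.abs(ev.imag).max(initial=0.0) > 1e-8:
                    warnings.warn("complex eigenvalues in weights; using real parts")
                self._eigs = np.sort(ev.real)
        return self._eigs

    def neighbor_counts(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def lambda_bounds(self) -> tuple[float, float]:
        ev = self.eigenvalues
        lo = 1.0 / ev.min() if ev.min() < 0 else -np.inf
        hi = 1.0 / ev.max() if ev.max() > 0 else np.inf
        return lo, hi


def build_weights(
    coords: np.ndarray,
    threshold_km: float = 35.0,
    style: str = "row_standardized",
) -> SpatialWeights:
    """Distance-band weights from planar (x, y) km coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("coordinates must be unique per unit")
    if style not in ("row_standardized", "binary"):
        raise ValueError(f"unknown weights style {style!r}")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold_km, output_type="ndarray")
    adj = np.zeros((n, n), dtype=bool)
    if pairs.size:
        adj[pairs[:, 0], pairs[:, 1]] = True
        adj[pairs[:, 1], pairs[:, 0]] = True
    isolated = ~adj.any(axis=1)
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} unit(s) have no neighbors at "
            f"{threshold_km} km; rows left as zeros"
        )
    return SpatialWeights(
        n=n, threshold_km=threshold_km, style=style, adjacency=adj, isolated=isolated
    )


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z: float
    p: float


def morans_i(
    values: Sequence[float],
    w: SpatialWeights,
    permutations: int | None = None,
    seed: int = 0,
) -> MoranResult:
    """Moran's I with the normality approximation (or a permutation p-value).

    I = (n / S0) * (z' W z) / (z' z) with z the centered values and S0 the
    total weight. Expectation under no autocorrelation is -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if np.isclose(x.std(), 0):
        raise ValueError("zero variance")
    W = w.matrix
    z = x - x.mean()
    s0 = W.sum()
    I = (n / s0) * (z @ W @ z) / (z @ z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    var_i = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
    zscore = (I - e_i) / np.sqrt(var_i)
    if permutations:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for b in range(permutations):
            zp = rng.permutation(z)
            sims[b] = (n / s0) * (zp @ W @ zp) / (zp @ zp)
        # two-sided permutation p, add-one correction
        p = (1 + np.sum(np.abs(sims - e_i) >= abs(I - e_i))) / (permutations + 1)
    else:
        p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(
        I=float(I), expected_I=e_i, variance_I=float(var_i), z=float(zscore), p=float(p)
    )


@dataclass
class SARFit:
    terms: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    z_beta: np.ndarray
    lam: float
    sigma2: float
    log_lik: float
    aic: float
    nagelkerke_r2: float
    residuals: np.ndarray  # raw: y* - X beta
    whitened_residuals: np.ndarray  # (I - lam W)(y* - X beta)
    dependent_transform: str
    n: int
    lambda_at_boundary: bool = False

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    @property
    def n_params(self) -> int:
        return len(self.terms) + 2  # beta, lambda, sigma^2

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se_beta, "z": self.z_beta}, index=self.terms
        )


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if "intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "intercept", 1.0)
    return X.to_numpy(dtype=float), list(X.columns)


def fit_sar_error(
    y: Sequence[float],
    X: pd.DataFrame,
    w: SpatialWeights,
    transform: str = "identity",
) -> SARFit:
    """Maximum-likelihood SAR spatial-error fit.

    Profiles the likelihood over lambda: for fixed lambda the model reduces
    to OLS of (I - lambda W) y* on (I - lambda W) X; the concentrated
    log-likelihood adds the exact log-determinant term. The Nagelkerke
    pseudo-R^2 compares against the intercept-only non-spatial model.
    """
    y = np.asarray(y, dtype=float)
    if transform == "square":
        ystar = y**2
    elif transform == "identity":
        ystar = y
    else:
        raise ValueError(f"unknown transform {transform!r}")
    Xmat, names = _design(X)
    n, p = Xmat.shape
    if np.linalg.matrix_rank(Xmat) < p:
        raise ValueError("singular design matrix")
    if n <= p + 2:
        raise ValueError("too few observations")
    W = w.matrix
    eigs = w.eigenvalues
    lo, hi = w.lambda_bounds()
    eps = 1e-6
    lo = max(lo, -0.999999) if np.isfinite(lo) else -0.999999
    hi = min(hi, 0.999999) if np.isfinite(hi) else 0.999999

    def negconc(lam: float) -> float:
        A_y = ystar - lam * (W @ ystar)
        A_X = Xmat - lam * (W @ Xmat)
        beta, *_ = np.linalg.lstsq(A_X, A_y, rcond=None)
        resid = A_y - A_X @ beta
        sigma2 = resid @ resid / n
        logdet = np.sum(np.log1p(-lam * eigs))
        ll = -n / 2 * (np.log(2 * np.pi * sigma2) + 1) + logdet
        return -ll

    res = optimize.minimize_scalar(
        negconc, bounds=(lo + eps, hi - eps), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    at_boundary = min(lam - lo, hi - lam) < 1e-4
    if at_boundary:
        warnings.warn(f"lambda estimate {lam:.4f} is at the parameter boundary")
    A_y = ystar - lam * (W @ ystar)
    A_X = Xmat - lam * (W @ Xmat)
    beta, *_ = np.linalg.lstsq(A_X, A_y, rcond=None)
    wres = A_y - A_X @ beta
    sigma2 = float(wres @ wres / n)
    log_lik = float(-res.fun)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A_X.T @ A_X)))
    raw_resid = ystar - Xmat @ beta
    k = p + 2
    aic = -2 * log_lik + 2 * k
    # intercept-only non-spatial reference
    r0 = ystar - ystar.mean()
    ll0 = float(-n / 2 * (np.log(2 * np.pi * (r0 @ r0 / n)) + 1))
    nag = (1 - np.exp(-(2 / n) * (log_lik - ll0))) / (1 - np.exp((2 / n) * ll0))
    return SARFit(
        terms=names,
        beta=beta,
        se_beta=se,
        z_beta=beta / se,
        lam=lam,
        sigma2=sigma2,
        log_lik=log_lik,
        aic=float(aic),
        nagelkerke_r2=float(nag),
        residuals=raw_resid,
        whitened_residuals=wres,
        dependent_transform=transform,
        n=n,
        lambda_at_boundary=at_boundary,
    )


def lr_test(full: SARFit, reduced: SARFit):
    """Likelihood-ratio test of nested SAR fits; returns (LR, df, p)."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    if full.dependent_transform != reduced.dependent_transform or full.n != reduced.n:
        raise ValueError("fits are not comparable")
    df = len(full.terms) - len(reduced.terms)
    lr = 2 * (full.log_lik - reduced.log_lik)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return float(lr), df, p


@dataclass
class EliminationTrace:
    steps: list[tuple[str, float, int, float]]  # (dropped term, LR, df, p)
    final: SARFit


def backward_eliminate(
    y: Sequence[float],
    X: pd.DataFrame,
    w: SpatialWeights,
    alpha: float = 0.05,
    protected: Sequence[str] = (),
    transform: str = "identity",
) -> EliminationTrace:
    """Stepwise backward elimination of nonsignificant covariates by LR test.

    At each step every unprotected term is dropped in turn and the reduced
    model refitted; the term with the largest LR p-value above *alpha* is
    removed. The intercept is always protected.
    """
    if "intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "intercept", 1.0)
    protected = set(protected) | {"intercept"}
    cols = list(X.columns)
    steps: list[tuple[str, float, int, float]] = []
    current = fit_sar_error(y, X[cols], w, transform)
    while True:
        candidates = [c for c in cols if c not in protected]
        if not candidates:
            break
        trials = []
        for c in candidates:
            reduced_cols = [x for x in cols if x != c]
            reduced = fit_sar_error(y, X[reduced_cols], w, transform)
            lr, df, p = lr_test(current, reduced)
            trials.append((p, c, lr, df, reduced))
        p, c, lr, df, reduced = max(trials, key=lambda t: t[0])
        if p <= alpha:
            break
        steps.append((c, lr, df, p))
        cols.remove(c)
        current = reduced
    return EliminationTrace(steps=steps, final=current)


def select_neighborhood(
    y: Sequence[float],
    X: pd.DataFrame,
    coords: np.ndarray,
    candidate_thresholds: Sequence[float],
    style: str = "row_standardized",
    transform: str = "identity",
) -> pd.DataFrame:
    """Fit one SAR model per neighborhood distance; compare AIC and residual
    Moran's I. Returns a table with the AIC-minimizing row flagged."""
    if len(candidate_thresholds) < 1:
        raise ValueError("need at least one candidate threshold")
    rows = []
    for thr in candidate_thresholds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = build_weights(coords, threshold_km=thr, style=style)
            fit = fit_sar_error(y, X, w, transform)
            mor = morans_i(fit.whitened_residuals, w)
        rows.append(
            {
                "threshold_km": thr,
                "aic": fit.aic,
                "lambda": fit.lam,
                "residual_moran_I": mor.I,
                "residual_moran_z": mor.z,
            }
        )
    out = pd.DataFrame(rows)
    out["best_aic"] = out["aic"] == out["aic"].min()
    return out
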