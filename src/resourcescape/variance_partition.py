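"""Hierarchical (LMG/Shapley) partitioning of variance after removing the
spatial component from SAR fits, and habitat-vs-functional-diversity model
comparison.

LMG importance of a predictor is its incremental R^2 averaged over all
orderings in which predictors can enter the model — the Shapley value of R^2
— so shares are order-invariant and sum exactly to the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spatial_models import SARFit, SpatialWeights

__all__ = [
    "PartitionResult",
    "ModelComparison",
    "despatialize",
    "lmg_shares",
    "compare_model_types",
]


@dataclass
class PartitionResult:
    shares: dict[str, float]  # per-predictor share of R^2, in percent
    full_r2: float  # full-model R^2, percent
    total_r2_excluding_protected: float  # percent
    protected: tuple[str, ...]

    def share(self, term: str) -> float:
        return self.shares[term]


def despatialize(
    fit: SARFit,
    y: Sequence[float],
    X: pd.DataFrame,
    w: SpatialWeights,
    mode: str = "trend_plus_whitened",
) -> np.ndarray:
    """Response with the fitted spatial error signal removed.

    ``trend_plus_whitened`` (default): y_adj = X beta + (I - lam W)(y* - X beta),
    i.e. the regression trend plus the whitened (spatially independent)
    residual — the autocorrelated part lam W u is subtracted out.
    ``trend_only``: y_adj = X beta.
    """
    ystar = np.asarray(y, dtype=float)
    if fit.dependent_transform == "square":
        ystar = ystar**2
    Xm = X.copy()
    if "intercept" not in Xm.columns:
        Xm.insert(0, "intercept", 1.0)
    if list(Xm.columns) != fit.terms:
        Xm = Xm[fit.terms]
    Xmat = Xm.to_numpy(dtype=float)
    if Xmat.shape[0] != fit.n:
        raise ValueError("dimension mismatch between fit and data")
    trend = Xmat @ fit.beta
    if mode == "trend_only":
        return trend
    if mode != "trend_plus_whitened":
        raise ValueError(f"unknown mode {mode!r}")
    u = ystar - trend
    eps = u - fit.lam * (w.matrix @ u)
    return trend + eps


def _r2(y: np.ndarray, cols: np.ndarray) -> float:
    """OLS R^2 of y on the given columns plus an intercept."""
    n = y.size
    X = np.column_stack([np.ones(n), cols]) if cols.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1 - resid @ resid / tss)


def lmg_shares(
    y_adj: Sequence[float],
    X: pd.DataFrame,
    protected: Sequence[str] = (),
) -> PartitionResult:
    """Exact LMG (Shapley) decomposition of R^2 across predictors.

    share(x) = sum over subsets S not containing x of
    [R^2(S + x) - R^2(S)] * |S|! (p - |S| - 1)! / p!.
    Exact enumeration, so at most 10 predictors. Protected terms (effort)
    participate in every subset evaluation but are excluded from the
    reported ``total_r2_excluding_protected``.
    """
    y = np.asarray(y_adj, dtype=float)
    preds = [c for c in X.columns if c != "intercept"]
    p = len(preds)
    if p == 0:
        raise ValueError("no predictors")
    if p > 10:
        raise ValueError("exact Shapley enumeration limited to 10 predictors")
    cols = {c: X[c].to_numpy(dtype=float) for c in preds}
    # precompute R^2 for every subset
    r2_cache: dict[frozenset, float] = {}
    for r in range(p + 1):
        for S in combinations(preds, r):
            mat = (
                np.column_stack([cols[c] for c in S]) if S else np.empty((y.size, 0))
            )
            if S and np.linalg.matrix_rank(np.column_stack([np.ones(y.size), mat])) < len(S) + 1:
                raise ValueError(f"rank-deficient predictor subset: {S}")
            r2_cache[frozenset(S)] = _r2(y, mat)
    shares = {}
    fp = factorial(p)
    for x in preds:
        others = [c for c in preds if c != x]
        total = 0.0
        for r in range(p):
            wgt = factorial(r) * factorial(p - r - 1) / fp
            for S in combinations(others, r):
                fs = frozenset(S)
                total += wgt * (r2_cache[fs | {x}] - r2_cache[fs])
        shares[x] = 100.0 * total
    full = 100.0 * r2_cache[frozenset(preds)]
    protected = tuple(t for t in protected if t in shares)
    total_excl = sum(v for k, v in shares.items() if k not in protected)
    return PartitionResult(
        shares=shares,
        full_r2=full,
        total_r2_excluding_protected=total_excl,
        protected=protected,
    )


@dataclass
class ModelComparison:
    table: pd.DataFrame  # rows: (response, model_type, term) with beta, z, r2_share
    summary: pd.DataFrame  # per (response, model_type): aic, total_r2, winner flags


def compare_model_types(
    fits: Mapping[tuple[str, str], tuple[SARFit, PartitionResult]],
) -> ModelComparison:
    """Side-by-side comparison of habitat vs functional-diversity model types.

    *fits* maps (response, model_type) to the retained SAR fit and its LMG
    partition. For each response both model types must be present; winners
    are flagged separately by lower AIC and by higher total R^2 (excluding
    protected terms), since the two can disagree.
    """
    responses = sorted({r for r, _ in fits})
    types = sorted({t for _, t in fits})
    for r in responses:
        missing = [t for t in types if (r, t) not in fits]
        if missing:
            raise ValueError(f"response {r!r} missing model type(s) {missing}")
    rows = []
    summaries = []
    for (resp, mtype), (fit, part) in fits.items():
        for i, term in enumerate(fit.terms):
            if term == "intercept":
                continue
            rows.append(
                {
                    "response": resp,
                    "model_type": mtype,
                    "term": term,
                    "beta": fit.beta[i],
                    "z": fit.z_beta[i],
                    "r2_share_pct": part.shares.get(term, np.nan),
                }
            )
        summaries.append(
            {
                "response": resp,
                "model_type": mtype,
                "aic": fit.aic,
                "total_r2_pct": part.total_r2_excluding_protected,
                "nagelkerke_r2": fit.nagelkerke_r2,
            }
        )
    summary = pd.DataFrame(summaries)
    summary["wins_by_aic"] = False
    summary["wins_by_r2"] = False
    for resp in responses:
        sub = summary[summary["response"] == resp]
        best_aic = sub["aic"].min()
        best_r2 = sub["total_r2_pct"].max()
        summary.loc[sub.index, "wins_by_aic"] = np.isclose(sub["aic"], best_aic)
        summary.loc[sub.index, "wins_by_r2"] = np.isclose(sub["total_r2_pct"], best_r2)
    return ModelComparison(table=pd.DataFrame(rows), summary=summary)
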