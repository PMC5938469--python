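"""Occurrence-weighted null distributions of FD and standardized FD (sFD).

The null holds component richness fixed and draws the same number of
components from the pool, each with probability proportional to the number
of sampling units in which it was recorded (so rare components do not have a
disproportionate influence). Observed FD is standardized against 1,000 such
draws; negative sFD means less functional diversity than expected at that
richness, the signature of environmental filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .functional_diversity import Dendrogram, FDConvention, fd_subsets_matrix

__all__ = [
    "PoolWeights",
    "NullDistribution",
    "StandardizedFD",
    "weighted_sample_without_replacement",
    "null_fd_distribution",
    "standardize_fd",
    "one_sample_t",
    "paired_t",
]

DEFAULT_N_ITER = 1000


@dataclass(frozen=True)
class PoolWeights:
    """component id -> occupancy count (number of units in which recorded)."""

    weights: Mapping[str, float]

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("occupancy counts must be non-negative")

    def positive_ids(self) -> list[str]:
        return [c for c, w in self.weights.items() if w > 0]

    @staticmethod
    def from_occurrences(unit_sets: Iterable[Iterable[str]]) -> "PoolWeights":
        counts: dict[str, int] = {}
        for s in unit_sets:
            for c in s:
                counts[c] = counts.get(c, 0) + 1
        return PoolWeights({c: counts[c] for c in sorted(counts)})


@dataclass(frozen=True)
class NullDistribution:
    richness_k: int
    n_iter: int
    mean_fd: float
    sd_fd: float
    seed: int
    pool_id: str

    def __post_init__(self):
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if self.sd_fd < 0:
            raise ValueError("sd_fd must be >= 0")


@dataclass(frozen=True)
class StandardizedFD:
    observed: float
    sfd: float | None  # None flags undefined (null SD was zero)

    @property
    def defined(self) -> bool:
        return self.sfd is not None


def _gumbel_topk(weights: np.ndarray, k: int, n_draws: int, rng: np.random.Generator):
    """Indices of k items per draw under successive weighted sampling without
    replacement (draw i with prob w_i / sum of remaining w, remove, repeat).

    Uses the Gumbel-top-k construction, which is equivalent in distribution
    to that successive-draw scheme.
    """
    logw = np.full(weights.shape, -np.inf)
    pos = weights > 0
    logw[pos] = np.log(weights[pos])
    keys = logw[None, :] + rng.gumbel(size=(n_draws, weights.size))
    part = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    return part


def weighted_sample_without_replacement(
    w: PoolWeights, k: int, rng: np.random.Generator
) -> list[str]:
    """Draw k distinct component ids, successively, proportional to weight."""
    ids = sorted(w.weights)
    wt = np.array([w.weights[c] for c in ids], dtype=float)
    n_pos = int((wt > 0).sum())
    if k > n_pos:
        raise ValueError(f"cannot draw {k} from {n_pos} positive-weight components")
    idx = _gumbel_topk(wt, k, 1, rng)[0]
    return [ids[i] for i in idx]


def pool_rng(seed: int, pool_id: str, k: int) -> np.random.Generator:
    """One RNG stream per (global seed, pool, richness).

    The null distribution depends only on the pool and the richness k, so
    units of equal richness share one stream: results are independent of unit
    processing order and identical component sets give identical sFD.
    """
    pool_key = int.from_bytes(pool_id.encode()[:8].ljust(8, b"\0"), "big")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(pool_key % (2**31), int(k)))
    return np.random.default_rng(ss)


def null_fd_distribution(
    t: Dendrogram,
    w: PoolWeights,
    k: int,
    n_iter: int = DEFAULT_N_ITER,
    conv: FDConvention = FDConvention(),
    seed: int = 0,
    pool_id: str = "pool",
    restrict_to: Iterable[str] | None = None,
) -> NullDistribution:
    """Mean/SD of FD over *n_iter* occupancy-weighted random draws of size k.

    *restrict_to* intersects the pool before weighting (e.g. island-specific
    pools). SD uses the n-1 denominator; when the eligible pool has exactly k
    members every draw is the full pool and SD is 0 (downstream sFD is then
    flagged undefined).
    """
    if k < 2:
        raise ValueError("richness k must be >= 2")
    ids = sorted(w.weights)
    if restrict_to is not None:
        allowed = set(restrict_to)
        ids = [c for c in ids if c in allowed]
    wt = np.array([w.weights[c] for c in ids], dtype=float)
    n_pos = int((wt > 0).sum())
    if k > n_pos:
        raise ValueError(f"richness {k} exceeds eligible pool size {n_pos}")
    rng = pool_rng(seed, pool_id, k)
    draws = _gumbel_topk(wt, k, n_iter, rng)
    leaf_idx = t.leaf_index(ids)
    membership = np.zeros((t.n_leaves, n_iter), dtype=bool)
    membership[leaf_idx[draws.T], np.arange(n_iter)[None, :]] = True
    fds = fd_subsets_matrix(t, membership, conv)
    return NullDistribution(
        richness_k=k,
        n_iter=n_iter,
        mean_fd=float(fds.mean()),
        sd_fd=float(fds.std(ddof=1)),
        seed=seed,
        pool_id=pool_id,
    )


def standardize_fd(observed: float, nd: NullDistribution) -> StandardizedFD:
    if nd.sd_fd == 0:
        return StandardizedFD(observed=observed, sfd=None)
    return StandardizedFD(observed=observed, sfd=(observed - nd.mean_fd) / nd.sd_fd)


def one_sample_t(values: Sequence[float], mu0: float = 0.0):
    """One-sample t test; returns (t, df, two-sided p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.isclose(x.std(ddof=1), 0):
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def paired_t(a: Sequence[float], b: Sequence[float]):
    """Paired t test (one-sample t of the differences against 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size >= 2 and np.all(a == b):
        return 0.0, int(a.size - 1), 1.0
    return one_sample_t(a - b, 0.0)
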