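"""Gower distances, UPGMA dendrograms, and dendrogram-based functional diversity.

Functional diversity (FD) of a set of components follows Petchey & Gaston's
branch-length metric: the total length of dendrogram branches required to
connect the components present. The dendrogram is built once per component
pool (by UPGMA on Gower distances) and reused for every sampling unit, so
standardized FD values are comparable across units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .resource_model import ResourceMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "FDConvention",
    "gower_distance",
    "upgma",
    "fd_subset",
    "total_length",
    "write_newick",
]


@dataclass(frozen=True)
class FDConvention:
    """Root-path handling for subset FD.

    With ``include_root_path=False`` (default) the spanning subtree is rooted
    at the lowest common ancestor of the components present, so a singleton
    has FD 0. With ``True`` the branches from that ancestor up to the global
    root are counted as well.
    """

    include_root_path: bool = False


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    ranges_used: np.ndarray  # observed range per retained category

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0) or np.any(self.d > 1 + 1e-12):
            raise ValueError("Gower distances must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path)


def gower_distance(
    m: ResourceMatrix, use_theoretical_ranges: bool = False
) -> DistanceMatrix:
    """Gower distance over mixed binary/ordinal categories.

    d(i, j) = mean over informative categories k of |x_ik - x_jk| / r_k,
    where r_k is the observed range of category k across the matrix (or the
    schema's theoretical range when *use_theoretical_ranges*). Categories with
    zero range carry no information and are dropped from both numerator and
    denominator; binary categories reduce to 0/1 mismatch terms.
    """
    if m.n_components < 2:
        raise ValueError("need at least 2 components for a distance matrix")
    x = m.values.astype(float)
    if use_theoretical_ranges:
        r = m.schema.max_levels.astype(float)
    else:
        r = x.max(axis=0) - x.min(axis=0)
    keep = r > 0
    if not keep.any():
        raise ValueError("no informative categories (all have zero range)")
    xs = x[:, keep] / r[keep]
    diff = np.abs(xs[:, None, :] - xs[None, :, :])
    d = diff.mean(axis=2)
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, 1.0)  # guard FP overshoot at the bound
    return DistanceMatrix(ids=list(m.component_ids), d=(d + d.T) / 2, ranges_used=r[keep])


@dataclass
class Dendrogram:
    """Rooted binary ultrametric tree; leaves at height 0.

    Nodes ``0..n-1`` are leaves (in ``leaf_ids`` order); node ``n-1+k`` is the
    k-th merge. ``children[k]`` are the two nodes merged at ``heights[k]``;
    merge heights are non-decreasing (UPGMA monotonicity), and the cophenetic
    distance between two leaves is the height of their lowest common ancestor.
    """

    leaf_ids: list[str]
    children: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float, merge height of each internal node

    # Derived, built lazily: per-edge lengths and leaf-under-edge incidence.
    _edge_lengths: np.ndarray | None = field(default=None, repr=False, compare=False)
    _edge_leaves: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.children = np.asarray(self.children, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.leaf_ids)
        if self.children.shape != (n - 1, 2) or self.heights.shape != (n - 1,):
            raise ValueError("malformed dendrogram arrays")
        if np.any(np.diff(self.heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.heights[node - n])

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def _build_edges(self) -> None:
        """Edge e runs from node e up to its parent; the root has no edge."""
        n = self.n_leaves
        n_nodes = 2 * n - 1
        parent_height = np.empty(n_nodes - 1)
        leaves_under = np.zeros((n_nodes, n), dtype=bool)
        leaves_under[np.arange(n), np.arange(n)] = True
        for k, (a, b) in enumerate(self.children):
            node = n + k
            leaves_under[node] = leaves_under[a] | leaves_under[b]
            parent_height[a] = self.heights[k]
            parent_height[b] = self.heights[k]
        node_heights = np.concatenate([np.zeros(n), self.heights])
        self._edge_lengths = parent_height - node_heights[: n_nodes - 1]
        if np.any(self._edge_lengths < -1e-9):
            raise ValueError("negative edge length")
        self._edge_lengths = np.maximum(self._edge_lengths, 0.0)
        self._edge_leaves = leaves_under[: n_nodes - 1]

    @property
    def edge_lengths(self) -> np.ndarray:
        if self._edge_lengths is None:
            self._build_edges()
        return self._edge_lengths

    @property
    def edge_leaves(self) -> np.ndarray:
        """Boolean (n_edges, n_leaves): leaf j lies below edge e's child node."""
        if self._edge_leaves is None:
            self._build_edges()
        return self._edge_leaves

    def leaf_index(self, ids: Iterable[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.leaf_ids)}
        try:
            return np.array([lut[c] for c in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown leaf id {exc.args[0]!r}") from None

    def cophenetic_matrix(self) -> np.ndarray:
        n = self.n_leaves
        coph = np.zeros((n, n))
        members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
        for k, (a, b) in enumerate(self.children):
            ma, mb = members.pop(a), members.pop(b)
            coph[np.ix_(ma, mb)] = self.heights[k]
            coph[np.ix_(mb, ma)] = self.heights[k]
            members[n + k] = np.concatenate([ma, mb])
        return coph


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering.

    The merge height of a new cluster is the unweighted mean of pairwise
    distances between all leaf pairs spanning the two merged clusters. Ties
    are broken toward the pair of clusters whose (smallest-leaf-id) labels
    sort lexicographically first, so builds are deterministic under any
    input order.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    # active clusters: node -> (size, representative label = min leaf id)
    d = dm.d.astype(float).copy()
    active: dict[int, tuple[int, str]] = {i: (1, dm.ids[i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    children = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    for k in range(n - 1):
        best = None
        for (i, j), dij in dist.items():
            li, lj = active[i][1], active[j][1]
            key = (dij, *sorted((li, lj)))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dist[(i, j)]
        node = n + k
        children[k] = (i, j)
        heights[k] = h
        (si, li), (sj, lj) = active.pop(i), active.pop(j)
        for other in list(active):
            a, b = (other, i) if other < i else (i, other)
            c, e = (other, j) if other < j else (j, other)
            dio, djo = dist.pop((a, b)), dist.pop((c, e))
            dist[(other, node)] = (si * dio + sj * djo) / (si + sj)
        dist.pop((i, j))
        active[node] = (si + sj, min(li, lj))
    return Dendrogram(leaf_ids=list(dm.ids), children=children, heights=heights)


def fd_subset(
    t: Dendrogram,
    present: Iterable[str],
    conv: FDConvention = FDConvention(),
) -> float:
    """FD of a component subset: total branch length of the minimal spanning subtree."""
    idx = t.leaf_index(list(present))
    if idx.size == 0:
        raise ValueError("empty component set")
    if len(set(idx.tolist())) != idx.size:
        idx = np.unique(idx)
    counts = t.edge_leaves[:, idx].sum(axis=1)
    k = idx.size
    if conv.include_root_path:
        on = counts >= 1
    else:
        on = (counts >= 1) & (counts < k)
    return float(t.edge_lengths[on].sum())


def fd_subsets_matrix(
    t: Dendrogram, membership: np.ndarray, conv: FDConvention = FDConvention()
) -> np.ndarray:
    """Vectorized FD for many subsets.

    *membership* is boolean (n_leaves, n_subsets); returns FD per subset.
    Used by the null-model loop where thousands of random draws share a tree.
    """
    counts = t.edge_leaves.astype(np.int32) @ membership.astype(np.int32)
    k = membership.sum(axis=0)[None, :]
    if conv.include_root_path:
        on = counts >= 1
    else:
        on = (counts >= 1) & (counts < k)
    return t.edge_lengths @ on


def total_length(t: Dendrogram) -> float:
    """Sum of all edge lengths (= FD of the full pool under either convention)."""
    return float(t.edge_lengths.sum())


def _newick_node(t: Dendrogram, node: int, parent_height: float) -> str:
    blen = parent_height - t.node_height(node)
    if node < t.n_leaves:
        return f"{t.leaf_ids[node]}:{blen:.10g}"
    a, b = t.children[node - t.n_leaves]
    h = t.node_height(node)
    inner = f"({_newick_node(t, a, h)},{_newick_node(t, b, h)})"
    return inner if node == t.root else f"{inner}:{blen:.10g}"


def to_newick(t: Dendrogram) -> str:
    return _newick_node(t, t.root, t.node_height(t.root)) + ";"


def write_newick(t: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(t) + "\n")
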