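import numpy as np
import pytest

from resourcescape.functional_diversity import (
    Dendrogram,
    DistanceMatrix,
    FDConvention,
    gower_distance,
    upgma,
)
from resourcescape.resource_model import (
    Category,
    Block,
    Kind,
    ResourceMatrix,
    ResourceSchema,
)


def small_schema() -> ResourceSchema:
    return ResourceSchema(
        (
            Category("strata_1", Block.FORAGING_STRATA, Kind.BINARY),
            Category("nest_1", Block.NEST_LOCATION, Kind.BINARY),
            Category("diet_1", Block.DIET, Kind.ORDINAL),
        )
    )


@pytest.fixture
def abc_matrix() -> ResourceMatrix:
    """Three components over (binary, binary, diet): the worked example with
    Gower distances d(A,B)=2/3, d(A,C)=8/9, d(B,C)=4/9."""
    return ResourceMatrix(
        schema=small_schema(),
        component_ids=["A", "B", "C"],
        provenance={"A": "native", "B": "native", "C": "exotic"},
        values=np.array([[1, 0, 3], [1, 1, 0], [0, 1, 1]]),
        component_kind="species",
    )


@pytest.fixture
def abc_tree(abc_matrix) -> Dendrogram:
    """UPGMA tree of the worked example: {B,C} at 4/9, root at 7/9."""
    return upgma(gower_distance(abc_matrix))


def random_tree(rng: np.random.Generator, n_leaves: int) -> Dendrogram:
    """UPGMA tree over random points; float distances make ties negligible."""
    pts = rng.random((n_leaves, 4))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    d /= max(d.max(), 1.0)
    ids = [f"L{i:03d}" for i in range(n_leaves)]
    return upgma(DistanceMatrix(ids=ids, d=d, ranges_used=np.ones(4)))


def fd_oracle(t: Dendrogram, present: set[str], conv: FDConvention) -> float:
    """Brute-force FD: union of root-ward edge paths of the present leaves,
    trimmed above their lowest common ancestor. Independent of the edge-count
    logic inside fd_subset."""
    n = t.n_leaves
    parent = {}
    for k, (a, b) in enumerate(t.children):
        parent[a] = n + k
        parent[b] = n + k
    leaf_of = {lid: i for i, lid in enumerate(t.leaf_ids)}

    def path_edges(node):
        out = []
        while node in parent:
            out.append(node)  # edge is identified by its child node
            node = parent[node]
        return out

    union: set[int] = set()
    paths = []
    for lid in present:
        p = path_edges(leaf_of[lid])
        paths.append(p)
        union.update(p)
    # edges common to every path lie above the LCA
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    edges = union if conv.include_root_path else union - common
    lengths = t.edge_lengths
    return float(sum(lengths[e] for e in edges))
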