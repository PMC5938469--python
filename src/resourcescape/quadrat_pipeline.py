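"""Per-quadrat assembly of the four FD/sFD measurements.

Each retained 10 x 10 km quadrat yields four functional diversities — native
community, exotic community, native landscape, exotic landscape — each
standardized against its occupancy-weighted null. Quadrats are filtered
first (sea cover, minimum component counts), and descriptive correlation
reports summarize how the four measurements covary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .functional_diversity import Dendrogram, FDConvention, fd_subset
from .null_models import (
    DEFAULT_N_ITER,
    NullDistribution,
    PoolWeights,
    null_fd_distribution,
    standardize_fd,
)

__all__ = [
    "QuadratTable",
    "filter_quadrats",
    "compute_quadrat_fd",
    "correlation_report",
    "read_quadrat_table",
    "write_quadrat_table",
]

# the four per-quadrat measurements: (field stem, component kind, provenance)
MEASUREMENTS = (
    ("community_native", "species", "native"),
    ("community_exotic", "species", "exotic"),
    ("landscape_native", "habitat", "native"),
    ("landscape_exotic", "habitat", "exotic"),
)


@dataclass
class QuadratTable:
    """Spatial grid of sampling units with occurrences and habitat presence."""

    ids: list[str]
    coords: np.ndarray  # (n, 2) centroid x, y in km
    effort: np.ndarray  # number of species lists per quadrat
    sea_fraction: np.ndarray
    species_present: list[set[str]]
    habitats_present: list[set[str]]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.effort = np.asarray(self.effort)
        self.sea_fraction = np.asarray(self.sea_fraction, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate quadrat ids")
        if len(np.unique(self.coords, axis=0)) != n:
            raise ValueError("duplicate quadrat coordinates")
        for name, arr in (("coords", self.coords), ("effort", self.effort),
                          ("sea_fraction", self.sea_fraction)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        if len(self.species_present) != n or len(self.habitats_present) != n:
            raise ValueError("presence list length mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep: np.ndarray) -> "QuadratTable":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return QuadratTable(
            ids=[self.ids[i] for i in idx],
            coords=self.coords[idx],
            effort=self.effort[idx],
            sea_fraction=self.sea_fraction[idx],
            species_present=[self.species_present[i] for i in idx],
            habitats_present=[self.habitats_present[i] for i in idx],
        )

    def species_weights(self, provenance: Mapping[str, str] | None = None,
                        group: str | None = None) -> PoolWeights:
        sets = self.species_present
        if provenance is not None and group is not None:
            sets = [{s for s in ss if provenance.get(s) == group} for ss in sets]
        return PoolWeights.from_occurrences(sets)

    def habitat_weights(self, provenance: Mapping[str, str] | None = None,
                        group: str | None = None) -> PoolWeights:
        sets = self.habitats_present
        if provenance is not None and group is not None:
            sets = [{h for h in hs if provenance.get(h) == group} for hs in sets]
        return PoolWeights.from_occurrences(sets)


def build_pools(
    species,
    habitats,
    q: "QuadratTable",
    combined_tree: bool = False,
) -> tuple[dict[str, Dendrogram], dict[str, PoolWeights]]:
    """Dendrograms and occupancy weights for the four measurement pools.

    Default: one UPGMA tree per provenance-specific pool (native species,
    exotic species, native habitats, exotic habitats), built once from the
    full pool matrix and reused for every quadrat. With *combined_tree* a
    single tree per component kind (all species / all habitats) is shared by
    both provenance groups. Occupancy weights are counted from *q*.
    """
    from .functional_diversity import gower_distance, upgma
    from .resource_model import split_by_provenance

    trees: dict[str, Dendrogram] = {}
    weights: dict[str, PoolWeights] = {}
    for stem, kind, prov in MEASUREMENTS:
        m = species if kind == "species" else habitats
        if combined_tree:
            tree = upgma(gower_distance(m))
        else:
            nat, exo = split_by_provenance(m)
            sub = nat if prov == "native" else exo
            if sub.n_components < 2:
                raise ValueError(f"pool {stem} has fewer than 2 components")
            tree = upgma(gower_distance(sub))
        trees[stem] = tree
        if kind == "species":
            weights[stem] = q.species_weights(m.provenance, prov)
        else:
            weights[stem] = q.habitat_weights(m.provenance, prov)
    return trees, weights


def read_quadrat_table(path: str | Path) -> QuadratTable:
    """Wide-format quadrat CSV: id, x_km, y_km, effort, sea_fraction,
    species (semicolon-joined), habitats (semicolon-joined)."""
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)

    def _split(cell: str) -> set[str]:
        return {s for s in str(cell).split(";") if s}

    return QuadratTable(
        ids=df["id"].tolist(),
        coords=df[["x_km", "y_km"]].to_numpy(float),
        effort=df["effort"].to_numpy(int),
        sea_fraction=df["sea_fraction"].to_numpy(float),
        species_present=[_split(c) for c in df["species"]],
        habitats_present=[_split(c) for c in df["habitats"]],
    )


def write_quadrat_table(q: QuadratTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": q.ids,
            "x_km": q.coords[:, 0],
            "y_km": q.coords[:, 1],
            "effort": q.effort,
            "sea_fraction": q.sea_fraction,
            "species": [";".join(sorted(s)) for s in q.species_present],
            "habitats": [";".join(sorted(h)) for h in q.habitats_present],
        }
    ).to_csv(path, index=False)


def filter_quadrats(
    q: QuadratTable,
    species_provenance: Mapping[str, str],
    habitat_provenance: Mapping[str, str],
    max_sea_fraction: float = 0.10,
    min_per_group: int = 2,
    per_provenance_group: bool = True,
) -> tuple[QuadratTable, dict[str, int]]:
    """Apply the quadrat inclusion rules; return (retained, exclusion log).

    Rules: sea cover at most *max_sea_fraction*; at least one species
    recorded; and at least *min_per_group* species and habitat types — by
    default within each provenance group (>=2 native and >=2 exotic of each
    kind), or in total when *per_provenance_group* is False.
    """
    keep = np.ones(q.n, dtype=bool)
    log = {"sea": 0, "no_species": 0, "min_components": 0}
    for i in range(q.n):
        if q.sea_fraction[i] > max_sea_fraction:
            keep[i] = False
            log["sea"] += 1
            continue
        sp, hb = q.species_present[i], q.habitats_present[i]
        if not sp:
            keep[i] = False
            log["no_species"] += 1
            continue
        if per_provenance_group:
            counts = [
                sum(1 for s in sp if species_provenance.get(s) == g)
                for g in ("native", "exotic")
            ] + [
                sum(1 for h in hb if habitat_provenance.get(h) == g)
                for g in ("native", "exotic")
            ]
        else:
            counts = [len(sp), len(hb)]
        if min(counts) < min_per_group:
            keep[i] = False
            log["min_components"] += 1
    if not keep.any():
        raise ValueError("no quadrats survive filters")
    return q.subset(keep), log


def compute_quadrat_fd(
    q: QuadratTable,
    trees: Mapping[str, Dendrogram],
    weights: Mapping[str, PoolWeights],
    species_provenance: Mapping[str, str],
    habitat_provenance: Mapping[str, str],
    conv: FDConvention = FDConvention(),
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per quadrat with richness, FD, and sFD for all four measurements.

    *trees* and *weights* are keyed by measurement stem ("community_native",
    "community_exotic", "landscape_native", "landscape_exotic"). Null
    distributions are cached per (measurement, richness): the null depends
    only on the pool and the number of components drawn, so quadrats of equal
    richness share one seeded distribution and results are independent of
    processing order. Undefined sFD (null SD = 0) is emitted as NaN.
    """
    null_cache: dict[tuple[str, int], NullDistribution] = {}
    count_cols = {
        "community_native": "richness_native",
        "community_exotic": "richness_exotic",
        "landscape_native": "n_native_habitats",
        "landscape_exotic": "n_exotic_habitats",
    }
    rows = []
    for i in range(q.n):
        row: dict[str, object] = {
            "id": q.ids[i],
            "x_km": q.coords[i, 0],
            "y_km": q.coords[i, 1],
            "effort": q.effort[i],
        }
        for stem, kind, prov in MEASUREMENTS:
            pool = q.species_present[i] if kind == "species" else q.habitats_present[i]
            provmap = species_provenance if kind == "species" else habitat_provenance
            members = sorted(s for s in pool if provmap.get(s) == prov)
            tree = trees[stem]
            unknown = [m for m in members if m not in tree.leaf_ids]
            if unknown:
                raise KeyError(
                    f"component(s) {unknown} of quadrat {q.ids[i]!r} absent "
                    f"from the {stem} pool tree"
                )
            k = len(members)
            row[count_cols[stem]] = k
            fd = fd_subset(tree, members, conv) if k >= 1 else np.nan
            row[f"fd_{stem}"] = fd
            if k >= 2:
                key = (stem, k)
                if key not in null_cache:
                    null_cache[key] = null_fd_distribution(
                        tree, weights[stem], k, n_iter=n_iter, conv=conv,
                        seed=seed, pool_id=stem,
                    )
                sfd = standardize_fd(fd, null_cache[key])
                row[f"sfd_{stem}"] = sfd.sfd if sfd.defined else np.nan
            else:
                row[f"sfd_{stem}"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["seed"] = seed
    out["n_iter"] = n_iter
    out["include_root_path"] = conv.include_root_path
    return out


def correlation_report(
    fd: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson correlations (with two-sided t-approximation p) per field pair.

    Incomplete cases are dropped per pair; zero-variance pairs are flagged
    with NaN rather than an error.
    """
    rows = []
    for a, b in pairs:
        sub = fd[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"fewer than 3 complete cases for ({a}, {b})")
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
            rows.append({"x": a, "y": b, "r": np.nan, "n": n, "p": np.nan,
                         "zero_variance": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"x": a, "y": b, "r": float(r), "n": n, "p": float(p),
                     "zero_variance": False})
    return pd.DataFrame(rows)
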