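"""Synthetic resource matrices, landscapes, and communities with known structure.

The generator emulates the shape of a national bird-atlas study: a pool of
62 native and 25 exotic species scored on 38 resource categories, 19 native
and 13 exotic habitat types on the same categories, a 10 km quadrat grid
with spatially autocorrelated habitat composition and survey effort, and
community assembly by occupancy-weighted draws with a tunable environmental
filtering strength. With filtering off, assembly IS the null process the
standardization uses, so sFD is calibrated around zero by construction;
positive filtering favours species functionally close to the resources the
quadrat provides, pushing sFD negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .null_models import _gumbel_topk
from .quadrat_pipeline import QuadratTable
from .resource_model import Kind, ResourceMatrix, default_schema
from .spatial_models import SpatialWeights

__all__ = [
    "SimulationConfig",
    "gen_resource_matrices",
    "gen_landscape",
    "gen_communities",
    "gen_sar_response",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; the dataset is a pure function of it."""

    n_native_species: int = 62
    n_exotic_species: int = 25
    n_native_habitats: int = 19
    n_exotic_habitats: int = 13
    grid_nx: int = 15
    grid_ny: int = 15
    quadrat_km: float = 10.0
    # environmental filtering strength per provenance group (0 = neutral)
    phi_native: float = 0.0
    phi_exotic: float = 0.0
    # latent trait-syndrome axes behind the diet block
    latent_axis_sd: float = 1.0
    # spatial range (km) of the Gaussian fields behind habitat composition
    habitat_spatial_range: float = 40.0
    # fraction of border quadrats given > 10% sea cover
    sea_border_fraction: float = 0.15
    # log-normal survey effort (number of checklists)
    effort_log_mean: float = 2.5
    effort_log_sd: float = 0.6
    # native-exotic richness coupling through a shared latent driver
    richness_coupling: float = 1.0
    # occupancy heterogeneity of the species pool (log-normal sd)
    occupancy_log_sd: float = 0.7
    # spatial-error response generator defaults
    sar_lambda: float = 0.6
    sar_beta: tuple[float, ...] = (1.0, 2.0, -1.0)
    sar_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_native_species, self.n_exotic_species,
               self.n_native_habitats, self.n_exotic_habitats) < 2:
            raise ValueError("pool sizes must be >= 2")
        if self.phi_native < 0 or self.phi_exotic < 0:
            raise ValueError("filtering strength must be >= 0")
        if abs(self.sar_lambda) >= 1:
            raise ValueError("|sar_lambda| must be < 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stage,))
        )


def _gen_matrix(rng: np.random.Generator, ids: list[str], provenance: dict[str, str],
                kind: str, latent_sd: float) -> ResourceMatrix:
    schema = default_schema()
    n = len(ids)
    values = np.zeros((n, len(schema)), dtype=int)
    binary = [i for i, c in enumerate(schema.categories) if c.kind is Kind.BINARY]
    diet = [i for i, c in enumerate(schema.categories) if c.kind is Kind.ORDINAL]
    prevalence = rng.uniform(0.2, 0.8, size=len(binary))
    values[:, binary] = rng.random((n, len(binary))) < prevalence[None, :]
    # three latent axes induce trait syndromes across the diet block
    z = rng.normal(0, latent_sd, size=(n, 3))
    loadings = rng.normal(0, 1, size=(3, len(diet)))
    score = z @ loadings + rng.normal(0, 1, size=(n, len(diet)))
    # map scores to ordinal 0-3 through fixed normal quantile cuts
    sd = np.sqrt(latent_sd**2 * (loadings**2).sum(axis=0) + 1.0)
    cuts = np.array([-0.8, 0.25, 1.1])  # skewed: 0 common, 3 rare
    lev = (score[:, :, None] > (cuts[None, None, :] * sd[None, :, None])).sum(axis=2)
    values[:, diet] = lev
    return ResourceMatrix(schema=schema, component_ids=ids, provenance=provenance,
                          values=values, component_kind=kind)


def gen_resource_matrices(cfg: SimulationConfig) -> tuple[ResourceMatrix, ResourceMatrix]:
    """Species resource-use and habitat resource-availability matrices."""
    sp_ids = [f"sp_n{i:02d}" for i in range(cfg.n_native_species)] + [
        f"sp_e{i:02d}" for i in range(cfg.n_exotic_species)
    ]
    sp_prov = {c: ("native" if c.startswith("sp_n") else "exotic") for c in sp_ids}
    hb_ids = [f"hb_n{i:02d}" for i in range(cfg.n_native_habitats)] + [
        f"hb_e{i:02d}" for i in range(cfg.n_exotic_habitats)
    ]
    hb_prov = {c: ("native" if c.startswith("hb_n") else "exotic") for c in hb_ids}
    species = _gen_matrix(cfg.rng(1), sp_ids, sp_prov, "species", cfg.latent_axis_sd)
    habitats = _gen_matrix(cfg.rng(2), hb_ids, hb_prov, "habitat", cfg.latent_axis_sd)
    return species, habitats


def grid_coords(cfg: SimulationConfig) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(cfg.grid_nx), np.arange(cfg.grid_ny), indexing="ij")
    return np.column_stack(
        [(xs.ravel() + 0.5) * cfg.quadrat_km, (ys.ravel() + 0.5) * cfg.quadrat_km]
    )


def _smooth_fields(rng: np.random.Generator, coords: np.ndarray, range_km: float,
                   n_fields: int) -> np.ndarray:
    """Standard-normal Gaussian fields with exponential covariance."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    cov = np.exp(-d / range_km) + 1e-8 * np.eye(len(coords))
    chol = np.linalg.cholesky(cov)
    return (chol @ rng.normal(size=(len(coords), n_fields)))


def gen_landscape(
    cfg: SimulationConfig, habitats: ResourceMatrix
) -> tuple[list[set[str]], np.ndarray, np.ndarray, np.ndarray]:
    """Habitat presence, sea fraction, and effort per quadrat.

    Each habitat's presence is a thresholded spatially autocorrelated
    Gaussian field; sea cover above the 10% filter threshold is placed on a
    fraction of border quadrats; effort is log-normal and spatially smooth.
    Returns (habitat sets, sea_fraction, effort, coords).
    """
    rng = cfg.rng(3)
    coords = grid_coords(cfg)
    nq = len(coords)
    fields = _smooth_fields(rng, coords, cfg.habitat_spatial_range,
                            habitats.n_components + 2)
    prevalence = rng.uniform(0.35, 0.75, size=habitats.n_components)
    from scipy.stats import norm

    thr = norm.ppf(1 - prevalence)
    present = fields[:, : habitats.n_components] > thr[None, :]
    hab_sets = [
        {habitats.component_ids[j] for j in np.flatnonzero(present[i])}
        for i in range(nq)
    ]
    # sea on the border
    ix, iy = coords[:, 0] // cfg.quadrat_km, coords[:, 1] // cfg.quadrat_km
    border = (ix == 0) | (iy == 0) | (ix == cfg.grid_nx - 1) | (iy == cfg.grid_ny - 1)
    sea = rng.uniform(0.0, 0.05, size=nq)
    sea_mask = border & (rng.random(nq) < cfg.sea_border_fraction)
    sea[sea_mask] = rng.uniform(0.11, 0.6, size=int(sea_mask.sum()))
    # spatially smooth log-normal effort
    effort = np.maximum(
        1, np.round(np.exp(cfg.effort_log_mean + cfg.effort_log_sd
                           * fields[:, habitats.n_components]))
    ).astype(int)
    return hab_sets, sea, effort, coords


def _cross_gower(species: ResourceMatrix, habitats: ResourceMatrix) -> np.ndarray:
    """Gower distance between every species row and habitat row, with ranges
    taken over the stacked matrices (shared schema makes them commensurate)."""
    xs = species.values.astype(float)
    xh = habitats.values.astype(float)
    both = np.vstack([xs, xh])
    r = both.max(axis=0) - both.min(axis=0)
    keep = r > 0
    a = xs[:, keep] / r[keep]
    b = xh[:, keep] / r[keep]
    return np.abs(a[:, None, :] - b[None, :, :]).mean(axis=2)


def gen_communities(
    cfg: SimulationConfig,
    species: ResourceMatrix,
    habitats: ResourceMatrix,
    hab_sets: list[set[str]],
    effort: np.ndarray,
    coords: np.ndarray,
) -> list[set[str]]:
    """Assemble one species set per quadrat.

    Richness per provenance group rises with a shared smooth latent driver
    (coupling native and exotic richness) and with survey effort. Given its
    richness, a group's members are drawn without replacement with weight
    base occupancy weight x exp(phi * overlap with the quadrat's resources),
    where overlap(s, q) = 1 - mean Gower distance between species s and the
    habitats present in q. phi = 0 is exactly occupancy-weighted random
    assembly — the same draw scheme the null models use.
    """
    rng = cfg.rng(4)
    nq = len(hab_sets)
    groups = {
        "native": [c for c in species.component_ids
                   if species.provenance[c] == "native"],
        "exotic": [c for c in species.component_ids
                   if species.provenance[c] == "exotic"],
    }
    phi = {"native": cfg.phi_native, "exotic": cfg.phi_exotic}
    sp_index = {c: i for i, c in enumerate(species.component_ids)}
    base_w = np.exp(rng.normal(0, cfg.occupancy_log_sd, size=species.n_components))
    driver = _smooth_fields(rng, coords, cfg.habitat_spatial_range, 1)[:, 0]
    log_eff = np.log(effort)
    eff_z = (log_eff - log_eff.mean()) / (log_eff.std() or 1.0)
    if cfg.phi_native > 0 or cfg.phi_exotic > 0:
        cross = _cross_gower(species, habitats)
        hb_index = {c: i for i, c in enumerate(habitats.component_ids)}
        overlap = [
            1.0 - cross[:, [hb_index[h] for h in hs]].mean(axis=1)
            if hs else np.zeros(species.n_components)
            for hs in hab_sets
        ]
    else:
        overlap = None
    communities: list[set[str]] = []
    for q in range(nq):
        chosen: set[str] = set()
        for grp, ids in groups.items():
            n_pool = len(ids)
            # richness: between 2 and the pool size, pushed up by the shared
            # driver and by effort
            logit = -0.6 + cfg.richness_coupling * 0.8 * driver[q] + 0.5 * eff_z[q]
            p_occ = 1.0 / (1.0 + np.exp(-logit))
            k = 2 + rng.binomial(n_pool - 2, p_occ * 0.45)
            idx = np.array([sp_index[c] for c in ids])
            w = base_w[idx].copy()
            if overlap is not None and phi[grp] > 0 and hab_sets[q]:
                # phi is in units of within-group SD of overlap, so its
                # strength does not depend on the trait-coding scale
                ov = overlap[q][idx]
                sd = ov.std()
                if sd > 0:
                    w = w * np.exp(phi[grp] * (ov - ov.mean()) / sd)
            pick = _gumbel_topk(w, k, 1, rng)[0]
            chosen.update(ids[i] for i in pick)
        communities.append(chosen)
    return communities


def gen_sar_response(
    X: np.ndarray,
    w: SpatialWeights,
    beta: np.ndarray,
    lam: float,
    sigma: float,
    seed: int,
) -> np.ndarray:
    """Draw y = X beta + (I - lam W)^(-1) eps with eps ~ N(0, sigma^2 I)."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = X.shape[0]
    eps = rng.normal(0, sigma, size=n)
    u = np.linalg.solve(np.eye(n) - lam * w.matrix, eps)
    return X @ beta + u


def simulate_dataset(cfg: SimulationConfig):
    """Full synthetic study: matrices plus a populated quadrat table."""
    species, habitats = gen_resource_matrices(cfg)
    hab_sets, sea, effort, coords = gen_landscape(cfg, habitats)
    communities = gen_communities(cfg, species, habitats, hab_sets, effort, coords)
    ids = [f"q{i:04d}" for i in range(len(coords))]
    table = QuadratTable(
        ids=ids,
        coords=coords,
        effort=effort,
        sea_fraction=sea,
        species_present=communities,
        habitats_present=hab_sets,
    )
    return species, habitats, table


def write_dataset(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the three input CSVs consumed by the pipeline."""
    from .quadrat_pipeline import write_quadrat_table
    from .resource_model import write_resource_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species, habitats, table = simulate_dataset(cfg)
    paths = {
        "species": out / "species_matrix.csv",
        "habitats": out / "habitat_matrix.csv",
        "quadrats": out / "quadrats.csv",
    }
    write_resource_matrix(species, paths["species"])
    write_resource_matrix(habitats, paths["habitats"])
    write_quadrat_table(table, paths["quadrats"])
    return paths
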