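#!/usr/bin/env python
"""Build the four functional dendrograms (native/exotic x species/habitat)
from the simulated resource matrices: Gower distances on the mixed
binary/ordinal categories, UPGMA clustering, Newick export.

Reads results/data/, writes results/trees/*.nwk and distance CSVs.
"""

from pathlib import Path

from resourcescape.functional_diversity import (
    gower_distance,
    total_length,
    upgma,
    write_newick,
)
from resourcescape.resource_model import read_resource_matrix, split_by_provenance

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "trees"
    out.mkdir(parents=True, exist_ok=True)
    species = read_resource_matrix(ROOT / "data" / "species_matrix.csv", "species")
    habitats = read_resource_matrix(ROOT / "data" / "habitat_matrix.csv", "habitat")
    for kind, matrix in (("species", species), ("habitat", habitats)):
        native, exotic = split_by_provenance(matrix)
        for prov, sub in (("native", native), ("exotic", exotic)):
            dm = gower_distance(sub)
            tree = upgma(dm)
            stem = f"{kind}_{prov}"
            dm.to_csv(out / f"{stem}_gower.csv")
            write_newick(tree, out / f"{stem}.nwk")
            print(
                f"{stem}: {sub.n_components} components, "
                f"total branch length {total_length(tree):.3f}"
            )


if __name__ == "__main__":
    main()
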