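#!/usr/bin/env python
"""Per-quadrat FD and occurrence-weighted null standardization (sFD) for
the four community/landscape measurements, plus the descriptive statistics:
richness/FD/sFD correlations between native and exotic communities and the
one-sample and paired t tests of sFD against its null expectation of zero.

Reads results/data/, writes results/quadrat_fd.csv and results/reports/.
"""

import json
import sys
from pathlib import Path

from resourcescape.null_models import one_sample_t, paired_t
from resourcescape.quadrat_pipeline import (
    build_pools,
    compute_quadrat_fd,
    correlation_report,
    filter_quadrats,
    read_quadrat_table,
)
from resourcescape.resource_model import read_resource_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0, n_iter: int = 1000) -> None:
    species = read_resource_matrix(ROOT / "data" / "species_matrix.csv", "species")
    habitats = read_resource_matrix(ROOT / "data" / "habitat_matrix.csv", "habitat")
    table = read_quadrat_table(ROOT / "data" / "quadrats.csv")
    kept, log = filter_quadrats(table, species.provenance, habitats.provenance)
    print(f"quadrats: {table.n} -> {kept.n} after filters {log}")
    trees, weights = build_pools(species, habitats, kept)
    fd = compute_quadrat_fd(
        kept, trees, weights, species.provenance, habitats.provenance,
        n_iter=n_iter, seed=seed,
    )
    fd.to_csv(ROOT / "quadrat_fd.csv", index=False)

    rep_dir = ROOT / "reports"
    rep_dir.mkdir(exist_ok=True)
    pairs = [
        ("richness_native", "richness_exotic"),
        ("fd_community_native", "fd_community_exotic"),
        ("sfd_community_native", "sfd_community_exotic"),
        ("fd_landscape_native", "fd_landscape_exotic"),
    ]
    corr = correlation_report(fd, pairs)
    corr.to_csv(rep_dir / "correlations.csv", index=False)
    print(corr.to_string(index=False))

    tests = {}
    for grp in ("native", "exotic"):
        vals = fd[f"sfd_community_{grp}"].dropna()
        t, df, p = one_sample_t(vals, 0.0)
        tests[f"one_sample_{grp}"] = {"mean_sfd": float(vals.mean()), "t": t,
                                      "df": df, "p": p}
        print(f"sFD {grp} community: mean {vals.mean():+.3f}, t = {t:.2f}, p = {p:.3g}")
    sub = fd[["sfd_community_native", "sfd_community_exotic"]].dropna()
    t, df, p = paired_t(sub["sfd_community_native"], sub["sfd_community_exotic"])
    tests["paired_native_minus_exotic"] = {"t": t, "df": df, "p": p}
    print(f"paired t (native - exotic sFD): t = {t:.2f}, p = {p:.3g}")
    (rep_dir / "sfd_t_tests.json").write_text(json.dumps(tests, indent=2))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
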