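#!/usr/bin/env python
"""Hierarchical partitioning of the variance not attributable to the
spatial component, and the habitat vs functional-diversity model-type
comparison table (per-term beta, Z, LMG R^2 share; per-model AIC and total
R^2 excluding effort).

Reads results/models/*.json + results/quadrat_fd.csv, writes
results/model_comparison.csv.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from resourcescape.spatial_models import build_weights, fit_sar_error
from resourcescape.variance_partition import (
    PartitionResult,
    compare_model_types,
    despatialize,
    lmg_shares,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(threshold_km: float = 35.0) -> None:
    fd = pd.read_csv(ROOT / "quadrat_fd.csv")
    fd["log_effort"] = np.log(fd["effort"])
    fits = {}
    for path in sorted((ROOT / "models").glob("*__*.json")):
        spec = json.loads(path.read_text())
        response, mtype = spec["response"], spec["model_type"]
        needed = [c for c in spec["terms"] if c != "intercept"]
        sub = fd.dropna(subset=[response] + needed)
        wsub = build_weights(sub[["x_km", "y_km"]].to_numpy(), threshold_km)
        y = sub[response].to_numpy(float)
        X = sub[needed].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_sar_error(y, X, wsub, transform=spec["transform"])
            y_adj = despatialize(fit, y, X, wsub)
            if needed:
                part = lmg_shares(y_adj, X[needed], protected=["log_effort"])
            else:  # every landscape term eliminated: nothing to partition
                part = PartitionResult(shares={}, full_r2=0.0,
                                       total_r2_excluding_protected=0.0,
                                       protected=())
        fits[(response, mtype)] = (fit, part)
    cmp = compare_model_types(fits)
    table = cmp.table.merge(cmp.summary, on=["response", "model_type"])
    table.to_csv(ROOT / "model_comparison.csv", index=False)
    print(
        cmp.summary.sort_values(["response", "model_type"])
        .round(2)
        .to_string(index=False)
    )
    wins = cmp.summary.groupby("model_type")["wins_by_aic"].sum()
    print("\nAIC wins by model type:")
    print(wins.to_string())


if __name__ == "__main__":
    main()
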