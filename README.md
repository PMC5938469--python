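# resourcescape

Functional characterization of landscapes and the communities they hold.

Community ecologists routinely describe bird communities by functional
diversity — how much trait space the species present span — but describe
the landscapes those communities occupy by typological habitat counts.
`resourcescape` puts both on the same currency: habitats are scored for the
*resources they make available* on the same 38-category grid (6 foraging
strata, 7 nest locations, 25 diet items scored 0–3) used to score species'
*resource use*, so a landscape has a functional diversity in exactly the
sense a community does. The package implements the full analysis chain on
that idea, with a synthetic-data generator with known structure as its
test bed. It is aimed at community ecologists and biodiversity-informatics
developers who want a tested, seedable reference implementation of this
pipeline.

## The pipeline

1. **Distances and dendrograms.** Mixed binary/ordinal trait matrices →
   Gower distances, d(i,j) = mean over informative categories of
   |x_ik − x_jk| / r_k → UPGMA dendrogram per pool (native/exotic ×
   species/habitats).
2. **Functional diversity.** FD of the components present in a quadrat is
   the total branch length of the minimal subtree connecting them
   (Petchey–Gaston branch-length FD). Four measurements per 10 × 10 km
   quadrat: native/exotic community FD and native/exotic landscape FD.
3. **Null standardization.** FD rises with richness, so each observed FD is
   standardized against 1,000 random same-richness draws from its pool,
   weighted by occupancy so rare components don't dominate:
   sFD = (FD − E[FD_null]) / SD[FD_null]. sFD < 0 means co-occurring
   components are more functionally similar than chance — environmental
   filtering.
4. **Spatial regression.** Community metrics are regressed on landscape
   characteristics with maximum-likelihood SAR spatial-error models
   (y = Xβ + u, u = λWu + ε) on 35-km distance-band weights, with
   log(effort) as a protected covariate and backward likelihood-ratio
   elimination at 5%.
5. **Variance partitioning.** After removing the fitted spatial component,
   predictor importance is the exact LMG/Shapley decomposition of R², and
   habitat-count models are compared with landscape-FD models by AIC and
   total R² (excluding effort).

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on
synthetic data (87 species, 32 habitat types, 15 × 15 quadrat grid,
filtering stronger on the exotic community):

```
$ python analysis/01_simulate.py
$ python analysis/02_functional_diversity.py
species_native: 62 components, total branch length 17.712
species_exotic: 25 components, total branch length 7.679
habitat_native: 19 components, total branch length 6.201
habitat_exotic: 13 components, total branch length 4.078
$ python analysis/03_null_standardization.py
quadrats: 225 -> 216 after filters {'sea': 9, 'no_species': 0, 'min_components': 0}
...
     richness_native      richness_exotic 0.571568 216 3.927541e-20
sFD native community: mean -0.265, t = -3.91, p = 0.000125
sFD exotic community: mean -0.398, t = -5.98, p = 9.35e-09
```

Reading this: nine border quadrats fail the 10%-sea filter; native and
exotic richness are positively correlated (r = 0.57) through their shared
environmental driver; and both communities sit significantly below their
null expectation (negative mean sFD), with the exotic community — built
with the stronger filtering parameter — further below. Scripts 04 and 05
then fit the SAR models for each response and model type and write the
comparison table (per-term β, Z, LMG R² share, AIC, total R²) to
`results/model_comparison.csv`; on this neutral-landscape simulation most
landscape terms are eliminated, which is the honest outcome at ~200
quadrats (see `docs/methods.md` on power).

Library use mirrors the scripts:

```python
from resourcescape.synthetic_data import SimulationConfig
from resourcescape.workflows import run_fd_study, filtering_tests

study = run_fd_study(SimulationConfig(seed=0, phi_native=1.5, phi_exotic=3.0))
print(filtering_tests(study.fd)["exotic"])   # {'mean_sfd': -0.398..., 't': -5.98..., ...}
```

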