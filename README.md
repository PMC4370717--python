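# agribirds

Tools for analysing how farmland bird communities respond to agricultural
intensity and to its spatial arrangement, built around the design of the
French Breeding Bird Survey (FBBS) and farm-accounting intensity data.

## The scientific problem

Whether conservation money is best spent in extensively or intensively
farmed regions depends on the *shape* of the biodiversity–intensity
relationship, and on whether the intensity of the *surrounding* regions
modulates it. This package implements a complete pipeline for that
question at national scale:

* **Agricultural intensity** is measured per Small Agricultural Region
  (SAR) as *Input Cost per hectare* (IC/ha, €/ha): the sum of seven
  input-cost categories (fertilizers, feedstuff, pesticides, seeds, fuel,
  veterinary products, irrigation water) over the farms of five
  production types, divided by their utilised agricultural area, averaged
  over three accounting years.
* **Spatial aggregation** of intensity is the difference between a
  region's intensity and the mean of its contiguous neighbours,

  AI_i = X_i − (Σ_j w_ij X_j) / (Σ_j w_ij),

  with *w* the binary contiguity matrix; regions with |AI| below the mean
  |AI| sit in neighbourhoods of similar intensity and are classed
  *aggregated*. Moran's I (with distance-class correlograms and
  permutation tests) quantifies the spatial structure.
* **The bird community** is summarised per 2 × 2 km survey square by four
  descriptors: species richness and three abundance-weighted trait means
  over a 22-species farmland community —

  CSI = Σ_i (N_i/N_tot)·SSI_i,  CTI = Σ_i (N_i/N_tot)·STI_i,
  CSIg = Σ_i (N_i/N_tot)·SSIg_i,

  where SSI is the coefficient of variation of a species' density across
  seven habitat classes (habitat specialisation), STI a diet-weighted
  trophic score in [1, 3], and SSIg a grassland-use score in [1, 4]
  (4 = unimproved grassland … 1 = arable). Counts follow the FBBS rules:
  five farmland points per square, maximum of the two spring visits,
  summed per square, averaged over surveyed years.
* **Models**: each descriptor is regressed on intensity (a natural cubic
  regression spline with 2 fixed degrees of freedom), altitude, land-use
  and climate covariates, with backward stepwise AIC selection,
  leave-one-out cross-validation error, and residual checks including a
  Moran permutation test between adjacent SARs; a linear model with an
  IC/ha × aggregation interaction estimates how aggregation shifts the
  intercept and slope of the intensity effect.

The national FBBS and farm-accounting datasets are not redistributable,
so the package includes a first-class synthetic generator
(`agribirds.synthetic_data`) that emulates their full structure — a
spatially autocorrelated intensity field on a SAR lattice, farm records
that reproduce it exactly, point-count records with winner/loser species
responses and a plantable neighbourhood-intensity interaction, and
covariate tables — making every stage testable end to end.

## Worked example

```python
import pandas as pd
from agribirds.synthetic_data import ScenarioConfig, generate_landscape, \
    generate_counts, generate_covariates
from agribirds.pipeline import run_analysis

cfg = ScenarioConfig(seed=1)          # 152 SARs, 332 sites, 22 species
ls = generate_landscape(cfg)
tables = dict(counts=generate_counts(cfg, ls), farms=ls.farms,
              edges=pd.DataFrame(ls.edges, columns=["unit_a", "unit_b"]),
              **generate_covariates(cfg, ls))
res = run_analysis(tables, seed=1)

print(res["sar_table"]["ic_per_ha"].mean())   # 405.1  (€/ha, generator target)
print(res["cv_errors"]["csig"])               # 0.86   (LOO-CV error, % of mean CSIg)
tt = res["fits"]["csig"].term_tests.set_index("term")
print(tt.loc["s(ic_per_ha)", "value"])        # 42.68  (F statistic of the smooth)
```

The mean IC/ha of 405.1 €/ha confirms the farm records reproduce the
planted intensity field; the CSIg model's smooth-intensity F of 42.7
reflects the strong convex-declining response of grassland specialists
programmed into the default scenario, and its ~1% cross-validation error
the low observation noise of the aggregated descriptor.

The same pipeline runs from the shell on delimited-text tables:

```bash
agribirds simulate --seed 1 --out scenario/
agribirds validate scenario/
agribirds run-all scenario/ --seed 1 --out results/
```

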