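# wcscomm

Community-composition analysis and predictive modelling of wildlife
crossing structure (WCS) use from camera-trap data.

Wildlife crossing structures — underpasses and overpasses that let
animals cross roads safely — are usually designed for a target species
but used by a whole mammal community. `wcscomm` asks which
characteristics of a crossing structure shape that community, and
predicts the expected species assemblage at structures that have not
been built yet. It implements, end to end:

1. **Event processing** — camera-trap photos of one species at one
   structure are chained into independent events while consecutive gaps
   are ≤ 30 minutes; each event is classified from per-individual
   interaction codes (A successful crossing, B entry/exit, C approach,
   D detection only, E day bed) and summarised as three monthly
   per-day rate matrices: total detections, successful crossings (Σ A)
   and failed crossings (Σ B + C + E).
2. **Community dissimilarity** — square-root transform, then
   zero-adjusted Bray–Curtis with a dummy-species constant d = 0.03
   (one detection in a 31-day month), so empty site-months compare as
   identical rather than undefined:
   `BC(x, y) = Σ|xᵢ − yᵢ| / (Σ(xᵢ + yᵢ) + 2d)`.
3. **Spatial/temporal eigenfunctions** — distance-based Moran's
   eigenvector maps (dbMEM/PCNM): PCO of a truncated distance matrix
   (threshold = longest minimum-spanning-tree edge, off-graph distances
   → 4t), giving orthogonal predictors ordered from broad to fine
   scale, with per-axis Moran's I.
4. **Predictor screening** — openness ratio `(height × width) / length`,
   log(x+1) transforms for skewed covariates, dummy coding (substrate
   with water as reference), VIF, AICc forward selection (dbMEM axes,
   then each predictor set conditioned on the spatial/temporal base),
   and PRESS-vs-SSE comparison of competing models.
5. **dbRDA and variation partitioning** — R² on total positive inertia
   of the PCO, Ezekiel's adjusted R² `1 − (1−R²)(n−1)/(n−p−1)`,
   permutation tests (Freedman–Lane for partial models), and the full
   2⁵−1 = 31-fraction inclusion–exclusion partition over the spatial,
   temporal, structural, environmental and anthropogenic predictor
   sets. Negative fractions are reported as-is.
6. **Predictive model (MRPC)** — OLS regression of retained PCO axes on
   mean-centred predictors using raw UTM coordinates and month (so the
   model extends to new sites), drop-one-site cross-validation with
   five Mantel correlations (M1–M5) between observed, fitted and
   predicted configurations, residual diagnostics (per-axis ACF, Mantel
   correlogram), and inverse-distance-weighted assemblage profiles for
   predicted sites.

A seeded synthetic-data generator emulates the motivating study design
(18 structures × ~a year of months × ~20 medium-large mammal species,
covariates drawn at the published means/SDs) with configurable
per-predictor-set effect sizes, spatial/temporal autocorrelation and
negative-binomial counts, so every stage is testable without any field
data.

## Worked example

```python
import numpy as np, pandas as pd
from wcscomm.synthetic import (SimulationConfig, generate_site_covariates,
                               generate_monthly_covariates, generate_counts)
from wcscomm.pipeline import partition_workflow

cfg = SimulationConfig(n_sites=12, n_months=10, n_species=12, seed=42)
sites = generate_site_covariates(cfg)
monthly = generate_monthly_covariates(cfg)
counts, truth = generate_counts(cfg, sites, monthly)
days = pd.PeriodIndex(counts.index.get_level_values(1), freq="M").days_in_month
rates = counts.div(np.asarray(days, dtype=float), axis=0)

result = partition_workflow(rates, sites, monthly, n_perm=199, seed=1)
for lab in result.set_labels:
    row = result.set_tests[result.set_tests["set"] == lab].iloc[0]
    print(f"{lab:<14s} unique={result.unique_fraction(lab)*100:6.2f}%  "
          f"F={row['pseudo_F']:.2f}  p={row['p_value']:.3f}")
print(f"residual       {result.residual*100:6.2f}%")
```

prints

```
spatial        unique=  5.58%  F=3.05  p=0.005
temporal       unique=  0.71%  F=2.01  p=0.010
structural     unique=  1.59%  F=2.15  p=0.005
environmental  unique=  1.83%  F=2.32  p=0.005
anthropogenic  unique=  2.51%  F=2.22  p=0.005
residual        75.45%
```

Each `unique` value is the exclusive share of community variation
(adjusted-R² scale) attributable to that predictor set after accounting
for all overlaps with the other four; the pseudo-F and permutation p
test each set conditionally on the others. Most variation in noisy
monthly count data is residual, as expected for camera-trap
communities.

The full pipeline — photos → events → matrices → dissimilarity → dbMEM
→ screening → partition → predictive model → validation — runs from a
YAML config:

```bash
wcscomm simulate --seed 1 --out data/
wcscomm run --config run.yaml
wcscomm report --run-dir run/
```

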