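# soilrisk

Ecological analysis of topsoil trace-element exposure and small-area
cancer mortality under **spatial misalignment**: soil concentrations are
measured at scattered sampling points, deaths are counted by
municipality, and the two must be linked through a spatial model.

The package is aimed at spatial epidemiologists and biostatisticians who
want a tested, reproducible implementation of the full chain:

1. **Indirect standardisation** — expected deaths per town from reference
   rates over 18 age groups × 2 sexes × 2 five-year periods
   (person-years = mid-period population × 5).
2. **Approach A (plug-in)** — ordinary kriging of log concentrations onto
   municipal centroids (variogram fitting, k-nearest-neighbour kriging
   with retained kriging variance), then a Bayesian Poisson ecological
   regression with Besag–York–Mollié random effects:

       O_i ~ Poisson(E_i λ_i)
       log λ_i = α + β·expos_i + Σ_j δ_j Soc_ij + γ·Indus_i + u_i + v_i

   with exposure coded as quartiles (q1 reference), as the quartile
   ordinal (trend test), or as continuous log concentration.
3. **Approach B (joint)** — the latent Matérn (ν = 1) concentration field
   is represented by its SPDE precision on a triangulated mesh (with a
   coarser boundary-extension ring) and estimated *jointly* with the
   disease model, so the uncertainty of the centroid exposure widens the
   credible interval of β instead of being ignored.
4. **Emitter contrast** — the posterior difference (uninformative priors)
   of mean concentration between towns with and without an industrial
   emitter within 5 km.

All posteriors come from an in-package adaptive HMC sampler with analytic
gradients and arviz convergence diagnostics; every run is reproducible by
seed. A synthetic-data module generates a full study universe with known
ground truth (grid municipalities, density-stratified sampling points,
log-normal concentrations over an exact Matérn field draw, Poisson
deaths), so every stage can be validated by parameter recovery.

## Worked example

```python
import numpy as np
from soilrisk import (
    SimConfig, GroundTruth, MaternFieldParams, simulate_universe,
    OrdinaryKriging, BymSpec, McmcConfig, fit_bym,
)

truth = GroundTruth(beta=np.log(1.2), sigma_u=0.1, sigma_v=0.1,
                    field=MaternFieldParams(practical_range=20.0, marginal_sd=0.6),
                    sigma_x=0.3)
uni = simulate_universe(SimConfig(nx=10, ny=10, n_samples=300, truth=truth), seed=11)

ok = OrdinaryKriging(n_neighbors=64)
ok.fit(uni.samples[["x_km", "y_km"]].to_numpy(),
       uni.samples["log_concentration"].to_numpy())
areas = uni.areas.assign(expos=ok.predict(uni.areas[["x_km", "y_km"]].to_numpy()))

spec = BymSpec(adjacency=uni.adjacency, exposure_coding="continuous_log")
fit = fit_bym(areas, spec, McmcConfig(n_warmup=400, n_draws=400), seed=1)
print(fit.rr_table.round(3).loc["beta"])
```

```
rr             1.199
median         1.195
q2.5           1.109
q97.5          1.307
significant     True
Name: beta, dtype: object
```

The row reads: per unit increase in log soil concentration the relative
risk of death is 1.199 (95% credibility interval 1.11–1.31) — covering
the generating value RR = 1.2 — and the interval excludes 1, so the
association is flagged. `fit.summary` carries the posterior of every
reported parameter, `fit.area_rr` the smoothed per-town relative risks,
and `fit.diagnostics` split R-hat / ESS.

The same analysis runs from the shell:

```bash
soilrisk run-all --seed 7 --outdir runs/demo
```

which writes the universe tables, standardised expected deaths, kriged
exposures, mesh, the approach-A (quartile, trend, continuous) and
approach-B fits as a single `rr_table.csv`, the emitter group comparison,
and a manifest of stage seeds and hashes. Rerunning with the same config
is byte-identical and skips completed stages.

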