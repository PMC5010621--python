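# Methods

This note records the statistical models implemented in `soilrisk`, the
choices made where the design was genuinely open, and what the synthetic
study universe does and does not emulate.

## Study design being emulated

The package targets a common ecological design in environmental
epidemiology: trace-element concentrations (e.g. arsenic or chromium,
mg kg⁻¹) are measured in topsoil at irregular point locations, while
cancer deaths are counted by municipality. The exposure of interest for
town *i* is the log soil concentration at its centroid, which is never
observed directly — the data are *spatially misaligned*. Two estimation
strategies are implemented:

- **Approach A (plug-in):** ordinary kriging interpolates log
  concentrations to centroids; the kriged value enters a Bayesian Poisson
  ecological regression as a known covariate. Simple, but the kriging
  error is ignored.
- **Approach B (joint):** the latent concentration field and the disease
  model are estimated jointly, with the field represented on a
  finite-element mesh through its SPDE precision. The centroid exposure
  is then a latent quantity whose posterior spread propagates into the
  credible interval of the exposure effect, which is therefore more
  conservative than the plug-in interval.

## Models

### Disease model (BYM)

For area *i* with observed deaths `O_i` and expected deaths `E_i`:

    O_i ~ Poisson(E_i λ_i)
    log λ_i = α + β·expos_i + Σ_j δ_j Soc_ij + γ·Indus_i + u_i + v_i

`u` is an intrinsic CAR (ICAR) effect on the municipal adjacency graph
with a sum-to-zero constraint per connected component, `v` is iid normal
(the Besag–York–Mollié decomposition). Exposure codings: quartile dummies
with the first quartile as reference, the quartile ordinal as a continuous
covariate (trend test, RR per quartile step), or the continuous log
concentration. The joint model supports only the continuous coding — a
factor coding of a latent Gaussian variable is not meaningful.

Quartile cut points use the linear-interpolation percentile rule (numpy
default, type 7); intervals are `[low, high)` except the last, closed.
A 95% credibility interval flags significance only by strict exclusion of
RR = 1.

### Exposure model

Observed log concentrations at sampling points `s_j`:

    log c_j ~ Normal(x(s_j), σ_x²)

where `x(·)` is a stationary Matérn Gaussian field with smoothness ν = 1
(the standard two-dimensional SPDE choice, which keeps the precision
assembly closed-form), parameterised by the practical range
ρ = √8/κ (km) and the marginal SD. The SPDE discretisation uses
piecewise-linear finite elements with a lumped (diagonal) mass matrix C
and stiffness matrix G:

    Q = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G),   σ² = 1/(4π κ² τ²)

Mesh construction caps interior edge lengths at a configured maximum and
surrounds the domain with a coarser extension ring so the SPDE boundary
conditions do not distort the field inside the study region (defaults:
extension width ≈ 1–2 field ranges, exterior edges 3× interior). A mesh
resolution can also be chosen from candidate edge lengths by an
information criterion (DIC by default, WAIC optional) computed on a
closed-form Gaussian field-only fit; with a 2-point tolerance the
coarsest adequate mesh is kept. This selection rule is a reconstruction
of common practice, not a reproduction of any specific published setting.

### Inference

All Bayesian models are fitted with an in-package adaptive Hamiltonian
Monte Carlo sampler (analytic gradients, dual-averaging step size
targeting 0.8 acceptance, diagonal mass matrix adapted during warmup,
jittered trajectory lengths, 2 chains by default). Random effects and the
field are non-centred in their scale parameters; the ICAR uses the
pairwise-difference density with a soft sum-to-zero constraint
(per-component sum ~ Normal(0, 0.001·n)). Design columns are centred
internally and the intercept is shifted back on report. Convergence is
monitored by split R-hat and bulk ESS (arviz); any reported parameter
with R-hat > 1.05 flags the fit as non-converged rather than failing
silently. Chains are exactly reproducible given a seed.

Priors (all exposed in config):

- fixed effects: Normal(0, 10²)
- σ_u, σ_v (random-effect SDs): half-Normal(1)
- σ_x (measurement error SD): half-Normal(1)
- field practical range: penalised-complexity-type prior with
  P(ρ < ρ₀/2) = 0.05, where ρ₀ is the configured initial range
- field marginal SD: exponential with P(σ > 2σ₀) = 0.05

These are reconstructions of standard weakly-informative practice; the
published analyses this design mirrors do not state their priors.

### Indirect standardisation

Expected deaths per town and sex are Σ over strata of (reference rate ×
person-years), with 18 age groups × 2 sexes × 2 five-year periods and
person-years = mid-period population × 5. With rates derived internally
from the study data themselves, Σ E_i = Σ O_i exactly per sex, a
conservation identity used as a correctness check. Sexes are standardised
and modelled separately throughout. Strata that are empty in a small
universe get rate 0 with a logged warning instead of failing.

### Group contrast at emitters

The difference in mean concentration (mg kg⁻¹) between towns with and
without an industrial emitter within 5 km (closed boundary: exactly
5 km counts) is summarised by the posterior of μ_a − μ_b under
independent normal models with a flat prior on each mean and Jeffreys
prior on each SD — each group mean then has an exact scaled Student-t
posterior, whose large-n limit is the Welch interval. A robust Student-t
(ν = 4) likelihood is available as an option. By default the comparison
uses the interpolated municipal concentrations.

## Synthetic study universe

The generator produces, at desk scale, data with exactly the structure
the analysis assumes: a 20 × 20 grid of 5 km cells (400 "towns" over
100 × 100 km; rook adjacency) standing in for thousands of municipalities,
and ~1,500 sampling points in three density strata with relative
densities 10:5:1 (emulating survey designs of roughly one point per 10,
20 and 100 km²). Concentrations are log-normal around one exact draw of
the Matérn field (dense Cholesky over samples and centroids jointly),
with defaults range 20 km, marginal SD 0.6, σ_x = 0.3 and mean log
concentration 3 (≈ 20 mg kg⁻¹) — plausible magnitudes chosen once as
configuration, not as claims about any real element, since the real
fields' variance and range are not published. Deaths are drawn from the
Poisson BYM model above, with expected counts built from a fixed
Gompertz-type age schedule of baseline rates and log-normal town
populations (median ≈ 3,000, giving E_i of order 20 per sex over the
study decade). Emitters are scattered uniformly; optionally the local
log-concentration mean is shifted upward within 5 km of an emitter to
mimic a contamination signal.

What the generator does **not** emulate: real geography (polygons,
coastlines, islands), non-stationarity or anisotropy of the field,
compositional constraints between elements, population migration, and
age–period–cohort structure. Passing recovery tests therefore show the
estimators are correct under their own assumptions at desk scale, not
that those assumptions hold for any particular national dataset.

## Numerical choices

- Matérn correlation uses the exact Bessel form; field simulation is
  exact via dense Cholesky with a 1e-10 diagonal jitter; coincident
  locations with zero nugget raise with the offending pair named.
- Kriging solves the covariance-form system with a Lagrange multiplier;
  the cross-covariance to the target excludes the nugget, so prediction
  at a sampled site is exact iff the nugget is zero and the kriging
  variance there equals zero iff the nugget is zero. Neighbourhoods are
  the k nearest samples (default 64; ties broken by sample order); the
  global dense solve is retained and used as the oracle in tests.
- Variogram fitting is weighted least squares (weights = pair counts)
  with a deterministic multistart over the range scale; fits pinned at a
  bound, or with a range below the smallest lag (pure-nugget
  degeneracy), are flagged.
- Mesh refinement inserts midpoints of over-long interior edges, nudged
  slightly off the segment because exactly collinear points are dropped
  by the Delaunay backend.
- The SPDE log-determinant uses the factorisation
  Q = τ²(κ²C + G)C⁻¹(κ²C + G): with eigenvalues of C^{-1/2}GC^{-1/2}
  precomputed once, log det Q is a cheap function of (κ, τ) inside HMC.
- Degenerate inputs fail loudly: all-zero expected counts, rank-deficient
  design matrices, quartiles collapsed by ties, self-intersecting domain
  polygons, points outside the mesh in strict mode.

## Problem sizes used by tests and the acceptance script

Simulation studies run at reduced scale chosen to make Monte Carlo checks
stable: 400 areas for BYM recovery (40 replicates, 400 warmup/500 draws ×
2 chains), 10 replicates for the trend test, and 20 paired replicates of
a 64-area universe (2 chains × 400 warmup/400 draws) for the plug-in vs
joint contrast; the SPDE fidelity check uses a 2.5 km mesh over
100 × 100 km. The paired
A/B battery samples at ~1 point per 30 km² — the average density of the
national geochemical survey being emulated — because the conservatism
contract (joint intervals at least as wide as plug-in) is a statement
about ignored interpolation error: at much denser sampling the kriging
error vanishes and the two approaches coincide, while the plug-in's
smoothed (lower-variance) exposure can even make its intervals the wider
ones. The battery's generating effect (RR 1.4 per unit log
concentration) is set large enough to be detectable at that density, as
the sign-concordance readout presupposes an association both approaches
can find. Chain lengths in the battery matter for the readout itself:
the joint posterior of β has heavy tails driven by field-hyperparameter
uncertainty, and short single chains truncate approach B's measured
interval width; the battery therefore uses two chains of 400 warmup/400
draws per fit. Full-country problem sizes are explicitly out of scope.

## Known limitations

- The hyperparameters of the field (range, SD) are weakly identified on
  domains spanning only a few correlation ranges; their chains mix more
  slowly than the regression parameters (R-hat on the range can exceed
  1.05 at short chain lengths; the exposure effect β is robust to this).
- The field mean μ_x and the overall field level trade off; only their
  sum is strongly identified. This does not affect β.
- The ICAR soft sum-to-zero constraint is a numerical device; constraint
  violations are of order 0.001·n in the raw scale.
- Areal exposure is the centroid value of the field, not an areal
  average (matching the construction being emulated); averaging over
  polygons is a possible extension, off by default.
- No multiplicity correction is applied across cancer sites or sexes;
  fits are independent per site and sex by design.
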