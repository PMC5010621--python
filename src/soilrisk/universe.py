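"""Synthetic study universe with known ground truth.

Emulates, at desk scale, a national ecological study design: a planar
domain partitioned into municipal areas (a regular grid of cells standing
in for town polygons), a set of topsoil sampling points with three
sampling-density strata, a latent Matérn log-concentration field observed
with measurement error at the sampling points, and per-area cancer death
counts generated from a Poisson log-linear relative-risk model with
spatially structured (ICAR) and unstructured random effects.

Everything random is driven by an explicit seed and the generating
parameters are returned as ground truth, so parameter-recovery tests can
compare estimates against the values that produced the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .fields import MaternFieldParams, simulate_matern_field

AGE_GROUPS = [f"{5 * k}-{5 * k + 4}" for k in range(17)] + ["85+"]
SEXES = ["men", "women"]
PERIODS = ["p1", "p2"]

#: Baseline annual mortality rates per person by age group (single cancer
#: site); a Gompertz-like schedule rising from ~1e-6 in childhood to ~7e-3
#: at 85+, the shape typical of adult solid tumours.
_AGE_MIDPOINTS = np.array([2.5 + 5 * k for k in range(17)] + [90.0])
BASE_RATES = 3.5e-6 * np.exp(0.095 * _AGE_MIDPOINTS)

#: Fixed age pyramid (fraction of population per age group), roughly a
#: southern-European municipal profile.
AGE_PYRAMID = np.exp(-0.5 * ((_AGE_MIDPOINTS - 35.0) / 28.0) ** 2)
AGE_PYRAMID = AGE_PYRAMID / AGE_PYRAMID.sum()

INDUSTRY_RADIUS_KM = 5.0  # closed boundary: distance <= 5 km flags an area


@dataclass
class GroundTruth:
    """Generating parameters of the synthetic universe.

    ``u`` and ``v`` are filled in by :func:`simulate_universe`;
    ``delta`` maps covariate name to its log-RR coefficient.
    """

    alpha: float = 0.0
    beta: float = 0.0
    delta: dict = dc_field(default_factory=dict)
    gamma: float = 0.0
    sigma_u: float = 0.1
    sigma_v: float = 0.1
    field: MaternFieldParams = dc_field(
        default_factory=lambda: MaternFieldParams(practical_range=20.0, marginal_sd=0.6)
    )
    sigma_x: float = 0.3
    mu_log_conc: float = 3.0
    u: np.ndarray | None = None
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.sigma_u, self.sigma_v, self.sigma_x) < 0:
            raise ValueError("sigma_u, sigma_v, sigma_x must be >= 0")


@dataclass
class SimConfig:
    """Configuration of the synthetic universe.

    The default 20 x 20 grid of 5 km cells (400 areas over a 100 x 100 km
    domain) with ~1,500 sampling points is a reduced-scale stand-in for a
    national study of thousands of towns and >10^4 soil samples.  The three
    sampling-density strata mimic survey designs with nominal densities of
    one point per 10, 20 and 100 km^2 (relative weights 10:5:1).
    """

    nx: int = 20
    ny: int = 20
    cell_km: float = 5.0
    n_samples: int = 1500
    density_weights: tuple = (10.0, 5.0, 1.0)
    mean_population: float = 3000.0
    population_sd_log: float = 0.8
    emitter_fraction: float = 0.05
    emitter_log_shift: float = 0.0
    truth: GroundTruth = dc_field(default_factory=GroundTruth)


@dataclass
class StudyUniverse:
    """A complete synthetic study: areas, samples, and the generating truth."""

    domain_bbox: tuple  # (xmin, ymin, xmax, ymax) in km
    areas: pd.DataFrame  # one row per municipality
    samples: pd.DataFrame  # one row per soil sampling point
    strata: pd.DataFrame  # long format: area_id, age_group, sex, period, population, deaths
    adjacency: list  # list of (i, j) undirected edges on area index
    truth: GroundTruth
    config: SimConfig

    @property
    def n_areas(self) -> int:
        return len(self.areas)


def grid_adjacency(nx: int, ny: int) -> list:
    """Rook adjacency (shared cell edges) on an nx x ny grid, as (i, j) pairs i < j."""
    edges = []
    for r in range(ny):
        for c in range(nx):
            i = r * nx + c
            if c + 1 < nx:
                edges.append((i, i + 1))
            if r + 1 < ny:
                edges.append((i, i + nx))
    return edges


def icar_draw(edges: list, n: int, sigma_u: float, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the intrinsic CAR prior with sum-to-zero constraint.

    The ICAR precision is the graph Laplacian scaled by 1/sigma_u^2; it is
    rank-deficient (one null vector per connected component), so the draw is
    taken in the orthogonal complement of the null space via an
    eigen-decomposition and each component is constrained to sum to zero.
    """
    if sigma_u == 0:
        return np.zeros(n)
    lap = np.zeros((n, n))
    for i, j in edges:
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    w, vec = np.linalg.eigh(lap)
    pos = w > 1e-9 * max(w.max(), 1.0)
    z = rng.standard_normal(int(pos.sum()))
    u = vec[:, pos] @ (z / np.sqrt(w[pos])) * sigma_u
    # project out per-component means (numerical safety; exact up to fp error)
    comp = _components(edges, n)
    for members in comp:
        u[members] -= u[members].mean()
    return u


def _components(edges: list, n: int) -> list:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.array(m) for m in groups.values()]


def _sample_locations(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sampling points in three vertical density strata (west dense, east sparse)."""
    width = cfg.nx * cfg.cell_km
    height = cfg.ny * cfg.cell_km
    w = np.asarray(cfg.density_weights, dtype=float)
    counts = np.floor(cfg.n_samples * w / w.sum()).astype(int)
    counts[0] += cfg.n_samples - counts.sum()
    xs, ys, strat = [], [], []
    band = width / len(w)
    for k, nk in enumerate(counts):
        xs.append(rng.uniform(k * band, (k + 1) * band, nk))
        ys.append(rng.uniform(0.0, height, nk))
        strat.append(np.full(nk, k))
    return np.column_stack([np.concatenate(xs), np.concatenate(ys)]), np.concatenate(strat)


def _populate_strata(areas: pd.DataFrame, rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    """Long-format population table: area x 18 ages x 2 sexes x 2 periods."""
    n = len(areas)
    totals = rng.lognormal(np.log(cfg.mean_population), cfg.population_sd_log, n)
    n_age = len(AGE_GROUPS)
    block = len(SEXES) * len(PERIODS) * n_age  # 72 rows per area
    # population[i, sex, period, age]; mild demographic drift per quinquennium
    period_scale = 0.5 * (1.0 + 0.05 * np.arange(len(PERIODS)))
    pop = (
        totals[:, None, None, None]
        * AGE_PYRAMID[None, None, None, :]
        * period_scale[None, None, :, None]
        * np.ones((1, len(SEXES), 1, 1))
    )
    return pd.DataFrame(
        {
            "area_id": np.repeat(areas["area_id"].to_numpy(), block),
            "age_group": np.tile(AGE_GROUPS, n * len(SEXES) * len(PERIODS)),
            "sex": np.tile(np.repeat(SEXES, len(PERIODS) * n_age), n),
            "period": np.tile(np.tile(np.repeat(PERIODS, n_age), len(SEXES)), n),
            "population": np.round(pop.ravel(), 3),
        }
    )


def place_industries(
    areas: pd.DataFrame,
    fraction: float,
    seed: int | np.random.Generator,
    domain_bbox: tuple | None = None,
    radius_km: float = INDUSTRY_RADIUS_KM,
) -> tuple:
    """Scatter industrial emitters and flag areas with an emitter within 5 km.

    ``fraction`` controls the number of emitters relative to the number of
    areas.  The 5 km radius is treated as closed (distance <= radius flags
    the area).  Returns ``(areas_with_flag, emitter_coordinates)``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    areas = areas.copy()
    n_emit = int(round(fraction * len(areas)))
    if n_emit == 0:
        areas["industry_within_5km"] = False
        return areas, np.empty((0, 2))
    if domain_bbox is None:
        xmin, ymin = areas[["x_km", "y_km"]].min()
        xmax, ymax = areas[["x_km", "y_km"]].max()
    else:
        xmin, ymin, xmax, ymax = domain_bbox
    emitters = np.column_stack(
        [rng.uniform(xmin, xmax, n_emit), rng.uniform(ymin, ymax, n_emit)]
    )
    cent = areas[["x_km", "y_km"]].to_numpy()
    d = cdist(cent, emitters)
    areas["industry_within_5km"] = (d.min(axis=1) <= radius_km)
    return areas, emitters


def simulate_universe(cfg: SimConfig, seed: int) -> StudyUniverse:
    """Generate a full synthetic study universe.

    Steps: lay out grid areas and their rook adjacency; scatter sampling
    points in three density strata; draw one joint Matérn field realisation
    at sampling points and centroids; form concentrations as
    ``c = exp(mu + x + measurement error)``; place emitters and optionally
    shift the local log-concentration mean near them; populate demographic
    strata, compute expected deaths from the built-in baseline rate
    schedule, and draw observed deaths from the Poisson relative-risk model
    with ICAR + iid random effects.
    """
    rng = np.random.default_rng(seed)
    truth = cfg.truth
    width, height = cfg.nx * cfg.cell_km, cfg.ny * cfg.cell_km
    bbox = (0.0, 0.0, width, height)

    # areas on a grid, centroids at cell centres
    xs = (np.arange(cfg.nx) + 0.5) * cfg.cell_km
    ys = (np.arange(cfg.ny) + 0.5) * cfg.cell_km
    gx, gy = np.meshgrid(xs, ys)
    n_areas = cfg.nx * cfg.ny
    areas = pd.DataFrame(
        {
            "area_id": [f"A{i:04d}" for i in range(n_areas)],
            "x_km": gx.ravel(),
            "y_km": gy.ravel(),
        }
    )
    edges = grid_adjacency(cfg.nx, cfg.ny)

    sample_xy, strat = _sample_locations(cfg, rng)
    n_samp = sample_xy.shape[0]

    # one exact joint field draw at samples + centroids
    all_xy = np.vstack([sample_xy, areas[["x_km", "y_km"]].to_numpy()])
    x_all = simulate_matern_field(all_xy, truth.field, rng)
    x_samp, x_cent = x_all[:n_samp], x_all[n_samp:]

    areas, emitters = place_industries(areas, cfg.emitter_fraction, rng, domain_bbox=bbox)
    if cfg.emitter_log_shift != 0.0 and len(emitters):
        d_se = cdist(sample_xy, emitters).min(axis=1)
        d_ce = cdist(areas[["x_km", "y_km"]].to_numpy(), emitters).min(axis=1)
        x_samp = x_samp + cfg.emitter_log_shift * (d_se <= INDUSTRY_RADIUS_KM)
        x_cent = x_cent + cfg.emitter_log_shift * (d_ce <= INDUSTRY_RADIUS_KM)

    log_c = truth.mu_log_conc + x_samp + rng.normal(0.0, truth.sigma_x, n_samp)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{j:05d}" for j in range(n_samp)],
            "x_km": sample_xy[:, 0],
            "y_km": sample_xy[:, 1],
            "density_stratum": strat.astype(int),
            "concentration": np.exp(log_c),
            "log_concentration": log_c,
        }
    )

    # socio-demographic covariates: two standardised continuous indicators
    soc1 = rng.standard_normal(n_areas)
    soc2 = rng.standard_normal(n_areas)
    areas["pct_unemployed"] = soc1
    areas["mean_income"] = soc2

    strata_df = _populate_strata(areas, rng, cfg)
    # population-size class from the decade-average total population
    pop_tot = strata_df.groupby("area_id", sort=False)["population"].sum()
    pop_per_area = pop_tot.reindex(areas["area_id"]).to_numpy() / 2.0  # per-quinquennium avg
    areas["population_total"] = pop_per_area
    areas["size_class"] = pd.cut(
        pop_per_area, [-np.inf, 2000.0, 10000.0, np.inf], labels=["rural", "semi-urban", "urban"]
    ).astype(str)

    # expected deaths per sex via indirect standardisation against BASE_RATES
    from .standardise import RateTable, expected_cases  # local import avoids cycle

    rates = RateTable.from_schedule(BASE_RATES)
    expected = expected_cases(strata_df, rates)

    # relative risk per area (shared across sexes)
    u = icar_draw(edges, n_areas, truth.sigma_u, rng)
    v = rng.normal(0.0, truth.sigma_v, n_areas) if truth.sigma_v > 0 else np.zeros(n_areas)
    expos = truth.mu_log_conc + x_cent  # latent log concentration at centroid
    lin = truth.alpha + truth.beta * expos + truth.gamma * areas[
        "industry_within_5km"
    ].to_numpy().astype(float) + u + v
    for name, coef in truth.delta.items():
        lin = lin + coef * areas[name].to_numpy().astype(float)
    lam = np.exp(lin)

    for sex in SEXES:
        e_sex = expected.set_index("area_id").loc[areas["area_id"], sex].to_numpy()
        if not np.any(e_sex > 0):
            raise ValueError("all expected deaths are zero; degenerate Poisson offsets")
        areas[f"expected_{sex}"] = e_sex
        areas[f"observed_{sex}"] = rng.poisson(e_sex * lam)
    areas["true_expos"] = expos
    areas["true_lambda"] = lam

    # merge simulated deaths back into the long strata table (proportional
    # allocation is not needed for the analysis; per-stratum deaths are drawn
    # so that national rates can be re-derived internally)
    strata_df = _draw_stratum_deaths(strata_df, areas, lam, rng)

    truth_filled = replace(truth, u=u, v=v)
    return StudyUniverse(
        domain_bbox=bbox,
        areas=areas,
        samples=samples,
        strata=strata_df,
        adjacency=edges,
        truth=truth_filled,
        config=cfg,
    )


def _draw_stratum_deaths(
    strata_df: pd.DataFrame, areas: pd.DataFrame, lam: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Allocate each area's observed deaths to strata proportionally to risk."""
    strata_df = strata_df.copy()
    age_idx = strata_df["age_group"].map({g: k for k, g in enumerate(AGE_GROUPS)}).to_numpy()
    py = strata_df["population"].to_numpy() * 5.0
    weight = BASE_RATES[age_idx] * py
    deaths = np.zeros(len(strata_df))
    sex_col = strata_df["sex"].to_numpy()
    area_col = strata_df["area_id"].to_numpy()
    for sex in SEXES:
        obs = areas[f"observed_{sex}"].to_numpy()
        mask = sex_col == sex
        rows_by_area: dict = {}
        idx_all = np.nonzero(mask)[0]
        for k in idx_all:  # rows are area-major, so this preserves order
            rows_by_area.setdefault(area_col[k], []).append(k)
        for a_pos, aid in enumerate(areas["area_id"].to_numpy()):
            rows = np.asarray(rows_by_area[aid])
            o = int(obs[a_pos])
            wgt = weight[rows]
            if wgt.sum() <= 0 or o == 0:
                continue
            deaths[rows] = rng.multinomial(o, wgt / wgt.sum()).astype(float)
    strata_df["deaths"] = deaths
    return strata_df
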