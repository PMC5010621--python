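import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from soilrisk.bym import FitResult
from soilrisk.hmc import McmcConfig
from soilrisk.joint import (
    JointExposureModel,
    JointSpec,
    compare_approaches,
    field_posterior_at,
    fit_joint,
)


@pytest.fixture(scope="module")
def joint_fit(small_universe, square_mesh):
    spec = JointSpec(
        mesh=square_mesh,
        adjacency=small_universe.adjacency,
        range_init=20.0,
        sd_init=0.6,
    )
    return fit_joint(
        small_universe.samples,
        small_universe.areas,
        spec,
        McmcConfig(n_warmup=400, n_draws=400),
        seed=3,
    )


def test_joint_interval_covers_generating_effect(joint_fit):
    lo, hi = joint_fit.summary.loc["beta", ["q2.5", "q97.5"]]
    assert lo < np.log(1.2) < hi
    assert joint_fit.meta["beta_semantics"] == "RR per unit log concentration"


def test_observation_level_parameters_identified(joint_fit):
    """Measurement error and field mean are well identified even on a
    small domain; the range is only weakly identified there (the domain
    spans ~2.5 correlation ranges), so it gets a broad factor band."""
    s = joint_fit.summary
    assert abs(s.loc["sigma_x", "median"] - 0.3) / 0.3 < 0.35
    assert abs(s.loc["mu_x", "mean"] - 3.0) < 0.3
    assert 20.0 / 3.0 < s.loc["field_range", "median"] < 20.0 * 3.0


def test_field_hyperparameters_recovered_at_scale():
    """Median posterior over 3 replicates at 800 samples on a 100 km
    domain recovers range, marginal SD and measurement error within 30%."""
    from soilrisk.fields import MaternFieldParams
    from soilrisk.mesh import build_mesh
    from soilrisk.universe import GroundTruth, SimConfig, simulate_universe

    mesh = build_mesh([(0, 0), (100, 0), (100, 100), (0, 100)], 9.0, extension_width=35.0)
    meds = []
    for seed in (1, 2, 3):
        cfg = SimConfig(
            nx=14, ny=14, cell_km=100.0 / 14.0, n_samples=800,
            truth=GroundTruth(
                beta=np.log(1.2), sigma_u=0.1, sigma_v=0.1,
                field=MaternFieldParams(20.0, 0.6), sigma_x=0.3,
            ),
        )
        uni = simulate_universe(cfg, seed)
        spec = JointSpec(mesh=mesh, adjacency=uni.adjacency, range_init=20.0, sd_init=0.6)
        fit = fit_joint(uni.samples, uni.areas, spec,
                        McmcConfig(n_warmup=350, n_draws=350), seed=seed)
        s = fit.summary
        meds.append([s.loc["field_range", "median"], s.loc["field_sd", "median"],
                     s.loc["sigma_x", "median"]])
    med = np.median(np.asarray(meds), axis=0)
    assert abs(med[0] - 20.0) / 20.0 < 0.30
    assert abs(med[1] - 0.6) / 0.6 < 0.30
    assert abs(med[2] - 0.3) / 0.3 < 0.30


def test_nearly_noiseless_dense_exposure_matches_plugin_glm(square_mesh):
    """When the field is observed almost without error at every centroid,
    the joint beta collapses to the plug-in Poisson GLM slope."""
    from soilrisk.fields import MaternFieldParams
    from soilrisk.universe import GroundTruth, SimConfig, simulate_universe

    cfg = SimConfig(
        nx=10, ny=10, cell_km=5.0, n_samples=600,
        truth=GroundTruth(
            beta=np.log(1.3), sigma_u=0.0, sigma_v=0.0,
            field=MaternFieldParams(25.0, 0.6), sigma_x=0.02,
        ),
    )
    uni = simulate_universe(cfg, seed=21)
    spec = JointSpec(mesh=square_mesh, adjacency=uni.adjacency,
                     include_u=False, include_v=False, range_init=25.0, sd_init=0.6)
    fit = fit_joint(uni.samples, uni.areas, spec, McmcConfig(n_warmup=300, n_draws=500), seed=4)
    X = sm.add_constant(uni.areas["true_expos"].to_numpy())
    glm = sm.GLM(
        uni.areas["observed_men"], X, family=sm.families.Poisson(),
        offset=np.log(uni.areas["expected_men"]),
    ).fit()
    assert abs(fit.summary.loc["beta", "mean"] - glm.params.iloc[1]) < max(
        3 * glm.bse.iloc[1], 0.05
    )


def test_field_posterior_projection(joint_fit, small_universe, square_mesh):
    # at a mesh vertex the projection is the vertex summary itself
    v_idx = 30
    at_vertex = field_posterior_at(square_mesh.vertices[[v_idx]], joint_fit)
    info = joint_fit.meta["_field"]
    post = info["post"]
    draws = np.array(
        [th[post.i_mux] + np.exp(th[post.i_lsd]) * th[v_idx] for th in info["draws"]]
    )
    assert at_vertex["mean"].iloc[0] == pytest.approx(draws.mean(), abs=1e-10)

    # conditioning: posterior SD at a densely sampled spot < prior marginal SD
    samp_xy = small_universe.samples[["x_km", "y_km"]].to_numpy()
    dense_spot = samp_xy[:200].mean(axis=0)
    at_spot = field_posterior_at(dense_spot[None, :], joint_fit)
    prior_sd = joint_fit.summary.loc["field_sd", "mean"]
    assert at_spot["sd"].iloc[0] < prior_sd

    out = field_posterior_at(np.array([[999.0, 999.0]]), joint_fit)
    assert bool(out["outside_mesh"].iloc[0])


def test_holdout_predictive_coverage(small_universe, square_mesh):
    """95% predictive intervals for held-out log concentrations achieve
    empirical coverage in the 88-99% band."""
    samples = small_universe.samples
    train, test = samples.iloc[:240], samples.iloc[240:]
    spec = JointSpec(mesh=square_mesh, adjacency=small_universe.adjacency,
                     range_init=20.0, sd_init=0.6)
    fit = fit_joint(train, small_universe.areas, spec,
                    McmcConfig(n_warmup=300, n_draws=300), seed=8)
    pred = field_posterior_at(test[["x_km", "y_km"]].to_numpy(), fit)
    sx = fit.summary.loc["sigma_x", "mean"]
    tot_sd = np.sqrt(pred["sd"] ** 2 + sx**2)
    inside = (
        (test["log_concentration"].to_numpy() > pred["mean"] - 1.96 * tot_sd)
        & (test["log_concentration"].to_numpy() < pred["mean"] + 1.96 * tot_sd)
    )
    assert 0.88 <= inside.mean() <= 0.995


def test_marginalisation_consistency(joint_fit, small_universe):
    """Plugging the field's posterior-mean exposure into a disease-side-only
    fit yields a beta inside the joint model's 95% interval."""
    from soilrisk.bym import BymSpec, fit_bym

    areas = small_universe.areas.copy()
    post_mean = field_posterior_at(areas[["x_km", "y_km"]].to_numpy(), joint_fit)
    areas["expos"] = post_mean["mean"].to_numpy()
    fit = fit_bym(areas, BymSpec(adjacency=small_universe.adjacency,
                                 exposure_coding="continuous_log"),
                  McmcConfig(n_warmup=300, n_draws=300), seed=13)
    lo, hi = joint_fit.summary.loc["beta", ["q2.5", "q97.5"]]
    assert lo <= fit.summary.loc["beta", "mean"] <= hi


def test_compare_approaches_bookkeeping():
    def stub(beta, width):
        s = pd.DataFrame(
            {"mean": [beta], "q2.5": [beta - width / 2], "q97.5": [beta + width / 2],
             "median": [beta]},
            index=["beta"],
        )
        return FitResult(summary=s, rr_table=pd.DataFrame(), area_rr=np.ones(1),
                         draws={}, diagnostics={}, converged=True)

    rep = compare_approaches(
        [stub(0.1, 0.2), stub(0.2, 0.2), stub(-0.05, 0.3)],
        [stub(0.12, 0.3), stub(0.15, 0.25), stub(0.01, 0.35)],
    )
    assert rep["mean_width_b"] > rep["mean_width_a"]
    assert rep["sign_agreement"] == pytest.approx(2.0 / 3.0)
    assert rep["width_b_ge_a_fraction"] == 1.0


def test_too_few_samples_rejected(small_universe, square_mesh):
    spec = JointSpec(mesh=square_mesh, adjacency=small_universe.adjacency)
    with pytest.raises(ValueError, match="at least 10"):
        fit_joint(small_universe.samples.iloc[:5], small_universe.areas, spec,
                  McmcConfig(50, 50), seed=0)


def test_estimator_wrapper(small_universe, square_mesh):
    est = JointExposureModel(
        mesh=square_mesh, adjacency=small_universe.adjacency,
        n_warmup=100, n_draws=100, seed=5,
    )
    assert est.get_params()["n_draws"] == 100
    est.fit(small_universe.samples, small_universe.areas)
    assert "beta" in est.summary_.index
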