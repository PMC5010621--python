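import numpy as np
import pandas as pd
import pytest

from soilrisk.fields import MaternFieldParams, simulate_matern_field
from soilrisk.kriging import OrdinaryKriging, attach_exposure, ordinary_kriging
from soilrisk.variogram import VariogramModel, empirical_variogram, fit_variogram


def test_empirical_variogram_trivial_pairs():
    xy = np.array([[0.0, 0.0], [1.0, 0.0]])
    same = empirical_variogram(xy, np.array([3.0, 3.0]), n_bins=1, max_lag=2.0)
    assert same["gamma"].iloc[0] == 0.0
    diff = empirical_variogram(xy, np.array([0.0, 2.0]), n_bins=1, max_lag=2.0)
    assert diff["gamma"].iloc[0] == pytest.approx(2.0)  # (1/2)(2^2)/1


def test_empirical_variogram_rejects_unpairable_inputs():
    xy = np.array([[0.0, 0.0], [50.0, 0.0]])
    with pytest.raises(ValueError, match="max_lag"):
        empirical_variogram(xy, np.array([0.0, 1.0]), n_bins=3, max_lag=1.0)


def test_fit_recovers_exact_exponential_curve():
    truth = VariogramModel("exponential", 0.2, 1.5, 12.0)
    lags = np.linspace(0.5, 30.0, 12)
    emp = pd.DataFrame({"lag": lags, "gamma": truth.semivariance(lags), "n_pairs": 50})
    m = fit_variogram(emp, "exponential")
    assert m.nugget == pytest.approx(0.2, abs=1e-4)
    assert m.partial_sill == pytest.approx(1.5, abs=1e-4)
    assert m.range_km == pytest.approx(12.0, abs=1e-3)


def test_flat_variogram_is_flagged_degenerate():
    emp = pd.DataFrame({"lag": [1.0, 2.0, 3.0, 4.0], "gamma": 0.8, "n_pairs": 30})
    m = fit_variogram(emp, "exponential")
    assert "at_bound" in m.flags


def test_variogram_recovery_from_simulated_fields():
    """Median over seeds: the fitted range is within 30% and the total sill
    within 25% of the generating Matérn parameters."""
    rho, sig = 20.0, 1.0
    p = MaternFieldParams(rho, sig)
    ranges, sills = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 150, (400, 2))
        z = simulate_matern_field(xy, p, seed=seed + 100)
        m = fit_variogram(empirical_variogram(xy, z, n_bins=15), "matern_nu1")
        ranges.append(m.range_km)
        sills.append(m.sill)
    assert abs(np.median(ranges) - rho) / rho < 0.30
    assert abs(np.median(sills) - sig**2) / sig**2 < 0.25


@pytest.fixture(scope="module")
def sample_cloud():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 50, (120, 2))
    y = rng.standard_normal(120)
    return X, y


def test_exact_interpolation_with_zero_nugget(sample_cloud):
    X, y = sample_cloud
    vg = VariogramModel("exponential", 0.0, 1.0, 15.0)
    ok = OrdinaryKriging(variogram=vg, n_neighbors=None).fit(X, y)
    pred, sd = ok.predict(X[:10], return_std=True)
    assert np.allclose(pred, y[:10], atol=1e-8)
    assert np.all(sd**2 < 1e-6)


def test_nugget_breaks_exactness_but_variance_positive(sample_cloud):
    X, y = sample_cloud
    vg = VariogramModel("exponential", 0.3, 1.0, 15.0)
    ok = OrdinaryKriging(variogram=vg, n_neighbors=None).fit(X, y)
    _, sd = ok.predict(X[:5], return_std=True)
    assert np.all(sd**2 > 0)


def test_constant_field_predicts_constant(sample_cloud):
    X, _ = sample_cloud
    vg = VariogramModel("matern_nu1", 0.1, 1.0, 15.0)
    ok = OrdinaryKriging(variogram=vg, n_neighbors=16).fit(X, np.full(len(X), 4.2))
    pred = ok.predict(np.array([[25.0, 25.0], [0.0, 50.0]]))
    assert np.allclose(pred, 4.2, atol=1e-10)


def test_weights_sum_to_one(sample_cloud):
    X, y = sample_cloud
    vg = VariogramModel("matern_nu1", 0.1, 1.0, 15.0)
    ok = OrdinaryKriging(variogram=vg, n_neighbors=32).fit(X, y)
    _, _, weights = ok.predict(
        np.random.default_rng(1).uniform(0, 50, (20, 2)), return_std=True, return_weights=True
    )
    for _, w in weights:
        assert abs(w.sum() - 1.0) < 1e-10


def test_neighbourhood_kriging_matches_dense_oracle():
    """With the neighbourhood spanning all samples, the k-NN path must
    reproduce an independently coded dense solve of the kriging equations."""
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 30, (40, 2))
    y = rng.standard_normal(40)
    vg = VariogramModel("exponential", 0.1, 1.2, 10.0)
    ok = OrdinaryKriging(variogram=vg, n_neighbors=40).fit(X, y)
    targets = rng.uniform(0, 30, (6, 2))
    pred, sd = ok.predict(targets, return_std=True)

    # independent dense solve
    from scipy.spatial.distance import cdist

    C = vg.covariance(cdist(X, X))
    n = len(X)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = A[n, :n] = 1.0
    for t in range(len(targets)):
        c0 = vg.covariance(cdist(X, targets[t][None, :]).ravel())
        sol = np.linalg.solve(A, np.append(c0, 1.0))
        p_ref = sol[:n] @ y
        v_ref = vg.sill - sol[:n] @ c0 - sol[n]
        assert abs(pred[t] - p_ref) < 1e-10
        assert abs(sd[t] ** 2 - v_ref) < 1e-10


def test_duplicate_samples_zero_nugget_named():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    vg = VariogramModel("exponential", 0.0, 1.0, 5.0)
    ok = OrdinaryKriging(variogram=vg, n_neighbors=None).fit(X, np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="coincide"):
        ok.predict(np.array([[0.5, 0.5]]))


def test_prediction_error_calibrated_against_kriging_variance(small_universe):
    """On synthetic data the mean squared prediction error at centroids is
    within the calibration band of the mean kriging variance."""
    uni = small_universe
    ok = OrdinaryKriging(n_neighbors=64)
    ok.fit(uni.samples[["x_km", "y_km"]].to_numpy(), uni.samples["log_concentration"].to_numpy())
    pred, sd = ok.predict(uni.areas[["x_km", "y_km"]].to_numpy(), return_std=True)
    mse = np.mean((pred - uni.areas["true_expos"].to_numpy()) ** 2)
    assert mse <= 1.5 * np.mean(sd**2) + 0.05


def test_interpolation_contracts_the_range_of_values(small_universe):
    """Kriged municipal values span a narrower range than the raw
    determinations (a tendency of the smoothing, checked statistically)."""
    uni = small_universe
    ok = OrdinaryKriging(n_neighbors=64)
    ok.fit(uni.samples[["x_km", "y_km"]].to_numpy(), uni.samples["log_concentration"].to_numpy())
    pred = ok.predict(uni.areas[["x_km", "y_km"]].to_numpy())
    raw_span = uni.samples["log_concentration"].max() - uni.samples["log_concentration"].min()
    assert pred.max() - pred.min() < raw_span


def test_attach_exposure_joins_by_id_and_round_trips(tmp_path, small_universe):
    uni = small_universe
    preds = pd.DataFrame(
        {
            "area_id": uni.areas["area_id"].to_numpy()[::-1],  # permuted order
            "pred_log": np.linspace(0, 1, len(uni.areas))[::-1],
            "krig_var": 0.1,
        }
    )
    out = attach_exposure(uni.areas, preds)
    assert np.allclose(out["expos"], np.linspace(0, 1, len(uni.areas)))

    from soilrisk.io import read_csv, write_csv

    path = tmp_path / "expos.csv"
    write_csv(out[["area_id", "expos", "krig_var"]], path)
    back = read_csv(path)
    assert np.array_equal(back["expos"].to_numpy(), out["expos"].to_numpy())

    with pytest.raises(ValueError, match="unknown area ids"):
        attach_exposure(uni.areas, preds.assign(area_id=["X"] * len(preds)))
    with pytest.raises(ValueError, match="missing predictions"):
        attach_exposure(uni.areas, preds.iloc[:-3])
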