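"""Hierarchical spatial regression: kernel, design, fitting, interpretation."""

import numpy as np
import pandas as pd
import pytest

from forestcti import (
    ModelSpec,
    SimulationConfig,
    build_design,
    effect_table,
    fit,
    generate_landscape,
    matern_cov,
    mean_thermophilization,
    simulate_response,
)
from forestcti.covariates import PREDICTORS, standardize
from forestcti.model import DESIGN_COLUMNS


class TestMaternKernel:
    def test_value_at_zero_distance(self):
        assert matern_cov(0.0, sigma_u=0.7, rho=10.0, nu=1.0) == pytest.approx(0.49)

    def test_monotone_decay(self):
        d = np.linspace(0, 100, 50)
        k = matern_cov(d, 0.5, 20.0, 1.0)
        assert np.all(np.diff(k) < 0)

    def test_nu_half_is_exponential(self):
        d = np.linspace(0, 80, 100)
        k = matern_cov(d, 0.6, 15.0, nu=0.5)
        assert np.allclose(k, 0.36 * np.exp(-d / 15.0), atol=1e-10)

    def test_psd_after_jitter(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (40, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        cov = matern_cov(d, 0.5, 25.0, 1.0)
        cov[np.diag_indices_from(cov)] += 1e-8 * 0.25
        assert np.min(np.linalg.eigvalsh(cov)) > 0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_cov(np.array([-1.0]), 0.5, 10.0, 1.0)


def synthetic_inputs(n_plots=30, seed=0, n_subplots=4):
    """Covariates, coordinates, and a CTI table with zero response."""
    cfg = SimulationConfig(n_plots=n_plots, n_subplots_per_plot=n_subplots, seed=seed)
    land = generate_landscape(cfg)
    coords = land.drop_duplicates("plot_id")[["plot_id", "x_km", "y_km"]]
    rng = np.random.default_rng(seed + 1000)
    cov = pd.DataFrame({"plot_id": land.plot_id, "subplot_id": land.subplot_id})
    for p in PREDICTORS:
        if p in ("x9", "x10"):
            cov[p] = rng.integers(0, 2, len(land))
        else:
            cov[p] = standardize(rng.normal(0, 1, len(land)))[0]
    cti = pd.DataFrame(
        [
            {"plot_id": r.plot_id, "subplot_id": r.subplot_id, "timepoint": tp,
             "variant": v, "cti_degC": 0.0}
            for r in cov.itertuples()
            for tp in (1, 2)
            for v in ("all", "mortality")
        ]
    )
    return cti, cov, coords


class TestBuildDesign:
    def test_two_rows_per_subplot(self):
        cti, cov, _ = synthetic_inputs(n_plots=5, n_subplots=2)
        design = build_design(cti, cov, "all")
        assert len(design) == 20

    def test_baseline_interactions_are_zero(self):
        cti, cov, _ = synthetic_inputs()
        design = build_design(cti, cov, "all")
        k0 = design[design["k"] == 0]
        inter = [c for c in DESIGN_COLUMNS if c.startswith("x1:")]
        assert (k0[inter] == 0.0).all().all()

    def test_variants_share_baseline_response(self):
        cti, cov, _ = synthetic_inputs()
        d_all = build_design(cti, cov, "all")
        d_mort = build_design(cti, cov, "mortality")
        a = d_all[d_all["k"] == 0].set_index(["plot_id", "subplot_id"])["Y"]
        m = d_mort[d_mort["k"] == 0].set_index(["plot_id", "subplot_id"])["Y"]
        pd.testing.assert_series_equal(a, m)

    def test_unstandardized_covariates_rejected(self):
        cti, cov, _ = synthetic_inputs()
        bad = cov.copy()
        bad["x2"] = bad["x2"] * 3 + 1
        with pytest.raises(ValueError, match="x2"):
            build_design(cti, bad, "all")

    def test_unknown_variant_rejected(self):
        cti, cov, _ = synthetic_inputs()
        with pytest.raises(ValueError):
            build_design(cti, cov, "senescence")


def _planted_design(n_plots=60, seed=3, beta1=0.0, beta12=0.0,
                    sigma=0.3, d=0.2, sigma_u=0.3, rho=30.0):
    cti, cov, coords = synthetic_inputs(n_plots=n_plots, seed=seed)
    design = build_design(cti, cov, "all", "weighted_effect")
    beta = np.zeros(len(DESIGN_COLUMNS))
    beta[0], beta[1], beta[12] = 10.0, beta1, beta12
    y = simulate_response(design, coords, beta, sigma, d, sigma_u, rho,
                          rng=np.random.default_rng(seed + 5000))
    design = design.copy()
    design["Y"] = y
    return design, coords


class TestFit:
    def test_collapse_to_ols(self):
        design, coords = _planted_design(n_plots=25)
        s = fit(design, coords, ModelSpec(fix_sigma_u=0.0, fix_d=0.0))
        X = design[list(DESIGN_COLUMNS)].to_numpy()
        ols = np.linalg.lstsq(X, design["Y"].to_numpy(), rcond=None)[0]
        assert np.max(np.abs(s.params["mean"].to_numpy() - ols)) < 1e-8

    def test_location_equivariance(self):
        design, coords = _planted_design(n_plots=20)
        spec = ModelSpec(fix_rho=30.0)  # same hyper-search space both times
        s1 = fit(design, coords, spec)
        shifted = design.copy()
        shifted["Y"] = shifted["Y"] + 5.0
        s2 = fit(shifted, coords, spec)
        diff = s2.params["mean"].to_numpy() - s1.params["mean"].to_numpy()
        assert diff[0] == pytest.approx(5.0, abs=1e-6)
        assert np.max(np.abs(diff[1:])) < 1e-6

    def test_row_permutation_invariance(self):
        design, coords = _planted_design(n_plots=20)
        s1 = fit(design, coords, ModelSpec())
        perm = design.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s2 = fit(perm, coords, ModelSpec())
        assert np.allclose(
            s1.params["mean"].to_numpy(), s2.params["mean"].to_numpy(), atol=1e-8
        )
        assert np.allclose(
            s1.params["sd"].to_numpy(), s2.params["sd"].to_numpy(), atol=1e-8
        )

    def test_raw_covariate_rescaling_is_absorbed(self):
        # multiplying a raw covariate by 10 before standardization leaves the
        # design, and hence every coefficient, unchanged
        rng = np.random.default_rng(4)
        x = rng.normal(0, 2, 100)
        z1, _ = standardize(x)
        z2, _ = standardize(10 * x)
        assert np.allclose(z1, z2, atol=1e-12)

    def test_planted_time_effect_recovered(self):
        design, coords = _planted_design(n_plots=80, beta1=0.04)
        s = fit(design, coords, ModelSpec())
        est = mean_thermophilization(s)
        assert est["estimate"] == pytest.approx(0.04, abs=3 * est["sd"])
        assert est["per_year"] == est["estimate"] / 10.0

    def test_singular_design_names_columns(self):
        design, coords = _planted_design(n_plots=15)
        design["x3"] = design["x2"]
        design["x1:x3"] = design["x1:x2"]
        with pytest.raises(ValueError, match="collinear"):
            fit(design, coords, ModelSpec())

    def test_mcmc_smoke(self):
        design, coords = _planted_design(n_plots=12)
        spec = ModelSpec(inference="mcmc", mcmc_walkers=8, mcmc_steps=60,
                         mcmc_burn=30, mcmc_thin=10, seed=1)
        s = fit(design, coords, spec)
        assert np.isfinite(s.params["mean"]).all()
        assert (s.params["q025"] <= s.params["q975"]).all()


class TestInterpretation:
    def test_dummy_coded_fit_rejected_for_population_mean(self):
        cti, cov, coords = synthetic_inputs(n_plots=10)
        design = build_design(cti, cov, "all", "dummy")
        rng = np.random.default_rng(0)
        design["Y"] = rng.normal(10, 0.5, len(design))
        s = fit(design, coords, ModelSpec(fix_sigma_u=0.0, fix_d=0.0))
        with pytest.raises(ValueError, match="weighted_effect"):
            mean_thermophilization(s)

    def test_effect_table_shape_and_determinism(self):
        design, coords = _planted_design(n_plots=15)
        s1 = fit(design, coords, ModelSpec())
        s2 = fit(design, coords, ModelSpec())
        t1 = effect_table({"all": s1})
        t2 = effect_table({"all": s2})
        assert len(t1) == 22 + 4  # coefficients + hyperparameters
        pd.testing.assert_frame_equal(t1, t2)

    def test_credible_interval_orders(self):
        design, coords = _planted_design(n_plots=15)
        s = fit(design, coords, ModelSpec())
        assert (s.params["q025"] <= s.params["mean"]).all()
        assert (s.params["mean"] <= s.params["q975"]).all()
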