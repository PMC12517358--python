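"""Von Mises densities, bin masses, and SSE fits of the pooling mixture."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crowdprofile.design import StimulusCondition, build_design, scaled_diameter
from crowdprofile.errors import BIN_CENTERS, bin_errors
from crowdprofile.observer import ObserverParams, simulate_session
from crowdprofile.pooling import (
    PoolingMixtureModel,
    UnflankedVonMisesModel,
    component_bin_mass,
    fit_pooling,
    fit_unflanked,
    model_probabilities,
    sse,
    von_mises_density,
)


class TestVonMisesDensity:
    def test_kappa_zero_is_uniform(self):
        theta = np.linspace(-180, 180, 19)
        np.testing.assert_allclose(von_mises_density(theta, 33.0, 0.0), 1 / 360.0)

    def test_normalizer_against_trapezoid(self):
        """Peak density matches a brute-force numeric normalizer to 1e-8."""
        grid = np.arange(0.0, 360.0, 0.01)
        for kappa in (1.0, 5.0, 30.0):
            unnorm = np.exp(kappa * np.cos(np.deg2rad(grid)))
            total = np.trapezoid(np.append(unnorm, unnorm[0]), dx=0.01)
            expected_peak = np.exp(kappa) / total
            assert von_mises_density(0.0, 0.0, kappa) == pytest.approx(
                expected_peak, abs=1e-8
            )

    def test_integrates_to_one(self):
        grid = np.arange(-180.0, 180.0, 0.01)
        dens = von_mises_density(grid, 25.0, 4.0)
        assert np.trapezoid(np.append(dens, dens[0]), dx=0.01) == pytest.approx(
            1.0, abs=1e-8
        )

    @given(st.floats(0.1, 170), st.floats(-180, 180), st.floats(0, 100))
    def test_symmetry_about_mean(self, x, mu, kappa):
        a = von_mises_density(mu + x, mu, kappa)
        b = von_mises_density(mu - x, mu, kappa)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-300)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            von_mises_density(0.0, 0.0, -1.0)


class TestComponentBinMass:
    def test_kappa_zero_uniform_bins(self):
        np.testing.assert_allclose(component_bin_mass(0.0, 0.0), 5 / 360.0)

    def test_masses_sum_to_one(self):
        for mu, kappa in ((0.0, 30.0), (-7.3, 8.0), (90.0, 250.0)):
            assert component_bin_mass(mu, kappa).sum() == pytest.approx(1.0, abs=1e-12)

    def test_against_fine_grid_integration(self):
        """Central-bin mass matches brute-force 0.001-degree integration."""
        grid = np.arange(-180.0, 180.0, 0.001)
        dens = von_mises_density(grid, 0.0, 30.0)
        total = dens.sum() * 0.001
        in_bin = np.abs(grid + 0.0005) < 2.5  # [-2.5, 2.5) around center 0
        expected = dens[in_bin].sum() * 0.001 / total
        assert component_bin_mass(0.0, 30.0, bin_center=0.0) == pytest.approx(
            expected, abs=1e-6
        )

    def test_unknown_center_rejected(self):
        with pytest.raises(ValueError):
            component_bin_mass(0.0, 10.0, bin_center=2.0)


class TestModelProbabilities:
    def test_pure_lapse_is_uniform(self):
        np.testing.assert_allclose(
            model_probabilities(1.0, 0.5, 0.0, 10.0, 10.0, 90.0), 1 / 72.0
        )

    def test_pure_target_is_single_von_mises(self):
        np.testing.assert_allclose(
            model_probabilities(0.0, 1.0, 2.0, 15.0, 10.0, 90.0),
            component_bin_mass(2.0, 15.0),
        )

    def test_equal_weight_symmetric_peaks(self):
        p = model_probabilities(0.0, 0.5, 0.0, 20.0, 20.0, 90.0)
        i0 = np.where(BIN_CENTERS == 0)[0][0]
        i90 = np.where(BIN_CENTERS == 90)[0][0]
        assert p[i0] == pytest.approx(p[i90], abs=1e-10)

    @given(
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(-10, 10),
        st.floats(0, 400),
        st.floats(0, 400),
        st.sampled_from([22.5, 45.0, 90.0, 180.0]),
    )
    def test_sums_to_one(self, wR, wT, muT, kT, kF, od):
        p = model_probabilities(wR, wT, muT, kT, kF, od)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(w_random=1.2),
            dict(w_target=-0.1),
            dict(mu_target=11.0),
            dict(kappa_target=-1.0),
        ],
    )
    def test_out_of_bounds_rejected(self, bad):
        kwargs = dict(
            w_random=0.1, w_target=0.5, mu_target=0.0, kappa_target=10.0,
            kappa_flanker=10.0, orientation_difference=90.0,
        )
        kwargs.update(bad)
        with pytest.raises(ValueError):
            model_probabilities(**kwargs)


class TestSse:
    def test_identical_is_zero(self):
        u = np.full(72, 1 / 72.0)
        assert sse(u, u) == 0.0

    def test_hand_summation_oracle(self):
        obs = np.zeros(72)
        obs[0] = 1.0
        pred = np.full(72, 1 / 72.0)
        expected = sum((o - p) ** 2 for o, p in zip(obs, pred))  # plain python
        assert sse(obs, pred) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx((1 - 1 / 72) ** 2 + 71 * (1 / 72) ** 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sse(np.zeros(71), np.zeros(72))


class TestFitUnflanked:
    def test_noiseless_recovery(self):
        probs = component_bin_mass(0.0, 30.0)
        model = UnflankedVonMisesModel().fit(BIN_CENTERS, probs)
        assert model.kappa_ == pytest.approx(30.0, abs=0.5)
        assert model.mu_ == pytest.approx(0.0, abs=0.1)

    def test_uniform_data_pins_kappa_low(self):
        model = UnflankedVonMisesModel().fit(BIN_CENTERS, np.full(72, 1 / 72.0))
        assert "kappa_at_lower_bound" in model.flags_
        assert model.kappa_ < 0.01

    def test_single_bin_pins_kappa_high(self):
        probs = np.zeros(72)
        probs[35] = 1.0  # all mass at center 0
        model = UnflankedVonMisesModel().fit(BIN_CENTERS, probs)
        assert "kappa_at_upper_bound" in model.flags_

    def test_simulated_recovery_rate(self):
        """kappa recovered within +/-30% in at least 90 of 100 seeded
        150-trial unflanked sessions (true kappa = 30)."""
        design = build_design(12.72, (), (), 150)
        params = ObserverParams.study_defaults()
        hits = 0
        for seed in range(100):
            trials = simulate_session(design, params, seed)
            dist = bin_errors([t.signed_error for t in trials])
            fit = fit_unflanked(dist)
            hits += abs(fit.kappa - 30.0) <= 0.3 * 30.0
        assert hits >= 90


class TestFitPooling:
    def test_noiseless_inversion(self):
        """Exact model-generated input: wT recovered to +/-0.02, SSE < 1e-8."""
        target = model_probabilities(0.05, 0.7, 0.0, 20.0, 20.0, 90.0)
        model = PoolingMixtureModel(
            orientation_difference=90.0, kappa_unflanked=30.0
        ).fit(BIN_CENTERS, target)
        assert model.w_target_ == pytest.approx(0.7, abs=0.02)
        assert model.sse_ < 1e-8

    def test_uniform_input_flagged_unidentifiable(self):
        model = PoolingMixtureModel(90.0, 30.0).fit(BIN_CENTERS, np.full(72, 1 / 72))
        assert model.w_random_ > 0.95
        assert model.sse_ == pytest.approx(0.0, abs=1e-12)
        assert "p_target_unidentifiable" in model.flags_

    def test_kappa_bounds_reordered_when_unflanked_below_floor(self):
        target = model_probabilities(0.05, 0.6, 0.0, 8.0, 8.0, 90.0)
        model = PoolingMixtureModel(90.0, kappa_unflanked=5.0).fit(BIN_CENTERS, target)
        assert "kappa_bounds_reordered" in model.flags_
        assert 5.0 - 1e-9 <= model.kappa_target_ <= 8.0 + 1e-9

    def test_sparse_histogram_flagged(self):
        probs = np.zeros(72)
        probs[[10, 35, 60]] = 1 / 3.0
        model = PoolingMixtureModel(90.0, 30.0).fit(BIN_CENTERS, probs)
        assert "underdetermined_histogram" in model.flags_

    def test_monotone_identifiability(self):
        """Fitted wT never decreases as true wT increases (noiseless input)."""
        fitted = []
        for w_true in np.linspace(0.1, 0.9, 9):
            target = model_probabilities(0.05, w_true, 0.0, 20.0, 20.0, 180.0)
            model = PoolingMixtureModel(180.0, 30.0).fit(BIN_CENTERS, target)
            fitted.append(model.w_target_)
        assert np.all(np.diff(fitted) >= -1e-9)

    def test_simulated_recovery_rate(self):
        """Delta=180 condition with spacing at the true midpoint (true
        wT = 0.5), 150 trials: fitted wT within +/-0.12 in >= 95/100 seeds."""
        ecc = 12.72
        L_true = 0.33 * ecc
        cond = StimulusCondition(ecc, 180.0, L_true, scaled_diameter(ecc), 150)
        params = ObserverParams.study_defaults()
        design_like = build_design(ecc, (180.0,), (L_true,), 150, include_unflanked=False)
        hits = 0
        for seed in range(100):
            trials = simulate_session(design_like, params, seed)
            dist = bin_errors([t.signed_error for t in trials])
            fit = fit_pooling(dist, orientation_difference=180.0, kappa_unflanked=30.0)
            hits += abs(fit.w_target - 0.5) <= 0.12
        assert hits >= 95

    def test_wrapper_uses_condition_offset(self):
        target = model_probabilities(0.05, 0.6, 0.0, 20.0, 20.0, 90.0)
        cond = StimulusCondition(12.72, 90.0, 4.0, scaled_diameter(12.72), 150)
        from crowdprofile.errors import ErrorDistribution

        dist = ErrorDistribution(
            probabilities=target / target.sum(), n_trials=150, condition=cond
        )
        fit = fit_pooling(dist, kappa_unflanked=30.0)
        assert fit.mu_flanker == 90.0
        assert fit.p_target == fit.w_target
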