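"""Quantitative-microscopy chain: well intensities, standard curve,
concentration inversion and one-phase-decay half-life."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopbpk import (
    OnePhaseDecay,
    StandardCurveRegressor,
    StudyDesign,
    build_standard_curve,
    concentration_from_intensity,
    fit_one_phase_decay,
    generate_decay_dataset,
    generate_plate,
    quantify_plate,
    well_intensity,
)
from nanopbpk.quantify import DecayFitError, ExtrapolationWarning, half_life_from_samples


class TestWellIntensity:
    def test_all_zero_images(self):
        w = well_intensity(np.zeros((9, 4, 4)), 0.0)
        assert w.corrected_intensity == 0.0

    def test_uniform_images(self):
        v, n_pix, b = 3.0, 16, 10.0
        w = well_intensity(np.full((9, 4, 4), v), b)
        assert w.corrected_intensity == pytest.approx(v * n_pix - b)

    def test_mean_of_sums_minus_background(self):
        images = [np.full((2, 2), s / 4) for s in (100.0, 110.0, 120.0)]
        w = well_intensity(images, 10.0)
        assert w.corrected_intensity == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            well_intensity(np.empty((0, 4, 4)), 0.0)


class TestStandardCurve:
    def test_exact_line_recovered(self):
        c = np.array([0.0, 10.0, 50.0, 100.0, 250.0])
        curve = build_standard_curve(c, 4.0 * c + 7.0)
        assert curve.slope == pytest.approx(4.0)
        assert curve.intercept == pytest.approx(7.0)
        assert curve.r2 == pytest.approx(1.0)

    def test_zero_concentration_standard_gives_finite_intercept(self):
        c = np.array([0.0, 0.0, 100.0, 200.0])
        y = 2.0 * c + np.array([1.0, -1.0, 0.5, -0.5])
        curve = build_standard_curve(c, y)
        assert np.isfinite(curve.intercept)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(21)
        c = np.linspace(0, 250, 10)
        y = 4.0 * c + 7.0 + rng.normal(0, 0.5, 10)
        est = StandardCurveRegressor().fit(c, y)
        # OLS slope standard error
        resid = y - est.predict(c)
        se = np.sqrt(resid.var(ddof=2) / np.sum((c - c.mean()) ** 2))
        assert abs(est.slope_ - 4.0) < 3 * se

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError):
            build_standard_curve([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            build_standard_curve([1.0, 2.0], [1.0, 2.0])


class TestConcentrationInversion:
    def test_intensity_at_intercept_is_zero(self):
        curve = build_standard_curve([0.0, 5.0, 10.0], [7.0, 27.0, 47.0])
        assert concentration_from_intensity(curve, 7.0) == pytest.approx(0.0, abs=1e-9)

    def test_exact_inversion(self):
        curve = build_standard_curve([0.0, 5.0, 10.0], [7.0, 27.0, 47.0])
        assert concentration_from_intensity(curve, 47.0) == pytest.approx(10.0)

    def test_below_intercept_clamped_with_flag(self):
        curve = build_standard_curve([0.0, 5.0, 10.0], [7.0, 27.0, 47.0])
        with pytest.warns(ExtrapolationWarning):
            assert concentration_from_intensity(curve, 2.0) == 0.0

    def test_round_trip_through_curve(self):
        slope, b = 3.5, 12.0
        c = np.array([0.0, 20.0, 80.0, 250.0])
        curve = build_standard_curve(c, slope * c + b)
        for conc in (0.0, 10.0, 137.5, 250.0):
            value, extrapolated = curve.invert(slope * conc + b)
            assert value == pytest.approx(conc, abs=1e-9)
            assert not extrapolated


class TestOnePhaseDecay:
    def test_noiseless_recovery_at_study_times(self):
        design = StudyDesign()
        t = np.asarray(design.blood_times)
        c = 250.0 * np.exp(-np.log(2) * t / 24.0)
        fit = fit_one_phase_decay(t, c)
        assert fit.C0 == pytest.approx(250.0, rel=1e-6)
        assert fit.t_half == pytest.approx(24.0, rel=1e-6)

    def test_half_life_identity(self):
        t = np.linspace(0, 48, 20)
        fit = fit_one_phase_decay(t, 10.0 * np.exp(-0.0693147 * t))
        assert fit.t_half == pytest.approx(10.0, abs=1e-4)

    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    @settings(deadline=None, max_examples=20)
    def test_scale_equivariance(self, scale):
        t = np.linspace(0, 48, 12)
        c = 100.0 * np.exp(-0.05 * t)
        a = fit_one_phase_decay(t, c)
        b = fit_one_phase_decay(t, scale * c)
        assert b.t_half == pytest.approx(a.t_half, rel=1e-6)
        assert b.C0 == pytest.approx(scale * a.C0, rel=1e-6)

    def test_duplicate_points_leave_fit_unchanged(self):
        t = np.linspace(0, 48, 12)
        c = 100.0 * np.exp(-0.05 * t)
        a = fit_one_phase_decay(t, c)
        b = fit_one_phase_decay(np.concatenate([t, t[:3]]), np.concatenate([c, c[:3]]))
        assert b.t_half == pytest.approx(a.t_half, rel=1e-6)

    def test_non_decaying_data_rejected(self):
        t = np.linspace(0, 10, 6)
        with pytest.raises(DecayFitError):
            fit_one_phase_decay(t, 1.0 + 0.5 * t)

    def test_estimator_interface(self):
        t = np.linspace(0, 48, 12)
        est = OnePhaseDecay().fit(t, 50.0 * np.exp(-0.1 * t))
        assert est.k_ == pytest.approx(0.1, rel=1e-6)
        assert est.predict([0.0])[0] == pytest.approx(50.0, rel=1e-6)
        assert "xtol" in est.get_params()

    def test_median_half_life_under_study_noise(self):
        # 10% multiplicative noise, 3 animals x 11 times, many replicate
        # studies: the pooled estimator's median lands close to truth
        design = StudyDesign()
        estimates = []
        for seed in range(200):
            ds = generate_decay_dataset(250.0, 24.0, design, sigma=0.10, seed=seed)
            fit = fit_one_phase_decay(ds.rows.time.values, ds.rows.concentration.values)
            estimates.append(fit.t_half)
        assert np.median(estimates) == pytest.approx(24.0, rel=0.05)


class TestPlateChain:
    def test_noiseless_plate_round_trips_exactly(self, phys):
        design = StudyDesign(seed=0)
        wells, layout = generate_plate(design, curve_truth=(40.0, 500.0), noise_frac=0.0)
        samples, curve = quantify_plate(wells, layout)
        assert curve.slope == pytest.approx(40.0, rel=1e-9)
        t = samples.time.values.astype(float)
        expected = 250.0 * np.exp(-np.log(2) * t / 24.0)
        assert samples.concentration.values == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_zero_standard_corrected_to_zero(self):
        design = StudyDesign(seed=0)
        wells, layout = generate_plate(design, curve_truth=(40.0, 500.0), noise_frac=0.0)
        from nanopbpk.quantify import plate_background

        bg = plate_background(wells, layout)
        blank = layout[(layout.role == "standard") & (layout.concentration == 0)].well.iloc[0]
        assert well_intensity(wells[blank], bg).corrected_intensity == pytest.approx(0.0, abs=1e-9)

    def test_recovered_slope_within_three_se_under_noise(self):
        design = StudyDesign(seed=7)
        wells, layout = generate_plate(design, curve_truth=(40.0, 500.0), noise_frac=0.01)
        _, curve = quantify_plate(wells, layout)
        # noise sd is 1% of full scale = 100 units; 12 standards over 0-250
        conc = layout[layout.role == "standard"].concentration.values
        se = 100.0 / np.sqrt(np.sum((conc - conc.mean()) ** 2))
        assert abs(curve.slope - 40.0) < 3 * se

    def test_group_half_life_from_plate(self):
        design = StudyDesign(seed=0)
        wells, layout = generate_plate(design, curve_truth=(40.0, 500.0), noise_frac=0.0)
        samples, _ = quantify_plate(wells, layout)
        report = half_life_from_samples(samples)
        assert report.t_half.iloc[0] == pytest.approx(24.0, rel=1e-6)
        per_animal = half_life_from_samples(samples, per_animal=True)
        assert len(per_animal) == design.n_animals
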