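"""Traveling-wave calibration: corrections, fits, and round trips."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twimsccs import (
    CalibrantIon,
    CalibrationError,
    CalibrationModel,
    ForwardModelSpec,
    doubly_corrected_time,
    edc_correct,
    estimate_ccs,
    fit_calibration,
    fit_exponent,
    gen_analyte_drift_time,
    gen_calibrant_set,
    read_calibrants_csv,
    reduced_ccs,
)


class TestEdcCorrect:
    def test_null_coefficient(self):
        assert edc_correct(10.0, 2500.0, 0.0) == 10.0

    def test_protein_instrument_arithmetic(self):
        # 1.57 * sqrt(2500)/1000 = 0.0785 ms
        assert edc_correct(10.0, 2500.0, 1.57) == pytest.approx(9.9215)

    def test_rna_instrument_arithmetic(self):
        # 1.41 * sqrt(10000)/1000 = 0.141 ms
        assert edc_correct(5.0, 10_000.0, 1.41) == pytest.approx(4.859)

    def test_consumed_drift_time_raises(self):
        with pytest.raises(CalibrationError, match="exhausted"):
            edc_correct(0.05, 10_000.0, 1.57)


class TestReducedCcs:
    def test_identity_parameters(self):
        assert reduced_ccs(1234.0, 1, 1.0) == pytest.approx(1234.0)

    def test_direct_arithmetic(self):
        assert reduced_ccs(1000.0, 10, 25.0) == pytest.approx(500.0)

    def test_inverse_in_charge(self):
        assert reduced_ccs(800.0, 10, 9.0) == pytest.approx(
            reduced_ccs(800.0, 5, 9.0) / 2)


class TestDoublyCorrectedTime:
    def test_identity_parameters(self):
        assert doubly_corrected_time(3.7, 1.0, 1, 1.0) == pytest.approx(3.7)

    def test_direct_arithmetic(self):
        # 4^0.5 * 2 * (1/4)^0.5 = 2
        assert doubly_corrected_time(4.0, 0.5, 2, 4.0) == pytest.approx(2.0)

    def test_linear_in_charge(self):
        assert doubly_corrected_time(4.0, 0.5, 6, 4.0) == pytest.approx(
            3 * doubly_corrected_time(4.0, 0.5, 2, 4.0))


class TestFitExponent:
    def test_recovers_generating_parameters(self, noise_free_spec,
                                            noise_free_calibrants):
        X, ln_A, r2 = fit_exponent(noise_free_calibrants, noise_free_spec.c_edc,
                                   noise_free_spec.gas_mass)
        assert X == pytest.approx(noise_free_spec.X_true, abs=1e-6)
        assert ln_A == pytest.approx(noise_free_spec.ln_A_true, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self, noise_free_spec):
        ions = [("a", 40_000.0, 12, 3500.0), ("b", 150_000.0, 24, 7000.0)]
        cal = gen_calibrant_set(noise_free_spec, ions)
        X, _, r2 = fit_exponent(cal, noise_free_spec.c_edc,
                                noise_free_spec.gas_mass)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert X == pytest.approx(noise_free_spec.X_true, abs=1e-9)

    def test_noisy_omega_recovery_unbiased(self, noise_free_spec):
        # 1% noise on the reduced cross-sections (the regression response):
        # the mean exponent over many instruments stays within 1% of truth
        xs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            clean = gen_calibrant_set(noise_free_spec)
            noisy = [CalibrantIon(c.label, c.neutral_mass, c.z,
                                  c.published_ccs * (1 + 0.01 * rng.standard_normal()),
                                  c.drift_time)
                     for c in clean]
            X, _, _ = fit_exponent(noisy, noise_free_spec.c_edc,
                                   noise_free_spec.gas_mass)
            xs.append(X)
        assert np.mean(xs) == pytest.approx(0.55, rel=0.01)

    def test_noisy_drift_time_recovery(self):
        # noise on drift times sits on the regression predictor, so the
        # fitted exponent carries a small attenuation (regression-dilution)
        # bias; the mean stays within ~2% of truth at 1% drift-time noise
        xs = []
        for seed in range(100):
            spec = ForwardModelSpec(X_true=0.55, ln_A_true=6.0,
                                    noise_sd_rel=0.01, seed=seed)
            cal = gen_calibrant_set(spec)
            X, _, _ = fit_exponent(cal, spec.c_edc, spec.gas_mass)
            xs.append(X)
        assert np.mean(xs) == pytest.approx(0.55, rel=0.02)

    def test_identical_times_singular(self):
        ions = [CalibrantIon("a", 40_000.0, 12, 3500.0, 8.0),
                CalibrantIon("b", 40_000.0, 12, 3600.0, 8.0)]
        with pytest.raises(CalibrationError, match="singular|identical"):
            fit_exponent(ions, 0.0, 28.0134)

    def test_single_calibrant_rejected(self):
        with pytest.raises(CalibrationError):
            fit_exponent([CalibrantIon("a", 40_000.0, 12, 3500.0, 8.0)],
                         1.57, 28.0134)


class TestFitCalibration:
    def test_noise_free_linear_r2_and_round_trip(self, noise_free_spec,
                                                 noise_free_calibrants):
        model = fit_calibration(noise_free_calibrants, noise_free_spec.c_edc,
                                noise_free_spec.gas_mass)
        assert model.r_squared_linear == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        assert model.slope == pytest.approx(noise_free_spec.slope_true, rel=1e-9)
        for ion in noise_free_calibrants:
            m = estimate_ccs(ion.label, ion.neutral_mass, ion.z,
                             ion.drift_time, model)
            assert m.estimated_ccs == pytest.approx(ion.published_ccs, rel=1e-12)

    def test_through_origin_variant(self, noise_free_spec, noise_free_calibrants):
        model = fit_calibration(noise_free_calibrants, noise_free_spec.c_edc,
                                noise_free_spec.gas_mass, through_origin=True)
        assert model.intercept == 0.0
        assert model.slope == pytest.approx(noise_free_spec.slope_true, rel=1e-9)

    def test_order_invariance(self, noise_free_spec, noise_free_calibrants):
        shuffled = list(noise_free_calibrants)
        random.Random(0).shuffle(shuffled)
        a = fit_calibration(noise_free_calibrants, noise_free_spec.c_edc,
                            noise_free_spec.gas_mass)
        b = fit_calibration(shuffled, noise_free_spec.c_edc,
                            noise_free_spec.gas_mass)
        assert a.X == pytest.approx(b.X, rel=1e-12)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)

    def test_serialization_round_trip(self, tmp_path, noise_free_spec,
                                      noise_free_calibrants):
        model = fit_calibration(noise_free_calibrants, noise_free_spec.c_edc,
                                noise_free_spec.gas_mass)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = CalibrationModel.from_json(str(p))
        assert back == model


class TestEstimateCcs:
    def test_monotone_in_drift_time(self, noise_free_spec, noise_free_calibrants):
        model = fit_calibration(noise_free_calibrants, noise_free_spec.c_edc,
                                noise_free_spec.gas_mass)
        ccs = [estimate_ccs("m", 80_000.0, 18, td, model).estimated_ccs
               for td in (6.0, 8.0, 10.0, 12.0)]
        assert ccs == sorted(ccs)

    def test_extrapolation_flag(self, noise_free_spec, noise_free_calibrants):
        model = fit_calibration(noise_free_calibrants, noise_free_spec.c_edc,
                                noise_free_spec.gas_mass)
        inside = gen_analyte_drift_time(noise_free_spec, 100_000.0, 20, 5500.0)
        assert not estimate_ccs("in", 100_000.0, 20, inside, model).extrapolated
        outside = gen_analyte_drift_time(noise_free_spec, 500_000.0, 40, 20_000.0)
        assert estimate_ccs("out", 500_000.0, 40, outside, model).extrapolated

    @given(st.floats(0.3, 0.8), st.floats(4.0, 8.0))
    @settings(max_examples=40, deadline=None)
    def test_round_trip_any_exponent(self, x_true, ln_a_true):
        # noise-free forward model is inverted exactly by the fitted chain
        spec = ForwardModelSpec(X_true=x_true, ln_A_true=ln_a_true, seed=0)
        cal = gen_calibrant_set(spec)
        model = fit_calibration(cal, spec.c_edc, spec.gas_mass)
        assert model.X == pytest.approx(x_true, abs=1e-6)
        td = gen_analyte_drift_time(spec, 75_000.0, 17, 4800.0)
        m = estimate_ccs("probe", 75_000.0, 17, td, model)
        assert m.estimated_ccs == pytest.approx(4800.0, rel=1e-9)

    def test_noisy_recovery_small_bias(self):
        # 1% drift-time noise: average CCS recovery bias stays below 0.5%
        errors = []
        for seed in range(100):
            spec = ForwardModelSpec(X_true=0.55, ln_A_true=6.0,
                                    noise_sd_rel=0.01, seed=seed)
            cal = gen_calibrant_set(spec)
            model = fit_calibration(cal, spec.c_edc, spec.gas_mass)
            truth = 5200.0
            td = gen_analyte_drift_time(spec, 90_000.0, 19, truth)
            m = estimate_ccs("probe", 90_000.0, 19, td, model)
            errors.append((m.estimated_ccs - truth) / truth)
        assert abs(np.mean(errors)) < 0.005


class TestCsvIo:
    def test_calibrant_csv(self, tmp_path, noise_free_calibrants):
        p = tmp_path / "cal.csv"
        lines = ["label,mass_da,charge,ccs_A2,drift_ms"] + [
            f"{c.label},{c.neutral_mass},{c.z},{c.published_ccs},{c.drift_time}"
            for c in noise_free_calibrants
        ]
        p.write_text("\n".join(lines) + "\n")
        back = read_calibrants_csv(p)
        assert back == noise_free_calibrants

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("label,mass_da\nx,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_calibrants_csv(p)
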