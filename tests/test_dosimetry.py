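"""Cumulated activity, residence times, dose, plasma comparator, half-life fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowdose import (
    RadionuclideConstants,
    ResidenceTimeSet,
    SValueTable,
    TimeActivityCurve,
    cumulated_concentration,
    fit_effective_half_life,
    plasma_rm_tac,
    remainder_residence,
    residence_time,
    rm_dose,
    scale_by_weight,
)
from marrowdose.errors import (
    ConfigurationError,
    DataError,
    DomainError,
    InconsistencyError,
)

ZR89 = RadionuclideConstants()


def tac(times, concs, volume=1.0, region="RM"):
    return TimeActivityCurve(region, np.asarray(times, float), np.asarray(concs, float), volume)


class TestRadionuclideConstants:
    def test_decay_constant_consistent_with_half_life(self):
        assert ZR89.decay_constant_per_h * ZR89.half_life_h == pytest.approx(math.log(2), rel=1e-12)

    def test_max_residence_time(self):
        assert ZR89.max_residence_time_h == pytest.approx(78.41 / math.log(2), rel=1e-12)


class TestCumulatedConcentration:
    def test_unit_trapezoid(self):
        assert cumulated_concentration(tac([0, 1], [1, 1]), tail=False) == pytest.approx(1.0)

    def test_dense_exponential_matches_closed_form(self):
        """Integral of C0 e^(-lambda t) sampled 0..600 h within 0.5 % of C0/lambda."""
        lam = ZR89.decay_constant_per_h
        t = np.arange(0.0, 601.0, 1.0)
        curve = tac(t, 1000.0 * np.exp(-lam * t))
        assert cumulated_concentration(curve, ZR89) == pytest.approx(1000.0 / lam, rel=0.005)

    def test_tail_term_alone_is_half_life_over_ln2(self):
        """Decay tail of a unit endpoint equals 78.41/ln2 = 113.12 h."""
        curve = tac([143.0, 144.0], [1.0, 1.0])
        with_tail = cumulated_concentration(curve, ZR89, lead_in="none")
        assert with_tail - 1.0 == pytest.approx(78.41 / math.log(2), rel=1e-12)

    def test_convergence_with_sampling_density(self):
        """Trapezoid error decreases monotonically as dt -> 0."""
        lam = ZR89.decay_constant_per_h
        errors = []
        for dt in (10.0, 1.0, 0.1):
            t = np.arange(0.0, 600.0 + dt / 2, dt)
            got = cumulated_concentration(tac(t, np.exp(-lam * t)), ZR89)
            errors.append(abs(got - 1.0 / lam))
        assert errors[0] > errors[1] > errors[2]

    def test_lead_in_rules(self):
        curve = tac([2.0, 4.0], [3.0, 3.0])
        base = 6.0  # trapezoid over [2, 4]
        assert cumulated_concentration(curve, tail=False, lead_in="none") == pytest.approx(base)
        assert cumulated_concentration(curve, tail=False, lead_in="constant") == pytest.approx(base + 6.0)
        assert cumulated_concentration(curve, tail=False, lead_in="linear") == pytest.approx(base + 3.0)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 100.0))
    def test_linearity_in_concentration(self, scale):
        t = np.array([1.0, 24.0, 48.0, 96.0, 144.0])
        c = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        a = cumulated_concentration(tac(t, c), ZR89)
        b = cumulated_concentration(tac(t, scale * c), ZR89)
        assert b == pytest.approx(scale * a, rel=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            cumulated_concentration(tac([1.0], [1.0]))

    def test_unsorted_or_negative_curve_rejected(self):
        with pytest.raises(DataError):
            tac([2.0, 1.0], [1.0, 1.0])
        with pytest.raises(DataError):
            tac([1.0, 2.0], [1.0, -1.0])


class TestResidenceTime:
    def test_definitional_identity(self):
        # cumulated activity = injected * 1 h  ->  tau = 1 h
        injected = 37.1
        cumc = injected * 1.0e6 / 1120.0  # Bq.h/mL over the reference volume
        assert residence_time(cumc, 1120.0, injected) == pytest.approx(1.0)

    def test_whole_body_physical_decay_only(self):
        """tau of the entire injection decaying physically = T_half/ln2 = 113.12 h."""
        injected = 1.0
        cumc = injected * 1.0e6 / math.log(2) * 78.41  # C0/lambda with C0 = A0/V, V = 1 mL
        assert residence_time(cumc, 1.0, injected) == pytest.approx(78.41 / math.log(2), rel=1e-9)

    def test_linear_in_volume(self):
        assert residence_time(50.0, 2000.0, 37.1) == pytest.approx(
            2 * residence_time(50.0, 1000.0, 37.1)
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            residence_time(0.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            residence_time(1.0, 1.0, -2.0)


class TestRemainderResidence:
    def test_no_source_organs(self):
        assert remainder_residence({}, ZR89) == pytest.approx(78.41 / math.log(2), rel=1e-12)

    def test_closure_with_full_tau(self):
        full = ZR89.max_residence_time_h
        assert remainder_residence({"RM": full}, ZR89) == pytest.approx(0.0, abs=1e-12)

    def test_excess_tau_rejected_naming_excess(self):
        with pytest.raises(InconsistencyError, match="exceed"):
            remainder_residence({"RM": 120.0}, ZR89)

    def test_closure_property_random_tau_sets(self):
        """tau_RB + sum(tau) = T_half/ln2 to machine precision, 50 random sets."""
        rng = np.random.default_rng(3)
        max_tau = ZR89.max_residence_time_h
        for _ in range(50):
            n = rng.integers(1, 8)
            parts = rng.dirichlet(np.ones(n)) * max_tau * rng.uniform(0, 1)
            taus = {f"organ{i}": float(p) for i, p in enumerate(parts)}
            rb = remainder_residence(taus, ZR89)
            assert rb + sum(taus.values()) == pytest.approx(max_tau, abs=1e-9)


class TestWeightScaling:
    def test_reference_weight_is_identity(self):
        assert scale_by_weight(5.0, 73.7, 73.7) == pytest.approx(5.0)

    def test_double_weight_halves_tau(self):
        assert scale_by_weight(5.0, 2 * 73.7, 73.7) == pytest.approx(2.5)

    def test_zero_weight_rejected(self):
        with pytest.raises(DomainError):
            scale_by_weight(5.0, 0.0, 73.7)


class TestRmDose:
    def _svalues(self, table):
        return SValueTable(
            s_mGy_per_MBq_h=table, reference_rm_volume_mL=1120.0, reference_body_weight_kg=73.7
        )

    def test_single_source_product(self):
        s = self._svalues({("RM", "RM"): 0.5, ("RM", "RB"): 0.0})
        taus = ResidenceTimeSet(tau_h={"RM": 2.0}, tau_remainder_h=0.0, injected_MBq=37.1)
        report = rm_dose(taus, s)
        assert report.self_rm_dose_mGy_per_MBq == pytest.approx(1.0)
        assert report.total_rm_dose_mGy_per_MBq == pytest.approx(1.0)

    def test_zero_taus_zero_dose(self):
        s = self._svalues({("RM", "RM"): 0.5, ("RM", "RB"): 0.2})
        taus = ResidenceTimeSet(tau_h={"RM": 0.0}, tau_remainder_h=0.0, injected_MBq=1.0)
        assert rm_dose(taus, s).total_rm_dose_mGy_per_MBq == 0.0

    def test_two_sources_hand_sum(self):
        s = self._svalues({("RM", "RM"): 0.3, ("RM", "liver"): 0.05, ("RM", "RB"): 0.01})
        taus = ResidenceTimeSet(
            tau_h={"RM": 2.0, "liver": 10.0}, tau_remainder_h=50.0, injected_MBq=37.1
        )
        report = rm_dose(taus, s)
        assert report.self_rm_dose_mGy_per_MBq == pytest.approx(0.6)
        assert report.total_rm_dose_mGy_per_MBq == pytest.approx(0.3 * 2 + 0.05 * 10 + 0.01 * 50)
        assert report.total_rm_dose_mGy_per_MBq >= report.self_rm_dose_mGy_per_MBq

    def test_missing_s_entry_names_the_pair(self):
        s = self._svalues({("RM", "RM"): 0.3, ("RM", "RB"): 0.01})
        taus = ResidenceTimeSet(
            tau_h={"RM": 1.0, "spleen": 1.0}, tau_remainder_h=0.0, injected_MBq=1.0
        )
        with pytest.raises(ConfigurationError, match="spleen"):
            rm_dose(taus, s)

    def test_table_requires_rm_and_rb_entries(self):
        with pytest.raises(ConfigurationError):
            self._svalues({("RM", "RM"): 0.3})

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_linearity_in_taus(self, scale):
        s = self._svalues({("RM", "RM"): 0.3, ("RM", "RB"): 0.01})
        t1 = ResidenceTimeSet(tau_h={"RM": 2.0}, tau_remainder_h=5.0, injected_MBq=1.0)
        t2 = ResidenceTimeSet(tau_h={"RM": 2.0 * scale}, tau_remainder_h=5.0 * scale, injected_MBq=1.0)
        assert rm_dose(t2, s).total_rm_dose_mGy_per_MBq == pytest.approx(
            scale * rm_dose(t1, s).total_rm_dose_mGy_per_MBq, rel=1e-9
        )


class TestPlasmaMethod:
    def test_fixed_factor_scales_concentrations(self):
        plasma = tac([1, 24, 48], [1000.0, 800.0, 600.0], region="plasma")
        rm = plasma_rm_tac(plasma)
        np.testing.assert_allclose(rm.conc_Bq_per_mL, [190.0, 152.0, 114.0])
        assert rm.region == "RM-plasma-method"

    def test_factor_one_is_identity(self):
        plasma = tac([1, 24], [500.0, 400.0], region="plasma")
        np.testing.assert_array_equal(plasma_rm_tac(plasma, 1.0).conc_Bq_per_mL, plasma.conc_Bq_per_mL)

    def test_empty_curve_stays_empty(self):
        plasma = tac([], [], region="plasma")
        assert len(plasma_rm_tac(plasma)) == 0

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(DomainError):
            plasma_rm_tac(tac([1, 2], [1, 1]), factor=0.0)


class TestEffectiveHalfLife:
    def test_exact_exponential_recovery(self):
        t = np.array([1.0, 24.0, 48.0, 96.0, 144.0])
        curve = tac(t, np.exp(-math.log(2) / 50.0 * t))
        assert fit_effective_half_life(curve) == pytest.approx(50.0, rel=1e-9)

    def test_constant_curve_flagged_infinite(self):
        with pytest.warns(UserWarning):
            assert fit_effective_half_life(tac([1, 24, 48], [5.0, 5.0, 5.0])) == math.inf

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(DomainError):
            fit_effective_half_life(tac([1, 24], [1.0, 0.0]))

    def test_recovery_under_multiplicative_noise(self):
        """Mean fit over 100 noisy replicates within 2 % of the generating 73 h."""
        rng = np.random.default_rng(42)
        t = np.array([1.0, 24.0, 48.0, 96.0, 144.0])
        true = 73.0
        clean = np.exp(-math.log(2) / true * t)
        fits = [
            fit_effective_half_life(tac(t, clean * (1 + rng.normal(0, 0.02, t.size))))
            for _ in range(100)
        ]
        assert np.mean(fits) == pytest.approx(true, rel=0.02)

    def test_phantom_series_recovers_generator_half_life(self, clean_phantom_run):
        """TAC from the delineated phantom fits the generator's 73 h, < 78.41 h."""
        from marrowdose import extract_tac

        spec, pets, result, _ = clean_phantom_run
        curve = extract_tac(result.c3_intraosseous[3], pets)
        fitted = fit_effective_half_life(curve)
        assert fitted == pytest.approx(spec.effective_half_life_h, rel=0.01)
        assert fitted < 78.41
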