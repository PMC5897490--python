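"""Generative model: GHK permeation, threshold curve, sweep synthesis,
population variability, detection-offset calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from anophys import analysis as A
from anophys import simulate as S
from anophys.pipeline import short_protocol, standard_protocol


class TestGHK:
    def test_symmetric_single_ion_zero_at_zero_mv(self):
        perm = S.PermeationSpec(ions=(S.IonSpec("Cl", -1, 140, 140, 1.0),))
        assert S.ghk_current(perm, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_continuous_at_zero(self, nonselective):
        eps = 1e-6
        left = S.ghk_current(nonselective, -eps)
        right = S.ghk_current(nonselective, eps)
        at0 = S.ghk_current(nonselective, 0.0)
        assert left == pytest.approx(at0, abs=1e-3)
        assert right == pytest.approx(at0, abs=1e-3)

    def test_biionic_reversal_matches_closed_form(self):
        # internal cation X vs external cation Y: V_rev = vt ln(P_Y c_Y / P_X c_X)
        perm = S.PermeationSpec(ions=(
            S.IonSpec("X", 1, 120.0, 0.0, 1.0),
            S.IonSpec("Y", 1, 0.0, 85.0, 1.7),
        ))
        expected = S.THERMAL_VOLTAGE_MV * math.log(1.7 * 85.0 / (1.0 * 120.0))
        assert S.ghk_reversal(perm) == pytest.approx(expected, abs=1e-6)

    def test_single_ion_reversal_is_nernst(self):
        perm = S.PermeationSpec(ions=(S.IonSpec("K", 1, 140.0, 14.0, 1.0),))
        nernst = S.THERMAL_VOLTAGE_MV * math.log(14.0 / 140.0)
        assert S.ghk_reversal(perm) == pytest.approx(nernst, abs=0.01)

    def test_calibrated_anion_ratio_reproduces_prepulse_current_ratio(self):
        spec = S.get_permeation("nonselective_calibrated")
        hi = S.ghk_current(spec, 140.0)
        lo = S.ghk_current(spec.with_bath(Na=10.0, Cl=10.0), 140.0)
        assert lo / hi == pytest.approx(0.69, abs=0.01)

    def test_bath_exchange_reversal_shifts(self):
        # equal cation/anion permeabilities: < 5 mV shift on NaCl reduction;
        # anion-only spec: full Nernst-predicted shift
        ns = S.get_permeation("nonselective")
        shift = (S.ghk_reversal(ns.with_bath(Na=10.0, Cl=10.0))
                 - S.ghk_reversal(ns))
        assert abs(shift) < 5.0
        an = S.get_permeation("anion_selective")
        nernst = S.THERMAL_VOLTAGE_MV * (math.log(136.0 / 10.0)
                                         - math.log(136.0 / 140.0))
        shift_an = (S.ghk_reversal(an.with_bath(Cl=10.0), bracket=(-150, 200))
                    - S.ghk_reversal(an))
        assert shift_an == pytest.approx(nernst, abs=0.01)


class TestTrueThreshold:
    def test_zero_ca_plateau(self):
        g = S.get_gating("WT-CHO")
        assert S.true_threshold(0.0, g) == pytest.approx(127.0)

    def test_saturating_ca_plateau(self):
        g = S.get_gating("WT-CHO")
        assert S.true_threshold(1e9, g) == pytest.approx(62.0, abs=1e-3)

    def test_ec50_gives_exact_midpoint(self):
        g = S.get_gating("WT-CHO")
        mid = 0.5 * (127.0 + 62.0)
        assert S.true_threshold(g.ec50_um, g) == pytest.approx(mid)

    def test_strictly_decreasing(self):
        g = S.get_gating("WT-CHO")
        cas = np.logspace(-2, 3, 30)
        vals = [S.true_threshold(c, g) for c in cas]
        assert np.all(np.diff(vals) < 0)

    def test_negative_ca_rejected(self):
        with pytest.raises(ValueError):
            S.true_threshold(-1.0, S.get_gating("WT-CHO"))


class TestSimulateSweepSet:
    def test_below_threshold_step_has_no_relaxation(self, quiet_gating,
                                                    nonselective,
                                                    standard_protocol):
        rec = S.simulate_sweep_set(quiet_gating, nonselective,
                                   standard_protocol, 3.0, seed=0)
        iv = A.extract_amplitudes(rec)
        far_below = iv.voltages_mV < 0
        # residual relaxation far below threshold is << noise / detection scale
        assert np.all(np.abs(iv.difference_pA[far_below]) < 0.5)

    def test_noiseless_relaxation_recovers_tau(self, quiet_gating,
                                               nonselective,
                                               standard_protocol):
        rec = S.simulate_sweep_set(quiet_gating, nonselective,
                                   standard_protocol, 3.0, seed=0)
        fit = A.fit_relaxation(rec, 14)  # +180 mV sweep
        assert fit.ok
        assert fit.tau_ms == pytest.approx(quiet_gating.tau_ms, rel=0.01)

    def test_outward_rectification(self, nonselective, standard_protocol):
        g = S.get_gating("WT-HEK")
        rec = S.simulate_sweep_set(g, nonselective, standard_protocol, 3.0,
                                   seed=5)
        iv = A.extract_amplitudes(rec)
        assert abs(iv.steady_pA[-1]) >= 10.0 * abs(iv.steady_pA[0])

    def test_quiet_at_holding_before_step(self, nonselective,
                                          standard_protocol):
        g = S.get_gating("WT-HEK")
        rec = S.simulate_sweep_set(g, nonselective, standard_protocol, 3.0,
                                   seed=5)
        khz = standard_protocol.sampling_khz
        baseline = rec.sweeps_pA[:, 5:int(standard_protocol.baseline_ms * khz) - 5]
        assert np.abs(baseline.mean()) < 3.0 * g.noise_sd_pA

    def test_deterministic_for_fixed_seed(self, nonselective,
                                          standard_protocol):
        g = S.get_gating("WT-HEK")
        a = S.simulate_sweep_set(g, nonselective, standard_protocol, 3.0, seed=9)
        b = S.simulate_sweep_set(g, nonselective, standard_protocol, 3.0, seed=9)
        np.testing.assert_array_equal(a.sweeps_pA, b.sweeps_pA)


class TestSimulatePopulation:
    def test_zero_variability_matches_single_cell(self, nonselective,
                                                  standard_protocol):
        g = S.get_gating("WT-HEK")
        pop = S.PopulationSpec(n=1, gating=g, perm=nonselective, ca_um=3.0,
                               midpoint_sd_mV=0.0, conductance_cv=0.0,
                               base_seed=21)
        rec_pop = S.simulate_population(pop, standard_protocol)[0]
        rec_single = S.simulate_sweep_set(g, nonselective, standard_protocol,
                                          3.0, seed=21)
        np.testing.assert_array_equal(rec_pop.sweeps_pA, rec_single.sweeps_pA)

    def test_same_seed_bit_identical(self, nonselective, standard_protocol):
        g = S.get_gating("WT-HEK")
        pop = S.PopulationSpec(n=4, gating=g, perm=nonselective, ca_um=3.0,
                               base_seed=3)
        a = S.simulate_population(pop, standard_protocol)
        b = S.simulate_population(pop, standard_protocol)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.sweeps_pA, rb.sweeps_pA)

    def test_population_mean_threshold_near_calibration_anchor(
            self, nonselective, standard_protocol):
        """WT population at 3 uM analysed end to end lands in the 88-mV band."""
        g = S.get_gating("WT-HEK")
        pop = S.PopulationSpec(n=31, gating=g, perm=nonselective, ca_um=3.0,
                               midpoint_sd_mV=15.6, base_seed=77)
        thr = []
        for rec in S.simulate_population(pop, standard_protocol):
            res = A.detect_threshold(A.extract_amplitudes(rec))
            if res.detected:
                thr.append(res.v_threshold_mV)
        sem = np.std(thr, ddof=1) / math.sqrt(len(thr))
        assert np.mean(thr) == pytest.approx(88.1, abs=2 * 2.8 + 2 * sem)


class TestSimulateControl:
    def test_zero_noise_is_exactly_ohmic(self, standard_protocol):
        rec = S.simulate_control(standard_protocol, noise_sd_pA=0.0,
                                 leak_ns=1.0, seed=0)
        khz = standard_protocol.sampling_khz
        i0 = int((standard_protocol.step_start_ms + 50) * khz)
        expected = standard_protocol.step_voltages * 1.0
        np.testing.assert_allclose(rec.sweeps_pA[:, i0], expected, atol=1e-9)

    def test_no_threshold_detected(self, standard_protocol):
        rec = S.simulate_control(standard_protocol, seed=4)
        res = A.detect_threshold(A.extract_amplitudes(rec))
        assert not res.detected

    def test_high_ca_background_only_at_top_voltages(self, standard_protocol):
        rec = S.simulate_control(standard_protocol, seed=4, ca_um=240.0)
        iv = A.extract_amplitudes(rec)
        res = A.detect_threshold(iv)
        assert res.detected and res.v_threshold_mV >= 160.0


class TestCalibrateDetectionOffset:
    def test_steep_gating_quantization_bias(self, nonselective,
                                            standard_protocol):
        """Near-step gating: detection falls on the first step at/above the
        midpoint, so the bias lies in [0, increment)."""
        g = replace(S.get_gating("WT-CHO"), slope_mV=0.5, noise_sd_pA=0.1,
                    cap_amp_pA=0.0, leak_ns=0.0, detection_offset_mV=0.0)
        for mid_off in (-7.0, -3.0, 0.5, 6.0):
            rec = S.simulate_sweep_set(g, nonselective, standard_protocol,
                                       3.0, seed=1, v_mid_offset_mV=mid_off)
            res = A.detect_threshold(A.extract_amplitudes(rec))
            true_mid = S.true_threshold(3.0, g) + mid_off
            assert res.detected
            bias = res.v_threshold_mV - true_mid
            assert 0.0 <= bias < standard_protocol.increment_mV

    def test_recalibration_is_a_fixed_point(self, nonselective):
        """Applying calibration to an already-calibrated set returns the
        stored offset to within the Monte-Carlo resolution."""
        sets = S.load_param_sets()
        entry = sets["gating"]["WT-HEK"]
        g = S.get_gating("WT-HEK")
        delta = S.calibrate_detection_offset(
            g, nonselective, standard_protocol(), 3.0,
            target_mean_mV=88.1, n_cells=400, base_seed=12345,
            midpoint_sd_mV=entry["midpoint_sd_mV"],
            conductance_cv=entry["conductance_cv"],
            bracket=(entry["detection_offset_mV"] - 8.0,
                     entry["detection_offset_mV"] + 8.0))
        assert delta == pytest.approx(entry["detection_offset_mV"], abs=1.5)

    def test_unreachable_target_raises(self, nonselective, standard_protocol):
        g = S.get_gating("WT-HEK")
        with pytest.raises(S.CalibrationError):
            S.calibrate_detection_offset(g, nonselective, standard_protocol,
                                         3.0, target_mean_mV=500.0,
                                         n_cells=30, bracket=(30.0, 50.0))


def test_parameter_set_lookup_errors():
    with pytest.raises(KeyError):
        S.get_gating("no-such-set")
    with pytest.raises(KeyError):
        S.get_permeation("no-such-spec")
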