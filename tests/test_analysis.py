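"""Amplitude windows, threshold statistic, relaxation and Hill fits,
tail-current reversal potentials."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anophys import analysis as A
from anophys import simulate as S
from anophys.pipeline import standard_protocol, tail_protocol
from anophys.recordings import Recording, RecordingMeta, build_step_protocol


def _make_iv(volts, diff, noise):
    volts = np.asarray(volts, dtype=float)
    return A.IVCurve(voltages_mV=volts, instantaneous_pA=np.zeros_like(volts),
                     steady_pA=np.asarray(diff, dtype=float),
                     difference_pA=np.asarray(diff, dtype=float),
                     noise_sd_pA=np.asarray(noise, dtype=float))


class TestExtractAmplitudes:
    def test_ohmic_sweeps_have_zero_difference(self):
        proto = build_step_protocol()
        v = proto.step_voltages[:, None]
        sweeps = np.broadcast_to(v * 0.8, (proto.n_sweeps, proto.n_samples)).copy()
        rec = Recording(sweeps_pA=sweeps, protocol=proto, meta=RecordingMeta())
        iv = A.extract_amplitudes(rec)
        np.testing.assert_allclose(iv.difference_pA, 0.0, atol=1e-9)
        np.testing.assert_allclose(iv.noise_sd_pA, 0.0, atol=1e-9)

    def test_difference_matches_closed_form(self, quiet_gating, nonselective):
        """The window difference equals the relaxation increment computed
        directly from the generative equation."""
        proto = standard_protocol()
        ca = 3.0
        rec = S.simulate_sweep_set(quiet_gating, nonselective, proto, ca, seed=0)
        iv = A.extract_amplitudes(rec)

        g = quiet_gating
        v_mid = S.true_threshold(ca, g) + g.detection_offset_mV
        khz = proto.sampling_khz
        t = np.arange(proto.n_samples) / khz

        def window_mean(v, lo, hi):
            p0 = 1.0 / (1.0 + math.exp(v_mid / g.slope_mV))  # p at 0 mV holding
            pinf = 1.0 / (1.0 + math.exp(-(v - v_mid) / g.slope_mV))
            sel = (t >= proto.step_start_ms + lo) & (t < proto.step_start_ms + hi)
            tloc = t[sel] - proto.step_start_ms
            p = pinf + (p0 - pinf) * np.exp(-tloc / g.tau_ms)
            return g.gmax * S.ghk_current(nonselective, v) * p.mean()

        for j in (12, 13, 14):
            v = proto.step_voltages[j]
            expected = window_mean(v, 275, 300) - window_mean(v, 5, 10)
            assert iv.difference_pA[j] == pytest.approx(expected, rel=0.01)

    def test_window_outside_step_rejected(self, quiet_gating, nonselective):
        rec = S.simulate_sweep_set(quiet_gating, nonselective,
                                   standard_protocol(), 3.0, seed=0)
        with pytest.raises(ValueError, match="window"):
            A.extract_amplitudes(rec, steady_window_ms=(280.0, 320.0))


class TestDetectThreshold:
    def test_constructed_first_crossing_at_100mv(self):
        volts = np.arange(-100.0, 181.0, 20.0)
        diff = np.where(volts >= 100.0, 50.0, 1.0)
        iv = _make_iv(volts, diff, np.full(volts.size, 10.0))
        res = A.detect_threshold(iv)
        assert res.v_threshold_mV == 100.0
        assert not res.left_censored

    def test_control_yields_none(self, standard_protocol):
        rec = S.simulate_control(standard_protocol, seed=11)
        res = A.detect_threshold(A.extract_amplitudes(rec))
        assert res.v_threshold_mV is None and not res.detected

    def test_negative_differences_never_trigger(self):
        volts = np.arange(-100.0, 181.0, 20.0)
        iv = _make_iv(volts, np.full(volts.size, -100.0),
                      np.full(volts.size, 1.0))
        assert not A.detect_threshold(iv).detected

    def test_left_censored_flag(self):
        volts = np.arange(-100.0, 181.0, 20.0)
        iv = _make_iv(volts, np.full(volts.size, 100.0),
                      np.full(volts.size, 1.0))
        res = A.detect_threshold(iv)
        assert res.v_threshold_mV == -100.0 and res.left_censored

    def test_empty_curve_rejected(self):
        iv = _make_iv([], [], [])
        with pytest.raises(ValueError):
            A.detect_threshold(iv)

    @given(st.lists(st.floats(-50.0, 400.0), min_size=15, max_size=15),
           st.floats(0.0, 200.0))
    def test_adding_positive_offset_never_raises_threshold(self, diffs, shift):
        volts = np.arange(-100.0, 181.0, 20.0)
        noise = np.full(volts.size, 10.0)
        base = A.detect_threshold(_make_iv(volts, diffs, noise))
        shifted = A.detect_threshold(
            _make_iv(volts, np.asarray(diffs) + shift, noise))
        if base.detected:
            assert shifted.detected
            assert shifted.v_threshold_mV <= base.v_threshold_mV


class TestFitRelaxation:
    def test_recovers_generative_tau(self, quiet_gating, nonselective):
        rec = S.simulate_sweep_set(quiet_gating, nonselective,
                                   standard_protocol(), 3.0, seed=0)
        for segment in ("activation", "tail"):
            fit = A.fit_relaxation(rec, 14, segment=segment)
            assert fit.ok, fit.quality_flag
            assert fit.tau_ms == pytest.approx(60.0, rel=0.01)

    def test_offset_invariance(self, quiet_gating, nonselective):
        rec = S.simulate_sweep_set(quiet_gating, nonselective,
                                   standard_protocol(), 3.0, seed=0)
        tau0 = A.fit_relaxation(rec, 14).tau_ms
        rec.sweeps_pA += 500.0
        tau1 = A.fit_relaxation(rec, 14).tau_ms
        assert tau1 == pytest.approx(tau0, rel=1e-6)

    def test_pure_leak_is_flagged_not_raised(self, standard_protocol):
        proto = standard_protocol
        v = proto.step_voltages[:, None] * 1.0  # 1 nS ohmic leak
        sweeps = np.broadcast_to(v, (proto.n_sweeps, proto.n_samples)).copy()
        rec = Recording(sweeps_pA=sweeps, protocol=proto, meta=RecordingMeta())
        fit = A.fit_relaxation(rec, 14)
        assert not fit.ok
        assert fit.quality_flag == "amplitude_within_noise"

    def test_too_short_segment_rejected(self, quiet_gating, nonselective):
        proto = build_step_protocol(step_ms=6.0, rate_khz=1.0, tail_ms=0.0,
                                    tail_mV=None)
        rec = S.simulate_sweep_set(quiet_gating, nonselective, proto, 3.0,
                                   seed=0)
        with pytest.raises(ValueError, match="samples"):
            A.fit_relaxation(rec, 0)


class TestEstimateVrev:
    @pytest.fixture
    def b_gating(self):
        return replace(S.get_gating("TMEM16B-like"), noise_sd_pA=0.0,
                       leak_ns=0.0, cap_amp_pA=0.0)

    def test_symmetric_single_ion_reverses_at_zero(self, b_gating):
        perm = S.PermeationSpec(ions=(S.IonSpec("Cl", -1, 140.0, 140.0, 1.0),))
        rec = S.simulate_sweep_set(b_gating, perm, tail_protocol(-40, 80),
                                   3.0, seed=0)
        assert A.estimate_vrev(rec).v_rev_mV == pytest.approx(0.0, abs=0.5)

    def test_anion_only_bath_change_shifts_by_nernst(self, b_gating):
        perm = S.get_permeation("anion_selective")
        proto = tail_protocol(-40, 80)
        v_hi = A.estimate_vrev(
            S.simulate_sweep_set(b_gating, perm, proto, 3.0, seed=0),
            fit_window_mV=15.0).v_rev_mV
        v_lo = A.estimate_vrev(
            S.simulate_sweep_set(b_gating, perm.with_bath(Cl=10.0), proto,
                                 3.0, seed=0),
            fit_window_mV=15.0).v_rev_mV
        nernst = S.THERMAL_VOLTAGE_MV * (math.log(136.0 / 10.0)
                                         - math.log(136.0 / 140.0))
        assert v_lo - v_hi == pytest.approx(nernst, abs=1.0)

    def test_nonselective_bath_change_shifts_little(self, quiet_gating):
        perm = S.get_permeation("nonselective")
        proto = tail_protocol(-50, 50)
        v_hi = A.estimate_vrev(
            S.simulate_sweep_set(quiet_gating, perm, proto, 3.0, seed=0)).v_rev_mV
        v_lo = A.estimate_vrev(
            S.simulate_sweep_set(quiet_gating,
                                 perm.with_bath(Na=10.0, Cl=10.0), proto,
                                 3.0, seed=0)).v_rev_mV
        assert abs(v_lo - v_hi) < 5.0

    def test_matches_analytic_ghk_reversal(self, b_gating):
        perm = S.get_permeation("anion_selective").with_bath(Cl=10.0)
        rec = S.simulate_sweep_set(b_gating, perm, tail_protocol(-40, 80),
                                   3.0, seed=0)
        est = A.estimate_vrev(rec, fit_window_mV=15.0).v_rev_mV
        analytic = S.ghk_reversal(perm, bracket=(-150.0, 200.0))
        assert est == pytest.approx(analytic, abs=0.5)

    def test_no_sign_change_is_out_of_range(self, b_gating):
        perm = S.get_permeation("anion_selective").with_bath(Cl=10.0)
        proto = tail_protocol(-40, 30)  # all below V_rev ~ +66 mV
        rec = S.simulate_sweep_set(b_gating, perm, proto, 3.0, seed=0)
        with pytest.raises(ValueError, match="out of range"):
            A.estimate_vrev(rec)

    def test_requires_prepulse_protocol(self, quiet_gating, nonselective):
        rec = S.simulate_sweep_set(quiet_gating, nonselective,
                                   standard_protocol(), 3.0, seed=0)
        with pytest.raises(ValueError, match="prepulse"):
            A.estimate_vrev(rec)


def hill_grid_oracle(ca, y, ec50_grid, h_grid):
    """Brute-force global search: linear plateaus for each (EC50, h)."""
    best = (np.inf, None)
    for ec50 in ec50_grid:
        for h in h_grid:
            basis = np.where(ca > 0, 1.0 / (1.0 + (ca / ec50) ** h), 1.0)
            X = np.column_stack([1.0 - basis, basis])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(((X @ coef - y) ** 2).sum())
            if sse < best[0]:
                best = (sse, (coef[0], coef[1], ec50, h))
    return best


class TestFitHill:
    CAS = np.array([0.0, 1.0, 3.0, 9.0, 100.0, 240.0])

    def hill(self, ca, base, ymax, ec50, h):
        return np.where(ca > 0, base + (ymax - base) / (1 + (ca / ec50) ** h),
                        ymax)

    def test_exact_recovery_on_noiseless_points(self):
        y = self.hill(self.CAS, 62.0, 127.0, 2.9, 1.5)
        fit = A.fit_hill(self.CAS, y)
        assert fit.converged
        assert fit.ec50_um == pytest.approx(2.9, abs=1e-6)
        assert fit.hill == pytest.approx(1.5, abs=1e-6)
        assert fit.i_max == pytest.approx(127.0, abs=1e-6)
        assert fit.i_base == pytest.approx(62.0, abs=1e-6)

    def test_zero_concentration_maps_to_max_plateau_exactly(self):
        y = self.hill(self.CAS, 10.0, 50.0, 5.0, 2.0)
        fit = A.fit_hill(self.CAS, y)
        assert fit.i_max == pytest.approx(50.0, abs=1e-6)

    def test_optimizer_beats_grid_search_oracle(self, rng):
        y = self.hill(self.CAS, 62.0, 127.0, 2.9, 1.5) + rng.normal(0, 2.0, 6)
        fit = A.fit_hill(self.CAS, y)
        sse_fit = float((fit.residuals**2).sum())
        ec50_grid = np.geomspace(0.3, 30, 40)
        h_grid = np.linspace(0.3, 4.0, 40)
        sse_grid, params = hill_grid_oracle(self.CAS, y, ec50_grid, h_grid)
        assert sse_fit <= sse_grid + 1e-6
        assert fit.ec50_um == pytest.approx(params[2],
                                            abs=np.diff(ec50_grid).max())
        assert fit.hill == pytest.approx(params[3], abs=h_grid[1] - h_grid[0])

    @given(base=st.floats(30.0, 70.0), span=st.floats(30.0, 90.0),
           ec50=st.floats(0.8, 20.0), h=st.floats(0.6, 3.0))
    def test_noiseless_round_trip_random_parameters(self, base, span, ec50, h):
        y = self.hill(self.CAS, base, base + span, ec50, h)
        fit = A.fit_hill(self.CAS, y)
        assert fit.ec50_um == pytest.approx(ec50, rel=1e-4)
        assert fit.hill == pytest.approx(h, rel=1e-4)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            A.fit_hill([0.0, 1.0, 3.0], [1.0, 2.0, 3.0])

    def test_flat_data_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            A.fit_hill(self.CAS, np.full(6, 5.0))
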