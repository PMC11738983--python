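"""FP one-site fit, melt-curve Tm extraction and two-point CPMG R2."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trapkin as tk
from trapkin.errors import (
    InsufficientDataError, InvalidParameterError, NoTransitionError,
)
from trapkin.ensemble_assays import intensities_from_polarization

FP_GRID = np.array([1, 2, 3, 5, 7.5, 10, 15, 20, 30, 40, 60, 80.0])


class TestPolarization:
    def test_isotropic_emission_is_zero(self):
        assert tk.polarization(2.0, 2.0) == pytest.approx(0.0)

    def test_fully_polarized_limit(self):
        assert tk.polarization(1.0, 0.0) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        assert tk.polarization(3.0, 1.0) == pytest.approx(0.5)

    def test_zero_total_intensity_rejected(self):
        with pytest.raises(InvalidParameterError):
            tk.polarization(0.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(-0.999, 0.999))
    def test_round_trip_identity(self, p):
        I_par, I_perp = intensities_from_polarization(p)
        assert tk.polarization(I_par, I_perp) == pytest.approx(p, abs=1e-12)


class TestOneSiteFp:
    def test_noiseless_round_trip_to_three_figures(self):
        curve = tk.simulate_fp_titration(9.4, 100.0, FP_GRID, noise_sd=0.0)
        fit = tk.fit_one_site_fp(curve)
        assert fit.converged
        assert fit.K_D_uM == pytest.approx(9.4, rel=1e-3)
        assert fit.P_max_mP == pytest.approx(100.0, rel=1e-3)

    def test_half_saturation_point(self):
        curve = tk.simulate_fp_titration(9.4, 100.0, [9.4], noise_sd=0.0)
        assert curve.P_mP[0] == pytest.approx(50.0)

    def test_noisy_triplicate_recovery(self):
        curve = tk.simulate_fp_titration(
            9.4, 100.0, FP_GRID, noise_sd=2.0, seed=4, n_replicates=3
        )
        fit = tk.fit_one_site_fp(curve)
        assert fit.K_D_uM == pytest.approx(9.4, rel=0.15)

    def test_scale_equivariance(self):
        curve = tk.simulate_fp_titration(9.4, 100.0, FP_GRID, noise_sd=0.0)
        scaled = tk.FPCurve(concentrations_uM=curve.concentrations_uM,
                            P_mP=3.0 * curve.P_mP)
        a = tk.fit_one_site_fp(curve)
        b = tk.fit_one_site_fp(scaled)
        assert b.K_D_uM == pytest.approx(a.K_D_uM, rel=1e-6)
        assert b.P_max_mP == pytest.approx(3.0 * a.P_max_mP, rel=1e-6)

    def test_background_subtraction(self):
        curve = tk.simulate_fp_titration(9.4, 100.0, FP_GRID, noise_sd=0.0)
        shifted = tk.FPCurve(concentrations_uM=curve.concentrations_uM,
                             P_mP=curve.P_mP + 7.0)
        fit = tk.fit_one_site_fp(shifted, background_mP=7.0)
        assert fit.K_D_uM == pytest.approx(9.4, rel=1e-3)

    def test_intensity_channel_input(self):
        P = 0.1 * FP_GRID / (9.4 + FP_GRID)  # dimensionless polarization
        I_par, I_perp = intensities_from_polarization(P)
        curve = tk.FPCurve(concentrations_uM=FP_GRID, I_parallel=I_par,
                           I_perpendicular=I_perp)
        fit = tk.fit_one_site_fp(curve)
        assert fit.K_D_uM == pytest.approx(9.4, rel=1e-3)

    def test_too_few_concentrations_rejected(self):
        curve = tk.simulate_fp_titration(9.4, 100.0, [1.0, 5.0, 20.0])
        with pytest.raises(InsufficientDataError):
            tk.fit_one_site_fp(curve)


class TestMeltTm:
    GRID = np.arange(20.0, 90.0 + 1e-9, 0.1)

    def test_noiseless_recovery(self):
        curve = tk.simulate_melt_curve(53.5, 1.5, 0.8, 1.1, self.GRID)
        t_m, dfir = tk.melt_tm(curve)
        assert t_m == pytest.approx(53.5, abs=0.05)
        assert dfir.shape == self.GRID.shape

    def test_thermal_shift_between_replicate_curves(self):
        # mean shift across replicate melts (the ensemble measurement is
        # itself replicated) recovers the 0.8 degC stabilization
        shifts = []
        for s in range(5):
            apo = tk.simulate_melt_curve(52.7, 1.5, 0.8, 1.1, self.GRID,
                                         noise_sd=0.002, seed=2 * s)
            holo = tk.simulate_melt_curve(53.5, 1.5, 0.8, 1.1, self.GRID,
                                          noise_sd=0.002, seed=2 * s + 1)
            shifts.append(tk.melt_tm(holo)[0] - tk.melt_tm(apo)[0])
        assert np.mean(shifts) == pytest.approx(0.8, abs=0.1)

    def test_noisy_recovery_within_instrument_precision(self):
        rng_seeds = range(10)
        errs = []
        for s in rng_seeds:
            curve = tk.simulate_melt_curve(53.5, 1.5, 0.8, 1.1, self.GRID,
                                           noise_sd=0.005, seed=s)
            errs.append(abs(tk.melt_tm(curve)[0] - 53.5))
        assert np.median(errs) < 0.2

    def test_flat_curve_raises_no_transition(self):
        curve = tk.simulate_melt_curve(53.5, 1.5, 1.0, 1.0, self.GRID)
        with pytest.raises(NoTransitionError):
            tk.melt_tm(curve)

    def test_monotone_linear_ratio_raises_no_transition(self):
        curve = tk.MeltCurve(temperature_C=self.GRID,
                             ratio=0.8 + 0.001 * (self.GRID - 20.0))
        with pytest.raises(NoTransitionError):
            tk.melt_tm(curve)

    def test_invariance_to_common_intensity_scaling(self):
        curve = tk.simulate_melt_curve(53.5, 1.5, 0.8, 1.1, self.GRID)
        scaled = tk.MeltCurve(temperature_C=self.GRID,
                              I330=5.0 * curve.I330, I350=5.0 * curve.I350)
        assert tk.melt_tm(scaled)[0] == pytest.approx(tk.melt_tm(curve)[0],
                                                      abs=1e-9)

    def test_too_few_points_rejected(self):
        curve = tk.MeltCurve(temperature_C=np.linspace(20, 90, 10),
                             ratio=np.linspace(0.8, 1.1, 10))
        with pytest.raises(InsufficientDataError):
            tk.melt_tm(curve)


class TestCpmgR2:
    def test_equal_intensities_give_zero(self):
        pair = tk.CPMGPair(I_short=1.0, I_long=1.0)
        assert tk.cpmg_r2(pair) == pytest.approx(0.0)

    def test_closed_form(self):
        pair = tk.CPMGPair(I_short=float(np.e), I_long=1.0,
                           t_short_s=0.0, t_long_s=0.1)
        assert tk.cpmg_r2(pair) == pytest.approx(10.0)

    def test_round_trip_at_reported_rate(self):
        pair = tk.simulate_cpmg_pair(R2=6.93, I0=1.0)
        assert tk.cpmg_r2(pair) == pytest.approx(6.93, rel=1e-9)

    def test_round_trip_slow_relaxation(self):
        pair = tk.simulate_cpmg_pair(R2=1.85, I0=2.5)
        assert tk.cpmg_r2(pair) == pytest.approx(1.85, rel=1e-9)

    def test_growing_signal_warns_and_returns_negative(self):
        pair = tk.CPMGPair(I_short=1.0, I_long=2.0)
        with pytest.warns(UserWarning):
            r2 = tk.cpmg_r2(pair)
        assert r2 < 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(r2=st.floats(0.0, 50.0), i0=st.floats(0.1, 10.0),
           t_long=st.floats(0.01, 0.5))
    def test_noiseless_inversion_for_any_delays(self, r2, i0, t_long):
        pair = tk.simulate_cpmg_pair(R2=r2, I0=i0, t_short=0.002,
                                     t_long=0.002 + t_long)
        assert tk.cpmg_r2(pair) == pytest.approx(r2, abs=1e-8)
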