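"""Filtering, segmentation and filtered-signal density characterization."""

import numpy as np
import pytest

import trapkin as tk
from trapkin.errors import FitError, InsufficientDataError, InvalidParameterError


def _make_trace(values, fs, **kw):
    return tk.TrapTrace(values=np.asarray(values, dtype=float), fs=fs, **kw)


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        trace = _make_trace(np.full(50_000, 0.5), fs=10_000.0)
        out = tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=100.0)
        np.testing.assert_allclose(out.values, 0.5, rtol=1e-9)

    def test_stopband_attenuation_at_10x_cutoff(self):
        # 30 Hz sine through a 3 Hz filter: two-pass 4th-order Butterworth
        # attenuates by (10^4)^2 in amplitude; >= 40x is generous.
        fs = 100_000.0
        t = np.arange(int(2 * fs)) / fs
        trace = _make_trace(np.sin(2 * np.pi * 30 * t), fs=fs)
        out = tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=None)
        rms_in = np.sqrt(np.mean(trace.values ** 2))
        interior = out.values[int(0.5 * fs):-int(0.5 * fs)]
        rms_out = np.sqrt(np.mean(interior ** 2))
        assert rms_in / rms_out >= 40.0

    def test_telegraph_plateaus_preserved(self):
        # dwells much longer than the 3 Hz settling time (~0.5 s) reach the
        # true levels to within 0.1% at mid-dwell
        fs = 10_000.0
        dwells = np.repeat([1.0, 1.01], int(2.0 * fs))
        values = np.tile(dwells, 5)
        trace = _make_trace(values, fs=fs)
        out = tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=None)
        period = int(4.0 * fs)
        mid_u = out.values[2 * period + int(1.0 * fs)]
        mid_b = out.values[2 * period + int(3.0 * fs)]
        assert mid_u == pytest.approx(1.0, rel=1e-3)
        assert mid_b == pytest.approx(1.01, rel=1e-3)

    def test_zero_phase_no_lag(self):
        # cross-correlation between input and output peaks at lag 0
        rng = np.random.default_rng(0)
        fs = 1000.0
        ev = tk.simulate_event_sequence(2.5, 2.7, 20.0, seed=4)
        cfg = tk.SimConfig(duration_s=20.0, fs_hz=fs,
                           sigma_unbound_V=0.0, sigma_bound_V=0.0, seed=0)
        trace = tk.render_trace(ev, cfg)
        out = tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=None)
        a = trace.values - trace.values.mean()
        b = out.values - out.values.mean()
        lags = np.arange(-200, 201)
        xc = [np.dot(a[max(0, l):len(a) + min(0, l)],
                     b[max(0, -l):len(b) - max(0, l)]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_cutoff_at_nyquist_rejected(self):
        trace = _make_trace(np.zeros(1000), fs=100.0)
        with pytest.raises(InvalidParameterError):
            tk.lowpass_filter(trace, cutoff_hz=50.0)

    def test_decimation_below_twice_cutoff_rejected(self):
        trace = _make_trace(np.zeros(1000), fs=1000.0)
        with pytest.raises(InvalidParameterError):
            tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=5.0)

    def test_decimated_true_state_durations_match_full_rate(self):
        # dwell durations measured on the decimated label track agree with
        # the full-rate track within one effective sample period
        cfg = tk.SimConfig(duration_s=30.0, fs_hz=2000.0, seed=3)
        trace = tk.simulate_trace(cfg)
        out = tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=100.0)

        def runs(labels, fs):
            change = np.flatnonzero(np.diff(labels)) + 1
            edges = np.concatenate(([0], change, [len(labels)]))
            return np.diff(edges) / fs

        full = runs(trace.true_state, trace.fs)
        deci = runs(out.true_state, out.effective_fs)
        full = full[full >= 2 / out.effective_fs]  # sub-sample dwells vanish
        assert abs(len(full) - len(deci)) <= max(3, 0.1 * len(full))


class TestSegmentTrace:
    def _filtered(self, duration_s, fs=100.0):
        n = int(duration_s * fs)
        return tk.FilteredTrace(values=np.zeros(n), fs=fs,
                                cutoff_hz=3.0, effective_fs=fs)

    def test_100s_splits_into_30_30_30_10(self):
        segs = tk.segment_trace(self._filtered(100.0), segment_s=30.0)
        assert [round(s.effective_duration_s) for s in segs] == [30, 30, 30, 10]

    def test_short_remainder_dropped(self):
        segs = tk.segment_trace(self._filtered(95.0), segment_s=30.0)
        assert [round(s.effective_duration_s) for s in segs] == [30, 30, 30]

    def test_total_kept_duration_accounting(self):
        segs = tk.segment_trace(self._filtered(110.0), segment_s=30.0)
        assert sum(s.effective_duration_s for s in segs) == pytest.approx(110.0)

    def test_short_trace_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            segs = tk.segment_trace(self._filtered(5.0), segment_s=30.0)
        assert len(segs) == 1
        assert segs[0].effective_duration_s == pytest.approx(5.0)

    def test_segments_concatenate_to_kept_input(self):
        trace = self._filtered(70.0)
        trace.values[:] = np.arange(trace.n)
        segs = tk.segment_trace(trace, segment_s=30.0)
        rebuilt = np.concatenate([s.values for s in segs])
        np.testing.assert_array_equal(rebuilt, trace.values[:rebuilt.size])


class TestTwoGaussianPdf:
    @staticmethod
    def _as_filtered(x):
        return tk.FilteredTrace(values=x, fs=100.0, cutoff_hz=3.0,
                                effective_fs=100.0)

    def test_mixture_recovery_fig2b_shape(self):
        rng = np.random.default_rng(1)
        n = 200_000
        bound = rng.random(n) < 0.78
        x = np.where(bound, rng.normal(1.01, 0.004, n), rng.normal(1.0, 0.002, n))
        fit = tk.fit_two_gaussian_pdf(self._as_filtered(x))
        assert fit.converged and not fit.single_state
        assert fit.A_B == pytest.approx(0.78, abs=0.05)
        assert fit.A_U == pytest.approx(0.22, abs=0.05)
        assert fit.sigma_B == pytest.approx(0.004, rel=0.2)
        assert fit.sigma_U == pytest.approx(0.002, rel=0.2)
        assert fit.A_B + fit.A_U == pytest.approx(1.0, abs=0.05)

    def test_single_gaussian_flags_single_state(self):
        rng = np.random.default_rng(2)
        fit = tk.fit_two_gaussian_pdf(
            self._as_filtered(rng.normal(1.0, 0.003, 50_000))
        )
        assert fit.single_state

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            tk.fit_two_gaussian_pdf(self._as_filtered(np.zeros(500)))


class TestNormalizedBoundIntensity:
    def _fit(self, mu_U, mu_B):
        return tk.MixtureFit(A_B=0.5, A_U=0.5, mu_B=mu_B, mu_U=mu_U,
                             sigma_B=0.004, sigma_U=0.002, converged=True)

    def test_identity_when_levels_equal(self):
        assert tk.normalized_bound_intensity(self._fit(1.0, 1.0)) == pytest.approx(100.0)

    def test_one_percent_contrast_gives_101(self):
        assert tk.normalized_bound_intensity(self._fit(1.00, 1.01)) == pytest.approx(101.0)

    def test_nonpositive_unbound_level_rejected(self):
        with pytest.raises(InvalidParameterError):
            tk.normalized_bound_intensity(self._fit(-1.0, 1.0))

    def test_single_state_fit_rejected(self):
        fit = self._fit(1.0, 1.001)
        fit.single_state = True
        with pytest.raises(FitError):
            tk.normalized_bound_intensity(fit)

    def test_pipeline_recovery_of_contrast(self, filtered_trace):
        fit = tk.fit_two_gaussian_pdf(filtered_trace)
        pct = tk.normalized_bound_intensity(fit)
        assert pct == pytest.approx(101.0, abs=0.2)
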