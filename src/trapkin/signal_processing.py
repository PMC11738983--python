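"""Trace containers and signal conditioning.

A trapping experiment records the light transmitted through the nanoaperture
on an avalanche photodiode at 100 kHz.  Ligand binding shifts the protein's
polarizability, so the transmission toggles between two closely spaced levels
(the bound level is ~1% above the unbound one) buried in state-dependent
photodetector noise.  The conditioning chain implemented here is:

1. zero-phase low-pass filtering at 3 Hz (4th-order Butterworth, applied
   forward-backward so dwell boundaries are not displaced), optionally
   followed by decimation to 100 Hz;
2. segmentation into ~30 s sections for state inference;
3. a two-Gaussian fit to the probability density of the filtered signal,
   which quantifies the two levels, their widths and their occupancies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, signal as sps

from .errors import FitError, InsufficientDataError, InvalidParameterError

__all__ = [
    "TrapTrace",
    "FilteredTrace",
    "MixtureFit",
    "lowpass_filter",
    "segment_trace",
    "fit_two_gaussian_pdf",
    "normalized_bound_intensity",
]


@dataclass
class TrapTrace:
    """A uniformly sampled transmission record.

    Parameters
    ----------
    values : ndarray
        Transmission samples in volts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    metadata : dict
        Acquisition metadata; the kinetics stage looks for ``P_total_uM``,
        ``L_total_uM`` and ``temperature_K`` here.
    true_state : ndarray, optional
        Ground-truth per-sample bound (1) / unbound (0) labels, present on
        synthetic traces so inference accuracy can be scored.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)
    true_state: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("trace contains non-finite values")
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state)
            if self.true_state.shape[0] != self.values.shape[0]:
                raise InvalidParameterError(
                    "true_state length does not match values length"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class FilteredTrace(TrapTrace):
    """A low-pass-filtered (and possibly decimated) trace.

    ``effective_fs`` is the post-decimation sampling rate; dwell durations
    downstream are integer multiples of ``1/effective_fs``.
    """

    cutoff_hz: float = np.nan
    effective_fs: float = np.nan

    def __post_init__(self):
        super().__post_init__()
        if np.isnan(self.effective_fs):
            self.effective_fs = self.fs

    @property
    def effective_duration_s(self) -> float:
        return self.n / self.effective_fs


@dataclass
class MixtureFit:
    """Two-Gaussian fit to the filtered-signal probability density.

    Areas are the integrals of each component over the voltage axis; for a
    normalized density they sum to ~1.  Components are labelled by mean:
    the higher level is the bound state (binding increases scattering).
    """

    A_B: float
    A_U: float
    mu_B: float
    mu_U: float
    sigma_B: float
    sigma_U: float
    converged: bool
    single_state: bool = False
    r_squared: float = np.nan

    def to_dict(self) -> dict:
        return {
            "A_B": self.A_B, "A_U": self.A_U,
            "mu_B": self.mu_B, "mu_U": self.mu_U,
            "sigma_B": self.sigma_B, "sigma_U": self.sigma_U,
            "converged": self.converged, "single_state": self.single_state,
            "r_squared": self.r_squared,
        }


def lowpass_filter(
    trace: TrapTrace,
    cutoff_hz: float = 3.0,
    decimate_to_hz: Optional[float] = 100.0,
    order: int = 4,
) -> FilteredTrace:
    """Zero-phase Butterworth low-pass, optionally decimating afterwards.

    The filter is applied forward and backward (``sosfiltfilt``), which gives
    unit gain at DC and zero phase shift, so state-transition times are not
    displaced -- a prerequisite for unbiased dwell durations.  Decimation is
    plain subsampling, safe because frequencies above ``cutoff_hz`` have
    already been removed.
    """
    if cutoff_hz <= 0 or cutoff_hz >= trace.fs / 2:
        raise InvalidParameterError(
            f"cutoff_hz must lie in (0, fs/2) = (0, {trace.fs / 2}); got {cutoff_hz}"
        )
    if decimate_to_hz is not None and decimate_to_hz < 2 * cutoff_hz:
        raise InvalidParameterError(
            "decimate_to_hz must be at least twice the cutoff to keep the "
            f"passband intact; got {decimate_to_hz} < 2*{cutoff_hz}"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.values)

    step = 1
    if decimate_to_hz is not None and trace.fs > decimate_to_hz:
        step = int(round(trace.fs / decimate_to_hz))
    values = filtered[::step]
    true_state = None if trace.true_state is None else trace.true_state[::step]
    return FilteredTrace(
        values=np.ascontiguousarray(values),
        fs=trace.fs,
        t0=trace.t0,
        metadata=dict(trace.metadata),
        true_state=true_state,
        cutoff_hz=cutoff_hz,
        effective_fs=trace.fs / step,
    )


def segment_trace(
    trace: FilteredTrace,
    segment_s: float = 30.0,
    min_remainder_s: float = 10.0,
) -> list[FilteredTrace]:
    """Split a filtered trace into consecutive ~``segment_s`` sections.

    A final remainder shorter than ``min_remainder_s`` is dropped (too short
    for a meaningful dwell-time fit); a trace shorter than ``min_remainder_s``
    altogether is passed through as a single segment with a warning.
    """
    if segment_s <= 0:
        raise InvalidParameterError("segment_s must be positive")
    fs = trace.effective_fs
    if trace.effective_duration_s < min_remainder_s:
        warnings.warn(
            f"trace of {trace.effective_duration_s:.1f} s is shorter than "
            f"{min_remainder_s} s; returning it as a single segment",
            stacklevel=2,
        )
        return [trace]
    seg_len = int(round(segment_s * fs))
    min_len = int(round(min_remainder_s * fs))
    segments = []
    for start in range(0, trace.n, seg_len):
        stop = min(start + seg_len, trace.n)
        if stop - start < min_len and start > 0:
            break  # short trailing remainder dropped
        segments.append(
            replace(
                trace,
                values=trace.values[start:stop].copy(),
                true_state=None if trace.true_state is None
                else trace.true_state[start:stop].copy(),
                t0=trace.t0 + start / fs,
            )
        )
    return segments


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    g1 = a1 / (np.sqrt(2 * np.pi) * s1) * np.exp(-0.5 * ((x - m1) / s1) ** 2)
    g2 = a2 / (np.sqrt(2 * np.pi) * s2) * np.exp(-0.5 * ((x - m2) / s2) ** 2)
    return g1 + g2


def fit_two_gaussian_pdf(trace: FilteredTrace, n_restarts: int = 5) -> MixtureFit:
    """Least-squares two-Gaussian fit to the filtered-signal density.

    The histogram uses Freedman-Diaconis binning with ``density=True`` so the
    fitted amplitudes are areas (state occupancies).  Initial component means
    are placed at the 25th/75th percentiles with deterministic jitter across
    restarts.  If the two fitted means are closer than one pooled standard
    deviation the signal is effectively unimodal and the fit is flagged
    ``single_state`` (no binding dynamics resolvable).
    """
    x = trace.values
    if x.shape[0] < 1000:
        raise InsufficientDataError(
            f"PDF fit requires >= 1000 samples, got {x.shape[0]}"
        )
    # Freedman-Diaconis binning, but never so coarse that two narrow levels
    # ~1% apart collapse into a handful of bins.
    n_bins = np.histogram_bin_edges(x, bins="fd").size - 1
    n_bins = int(np.clip(n_bins, 64, 512))
    density, edges = np.histogram(x, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = float(edges[1] - edges[0])

    q25, q75 = np.percentile(x, [25, 75])
    spread = max(q75 - q25, 4 * bin_w)
    sigma_min = 0.25 * bin_w
    lower = [0.0, centers[0] - spread, sigma_min, 0.0, centers[0] - spread, sigma_min]
    upper = [2.0, centers[-1] + spread, 10 * spread,
             2.0, centers[-1] + spread, 10 * spread]

    # seed the component means at the two most prominent histogram peaks;
    # fall back to the 25th/75th percentiles for unimodal shapes
    peaks, props = sps.find_peaks(density, prominence=0.05 * density.max())
    if peaks.size >= 2:
        top2 = peaks[np.argsort(density[peaks])[-2:]]
        m_lo, m_hi = np.sort(centers[top2])
    else:
        m_lo, m_hi = q25, q75
    sigma0 = max(min(np.std(x) / 2, 0.25 * (m_hi - m_lo)), 2 * bin_w)

    best = None
    best_cost = np.inf
    # deterministic jitter pattern over restarts
    offsets = np.linspace(-0.5, 0.5, max(n_restarts, 1))
    for off in offsets:
        p0 = [0.5, m_lo + off * sigma0, sigma0, 0.5, m_hi - off * sigma0, sigma0]
        try:
            popt, _ = optimize.curve_fit(
                _two_gauss, centers, density, p0=p0,
                bounds=(lower, upper), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = density - _two_gauss(centers, *popt)
        cost = float(resid @ resid)
        if cost < best_cost:
            best_cost = cost
            best = popt

    if best is None:
        return MixtureFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          converged=False)

    a1, m1, s1, a2, m2, s2 = best
    if m1 >= m2:
        (a1, m1, s1), (a2, m2, s2) = (a2, m2, s2), (a1, m1, s1)
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - best_cost / ss_tot if ss_tot > 0 else np.nan
    pooled = np.sqrt(0.5 * (s1 ** 2 + s2 ** 2))
    single = (m2 - m1) < pooled
    return MixtureFit(
        A_B=float(a2), A_U=float(a1), mu_B=float(m2), mu_U=float(m1),
        sigma_B=float(s2), sigma_U=float(s1),
        converged=True, single_state=bool(single), r_squared=float(r2),
    )


def normalized_bound_intensity(fit: MixtureFit) -> float:
    """Bound level as a percentage of the unbound level, ``100 * mu_B / mu_U``."""
    if not fit.converged or fit.single_state:
        raise FitError(
            "normalized bound intensity requires a converged two-state fit"
        )
    if fit.mu_U <= 0:
        raise InvalidParameterError(
            f"unbound level must be positive, got {fit.mu_U}"
        )
    return 100.0 * fit.mu_B / fit.mu_U
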