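"""Ensemble binding assays: fluorescence polarization, thermal shift, CPMG.

These are the orthogonal bulk measurements used to corroborate the
single-molecule kinetics:

* **Fluorescence polarization (FP).**  A fluorescent ligand tumbles slowly
  when protein-bound, so the emitted light stays polarized.  Titrating
  protein at fixed ligand and fitting the one-site binding isotherm
  ``P = P_max * C / (K_D + C)`` yields the equilibrium dissociation
  constant.
* **Thermal shift (nanoDSF).**  The melting temperature Tm is read from the
  extremum of the first derivative of the intrinsic-fluorescence intensity
  ratio I350/I330 versus temperature; ligand binding shifts Tm upward.
* **Two-point CPMG.**  The transverse relaxation rate R2 follows from the
  intensity ratio of two spin-echo experiments with different transverse
  delays: ``R2 = ln(I_short / I_long) / (t_long - t_short)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, signal as sps

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NoTransitionError,
)

__all__ = [
    "FPCurve", "FPFit", "MeltCurve", "CPMGPair",
    "polarization", "fit_one_site_fp", "melt_tm", "cpmg_r2",
]


@dataclass
class FPCurve:
    """A fluorescence-polarization titration.

    Either raw channel intensities (``I_parallel``/``I_perpendicular``) or
    precomputed polarization in millipolarization units (``P_mP``) may be
    supplied; replicate points simply repeat their concentration.
    """

    concentrations_uM: np.ndarray
    P_mP: Optional[np.ndarray] = None
    I_parallel: Optional[np.ndarray] = None
    I_perpendicular: Optional[np.ndarray] = None
    ligand_concentration_uM: Optional[float] = None
    temperature_K: Optional[float] = None

    def __post_init__(self):
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        if np.any(self.concentrations_uM < 0):
            raise InvalidParameterError("concentrations must be non-negative")
        if self.P_mP is None:
            if self.I_parallel is None or self.I_perpendicular is None:
                raise InvalidParameterError(
                    "provide either P_mP or both intensity channels"
                )
            self.I_parallel = np.asarray(self.I_parallel, dtype=float)
            self.I_perpendicular = np.asarray(self.I_perpendicular, dtype=float)
            self.P_mP = 1000.0 * polarization(self.I_parallel, self.I_perpendicular)
        else:
            self.P_mP = np.asarray(self.P_mP, dtype=float)
        if self.P_mP.shape != self.concentrations_uM.shape:
            raise InvalidParameterError(
                "polarization and concentration arrays must have equal length"
            )


@dataclass
class FPFit:
    """One-site binding fit result (Kd in μM, plateau polarization in mP)."""

    K_D_uM: float
    P_max_mP: float
    r_squared: float
    converged: bool
    intercept_mP: float = 0.0

    def to_dict(self) -> dict:
        return {
            "K_D_uM": self.K_D_uM, "P_max_mP": self.P_max_mP,
            "r_squared": self.r_squared, "converged": self.converged,
            "intercept_mP": self.intercept_mP,
        }


@dataclass
class MeltCurve:
    """A thermal-denaturation scan: temperature grid plus the two intrinsic
    fluorescence channels (or a precomputed I350/I330 ratio)."""

    temperature_C: np.ndarray
    I330: Optional[np.ndarray] = None
    I350: Optional[np.ndarray] = None
    ratio: Optional[np.ndarray] = None

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        if np.any(np.diff(self.temperature_C) <= 0):
            raise InvalidParameterError("temperature grid must be strictly increasing")
        if self.ratio is None:
            if self.I330 is None or self.I350 is None:
                raise InvalidParameterError("provide either ratio or both channels")
            self.I330 = np.asarray(self.I330, dtype=float)
            self.I350 = np.asarray(self.I350, dtype=float)
            if np.any(self.I330 <= 0) or np.any(self.I350 <= 0):
                raise InvalidParameterError("intensities must be positive")
            self.ratio = self.I350 / self.I330
        else:
            self.ratio = np.asarray(self.ratio, dtype=float)
        if self.ratio.shape != self.temperature_C.shape:
            raise InvalidParameterError("ratio and temperature grids must match")


@dataclass
class CPMGPair:
    """Intensities of two spin-echo experiments at short/long transverse delay."""

    I_short: float
    I_long: float
    t_short_s: float = 0.002
    t_long_s: float = 0.102

    def __post_init__(self):
        if self.t_long_s <= self.t_short_s:
            raise InvalidParameterError("t_long must exceed t_short")
        if self.I_short <= 0 or self.I_long <= 0:
            raise InvalidParameterError("intensities must be positive")


def polarization(I_parallel, I_perpendicular):
    """Fluorescence polarization ``P = (I_par - I_perp) / (I_par + I_perp)``.

    Dimensionless, bounded by [-1, 1] for non-negative intensities.
    """
    I_parallel = np.asarray(I_parallel, dtype=float)
    I_perpendicular = np.asarray(I_perpendicular, dtype=float)
    total = I_parallel + I_perpendicular
    if np.any(total <= 0):
        raise InvalidParameterError("total intensity must be positive")
    return (I_parallel - I_perpendicular) / total


def intensities_from_polarization(P, total_intensity=2.0):
    """Invert :func:`polarization`: channel intensities realizing P at a given
    total intensity.  Convenience for round-trip checks."""
    P = np.asarray(P, dtype=float)
    if np.any(np.abs(P) > 1):
        raise InvalidParameterError("polarization must lie in [-1, 1]")
    I_par = 0.5 * total_intensity * (1.0 + P)
    I_perp = 0.5 * total_intensity * (1.0 - P)
    return I_par, I_perp


def _one_site(C, P_max, K_D):
    return P_max * C / (K_D + C)


def _one_site_intercept(C, P_max, K_D, b):
    return P_max * C / (K_D + C) + b


def fit_one_site_fp(
    curve: FPCurve,
    background_mP: float = 0.0,
    free_intercept: bool = False,
) -> FPFit:
    """Fit the one-site binding isotherm to a polarization titration.

    ``background_mP`` (e.g. from ligand-only control wells) is subtracted
    before fitting.  The default model passes through the origin, matching
    the isotherm ``P = P_max*C/(K_D + C)``; ``free_intercept`` adds a fitted
    offset for data with residual baseline polarization.
    """
    C = curve.concentrations_uM
    P = curve.P_mP - background_mP
    if np.unique(C).size < 4:
        raise InsufficientDataError(
            "one-site fit requires at least 4 distinct concentrations"
        )
    p_max0 = 1.2 * float(np.max(P))
    if p_max0 <= 0:
        raise InvalidParameterError("polarization data have no positive signal")
    # Kd guess: concentration where P crosses half of the observed maximum
    order = np.argsort(C)
    half = 0.5 * np.max(P)
    above = P[order] >= half
    kd0 = float(C[order][above][0]) if above.any() else float(np.median(C[C > 0]))
    kd0 = max(kd0, 1e-6)

    try:
        if free_intercept:
            popt, _ = optimize.curve_fit(
                _one_site_intercept, C, P, p0=[p_max0, kd0, 0.0],
                bounds=([0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            p_max, kd, b = popt
            model = _one_site_intercept(C, *popt)
        else:
            popt, _ = optimize.curve_fit(
                _one_site, C, P, p0=[p_max0, kd0],
                bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
            p_max, kd = popt
            b = 0.0
            model = _one_site(C, *popt)
    except RuntimeError:
        return FPFit(np.nan, np.nan, np.nan, converged=False)

    resid = P - model
    ss_tot = float(np.sum((P - P.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    return FPFit(
        K_D_uM=float(kd), P_max_mP=float(p_max), r_squared=r2,
        converged=True, intercept_mP=float(b),
    )


def melt_tm(curve: MeltCurve, smooth_window_degC: float = 2.0):
    """Melting temperature from the derivative of the I350/I330 ratio.

    The ratio is smoothed with a Savitzky-Golay filter spanning roughly
    ``smooth_window_degC`` and the (equally smoothed) first derivative is
    taken; Tm is located at the largest-magnitude derivative extremum.  The
    extremum search excludes one smoothing window at each end of the scan,
    where the polynomial edge fit amplifies noise, and the grid-level peak
    is refined by the intensity-weighted centroid of the contiguous region
    above half the peak magnitude, which is far more stable against
    point-to-point noise than the raw argmax.  Returns ``(T_m, dFIR)``
    where ``dFIR`` is the smoothed derivative on the input grid.

    Raises :class:`NoTransitionError` when the derivative has no resolvable
    peak (flat or featureless-monotone ratio).
    """
    T = curve.temperature_C
    r = curve.ratio
    if T.size < 20:
        raise InsufficientDataError("melt curve needs at least 20 grid points")
    dT = float(np.median(np.diff(T)))
    win = int(round(smooth_window_degC / dT))
    win = max(win | 1, 5)  # odd, at least 5
    win = min(win, T.size - 1 if (T.size - 1) % 2 == 1 else T.size - 2)
    smoothed = sps.savgol_filter(r, window_length=win, polyorder=3)
    d = sps.savgol_filter(smoothed, window_length=win, polyorder=3,
                          deriv=1, delta=dT)

    mag = np.abs(d)
    margin = min(win, (T.size - 1) // 3)
    core = mag.copy()
    core[:margin] = 0.0
    core[-margin:] = 0.0
    peak = float(core.max())
    floor = float(np.median(mag[margin:-margin] if margin else mag))
    scale = max(float(np.max(np.abs(r))), 1e-300)
    if peak < 1e-12 * scale or peak < 2.0 * floor:
        raise NoTransitionError(
            "derivative of the fluorescence ratio shows no transition peak"
        )
    i = int(np.argmax(core))
    half = 0.5 * mag[i]
    lo = i
    while lo > 0 and mag[lo - 1] >= half:
        lo -= 1
    hi = i
    while hi < T.size - 1 and mag[hi + 1] >= half:
        hi += 1
    weights = mag[lo:hi + 1]
    t_m = float(np.sum(T[lo:hi + 1] * weights) / np.sum(weights))
    return t_m, d


def cpmg_r2(pair: CPMGPair) -> float:
    """Transverse relaxation rate from a two-delay CPMG pair.

    ``R2 = ln(I_short / I_long) / (t_long - t_short)``; exact for a
    mono-exponential decay.  If the long-delay intensity is not smaller than
    the short-delay one the returned rate is negative (unphysical growth) and
    a warning is issued.
    """
    if pair.I_long >= pair.I_short and pair.I_long != pair.I_short:
        warnings.warn(
            "I_long >= I_short: signal grows with delay, R2 will be negative",
            stacklevel=2,
        )
    return float(np.log(pair.I_short / pair.I_long) / (pair.t_long_s - pair.t_short_s))
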