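"""Residence times, exponential CDF fits and mass-action kinetics.

For a 1:1 binding scheme P + L <-> PL observed on a single protein, the
residence times in the bound and unbound states are exponential with means
tau_off and tau_on.  The rate constants follow from

    k_off = 1 / tau_off
    k_on  = 1 / (tau_on * [L]_free)
    K_D   = k_off / k_on = tau* [L]_free,     tau* = tau_on / tau_off

At micromolar affinity the protein and ligand concentrations are comparable,
so complex formation depletes the free ligand appreciably and [L]_free
cannot be approximated by the total ligand concentration.  Writing the
equilibrium condition with mass balance gives the quadratic

    (1 + tau*) [PL]^2 - ([P]_t + (1 + tau*) [L]_t) [PL] + [P]_t [L]_t = 0

whose physical (smaller) root is the equilibrium complex concentration;
[L]_free = [L]_t - [PL] then closes the system.  The standard free energy is
dG = R T ln K_D with K_D expressed in molar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import InsufficientDataError, InvalidParameterError, TrapkinError
from .state_inference import StatePath, _run_lengths

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DwellSet",
    "ExpFit",
    "KineticsResult",
    "extract_dwells",
    "fit_exponential_cdf",
    "solve_complex_concentration",
    "compute_kinetics",
    "kinetics_from_taus",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)


@dataclass
class DwellSet:
    """Pooled bound/unbound residence times (seconds).

    ``censored_count`` counts edge dwells dropped because their start or end
    was not observed; ``source_segments`` records which segments
    contributed.
    """

    bound_s: np.ndarray
    unbound_s: np.ndarray
    censored_count: int = 0
    source_segments: list = field(default_factory=list)

    def __post_init__(self):
        self.bound_s = np.asarray(self.bound_s, dtype=float)
        self.unbound_s = np.asarray(self.unbound_s, dtype=float)
        if np.any(self.bound_s <= 0) or np.any(self.unbound_s <= 0):
            raise InvalidParameterError("dwell durations must be positive")

    @property
    def n_events(self) -> int:
        return self.bound_s.size + self.unbound_s.size

    @classmethod
    def pool(cls, dwell_sets: Sequence["DwellSet"]) -> "DwellSet":
        """Concatenate dwells across segments of one trapping event."""
        sets = list(dwell_sets)
        if not sets:
            return cls(np.empty(0), np.empty(0))
        return cls(
            bound_s=np.concatenate([s.bound_s for s in sets]),
            unbound_s=np.concatenate([s.unbound_s for s in sets]),
            censored_count=sum(s.censored_count for s in sets),
            source_segments=[seg for s in sets for seg in s.source_segments],
        )


@dataclass
class ExpFit:
    """Single-exponential fit ``F(x) = 1 - exp(-x/tau)`` to a dwell CDF.

    ``tau_mle`` is the closed-form maximum-likelihood estimate (the sample
    mean), kept alongside the least-squares value as an internal
    cross-check.
    """

    tau: float
    r_squared: float
    n_events: int
    method: str = "cdf-least-squares"
    tau_mle: float = np.nan

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau, "r_squared": self.r_squared,
            "n_events": self.n_events, "method": self.method,
            "tau_mle_s": self.tau_mle,
        }


@dataclass
class KineticsResult:
    """Depletion-corrected rate constants and thermodynamics."""

    tau_on_s: float
    tau_off_s: float
    tau_star: float
    P_total_uM: float
    L_total_uM: float
    PL_uM: float
    L_free_uM: float
    k_on_per_s_uM: float
    k_off_per_s: float
    K_D_uM: float
    delta_G_kcal_mol: float
    temperature_K: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tau_on_s", "tau_off_s", "tau_star", "P_total_uM", "L_total_uM",
            "PL_uM", "L_free_uM", "k_on_per_s_uM", "k_off_per_s", "K_D_uM",
            "delta_G_kcal_mol", "temperature_K",
        )}


def extract_dwells(
    path: StatePath,
    effective_fs: float,
    drop_edges: bool = True,
    segment_id=None,
) -> DwellSet:
    """Run-length encode a state path into residence times.

    With ``drop_edges`` (default) the first and last dwell of the segment
    are discarded as censored: their true start/end was not observed, so
    keeping them would bias the dwell distribution short.
    """
    if effective_fs <= 0:
        raise InvalidParameterError("effective_fs must be positive")
    starts, lengths, states = _run_lengths(np.asarray(path.labels))
    n_runs = len(starts)
    censored = 0
    if drop_edges:
        if n_runs < 3:
            warnings.warn(
                f"segment has only {n_runs} dwell(s); all are edge-censored, "
                "returning an empty dwell set",
                stacklevel=2,
            )
            return DwellSet(
                np.empty(0), np.empty(0), censored_count=n_runs,
                source_segments=[segment_id] if segment_id is not None else [],
            )
        lengths = lengths[1:-1]
        states = states[1:-1]
        censored = 2
    durations = lengths / effective_fs
    return DwellSet(
        bound_s=durations[states == 1],
        unbound_s=durations[states == 0],
        censored_count=censored,
        source_segments=[segment_id] if segment_id is not None else [],
    )


def fit_exponential_cdf(
    durations: Sequence[float],
    min_events: int = 5,
) -> ExpFit:
    """Least-squares fit of ``1 - exp(-x/tau)`` to the empirical dwell CDF.

    The empirical CDF is evaluated at the sorted durations with plotting
    positions ``(i - 0.5)/n``; tau is initialized at the sample mean.  On
    non-convergence the fit falls back to the maximum-likelihood estimate
    (the sample mean) and says so in ``method``.
    """
    x = np.sort(np.asarray(durations, dtype=float))
    n = x.size
    if n < min_events:
        raise InsufficientDataError(
            f"exponential fit requires >= {min_events} events, got {n}"
        )
    if np.any(x <= 0):
        raise InvalidParameterError("durations must be positive")
    F = (np.arange(1, n + 1) - 0.5) / n
    tau_mle = float(x.mean())

    def model(t, tau):
        return 1.0 - np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, x, F, p0=[tau_mle], bounds=(1e-12, np.inf), maxfev=10000
        )
        tau = float(popt[0])
        method = "cdf-least-squares"
    except RuntimeError:
        tau = tau_mle
        method = "mle"
    resid = F - model(x, tau)
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    return ExpFit(tau=tau, r_squared=r2, n_events=n, method=method,
                  tau_mle=tau_mle)


def solve_complex_concentration(
    P_total: float,
    L_total: float,
    tau_star: float,
) -> float:
    """Equilibrium complex concentration from the ligand-depletion quadratic.

    Solves ``(1 + tau*) [PL]^2 - ([P]_t + (1 + tau*) [L]_t) [PL]
    + [P]_t [L]_t = 0`` for the physical root 0 <= [PL] <= min([P]_t,
    [L]_t), using the numerically stable quadratic formula.  All
    concentrations in μM.
    """
    if P_total <= 0 or L_total <= 0:
        raise InvalidParameterError("total concentrations must be positive")
    if tau_star <= 0:
        raise InvalidParameterError("tau_star must be positive")
    a = 1.0 + tau_star
    b = -(P_total + (1.0 + tau_star) * L_total)
    c = P_total * L_total
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise TrapkinError(
            "depletion quadratic has no real root; inputs are inconsistent"
        )
    # b < 0 always, so the stable split is q = (-b + sqrt(disc)) / 2
    q = 0.5 * (-b + np.sqrt(disc))
    pl = c / q  # smaller root
    upper = min(P_total, L_total)
    if not (-1e-9 * upper <= pl <= upper * (1 + 1e-9)):
        raise TrapkinError(
            f"physical root not found: PL={pl} outside [0, {upper}]"
        )
    return float(np.clip(pl, 0.0, upper))


def _tau_of(fit) -> float:
    """Accept an ExpFit or a plain mean dwell time in seconds."""
    return float(getattr(fit, "tau", fit))


def compute_kinetics(
    tau_on_fit,
    tau_off_fit,
    P_total_uM: float,
    L_total_uM: float,
    temperature_K: float = 308.15,
) -> KineticsResult:
    """Rate constants and thermodynamics from fitted mean dwell times.

    ``tau_on_fit``/``tau_off_fit`` may be :class:`ExpFit` results or plain
    dwell-time means in seconds.  The free-ligand concentration comes from
    the depletion quadratic (no [L]_free ~ [L]_total approximation); the
    default temperature corresponds to the ~35 °C trapping conditions.
    """
    tau_on = _tau_of(tau_on_fit)
    tau_off = _tau_of(tau_off_fit)
    if tau_on <= 0 or tau_off <= 0:
        raise InvalidParameterError("dwell time constants must be positive")
    if temperature_K <= 0:
        raise InvalidParameterError("temperature must be positive")
    tau_star = tau_on / tau_off
    pl = solve_complex_concentration(P_total_uM, L_total_uM, tau_star)
    l_free = L_total_uM - pl
    if l_free <= 0:
        raise TrapkinError("free ligand concentration is non-positive")
    k_off = 1.0 / tau_off
    k_on = 1.0 / (tau_on * l_free)
    k_d = tau_star * l_free
    delta_g = GAS_CONSTANT_KCAL * temperature_K * np.log(k_d * 1e-6)
    return KineticsResult(
        tau_on_s=tau_on, tau_off_s=tau_off, tau_star=tau_star,
        P_total_uM=P_total_uM, L_total_uM=L_total_uM,
        PL_uM=pl, L_free_uM=l_free,
        k_on_per_s_uM=k_on, k_off_per_s=k_off, K_D_uM=k_d,
        delta_G_kcal_mol=float(delta_g), temperature_K=temperature_K,
    )


def kinetics_from_taus(
    tau_on_s: float,
    tau_off_s: float,
    P_total_uM: float,
    L_total_uM: float,
    temperature_K: float = 308.15,
) -> KineticsResult:
    """Convenience wrapper of :func:`compute_kinetics` for plain tau values."""
    return compute_kinetics(
        tau_on_s, tau_off_s, P_total_uM, L_total_uM, temperature_K
    )
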