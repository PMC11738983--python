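"""Ground-truth generators for every stage of the analysis.

The trapped-protein transmission signal is modelled as a two-state telegraph
process: the protein-ligand complex (bound) scatters more light than the free
protein, so the transmission toggles between two levels whose separation is
~1% of the baseline.  Residence times in each state are exponential — the
memoryless 1:1 binding scheme P + L <-> PL — with bound-exit rate ``k_off``
and unbound-exit rate ``k_on * [L]_free``.  On top of the telegraph sit
state-dependent white Gaussian noise (the bound, extended conformation is
noisier) and an optional linear drift.

Generated traces carry their true per-sample state labels so inference
accuracy can be scored exactly.  Companion generators produce synthetic
FP titrations, melt curves and CPMG pairs obeying the closed forms their
fitters assume, giving every fitter a noiseless round-trip oracle.

Reproducibility: each generator takes one integer seed.  ``simulate_trace``
splits its seed into two documented child streams (child 0: dwell sampling,
child 1: photodetector noise) so the event sequence and the noise are
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble_assays import CPMGPair, FPCurve, MeltCurve
from .errors import InvalidParameterError
from .signal_processing import TrapTrace

__all__ = [
    "EventSequence",
    "SimConfig",
    "simulate_event_sequence",
    "render_trace",
    "simulate_trace",
    "simulate_fp_titration",
    "simulate_melt_curve",
    "simulate_cpmg_pair",
]


@dataclass(frozen=True)
class EventSequence:
    """A continuous-time realization of the two-state binding process.

    ``dwell_durations_s[i]`` is spent in state ``(state_at_start + i) % 2``
    (0 = unbound, 1 = bound).  The final dwell is truncated at
    ``total_duration_s``; consumers treat the first and last dwell as
    censored.
    """

    state_at_start: int
    dwell_durations_s: np.ndarray
    total_duration_s: float

    def states(self) -> np.ndarray:
        """State of each dwell, alternating from ``state_at_start``."""
        n = len(self.dwell_durations_s)
        return (self.state_at_start + np.arange(n)) % 2

    @property
    def n_dwells(self) -> int:
        return len(self.dwell_durations_s)

    def boundaries(self) -> np.ndarray:
        """Cumulative dwell end-times (last entry == total_duration_s)."""
        return np.cumsum(self.dwell_durations_s)


@dataclass
class SimConfig:
    """Parameters of the synthetic trapping experiment.

    Defaults reproduce the reference study conditions: k_off = 1/0.40 s⁻¹,
    k_on chosen so the equilibrium free-ligand concentration at 10 μM protein
    / 20 μM ligand gives a mean unbound dwell of 0.37 s; bound level 1%
    above a 1.0 V unbound baseline; state noise σ = 0.002 V (unbound) /
    0.004 V (bound); 100 kHz sampling.
    """

    k_off: float = 1.0 / 0.40          # 1/s, bound-state exit rate
    k_on: float = 0.182578             # 1/(s*uM)
    P_total_uM: float = 10.0
    L_total_uM: float = 20.0
    mu_unbound_V: float = 1.0
    contrast: float = 1.01             # mu_bound = contrast * mu_unbound
    sigma_unbound_V: float = 0.002
    sigma_bound_V: float = 0.004
    fs_hz: float = 100_000.0
    duration_s: float = 100.0
    drift_slope_V_per_s: float = 0.0
    temperature_K: float = 308.15
    seed: int = 0

    def __post_init__(self):
        for name in ("k_off", "k_on", "P_total_uM", "L_total_uM",
                     "fs_hz", "duration_s", "temperature_K"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.contrast <= 1.0:
            raise InvalidParameterError(
                "contrast must exceed 1 (the bound state scatters more)"
            )
        if self.sigma_unbound_V < 0 or self.sigma_bound_V < 0:
            raise InvalidParameterError("noise widths must be non-negative")

    @property
    def mu_bound_V(self) -> float:
        return self.mu_unbound_V * self.contrast

    @property
    def K_D_uM(self) -> float:
        return self.k_off / self.k_on

    @property
    def PL_uM(self) -> float:
        """Equilibrium complex concentration from the mass-balance quadratic
        K_D = (P_t - PL)(L_t - PL)/PL (smaller root; no free-ligand
        approximation)."""
        p, l, kd = self.P_total_uM, self.L_total_uM, self.K_D_uM
        b = -(p + l + kd)
        disc = b * b - 4.0 * p * l
        q = 0.5 * (-b + np.sqrt(disc))
        return p * l / q  # smaller root, always in [0, min(p, l)]

    @property
    def L_free_uM(self) -> float:
        return self.L_total_uM - self.PL_uM

    @property
    def k_on_eff(self) -> float:
        """Pseudo-first-order unbound-exit rate k_on * [L]_free, 1/s."""
        return self.k_on * self.L_free_uM


def simulate_event_sequence(
    k_off: float,
    k_on_eff: float,
    duration_s: float,
    initial_state: int = 0,
    seed=None,
) -> EventSequence:
    """Sample alternating exponential dwells of the two-state process.

    Unbound dwells are Exp(mean ``1/k_on_eff``), bound dwells
    Exp(mean ``1/k_off``).  The final dwell is truncated so the durations
    sum exactly to ``duration_s``.
    """
    if k_off <= 0 or k_on_eff <= 0:
        raise InvalidParameterError("rates must be positive")
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    if initial_state not in (0, 1):
        raise InvalidParameterError("initial_state must be 0 or 1")

    rng = np.random.default_rng(seed)
    scale = {0: 1.0 / k_on_eff, 1: 1.0 / k_off}
    mean_dwell = 0.5 * (scale[0] + scale[1])

    chunks = []
    n_drawn = 0
    total = 0.0
    while total < duration_s:
        n = max(16, int(1.2 * (duration_s - total) / mean_dwell) + 16)
        states = (initial_state + n_drawn + np.arange(n)) % 2
        batch = rng.exponential(np.where(states == 0, scale[0], scale[1]))
        chunks.append(batch)
        n_drawn += n
        total += float(batch.sum())

    d = np.concatenate(chunks)
    cum = np.cumsum(d)
    k = int(np.searchsorted(cum, duration_s))
    d = d[: k + 1].copy()
    d[-1] = duration_s - (cum[k - 1] if k > 0 else 0.0)
    return EventSequence(
        state_at_start=initial_state,
        dwell_durations_s=d,
        total_duration_s=float(duration_s),
    )


def render_trace(
    events: EventSequence,
    cfg: SimConfig,
    noise_seed=None,
) -> TrapTrace:
    """Render an event sequence into a sampled transmission trace.

    Sample i at time ``t_i = i / fs`` takes the value
    ``mu(state) + drift_slope * t_i + N(0, sigma(state))``.  The returned
    trace carries the true per-sample state labels and the acquisition
    metadata from ``cfg``.
    """
    if events.n_dwells == 0:
        raise InvalidParameterError("event sequence is empty")
    n = int(round(cfg.fs_hz * events.total_duration_s))
    if n < 2:
        raise InvalidParameterError(
            "fs * duration must give at least 2 samples"
        )
    t = np.arange(n) / cfg.fs_hz
    edges = events.boundaries()
    idx = np.searchsorted(edges, t, side="right")
    idx = np.minimum(idx, events.n_dwells - 1)  # t == total_duration edge case
    state = ((events.state_at_start + idx) % 2).astype(np.int8)

    mu = np.where(state == 1, cfg.mu_bound_V, cfg.mu_unbound_V)
    sigma = np.where(state == 1, cfg.sigma_bound_V, cfg.sigma_unbound_V)
    rng = np.random.default_rng(cfg.seed if noise_seed is None else noise_seed)
    values = mu + cfg.drift_slope_V_per_s * t + rng.standard_normal(n) * sigma

    return TrapTrace(
        values=values,
        fs=cfg.fs_hz,
        metadata={
            "P_total_uM": cfg.P_total_uM,
            "L_total_uM": cfg.L_total_uM,
            "temperature_K": cfg.temperature_K,
            "seed": cfg.seed,
            "label": "synthetic",
        },
        true_state=state,
    )


def simulate_trace(cfg: SimConfig) -> TrapTrace:
    """Full synthetic trapping trace: event sequence + rendered signal.

    ``cfg.seed`` is split into two child streams — child 0 drives the dwell
    sampling, child 1 the per-sample noise — so either component can be
    reproduced independently.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(2)
    events = simulate_event_sequence(
        k_off=cfg.k_off,
        k_on_eff=cfg.k_on_eff,
        duration_s=cfg.duration_s,
        initial_state=0,
        seed=children[0],
    )
    return render_trace(events, cfg, noise_seed=children[1])


def simulate_fp_titration(
    K_D: float,
    P_max: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed=None,
    n_replicates: int = 1,
) -> FPCurve:
    """Synthetic one-site FP titration: ``P(C) = P_max*C/(K_D + C)`` + noise.

    With ``n_replicates > 1`` the concentration grid is repeated and each
    replicate receives independent Gaussian noise (sd in mP).
    """
    if K_D <= 0:
        raise InvalidParameterError("K_D must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be non-negative")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    conc = np.tile(conc, n_replicates)
    rng = np.random.default_rng(seed)
    P = P_max * conc / (K_D + conc)
    if noise_sd > 0:
        P = P + rng.normal(0.0, noise_sd, size=conc.shape)
    return FPCurve(concentrations_uM=conc, P_mP=P)


def simulate_melt_curve(
    T_m: float,
    width: float,
    ratio_low: float,
    ratio_high: float,
    T_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed=None,
) -> MeltCurve:
    """Synthetic two-state melt curve on a temperature grid.

    The noiseless I350/I330 ratio is the logistic
    ``ratio_low + (ratio_high - ratio_low) / (1 + exp((T_m - T)/width))``,
    whose derivative extremum sits exactly at ``T_m``.  ``noise_sd`` is the
    *fractional* standard deviation of multiplicative noise applied
    independently to both intensity channels (I330 is a unit baseline).
    """
    if width <= 0:
        raise InvalidParameterError("width must be positive")
    T = np.asarray(T_grid, dtype=float)
    if T.size < 5:
        raise InvalidParameterError("temperature grid needs at least 5 points")
    if np.any(np.diff(T) <= 0):
        raise InvalidParameterError("temperature grid must be strictly increasing")
    ratio = ratio_low + (ratio_high - ratio_low) / (1.0 + np.exp((T_m - T) / width))
    rng = np.random.default_rng(seed)
    I330 = np.ones_like(T)
    I350 = ratio.copy()
    if noise_sd > 0:
        I330 = I330 * (1.0 + rng.normal(0.0, noise_sd, size=T.shape))
        I350 = I350 * (1.0 + rng.normal(0.0, noise_sd, size=T.shape))
    return MeltCurve(temperature_C=T, I330=I330, I350=I350)


def simulate_cpmg_pair(
    R2: float,
    I0: float = 1.0,
    t_short: float = 0.002,
    t_long: float = 0.102,
    noise_sd: float = 0.0,
    seed=None,
) -> CPMGPair:
    """Synthetic two-delay CPMG intensities ``I(t) = I0 * exp(-R2*t)`` + noise."""
    if I0 <= 0:
        raise InvalidParameterError("I0 must be positive")
    if R2 < 0:
        raise InvalidParameterError("R2 must be non-negative")
    if not t_long > t_short >= 0:
        raise InvalidParameterError("require t_long > t_short >= 0")
    rng = np.random.default_rng(seed)
    I_s = I0 * np.exp(-R2 * t_short)
    I_l = I0 * np.exp(-R2 * t_long)
    if noise_sd > 0:
        I_s += rng.normal(0.0, noise_sd)
        I_l += rng.normal(0.0, noise_sd)
    return CPMGPair(I_short=float(I_s), I_long=float(I_l),
                    t_short_s=float(t_short), t_long_s=float(t_long))
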