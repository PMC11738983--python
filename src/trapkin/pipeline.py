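"""End-to-end analysis: raw trace -> filtered -> states -> dwells -> kinetics.

``run_analysis`` executes the stages in acquisition order: 3 Hz low-pass
filtering with decimation, ~30 s segmentation, per-segment two-state HMM
with restarts, spurious-transition correction, pooled dwell extraction with
edge censoring, single-exponential CDF fits for both states, and the
depletion-corrected kinetics.  A two-Gaussian fit to the pooled filtered
signal quantifies the level contrast.  Everything is deterministic given the
trace and the configured seeds, and the report serializes to JSON
losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .dwell_kinetics import (
    DwellSet, ExpFit, KineticsResult,
    compute_kinetics, extract_dwells, fit_exponential_cdf,
)
from .errors import ConfigurationError, StageError
from .signal_processing import (
    MixtureFit, TrapTrace, fit_two_gaussian_pdf, lowpass_filter, segment_trace,
)
from .state_inference import correct_spurious_transitions, fit_two_state_hmm

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Tunables of the analysis chain.

    The defaults are the reference processing chain: 3 Hz cutoff, decimation
    to 100 Hz, 30 s segments, 20 HMM restarts, 0.05 s / 10% spurious-
    transition rule — so a default-constructed config is the zero-knob path.
    Concentrations may be given here or carried in the trace metadata.
    """

    cutoff_hz: float = 3.0
    decimate_to_hz: float = 100.0
    segment_s: float = 30.0
    n_restarts: int = 20
    hmm_tol: float = 1e-8
    hmm_max_iter: int = 500
    hmm_seed: int = 0
    min_dwell_s: float = 0.05
    midpoint_frac: float = 0.10
    min_events: int = 5
    drop_edges: bool = True
    P_total_uM: Optional[float] = None
    L_total_uM: Optional[float] = None
    temperature_K: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisReport:
    """Machine-readable record of one analyzed trapping event."""

    kinetics: Optional[KineticsResult]
    bound_fit: Optional[ExpFit]
    unbound_fit: Optional[ExpFit]
    mixture: Optional[MixtureFit]
    n_events: int
    censored_count: int
    segments: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kinetics": self.kinetics.to_dict() if self.kinetics else None,
            "bound_fit": self.bound_fit.to_dict() if self.bound_fit else None,
            "unbound_fit": self.unbound_fit.to_dict() if self.unbound_fit else None,
            "mixture": self.mixture.to_dict() if self.mixture else None,
            "n_events": self.n_events,
            "censored_count": self.censored_count,
            "segments": self.segments,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_analysis(trace: TrapTrace, config: Optional[AnalysisConfig] = None) -> AnalysisReport:
    """Run the full analysis chain on one trapping trace.

    Raises :class:`ConfigurationError` if concentrations are missing, and
    :class:`StageError` (carrying the stage name and the partial report
    assembled so far) if a downstream stage fails.
    """
    config = config or AnalysisConfig()
    p_total = config.P_total_uM
    if p_total is None:
        p_total = trace.metadata.get("P_total_uM")
    l_total = config.L_total_uM
    if l_total is None:
        l_total = trace.metadata.get("L_total_uM")
    temperature = config.temperature_K
    if temperature is None:
        temperature = trace.metadata.get("temperature_K", 308.15)
    if p_total is None or l_total is None:
        raise ConfigurationError(
            "total protein and ligand concentrations are required: set "
            "P_total_uM / L_total_uM in the config or in the trace metadata"
        )

    report = AnalysisReport(
        kinetics=None, bound_fit=None, unbound_fit=None, mixture=None,
        n_events=0, censored_count=0,
        provenance={
            "software_version": __version__,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "trace_metadata": {k: trace.metadata[k] for k in sorted(trace.metadata)},
            "trace_n_samples": int(trace.n),
            "trace_fs_hz": float(trace.fs),
        },
    )

    try:
        filtered = lowpass_filter(
            trace, cutoff_hz=config.cutoff_hz,
            decimate_to_hz=config.decimate_to_hz,
        )
    except Exception as exc:
        raise StageError("lowpass_filter", exc, report) from exc

    try:
        report.mixture = fit_two_gaussian_pdf(filtered)
    except Exception as exc:
        raise StageError("fit_two_gaussian_pdf", exc, report) from exc

    try:
        segments = segment_trace(filtered, segment_s=config.segment_s)
    except Exception as exc:
        raise StageError("segment_trace", exc, report) from exc

    dwell_sets = []
    try:
        for i, segment in enumerate(segments):
            path = fit_two_state_hmm(
                segment,
                n_restarts=config.n_restarts,
                tol=config.hmm_tol,
                max_iter=config.hmm_max_iter,
                seed=config.hmm_seed + i,
            )
            seg_info = {
                "index": i,
                "t0_s": segment.t0,
                "duration_s": segment.effective_duration_s,
                "single_state": path.single_state,
                "mu_U": path.mu_U, "mu_B": path.mu_B,
                "sigma_U": path.sigma_U, "sigma_B": path.sigma_B,
                "log_likelihood": path.log_likelihood,
                "n_restarts_used": path.n_restarts_used,
            }
            if path.single_state:
                seg_info["n_dwells"] = 0
                report.segments.append(seg_info)
                continue
            path = correct_spurious_transitions(
                path, segment,
                min_dwell_s=config.min_dwell_s,
                midpoint_frac=config.midpoint_frac,
            )
            dwells = extract_dwells(
                path, segment.effective_fs,
                drop_edges=config.drop_edges, segment_id=i,
            )
            seg_info["n_dwells"] = int(dwells.n_events)
            report.segments.append(seg_info)
            dwell_sets.append(dwells)
    except Exception as exc:
        raise StageError("state_inference", exc, report) from exc

    pooled = DwellSet.pool(dwell_sets)
    report.n_events = int(pooled.n_events)
    report.censored_count = int(pooled.censored_count)

    try:
        report.bound_fit = fit_exponential_cdf(
            pooled.bound_s, min_events=config.min_events
        )
        report.unbound_fit = fit_exponential_cdf(
            pooled.unbound_s, min_events=config.min_events
        )
    except Exception as exc:
        raise StageError("fit_exponential_cdf", exc, report) from exc

    try:
        report.kinetics = compute_kinetics(
            report.unbound_fit, report.bound_fit,
            P_total_uM=float(p_total), L_total_uM=float(l_total),
            temperature_K=float(temperature),
        )
    except Exception as exc:
        raise StageError("compute_kinetics", exc, report) from exc

    return report
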