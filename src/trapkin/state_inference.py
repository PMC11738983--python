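"""Bound/unbound state assignment for filtered trapping traces.

Each ~30 s filtered segment is fit with a two-state Gaussian-emission hidden
Markov model trained by expectation-maximization from 20 randomized
initializations; the best-likelihood model is kept and the most-probable
state path (Viterbi) gives per-sample labels — the step function of the
trapping record.  States are relabelled so that the higher emission mean is
the bound state (binding increases optical scattering).

Because noise can still produce brief label flips, a correction pass then
scans the step function left-to-right: any dwell no longer than 0.05 s whose
mean filtered-signal value lies within 10% of the level separation from the
midpoint between the two states is treated as noise and reverted to the
preceding dwell's state, merging it with its neighbours.  Passes repeat
until a fixpoint.  The correction conserves total labelled duration exactly
and never creates new transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .errors import FitError, InsufficientDataError, InvalidParameterError
from .signal_processing import FilteredTrace

__all__ = ["StatePath", "fit_two_state_hmm", "correct_spurious_transitions"]


@dataclass
class StatePath:
    """Per-sample binary state labels with the fitted emission model.

    ``labels`` is aligned to the filtered segment it was fit on; 1 = bound
    (higher mean), 0 = unbound.  ``single_state`` marks segments whose two
    fitted levels are closer than half the pooled noise width — these show
    no resolvable binding dynamics and are excluded from kinetics.
    """

    labels: np.ndarray
    mu_U: float
    mu_B: float
    sigma_U: float
    sigma_B: float
    log_likelihood: float
    n_restarts_used: int
    single_state: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.mu_B + self.mu_U)

    @property
    def separation(self) -> float:
        return self.mu_B - self.mu_U


def _run_lengths(labels: np.ndarray):
    """Run-length encode: returns (start_indices, lengths, states)."""
    n = labels.shape[0]
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return starts, ends - starts, labels[starts]


def fit_two_state_hmm(
    segment: FilteredTrace,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed=None,
    expected_dwell_s: float = 0.4,
) -> StatePath:
    """Fit a two-state Gaussian HMM to a filtered segment with restarts.

    The signal is standardized before fitting; restart emission means are
    drawn around the 25th/75th percentiles with jitter, and the transition
    matrix is initialized for dwells of ``expected_dwell_s`` at the
    segment's effective sampling rate.  ``tol`` is the relative
    log-likelihood change declaring EM convergence.

    The two states share one emission variance (tied covariance).  After
    heavy low-pass filtering the apparent width of each level is dominated
    by transition-ramp samples rather than by the state's own noise, and a
    shared width keeps the Viterbi decision boundary at the midpoint
    between the levels instead of letting the wider state swallow the
    ramps.  Per-state noise widths are reported from the labelled residuals
    afterwards.
    """
    import logging

    from hmmlearn.hmm import GaussianHMM

    logging.getLogger("hmmlearn").setLevel(logging.ERROR)

    x = np.asarray(segment.values, dtype=float)
    n = x.shape[0]
    if n < 100:
        raise InsufficientDataError(
            f"HMM fit requires >= 100 samples, got {n}"
        )
    fs = segment.effective_fs

    loc = float(np.mean(x))
    scale = float(np.std(x))
    if scale == 0.0:
        # constant signal: trivially single-state
        return StatePath(
            labels=np.zeros(n, dtype=np.int8),
            mu_U=loc, mu_B=loc, sigma_U=0.0, sigma_B=0.0,
            log_likelihood=np.nan, n_restarts_used=0, single_state=True,
        )
    z = ((x - loc) / scale).reshape(-1, 1)

    q25, q75 = np.percentile(z, [25, 75])
    if q75 - q25 <= 0:
        q25, q75 = -1.0, 1.0
    p_switch = min(0.4, 1.0 / (expected_dwell_s * fs))
    transmat0 = np.array([[1 - p_switch, p_switch],
                          [p_switch, 1 - p_switch]])
    var0 = max((0.25 * (q75 - q25)) ** 2, 1e-6)

    rng = np.random.default_rng(seed)
    best = None
    best_ll = -np.inf
    n_used = 0
    for _ in range(n_restarts):
        jitter = 0.25 * (q75 - q25)
        m0 = q25 + jitter * rng.standard_normal()
        m1 = q75 + jitter * rng.standard_normal()
        model = GaussianHMM(
            n_components=2,
            covariance_type="tied",
            min_covar=1e-12,
            n_iter=max_iter,
            tol=tol * n,  # hmmlearn's tol is absolute in total log-likelihood
            init_params="",
            params="stmc",
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        model.startprob_ = np.array([0.5, 0.5])
        model.transmat_ = transmat0.copy()
        model.means_ = np.array([[m0], [m1]])
        model.covars_ = np.array([[var0]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(z)
                ll = float(model.score(z))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if np.isfinite(ll):
            n_used += 1
            if ll > best_ll:
                best_ll = ll
                best = model

    if best is None:
        raise FitError("all HMM restarts failed to converge")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, states = best.decode(z)  # Viterbi
    means = best.means_.ravel()
    order = np.argsort(means)        # order[0] -> unbound, order[1] -> bound
    labels = np.where(states == order[1], 1, 0).astype(np.int8)

    mu_u = loc + scale * means[order[0]]
    mu_b = loc + scale * means[order[1]]
    # per-state widths from the labelled residuals (emission variance itself
    # is tied during fitting, see docstring)
    tied_sigma = scale * float(np.sqrt(np.ravel(best.covars_)[0]))
    sig_u = float(np.std(x[labels == 0])) if np.any(labels == 0) else tied_sigma
    sig_b = float(np.std(x[labels == 1])) if np.any(labels == 1) else tied_sigma
    pooled = np.sqrt(0.5 * (sig_u ** 2 + sig_b ** 2))
    # Degeneracy: levels closer than half the pooled noise width, or the
    # two-state model failing a BIC comparison against a single Gaussian
    # (4 extra parameters), mean no binding dynamics are resolvable.
    ll_single = -0.5 * n * (np.log(2 * np.pi) + 1.0)  # z is standardized
    bic_gain = best_ll - ll_single - 2.0 * np.log(n)
    single = (mu_b - mu_u) < 0.5 * pooled or bic_gain <= 0.0
    if single:
        labels = np.zeros(n, dtype=np.int8)
    return StatePath(
        labels=labels,
        mu_U=float(mu_u), mu_B=float(mu_b),
        sigma_U=float(sig_u), sigma_B=float(sig_b),
        log_likelihood=best_ll, n_restarts_used=n_used,
        single_state=bool(single),
    )


def correct_spurious_transitions(
    path: StatePath,
    segment: FilteredTrace,
    min_dwell_s: float = 0.05,
    midpoint_frac: float = 0.10,
    max_passes: int = 10,
    midpoint_frac_mode: str = "separation",
) -> StatePath:
    """Remove noise-induced brief state flips from a decoded path.

    Scanning left to right, every dwell of duration <= ``min_dwell_s``
    (inclusive) has the mean of its filtered-signal samples compared with the
    midpoint ``m = (mu_B + mu_U)/2``.  If the mean deviates from ``m`` by
    less than ``midpoint_frac`` of the level separation (mode
    ``"separation"``, default) or of ``|m|`` itself (mode ``"midpoint"``),
    the dwell is judged noise and reverted to the preceding dwell's state
    (a leading candidate dwell reverts to the *following* state).  Reverting
    merges the dwell with its neighbours; passes repeat until no change or
    ``max_passes``.  Total duration is conserved exactly and no new
    transitions are ever created.
    """
    fs = segment.effective_fs
    if min_dwell_s < 1.0 / fs:
        raise InvalidParameterError(
            "min_dwell_s must be at least one effective sample period"
        )
    if midpoint_frac_mode not in ("separation", "midpoint"):
        raise InvalidParameterError(
            f"unknown midpoint_frac_mode {midpoint_frac_mode!r}"
        )
    labels = np.array(path.labels, dtype=np.int8, copy=True)
    starts, lengths, states = _run_lengths(labels)
    if len(starts) <= 1 or path.single_state:
        return dc_replace(path, labels=labels)

    x = np.asarray(segment.values, dtype=float)
    if x.shape[0] != labels.shape[0]:
        raise InvalidParameterError("path is not aligned to the segment")
    m = path.midpoint
    if midpoint_frac_mode == "separation":
        threshold = midpoint_frac * path.separation
    else:
        threshold = midpoint_frac * abs(m)
    max_len = int(round(min_dwell_s * fs))  # dwell <= min_dwell_s, inclusive

    for _ in range(max_passes):
        # mutable run list: [state, start, end)
        runs = [[int(s), int(a), int(a + ln)]
                for s, a, ln in zip(states, starts, lengths)]
        changed = False
        i = 0
        while i < len(runs):
            state, a, b = runs[i]
            if (b - a) <= max_len and len(runs) > 1:
                mean = float(x[a:b].mean())
                if abs(mean - m) < threshold:
                    target = runs[i - 1][0] if i > 0 else runs[i + 1][0]
                    if target != state:
                        runs[i][0] = target
                        changed = True
                        # merge with identical neighbours; rescan from merge
                        j = i
                        if j > 0 and runs[j - 1][0] == target:
                            runs[j - 1][2] = runs[j][2]
                            del runs[j]
                            j -= 1
                        if j + 1 < len(runs) and runs[j + 1][0] == target:
                            runs[j][2] = runs[j + 1][2]
                            del runs[j + 1]
                        i = j
            i += 1
        if not changed:
            break
        for state, a, b in runs:
            labels[a:b] = state
        starts, lengths, states = _run_lengths(labels)
        if len(starts) <= 1:
            break

    return dc_replace(path, labels=labels)
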