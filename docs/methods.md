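# Methods

`trapkin` analyses single-molecule ligand-binding recordings from
nanoaperture optical tweezers (NOT). A protein trapped at the aperture
changes its optical polarizability when a ligand binds, so the transmitted
laser intensity — recorded on an avalanche photodiode at 100 kHz — toggles
between two closely spaced levels. The package turns such a trace into
bound/unbound state paths, dwell-time distributions, and mass-action rate
constants with an explicit ligand-depletion correction, and implements the
companion ensemble assays (fluorescence polarization, thermal shift,
two-point CPMG). A synthetic-data module generates traces and assay
datasets with known ground truth so every stage is testable without
experimental recordings.

## The binding model

The 1:1 scheme P + L ⇌ PL, observed on a single protein, is a two-state
continuous-time Markov process. Residence times are exponential:

- bound dwells with mean τ_off, so k_off = 1/τ_off;
- unbound dwells with mean τ_on, where the exit rate is the
  pseudo-first-order association rate k_on·[L]_free, so
  k_on = 1/(τ_on·[L]_free).

At micromolar affinity the protein (10 μM) and ligand (20 μM)
concentrations are comparable, so complex formation depletes the free
ligand and [L]_free ≈ [L]_t would bias k_on and K_D. Writing
K_D = τ*·[L]_free with τ* = τ_on/τ_off and imposing mass balance yields

    (1 + τ*)[PL]² − ([P]_t + (1 + τ*)[L]_t)[PL] + [P]_t[L]_t = 0,

whose smaller root is the physical equilibrium complex concentration
(`solve_complex_concentration`, stable quadratic formula, guarded to lie in
[0, min([P]_t, [L]_t)]). Then [L]_free = [L]_t − [PL],
K_D = τ*·[L]_free = k_off/k_on (an exact algebraic identity in the
implementation), and ΔG° = RT ln K_D with K_D converted to molar
(R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹). The default temperature is 308.15 K,
matching the ~35 °C plasmonic-heating conditions of trapping experiments.
With τ_on = 0.37 s, τ_off = 0.40 s, 10/20 μM this gives [PL] = 5.19 μM,
[L]_free = 14.81 μM, K_D = 13.69 μM, k_off = 2.50 s⁻¹ — the package's
worked example.

## Signal conditioning

- **Low-pass filter.** 4th-order Butterworth at 3 Hz, applied
  forward–backward (`sosfiltfilt`): unit DC gain and zero phase, so state
  boundaries are not displaced and dwell durations stay unbiased. The
  cutoff trades noise rejection against event merging: dwells shorter than
  the ~0.15 s rise time are irreversibly flattened (see *Limitations*).
- **Decimation** to 100 Hz (plain subsampling after filtering; the
  passband is untouched). This makes the 0.05 s correction threshold an
  integer 5 samples and removes the massive sample-to-sample correlation
  the HMM would otherwise see at 100 kHz.
- **Segmentation** into 30 s sections; a trailing remainder shorter than
  10 s is dropped as too short for a meaningful dwell fit.
- **Level characterization.** A two-Gaussian model is least-squares fit to
  the Freedman–Diaconis histogram (floored at 64 bins so two levels 1%
  apart stay resolved) of the filtered signal; components are labelled by
  mean (higher = bound) and the bound/unbound level ratio is reported as a
  percentage. Fits whose means are closer than one pooled σ are flagged
  effectively unimodal.

## State inference

Each segment is fit with a two-state Gaussian-emission HMM trained by EM
from 20 randomized initializations (means seeded at the 25th/75th signal
percentiles with jitter, transition matrix initialized for ~0.4 s dwells);
the best-likelihood model is kept and Viterbi decoding gives the step
function. Two deliberate modelling choices:

- **Tied emission variance.** After heavy filtering, each level's apparent
  width is dominated by transition-ramp samples rather than by the state's
  own photodetector noise. With per-state variances, EM lets the wider
  state absorb the ramps, which biases its mean and drags the Viterbi
  boundary off the level midpoint (measured label accuracy dropped to
  ~88% on synthetic traces). A shared variance keeps the decision boundary
  at the midpoint; per-state noise widths are reported afterwards from the
  labelled residuals.
- **Single-state detection.** A segment is excluded from kinetics when the
  fitted levels are closer than half the pooled noise width, or when the
  two-state model fails a BIC comparison against a single-Gaussian null
  (4 extra parameters). The BIC test is what actually catches a
  constant-plus-noise segment: EM happily splits a pure Gaussian into two
  modes ~1.6σ apart, so a separation threshold alone cannot.

**Spurious-transition correction.** Scanning the decoded path left to
right, any dwell ≤ 0.05 s whose mean filtered value lies within 10% of the
*level separation* from the midpoint (μ_B + μ_U)/2 is judged noise and
reverted to the preceding dwell's state (a leading dwell reverts to the
following state), merging it with its neighbours; passes repeat to a
fixpoint. The 10% tolerance is interpreted as a fraction of the separation
rather than of the midpoint's absolute value, because the latter would make
the rule depend on the arbitrary detector baseline; the alternative reading
is available via `midpoint_frac_mode="midpoint"`. The correction conserves
total duration exactly, never creates transitions, and is idempotent at the
fixpoint.

## Dwell statistics

Edge dwells of each segment are censored (their start or end was not
observed) and dropped rather than survival-corrected — with hundreds of
events per trace the bias from two censored dwells per 30 s segment is
negligible. Pooled durations per state are fit with the single-exponential
CDF 1 − exp(−x/τ) by unweighted least squares at plotting positions
(i − 0.5)/n, τ initialized at the sample mean; the closed-form MLE (the
sample mean) is computed alongside as a cross-check and as the fallback on
non-convergence. On exponential data the two estimators agree to O(1/√n).

## Ensemble assays

- **Fluorescence polarization.** P = (I∥ − I⊥)/(I∥ + I⊥); the one-site
  isotherm P = P_max·C/(K_D + C) is fit by bounded nonlinear least squares
  (K_D seeded at the half-maximum concentration, P_max at 1.2× the
  observed maximum). The model passes through the origin by default (the
  isotherm predicts P = 0 at C = 0); an optional intercept and a scalar
  control-well background subtraction are provided.
- **Thermal shift.** Tm is the extremum of the first derivative of the
  I350/I330 ratio. The estimator smooths the ratio with a Savitzky–Golay
  filter (default window 2 °C, cubic), takes the equally smoothed
  derivative, excludes one smoothing window at each scan edge (where the
  polynomial edge fit amplifies noise), and refines the grid-level peak by
  the intensity-weighted centroid of the contiguous half-maximum region.
  The centroid replaces a naive argmax because point noise on a 0.1 °C
  grid makes the argmax jitter by ~0.5 °C and occasionally jump to an edge
  artifact entirely; with the centroid the median error at 0.5%
  multiplicative channel noise is ~0.1 °C, matching instrument-level
  precision. A flat or featureless-monotone ratio (derivative peak below
  twice the derivative's median magnitude) raises a no-transition error.
- **Two-point CPMG.** R2 = ln(I_short/I_long)/(t_long − t_short), exact
  for mono-exponential decay at the 2/102 ms delays; non-decaying pairs
  return a negative rate with a warning rather than an exception.

## Synthetic data: what it emulates, and what not

The generator produces alternating exponential dwells (bound-exit rate
k_off, unbound-exit rate k_on·[L]_free with [L]_free from the equilibrium
mass balance), rendered at 100 kHz with state-dependent white Gaussian
noise and optional linear drift. Defaults are the reference study
conditions: k_off = 1/0.40 s⁻¹; k_on = 0.1826 μM⁻¹s⁻¹, chosen so the
equilibrium at 10/20 μM gives a mean unbound dwell of exactly 0.37 s;
unbound level 1.0 V (the absolute detector voltage is arbitrary); bound
level 1% higher; σ_unbound = 0.002 V, σ_bound = 0.004 V (the extended,
bound conformation is noisier). Traces begin inside the trapped regime —
the trapping-onset transient is not simulated because the analysis operates
only on post-trapping signal. One integer seed is split into two documented
child streams (dwell sampling; detector noise) so either component is
independently reproducible.

Not emulated: 1/f and shot noise (no published model for this signal),
multi-protein trapping events, trap-stiffness or local-heating physics, and
baseline wander beyond a linear slope. Passing tests therefore demonstrate
correctness of the analysis under the stated statistical model, not
robustness to every artifact of real recordings.

Assay generators produce data obeying exactly the closed forms their
fitters assume (one-site isotherm; logistic melt whose derivative extremum
sits at Tm, with multiplicative channel noise; mono-exponential CPMG
decay), so each generator/fitter pair has a noiseless round-trip identity.

## Numerical choices and degenerate inputs

- Depletion quadratic solved with the sign-aware stable formula; the
  self-consistency identity (P_t − PL)(L_t − PL)/PL = τ*(L_t − PL) holds to
  10⁻⁹ relative across the tested parameter space.
- EM convergence: relative log-likelihood change < 10⁻⁸ or 500 iterations;
  constant segments short-circuit to a single-state path.
- Exponential CDF fit requires ≥ 5 events; analyses with fewer events in
  either state fail loudly.
- A dwell exactly at the 0.05 s threshold is a correction candidate
  (inclusive comparison, in integer samples at the effective rate).

## Problem sizes

Desk-scale defaults keep every check fast on one CPU: end-to-end recovery
uses a single 600 s trace (~10⁶ events would be ideal; ~10³ is what 600 s
carries, giving τ* a ~6% sampling error, which dominates the end-to-end
K_D uncertainty); stage-level rate recovery uses 10⁴ dwell draws; the
level-contrast check uses 100 s of signal; assay recoveries use the
1–80 μM titration grid in triplicate and 20–90 °C melts at 0.1 °C.

## Known limitations

- The 3 Hz filter merges dwells shorter than its rise time: both dwell
  classes inflate (0.40/0.37 s true means appear as ~0.6 s) and the event
  count drops by roughly a third. The ratio τ* is nearly invariant because
  the inflation is symmetric when τ_on ≈ τ_off — this is what makes K_D
  recoverable to ~10% — but per-sample label accuracy is capped near
  95–97% and individual rate constants (k_on, k_off) from filtered traces
  are biased low by the same inflation. Comparisons of k_off against truth
  should use unfiltered dwell statistics.
- The reported ΔG° follows the stated 308.15 K convention; at micromolar
  K_D it is ~−6.9 kcal/mol, modestly sensitive to the temperature
  convention chosen.
- The exponential CDF fit assumes a single kinetic phase; multi-exponential
  dwell distributions are out of scope and will show up only as a depressed
  r².
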