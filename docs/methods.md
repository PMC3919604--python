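# Methods

This note records the models implemented in `flapsm`, the defaults and
their rationale, the numerical choices that matter, and what the
synthetic-data validation does and does not demonstrate.

## Two-state conformational model

The free 5′-flap substrate is modelled as a continuous-time two-state
Markov (telegraph) process: a bent, Y-shaped conformer (state 1, low
FRET, E ≈ 0.37) and an extended conformer (state 2, high FRET, E ≈ 0.6),
with rates `k_forward` (1→2) and `k_backward` (2→1), both in s⁻¹.
Stationary occupancy of state 1 is k_b/(k_f + k_b); dwell times in each
state are exponential with that state's exit rate. Paths are sampled
exactly (event-by-event, Gillespie), not on a time grid, so the
generator has no discretization error of its own.

Two standard consequences anchor the analysis:

* the donor–acceptor cross-correlation (and each channel's
  autocorrelation) decays as exp(−(k_f + k_b)τ), so a monoexponential
  fit of the averaged cross-correlation estimates the *summed* rate
  even when individual dwells are unresolvable;
* frame averaging of dynamics faster than the camera integration time
  collapses the two states into a single histogram peak at the
  occupancy-weighted efficiency.

## Detection model (TIRF rendering)

Per frame of length Δt, the expected counts are time averages over the
frame of

    I_D = B · pife(state) · (1 − E(state)) / γ + bg_D
    I_A = B · E(state) + bg_A

with `B` the total detected rate per frame at E = 0 (counts/frame), `γ`
the detection-correction factor, and `pife` the state-dependent donor
brightness multiplier. Averages over within-frame state mixtures are
exact (integrals of the piecewise-constant path); the co-occurrence of
within-frame state changes with blinking or bleaching edges is treated
as independent, an approximation only active in single transition
frames. Noise is Poisson by default (Gaussian available for speed at
high counts; `"none"` for exact-value tests).

γ defaults to 1 everywhere: the package works in *apparent* efficiencies
E_app = I_A/(I_A + γI_D), as is standard for TIRF data without per-dye
calibration. γ is a configuration knob, never inferred.

Photophysical artefacts are single-step: donor or acceptor photobleach
(exponential waiting times, or forced at a given time in tests), and
acceptor blinking as a second telegraph process. When the acceptor is
dark, bleached or cleaved away, the transferred energy returns to the
donor: I_D rises to B·pife/γ, conserving B = I_D + I_A at γ = 1, pife = 1.
Blinking is modelled on the acceptor only — the dominant artefact for
cyanine acceptors under continuous donor excitation; donor blinking is
omitted.

Brightness and background defaults (500 counts/frame total over a
20-count background for the 100–200 ms single-molecule experiments; 300
over 10 for the 16 ms fast-exchange traces) are fixture choices at
realistic TIRF signal-to-noise, not measured values.

## Injection experiments

A real-time injection trace is piecewise: unbound (E_unbound) until
`t_injection + Exp(k_bind)`; bound (E_bound, donor multiplied by
`pife_bound`) until a further `Exp(k_cleave)`; after cleavage the
acceptor strand departs (acceptor at background, FRET channel closed).
Cleavage is one lumped exponential step covering catalysis and product
release. With probability `p_delayed_pife_loss` the clamp remains on the
nicked product and the donor enhancement persists a further
`Exp(k_pife_loss)`; otherwise PIFE is lost simultaneously with cleavage,
which makes the cleavage step *non-anticorrelated* (the donor drops with
the acceptor instead of recovering). Ground-truth event times ride along
in the trace metadata, always ordered injection < binding ≤ cleavage ≤
PIFE loss.

## Titration models

Ensemble titrations use one of two forms:

* **two-state Hill**: y = b + a·xⁿ/(Kⁿ + xⁿ) — for the Mg²⁺-induced
  conformational transition (K in mM, n dimensionless);
* **quadratic tight binding**: y = b + a·f with
  f = ((P + D + K) − √((P + D + K)² − 4PD))/(2D), P the titrant, D the
  probe total — required whenever the probe concentration is comparable
  to K_D (here 5–50 nM probe against K_D of 1.6–160 nM), because ligand
  depletion bends the isotherm.

Both are available in the simulator (with additive or multiplicative
replicate noise) and in the fitter; the fitter can share n/K (Hill) or
K_D (binding) across datasets while keeping baselines and amplitudes
per-dataset — the "global fit" used throughout.

## Fitting choices

* **Weighting.** Per-point inverse-variance weights estimated from ~3
  replicates are statistically poisonous: the sample variances have two
  degrees of freedom, and weighting by their reciprocals inflates the
  parameter variance ~60% above the Cramér–Rao bound in Monte Carlo.
  The replicate scatter is therefore *pooled across concentrations into
  one variance per dataset*: equal weights within a curve, honest
  inverse-variance weighting between curves in a global fit. Externally
  computed per-point standard errors (e.g. bootstrap SEs of
  single-molecule mean efficiencies, which rest on ~50 molecules) are
  trusted as supplied.
* **Restarts.** Every titration fit runs 10 log-normally jittered
  restarts of the Levenberg–Marquardt optimizer and keeps the best
  χ²; the jitter stream is seeded, so fits are deterministic.
* **Bounds.** The Hill exponent is confined to (0.2, 5) to exclude
  degenerate step-function fits.
* **Exponential rates.** Decay curves are fitted by least squares;
  dwell samples use the censoring-aware maximum likelihood estimator
  rate = n_events / Σ(observed time), SE = rate/√n_events, which is
  exact for exponential data under right-censoring. All-censored
  samples are rejected as unidentifiable.
* **Bootstrap.** `bootstrap_se` resamples replicates within each
  (dataset, concentration) cell (default 200 draws) as an independent
  uncertainty check on the least-squares standard errors.

## FRET, distances and geometry

Distances follow R = R₀((1−E)/E)^(1/6); R₀ defaults to 53 Å for
Cy3–Cy5. For the fluorescein–Cy3 pair no published value is adopted;
the 56 Å default is literature-typical and flagged as configuration.
Arm lengths for kink-angle work are composed as 3.4 Å/bp plus a 5 Å
terminal-stacking offset for Cy3 and a configurable free-linker length
(default 10 Å) for fluorescein; the kink angle follows the law of
cosines, with the triangle inequality enforced to a relative tolerance.

**PIFE correction.** A protein binding near Cy3 raises its quantum
yield α-fold. Since γ = η_AΦ_A/(η_DΦ_D), the enhanced state has
effective γ′ = γ/α, and the Förster radius becomes R₀′ = R₀·α^(1/6)
(R₀⁶ ∝ Φ_D). Composing the two corrections on intensity-ratio data the
α factors cancel exactly: ratiometric FRET distances are invariant to a
pure donor quantum-yield change, and the corrected pipeline reduces to
the uncorrected one at α = 1 (and, on E_app data, at every α — verified
against the generator by round-trip). The correction that genuinely
moves numbers applies to donor-quenching efficiencies measured against
an unenhanced donor-only reference, E_corr = 1 − (1 − E)/α, provided as
`donor_quench_corrected_efficiency`.

## Single-molecule trace analysis

* **Change points.** Steps are detected by binary segmentation on the
  (donor, acceptor) channel pair: recursive best mean-shift splits,
  accepted while the SSE gain on MAD-standardized channels exceeds a
  BIC-style penalty `3·(p+1)·ln n` (p = number of channels). The
  penalty multiplier was calibrated on simulated null traces (static
  state, Poisson noise) to a spurious-detection rate of ~0 per
  3000-frame trace; the bleach-only false-cleavage rate is asserted
  ≤ 5% in the suite. Minimum segment length 3 frames.
* **Filtering.** A trace is truncated at the earliest segment from
  which the acceptor (or the total intensity) never recovers —
  photobleach — and acceptor-dark segments that *do* recover are masked
  as blinks. The mask is recomputed on the truncated record, making the
  filter a fixed point (idempotent). Traces whose 90th-percentile total
  intensity sits within shot noise of background are rejected as dark.
* **Histograms and mixtures.** E_app frames are clamped to [−0.2, 1.2]
  for histogramming only (default bin width 0.025). Mixtures are EM
  fits with a 10⁻⁴ variance floor; the component count (1 or 2) is
  chosen by BIC when unspecified.
* **HMM.** Two-state Gaussian-emission HMM with pooled emissions across
  traces and per-trace Viterbi paths (heterogeneous trace lengths make
  per-trace emission fits unstable). Exit rates come from the censored
  dwell MLE with first and last dwells of every path flagged censored.
  If the emission means separate by less than the larger emission SD,
  or one state holds under 0.5% of frames, the record is reported as
  one-state rather than returning noise-split rates.
* **Event detection.** Change points are classified in time order:
  *binding* is the first post-injection step down in E_app (≥ 0.05 by
  default) with a surviving acceptor; *cleavage* is the acceptor's
  terminal fall to background, credited only when a binding step
  preceded it; a donor-only later step down is the delayed *PIFE loss*,
  and a donor drop coincident with cleavage marks the simultaneous
  (non-anticorrelated) variant. Steps within 4 frames of the acceptor
  loss are treated as integration artefacts of the loss itself, not
  binding. Transition classification uses before/after means over
  5-frame windows with a z ≥ 4 significance test and a 10% dead band.
* **Cleavage vs photobleach.** The experimental discriminator (direct
  acceptor excitation) is hardware; the in-software surrogate is the
  rule above — an acceptor loss with no preceding binding step is
  classified photobleached, and molecules lost this way leave the
  binding-rate estimate as dwells censored at the loss time. This is a
  surrogate, not a reproduction of the control.
* **sm titrations.** Mean E_app per concentration over all retained
  frames, with a bootstrap-over-molecules SE (200 draws) that feeds the
  weighted binding fit. Immobilized molecules cannot deplete the
  titrant, so the depletion isotherm is evaluated with a vanishing
  probe term.

## Accessible volumes

The single-radius AV model: the dye is a sphere (default radius 3.5 Å)
on a linker of given length and width (default 4.5 Å) attached to one
atom. On a cubic grid (default 2 Å) centred on the attachment point,
shortest through-grid paths (26-connectivity Dijkstra, Euclidean edge
weights) define reachability: a grid point belongs to the AV if its
path length is within the linker length, every path node clears all
atom surfaces by half the linker width, and the point itself clears
them by the dye radius. The attachment atom is exempt from clash tests.
The mean dye position is the centroid of the allowed points; distances
between AVs are distances between centroids (R_mp). The through-grid
metric overestimates Euclidean distances by up to ~8% at 26-connectivity,
which slightly shrinks the AV shell; halving the grid spacing moves the
centroid by less than a spacing (verified). The FRET-averaged distance
⟨R⟩ is not computed — a documented limitation. Linker parameters for
specific dyes are configuration, not claims.

## Validation by parameter recovery

No public dataset exists for these assays, so every pipeline is
validated by recovery of known ground truth under the study's designs
(`flapsm/validation.py`, exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`): Mg²⁺ Hill titrations (10 points 0–30 mM,
triplicate, σ_E = 0.02), 15 × 60 s cross-correlation traces at 16 ms,
three-vector binding isotherms at 5 nM probe (σ_E = 0.01), a PIFE
titration at 50 nM probe (2% multiplicative noise), single-molecule
titrations of 50 molecules × 8 concentrations (20 s traces at 100 ms),
and injection experiments of 300 molecules × 600 s at 200 ms. These
sizes are the designs being emulated, chosen once; the acceptance script
reruns all of them in a few seconds of CPU.

Two recoveries sit near their information limits, by design of the
emulated experiments rather than of the estimators. For the global Hill
fit, the Cramér–Rao bound at the stated noise and amplitudes is
sd(n) ≈ 0.11 — the fitted estimator is unbiased and achieves this bound
(verified by Monte Carlo and against a brute-force grid-search oracle)
— so individual synthetic datasets scatter by about ±0.1 in n around
truth. Likewise the single-molecule K_D at 50 molecules per
concentration carries an irreducible binomial sampling noise of ≈ 5 nM
on a 23 nM constant. Recovery tests at such designs characterize the
information in the experiment, not a defect of the fit.

## What the generator does not emulate

Photon-by-photon statistics (interphoton times, triplet states),
polarization and orientation (κ² is the isotropic average baked into
R₀), spectral crosstalk and direct acceptor excitation, donor blinking,
intensity drift, diffusing background, and spot-detection/registration
errors upstream of trace extraction. Passing recovery tests therefore
demonstrates correctness of the inference given the stated generative
assumptions; real traces violate them in ways the filtering and
dead-band defaults absorb only partially, and the defaults are exposed
as parameters for that reason.
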