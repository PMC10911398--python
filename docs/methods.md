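# Methods

## The one-pool model

The readily releasable pool (RRP) is treated as a single compartment of
primed synaptic vesicles. Vesicles enter by priming from an effectively
unlimited upstream pool at rate `k1` (vesicles/s), and each primed
vesicle independently either deprimes (hazard `k_minus1`, 1/s) or fuses
spontaneously (hazard `kf`, 1/s):

    dRRP/dt = k1 − (k_minus1 + kf) · RRP

The model's closed forms follow directly: the steady state is
`RRP∞ = k1/(k_minus1+kf)`, relaxation toward it is exponential with
rate `k_minus1+kf`, and the spontaneous release (mEPSC) rate at rest is
`r_mini = kf · RRP∞`. As a continuous-time Markov chain the model is a
birth–death process with constant immigration, whose stationary
occupancy is Poisson with mean `RRP∞` — this fixes both the correct
burn-in-free initial condition for simulations and the expected Fano
factor of 1 used in the tests.

Hypertonic sucrose multiplies the fusion hazard by a fold-increase
`N_suc` (dimensionless, ≥1). If `kf·N_suc ≫ k_minus1`, the late
("plateau") release rate during a sucrose application approaches `k1`,
which is what makes the sucrose plateau a priming-rate assay. For
finite `N_suc` the plateau is `kf·N_suc·k1/(k_minus1+kf·N_suc)`, and
the inversion routines account for this.

Three estimators of increasing realism invert the model from the
observable triple (RRP size, mini rate, plateau rate):

1. `estimate_rates` — idealised (`N_suc → ∞`): `kf = r_mini/RRP`,
   `k1 = plateau`, `k_minus1 = k1/RRP − kf`. Exact round trip on its
   own forward model.
2. `estimate_rates_finite_nsuc` — closed-form solution of the
   two-equation system with the finite-`N_suc` plateau. Linear after
   substitution; no iteration. Converges to (1) as `N_suc → ∞`;
   a negative implied `k_minus1` is flagged (and the raw value kept),
   never silently clipped.
3. `estimate_rates_from_sucrose` — additionally models what the trace
   analysis *measures*: the transient charge is the time integral of
   the fusion-rate excess over the plateau, which falls short of the
   resting RRP by the pool held at the sucrose steady state and by the
   plateau fraction `g = kf·N_suc/(k_minus1+kf·N_suc) < 1`, and the
   solution-exchange ramp delays the hazard step. The expected
   transient is evaluated piecewise-exactly (midpoint piecewise-constant
   hazard across the ramp, exact exponential update per piece, 200
   pieces over 10 exchange time constants) and the two-dimensional root
   in `(log k1, log k_minus1)` is solved with `scipy.optimize.least_squares`,
   initialised from (2). For the wildtype parameter regime the
   difference between the measurable transient and the resting RRP is
   ≈4%, which is why the pipeline uses this estimator: the simpler
   closures would fail a 3-standard-error recovery check on `kf` and
   `k_minus1` even with perfect traces.

## Synthetic data generator

`simulate_pool` runs the exact Gillespie algorithm on the birth–death
chain (channels: priming `k1`; depriming `n·k_minus1`; fusion
`n·kf·s(t)`). During the solution-exchange ramp, where
`s(t) = 1+(N_suc−1)(1−e^{−t/τ})` is time-dependent, candidate fusion
events are drawn at the `N_suc` upper bound and accepted with
probability `s(t)/N_suc` (thinning), so the simulation stays exact.
`initial_pool="steady"` draws from the Poisson stationary law.

`render_trace` converts fusion times into a current trace: each event
contributes a difference-of-exponentials unitary waveform (defaults:
rise 0.5 ms, decay 3 ms, charge 0.05 pC, lognormal amplitude jitter
with CV 0.3 and mean 1), normalised so the discrete waveform integrates
exactly to the event charge; the protocol's leak shift (default
−20 pA) ramps with the exchange time constant (default 0.05 s, the
speed of local perfusion onto a micro-island autapse); Gaussian
instrument noise (default SD 3 pA) is added at 20 kHz sampling. Every
random stream is an explicit seed argument; cells derive four
independent sub-streams (pool/noise × spontaneous/sucrose) from one
integer.

`simulate_train` interleaves exact Gillespie segments between stimuli
with binomial release (`p_vr` per primed vesicle per action potential),
optionally with a decaying facilitation increment.

The waveform constants (unitary charge, kinetics, noise level) are
plumbing, not scientific claims: no published value constrains them, so
they are configurable defaults chosen at a typical AMPA-mEPSC scale,
and the analysis reads them from trace metadata the way a practitioner
would calibrate them from isolated minis.

What the generator deliberately does **not** emulate: postsynaptic
receptor kinetics and saturation, dendritic filtering and series-
resistance artefacts, multi-pool/super-primed substructure, calcium
dynamics, and heterogeneity of release sites. Passing recovery tests
therefore demonstrates the correctness and statistical calibration of
the analysis chain under the model's own assumptions, not robustness to
every failure mode of real recordings.

## Trace analysis

**Variance–mean baseline correction.** Hypertonic solutions shift the
leak current, so the plateau cannot be referenced to the pre-application
baseline. Synaptic release is shot noise — variance proportional to
rate — while the mean current is baseline plus rate-proportional
synaptic current, so variance vs. mean across 50-ms bins of the
application is linear, and extrapolating the regression to the
zero-release variance yields the true baseline. Implementation choices
that matter:

* *Detrending*: bin variances are computed after subtracting a local
  quadratic (Savitzky–Golay, 10-ms window). A plain running average
  leaks the curvature of the fast depletion transient into the
  variance; a quadratic does not.
* *Zero-release anchor*: the reference variance (and the
  pre-application baseline) come from a quiescent stretch with
  detected events censored (3 ms before to 25 ms after each peak, at a
  deliberately low 3σ threshold — false positives merely discard clean
  samples). Without censoring, resting minis inflate the anchor and
  bias the baseline by exactly the resting release current
  (`r_mini·q`, ≈1 pA for the high-frequency mutants).
* *Exchange ramp*: for fast-depleting cells the entire RRP empties
  while the solution is still exchanging, so the known ramp shape
  (bin-averaged `1−e^{−t/τ}`) enters the regression as a second
  regressor; the corrected baseline is read off at full exchange.
* *Weighting*: the sampling error of a bin variance scales with the
  variance itself, so the fit is iteratively reweighted with
  `1/fitted²` (3 iterations). A non-significantly-positive slope
  (one-sided t-test, p ≥ 0.05) triggers a flagged fallback to the raw
  pre-application baseline.

**Transient (RRP) charge and plateau.** The baseline-subtracted
current is integrated over the application; the plateau is the mean
over the final 20% (configurable — the transient/plateau boundary is a
per-protocol choice with no single published rule); the transient
charge is the integral minus the plateau contribution. Subtracting the
measured plateau makes the transient charge insensitive to residual
baseline error (the error cancels to first order). The subtracted
baseline ramps with the exchange time constant when known.

**Spectral plateau rate.** The mean-based plateau inherits the
corrected-baseline error, which dominates when the plateau is only a
few pA (mutants with low `k1`). The pipeline therefore estimates the
plateau *rate* from the shot-noise spectrum: the Welch PSD of the
plateau segment (last 60% of the application) is fitted as
`rate · (shot spectrum of the unitary waveform) + (white noise floor)`
by weighted linear least squares. By Campbell's theorem the shot
component's shape is known exactly from the waveform, so the fit is
baseline-free and needs no quiescent anchor. Frequencies below 30 Hz
are excluded to stay clear of drift. A time-domain Campbell variant
(`plateau_rate_campbell`) is provided for comparison; the mean-based
plateau current is still computed and reported.

**Mini detection.** Events are local minima of the 1-ms-smoothed trace
exceeding 5× the (MAD-estimated) smoothed noise SD, with a matching
prominence requirement (rejects noise wiggles riding on decay tails)
and a 2-ms minimum separation. The reported rate applies a
non-paralyzable dead-time correction `r = m/(1−m·τ)`; the effective
dead time τ is calibrated by probing the detector itself with
noise-free event pairs over a grid of separations and amplitude
quantiles (≈3.5–4 ms for the default waveform — set by the kernel
width, not by the separation rule). At 16–20 Hz mini rates the
uncorrected loss is 3–6%.

**Trains.** Cumulative evoked charge is regressed on time over the
last 20 of 50 stimuli (configurable) and extrapolated to time zero (one
inter-stimulus interval before the first stimulus, so a
depression-free train extrapolates to zero and is flagged invalid).
Intercept = train-probed RRP, slope = priming rate, first
charge/intercept = release probability, charge (or amplitude) ratio of
stimuli 2/1 = paired-pulse ratio. Non-positive intercepts (insufficient
depletion, e.g. low-`p` mutants) are flagged, mirroring the known
failure mode of back-extrapolation at low release probability.

**Synchronous fraction.** Cumulative charge after a stimulus is fitted
with a double exponential (amplitudes ≥0, `tau` sorted); the fast
amplitude share is the synchronous fraction, with a flagged
single-exponential fallback.

## Energy landscapes

Under Arrhenius kinetics with a mutation-independent prefactor, a rate
change maps to an activation-energy difference
`ΔEa = RT·ln(k_ref/k_mut)`. Applying this to `k1`, `k_minus1`, and
`kf` in sequence — with the pre-primed state anchored at the same
level — yields mutant-minus-reference offsets of the priming transition
state, the RRP state, and the fusion transition state. Only
differences are ever emitted (the prefactor is unknown), energies are
reported per molecule (kBT) and per mole (kJ/mol, RT = 2.479 kJ/mol at
298.15 K), the post-fusion level is marked unknown, and a caveat is
attached to priming offsets (priming may be collision-limited, which
would violate the constant-prefactor assumption).

## Electrostatic charge–rate model

The per-vesicle fusion rate as a function of net SNARE-surface charge
`Z` is modelled as a saturating log-linear (logistic-in-rate) curve

    k(Z) = K·k0·e^{βZ} / (K + k0·(e^{βZ} − 1)),

anchored by `k(0) = k0 = 0.00029 s⁻¹`, ceiling
`K = f·k_max = 0.030·6000 = 180 s⁻¹`, and sub-saturated slope β. The
exact parameterisation of the original model is not reprinted in the
sources available to this package, so this form was adopted as the
simplest curve honouring all three printed anchors; all outputs label
it. β defaults to 0.55575 kBT/charge, calibrated so a 22.47-fold
sub-saturated rate ratio corresponds to 5.6 charges (a documented
calibration, not ground truth, and configurable). Evoked release lives
on the same curve translated by 35 positive charges. The inverse
(rate → charge) is closed-form and exact to 1e−10 over the open range;
`downscale_peak_rate` implements amplitude-ratio rescaling of peak
rates for conditions too small to deconvolve (the printed amplitude
pair 0.2668/0.0475 nA gives the factor 5.617). The interpretation of
`f = 0.030` as a ceiling scaling (rather than a participating-vesicle
fraction) is an explicit choice; with only rate data the two are not
distinguishable.

## Numerical and statistical conventions

* Inward currents are negative in traces; derived charges are reported
  as positive magnitudes (pC).
* Estimates are reported in both charge and vesicle units via the
  configured unitary charge.
* Flags (`baseline_fallback`, `negative_k_minus1`,
  `no_positive_solution`, `solver_not_converged`, estimation failures)
  travel machine-readably in output tables; flagged values are reported,
  not dropped or clipped.
* Seeds are explicit everywhere; per-cell and per-stream seeds are
  spawned from one root via `numpy.random.SeedSequence`, so every
  output is reproducible from the manifest.
* Recovery benchmarks and the acceptance script use 50 cells per
  condition, a 60-s spontaneous segment and a 5-s sucrose application
  per cell at 20 kHz — cohort sizes chosen to put the standard error of
  each recovered rate near 1–3% so that 3-SE checks are informative.

## Known limitations

* The exchange time constant must be approximately known for the ramp
  regressor and ramped baseline subtraction; an error in τ biases the
  fast-depleting conditions most.
* The spectral plateau estimator assumes the unitary waveform (shape
  and amplitude moments) is known from calibration; systematic waveform
  mis-specification propagates linearly into `k1`.
* Back-extrapolation of trains is only meaningful with substantial
  depletion; low-`p` conditions are flagged rather than estimated.
* The one-pool model has no super-primed substructure, so differences
  between sucrose-probed and train-probed pools are descriptive, not
  mechanistic, in this package.
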