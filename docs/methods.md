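# Methods

## The pacemaker model

Each respiratory pacemaker — the pre-Bötzinger complex (preBötC, inspiratory)
and the parafacial respiratory group (pFRG, expiratory) — is a map-based
neuron: a discrete-time FitzHugh–Nagumo-type system of Courbage–Nekorkin form,

    x[n+1] = x[n] + F(x[n]) − y[n] − β·H(x[n] − d) + I_T[n] + I_syn[n]
    y[n+1] = y[n] + ε·(x[n] − J)

`x` plays the role of the membrane potential, `y` aggregates the outward
(recovery) currents, `H` is the Heaviside step (convention `H(0) = 1`), and
`F` is a continuous piecewise-linear caricature of the cubic nullcline with
outer slopes `−m0` and middle slope `+m1`, joined at

    x_lo = a·m1/(m0 + m1),      x_hi = (m0 + a·m1)/(m0 + m1).

The excitability `J` positions the fixed point: below `x_lo` the unit rests
quietly, inside `(x_lo, x_hi)` it oscillates, above `x_hi` it sits at a
depolarized rest.  With the default constants

    ε = 0.005, β = 0.4, d = 0.4, a = 0.2, m0 = 0.864, m1 = 0.65,
    δ = 0.2, x_th = −0.02

the oscillatory window produces chaotic spike-bursting throughout
(Jacobian-product Lyapunov exponents 0.03–0.5 per step across the window; we
verified this with a Benettin iteration independent of the time-series
estimators shipped in `nonlinear`).  A genuinely periodic *bursting* regime
does not exist under these constants — regular firing occurs only as tonic
spiking at reduced reset gain — so the shipped non-chaotic control preset
(`tonic`, β = 0.15, J = 0.3) spikes regularly rather than bursting
periodically.

### Rebound (calcium) current

`I_T = δ·G(k)·H(x − x_th)` with `G(k) = k` implements a low-threshold
calcium current: the de-inactivation level `k` charges toward 1 at rate
`1/τ2` per step while the unit is hyperpolarized below `x_th` and discharges
at rate `1/τ1` while above it.  Hence a hyperpolarization of at least `τ2`
steps recruits a maximal post-inhibitory rebound burst whose duration is set
by `τ1`, and no rebound is possible when the unit's rest already lies below
`x_th` (the calcium channel then never reopens).  Pacemaker-specific values:
pFRG `τ1 = 10, τ2 = 2`; preBötC `τ1 = 5, τ2 = 10`.

### Coupling and the inspiratory off-switch

Chemical synapses are rectangular pulses: each presynaptic spike injects the
constant `K` (positive excitatory, negative inhibitory) into the target for
`τ_syn` steps.  The network uses an excitatory pFRG→preBötC synapse
(`K = +0.1`) and an inhibitory preBötC→pFRG synapse (`K = −0.3`), both with
`τ_syn = 5`.  The inspiratory off-switch mirrors the pFRG's instantaneous
rebound current as an inhibitory input to the preBötC — an inhibitory pulse
with exactly the amplitude and duration of the rebound burst — and is
enabled in the pFRG-driven (disease) schemes, where the pFRG terminates
inspiration; in the preBötC-driven (healthy) schemes inspiratory bursts
terminate intrinsically through `y`.

### Regime presets

Panel-specific excitability values are not printed anywhere; the shipped
presets were found by a grid search over `(J1, J2)` with the coupling fixed,
selected to satisfy the regime classifier and re-checked across seeds:

| preset    | J1 (pFRG) | J2 (preBötC) | off-switch | label |
|-----------|-----------|--------------|------------|-------|
| regime_A  | −0.30     | 0.25         | off        | no_handshake |
| regime_B  | −0.22     | 0.25         | off        | dominant_preBot_occasional_pfrg |
| regime_C  | 0.18      | 0.00         | on         | full_handshake |
| regime_D  | 0.30      | 0.20         | on         | half_handshake |
| tonic     | 0.30 (β=0.15) | 0.30 (β=0.15) | off  | non-chaotic control |

In A the pFRG rests below `x_th`, so inhibition can never recruit a rebound
and the unit stays silent.  In B the rest sits between the two regimes and
rebounds fire for only a minority of preBötC cycles.  In C the pFRG bursts
chaotically and drives the quiescent-but-excitable preBötC; the off-switch
then suppresses reactivation, producing the full handshake
(pre-inspiratory burst → preBötC burst → rebound → pause).  In D both units
are intrinsically bursting and the rebound re-triggers the next preBötC
activation (half handshake).  Half-handshake configurations at lower
excitabilities exist but lock onto exactly periodic orbits; regime_D was
chosen inside the chaotic part of that family (driver exponent ≈ 0.33 per
step, stable across seeds).

### Classification

The regime classifier works on spike times, not burst intervals, because the
handshake phases of one cycle (pre-inspiratory burst, suppression pause,
rebound) merge into a single detected burst under any inter-spike-gap
criterion.  A preBötC burst counts as *triggered* when a pFRG spike falls
within 60 steps before its onset and *rebounded* when one falls within 60
steps after its offset; the trigger is *rebound-like* when that preceding
spike lies within 60 steps of the previous preBötC offset.  Labels:
parafacial silent → no handshake; parafacial active in under half the
cycles → preBötC-dominant; otherwise full vs half handshake by whether the
majority of triggers are fresh pre-inspiratory bursts or recycled rebounds.
Fewer than 5 cycles → unclassified.

Other conventions: spikes are upward crossings of a fixed threshold
(`0.3`, mid-range of the spike upstroke) during simulation, or of the
post-transient range midpoint offline; bursts group spikes whose intervals
do not exceed 3× the median inter-spike interval; initial conditions default
to uniform draws on `[−0.05, 0.05]` under a mandatory seed; the first 5000
steps are discarded as transient; iteration aborts if `|x|` or `|y|`
exceeds 7 (≈10× the oscillation range), signalling bad parameters.

## Airflow analysis

Breaths are delimited at inspiratory-onset zero crossings with a hysteresis
band of ±2% of the flow range and a 0.3-s minimum phase duration to reject
chatter; partial first/last breaths are dropped; volumes integrate each
phase trapezoidally.  The linear descriptors are the coefficient of
variation (sample SD over mean, ddof = 1) and the lag-one-breath
autocorrelation.  The first 120 s of a recording are excluded by default.

## Chaos pipeline

**Noise titration.**  Candidate polynomial autoregressive (Volterra–Wiener)
terms over lags 1..κ and total degree ≤ d (defaults κ = 6, d = 3; reduced
automatically for short series so the term count stays below a third of the
observations) are orthogonalized in canonical order (constant, linear terms,
quadratics, …); nested prefix models are scored by an information criterion
and the best degree-1 prefix competes against the best overall prefix in a
one-sided variance-ratio F-test at the 1% level.  The criterion is
`½·ln(SSE_r/SSE_0) + (ln N / 2N)·r` — a BIC-flavored penalty.  The more
common `r/N` penalty admits enough spurious nonlinear terms on short linear
AR nulls (n ≈ 250) to inflate the empirical test size to ≈3.5%; the stronger
penalty restores the nominal level (measured size ≤0.5% over 200 null runs)
at no measurable cost in power on clean or moderately noisy chaotic series.
Once nonlinearity is detected, Gaussian white noise with variance stepped in
1% increments of the signal power (series variance) is added until detection
fails; the noise limit NL is the last still-detected percent, averaged over
5 repeats with split seeds, with failed repeats counted as zero.

**Embedding.**  Lag = first drop of the autocorrelation below 1/e;
dimension = smallest m whose false-nearest-neighbor fraction (distance-ratio
15, loneliness 2 attractor radii) falls below 5%, with neighbors closer than
float noise (exact recurrences of periodic signals) skipped.  Theiler window
defaults to the embedding lag.

**Lyapunov exponent** (Rosenstein): each delay vector's nearest admissible
neighbor is tracked forward; the slope of the mean log-distance curve over
its initial rise (up to 80% of the span; the whole curve when flat, which
yields ≈0 for periodic signals) is λ_L per step.  Distances are floored at
10⁻¹²·SD so exactly recurring orbits contribute zero divergence instead of
−∞.

**Correlation dimension** (Grassberger–Procaccia): correlation integrals use
Chebyshev distances with exact admissible-pair normalization; the scaling
region is the widest ln–ln window (≥4 points) whose local slopes vary under
15% of their mean, preferring windows at least a decade wide; its
least-squares slope is D_corr.

**Surrogates**: Fourier phase randomization preserving DC and Nyquist; the
paired group test is the two-sided Wilcoxon signed-rank (exact enumeration
for n ≤ 25 without ties, normal approximation with tie handling above;
all-zero differences return p = 1 with a warning).

## BOLD forward model

The hemodynamic kernel is a double-gamma mixture (response delay 6 s,
undershoot delay 16 s, dispersions 1 s, response:undershoot ratio 6, onset
0, length 32 s), sampled on the simulation grid.  Neural states default to
the binarized spike train of each unit.  Because no step-to-seconds mapping
is printed, the clock is calibrated per run so the driving unit's mean burst
period equals 4 s (a physiological breath); the calibrated `dt` is recorded
in every output.  Signals are convolved, given a common scale such that the
mean channel SD equals the measurement-noise SD of 0.25 (the reference
protocol chose its noise SD equal to the SD of the measured BOLD series; a
common factor leaves normalized AlFO unchanged), sampled at TR = 2 s, and
corrupted with seeded Gaussian noise.

AlFO is the mean square-root power spectral density over 0.01–0.08 Hz of
the linearly detrended series (plain periodogram — the reference specifies
an FFT power spectrum, not a tapered estimator), normalized by the mean
across the two simulated channels; real ROI series may instead supply an
external global reference and are residualized on physiological covariates
(RVT, cardiac RR, end-tidal CO2, saturation) by OLS first.  Each simulated
run covers at least 250 action potentials per spiking pacemaker, extended
when necessary to the 200-s minimum that resolves the 0.01-Hz band edge;
the no-handshake scheme's silent parafacial contributes a flat state series
rather than an error.  Five runs per scheme are averaged.

## Synthetic data

The generators produce the study's test conditions: logistic-map and Hénon
series as chaotic alternatives with known exponents (ln 2 and ≈0.419 per
step) and dimension (Hénon ≈ 1.2), Gaussian AR processes as the linear
null at the breath-count scale of a recording (n = 250 ≈ a 13-minute
recording at rest), sinusoidal flow at 400 Hz for segmentation, CPG-driven
breath series, and smooth AR(1) covariate channels around physiological set
points (RVT 7 L/min, RR 0.9 s, end-tidal CO2 40 mmHg, saturation 97.5%).
All stochastic generators require seeds and are reproducible.

## Known limitations

* Breath-indexed series derived from the CPG (`gen_model_breaths`) are
  *not* detectably nonlinear: with per-step exponents of 0.16–0.59 and
  cycles of 150–300 steps, successive bursts are separated by ~50–100
  Lyapunov times, so every per-burst observable is fully mixed and titration
  correctly reports NL = 0.  Chaos in the model is certified on the
  step-resolved membrane series instead.  Real breathing keeps
  breath-to-breath memory because its dynamical timescale is commensurate
  with the breath; the map's is not — passing tests on model breath series
  therefore say nothing about real airflow, which is why the titration
  operators are validated on logistic/AR series at matched length.
* The regime presets are one realized coupling; the handshake labels are
  robust across seeds for the shipped values but not across arbitrary
  couplings.
* The tonic control differs from the bursting presets in β, not J: under
  the fixed printed constants the entire oscillatory J-window is chaotic.
* Simulated AlFO normalization uses the two simulated channels as the
  global reference (the natural choice with two regions); supplied ROI data
  can use any external reference.
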