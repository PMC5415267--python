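# Methods

## Model

Each of M populations consists of N homogeneous generalized
integrate-and-fire (GIF) neurons with escape noise. The membrane
potential obeys

    tau_m du/dt = -u + mu(t) + R I_syn(t),      mu(t) = u_rest + RI_ext(t),

is reset to u_r after a spike and clamped there for an absolute
refractory period t_ref. Each spike also adds a kernel
theta(t) = sum_l (J_l/tau_l) e^{-t/tau_l} (for t >= t_ref; infinite
inside the dead time) to a dynamic threshold, producing spike-frequency
adaptation when J_l > 0 and facilitation when J_l < 0. Spikes are
emitted stochastically with conditional intensity ("escape rate")

    lambda(t) = c exp[(u(t) - theta_total(t)) / delta_u].

A GLM (spike-response) variant replaces the reset by an additive
spike-after-potential kernel eta(t) on the membrane potential; with
eta = (u_r - u_th) e^{-(t - t_ref)/tau_m} it approximates the GIF
variant at low rates (the mapping is not exact because the GLM does not
pin the potential to a fixed value at the spike).

Synapses are current-based exponential kernels with delay:
eps(s) = Theta(s - Delta) e^{-(s - Delta)/tau_s}/tau_s. Connectivity is
random with fixed in-degree: every neuron receives exactly
round(p[a, b] N[b]) synapses from population b, sampled without
replacement and without self-connections. The one exception is full
connectivity (p = 1), where the in-degree equals N and the
self-connection is included: this is exactly the configuration assumed
by the mean-field description, which becomes exact in that limit.

## Three levels of simulation

**Microscopic** (`run_micro`): every neuron individually. One Bernoulli
draw per active neuron per step.

**Survival-number process** (`run_density_micro`): for a single
population, the distribution m(t_l, t_k) of last spike times is tracked
exactly; each occupied bin loses a Binomial(m, P) number of neurons per
step. The neuron count sum_k m(t_l, t_k) = N is conserved exactly
(integer bookkeeping); this is asserted at every step. This process is
the stochastic system whose moment closure gives the mesoscopic
equations, and serves as an exact reference for renewal statistics.

**Mesoscopic** (`run_meso`): per population, a finite history of K
last-spike bins carries the expected survival numbers m_k, their
variances v_k, the per-bin membrane potentials u_k and hazards
lambda_k; neurons whose last spike is older than T = K dt form a lumped
"free" pool with expected size x and summed variance z. Each step:

1. Exact one-step integration of the coupled (h, y) input system under
   piecewise-constant inputs (closed-form exponential propagator,
   including the tau_s = tau_m degenerate limit).
2. Free-neuron threshold from exponential adaptation variables g_l
   driven by the activity leaving the explicit history.
3. One O(K) sweep accumulates the quasi-renewal threshold
   theta_tilde(t) = delta_u (1 - e^{-theta(t)/delta_u}) of all older
   cohorts into each bin's effective threshold, evaluated directly at
   the advanced time t_{l+1}; hazards at t_l are reused from the
   previous step, giving trapezoidal averages and per-bin firing
   probabilities P_k = 1 - exp(-lambda_bar dt).
4. Effective firing probability P_Lambda = (sum_k P_k v_k + P_free z) /
   (sum_k v_k + z): a variance-weighted average that assigns the
   normalization deficit of the pseudo-density (the "holes and
   overshoots" left behind by past fluctuations) the hazard of the bins
   where those deviations live.
5. Expected count nbar = sum_k P_k m_k + P_free x +
   P_Lambda (N - sum_k m_k - x), clipped to [0, N].
6. One random draw per population: Delta_n ~ Binomial(N, nbar/N) by
   default (Poisson truncated at N, Gaussian, and deterministic
   Delta_n = nbar are provided as alternatives).
7. Moment updates m_k <- (1 - P_k) m_k, v_k <- (1 - P_k)^2 v_k +
   P_k m_k, absorption of the oldest bin into (x, z), and boundary
   conditions m = Delta_n, v = 0, u = u_r for the newest bin.

All three levels share the same elementary numerics (exponential
propagators, trapezoidal hazard average, identical refractory-age
conventions), so cross-level comparisons isolate the population-level
approximations.

## Parameters and defaults

Single-neuron defaults are tau_m = 20 ms, t_ref = 4 ms, u_th = 15 mV,
u_r = 0 mV, c = 10 Hz, delta_u = 2 mV, delay 1 ms, tau_s = 3 ms
(excitatory) / 6 ms (inhibitory). The eight-population cortical-column
preset uses tau_m = 10 ms, t_ref = 2 ms, delta_u = 5 mV (standing in
for the external Poisson noise of the original model), tau_s = 0.5 ms
and delay 1.5 ms uniformly, with its published sizes, connection
probabilities, weights (0.176 / -0.702 mV; the L4e -> L2/3e projection
carries 0.351 mV) and fitted resting potentials.

The history length T is chosen per population ("auto") as the smallest
grid-aligned T with T >= 5 max(t_ref, tau_m) and kernel envelope
sum_l |J_l/tau_l| e^{-T/tau_l} <= 0.01 delta_u, so that beyond T the
quasi-renewal kernel is indistinguishable from the raw kernel. Both the
multiplier and tolerance are exposed.

Time steps must satisfy dt <= t_ref (at most one spike per neuron per
bin) and dt <= min delay (hard errors otherwise); the accuracy
condition of the trapezoidal hazard average can additionally be checked
on a probe trajectory (`validate_dt`), emitting a warning when
((d(u - theta)/dt)^2 + delta_u |d^2(u - theta)/dt^2|) dt^2 exceeds 10%
of 12 delta_u^2.

## Numerical choices

- The escape-rate exponent is clamped at +20 before exponentiation;
  firing probabilities saturate through 1 - exp(-lambda dt) long before
  the clamp matters.
- Absolute refractoriness is a case split (lambda = 0 for ages
  <= round(t_ref/dt)), not an infinite threshold value.
- The cohort whose dead time expires during the current step fires with
  the half-trapezoid probability 1 - exp(-lambda(t_{l+1}) dt/2); the
  closed-form dead-time-Poisson reference uses the same convention, and
  with it the general integrator reproduces that exact special case to
  machine precision.
- Bins whose survival mean and variance have both decayed below
  1e-15 N skip the hazard evaluation; contributions at that level are
  below every tolerance used anywhere in the package.
- When all variances vanish (e.g. immediately after the synchronized
  start), P_Lambda falls back to P_free, the N -> infinity consistent
  choice; the correction term multiplies a vanishing bracket there.
- Delays and t_ref are rounded to grid multiples with a warning.
- Initialization synchronizes all neurons at t = -dt. For stationary
  statistics a deterministic warm-up (Delta_n = nbar fed back without
  sampling, `burn_in_deterministic`) relaxes this transient before
  stochastic sampling starts; analyses additionally discard an initial
  stretch of the sampled trace.

Renewal theory (`renewal_theory`, `renewal_spectrum`) integrates the
hazard on a grid aligned to t_ref with all quadrature restricted to the
ISI support [t_ref, inf) — the dead-time part is handled in closed
form, so the hazard discontinuity costs no accuracy — and appends an
analytic exponential tail where the hazard has reached its asymptote.
The spectrum is evaluated through the deficit D(f) = 1 - P_isi~(f)
computed directly from integral of p(t)(1 - e^{2 pi i f t}) dt, which
avoids the catastrophic cancellation of the textbook form at low
frequencies; the grid is refined to at least 50 points per period of
the highest requested frequency.

The empirical spectrum estimator uses non-overlapping rectangular
segments with per-segment mean removal, normalized so that a Poisson
population of rate r gives the flat density r/N. Segment length
matters: near the deep low-frequency dip of strongly refractory
populations, 1 s segments leak power from the spectral peak into the
dip (tens of percent there); 20 s segments make leakage negligible and
are used for all quantitative comparisons.

## Accuracy of the mesoscopic closure

The variance-weighted effective rate is a closure, not an identity.
Its accuracy was probed against exact references:

- Dead-time Poisson population (no reset): the reduction is exact;
  verified to ~1e-15 relative per step, and the sampled spectrum
  matches renewal theory within estimator noise in every band.
- Survival-number process for reset (LIF) neurons: matches renewal
  theory in every frequency band within noise (it is exact for renewal
  dynamics).
- Mesoscopic LIF population in the strongly refractory regime
  (mu = 30 mV, rate ~37 Hz): band-wise deviations of the sampled
  spectrum from renewal theory of order 10-15% appear in the
  low-frequency dip (excess below ~20 Hz, deficit around 20-100 Hz),
  while the spectrum above ~100 Hz is accurate to a few percent. These
  deviations are a property of the moment closure at finite N, not of
  the implementation: the same code is exact in the special case, and
  the deterministic path agrees with an independent brute-force
  reference integrator to ~1e-9.

## Fixed-in-degree corner case

At p = 1 a fixed in-degree of p N cannot be realized without either a
self-connection or dropping one partner. The self-connection is used
(see Model above); for p < 1 autapses and multapses are excluded.

## Choices for the reported experiments

- Cortical-column rates: dt = 0.5 ms; 24 s stationary average after a
  2 s burn-in (no adaptation), and a 12 s burn-in covering the
  tau_theta = 1 s adaptation transient followed by a 22 s average
  (with adaptation). Statistical error of the averages is well below
  1% of the target rates.
- Renewal-spectrum comparison: 2400 s of stationary data in 120
  segments of 20 s; the mean relative error metric over 1-500 Hz then
  carries an estimator noise floor of ~7%.
- Micro-meso comparison (E-I network, C = N = 50): 200 s per level.
  Band power is averaged per 1 s segment first and the Monte-Carlo
  error taken across segments — the network's slow amplitude modulation
  correlates periodogram ordinates within a segment, so the naive
  "independent ordinates" error bar would be several-fold too small.
  Agreement is judged by overlapping simultaneous 95% bands
  (Bonferroni-corrected across the ~21 log-spaced bands).  The residual
  systematic deviation of the mesoscopic spectrum from the microscopic
  one is about -5 to -8% on the falling flank of the finite-size
  resonance (45-140 Hz here) and a few percent elsewhere, consistent
  with the closure accuracy measured against renewal theory; part of
  the high-frequency excess shrinks with dt (one-draw binomial sampling
  versus heterogeneous per-neuron Bernoulli draws during synchronized
  volleys).
- 1/N scaling: measured in the 200-500 Hz band, away from the
  finite-size resonance of the E-I loop. Near the resonance the
  response to sampling noise is weakly nonlinear at small N and the
  apparent exponent is steeper than 1; in the renewal-dominated band
  the exponent is clean (measured slope -1.01 across N = 50-800).
- Bistable switching: dt = 0.5 ms (coarser than the 0.2 ms used for the
  other small networks; the adapting condition carries a ~1.4 s
  explicit history and dominates the cost), 900 s (no adaptation) and
  420 s (adaptation) of simulated time, giving > 50 completed dominance
  periods per condition.

## Winner-take-all wiring

The bistable preset's architecture is: each excitatory population
excites itself and the shared inhibitory population; the inhibitory
population inhibits both excitatory populations and itself; there is no
direct coupling between the two excitatory populations. With the
published weights this yields bistable winner-take-all dynamics whose
switching is purely noise-driven (dominance-time CV ~ 1 without
adaptation) and becomes markedly more regular with weak slow adaptation
— the qualitative signature the configuration is meant to reproduce.

## What the synthetic fixtures do and do not cover

`fixture_generator` produces Poisson count traces (estimator
normalization), square waves and telegraph processes (switching
detection) with exactly known statistics. They validate the analysis
machinery in isolation; they do not emulate refractory or adaptive
structure, which is exercised by the simulators themselves.

## Known limitations

- The quasi-renewal approximation assumes slow threshold kernels;
  bursty (biphasic, fast) kernels are reproduced only qualitatively,
  with the population variance overestimated.
- The mean-field input approximation requires dense connectivity; for
  small p and small N jointly the description degrades.
- Conductance-based synapses, short-term plasticity and spatial
  continuum extensions are out of scope.
- The closure's spectral accuracy in strongly refractory regimes is
  ~10-15% in the low-frequency dip (see above).
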