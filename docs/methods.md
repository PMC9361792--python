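# Methods

## The LP-like neuron model

The conductance-based model is a two-compartment caricature of the lateral
pyloric (LP) neuron of the crustacean stomatogastric ganglion: a
soma/neurite compartment that produces slow-wave depolarizations and a
coupled axon compartment that produces spikes, which appear at the soma as
small spikelets. Membrane currents follow the Hodgkin–Huxley form
*I* = ḡ·*m*^p·*h*^q·(*V*−*E*), with first-order gating
d*z*/d*t* = (*z*∞−*z*)/τ_z. The soma carries leak (*E* = −50 mV), the
transient potassium current *I*_A (*m*²*h*, *E* = −80 mV), a
Goldman–Hodgkin–Katz calcium current (*m*³*h*, calcium-dependent
inactivation), the calcium-activated potassium current *I*_K(Ca)
(*mh*, *E* = −80 mV, Hill-type calcium activation with half-saturation
1.43 µM), the hyperpolarization-activated current *I*_h (*m*, *E* = −20 mV)
and the modulator-activated current *I*_MI (*m*, *E* = −10 mV, activation
midpoint −48 mV). The axon carries leak (−55 mV), *I*_Na (*m*³*h*, +70 mV)
and the delayed rectifier (*m*⁴, −80 mV).

The calcium current uses the GHK flux form
*I*_Ca = *P*·*m*³*h*·ζ·([Ca]ₒe^(−ζ)−[Ca]ᵢ)/(e^(−ζ)−1) with
ζ = *z*F*V*/RT at 283.15 K ([Ca]ₒ = 13 mM); the *V* = 0 singularity is
removable and evaluated by series expansion below |ζ| < 10⁻⁴. The scaled
permeability *P* absorbs the physical prefactors so the current comes out
in nA. Intracellular calcium relaxes to 0.02 mM with τ = 25 ms and is
driven by the calcium current through a lumped flux factor (mM·ms⁻¹·nA⁻¹)
that stands in for the per-cluster permeability, valence, Faraday constant
and microdomain volume of the full bookkeeping.

**Units.** mV, ms, nA, µS, nF, mM throughout, so τ = C/g is in ms and
I = g·(V−E) in nA.

### Gating transcription

The gating midpoints, slopes and time-constant coefficients live in a
single table, `modvar/gates.py`, which both the compiled kernel and the
test suite read. Several cells of the source gating table reached us only
as flattened stacked fractions; `gates.py` documents every interpretive
choice. The consequential ones:

* *I*_h activation opens with hyperpolarization (midpoint −70 mV, slope
  −3 mV); the sign is required for the sag and rebound to exist.
* The axonal *I*_Na activation cell admits several readings; midpoint
  −22 mV with slope 8 mV was chosen because, of the plausible readings, it
  is the one at which the axon sustains tonic spiking across the whole
  conductance range the families sample instead of entering depolarization
  block at moderate drive, and the somatic rebound plateau is
  suprathreshold.
* Calcium-dependent gate scales were adjusted to dynamically meaningful
  values (0.5 mM for *I*_Ca inactivation, 0.03 mM for *I*_K(Ca)
  inactivation); the literal printed scales would pin those gates at zero
  with [Ca] in mM.

### Parameters not fixed by the model description

Capacitances (soma 1 nF, axon 0.5 nF), the axial coupling conductance
(0.3 µS), the calcium flux factor (0.015 mM ms⁻¹ nA⁻¹) and the reference
maximal conductances (`LPParameters` defaults) were hand-tuned, once, to a
reference phenotype: rest near −49 mV and silent at the low baseline
ḡ_MI = 0.02 µS; a slow depolarizing sag during a −5 nA step (h-current);
a rebound burst with first-spike latency inside (0.1, 1.5) s that tapers
within the 10 s post-release window; a monotone f–I curve with rheobase
1–2 nA; tonic firing when ḡ_MI is raised above ≈0.1 µS. These five
behaviors, not any numeric target, were the tuning criteria.

### Integration

Exponential Euler for the eleven gating variables and for calcium (both
exactly linear given the instantaneous voltage), semi-implicit Euler for
the two voltages, default dt = 0.05 ms (admissible range (0, 0.1] ms).
The scheme is unconditionally stable for the gates and preserves [0, 1];
the guard on accuracy is behavioral: halving dt changes the spike count of
a reference step response by ≤ 1 spike and the first-spike latency by
< 1 ms (asserted in the suite). Blow-up (|V| > 200 mV) raises an error
naming the failure time. Calcium is floored at 10⁻⁹ mM as a numerical
safety net. The kernel is numba-compiled; a 160 s protocol integrates in
roughly one second.

## Protocols

* **f–I, experimental layout**: 5 s steps, 0 → 5 nA in 0.5 nA increments,
  then the descending limb; the 5 nA apex is not repeated by default
  (configurable), giving 21 steps. No inter-step rest by default.
* **f–I, model layout**: 32 ascending 5 s steps, −10 → 5.5 nA; the wide
  subthreshold range stabilizes the threshold parameter of the power fit.
* **Rebound (DC)**: −5 nA for 10 s, 10 s release, five sweeps.
* **Rebound (periodic)**: twenty −5 nA pulses, 1 s on / 1 s off; only the
  last ten pulses are analyzed (steady state).

Waveforms are explicit segment programs with epoch labels that tile the
waveform exactly; they serialize to CSV round-trip.

## Analysis definitions

* **Spike detection**: upward crossing of −20 mV with a 2 ms refractory
  gap (defaults; recorded in outputs). Model analyses detect on the axon
  voltage.
* **Per-step frequency**: mean of reciprocal interspike intervals inside
  the step; fewer than two spikes counts as 0 Hz, so subthreshold steps
  enter f–I fits as zeros. All ISIs in the step are used (no adaptation
  window).
* **Rebound latency**: time from release of hyperpolarization to the first
  spike inside the analysis window (10 s for DC rebound, 1 s for periodic);
  no spike is recorded as missing, and such sweeps are excluded listwise
  from group statistics with counts reported.
* **Cumulative spike histogram**: release-aligned pooled histogram (200 ms
  bins for DC rebound, 100 ms for periodic); its running sum ends exactly
  at the total spike count. For fitting, the pooled cumulative is divided
  by the number of sweeps, so the sigmoid plateau *a* is spikes per sweep.
* **Latency time constant (periodic rebound)**: the 1-based pulse index at
  which latency first drops to 63% of its total drop; zero drop maps to
  pulse 1 by convention.
* **Hysteresis**: mean in-band (2–4 nA inclusive) frequency of the
  ascending limb divided by that of the descending limb; a zero descending
  mean makes the ratio undefined (missing), a zero ascending mean gives 0.

## Curve fits

All fits are bounded least squares (scipy) from five seeded starts,
tolerance 10⁻¹⁰, invariant to point order; ties break to the lowest
residual, then the lowest exponent. Degenerate inputs (constant y, too few
points) raise a typed fit failure rather than returning garbage.

* **Power law** *f* = *a*(*I*−*I*₀)^*b*, 0 ≤ *b* ≤ 1, model value 0 below
  *I*₀. By default only suprathreshold points enter the residual and *I*₀
  is a free parameter initialized at the largest silent current and bounded
  above by the first spiking current. Two variants are available:
  `include_zero` adds the silent steps to the residual, and `fix_i0` pins
  *I*₀ at the largest silent current and fits only (*a*, *b*). The pinned
  variant is used for the LIF family, where the analytic curve makes the
  threshold directly observable — treating *I*₀ as measured rather than
  extrapolated removes an *I*₀/*b* trade-off that otherwise inflates the
  apparent spread of both parameters. LP-model family fits keep the free
  default.
* **Sigmoid** *f*(*x*) = *a*/(1+exp(−(*x*−*x*₁/₂)/*k*)), rising with *x*
  for *k* > 0. Synaptic I–V mode applies lower bounds *a* ≥ −10 nA,
  *x*₁/₂ ≥ −80 mV with the slope sign free; cumulative-time mode
  constrains *a* ≥ 0, *x*₁/₂ ≥ 0, *k* > 0 so the reported slope factor is
  positive.
* **Modulator I–V** *f*(*V*) = *a*(*V*−*b*)/(1+exp(−(*V*−*V*₁/₂)/*k*)),
  bounds 0 ≤ *a*, 0 ≤ *b* ≤ 40 mV, −40 ≤ *V*₁/₂ ≤ 0 mV,
  0.1 ≤ *k* ≤ 20 mV; with these bounds the curve is ≈0 at −80 mV, crosses
  zero at the reversal *b*, and its minimum over the sampled span is the
  peak inward current. A fit pinned at an all-bounds corner is flagged,
  not raised. Only the descending ramp limb is fitted (the ascending limb
  recruits a transient component that is out of scope).

## Variability statistics

Ratio-scale parameters use the sample-size-adjusted coefficient of
variation CV = (SD/|mean|)·(1+1/4*n*) — the standard small-sample
unbiasing, isolated in one function so an alternative correction can be
swapped. Interval-scale parameters (and rebound latency, whose zero point
is set by the protocol) use the SD. Bounded variables are transformed
before normality-based testing: base-10 logarithm for positive bounded
quantities, arctan(π·x) for quantities bounded in [0, 1]; both are
monotone and invertible, so rank-based results are unchanged.

Condition comparisons are gated exactly: one-way ANOVA when every group
passes Shapiro–Wilk and the groups pass Levene's test (centered on the
mean), otherwise Kruskal–Wallis rank ANOVA; post hoc pairs use Tukey's HSD
in the first branch and Dunn's rank test (Bonferroni-adjusted) in the
second, which is hand-implemented because no installed library provides
it. Reports carry which branch fired, group n's, and means (ANOVA) or
medians (ranks); α = 0.05; all tests are unpaired. A table with no
variance anywhere returns a null comparison (p = 1) rather than an error.

## Families and modulation sweeps

Families are generated by seeded rejection sampling — a deliberately
transparent, dependency-light stand-in for posterior-based inference: draw
parameter vectors uniformly from a prior (default [0.25×, 4×] of the
reference set), simulate the relevant protocol, keep members that satisfy
the selection criteria. Rebound families sample the six somatic parameters
(leak, ḡ_A, ḡ_h, ḡ_KCa, ḡ_MI, P_Ca) and keep members whose rebound latency
lies in (0.1, 1.5) s with a fittable histogram. f–I families additionally
sample the axonal conductances and the *I*_Na inactivation time-constant
scale, and keep members whose power-fit scale is *a* ≥ 6 and which avoid
depolarization block both at baseline and at the largest tested ḡ_MI
increment. Optional windows (target ± tolerance per summary statistic) can
further constrain acceptance. Acceptance is idempotent: re-filtering an
accepted family changes nothing, which the suite checks by re-simulation.

Depolarization block is defined operationally: the mean voltage over the
final half of a suprathreshold epoch exceeds the spike-detection threshold
while that half contains no spikes.

Modulation is applied either as a fixed increment Δḡ_MI added to every
member or as per-member increments drawn from Normal(mean, σ²), truncated
so total ḡ_MI stays non-negative; increments are recorded. The sweep
re-simulates every member at every level and reports per-level means, SDs
and adjusted CVs of the output parameters, with per-level exclusion counts
(no rebound spike, depolarization block, integration failure); exceeding
50% exclusions raises a warning.

Because the model is deterministic, the rebound protocol in family runs
uses two cycles — one to condition the slow states, one analyzed — rather
than five identical sweeps.

## The LIF family

The LIF neuron (C_m = 100 nF, E_leak = −60 mV, E_MI = +10 mV,
v_th = −40 mV, v_reset = −80 mV) has the closed-form rate
*f* = 1/(τ_m ln[(v_ss−v_reset)/(v_ss−v_th)]), τ_m = C_m/(g_leak+g_MI-L),
v_ss the conductance-weighted equilibrium. The family experiment samples
g_leak ~ Uniform[0.05, 0.2) µS once (fixed seed) and evaluates the
analytic rate on the −50…100 nA grid (1 nA steps — the grid step is a
package choice; only the range is inherited) at g_MI-L ∈ {0, 0.2, 0.36} µS.
Rates above 20 Hz are dropped (not clipped) before fitting so every
condition is fitted over the same frequency range, and the threshold-pinned
power fit is used (see above). A brute-force Euler threshold/reset
integration at dt = 0.01 ms is kept as an independent oracle and agrees
with the closed form to < 0.5% relative.

## Synthetic data generators

Every pipeline input has a seeded generator with the ground truth embedded
in its returned metadata: power-law f–I observations with optional
hysteresis factor and Gaussian frequency noise; rebound sweeps drawn by
inverse-transform sampling from the logistic density truncated to
[latency, horizon] with Poisson per-sweep counts (so the expected
cumulative histogram follows the sigmoid and no spike precedes the
latency); voltage-clamp step families with specified transient/persistent
amplitudes and inactivation kinetics, a slow h-current relaxation, a
logistic synaptic I–V, and a triangular ramp pair whose difference is the
modulator I–V curve; and per-animal × condition tables of independent
normal draws. These generators emulate the *statistical* structure the
analyses assume — not electrode artifacts, channel noise, bursting
ultrastructure or correlated conductance expression — so closed-loop
recoveries certify the analysis chain, not realism of the noise model.

## Problem sizes

The default suite and the acceptance script run at reduced scale, chosen
as the smallest sizes at which the qualitative family phenomena are stable
run-to-run: model families of n = 30 members (sampling budgets 200–250),
five fixed rebound increments (0–0.1 µS), four f–I increments (0–0.2 µS),
one distributed-increment condition (mean 0.025 µS, σ² = 0.1 µS²), and an
LIF family of n = 500. Full-scale runs (larger families, denser level
grids) go through the CLI and `RunConfig`.

## Known limitations

* The gating-table transcription is best-effort; cells listed in
  `gates.py` are interpretive. The reference phenotype, not the exact
  published trajectories, is the calibration target.
* In the rebound families the modulator robustly compresses
  across-member variability: the CVs of latency and of all three
  cumulative-histogram parameters fall monotonically with fixed Δḡ_MI,
  and variable increments at the same mean raise variability again. In
  the f–I families the same manipulation reproduces the mean effects
  (leftward *I*₀ shift, shallower exponent) but compresses parameter
  spread only weakly or not at all: CV(*a*) stays flat-to-rising, and the
  spread of *b* falls only under the threshold-pinned fit convention. The
  *a*-spread in these families is dominated by the sampled axonal
  conductances, which the somatic modulator conductance cannot reach, and
  the sampled axon stays clear of depolarization block over the tested
  range, removing a shared firing-rate ceiling that would otherwise pull
  members together.
* Family priors are uniform and independent per parameter; correlated
  conductance expression is not modeled.
* The condition-table pipeline assumes unpaired, independent draws per
  condition; the generator's optional per-row random effect for paired
  designs is not exposed in the analysis.
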