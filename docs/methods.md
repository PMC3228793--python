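# Methods

## Model and assumptions

The synapse is the phenomenological Tsodyks–Markram (TM) two-variable
model.  A fraction `x ∈ [0,1]` of neurotransmitter resources is available;
`u ∈ [0,1]` is the occupancy of the release machinery's Ca²⁺ sensors.
Between spikes both relax exponentially (`x` toward 1 at `Ω_d`, `u` toward
0 at `Ω_f`); a spike first increments utilization, `u⁺ = u + U₀(1−u)`, then
releases `RR = u⁺x` and depletes `x → x(1−u⁺)`.  The jump ordering —
facilitation before release — is a modelling commitment, pinned by the
requirement that a single spike from rest release exactly `U₀` and that the
200-Hz facilitation-then-depression protocol with
`(Ω_d, Ω_f, U₀) = (10 s⁻¹, 1.25 s⁻¹, 0.1)` peak at `RR = 0.2` on the third
spike; the alternative ordering (release with the pre-increment `u`)
reproduces neither.  Simultaneous spike and gliotransmitter events are
resolved deterministically with the gliotransmitter update first, treating
receptor modulation as fast relative to release.

Both between-spike flows are linear, so the simulator is event-driven and
exact: state is only touched at events, with closed-form exponentials in
between.  `ode_oracle` provides an independent brute-force check
(fixed-step RK4 by default, Euler for convergence-order demonstrations);
the two agree to `|ΔRR| ≤ 10⁻⁶` at RK4 step 10⁻³ s, and far better in
practice (~10⁻¹¹ measured).

The astrocyte mirrors this description: an available gliotransmitter
fraction `x_A` recovering at `Ω_A`, a constant released fraction `U_A` per
gliotransmitter release event (GRE), an extracellular glutamate increment
`g_scale · U_A · x_A` (with `g_scale` the lumped product
ρ_A·n_v·G_v ≈ 130 µM) cleared monoexponentially at `Ω_c`, and presynaptic
receptor activation `dΓ/dt = O_G·G_A·(1−Γ) − Ω_G·Γ`.  The basal release
probability is the first-order law `U₀(Γ) = U₀*(1−Γ) + αΓ`; `α` lumps the
receptor type (α < U₀* release-decreasing, α > U₀* release-increasing,
α = U₀* silent).  Homosynaptic feedback (the synapse's own glutamate
driving the astrocyte) is deliberately out of scope: the astrocyte is an
exogenous modulator, as in the heterosynaptic experimental configuration.

## Numerical scheme for receptor activation

Clearance is three to four orders of magnitude faster than receptor
unbinding (`Ω_c ≈ 60 s⁻¹` vs `Ω_G ≈ 1/60 s⁻¹`), so by default each
glutamate pulse is collapsed to an impulse on Γ:

    Γ → Γ + (1 − Γ)(1 − exp(−O_G·ΔG/Ω_c)),

obtained by integrating the Γ equation across the pulse with unbinding
frozen; between events Γ decays as `exp(−Ω_G·dt)`.  The relative error of
the impulse approximation is O(Ω_G/Ω_c) (~3·10⁻⁴ at default rates).  An
exact mode (`scheme="exact"`, stiff Radau integration of the driven ODE at
rtol 10⁻¹⁰) backs every approximation claim in the test suite; the
saw-tooth trajectories agree within 1% of the Γ peak whenever
`Ω_c/Ω_G ≥ 10³`.

## Steady-state theory

Averaging over stationary drive at rate `f` gives
`⟨u⟩ = U₀f/(Ω_f + U₀f)` (exact: the `u` equation is linear),
`u⁺ = ⟨u⟩ + U₀(1−⟨u⟩)`, `⟨x⟩ = Ω_d/(Ω_d + f·u⁺)` and
`RR_ss = u⁺⟨x⟩`.  The single approximation is the moment closure
`⟨u⁺x⟩ ≈ ⟨u⁺⟩⟨x⟩`.  Against long Poisson-driven simulations over the
parameter domain used throughout (Ω_d ∈ [1,10] s⁻¹, Ω_f = 2.5 s⁻¹,
U₀ ∈ [0.05,0.9]) the closure error stays below the 10% validity bound and
peaks near 4–6 Hz (12% allowance there); a measured sweep put the worst
case near 4.5% at 5 Hz.  Note the bound is about *trial-averaged
stochastic* drive: strictly periodic drive adds a separate O(f/Ω)
discretization bias, so the validity tests use Poisson trains.

Closed forms derived from RR_ss (each verified against a numerical
oracle in the tests):

* switching threshold `U_thr = Ω_d/(Ω_d + Ω_f)` (sign change of the
  low-frequency slope);
* facilitating limiting frequency: positive root of
  `U₀f² + 2U₀Ω_f f − Ω_f(Ω_d − U₀(Ω_d+Ω_f)) = 0` (the argmax of RR_ss);
* depressing limiting frequency: the curve is monotone, so the cut-off is
  defined **operationally** as the half-power point `RR_ss(f) = U₀/√2`
  (positive root of the corresponding quadratic).  This is a package
  definition, flagged as `cutoff_rule="half_power"` in every regime
  report; any alternative cut-off convention rescales the depressing
  branch but preserves the branch discontinuity at `U_thr`.

For periodic GREs at rate `f_C`, the astrocytic variables reach a periodic
orbit with exact per-event fixed points: pre-GRE pool
`x* = (1−e_A)/(1−(1−U_A)e_A)` with `e_A = exp(−Ω_A/f_C)`, pulse
`ΔG = β·x*` (β = U_A·g_scale, the lumped releasable glutamate), jump
survival `ε = exp(−O_G·ΔG/Ω_c)`, peak `Γ_p = (1−ε)/(1−ε·e_G)` with
`e_G = exp(−Ω_G/f_C)`, and saw-tooth average
`⟨Γ⟩ = Γ_p(1−e_G)f_C/Ω_G`.  Then `⟨U₀⟩(f_C) = U₀*(1−⟨Γ⟩) + α⟨Γ⟩`.  The
exact periodic average was chosen over a naive continuous-flux mean field
because the per-GRE receptor jump is not small (O_G·ΔG/Ω_c ≈ 0.5–1 at
default parameters); the event-driven simulator averaged over one GRE
period is the release-blocking oracle and agrees to ~10⁻⁴ relative.
`⟨U₀⟩` is continuous and monotone from `U₀*` (f_C → 0) toward the
asymptote `U₀* + (α−U₀*)·ξ/(ξ+Ω_G)` with `ξ = O_G·g_scale·Ω_A/Ω_c`; at
default rates ξ/(ξ+Ω_G) ≈ 0.987, so the high-rate limit is `α` to within
~1.3% — reaching `α` exactly requires the stated scale separation
`ξ ≫ Ω_G`.  The threshold GRE frequency `f_thr` solves
`⟨U₀⟩(f_C) = U_thr` by bisection on log f_C (residual ≤ 10⁻¹⁰); it exists
iff `U_thr` lies strictly between the two ends of the curve, and the
absence of a crossing is returned as an explicit `None`, not an exception.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| Ω_d | resource recovery rate | per experiment | s⁻¹ |
| Ω_f | utilization decay rate | per experiment | s⁻¹ |
| U₀* | basal release probability | per experiment | — |
| U_A | released astro fraction per GRE | 0.5 | — |
| Ω_A | astro pool recovery | 0.6 | s⁻¹ |
| g_scale | glutamate per unit released fraction (ρ_A·n_v·G_v) | 130 | µM |
| Ω_c | extracellular clearance | 60 | s⁻¹ |
| O_G | receptor binding rate | 1 | µM⁻¹s⁻¹ |
| Ω_G | receptor-effect decay | 1/60 (printed as 1 min⁻¹) | s⁻¹ |
| α | effect parameter | per experiment | — |
| C_thr | Ca²⁺ exocytosis threshold | 0.5 | normalized Ca |

The gliotransmission defaults are the published hippocampal set
(Ω_c, O_G, g_scale, U_A); Ω_G uses the minute-scale receptor decay printed
with the main coupled protocols.  Ω_A is not printed anywhere in the
available sources; 0.6 s⁻¹ (pool recovery over ~2 s, comfortably faster
than minute-scale Ca²⁺ oscillations yet slow enough to show depletion at
high GRE rates) is this package's choice and can be overridden in any
config.  All internal state is in seconds, s⁻¹ and µM; the config layer
accepts `omega_g_per_min` and converts at the boundary.  Synapse initial
conditions default to rest (u=0, x=1) and are exposed because transient
responses depend on them.

## Stimulus generators and what they emulate

Poisson trains (exponential inter-arrivals, mandatory integer seed, KS-
tested against the exponential law) stand in for irregular cortical input;
the ensemble protocols default to the printed drive of 1.5 Hz and n = 100
trials.  The Ca²⁺ trace generators are *stereotypes*, not biophysics: a
raised-cosine oscillator whose amplitude (AM), frequency (FM) or both
(AFM) follow a linear modulation law, standing in for IP₃-driven
limit-cycle dynamics.  Exact waveform shape is irrelevant downstream —
only the threshold-crossing times matter, extracted with rising-edge
semantics and linear interpolation (a plateau above threshold triggers at
most once).  Consequently, passing tests demonstrate the event-level logic
(GRE timing → receptor activation → release modulation), not any claim
about real Ca²⁺ waveforms, stochastic Ca²⁺ dynamics, spatial waves, or
transporter saturation (clearance is a single exponential by design).

## Paired-pulse classification

For every consecutive spike pair, PPR = RR₂/RR₁; PPR < 1 is PPD, PPR > 1
with Δu ≥ 0 is PPF, and PPR > 1 with Δu < 0 (necessarily Δx > 0) is
recovery from depression — a resource-driven, not Ca²⁺-driven, increase.
Edge conventions are package choices: exact ties default to PPD
(conservative against the headline astrocyte-induced-PPF effect) and
RR₁ = 0 pairs are excluded and counted separately.  The headline PPF/PPD
ratio excludes recovery pairs by default (`include_recovery_as_ppf`
folds them in).  Summaries report both the mean ± SD of per-trial ratios
(trials with zero PPD pairs are skipped for that statistic and counted)
and the pooled-count ratio, which is what the directional tests compare.

## Problem sizes

Deterministic anchors use 4000-point log-frequency grids and trains of
15–30 spikes.  Oracle equivalence uses 100 random 50-spike trains; the
mean-field validity sweep uses 20 random parameter sets × 8 frequencies ×
80 000 Poisson spikes (Monte-Carlo SE ≈ 0.4%, far inside the 10% band);
ensemble protocols use n = 100 trials of 60–120 s at 1.5 Hz.  These sizes
were chosen so every statistical conclusion has comfortable margin while
the whole suite runs in well under a minute per heavy test.

## Known limitations

* No postsynaptic model: RR is the output quantity; no currents, quantal
  noise or axonal delays.
* The depressing-branch cut-off is an operational definition (see above).
* The mean-field frequency response describes trial-averaged stochastic
  drive; applying it to strictly periodic drive incurs an extra
  discretization bias at intermediate frequencies.
* The gliotransmission steady state assumes strictly periodic GREs;
  irregular GRE trains are simulated, not covered by the closed form.
* Γ is driven only by astrocyte-derived glutamate; synaptically released
  glutamate does not activate the presynaptic receptors in this model.
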