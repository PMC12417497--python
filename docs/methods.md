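# Methods

This note documents the model equations, parameter choices, numerical
schemes and known limitations of `spindlearm`. Everything stated here is
computed by the package itself (the test suite and
`scripts/acceptance.py`); no external data enter the simulation — all
inputs are configuration.

## Arm mechanics

The arm is a planar double pendulum in the vertical XZ-plane. Generalized
coordinates are the shoulder angle ψ (from the downward vertical, positive
toward +X) and the interior elbow angle φ (π = fully extended). The
absolute forearm angle is β = ψ + (π − φ), so the hand sits at

    elbow = (L₁ sin ψ, −L₁ cos ψ),  hand = elbow + (L₂ sin β, −L₂ cos β).

Segment lengths are not free parameters of the reaching task: the central
posture (ψ, φ) = (0°, 90°) must place the hand at (0.33, −0.33) m, which
forces L₁ = L₂ = 0.33 m under these conventions. Masses are 2.10 kg
(upper arm) and 1.65 kg (forearm); the load perturbation adds a 1 kg point
mass at the forearm centre of mass.

Segments are uniform rods (COM at mid-segment, I = mL²/12; COM fractions
configurable). The equations of motion M(q)q̈ + C(q, q̇)q̇ + G(q) + b q̇ = τ
are derived in absolute segment angles and mapped to (ψ, φ); viscous joint
damping b = 0.1 N·m·s/rad stabilises long rollouts (the value is a modelling
choice, not measured). Soft joint stops (spring 50 N·m/rad, damper
1 N·m·s/rad, engaged only outside ψ ∈ [−60°, 120°], φ ∈ [10°, 175°])
prevent non-physical wrap-around during badly coordinated early
optimisation candidates; setting the stop stiffness to zero disables the
stops entirely, which the energy-conservation test uses.

Integration is fixed-step classical Runge-Kutta (RK4) at h = 10⁻⁴ s with
states sampled on a 1 ms grid. Convergence is verified by step-halving
(hand-path change < 10⁻⁵ m over 0.8 s) and by energy conservation of the
undamped free swing (drift < 10⁻⁶ J over 0.8 s).

## Muscle-tendon units

Six MTUs with constant signed moment arms act on the two joints
(flexion-positive convention; MEF ±0.03 m elbow, MSA ±0.05 m shoulder,
biarticular muscles both). The muscle path length is linear in the joint
angles, anchored at the central posture where each CE sits at its optimal
length and the serial elastic element (SEE) is exactly slack — the
quiescent muscle is therefore in true equilibrium transmitting zero force.

Element forces (all parameters per muscle, uniform defaults;
F_max = 1000 N, l_opt = 0.10 m, l_SEE,0 = 0.15 m):

* force-length f_L(λ) = exp(−(|λ−1|/0.45)³), λ = l_CE/l_opt;
* force-velocity: Hill hyperbola f_V(v̂) = (1 + v̂/v̂_max)/(1 − v̂/(v̂_max·0.25))
  for shortening (v̂_max = 10 l_opt/s), zero below −v̂_max, and a smooth
  eccentric branch f_V = e_max − (e_max−1)·exp(−k₀v̂/(e_max−1)) saturating
  at e_max = 1.5 with slope matched at v̂ = 0;
* PEE: 2·F_max·max(0, λ−1)²; PDE: 50 N·s/m; SDE: 300 N·s/m;
* SEE: quadratic toe F_max(ε/0.04)² up to ε = 0.08, then linear
  continuation with matched slope.

Activation follows Hatze-type calcium kinetics, γ̇_c = m_h(u − γ_c) with
m_h = 10 s⁻¹, and the static nonlinearity
a = (a_min + (ρ(λ)γ_c)³)/(1 + (ρ(λ)γ_c)³), ρ(λ) = c_ρ λ, a_min = 0.005.
The active CE force is driven by the rescaled activity
(a − a_min)/(1 − a_min): the activation floor then produces exactly zero
force, which keeps the slack rest state stationary and makes a fully
silent circuit mechanically inert. c_ρ = 3.0 is the calibration constant
of the loop: it is set so that the tonic motoneuron firing elicited by the
380 pA descending current yields mid-level (≈ 0.5) plateau activation in
the closed loop (the acceptance script recomputes this number).

The CE rate is the root of F_SEE + F_SDE = F_CE(v) + F_PEE + F_PDE. The
left side is strictly decreasing and the right side strictly increasing in
v, so the root is unique; it is found by bracketed bisection to 10⁻¹⁰ N in
[−2, 2]·v̂_max·l_opt, widening the bracket once before aborting. A grid-scan
oracle in the tests confirms the root to < 10⁻⁶ m/s on 1000 random states.
The transmitted force is clamped at zero (a tendon cannot push).

## Spindles

Each muscle carries one spindle with bag1, bag2 and chain fibers whose
length is slaved to the extrafusal CE length (quasi-static sensory-stretch
mapping — no independent intrafusal mechanical ODE). This keeps the loop
fast while preserving length, velocity and fusimotor coding. Polar regions
are activated through the same Hatze kinetics: dynamic gamma → bag1,
static gamma → bag2 + chain. Sensory stretch per fiber is
s_f = max(0, (λ − λ_rest) + β_a·â_f) with λ_rest = 0.95, β_a = 0.10 and
â_f the polar activity above the activation floor (so zero gamma
contributes no bias and the unbiased spindle is silent at λ_rest).

Primary contributions P_f = clamp(K_L,f·s_f + K_V,f·(1 + c_dyn·â_bag1·[f =
bag1])·max(0, dλ/dt), 0, 300 pps) with K_L = (50, 150, 150),
K_V = (120, 20, 20), c_dyn = 2. The Ia rate combines the dynamic branch
(bag1) and static branch (bag2 + chain) with partial occlusion
(S_occ = 0.156, the classical convention): the larger branch dominates and
the smaller contributes the occlusion fraction. The II rate reads the
static fibers only (0.5·K_L,bag2·s_bag2 + K_L,chain·s_chain), hence codes
length but not velocity. All rates are clamped to [0, 300] pulses/s.

Consequences verified by tests: ramp responses exceed hold responses
(velocity sensitivity), static gamma raises the II steady state, dynamic
gamma boosts the Ia ramp response without moving II, and isometric
unbiased spindles are silent — muscles can be strongly active yet
afferently quiet.

## Spinal circuit

Each pool (α, γ_d, γ_s motoneurons; Ia, propriospinal, Renshaw
interneurons; per muscle) is one leaky integrate-and-fire point neuron
with alpha-shaped synaptic currents on separate excitatory and inhibitory
ports: C_m = 250 pF, τ_m = 10 ms, E_L = V_reset = −70 mV, V_th = −55 mV,
t_ref = 2 ms, τ_syn = 2 ms. Every neuron receives a constant 380 pA
descending current standing in for supraspinal drive; with these
parameters the rheobase is 375 pA, so 380 pA is just suprathreshold
(tonic ISI = t_ref + τ_m ln(ΔV_∞/(ΔV_∞ − θ)) ≈ 45.31 ms ≈ 22 Hz).

Subthreshold dynamics are linear and are integrated with the exact affine
propagator exp(AΔt) at Δt = 0.1 ms (a forward-Euler path at 0.01 ms is
kept for validation and agrees on spike counts). All synapses have a 1 ms
delay, implemented with ring buffers. Spindle afferents enter through
Poisson encoders (Bernoulli thinning at rate·Δt, zero-order-held rates).

Connectivity is generated from the muscle-relation table (3 antagonist,
4 synergist, 4 partial-synergist symmetric pairs) by a normative rule
table with three blocks — afferent (38 edges: Ia and II to homonymous α,
Ia to synergist α, Ia to Ia-interneurons, Ia and II to propriospinal
neurons), interneuronal (70 edges: Ia-interneuron and propriospinal
inhibition of antagonists, propriospinal excitation of homonymous α and
both γ pools, flexible partial-synergist routes, Renshaw inhibition of
antagonist Ia-interneurons and homonymous γ pools) and the Renshaw core
(42 edges: α→Renshaw homonymous + synergist, Renshaw→α homonymous +
synergist, Renshaw→Renshaw antagonist + partial-synergist). The complete
circuit has exactly 150 connections; the simple variant is exactly the
Renshaw core (42). Only the block totals, pathway names, afferent routing
rules and relation scopes are externally constrained; the per-rule
decomposition is this package's reconstruction using physiologically
attested motifs, and is config-exposed.

Weights are peak synaptic-current amplitudes in pA: excitatory start at
5.0 (bounds [0, 10]), inhibitory at −5.0 ([−10, 0]), flexible
(partial-synergist) at 2.0 ([−10, 10]), routed to the excitatory or
inhibitory port by their current sign. A global synaptic gain g_syn = 20
scales all weights at delivery — 5 pA peaks would be negligible against
the 380 pA drive — and is not part of the optimised vector.

## Closed loop

An episode is 0.8 s split into eight 0.1 s exchange windows, executed as
a single-process neural-then-mechanical staggered scheme per window: the
circuit is simulated first (encoder rates frozen at the window start), its
α/γ_d/γ_s spikes are converted to stimulation traces, the mechanical plant
integrates over the same interval, and the spindles' instantaneous Ia/II
rates at the window end become the encoder rates of the next window. This
realises exactly the exchange semantics of a two-simulator lockstep
co-simulation (spikes forward, rates back, every 0.1 s) without
inter-process machinery; afferent information from window w can influence
spiking only from window w + 1. First-window encoder rates are zero (no
afferent data exists yet). Instantaneous end-of-window rates are the
default hand-over — the simplest reading of a rate-updated encoder — and
`run_episode(..., encoder_rate_mode="mean")` switches to window-mean
rates instead.

Spike-to-stimulation conversion is all-or-nothing with exponential decay:
u jumps to 1 at each spike time and decays as exp(−(t − t_last)/τ) with
τ = 10 ms; a new spike resets the trace to 1 (non-additive). Traces carry
across window boundaries through the last-spike time.

A silent circuit (zero weights, zero descending current) leaves the
stimulation identically zero, and the windowed episode then coincides with
one uninterrupted integration of the passive plant — the co-simulation
plumbing adds nothing. Because the simulation is deterministic given
(connectome, scenario, seed), episode logs are bit-identical across runs.

## Task and learning

Eight targets form a 3×3 grid with 0.1 m spacing around the start hand
position (0.33, −0.33) m, centre excluded, numbered row-major with the
top row first (T1 = (0.23, −0.23) … T8 = (0.43, −0.43)). Scenarios cross
two circuit variants with the 1 kg forearm perturbation.

The cost is the switched Euclidean objective: if both |x_end − x_ref| and
|z_end − z_ref| are below 0.05 m, J is the endpoint distance; otherwise J
sums the distances of all trajectory points (801 samples at 1 ms — the
sampling is config-exposed since it scales the sum branch). The branch is
evaluated per candidate. Switching can only decrease the reported cost
(an endpoint distance never exceeds an all-points sum).

The optimizer is an in-package implementation of the standard
(μ/μ_w, λ)-CMA-ES with weighted recombination, cumulative step-size
adaptation and rank-one + rank-μ covariance updates. Box bounds are
enforced by projecting sampled candidates onto the box before evaluation
(the repaired candidates enter the update). Initial mean = initial weight
vector; σ₀ = 2.0 (≈ 1/5 of the bound range — chosen for bound-scaled
search). Termination at the generation budget or best cost < 10⁻⁴. A
failed episode scores +∞. Episode seeds derive deterministically from
(run seed, generation, candidate), making optimisations exactly
reproducible. The reference experiment budget is population 150 ×
1000 generations per target; the test suite exercises a scaled-down
budget (population 20, 50 generations, target T7) that demonstrates
learnability — the best cost falls far below half the initial-weights
cost — at desk scale (~10⁴ episodes would be needed per full-budget
optimisation, ~10⁶ for the full study).

## Numerical and design notes

* Bisection tolerance 10⁻¹⁰ N; bracket widened once, then the episode
  aborts (scored +∞ under optimisation). States that genuinely exceed the
  widened bracket correspond to tendon strains outside the model's
  intended regime.
* The eccentric force-velocity branch is slope-matched at v̂ = 0, so the
  balance residual is C¹ at the isometric point and strictly monotone.
* Hand-trajectory timing is inspected with markers every 50 ms (17 per
  episode); closely spaced markers mean slow movement.
* "Reached" is quantified as endpoint error < 0.05 m (reusing the cost
  switch threshold); the radius is config-exposed.
* No-connection entries in exported matrices are NaN, distinct from a
  flexible synapse at weight 0.0.
* The LIF ISI test tolerates 0.15 ms against the closed form — the
  0.1 ms clock quantises threshold crossings.

## What the synthetic conditions do and do not show

All inputs are synthetic by construction (the system is a model, not a
data pipeline): scripted spike trains and length ramps exercise the
transduction chain, and closed-loop episodes generate their own afferent
streams. Passing tests demonstrate internal consistency — printed
structural totals, closed-form neuron and conversion behavior, calibrated
mid-level activation, causality and determinism of the exchange scheme,
and scaled-down learnability. They do not demonstrate fidelity to
recorded human kinematics: muscle parameters are uniform stand-ins,
moment arms are constant, the descending command is a constant current,
and single neurons represent whole pools. Trajectories are accordingly
ataxic (oscillatory, over/undershooting) — consistent with a spinal
system lacking cerebellar correction, but not a quantitative match to any
subject.

## Known limitations

* Constant moment arms and uniform Hill parameters instead of the cited
  anatomical geometry; rod inertias and joint damping are stand-ins.
* No Golgi tendon organs, hence no Ib pathway; no group II interneurons;
  intrafusal mechanics are quasi-static.
* One neuron per pool; no conduction-distance delays; no fiber
  recruitment within a muscle.
* The full four-scenario, eight-target learning study at the reference
  budget (≈ 1.5·10⁵ episodes per target) is supported by the API but not
  run by the test suite; the suite verifies the machinery and a
  scaled-down learning run.
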