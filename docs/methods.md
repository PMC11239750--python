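# Methods

## Scope and model class

`coroflow` predicts fractional flow reserve (FFR) on reduced-order (0D)
coronary trees and quantifies the effect of the pressure guidewire that is
physically present during the invasive measurement. The full-fidelity
version of this problem is a 3D incompressible Navier–Stokes computation on
a CCTA-segmented lumen; here every vessel segment is collapsed to a lumped
loss element and the solve becomes a small nonlinear network problem. This
is the central fidelity trade-off of the package: it makes a 96-simulation
paired cohort study run in seconds-to-minutes on one CPU, at the price of
entrance, curvature and 3D jet effects that a lumped model cannot represent.
Consequences of that trade-off are flagged throughout this note.

## Segment loss models

* **Plain lumen** — Hagen–Poiseuille, R = 8μL/(πr⁴), i.e. fully developed
  laminar flow in a straight rigid cylinder.
* **Lumen with guidewire** — exact concentric annular-Poiseuille closed
  form, R = 8μL/(π[r_o⁴ − r_i⁴ − (r_o² − r_i²)²/ln(r_o/r_i)]). For a
  0.036 cm wire in a 2 mm-diameter vessel this multiplies the viscous
  resistance by ≈ 2.2 (the closed form is verified against numerical
  quadrature of the annular velocity profile to 1e-6 in the test suite).
  The wire is assumed rigid, static and concentric; a real wire lies
  eccentric against the wall, which would lower the added resistance, and
  short segments at coronary Reynolds numbers (~10²) never develop the
  annular profile, so the fully developed form is an upper-bound-flavoured
  estimate of the wire's viscous drag.
* **Stenosis** — a Young–Tsai-type loss across the throat,
  ΔP = R_v·q + K_t·(ρ/2A₀²)(A₀/A_s − 1)²·q|q|,
  where R_v is the viscous (annular if wired) resistance of the throat,
  A₀/A_s are healthy/throat cross-sections (both reduced by the wire's
  cross-section when it traverses the segment), and K_t = 1.52 is the
  classical empirical expansion-loss coefficient for smooth axisymmetric
  constrictions. Severity is parameterised by fractional **area** reduction
  `degree = 1 − A_s/A₀` (not diameter reduction — a 70% area stenosis is a
  ~45% diameter stenosis). Both loss terms are odd in q, so retrograde flow
  is handled consistently.

All computation is in CGS internally; pressures cross the API in mmHg and
flows in mL/s, with the single conversion constant 1333.22 dyn/cm² per
mmHg defined in one place.

## Prediction pipeline

1. Total resting coronary flow q_cor = 0.045·CO (CO in L/min, converted to
   mL/s). The 4.5% fraction is the standard resting coronary share of
   cardiac output.
2. Outlet split by either distal Murray weighting (d^m with exponent m = 3
   by default; FFR sensitivity to m over [2, 3] is known to be very low and
   the sweep is monotone/continuous in the tests) or a stem-and-crown
   vessel-length rule. Crown length is defined as the summed length of all
   segments distal to and including the outlet's terminal segment; for a
   tree with no structure beyond its terminals this reduces to the terminal
   segment length. Only the modelled tree enters the crown sums.
3. Resting solve (Scenario I): inlet pressure = MAP, outlet flows
   prescribed. On a tree the prescribed outlet flows determine every
   segment flow exactly, so nodal pressures follow by marching from the
   inlet — no iteration.
4. Peripheral resistance per outlet, R_bln = (p_out − p_v)/q_out, with
   venous reference p_v = 5 mmHg. An outlet pressure at or below p_v is
   rejected as unphysiological (resting ischemia — the model's calibration
   premise breaks).
5. Hyperemia: R_hyp = R_bln/TCRI with TCRI = 3, the population-typical
   total coronary resistance index under adenosine. Double division is
   guarded against.
6. Pulsatile hyperemic solve (Scenario II): see below.
7. FFR = mean(p_d)/mean(p_a) over the final simulated cycle.

Peripheral resistances are always calibrated on the **wire-absent** resting
state and reused for the wire-included run: clinically there is no wire in
the artery at rest, and holding the boundary conditions fixed isolates the
wire's epicardial effect in the paired comparison.

## Windkessel coronary beds and the transient solve

Each outlet is loaded by a five-element coronary-bed model: arterial path
Ra–Ca–Ra_micro, venous path Rd to p_v, joined by the myocardial compliance
Cmyo referenced to the left-ventricular pressure P_LV(t). Splits of R_hyp
are 0.01/0.84/0.15 (Ra/Ra_micro/Rd) and of the outlet compliance
0.025/0.975 (Ca/Cmyo); the last element takes the arithmetic remainder so
totals are conserved to rounding. Per-outlet compliance is a coronary
fraction (default 0.045, mirroring the flow fraction, configurable) of the
1.7 mL/mmHg total arterial compliance, split among outlets by Murray
weights regardless of the flow setup, because peripheral compliance is
assumed proportional to flow.

State equations per outlet (p1 across Ca, p2 across Cmyo):

    q_in = (p_out − p1)/Ra
    Ca·dp1/dt = q_in − (p1 − p2)/Ra_micro
    Cmyo·d(p2 − P_LV)/dt = (p1 − p2)/Ra_micro − (p2 − p_v)/Rd

Sign conventions are fixed by the DC limit: at constant drive the steady
inflow must equal (p_out − p_v)/(Ra + Ra_micro + Rd), which the test suite
checks to 1e-6 relative. Rising P_LV injects charge into the myocardial
node and transiently throttles inflow — the systolic impediment that gives
coronary flow its diastolic-dominant pattern.

Coupling is semi-implicit at Δt = 1 ms: each step solves the (small)
nonlinear tree network by damped Newton with an analytic Jacobian (residual
tolerance 1e-8 mmHg), holding the capacitor pressures frozen, then advances
the two-state linear system by backward Euler (unconditionally stable).
Capacitor states initialise from the steady solution, so periodicity —
cycle-mean p_d changing < 1e-3 relative between cycles — is typically
reached in 2–3 cycles (cap 10; non-convergence is reported on the result,
not raised). Halving Δt changes cohort FFR values by < 1e-3 (tested).

A steady fast path (`run_hyperemic_steady`, compliances open, outlets
loaded by Ra + Ra_micro + Rd) agrees with the transient cycle-mean FFR
within 0.02 per lesion (tested); it is used for cohort calibration and
anywhere speed matters, which is legitimate because FFR is a ratio of
cycle-averaged pressures and the averaged network is nearly algebraic.

### Waveforms

Aortic and LV waveforms are documented analytic stand-ins, not digitised
clinical tracings: the aortic shape is a constant base plus two Gaussian
bumps (broad systolic wave, smaller dicrotic wave), affinely rescaled so
the cycle mean equals the patient's MAP and max−min equals the pulse
pressure; the LV shape is a squared-sine systolic pulse (systolic fraction
0.35) scaled so its peak reaches MAP + pulse/2 (a systolic-pressure proxy,
configurable) and its diastolic value is 0. Because FFR averages pressures
over the cycle, its sensitivity to the waveform shapes is small — the
steady/transient 0.02 agreement quantifies exactly this.

Cycle duration (0.8 s) and pulse pressure (40 mmHg) are package defaults,
overridable per patient; the packaged clinical table records only MAP, CO
and dominance. If systolic/diastolic pressures are supplied instead of MAP,
the conventional estimate MAP = (SBP + 2·DBP)/3 applies. Dominance is
carried as metadata only; synthetic trees do not branch differently by
dominance.

## Synthetic cohorts

The generator emulates the features of segmented coronary trees that drive
the pipeline: binary branching with Murray-consistent radii
(|r_p³ − r_l³ − r_r³|/r_p³ < 1e-10 by construction), minor-daughter flow
share drawn uniformly from [0.40, 0.50], segment lengths 8–12 lumen radii
(typical epicardial inter-branch distances), root radius 0.15 cm (proximal
coronary calibre), 3 generations (4 outlets) by default. The p_d sensor is
placed by walking ~2.5 cm distal from the lesion along the largest-radius
chain, clipped to the branch end, and read at that segment's distal node.
The default wire course runs from the tree inlet to the sensor segment (the
clinical wire enters at the ostium); `wire.path_mode: stenotic_branch`
restricts it to the lesion's branch.

Cohorts are calibrated: for each severity class, target FFR values are
drawn from the interior of the class interval (0.03 margin; targets above
the healthy-tree FFR ceiling are clipped just below it) and the stenosis
degree is bisected against the wire-absent steady-mode FFR to within
0.005 — valid because FFR is strictly decreasing in degree (tested). Each
synthetic lesion is paired with a packaged invasive measurement of the same
class so diagnostic statistics can be computed. A single seeded
`numpy.random.Generator` drives everything; no global state.

What the generator does **not** emulate: real lumen irregularity,
curvature, tapering within segments, serial/diffuse disease, side-branch
anatomy beyond the binary tree, and dominance-dependent topology. Passing
tests therefore demonstrate the pipeline's internal consistency and the
direction/scaling of the wire effect — not agreement with any specific
patient anatomy.

## Magnitudes, and what they mean

Because the whole q_cor feeds a 4-outlet tree, per-branch hyperemic flows
(and hence viscous losses) are higher than in a fully segmented anatomy: a
lesion-free default tree predicts FFR ≈ 0.91 (pure viscous loss), and the
wire's mean FFR drop in the mildest class is ≈ 7% rather than the ~2%
reported for 3D patient-specific studies, for the same reason plus the
fully developed annular-drag assumption. The severity *ordering* is the
robust, transferable result: the mean percentage FFR drop increases
strictly from class 4 to class 1 (mildest to most severe) under both flow
setups, with the most severe class dropping ≳3× the mildest — wire
inclusion matters most exactly where the clinical decision is most
sensitive. These aggregates are recomputed from scratch by
`scripts/acceptance.py`; no number in this note is asserted anywhere
without being computed at run time.

## Problem sizes and runtimes

Default study: 24 lesions (6 per class) × 2 flow setups × 2 wire states =
96 pulsatile simulations at Δt = 1 ms, 0.8 s cycles, ≤ 10 cycles each —
about half a minute on one CPU. Cohort calibration uses the steady path
(~10–20 solves per lesion, milliseconds each). The test suite, including
the full paired study and a Δt-halving sweep over the cohort, runs in about
a minute.

## Known limitations

* Rigid walls, Newtonian rheology, laminar fully developed losses; no
  fluid–structure interaction, no wire motion or eccentricity.
* TCRI is a population constant (3), not patient-specific; lesion-induced
  microvascular dysfunction is not modelled.
* The coronary share of total arterial compliance (0.045) is an assumption
  by analogy with the flow fraction; it is configurable and FFR is
  insensitive to it in the tested range.
* Percent-change aggregates are lesion-weighted (not patient-weighted), and
  classes are assigned by invasive FFR when available, else by predicted
  FFR.
* The Bland–Altman difference direction is invasive − predicted (positive
  bias = model under-predicts); it is configurable and always labelled in
  outputs.
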