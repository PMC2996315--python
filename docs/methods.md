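# Methods

## Model geometry

All three cross-bridge models live in a two-dimensional frame: x runs
along the thick-filament axis (positive toward the binding site), y is
the radial separation, and the cross-bridge anchors at the origin on the
thick-filament surface.  Binding sites sit on the plane `y = ssLS`, the
surface-to-surface thick-to-thin gap.  There is no azimuthal degree of
freedom, no steric interaction between segments beyond the spring
network, and the rigid globular domain's fixed attachment angle to actin
is absorbed into the rest geometry, so the head is a point.

Springs are linearly elastic: energy `½k(v − v_rest)²` with `v` an angle
(torsional, pN·nm/rad) or a length (extensional, pN/nm).  The tabulated
torsional stiffnesses are printed per-radian; we read them as torque
stiffnesses (pN·nm/rad) so that `½kΔθ²` is an energy in pN·nm — the only
dimensionally consistent reading.

Angle conventions matter and were fixed by two independent checks.  The
4sXB base angle is the elevation of S2 above the filament axis (rest 40°,
unchanged by the stroke).  The converter angle is measured between the
LCD and the filament axis *pointing away from the binding site*; its rest
value swings 125° → 70°, which places the pre-stroke head at
(13.55, 14.61) nm and the post-stroke head at (4.76, 15.77) nm.  Two
consequences confirm the convention: (i) the derived 2sXB rest values —
computed, per the parameter table's own prescription, so the 2sXB head
co-locates with the 4sXB head — come out at 47.16°/19.93 nm and
73.20°/16.47 nm, matching the rounded tabulated 47/20 and 73/16; (ii)
the lattice correction factor calibrates to 6.90 nm (below).

The 2sXB geometry is closed-form (arm = base-to-tip distance, base angle
= elevation).  The 4sXB's converter point is placed by minimising the
four-spring energy at fixed base and tip: L-BFGS-B on the analytic
gradient, started from the state's rest converter, energy tolerance
1e-8 pN·nm, 500 iterations, with five jittered restarts before declaring
failure.  Unit tests verify the optimum against an exhaustive 0.05 nm
converter grid on random tips, and verify that the analytic tip-gradient
(used for forces) matches finite differences of the optimised energy —
the envelope property of a minimised inner variable.  Tips with radial
separation ≤ 0.5 nm are rejected as unphysical rather than extrapolated.

## Lattice spacing

Internally everything is ssLS; externally spacings are reported as d10.
In the hexagonal lattice the nearest thick-to-thin center distance is
`2·d10/3`, so `d10 = (3/2)(ssLS + c)` with `c` the filament-radius
correction.  `c` is calibrated mechanically: find the ssLS at which the
post-stroke cross-bridge at its unstrained axial offset exerts zero
radial force (a Brent root search on the radial force; by construction
this is the post-stroke rest radial, 15.77 nm) and map that spacing to
the rest d10 of 34 nm, giving c = 6.896 nm.  A purely additive
`d10 = ssLS + c` was rejected: it would require c ≈ 18.2 nm, far from
the established ~6.9 nm filament-radius scale.  Moving the rest d10 by
+1 nm moves c by +2/3 nm (the lattice factor), which the tests pin down.
The studied window is d10 ∈ [30, 38] nm; values outside warn but
compute.

## Free energies and forces

`G₁ ≡ 0` everywhere (the unbound head supports no strain).  For bound
states, `G_i = −ε_i·ΔG_ATP·kT + U_i(tip)` with `U_i` the total elastic
energy under state-i rest values (converter re-relaxed per state for the
4sXB).  Efficiencies are ε₂ = 0.28 and ε₃ = 0.68.  The ATP budget is
`ΔG_ATP = 13 kT + ln([ATP]/([ADP][Pi])) = 23.93 kT` at 5 mM ATP, 30 µM
ADP, 3 mM Pi — the standard concentrations of this model lineage.
kT = 4.11 pN·nm (≈ 298 K; the temperature is configurable, nothing below
depends sensitively on it).  None of the geometric results (rest tips,
correction factor, energy-minimum positions, step sizes) depend on
ΔG_ATP or the efficiencies; only rate magnitudes do.

The reaction force holding the head at a position is `−∇U` (state 3 for
the force landscapes), with radial positive = expansive.  At rest
spacing the radial force is zero exactly at the post-stroke rest offset,
expansive below and compressive above — the calibration fixed point.

Axial energy minima are located by 0.5 nm grid pre-bracketing plus
bounded scalar minimisation to 1e-4 nm over a ±25 nm window.  Step size
at a spacing is the axial distance between the pre- and post-stroke
energy minima on the binding plane (positive = forward stroke).

## Kinetics

Three states: unbound (M·ADP·Pi), loosely bound pre-stroke
(A·M·ADP·Pi), post-stroke (A·M·ADP); transitions only along the cycle
1↔2, 2↔3, 3↔1.

**Attachment (1→2)** is a two-step Monte Carlo.  Diffusion: each spring
is offset independently from its pre-stroke rest with a Gaussian of
variance kT/k — the exact Boltzmann distribution of a harmonic degree of
freedom, satisfying equipartition by construction — and the head
position follows by forward kinematics.  (An alternative reading of
"energy drawn from the Boltzmann density", an exponential energy draw
mapped to an offset, also satisfies equipartition but is not the
stationary law of a harmonic spring in a thermal bath; the Gaussian is
used.)  Binding: `P = min(1, τ·e^{−d²})` per 1 ms step, with d the
tip-to-site distance in nm and τ = 12 (4sXB) / 72 (2sXB) chosen to make
the two models' attachment rates consistent — the 4-spring cloud is
wider, so it needs the smaller capture scale.  Ensemble rate constants
average P over N = 10⁴ independent draws and convert by
`r = −ln(1−P̄)/Δt` (a `P̄/Δt` mode is available); standard errors are
propagated and always reported.

**Power stroke (2→3)**:
`r23 = (r23_max/2)(1 + tanh(β + κ(G₂−G₃)/kT))` with r23_max = 1200/s,
β = 4, κ = 0.4 — the single-spring lineage's sigmoid with the axial
strain argument generalised to the full two-dimensional free-energy
difference.  It depends only on G₂−G₃, is near-maximal wherever the
stroke is downhill, and shuts off smoothly where it is strongly uphill.

**Detachment (3→1)**: `r31 = r31_rest·exp(α·U₃/kT)` with U₃ the
post-stroke strain energy at the site.  The explicit axial-position
asymmetry of the single-spring lineage's detachment law is deliberately
dropped; only the energy carries position dependence.  The two constants
are calibrated in closed form from the two published detachment floors:
r31_rest = 20/s (the slowest detachment at rest spacing, where U₃ = 0)
and α = ln(260/20)·kT/U₃*(38 nm) = 2.809, where U₃*(38) = 3.75 pN·nm is
the minimal strain on the 38 nm binding plane, a purely geometric
quantity.  `calibrate_detachment` recomputes the calibration; a test
pins the shipped default against it.

**Reverse rates** follow detailed balance,
`r_rev = r_fwd·exp(ΔG_fwd/kT)` with ΔG_fwd the forward free-energy
change (exponent clamped at ±50).  The 2→1 reverse balances the
ensemble attachment rate; the 3→1 reverse balances against the full
remaining ATP budget (a fresh hydrolysis follows detachment), making
rebinding into state 3 negligible (< 0.05/s) everywhere studied.

One caveat the implementation makes explicit: attachment does *not*
decrease monotonically with lattice spacing at every axial offset.  At
offsets below the attachment peak the diffusion cloud's arc passes
closer to the farther binding plane, and r12 can rise with d10; the
monotone decrease holds across the high-rate region at and beyond the
peak.

## Monte-Carlo simulator

Fixed 1 ms steps following the single-cross-bridge protocol: unbound →
diffuse, test binding; bound → test forward then reverse transition,
at most one event per step (at these step sizes transition probabilities
are ≪ 1 except for deeply strained detachment, so the resolution order
is second-order).  Bound-state rates are precomputed once per site
context; per-step probabilities are `1 − e^{−rΔt}`.  All randomness
comes from one seeded generator with pre-drawn streams, so identical
seed and configuration give byte-identical trajectories.  Long-run
occupancies are validated against the analytic steady state of the
master equation built from the same rate constants, and post-stroke
dwell times against the competing-exponential expectation
`1/(r31 + r32)`.

The simulator (and the kinetics it samples) is the package's synthetic
data source; it emulates an isometric single cross-bridge facing one
binding site at a fixed spacing.  It does not emulate filament
compliance, site realignment, multi-site competition, calcium
regulation, or ensemble mechanics — so a passing suite says the
single-cross-bridge laws are implemented faithfully, not that those
collective effects are captured.

## Scans and masking

`scan_landscape` evaluates named layers (state energies, six rates,
force components) on rectangular axial × d10 grids; defaults are
−5…25 nm at 0.25 nm and 30…38 nm at 0.5 nm, with extrema refined
parabolically (deterministic layers are bit-identical across runs;
stochastic layers are seed-reproducible, one diffusion ensemble per d10
row).  Cells where a cross-bridge is unlikely to generate force can be
masked by a threshold on the sum of the normalised attachment rate and
normalised inverse detachment rate; the default threshold is chosen
adaptively to retain ≥ 95% of the total attachment flux, and both rule
and threshold are recorded in the grid provenance.  Per-cell solver
failures become NaN with a logged warning and a provenance count.

## Problem sizes

Default study sizes: 10⁴ diffuse-and-bind trials per rate estimate
(standard errors reported; estimates at N and 4N agree within two
combined SE), 0.5 nm d10 and 0.25 nm axial grids with local refinement,
and simulator runs of 10–200 s (10⁴–2·10⁵ steps) for occupancy and
dwell statistics.  The test suite uses these sizes or modest fractions
of them; every stochastic check is seeded.

## Known limitations

- Step-size maxima: under the definition above with the tabulated
  parameters, the 2sXB step at rest spacing is bounded below ~7.4 nm
  for *any* positive stiffnesses (at the pure-rotation point both
  spring terms still push the state-2 minimum outward), and the 4sXB
  curve decreases monotonically across the window (its state-2 minimum
  shifts ~0.7 nm per nm of d10 while its state-3 minimum is nearly
  invariant).  The implemented maxima are 11.0 nm (4sXB, at the 30 nm
  edge) and 7.9 nm (2sXB, near 36 nm).  Published smaller maxima with
  an interior peak for both models are not reachable from the stated
  definition plus the tabulated rest geometry; the discrepancy is
  reported, not tuned away.
- Post-stroke force components at a fixed offset grow faster with d10
  radially than axially here; published "both components halve from
  38 to 35 nm" holds for the force magnitude only approximately
  (vector-magnitude ratios 0.45 for the 4sXB at 10 nm offset, 0.70 for
  the 2sXB at 12 nm).
- The power-stroke sigmoid's shape constants (β, κ, r23_max) are taken
  from the single-spring lineage, not refit; only their energy argument
  is new.
- Two-dimensional, single cross-bridge, one rigid binding site; no
  regulation, no compliance, no ensemble coupling.
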