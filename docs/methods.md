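# Model and methods

`lamelliflow` is an agent-based Brownian-dynamics model of the branched
actin network in a lamellipodium: F-actin, Arp2/3 complexes, actin
cross-linking proteins (ACPs), myosin minifilaments, an elastic substrate
mesh, and transient nascent focal adhesions (FAs), in a thin periodic slab
whose +y boundary is the leading edge and whose -y boundary is the
lamellipodium/lamella interface.  The model reproduces a *dynamic steady
state*: assembly at the leading edge, motor-driven contraction and
disassembly at the rear, and a retrograde flow resisted by adhesion
friction.

## Mechanics

Every component is a set of cylindrical segments defined by endpoints.
Endpoints obey the inertia-free Langevin equation
`F_i - zeta_i dr_i/dt + F^T_i = 0`, integrated with forward Euler at a fixed
time step (reference `dt = 1.15e-5 s`).  Segment drag uses the approximate
cylinder form `zeta = 3 pi mu r_c (3 + 2 r0/rc)/5`; motor backbones multiply
this by 1000 (the model's device for keeping motors near the rear), and
substrate nodes by a configurable factor (default 100) representing the
large effective friction of coarse-grained substrate material; this also
keeps the mesh substep stable (below).

Deterministic forces are harmonic: extension `1/2 ks (r - r0)^2`, bending
`1/2 kb (theta - theta0)^2`, the branch-plane torsion
`1/2 kt phi^2`, volume exclusion between actin segments closer than their
7-nm diameter, repulsive +y/z walls, and the adhesion link springs.  A
junction restrains four angles (body straight; body-mother 90 deg;
body-daughter 20 deg; mother-daughter 70 deg) plus the coplanarity torsion.
All gradients are analytic (including the tangent-rotation terms of the
motor two-spring attachment) and are verified against central finite
differences of an independent Python energy function at 1e-6 relative
tolerance.

Numerical regularization: angle gradients carry a sine floor (sin >= 0.05)
and the torsion is skipped when either bond pair is within ~3 degrees of
collinear, where the dihedral is ill-conditioned.  Both limits are far from
any equilibrium geometry.

The stochastic force is sampled per endpoint and component with zero mean
and variance exactly `2 kBT zeta / dt`, using a *uniform* distribution
rather than a Gaussian: the fluctuation-dissipation theorem and every
diffusion observable constrain only the first two moments, and uniform
draws are several times cheaper in the hot loop.  The suite verifies the
moments, independence, and the Einstein relation `D = kBT/zeta` (within
10%).

## Stochastic kinetics

Events are Bernoulli trials per candidate and step with
`p = 1 - exp(-k dt)`, executed in a fixed order (depolymerize, sever,
polymerize, nucleate, then the binding group), which together with a single
explicit xorshift128+ stream makes runs bit-reproducible per seed.

* **Nucleation**: a new segment appears in the xy plane at z = 0 at a
  constant whole-domain rate (during assembly: at the -y boundary with +y
  polarity).
* **Polymerization** adds a collinear segment at the barbed end at
  `k+_A * [free monomer]`; blocked beyond the 0.98-um cap (7 segments),
  outside the assembly band (steady phase), or when the free pool would
  drop below its 10% floor.
* **Depolymerization** removes the pointed segment at `k-_A`
  (disassembly band only in the steady phase); proteins bound to the
  removed segment lose that one connection and may rebind.
* **Severing** is evaluated per interior joint at
  `k_sev = k0_sev exp(lambda_sev theta)` with theta the instantaneous
  bending angle in degrees; acceptance removes the barbed-side segment at
  the joint and splits the filament.  Because `k0_sev ~ 1e-45/s`, severing
  only fires where motor-driven buckling bends joints past ~80 degrees,
  which localizes disassembly inside compacted regions.
* **ACP binding**: arms bind 7-nm lattice sites at `k+_ACP`; the second arm
  must reach a different filament; cross-links are permanent.
* **Arp2/3**: binds a site at `k+_Arp` and immediately nucleates a
  one-segment daughter at 70 degrees, azimuth drawn uniformly on the
  half-cone with a +y (leading-edge) bias; junction connections are
  permanent while their supporting segments exist.
* **Motors**: see below.  **Adhesions**: each mesh node can hold one link
  to an actin endpoint within 200 nm (both inside the FA region), born at
  its rest length and rupturing as a slip bond
  `k_u = k0_u exp(lambda_u |F| / kBT)` (plain `k0_u` when compressed).

Binding, motor and adhesion kinetics are sampled every `n_kin = 10` steps
with window-scaled probabilities (all such rates x window << 1); chain
kinetics run every step.  Free ACP/Arp2/3 agents are represented as single
compact diffusing points and expand to their two-segment bodies on first
binding; this is a coarse-graining of the folded free conformation that
removes the force cost of idle agents.

## Motor model

A motor is a stiff backbone (8 points, 7 segments of 42 nm) with one arm
per point; an arm lumps 4 myosin heads.  Arm attachment uses the two-spring
model (transverse rest length 10 nm; longitudinal rest length 0), and the
longitudinal spring force component along the filament axis defines the
opposing load.  Arm kinetics derive from a three-state cycle
(unbound / pre-stroke B / post-stroke P) with the ATP-dependent unbinding
rate `k20` as the P->U transition and a load-gated power stroke
`k12(F) = k12_0 (1 - F/F_stall)_+`:

    k_w(F) = k12(F) (k20 + k21) / (k12(F) + k20 + k21)
    k_u(F) = (k10 (k20 + k21) + k20 k12(F)) / (k12(F) + k20 + k21)

`k12_0` has a closed-form calibration to the printed unloaded velocity
(120 nm/s at the reference `k20 = 17/s`); stall is exact at 5.33 pN.  With
`k10 < k20` the occupancy shift toward B under load makes `k_u` *decrease*
(catch bond); beyond stall an explicit slip factor
`exp((F - F_stall)/F_slip)` (F_slip = 4 pN) releases overstretched arms —
the printed monotonicity constraint covers only [0, F_stall].  Both rates
grow with `k20`, reproducing the reported trend.  A motor whose arms all
release relocates instantly onto F-actin in the motor region, or waits
dormant when none exists.

## Substrate

The substrate is an equilateral triangulated mesh at z = 0 (chains 50 nm,
`ks = 1e-4 N/m`; interior angles 60 deg, `kb = 2.4e-20 N m`); node z never
changes.  The effective stiffness probe pins the patch boundary, applies an
in-plane point force to a central node, and relaxes with damped (FIRE)
dynamics to a residual below 1e-6 of the load; `kappa_eff = F/u`.  Because
a point-load response in 2D diverges logarithmically with patch size, the
printed `kappa_eff ~ 2.4e-4 N/m` pins the probe geometry; the default patch
(0.25 x 0.22 um, 36 nodes) reproduces it and the probe preserves the
reported monotonic trends in `ks_sub`, `kb_sub`, and `r0_sub`.

## Composition conventions

Actin amount is `C_A x volume x N_Av / 52` segments (370 monomers/um over
140 nm).  The density ratios are molar (per actin monomer):
`N_Arp = R_Arp N_mono`; motors are minifilament agents of 32 heads
(16 myosin dimers), `N_M = 2 R_M N_mono / 32`; cross-linker agents
coarse-grain a cluster of 4 molecules, `N_ACP = R_ACP N_mono / 4`, keeping
the agent count tractable while preserving the cross-linking density the
reference condition needs.  An earlier segment-count reading of the ratios
produced ~9 junctions per quarter domain — a network that cannot branch to
the leading edge — and was rejected.

## Phases and scenario schedule

Assembly: seed filaments every ~0.25 um at the -y boundary (pointed ends
anchored by the sticky boundary), all dynamics active except motor walking,
polymerization/depolymerization ungated; ends when ~90% of actin is
incorporated or at a time cap.  Steady phase: walking on, polymerization
confined to the assembly band, depolymerization to the disassembly band;
recycled monomers feed the leading edge.  Measurements: flow speed every
2 s from the finite-difference displacement of actin endpoints in the
flow-measurement band (identity tracked with per-point generation
counters); 40-bin density profiles, their coefficient of variation, and the
total substrate force every 1 s.

## Default-decision parameters

The printed parameter table of the source is not available in text form, so
stiffnesses, viscosity (0.86 Pa s), kBT (300 K), binding rate constants,
adhesion constants and the nucleation rate are package decisions, tagged
`"default-decision"` in `params.py`.  Guiding constraints: actin
persistence length ~9 um (`kb_A = 2.7e-19 N m`); extensional stiffnesses
large enough that bond-length fluctuations stay ~1% of the rest length but
soft enough for stable Euler integration (`ks_A = 2e-3 N/m`); adhesion
constants (`k+_C = 3/s`, `k0_u = 1/s`, `lambda_u = 8 nm`,
`ks_C = 1e-4 N/m`) chosen so that at the reference condition total adhesion
friction sits *below* the stall thrust of the motor pool — the regime the
source identifies as producing a steady flow — while a larger FA region or
fewer motors tip the balance to stalling; nucleation (60/s) high enough
that assembly leaves the network rooted at the rear.

## Reduced-scale regression conditions

The full reference condition (5 x 2.5 x 0.1 um, 300 s) is provided as a
preset but is a production run.  Qualitative regime comparisons use a
reduced domain (2.0 x 1.25 x 0.1 um; periodic x makes the width a purely
statistical choice) at the same actin density with regions scaled
proportionally, a 4x time step (4.6e-5 s; every stiffness
keeps a comfortable Euler stability margin at the default values, verified
by the instability guard), ~12 s of steady phase after assembly, and
three seeds per condition.  These runs sit in the early, transient part of
the steady state (the source itself shows a rear-starvation transient over
the first ~100 s at full scale), so the suite asserts *orderings* — flow
with/without the FA region, flow with scarce vs reference motors, density
CV with and without severing — never values.  Even as orderings these are
demanding at desk scale: motor engagement is strongly seed-dependent in a
quarter domain, and the motor-density ordering in particular sits within
about one standard error of the window noise at these run lengths.

## Known limitations

* No deformable leading-edge membrane and no polymerization force against
  the boundary; flow is driven purely by rear contraction.
* No ATP-state aging of subunits, no explicit cofilin, no FA maturation.
* The reduced-scale runs resolve the early flow regime, not the recovered
  long-time steady state; quantitative flow values at desk scale are not
  comparable to full-scale ones, and severing-dependent contrasts (the
  reference condition severs only a handful of times in 20 s) sit at the
  edge of resolvability there.
* The monomer pool is closed; when turnover pauses, the pool can sit at its
  10% floor with polymerization and nucleation blocked until
  depolymerization resumes.
* Uniform (not Gaussian) thermal forces; correct to second moments only.
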