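# Methods

## Model overview

`ciliaswim` simulates a spherical microswimmer propelled by a small number of
long cilia (cilium length L comparable to the body radius R) in a thermal,
particle-based solvent, and analyzes the resulting swimming trajectories.
The three layers are:

1. an MPC/SRD solvent (stochastic rotation dynamics) with a cell-level
   canonical thermostat,
2. a mechano-elastic swimmer — a spring-mesh sphere carrying three-filament
   bead-spring cilia whose beat is driven by a prescribed local-curvature
   program with an energy-injection cap and coordinated by a metachronal
   phase field Psi(phi, theta) = k_phi phi + k_theta theta,
3. a kinematics layer that measures propulsion velocity, spin, the
   orientation autocorrelation and its helix-plus-noise fit
   C(tau) = (cos^2 a + sin^2 a cos(Omega_c tau)) e^(-kappa tau), helix
   geometry, rotational-diffusion scales and swimming efficiency.

Units: cell size a, fluid particle mass m and thermal energy kBT are all 1.
Time is measured in a sqrt(m/kBT).

## Fluid

Streaming interval h = 0.05, rotation angle alpha0 = 130 deg, density
rho = 10 particles per cell. Each collision rotates the particle velocities
relative to the cell center-of-mass velocity about a per-cell random axis;
mass and per-cell momentum are conserved exactly. A random grid shift,
uniform in [0, a)^3 and redrawn every step, restores Galilean invariance
(the mean free path h sqrt(kBT/m) = 0.05 a is far below the cell size, the
regime where the shift matters); it can be disabled in the configuration.

The thermostat is the exact canonical Maxwell-Boltzmann-scaling variant:
each cell's relative kinetic energy is replaced by a draw from the gamma
distribution with shape 3(Nc-1)/2 and scale kBT, by rescaling the relative
velocities; cell momentum is untouched, cells with fewer than two particles
are skipped, and the signed removed energy is ledgered — its long-run rate is
the dissipated power of an actuated swimmer.

Viscosity. The kinetic-theory closed forms (molecular chaos, fluctuating
occupancy)

    eta_kin = (rho kBT h/a^3) [5 rho/((rho-1+e^-rho)(2-cos a0-cos 2a0)) - 1/2]
    eta_col = (m/(18 a h)) (1-cos a0)(rho-1+e^-rho)

give eta = 0.736 + 16.43 = 17.16 at the default parameters. The measurement
route tracks the equilibrium decay of the six transverse momentum modes at
the fundamental wave vectors, exp(-eta k^2 t / rho m); because the estimator
variance is dominated by slow large-scale fluctuations, several independent
replicate runs are pooled (default 3 x 8000 steps in a (10a)^3 box, giving a
~2% standard error).

Angular momentum is not conserved by SRD collisions; this known property of
the method is accepted (no angular-momentum-conserving variant is provided).

## Swimmer construction

Body: an icosahedral subdivision sphere (level 3 -> 642 surface vertices,
1280 faces, 1920 edges) plus a center particle — 643 particles at the
production size R = 8a. Surface vertices are joined along mesh edges and
radially to the center by stiff springs; per-spring stiffness is set so the
single-spring thermal bond fluctuation sqrt(kBT/k) is 2% of the rest length.
All swimmer particles carry the heavy mass M = rho a^3 m = 10, which gives
good no-slip hydrodynamic coupling when they are included in the collision
step. The two subdivision poles (on +-z at build time) define the body axis
n; an equatorial vertex provides the body-fixed marker used to measure spin.

Cilium: three bead-spring filaments (N_c = 26 beads each at production
scale) on a prism with equilateral cross-section of side l_c, where
l_c = (L + (3/16)R)/(N_c - 1) = 0.5 a at the defaults (L = 1.375 R, with a
clamped segment of (3/16) R inside the body). Within each level the three
beads are linked in-plane, and both diagonals connect adjacent levels.
Because every such pairwise-spring prism admits an exact zero-energy
sharp-fold deformation (a mirror reflection through a cross-section plane
preserves all spring lengths), each filament also carries
next-nearest-neighbor springs of rest length 2 l_c: these block folds while
costing only a fourth-order penalty under smooth bending. Anchoring: beads 1
and 4 of every filament are tied to the surface vertex nearest the base and
to that vertex's mesh neighbors (rest = as-built distances), clamping the
cilium like an embedded basal body.

Spring stiffness defaults (unprinted in the source material; chosen once so
that the passive cilium persistence length is far above L, thermal bond
fluctuations stay below 2%, and the velocity-Verlet substep is stable):
backbone 5000, cross-links 2000, anti-fold 2500, anchors 5000, body springs
kBT/(0.02 r0)^2 per spring. All are configurable.

## Beat actuation

The beat prescribes a target local curvature c(s, u) of the cilium
(arclength s from the sphere surface, stroke phase u) plus a clamped base
angle beta(u), and maps them onto spring rest lengths:

* curvature map: the bond of the active filament at arclength s gets rest
  l_c (1 - c(s) b) with moment arm b = (sqrt 3/2) l_c — the distance from
  the active filament to the neutral line through the passive pair. The
  active-passive diagonal cross-links and the active filament's anti-fold
  springs follow the same linear strain field (arms b/2 and b), so a
  uniformly bent prism is stress-free at exactly the prescribed curvature; a
  static relaxation test recovers an imposed arc curvature to better than 1%.
  (Using the cross-section side itself as the arm, with unmodulated
  cross-links, under-realizes the curvature by a factor ~2.)
* base clamp: the anchor rest lengths follow a rigid virtual rotation of the
  clamped beads by beta about the beat-plane normal; beta sweeps linearly
  from -45 deg to +45 deg over the power stroke and back over the recovery.

The exact analytic curvature program of the source model was not available,
so a parametric stand-in with the same phenomenology is used: during the
power stroke a small uniform counter-bend c = -c0 sin(pi u)/L (default
c0 = 0.25) keeps the cilium extended while the base sweep drives it; during
recovery a localized bend of amplitude c1/L (default 5.0) and width w = 0.4 L
travels from base to tip (center at u (L+w)), with a 5%-of-stroke smoothing
envelope at the switches so the cycle is continuous. These defaults were
calibrated against quasi-static shape tests: the tip sweeps a wide loop —
extended during the power stroke, pulled down to ~0.4 R above the surface
during the return — giving the non-reciprocal cycle that propulsion
requires. Duty cycle tau_p/tau_b = 1/3 (the recovery is the longer stroke).

Energy cap. A rest-length update that would raise the elastic energy (at the
current configuration) by more than eps_max = 1 kBT per MPC step is scaled
down to inject exactly eps_max. The cap is applied per modulated bond: each
"molecular motor" stalls independently. A per-cilium cap was tried first and
rejected, because the power budget it allows (1 kBT per step per cilium,
i.e. 340 kBT/time for 17 cilia) is an order of magnitude below the
dissipated power implied by the published efficiency and speed of this
swimmer class (~20 kBT per step per cilium), and it indeed starved the beat
in pilot runs. Injected work is ledgered per cilium; energy bookkeeping
closes per step, dKE + dPE = W_in - E_removed, up to Verlet error.

Metachronal coordination. Deterministic mode: each cilium's local beat time
is offset by (Psi/360) tau_b with Psi = k_phi phi + k_theta theta; the phase
lag between the rings (45 deg apart) is chi = k_theta x 45 deg. k_phi = 0
with chi > 0 is symplectic, chi < 0 antiplectic; k_phi > 0 gives the chiral
dexioplectic/laeoplectic waves. Self-organized mode: each cilium switches
power -> recovery when its base-to-tip axis tilts beyond a threshold angle
(default 60 deg) from the local surface normal, and recovery -> power when
its maximal backbone curvature exceeds a critical value (default 1.5/L) —
i.e. the fully curled state marks the end of the return stroke. Both
thresholds are configurable; switches are suppressed during the first 20% of
a stroke so a fresh stroke cannot re-trigger instantly.

## Coupled integration

One MPC interval: (1) beat update of the rest lengths (at the interval's end
time), (2) velocity-Verlet MD of the swimmer springs over h (default 50
substeps; stability requires omega_max dt < ~0.2) concurrently with ballistic
fluid streaming, (3) a joint collision + thermostat step in which the swimmer
particles are binned into the same cells as the fluid. Swimmer coordinates
are kept unwrapped and wrapped only for cell binning. The swimmer feels the
fluid only through the collision step; there are no excluded-volume
interactions between cilia (steric effects enter only via fluid and
springs). Runs are bitwise reproducible for a fixed seed: a single generator
supplies, in fixed order per step, the grid shift, the rotation axes and the
thermostat draws.

## Trajectory analysis

v_n(t) is the centered-difference center velocity projected on n(t);
averages are taken over whole beat periods. Spin Omega_n unwraps the marker
angle in a parallel-transported frame (removing apparent rotation from axis
wobble). The orientation autocorrelation is fitted by weighted nonlinear
least squares with multi-start over Omega_c (spectral peaks plus a coarse
grid); weights scale with the square root of the number of contributing lag
pairs, and the lag window is refined once to ~5/kappa. Fits with 1/kappa
beyond the data span, or with unresolved/vanishing oscillation, are flagged
rather than trusted.

Frequency convention: the autocorrelation model uses Omega_c in radians per
time internally; the helix formulas P_h = v cos(a)/Omega_c and
R_h = v sin(a)/(2 pi Omega_c) are only mutually consistent with Omega_c in
cycles per time, so the conversion happens once at that reporting boundary
and the convention is recorded in the fit metadata. The identities
cos^2 a = P_h^2/(P_h^2 + 4 pi^2 R_h^2) and P_h/(2 pi R_h) = cot(a) then hold
exactly by construction.

Passive scales: D_rot = kBT/(8 pi eta_f R^3), tau_rot = 1/(2 D_rot); a
measured decorrelation reduction factor f = 1/(kappa tau_rot) maps to a
hydrodynamic radius R f^(1/3); f < 1 (faster-than-passive decorrelation,
i.e. dominant active noise) is flagged. Efficiency is
6 pi eta_f R <v_n>^2 / <P> with <P> the thermostat-removal rate; both the
raw rate and a baseline-subtracted value (equilibrium removal averages to
zero, so the distinction matters only at short averaging times) can be
formed from the ledgers.

## Synthetic fixtures

The helix generator produces exact noise-free orientation series
n(t) = cos(a) e_par + sin(a) e_perp(t), an integrated center path, and a
marker that parallel-transports plus spins at a chosen Omega_n (so the spin
estimator recovers it identically). Rotational-diffusion noise rotates the
whole helix frame with diffusion coefficient kappa/2, which multiplies the
axis autocorrelation by exactly e^(-kappa tau). What it does not emulate:
beat-cycle velocity modulation, translation-rotation coupling, active
(non-thermal, non-isotropic) noise, or finite sampling of the marker —
passing analysis tests on these fixtures therefore validates the estimators,
not the simulation physics.

## Problem sizes and scaled-down presets

The production conditions (R = 8a, box (100a)^3, N_b = 643, N_c = 26,
tau_b = 180 — the beat period follows from keeping the swimmer Reynolds
number rho R^2/(tau_b eta_f) = 0.2) correspond to 10^7 fluid particles and
3600 MPC steps per beat period; they are exposed through the "full" presets
for offline reproduction. The test suite runs two geometry-preserving
reductions (constant L/R = 1.375, clamp fraction 3/16, d/L, Reynolds-number
scale): "reduced" (R = 4a, box (32a)^3, N_c = 13, tau_b = 45) for the
passive validation runs, and "tiny" (R = 3a, box (20a)^3, N_c = 10,
tau_b = 32) for the actuated ordering runs. The tiny beat period was chosen
(over a first candidate tau_b = 16) so that the cilium can follow its
curvature program at a biologically sensible sperm number; at tau_b = 16 the
beat is too fast for the filament's elasto-hydrodynamic response and
propulsion collapses. At the tiny scale the 5-7-5 swimmer reaches
~0.16 body radii per beat for the optimal antiplectic lag — smaller than the
production-scale figure (the 10-bead cilium resolves the recovery curl only
coarsely, and periodic images are closer), but with all sign and ordering
structure intact.

## Numerical choices and degenerate inputs

- MD substep h/50 (stability margin ~3x for the default stiffnesses);
  overdamped steepest descent for stiff-mode relaxation and lightly damped
  dynamics (gamma ~ softest mode frequency) for bending-mode relaxation.
- Thermostat gamma draws use shape 1.5 (Nc-1); empty/singleton cells draw
  shape 0 (no-op).
- Helix fits: alpha = 0 makes Omega_c unidentifiable (flagged); Omega_c = 0
  with alpha > 0 is an inconsistent geometry (flagged, R_h = 0, P_h = inf).
- Random placement rejects draws violating the minimum great-circle
  separation or the pole exclusion (the two tangent-field singularities are
  confined to the excluded poles), and raises after a bounded number of
  tries when the packing is infeasible.
- NaN guard: runs abort with a diagnostic if coordinates go non-finite.

## Known limitations

- The curvature program is a calibrated stand-in, not the original analytic
  beat; absolute speeds and efficiencies at production scale depend on it.
- Diffusion measurements on the mesh sphere must exclude the hydrodynamic
  transients: the rotational MSD slope is meaningful only beyond the local
  momentum-diffusion time rho R^2/eta (~10 time units at R = 4a), and the
  translational slope additionally needs the periodic-image backflow to
  establish (rho L^2/(pi^2 eta), ~60 time units in a (32a)^3 box). Fitted on
  shorter windows both appear 15-25% low. With windowed fits the measured
  coefficients agree with the geometric-radius Stokes-Einstein predictions
  (Hasimoto periodic correction applied to translation).
- The molecular-chaos kinetic-theory viscosity formula is accurate (~1-2%)
  at the study conditions and for moderate single-parameter variations, but
  degrades when a large mean free path meets low cell occupancy (measured
  -17% at rho = 5, h = 0.1); it should not be used as an oracle there.
- No walls, no external flow, single swimmer only; cilia interact only
  hydrodynamically and through the shared body.
- The self-organized trigger mode is provided on the spherical swimmer; a
  planar cilia carpet (which needs bounding walls) is out of scope.
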