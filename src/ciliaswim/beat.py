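"""Curvature-actuated cilia beat and metachronal-wave coordination.

A beat cycle is a power stroke of duration tau_p (cilium extended, sweeping
towards the power-stroke direction p) followed by a recovery stroke of
duration tau_r > tau_p (a localized high-curvature bend travels from base to
tip while the cilium returns close to the surface).  The beat is produced by
two actuation channels:

* the bond rest lengths of the active filament follow a prescribed local
  curvature program c(s, u): the bond at arclength s gets rest length
  l_c (1 - c(s) b), where b is the distance from the active filament to the
  neutral line of the passive pair ((sqrt 3/2) x cross-section side);
* the clamped base orientation sweeps in the beat plane between -beta_max and
  +beta_max through the anchor-spring rest geometry.

Energy injection is capped: a rest-length update that would raise the
elastic energy by more than eps_max (default 1 kBT) in one MPC step is
scaled down to meet the cap — mimicking the stall force of the molecular
motors.  The cap acts per modulated bond by default (each "motor" stalls
independently) or, optionally, per cilium.

Metachronal coordination imposes a per-cilium phase
Psi(phi, theta) = k_phi phi + k_theta theta (a traveling wave over the
surface), or, in the self-organized mode, each cilium switches stroke when
geometric triggers (critical curvature, maximum axis angle) fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrokeProgram",
    "WavePattern",
    "TriggerRule",
    "BeatState",
    "phase_field",
    "classify_wave",
    "target_curvature",
    "base_angle",
    "stroke_clock_deterministic",
    "stroke_trigger_selforganized",
    "restlength_update",
    "POWER",
    "RECOVERY",
]

POWER, RECOVERY = 0, 1


@dataclass
class StrokeProgram:
    """Timing and curvature program of one beat cycle.

    Curvature amplitudes are in units of 1/L (cilium length), the bump width
    in units of L; tau_* in simulation time units.  eps_max is the energy cap
    per MPC step in units of kBT, applied per modulated bond by default
    (``cap_granularity="bond"``, mimicking the stall force of the individual
    molecular motors) or collectively per cilium ("cilium").
    """

    tau_p: float = 8.0
    tau_r: float = 16.0
    c0_L: float = 0.25        # uniform counter-bend amplitude, power stroke
    c1_L: float = 5.0         # traveling-bump amplitude, recovery stroke
    w_L: float = 0.4          # bump width / L
    beta_max_deg: float = 45.0  # base-angle sweep amplitude
    smooth: float = 0.05      # stroke-switch smoothing window (fraction of stroke)
    eps_max: float = 1.0
    cap_granularity: str = "bond"   # "bond" | "cilium"

    def __post_init__(self) -> None:
        if self.tau_p <= 0 or self.tau_r <= 0:
            raise ValueError("stroke durations must be positive")

    @property
    def tau_b(self) -> float:
        return self.tau_p + self.tau_r


@dataclass
class WavePattern:
    """Imposed metachronal wave vector (k_phi, k_theta).

    k_phi (latitudinal wave number) must be an integer for the wave to close
    around circles of latitude; k_theta (longitudinal) is real.  The phase lag
    between neighboring rings (45 deg apart) is chi = k_theta * 45 deg.
    """

    k_phi: int = 0
    k_theta: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.k_phi - round(self.k_phi)) > 1e-12:
            raise ValueError("k_phi must be an integer")
        self.k_phi = int(round(self.k_phi))

    @property
    def chi_deg(self) -> float:
        return self.k_theta * 45.0

    @classmethod
    def from_chi(cls, chi_deg: float, k_phi: int = 0) -> "WavePattern":
        return cls(k_phi=k_phi, k_theta=chi_deg / 45.0)


@dataclass
class TriggerRule:
    """Geometric stroke-switch triggers for the self-organized mode."""

    critical_curvature: float       # 1/length; recovery -> power
    max_axis_angle_deg: float       # power -> recovery

    def __post_init__(self) -> None:
        if self.critical_curvature <= 0 or self.max_axis_angle_deg <= 0:
            raise ValueError("trigger thresholds must be positive")


def phase_field(phi_deg: float, theta_deg: float, pattern: WavePattern) -> float:
    """Local beat phase Psi = k_phi phi + k_theta theta, in degrees.

    A cilium with phase Psi starts its beat cycle (Psi/360) tau_b later than
    the Psi = 0 cilium.
    """
    if not (-90.0 < theta_deg < 90.0):
        raise ValueError("latitude must be in (-90, 90) degrees")
    return pattern.k_phi * (phi_deg % 360.0) + pattern.k_theta * theta_deg


def classify_wave(pattern: WavePattern) -> str:
    """Metachronal wave class from the wave vector.

    With no latitudinal component (k_phi = 0) a positive phase lag chi is a
    symplectic wave (traveling with the power stroke), a negative chi
    antiplectic; with k_phi > 0 the wave is dexioplectic (k_theta > 0) or
    laeoplectic (k_theta < 0).
    """
    if pattern.k_phi == 0:
        if pattern.k_theta > 0:
            return "symplectic"
        if pattern.k_theta < 0:
            return "antiplectic"
        return "synchronous"
    return "dexioplectic" if pattern.k_theta > 0 else "laeoplectic"


# --------------------------------------------------------------------------
# stroke clocks
# --------------------------------------------------------------------------

def stroke_clock_deterministic(t: float, psi_deg: float,
                               program: StrokeProgram) -> tuple[int, float]:
    """Deterministic stroke state: (POWER|RECOVERY, stroke phase u in [0,1))."""
    t_local = (t - psi_deg / 360.0 * program.tau_b) % program.tau_b
    if t_local < program.tau_p:
        return POWER, t_local / program.tau_p
    return RECOVERY, (t_local - program.tau_p) / program.tau_r


def stroke_trigger_selforganized(stroke: int, u: float,
                                 centerline: np.ndarray,
                                 surface_normal: np.ndarray,
                                 rule: TriggerRule,
                                 min_phase: float = 0.2) -> bool:
    """Geometric switch decision for one cilium.

    During the power stroke, switch to recovery once the base-to-tip axis
    tilts more than max_axis_angle away from the local surface normal; during
    recovery, switch back to power once the maximal backbone curvature exceeds
    the critical curvature (the fully curled state marks the end of the
    return).  Switches are suppressed for the first ``min_phase`` of a stroke
    so a fresh stroke cannot re-trigger instantly.
    """
    if u < min_phase:
        return False
    axis = centerline[-1] - centerline[0]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("degenerate (zero-length) cilium axis")
    axis /= norm
    if stroke == POWER:
        ang = np.degrees(np.arccos(np.clip(axis @ surface_normal, -1.0, 1.0)))
        return ang > rule.max_axis_angle_deg
    return _max_curvature(centerline) > rule.critical_curvature


def _max_curvature(centerline: np.ndarray) -> float:
    seg = np.diff(centerline, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    t = seg / ds[:, None]
    dt = np.linalg.norm(np.diff(t, axis=0), axis=1)
    return float((dt / (0.5 * (ds[1:] + ds[:-1]))).max())


# --------------------------------------------------------------------------
# curvature program (parametric power/recovery stand-in)
# --------------------------------------------------------------------------

def target_curvature(s: np.ndarray, stroke: int, u: float,
                     program: StrokeProgram, L: float) -> np.ndarray:
    """Prescribed local curvature c(s) at stroke phase u (1/length units).

    Power stroke: a small uniform counter-bend -c0 sin(pi u) — the cilium
    stays extended while the base sweep drives the stroke.  Recovery: a
    localized bend of width w and amplitude c1 travels from base to tip,
    c(s) = c1 exp(-((s - u(L+w))/w)^2), with a short amplitude envelope at the
    stroke switches so the cycle is continuous.  Arclength s is measured from
    the sphere surface; the clamped sub-surface segment (s < 0) is not bent.
    """
    s = np.asarray(s, dtype=float)
    c = np.zeros_like(s)
    outside = s >= 0.0
    env = np.clip(min(u / program.smooth, (1.0 - u) / program.smooth, 1.0), 0.0, 1.0)
    if stroke == POWER:
        c[outside] = -(program.c0_L / L) * np.sin(np.pi * np.clip(u, 0, 1))
    else:
        w = program.w_L * L
        x_c = u * (L + w)
        c[outside] = (program.c1_L / L) * env * np.exp(
            -((s[outside] - x_c) / w) ** 2)
    return c


def base_angle(stroke: int, u: float, program: StrokeProgram) -> float:
    """Clamping angle beta (radians) of the sub-surface segment in the beat plane.

    Sweeps linearly from -beta_max to +beta_max over the power stroke (tilting
    the cilium towards +p) and back during recovery.  The sweep extrapolates
    linearly for u > 1: in the trigger-driven (self-organized) mode the base
    keeps driving until the geometric switch fires.
    """
    b = np.deg2rad(program.beta_max_deg)
    u = max(u, 0.0)
    if stroke == POWER:
        return -b + 2.0 * b * u
    return b - 2.0 * b * u


# --------------------------------------------------------------------------
# rest-length update with energy cap
# --------------------------------------------------------------------------

def _rotate_about(vectors: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    cross = np.cross(np.broadcast_to(axis, vectors.shape), vectors)
    dot = vectors @ axis
    return vectors * c + cross * s + np.outer(dot, axis) * (1.0 - c)


def restlength_update(positions: np.ndarray, spring_rest: np.ndarray,
                      spring_i: np.ndarray, spring_j: np.ndarray,
                      spring_k: np.ndarray, slot, stroke: int, u: float,
                      program: StrokeProgram) -> float:
    """Drive one cilium: set its curvature-modulated and anchor rest lengths.

    Active bonds get l_c (1 - c(s) b) with moment arm b = (sqrt 3/2) side,
    the distance from the active filament to the neutral line through the
    passive pair; the active-passive diagonal cross-links follow the same
    linear strain field (arm b/2 at their mid-section offset), so a uniformly
    bent prism is stress-free at exactly the prescribed curvature.  Anchor
    rest lengths follow a rigid virtual rotation of the clamped beads
    by the base angle beta about the beat-plane normal (rest lengths are
    scalar distances of the as-built geometry, so they are frame independent).
    The prospective elastic-energy increase at the current configuration is
    computed first; if it exceeds eps_max, the whole update is scaled down
    (towards the previous rest lengths) to inject exactly eps_max.  Returns
    the signed injected work.

    Mutates ``spring_rest`` in place.
    """
    c = target_curvature(slot.mod_s, stroke, u, program, slot.L)
    if np.any(np.abs(c) * slot.mod_arm >= 1.0):
        raise ValueError("curvature too large: bond rest length would vanish")
    axial = slot.mod_axial * (1.0 - c * slot.mod_arm)
    new_mod = np.sqrt(axial * axial + slot.mod_trans * slot.mod_trans)
    beta = base_angle(stroke, u, program)
    rotated = _rotate_about(slot.anchor_bead_local, slot.q, beta)
    new_anchor = np.linalg.norm(rotated + slot.pivot - slot.anchor_vertex_pos,
                                axis=1)

    idx = np.concatenate([slot.mod_springs, slot.anchor_springs])
    new = np.concatenate([new_mod, new_anchor])
    old = spring_rest[idx]
    delta = new - old
    d = np.linalg.norm(positions[spring_i[idx]] - positions[spring_j[idx]], axis=1)
    e = d - old
    k = spring_k[idx]
    a = 0.5 * k * delta * delta
    b = -k * e * delta
    eps = program.eps_max
    if program.cap_granularity == "cilium":
        a_tot, b_tot = float(a.sum()), float(b.sum())
        lam = 1.0
        if a_tot + b_tot > eps and a_tot > 0.0:
            lam = (-b_tot + np.sqrt(b_tot * b_tot + 4.0 * a_tot * eps)) \
                / (2.0 * a_tot)
            lam = float(np.clip(lam, 0.0, 1.0))
        spring_rest[idx] = old + lam * delta
        return float(a_tot * lam * lam + b_tot * lam)
    # per-bond cap: each spring's energy increase limited independently
    lam = np.ones_like(delta)
    over = (a + b > eps) & (a > 0.0)
    lam[over] = np.clip(
        (-b[over] + np.sqrt(b[over] ** 2 + 4.0 * a[over] * eps))
        / (2.0 * a[over]), 0.0, 1.0)
    spring_rest[idx] = old + lam * delta
    return float(np.sum(a * lam * lam + b * lam))


@dataclass
class BeatState:
    """Per-cilium stroke bookkeeping and the injected-work ledger."""

    n_cilia: int
    mode: str = "deterministic"            # or "selforganized"
    stroke: np.ndarray = field(default=None)
    stroke_start: np.ndarray = field(default=None)
    work_injected: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.stroke is None:
            self.stroke = np.zeros(self.n_cilia, dtype=np.int64)
        if self.stroke_start is None:
            self.stroke_start = np.zeros(self.n_cilia)
        if self.work_injected is None:
            self.work_injected = np.zeros(self.n_cilia)

    @property
    def total_work(self) -> float:
        return float(self.work_injected.sum())
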