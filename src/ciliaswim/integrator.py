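"""Coupled time stepping of the swimmer and the MPC fluid.

One MPC interval h consists of: (1) the beat program advances the rest
lengths of every cilium (energy-capped, injected work ledgered), (2) the
spring network of the swimmer is integrated with velocity-Verlet molecular
dynamics over h (md_substeps_per_h substeps) while the fluid streams
ballistically over the same interval, and (3) all swimmer particles are
sorted into the collision cells together with the fluid particles and take
part in the momentum exchange and the cell-level thermostat.  The coupling
to the fluid happens only in the collision step.

The swimmer is stored unwrapped (it may drift across the periodic box); it is
wrapped only for the cell assignment.  Energy bookkeeping closes per step:
d(KE) + d(PE) = W_in - E_removed up to the Verlet discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import mpc_fluid as mpc
from .beat import (POWER, RECOVERY, BeatState, StrokeProgram, TriggerRule,
                   restlength_update, stroke_clock_deterministic,
                   stroke_trigger_selforganized)
from .kinematics import Trajectory
from .swimmer import SwimmerAssembly

__all__ = [
    "SimulationState",
    "make_simulation",
    "md_substep",
    "step",
    "run",
    "relax_assembly",
    "spring_energy",
    "swimmer_kinetic_energy",
]


# --------------------------------------------------------------------------
# molecular dynamics of the spring network
# --------------------------------------------------------------------------

@njit(cache=True)
def _spring_forces(pos, si, sj, kk, rest, out):
    out[:] = 0.0
    for s in range(si.shape[0]):
        i = si[s]
        j = sj[s]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        f = -kk[s] * (r - rest[s]) / r
        out[i, 0] += f * dx
        out[i, 1] += f * dy
        out[i, 2] += f * dz
        out[j, 0] -= f * dx
        out[j, 1] -= f * dy
        out[j, 2] -= f * dz


@njit(cache=True)
def _md_substeps(pos, vel, mass, si, sj, kk, rest, dt, n_sub, ext_force):
    n = pos.shape[0]
    f = np.empty((n, 3))
    _spring_forces(pos, si, sj, kk, rest, f)
    f += ext_force
    for _ in range(n_sub):
        for i in range(n):
            h = 0.5 * dt / mass[i]
            vel[i, 0] += h * f[i, 0]
            vel[i, 1] += h * f[i, 1]
            vel[i, 2] += h * f[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        _spring_forces(pos, si, sj, kk, rest, f)
        f += ext_force
        for i in range(n):
            h = 0.5 * dt / mass[i]
            vel[i, 0] += h * f[i, 0]
            vel[i, 1] += h * f[i, 1]
            vel[i, 2] += h * f[i, 2]


@njit(cache=True)
def _damped_md(pos, vel, mass, si, sj, kk, rest, dt, n_sub, damp):
    n = pos.shape[0]
    f = np.empty((n, 3))
    _spring_forces(pos, si, sj, kk, rest, f)
    for _ in range(n_sub):
        for i in range(n):
            h = 0.5 * dt / mass[i]
            for d in range(3):
                vel[i, d] = (vel[i, d] + h * f[i, d]) * damp
                pos[i, d] += dt * vel[i, d]
        _spring_forces(pos, si, sj, kk, rest, f)
        for i in range(n):
            h = 0.5 * dt / mass[i]
            for d in range(3):
                vel[i, d] += h * f[i, d]


@njit(cache=True)
def _relax(pos, si, sj, kk, rest, step_size, n_iter):
    """Overdamped relaxation (steepest descent) to a static spring equilibrium."""
    n = pos.shape[0]
    f = np.empty((n, 3))
    for _ in range(n_iter):
        _spring_forces(pos, si, sj, kk, rest, f)
        for i in range(n):
            pos[i, 0] += step_size * f[i, 0]
            pos[i, 1] += step_size * f[i, 1]
            pos[i, 2] += step_size * f[i, 2]


def spring_energy(pos: np.ndarray, si, sj, kk, rest) -> float:
    d = np.linalg.norm(pos[si] - pos[sj], axis=1)
    return float(0.5 * np.sum(kk * (d - rest) ** 2))


def swimmer_kinetic_energy(vel: np.ndarray, mass: np.ndarray) -> float:
    return float(0.5 * np.sum(mass * (vel * vel).sum(axis=1)))


def md_substep(positions, velocities, masses, spring_i, spring_j, spring_k,
               spring_rest, dt: float, n_sub: int = 1,
               ext_force: np.ndarray | None = None) -> None:
    """Velocity-Verlet update of the spring network, in place."""
    if ext_force is None:
        ext_force = np.zeros_like(positions)
    _md_substeps(positions, velocities, masses,
                 spring_i, spring_j, spring_k, spring_rest,
                 dt, n_sub, ext_force)


def relax_assembly(positions, spring_i, spring_j, spring_k, spring_rest,
                   step_size: float = 2e-5, n_iter: int = 2000) -> None:
    """Relax a spring network to static equilibrium (overdamped, in place).

    Steepest descent; adequate for stiff modes.  For configurations that must
    equilibrate soft (bending) modes use :func:`relax_damped`.
    """
    _relax(positions, spring_i, spring_j, spring_k, spring_rest,
           step_size, n_iter)


def relax_damped(positions, spring_i, spring_j, spring_k, spring_rest,
                 masses: np.ndarray | None = None, dt: float = 0.002,
                 gamma: float = 0.05, total_time: float = 400.0) -> None:
    """Relax via lightly damped dynamics (in place).

    Converges soft bending modes far faster than steepest descent; gamma
    should be of the order of the softest mode frequency.
    """
    if masses is None:
        masses = np.full(len(positions), 10.0)
    vel = np.zeros_like(positions)
    n_sub = int(round(total_time / dt))
    _damped_md(positions, vel, masses, spring_i, spring_j, spring_k,
               spring_rest, dt, n_sub, 1.0 - gamma * dt)


# --------------------------------------------------------------------------
# coupled state
# --------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Full state of a coupled swimmer + fluid simulation."""

    fluid_params: mpc.FluidParams
    fluid: mpc.FluidState
    assembly: SwimmerAssembly
    positions: np.ndarray          # swimmer, unwrapped
    velocities: np.ndarray
    spring_rest: np.ndarray        # live copy (beat program mutates it)
    program: StrokeProgram
    beat_state: BeatState
    rng: np.random.Generator
    md_substeps_per_h: int = 50
    time: float = 0.0
    work_in: float = 0.0           # cumulative injected work
    energy_removed: float = 0.0    # cumulative thermostat removal
    accounting: mpc.CollisionAccounting = field(default_factory=mpc.CollisionAccounting)
    trigger: TriggerRule | None = None
    actuate: bool = True


def make_simulation(assembly: SwimmerAssembly, fluid_params: mpc.FluidParams,
                    program: StrokeProgram, seed: int = 0,
                    md_substeps_per_h: int = 50,
                    mode: str = "deterministic",
                    trigger: TriggerRule | None = None,
                    actuate: bool = True) -> SimulationState:
    """Place the swimmer at the box center in a fresh equilibrium fluid."""
    if md_substeps_per_h < 1:
        raise ValueError("md_substeps_per_h must be >= 1")
    rng = np.random.default_rng(seed)
    fluid = mpc.init_fluid(fluid_params, rng)
    pos = assembly.positions + fluid_params.box / 2.0
    sigma = np.sqrt(fluid_params.kBT / assembly.masses[0])
    vel = rng.normal(0.0, sigma, size=pos.shape)
    vel -= vel.mean(axis=0)
    beat_state = BeatState(n_cilia=len(assembly.cilia), mode=mode)
    if mode == "selforganized" and trigger is None:
        raise ValueError("self-organized mode needs a TriggerRule")
    return SimulationState(
        fluid_params=fluid_params, fluid=fluid, assembly=assembly,
        positions=pos, velocities=vel,
        spring_rest=assembly.spring_rest.copy(), program=program,
        beat_state=beat_state, rng=rng, md_substeps_per_h=md_substeps_per_h,
        trigger=trigger, actuate=actuate)


def _cilium_centerline(sim: SimulationState, ci: int) -> np.ndarray:
    slot = sim.assembly.cilia[ci]
    beads = sim.positions[slot.bead_offset:slot.bead_offset + 3 * slot.n_beads]
    return beads.reshape(3, slot.n_beads, 3).mean(axis=0)


def _advance_beat(sim: SimulationState, t_next: float) -> float:
    """Update all rest-length programs for the step ending at t_next."""
    w = 0.0
    bs = sim.beat_state
    for ci, slot in enumerate(sim.assembly.cilia):
        if bs.mode == "deterministic":
            stroke, u = stroke_clock_deterministic(t_next, slot.phase_deg,
                                                   sim.program)
        else:
            dur = sim.program.tau_p if bs.stroke[ci] == POWER else sim.program.tau_r
            # not clamped: the drive keeps advancing until the trigger fires
            u = (t_next - bs.stroke_start[ci]) / dur
            center = _cilium_centerline(sim, ci)
            normal = center[0] - sim.positions[sim.assembly.center_index]
            normal /= np.linalg.norm(normal)
            if stroke_trigger_selforganized(bs.stroke[ci], u, center, normal,
                                            sim.trigger):
                bs.stroke[ci] = RECOVERY if bs.stroke[ci] == POWER else POWER
                bs.stroke_start[ci] = t_next
                u = 0.0
            stroke = int(bs.stroke[ci])
        dw = restlength_update(sim.positions, sim.spring_rest,
                               sim.assembly.spring_i, sim.assembly.spring_j,
                               sim.assembly.spring_k, slot, stroke, u,
                               sim.program)
        bs.stroke[ci] = stroke
        bs.work_injected[ci] += dw
        w += dw
    return w


def step(sim: SimulationState) -> tuple[float, float]:
    """Advance one MPC interval h.  Returns (injected work, energy removed)."""
    p = sim.fluid_params
    h = p.h
    w_in = _advance_beat(sim, sim.time + h) if sim.actuate else 0.0
    # swimmer MD concurrent with fluid streaming
    dt = h / sim.md_substeps_per_h
    md_substep(sim.positions, sim.velocities, sim.assembly.masses,
               sim.assembly.spring_i, sim.assembly.spring_j,
               sim.assembly.spring_k, sim.spring_rest, dt,
               sim.md_substeps_per_h)
    mpc.stream(sim.fluid, h, p.box)
    removed, _, counts = mpc.collide(
        sim.fluid, p, sim.rng,
        embedded_vel=sim.velocities, embedded_pos=sim.positions,
        embedded_mass=sim.assembly.masses, apply_thermostat=True)
    sim.accounting.record(removed, counts)
    sim.time += h
    sim.work_in += w_in
    sim.energy_removed += removed
    return w_in, removed


def run(sim: SimulationState, n_steps: int, output_stride: int = 10,
        check_every: int = 200) -> Trajectory:
    """Advance n_steps MPC intervals, recording the trajectory every stride.

    Records body center, main axis n (polar-pair direction), the body-fixed
    equatorial marker, and the cumulative work/dissipation ledgers.  Runs are
    bitwise reproducible for a fixed seed.  Raises on numerical blow-up.
    """
    n_frames = n_steps // output_stride + 1
    times = np.empty(n_frames)
    center = np.empty((n_frames, 3))
    axis = np.empty((n_frames, 3))
    marker = np.empty((n_frames, 3))
    w_in = np.empty(n_frames)
    e_rem = np.empty(n_frames)
    frame = 0

    def record():
        nonlocal frame
        times[frame] = sim.time
        center[frame] = sim.positions[sim.assembly.center_index]
        axis[frame] = sim.assembly.axis(sim.positions)
        marker[frame] = sim.assembly.marker(sim.positions)
        w_in[frame] = sim.work_in
        e_rem[frame] = sim.energy_removed
        frame += 1

    record()
    for i in range(1, n_steps + 1):
        step(sim)
        if i % output_stride == 0:
            record()
        if i % check_every == 0 and not np.isfinite(sim.positions).all():
            raise FloatingPointError(
                f"non-finite swimmer coordinates at step {i} "
                f"(t={sim.time:.3f}); reduce the MD substep or stiffness")
    return Trajectory(times=times[:frame], center=center[:frame],
                      axis=axis[:frame], marker=marker[:frame],
                      work_in=w_in[:frame], energy_removed=e_rem[:frame],
                      meta={"h": sim.fluid_params.h,
                            "tau_b": sim.program.tau_b,
                            "n_steps": n_steps,
                            "output_stride": output_stride})
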