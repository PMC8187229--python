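"""Multi-particle collision dynamics (MPC/SRD) solvent.

The solvent is a set of point particles that stream ballistically for a time
interval ``h`` and then exchange momentum inside the cells of a cubic lattice
with spacing ``a``: in each cell, velocities relative to the cell's
center-of-mass velocity are rotated by a fixed angle ``alpha0`` about a random
axis (stochastic rotation dynamics).  Mass and linear momentum are conserved
exactly per cell; angular momentum is not (a known property of SRD).  A
cell-level canonical Maxwell-Boltzmann-scaling thermostat keeps the
temperature at ``kBT`` by resampling each cell's relative kinetic energy from
the exact gamma distribution for its degrees of freedom.

Units: the cell size ``a``, fluid particle mass ``m`` and thermal energy
``kBT`` define the unit system (all three default to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "FluidParams",
    "FluidState",
    "CollisionAccounting",
    "init_fluid",
    "stream",
    "sort_into_cells",
    "collide",
    "thermostat",
    "kinetic_temperature",
    "srd_viscosity_theory",
    "measure_viscosity",
]


# --------------------------------------------------------------------------
# parameters and state
# --------------------------------------------------------------------------

@dataclass
class FluidParams:
    """SRD fluid parameters.

    box_lengths are integer multiples of the cell size ``a``.  Defaults follow
    the study conditions: h=0.05, a=1, alpha0=130 deg, rho=10 particles per
    cell, kBT=1, m=1.
    """

    box_lengths: tuple[int, int, int] = (10, 10, 10)
    a: float = 1.0
    h: float = 0.05
    alpha0_deg: float = 130.0
    rho: float = 10.0
    kBT: float = 1.0
    mass: float = 1.0
    grid_shift: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.box_lengths):
            raise ValueError("box lengths must be positive")
        for L in self.box_lengths:
            if abs(L / self.a - round(L / self.a)) > 1e-9:
                raise ValueError("box lengths must be integer multiples of a")
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if not (0.0 < self.alpha0_deg < 180.0):
            raise ValueError("rotation angle must be in (0, 180) degrees")
        if self.h <= 0:
            raise ValueError("timestep must be positive")

    @property
    def box(self) -> np.ndarray:
        return np.asarray(self.box_lengths, dtype=float)

    @property
    def n_cells_per_axis(self) -> np.ndarray:
        return np.rint(self.box / self.a).astype(np.int64)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.n_cells_per_axis))

    @property
    def n_particles(self) -> int:
        return int(round(self.rho * np.prod(self.box / self.a)))


@dataclass
class FluidState:
    """Positions and velocities of the point-particle solvent."""

    positions: np.ndarray   # (N, 3), wrapped into the periodic box
    velocities: np.ndarray  # (N, 3)
    masses: np.ndarray      # (N,)


@dataclass
class CollisionAccounting:
    """Running energy/occupancy bookkeeping of the collision step."""

    energy_removed_by_thermostat: float = 0.0
    steps: int = 0
    occupancy_min: int = 0
    occupancy_max: int = 0
    occupancy_mean: float = 0.0

    def record(self, removed: float, counts: np.ndarray) -> None:
        self.energy_removed_by_thermostat += removed
        self.steps += 1
        self.occupancy_min = int(counts.min())
        self.occupancy_max = int(counts.max())
        self.occupancy_mean = float(counts.mean())


# --------------------------------------------------------------------------
# initialization and streaming
# --------------------------------------------------------------------------

def init_fluid(params: FluidParams, rng: np.random.Generator | None = None) -> FluidState:
    """Uniform random positions; Maxwell-Boltzmann velocities with zero net momentum."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_particles
    if n <= 0:
        raise ValueError("no fluid particles: check box and density")
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * params.box
    sigma = np.sqrt(params.kBT / params.mass)
    vel = rng.normal(0.0, sigma, size=(n, 3))
    vel -= vel.mean(axis=0)  # equal masses: zero total momentum
    masses = np.full(n, params.mass)
    return FluidState(pos, vel, masses)


@njit(cache=True)
def _stream_kernel(pos, vel, h, box):
    for i in range(pos.shape[0]):
        for d in range(3):
            x = pos[i, d] + vel[i, d] * h
            x -= box[d] * np.floor(x / box[d])
            pos[i, d] = x


def stream(state: FluidState, h: float, box: np.ndarray) -> None:
    """Ballistic motion for a time interval h, positions wrapped periodically.

    In-place: r <- (r + v h) mod box; velocities unchanged.
    """
    _stream_kernel(state.positions, state.velocities, h,
                   np.asarray(box, dtype=float))


# --------------------------------------------------------------------------
# collision step (numba kernels)
# --------------------------------------------------------------------------

@njit(cache=True)
def _cell_index_kernel(pos, shift, a, nc):
    n = pos.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        ix = np.int64(np.floor((pos[i, 0] + shift[0]) / a)) % nc[0]
        iy = np.int64(np.floor((pos[i, 1] + shift[1]) / a)) % nc[1]
        iz = np.int64(np.floor((pos[i, 2] + shift[2]) / a)) % nc[2]
        out[i] = (ix * nc[1] + iy) * nc[2] + iz
    return out


def sort_into_cells(positions: np.ndarray, params: FluidParams,
                    shift: np.ndarray) -> np.ndarray:
    """Linear cell index of every particle on the (shifted) collision grid."""
    return _cell_index_kernel(positions, np.asarray(shift, dtype=float),
                              params.a, params.n_cells_per_axis)


@njit(cache=True)
def _counting_sort(cells, n_cells):
    n = cells.shape[0]
    counts = np.zeros(n_cells, np.int64)
    for i in range(n):
        counts[cells[i]] += 1
    starts = np.empty(n_cells + 1, np.int64)
    starts[0] = 0
    for c in range(n_cells):
        starts[c + 1] = starts[c] + counts[c]
    order = np.empty(n, np.int64)
    fill = starts[:-1].copy()
    for i in range(n):
        c = cells[i]
        order[fill[c]] = i
        fill[c] += 1
    return counts, starts, order


@njit(cache=True)
def _srd_cell_kernel(vel, mass, starts, order, axes, cos_a, sin_a,
                     e_target, do_rotate, do_thermostat):
    """Per-cell SRD rotation and/or Maxwell-Boltzmann-scaling thermostat.

    e_target[c] is a pre-drawn canonical relative kinetic energy for cell c
    (gamma distributed with shape 3(Nc-1)/2); ignored unless do_thermostat.
    Returns the signed energy removed by the thermostat.
    """
    n_cells = starts.shape[0] - 1
    removed = 0.0
    for c in range(n_cells):
        lo, hi = starts[c], starts[c + 1]
        nc = hi - lo
        if nc == 0:
            continue
        # cell center-of-mass velocity
        mtot = 0.0
        px = 0.0
        py = 0.0
        pz = 0.0
        for k in range(lo, hi):
            i = order[k]
            m = mass[i]
            mtot += m
            px += m * vel[i, 0]
            py += m * vel[i, 1]
            pz += m * vel[i, 2]
        ux = px / mtot
        uy = py / mtot
        uz = pz / mtot
        if do_rotate and nc > 1:
            ax = axes[c, 0]
            ay = axes[c, 1]
            az = axes[c, 2]
            for k in range(lo, hi):
                i = order[k]
                rx = vel[i, 0] - ux
                ry = vel[i, 1] - uy
                rz = vel[i, 2] - uz
                dot = ax * rx + ay * ry + az * rz
                cx = ay * rz - az * ry
                cy = az * rx - ax * rz
                cz = ax * ry - ay * rx
                vel[i, 0] = ux + rx * cos_a + cx * sin_a + ax * dot * (1.0 - cos_a)
                vel[i, 1] = uy + ry * cos_a + cy * sin_a + ay * dot * (1.0 - cos_a)
                vel[i, 2] = uz + rz * cos_a + cz * sin_a + az * dot * (1.0 - cos_a)
        if do_thermostat and nc > 1:
            ek = 0.0
            for k in range(lo, hi):
                i = order[k]
                rx = vel[i, 0] - ux
                ry = vel[i, 1] - uy
                rz = vel[i, 2] - uz
                ek += 0.5 * mass[i] * (rx * rx + ry * ry + rz * rz)
            if ek > 0.0:
                s = np.sqrt(e_target[c] / ek)
                for k in range(lo, hi):
                    i = order[k]
                    vel[i, 0] = ux + s * (vel[i, 0] - ux)
                    vel[i, 1] = uy + s * (vel[i, 1] - uy)
                    vel[i, 2] = uz + s * (vel[i, 2] - uz)
                removed += ek - e_target[c]
    return removed


_EMPTY = np.empty((0, 3))


def _random_axes(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on the sphere."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def collide(state: FluidState, params: FluidParams, rng: np.random.Generator,
            embedded_vel: np.ndarray | None = None,
            embedded_pos: np.ndarray | None = None,
            embedded_mass: np.ndarray | None = None,
            shift: np.ndarray | None = None,
            cells: np.ndarray | None = None,
            apply_thermostat: bool = False):
    """SRD collision over all particles (fluid plus embedded swimmer beads).

    Velocities relative to the cell center-of-mass velocity are rotated by
    alpha0 about a per-cell random unit axis; cell momentum is conserved
    exactly.  Embedded particles are sorted into the same cells with their own
    (heavy) mass and participate in the momentum exchange; their velocities
    are updated in place.  With ``apply_thermostat`` the canonical cell-level
    thermostat is applied in the same pass.

    Returns ``(energy_removed, cells, counts)``; the cell assignment can be
    reused by a separate :func:`thermostat` call.
    """
    if embedded_vel is None:
        all_pos = state.positions
        all_vel = state.velocities
        all_mass = state.masses
    else:
        all_pos = np.concatenate([state.positions, embedded_pos % params.box])
        all_vel = np.concatenate([state.velocities, embedded_vel])
        all_mass = np.concatenate([state.masses, embedded_mass])

    if cells is None:
        if shift is None:
            shift = (rng.uniform(0.0, params.a, size=3) if params.grid_shift
                     else np.zeros(3))
        cells = sort_into_cells(all_pos, params, shift)
    counts, starts, order = _counting_sort(cells, params.n_cells)
    axes = _random_axes(rng, params.n_cells)
    alpha = np.deg2rad(params.alpha0_deg)
    if apply_thermostat:
        e_target = _draw_cell_energies(rng, counts, params.kBT)
    else:
        e_target = np.zeros(params.n_cells)
    removed = _srd_cell_kernel(all_vel, all_mass, starts, order, axes,
                               np.cos(alpha), np.sin(alpha), e_target,
                               True, apply_thermostat)
    nf = state.velocities.shape[0]
    if embedded_vel is None:
        state.velocities = all_vel
    else:
        state.velocities[:] = all_vel[:nf]
        embedded_vel[:] = all_vel[nf:]
    return removed, cells, counts


def _draw_cell_energies(rng: np.random.Generator, counts: np.ndarray,
                        kBT: float) -> np.ndarray:
    """Canonical relative kinetic energies: Gamma(3(Nc-1)/2, kBT) per cell."""
    shape = 1.5 * np.clip(counts - 1, 0, None).astype(float)
    return rng.gamma(shape, kBT)


def thermostat(state: FluidState, params: FluidParams, rng: np.random.Generator,
               cells: np.ndarray,
               embedded_vel: np.ndarray | None = None,
               embedded_mass: np.ndarray | None = None) -> float:
    """Cell-level canonical (Maxwell-Boltzmann scaling) thermostat.

    Each cell's kinetic energy relative to its center-of-mass motion is
    rescaled to an exact draw from the canonical gamma distribution with
    3(Nc-1)/2 degrees-of-freedom pairs at kBT; the cell momentum is unchanged.
    Cells with fewer than two particles are untouched.  Returns the signed
    energy removed (positive when energy flowed out of the system).
    """
    if embedded_vel is None:
        all_vel = state.velocities
        all_mass = state.masses
    else:
        all_vel = np.concatenate([state.velocities, embedded_vel])
        all_mass = np.concatenate([state.masses, embedded_mass])
    counts, starts, order = _counting_sort(cells, params.n_cells)
    e_target = _draw_cell_energies(rng, counts, params.kBT)
    removed = _srd_cell_kernel(all_vel, all_mass, starts, order, _EMPTY,
                               1.0, 0.0, e_target, False, True)
    nf = state.velocities.shape[0]
    if embedded_vel is not None:
        state.velocities[:] = all_vel[:nf]
        embedded_vel[:] = all_vel[nf:]
    return removed


def kinetic_temperature(state: FluidState) -> float:
    """Instantaneous kinetic temperature, kBT = <m v^2>/3 (total momentum removed)."""
    p = (state.masses[:, None] * state.velocities).sum(axis=0)
    vcm = p / state.masses.sum()
    rel = state.velocities - vcm
    ke = 0.5 * (state.masses * (rel * rel).sum(axis=1)).sum()
    ndof = 3 * (state.positions.shape[0] - 1)
    return 2.0 * ke / ndof


# --------------------------------------------------------------------------
# transport-coefficient diagnostics
# --------------------------------------------------------------------------

def srd_viscosity_theory(params: FluidParams) -> dict[str, float]:
    """Kinetic-theory shear viscosity of the SRD fluid (kinetic + collisional).

    Standard molecular-chaos closed forms for stochastic rotation dynamics
    with a fluctuating (Poisson) cell occupancy of mean rho:

        eta_kin = (rho kBT h / a^3) * [ 5 rho /
                  ((rho - 1 + e^-rho)(2 - cos a0 - cos 2 a0)) - 1/2 ]
        eta_col = (m / (18 a h)) * (1 - cos a0) * (rho - 1 + e^-rho)
    """
    rho, h, a, m = params.rho, params.h, params.a, params.mass
    al = np.deg2rad(params.alpha0_deg)
    occ = rho - 1.0 + np.exp(-rho)
    eta_kin = (rho * params.kBT * h / a**3) * (
        5.0 * rho / (occ * (2.0 - np.cos(al) - np.cos(2.0 * al))) - 0.5)
    eta_col = (m / (18.0 * a * h)) * (1.0 - np.cos(al)) * occ
    return {"kinetic": float(eta_kin), "collisional": float(eta_col),
            "total": float(eta_kin + eta_col)}


def measure_viscosity(params: FluidParams, rng: np.random.Generator | None = None,
                      n_steps: int = 8000, n_equil: int = 200,
                      n_replicates: int = 3) -> dict[str, float]:
    """Shear viscosity from the equilibrium decay of transverse momentum modes.

    Tracks the complex amplitudes of the six transverse velocity modes at the
    fundamental wave vector along each box axis; their autocorrelation decays
    as exp(-nu k^2 t) with nu = eta a^3/(rho m).  Independent replicate runs
    are pooled (6 x n_replicates mode estimates) to suppress the slow
    large-scale velocity fluctuations that dominate the estimator variance.
    Returns the estimate with a standard error from the mode-to-mode spread;
    a large relative error (>0.2) marks insufficient sampling.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    box = params.box
    k = 2.0 * np.pi / box  # fundamental along each axis
    # (axis of k, velocity component) pairs, component transverse to k
    modes = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    nus = []
    for _ in range(n_replicates):
        state = init_fluid(params, rng)
        amps = np.empty((n_steps, len(modes)), dtype=complex)
        for step in range(n_equil + n_steps):
            stream(state, params.h, box)
            collide(state, params, rng, apply_thermostat=True)
            if step >= n_equil:
                for j, (ax, comp) in enumerate(modes):
                    phase = np.exp(1j * k[ax] * state.positions[:, ax])
                    amps[step - n_equil, j] = \
                        (state.velocities[:, comp] * phase).sum()
        for j, (ax, comp) in enumerate(modes):
            c = _autocorr(amps[:, j])
            # log-linear fit over the initial decay (down to ~0.4)
            n_fit = int(np.argmax(c < 0.4)) if np.any(c < 0.4) else len(c)
            n_fit = max(n_fit, 8)
            t = np.arange(n_fit) * params.h
            slope = np.polyfit(t, np.log(np.clip(c[:n_fit], 1e-12, None)), 1)[0]
            nus.append(-slope / k[ax] ** 2)
    nus = np.asarray(nus)
    rho_m = params.rho * params.mass / params.a**3
    eta = float(nus.mean() * rho_m)
    err = float(nus.std(ddof=1) / np.sqrt(len(nus)) * rho_m)
    return {"eta": eta, "stderr": err,
            "flagged": bool(err > 0.2 * abs(eta))}


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of a (complex) series via FFT."""
    n = len(x)
    x = x - x.mean()
    f = np.fft.fft(x, 2 * n)
    acf = np.fft.ifft(f * np.conj(f))[:n].real
    acf /= np.arange(n, 0, -1)
    return acf / acf[0]
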