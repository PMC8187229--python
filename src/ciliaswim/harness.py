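"""Experiment configuration, presets, synthetic fixtures and serialization.

Presets encode the study conditions (body of radius R = 8a with 643 mesh
particles, cilia of length L = 1.375 R with 26 beads per filament, fluid
h = 0.05, alpha0 = 130 deg, rho = 10, box (100a)^3) together with two
scaled-down variants that preserve the dimensionless geometry ratios
(L/R, (3/16)R/R, d/L): "reduced" (R = 4a, box (32a)^3) and the smaller
"tiny" (R = 3a, box (20a)^3) used for desk-scale property tests.  Beat
periods are chosen to keep the swimmer Reynolds number rho R^2/(tau_b eta_f)
near 0.2 at every scale.

The synthetic-helix generator produces orientation/center time series of an
ideal helical swimmer — axis n(t) = cos(alpha) e_par + sin(alpha) e_perp(t)
with e_perp rotating at Omega_c — optionally blurred by isotropic rotational
diffusion at rate kappa/2, which makes the orientation autocorrelation decay
exactly as (cos^2 a + sin^2 a cos(Omega_c tau)) e^(-kappa tau).  These series
are the independent fixtures for the trajectory-analysis layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import swimmer as sw
from .beat import StrokeProgram, TriggerRule, WavePattern, phase_field
from .integrator import SimulationState, make_simulation, run
from .kinematics import Trajectory
from .mpc_fluid import FluidParams

__all__ = [
    "ExperimentConfig",
    "SyntheticHelixSpec",
    "preset",
    "build_assembly",
    "build_simulation",
    "run_experiment",
    "generate_synthetic_helix",
    "write_trajectory",
    "read_trajectory",
    "export_trajectory_xyz",
    "write_vtk_polydata",
    "export_assembly_vtk",
    "seed_streams",
]

SCHEMA_VERSION = "1"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class BodyConfig:
    R: float = 8.0
    target_vertex_count: int = 642
    mass: float = 10.0


@dataclass
class CiliaConfig:
    L: float = 11.0
    n_beads: int = 26
    k_backbone: float = 5000.0
    k_cross: float = 2000.0
    k_anchor: float = 5000.0


@dataclass
class PlacementConfig:
    mode: str = "rings"            # rings | random
    n_eq: int = 7
    theta_r_deg: float = 0.0
    n_total: int = 17              # random mode
    min_sep: float = 4.0           # arc length, random mode
    pole_exclusion: float = 2.0    # arc length, random mode


@dataclass
class BeatConfig:
    tau_p: float = 60.0
    tau_r: float = 120.0
    k_phi: int = 0
    chi_deg: float = 0.0
    eps_max: float = 1.0
    mode: str = "deterministic"    # deterministic | selforganized
    c0_L: float = 0.25
    c1_L: float = 5.0
    w_L: float = 0.4
    beta_max_deg: float = 45.0
    trigger_c_crit_L: float = 1.5  # critical curvature in units of 1/L
    trigger_angle_deg: float = 60.0


@dataclass
class RunSettings:
    n_beat_periods: float = 4.0
    md_substeps_per_h: int = 50
    output_stride: int = 10
    seed: int = 0


@dataclass
class ExperimentConfig:
    """Full run configuration; every default is recorded in the provenance."""

    fluid: FluidParams = field(default_factory=FluidParams)
    body: BodyConfig = field(default_factory=BodyConfig)
    cilia: CiliaConfig = field(default_factory=CiliaConfig)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    beat: BeatConfig = field(default_factory=BeatConfig)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fluid"]["box_lengths"] = list(self.fluid.box_lengths)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d.pop("schema_version", None)
        fl = dict(d["fluid"])
        fl["box_lengths"] = tuple(fl["box_lengths"])
        return cls(fluid=FluidParams(**fl), body=BodyConfig(**d["body"]),
                   cilia=CiliaConfig(**d["cilia"]),
                   placement=PlacementConfig(**d["placement"]),
                   beat=BeatConfig(**d["beat"]), run=RunSettings(**d["run"]))

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_SCALES = {
    # R, box edge, vertex count, n_beads, tau_b
    "full": (8.0, 100, 642, 26, 180.0),
    "reduced": (4.0, 32, 162, 13, 45.0),
    "tiny": (3.0, 20, 162, 10, 32.0),
}


def preset(name: str, scale: str = "full", seed: int = 0) -> ExperimentConfig:
    """Named experiment presets: "5-7-5", "4-6-4" or "random-N".

    ``scale`` selects the full study conditions or a geometry-preserving
    scaled-down variant ("reduced", "tiny") for desk-scale runs.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    R, edge, nverts, n_beads, tau_b = _SCALES[scale]
    cfg = ExperimentConfig()
    cfg.fluid = FluidParams(box_lengths=(edge, edge, edge), seed=seed)
    cfg.body = BodyConfig(R=R, target_vertex_count=nverts)
    cfg.cilia = CiliaConfig(L=1.375 * R, n_beads=n_beads)
    cfg.beat.tau_p = tau_b / 3.0
    cfg.beat.tau_r = 2.0 * tau_b / 3.0
    cfg.run.seed = seed
    if name == "5-7-5":
        cfg.placement = PlacementConfig(mode="rings", n_eq=7)
    elif name == "4-6-4":
        cfg.placement = PlacementConfig(mode="rings", n_eq=6)
    elif name == "random-N":
        d = sw.mean_cilia_spacing(R, 17)
        cfg.placement = PlacementConfig(mode="random", n_total=17,
                                        min_sep=0.5 * d,
                                        pole_exclusion=0.5 * d)
        cfg.beat.mode = "selforganized"
    else:
        raise ValueError(f"unknown preset {name!r}")
    return cfg


# --------------------------------------------------------------------------
# building and running
# --------------------------------------------------------------------------

def seed_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Expand one seed into named independent generators (order-stable)."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def build_assembly(cfg: ExperimentConfig) -> sw.SwimmerAssembly:
    mesh = sw.build_body(cfg.body.R, cfg.body.target_vertex_count,
                         mass=cfg.body.mass, kBT=cfg.fluid.kBT)
    pc = cfg.placement
    if pc.mode == "rings":
        sites = sw.place_cilia_rings(pc.n_eq, pc.theta_r_deg)
    elif pc.mode == "random":
        rng = seed_streams(cfg.run.seed, "placement")["placement"]
        sites = sw.place_cilia_random(pc.n_total, cfg.body.R, pc.min_sep,
                                      pc.pole_exclusion, rng)
    else:
        raise ValueError(f"unknown placement mode {pc.mode!r}")
    pattern = WavePattern.from_chi(cfg.beat.chi_deg, cfg.beat.k_phi)
    cilia, phases = [], []
    for (phi, theta, tr) in sites:
        c = sw.build_cilium(cfg.body.R, cfg.cilia.L, cfg.cilia.n_beads,
                            (phi, theta), tr,
                            k_backbone=cfg.cilia.k_backbone,
                            k_cross=cfg.cilia.k_cross)
        sw.anchor_cilium(c, mesh, k_anchor=cfg.cilia.k_anchor)
        cilia.append(c)
        phases.append(phase_field(phi, theta, pattern))
    return sw.assemble(mesh, cilia, phases)


def stroke_program(cfg: ExperimentConfig) -> StrokeProgram:
    b = cfg.beat
    return StrokeProgram(tau_p=b.tau_p, tau_r=b.tau_r, c0_L=b.c0_L,
                         c1_L=b.c1_L, w_L=b.w_L,
                         beta_max_deg=b.beta_max_deg, eps_max=b.eps_max)


def build_simulation(cfg: ExperimentConfig,
                     assembly: sw.SwimmerAssembly | None = None
                     ) -> SimulationState:
    if assembly is None:
        assembly = build_assembly(cfg)
    trig = None
    if cfg.beat.mode == "selforganized":
        trig = TriggerRule(cfg.beat.trigger_c_crit_L / cfg.cilia.L,
                           cfg.beat.trigger_angle_deg)
    return make_simulation(assembly, cfg.fluid, stroke_program(cfg),
                           seed=cfg.run.seed,
                           md_substeps_per_h=cfg.run.md_substeps_per_h,
                           mode=cfg.beat.mode, trigger=trig)


def run_experiment(cfg: ExperimentConfig) -> Trajectory:
    """Build, run and annotate a full experiment from its configuration."""
    sim = build_simulation(cfg)
    tau_b = sim.program.tau_b
    n_steps = int(round(cfg.run.n_beat_periods * tau_b / cfg.fluid.h))
    traj = run(sim, n_steps, cfg.run.output_stride)
    traj.meta["provenance"] = cfg.to_dict()
    traj.meta["R"] = cfg.body.R
    traj.meta["L"] = cfg.cilia.L
    return traj


# --------------------------------------------------------------------------
# synthetic helical trajectories
# --------------------------------------------------------------------------

@dataclass
class SyntheticHelixSpec:
    """Parameters of an ideal (optionally noisy) helical swimmer fixture."""

    alpha_deg: float = 30.0
    omega_c: float = 0.5          # circling frequency, rad/time
    kappa: float = 0.0            # decorrelation rate (noise mode only)
    v_n: float = 1.0
    omega_n: float = 0.0          # body spin, rad/time
    duration: float = 200.0
    dt: float = 0.1
    noise: str = "none"           # none | rotational_diffusion
    seed: int = 0


def generate_synthetic_helix(spec: SyntheticHelixSpec,
                             rng: np.random.Generator | None = None
                             ) -> Trajectory:
    """Orientation/center series of an ideal helical swimmer.

    Noise mode "rotational_diffusion" applies an isotropic random rotation of
    the helix frame each step with diffusion coefficient kappa/2, so the axis
    autocorrelation decays with the extra factor e^(-kappa tau).  The marker
    co-rotates about n at omega_n on top of parallel transport, so the spin
    estimator recovers omega_n exactly in the noise-free case.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.duration / spec.dt)) + 1
    times = np.arange(n_t) * spec.dt
    al = np.deg2rad(spec.alpha_deg)
    frame = np.eye(3)  # columns: ex, ey, e_par
    axis = np.empty((n_t, 3))
    marker = np.empty((n_t, 3))
    center = np.empty((n_t, 3))
    center[0] = 0.0
    d_noise = 0.5 * spec.kappa if spec.noise == "rotational_diffusion" else 0.0
    sigma = np.sqrt(2.0 * d_noise * spec.dt)
    m_prev = None
    for i, t in enumerate(times):
        e_perp = frame[:, 0] * np.cos(spec.omega_c * t) + \
            frame[:, 1] * np.sin(spec.omega_c * t)
        n = np.cos(al) * frame[:, 2] + np.sin(al) * e_perp
        n /= np.linalg.norm(n)
        axis[i] = n
        if m_prev is None:
            m = frame[:, 1] if abs(n[1]) < 0.9 else frame[:, 0]
            m = m - (m @ n) * n
            m /= np.linalg.norm(m)
        else:
            m = _transport_vec(m_prev, axis[i - 1], n)
            m = _rotate_vec(m, n, spec.omega_n * spec.dt)
            m = m - (m @ n) * n
            m /= np.linalg.norm(m)
        marker[i] = m
        m_prev = m
        if i + 1 < n_t:
            center[i + 1] = center[i] + spec.v_n * n * spec.dt
            if sigma > 0.0:
                rot = _rotation_matrix(rng.normal(0.0, sigma, size=3))
                frame = rot @ frame
    return Trajectory(times=times, center=center, axis=axis, marker=marker,
                      meta={"synthetic": asdict(spec)})


def _rotate_vec(v, axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _transport_vec(v, a, b):
    ax = np.cross(a, b)
    s = np.linalg.norm(ax)
    if s < 1e-15:
        return v.copy()
    ax = ax / s
    ang = np.arctan2(s, np.clip(a @ b, -1, 1))
    return _rotate_vec(v, ax, ang)


def _rotation_matrix(phi_vec: np.ndarray) -> np.ndarray:
    ang = np.linalg.norm(phi_vec)
    if ang < 1e-15:
        return np.eye(3)
    k = phi_vec / ang
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * kx @ kx


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def write_trajectory(path: str, traj: Trajectory) -> None:
    """Lossless, schema-versioned trajectory container (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["meta"] = json.dumps(traj.meta, default=_json_default)
        f.create_dataset("time", data=traj.times)
        f.create_dataset("center", data=traj.center)
        f.create_dataset("axis_n", data=traj.axis)
        f.create_dataset("marker", data=traj.marker)
        if traj.work_in is not None:
            f.create_dataset("Win", data=traj.work_in)
        if traj.energy_removed is not None:
            f.create_dataset("Eremoved", data=traj.energy_removed)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_trajectory(path: str) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported trajectory schema {f.attrs.get('schema_version')!r}")
        return Trajectory(
            times=f["time"][...], center=f["center"][...],
            axis=f["axis_n"][...], marker=f["marker"][...],
            work_in=f["Win"][...] if "Win" in f else None,
            energy_removed=f["Eremoved"][...] if "Eremoved" in f else None,
            meta=json.loads(f.attrs["meta"]))


def export_trajectory_xyz(path: str, traj: Trajectory, stride: int = 1) -> None:
    """XYZ dump for external viewers: center (C), axis tip (N), marker tip (M)."""
    with open(path, "w") as fh:
        for i in range(0, len(traj), stride):
            fh.write("3\n")
            fh.write(f"t={traj.times[i]:.6g}\n")
            c = traj.center[i]
            n = c + traj.axis[i]
            m = c + traj.marker[i]
            fh.write(f"C {c[0]:.8g} {c[1]:.8g} {c[2]:.8g}\n")
            fh.write(f"N {n[0]:.8g} {n[1]:.8g} {n[2]:.8g}\n")
            fh.write(f"M {m[0]:.8g} {m[1]:.8g} {m[2]:.8g}\n")


def write_vtk_polydata(path: str, points: np.ndarray,
                       lines: np.ndarray | None = None) -> None:
    """Minimal legacy-ASCII VTK PolyData writer (points + line cells)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nciliaswim scene\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        if lines is not None and len(lines):
            fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
            for (i, j) in lines:
                fh.write(f"2 {i} {j}\n")


def export_assembly_vtk(path: str, assembly: sw.SwimmerAssembly) -> None:
    springs = np.stack([assembly.spring_i, assembly.spring_j], axis=1)
    write_vtk_polydata(path, assembly.positions, springs)
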