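"""Construction of the ciliated-microswimmer body and cilia.

The body is a sphere of radius R triangulated by icosahedral subdivision:
surface vertices are joined to their mesh neighbors and to a center particle
by stiff harmonic springs, which makes the body essentially rigid.  Two
antipodal vertices (the subdivision poles, placed on +-z at build time) define
the body-fixed main axis n.

Each cilium is three semiflexible bead-spring filaments arranged as a prism
with an equilateral triangular cross-section; inter-filament cross-links
(in-plane and diagonal) retain the prism shape.  The cilium extends a segment
of length (3/16)R below the sphere surface, and beads 1 and 4 of every
filament are tied by stiff springs to the nearest surface vertex and that
vertex's neighbors — a clamped anchoring that mimics an embedded basal body.

Cilia are placed either on three latitudinal rings (equator and +-45 deg,
polar counts reduced by ~1/cos 45 = sqrt 2) or randomly with a
minimum-separation and pole-exclusion constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BodyMesh",
    "Cilium",
    "SwimmerAssembly",
    "build_body",
    "build_cilium",
    "anchor_cilium",
    "place_cilia_rings",
    "place_cilia_random",
    "assemble",
    "icosphere",
    "local_frame",
    "DEFAULT_MASS",
]

# swimmer particles are heavy: M = rho a^3 m gives good no-slip coupling
DEFAULT_MASS = 10.0


# --------------------------------------------------------------------------
# icosphere mesh
# --------------------------------------------------------------------------

def icosphere(subdivision: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere with the two 5-valence poles exactly on +-z.

    Returns (vertices, faces); vertex 0 is the north pole, vertex 1 the south
    pole.  Level n has 10*4^n + 2 vertices, 20*4^n faces, 30*4^n edges.
    """
    # icosahedron in polar orientation: 2 poles + two staggered rings of 5
    lat = np.arctan(0.5)
    verts = [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0)]
    for i in range(5):  # upper ring
        phi = 2.0 * np.pi * i / 5.0
        verts.append((np.cos(lat) * np.cos(phi), np.cos(lat) * np.sin(phi),
                      np.sin(lat)))
    for i in range(5):  # lower ring, offset by 36 deg
        phi = 2.0 * np.pi * (i + 0.5) / 5.0
        verts.append((np.cos(lat) * np.cos(phi), np.cos(lat) * np.sin(phi),
                      -np.sin(lat)))
    u = [2, 3, 4, 5, 6]
    l = [7, 8, 9, 10, 11]
    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append((0, u[i], u[j]))
        faces.append((1, l[j], l[i]))
        faces.append((u[i], l[i], u[j]))
        faces.append((u[j], l[i], l[j]))
    verts = [np.asarray(v) for v in verts]
    for _ in range(subdivision):
        midpoint: dict[tuple[int, int], int] = {}
        new_faces = []

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                verts.append(m)
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        for (i, j, k) in faces:
            a, b, c = mid(i, j), mid(j, k), mid(k, i)
            new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
        faces = new_faces
    return np.asarray(verts), np.asarray(faces, dtype=np.int64)


def _edges_from_faces(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


@dataclass
class BodyMesh:
    """Spring-mesh sphere: surface triangulation plus a center particle."""

    R: float
    vertices: np.ndarray        # (Ns, 3) body frame, |v| = R
    faces: np.ndarray           # (F, 3)
    edges: np.ndarray           # (E, 2)
    edge_rest: np.ndarray
    edge_k: np.ndarray
    radial_k: np.ndarray        # surface -> center springs, rest = R
    polar_pair: tuple[int, int]  # (north, south) vertex indices, on +-z
    mass: float = DEFAULT_MASS

    @property
    def n_surface(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_particles(self) -> int:
        return self.n_surface + 1  # + center

    def neighbor_lists(self) -> list[np.ndarray]:
        nb = [[] for _ in range(self.n_surface)]
        for i, j in self.edges:
            nb[i].append(j)
            nb[j].append(i)
        return [np.asarray(sorted(x), dtype=np.int64) for x in nb]

    @property
    def mean_edge_length(self) -> float:
        return float(self.edge_rest.mean())


def build_body(R: float, target_vertex_count: int = 642,
               accept_nearest: bool = False, mass: float = DEFAULT_MASS,
               fluctuation_fraction: float = 0.02,
               kBT: float = 1.0) -> BodyMesh:
    """Icosphere spring mesh of radius R with ~target_vertex_count surface vertices.

    The default (642 surface vertices, subdivision 3) plus the center particle
    gives the 643-particle body.  Spring stiffness is set per spring so the
    thermal bond-length fluctuation sqrt(kBT/k) stays below
    ``fluctuation_fraction`` of the rest length.
    """
    n = (target_vertex_count - 2) / 10.0
    level = np.log(n) / np.log(4.0) if n > 0 else -1.0
    if abs(level - round(level)) > 1e-9:
        if not accept_nearest:
            raise ValueError(
                f"{target_vertex_count} surface vertices is not 10*4^n + 2; "
                "pass accept_nearest=True for the closest subdivision")
        level = max(round(level), 0)
    level = int(round(level))
    verts, faces = icosphere(level)
    verts = verts * R
    edges = _edges_from_faces(faces)
    rest = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    sigma = fluctuation_fraction
    edge_k = kBT / (sigma * rest) ** 2
    radial_k = np.full(len(verts), kBT / (sigma * R) ** 2)
    return BodyMesh(R=R, vertices=verts, faces=faces, edges=edges,
                    edge_rest=rest, edge_k=edge_k, radial_k=radial_k,
                    polar_pair=(0, 1), mass=mass)


# --------------------------------------------------------------------------
# local surface frames
# --------------------------------------------------------------------------

def local_frame(phi_deg: float, theta_deg: float, theta_r_deg: float = 0.0):
    """(e_r, p, q) at longitude phi, latitude theta (theta=0 is the equator).

    p is the power-stroke direction: the local polar direction e_theta
    (towards the north pole) rotated about e_r by the tilt theta_r; q = e_r x p
    completes the right-handed triad (q is the beat-plane normal).
    """
    phi = np.deg2rad(phi_deg)
    th = np.deg2rad(theta_deg)
    e_r = np.array([np.cos(th) * np.cos(phi), np.cos(th) * np.sin(phi),
                    np.sin(th)])
    e_th = np.array([-np.sin(th) * np.cos(phi), -np.sin(th) * np.sin(phi),
                     np.cos(th)])
    e_ph = np.array([-np.sin(phi), np.cos(phi), 0.0])
    tr = np.deg2rad(theta_r_deg)
    p = np.cos(tr) * e_th + np.sin(tr) * e_ph
    q = np.cross(e_r, p)
    return e_r, p, q


# --------------------------------------------------------------------------
# cilium construction
# --------------------------------------------------------------------------

@dataclass
class Cilium:
    """Three-filament prism cilium in body-frame coordinates (pre-assembly)."""

    R: float
    L: float
    n_beads: int                 # beads per filament (N_c)
    bond_rest: float             # l_c
    side: float                  # cross-section triangle side
    positions: np.ndarray        # (3, N_c, 3) as-built bead positions
    bonds: np.ndarray            # (n_bonds, 2) local bead index pairs
    bond_k: np.ndarray
    bond_rest0: np.ndarray
    active_bonds: np.ndarray     # local bond indices of the active filament
    bond_s: np.ndarray           # arclength above the surface at bond midpoints
    base: tuple[float, float]    # (phi_deg, theta_deg)
    theta_r_deg: float
    e_r: np.ndarray
    p: np.ndarray                # power-stroke direction (beat plane = span(e_r, p))
    q: np.ndarray                # beat-plane normal
    pivot: np.ndarray            # base point on the sphere surface
    active_filament: int = 0
    # filled by anchor_cilium:
    anchor_bead: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    anchor_vertex: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    anchor_rest: np.ndarray = field(default_factory=lambda: np.empty(0))
    anchor_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    # curvature-modulated springs (active bonds + active-passive diagonals):
    # rest(c) = sqrt((axial (1 - c arm))^2 + trans^2) evaluated at s
    mod_springs: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mod_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    mod_axial: np.ndarray = field(default_factory=lambda: np.empty(0))
    mod_trans: np.ndarray = field(default_factory=lambda: np.empty(0))
    mod_arm: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_particles(self) -> int:
        return 3 * self.n_beads

    def flat_positions(self) -> np.ndarray:
        return self.positions.reshape(-1, 3)


def build_cilium(R: float, L: float, n_beads: int,
                 base: tuple[float, float], theta_r_deg: float = 0.0,
                 k_backbone: float = 5000.0, k_cross: float = 2000.0,
                 k_next: float = 2500.0,
                 side: float | None = None) -> Cilium:
    """Straight radial three-filament cilium of outside length L at ``base``.

    The filaments span L + (3/16)R along e_r (the sub-surface clamped segment
    is (3/16)R), with n_beads beads and n_beads-1 bonds of rest length
    l_c = (L + (3/16)R)/(n_beads-1) each.  The active filament (index 0) sits
    on the +p side of the cross-section, so shortening its bonds bends the
    cilium towards the power-stroke direction p.

    Next-nearest-neighbor springs (rest 2 l_c, stiffness k_next) along every
    filament suppress the sharp-fold mode of the prism, which would otherwise
    be a zero-energy deformation of the pairwise spring network; their cost
    under smooth bending is only fourth order in the curvature.
    """
    if not (-180.0 <= theta_r_deg < 180.0):
        raise ValueError("theta_r must be in [-180, 180) degrees")
    inner = (3.0 / 16.0) * R
    span = L + inner
    l_c = span / (n_beads - 1)
    if side is None:
        side = l_c
    e_r, p, q = local_frame(base[0], base[1], theta_r_deg)
    pivot = R * e_r
    # equilateral cross-section, circumradius side/sqrt(3); active at +p
    d = side / np.sqrt(3.0)
    offsets = [d * (np.cos(a) * p + np.sin(a) * q)
               for a in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)]
    radii = (R - inner) + l_c * np.arange(n_beads)
    pos = np.empty((3, n_beads, 3))
    for f in range(3):
        pos[f] = radii[:, None] * e_r[None, :] + offsets[f][None, :]

    def gid(f, i):
        return f * n_beads + i

    # bending moment arm: distance from the active filament to the neutral
    # line through the two passive filaments
    arm = (np.sqrt(3.0) / 2.0) * side
    bonds, rest0, ks, active, s_mid = [], [], [], [], []
    mod_springs, mod_s, mod_axial, mod_trans, mod_arm = [], [], [], [], []
    flat = pos.reshape(-1, 3)
    for f in range(3):
        for i in range(n_beads - 1):
            bonds.append((gid(f, i), gid(f, i + 1)))
            rest0.append(l_c)
            ks.append(k_backbone)
            if f == 0:
                active.append(len(bonds) - 1)
                s_mid.append((i + 0.5) * l_c - inner)
                mod_springs.append(len(bonds) - 1)
                mod_s.append(s_mid[-1])
                mod_axial.append(l_c)
                mod_trans.append(0.0)
                mod_arm.append(arm)
        for i in range(n_beads - 2):   # anti-fold springs
            bonds.append((gid(f, i), gid(f, i + 2)))
            rest0.append(2.0 * l_c)
            ks.append(k_next)
            if f == 0:
                # follow the active filament's programmed strain, otherwise
                # these springs would fight the imposed curvature head-on
                mod_springs.append(len(bonds) - 1)
                mod_s.append((i + 1.0) * l_c - inner)
                mod_axial.append(2.0 * l_c)
                mod_trans.append(0.0)
                mod_arm.append(arm)
    # in-plane triangle links and both diagonals per level
    for i in range(n_beads):
        for f in range(3):
            g = (f + 1) % 3
            bonds.append((gid(f, i), gid(g, i)))
            rest0.append(side)
            ks.append(k_cross)
            if i + 1 < n_beads:
                for (aa, bb) in ((f, g), (g, f)):
                    bonds.append((gid(aa, i), gid(bb, i + 1)))
                    rest0.append(float(np.linalg.norm(
                        flat[gid(aa, i)] - flat[gid(bb, i + 1)])))
                    ks.append(k_cross)
                    if 0 in (aa, bb):
                        # active-passive diagonal: mid-section offset sits
                        # halfway between active filament and neutral line
                        mod_springs.append(len(bonds) - 1)
                        mod_s.append((i + 0.5) * l_c - inner)
                        mod_axial.append(l_c)
                        mod_trans.append(side)
                        mod_arm.append(0.5 * arm)
    return Cilium(R=R, L=L, n_beads=n_beads, bond_rest=l_c, side=side,
                  positions=pos, bonds=np.asarray(bonds, dtype=np.int64),
                  bond_k=np.asarray(ks), bond_rest0=np.asarray(rest0),
                  active_bonds=np.asarray(active, dtype=np.int64),
                  bond_s=np.asarray(s_mid), base=base,
                  theta_r_deg=theta_r_deg, e_r=e_r, p=p, q=q, pivot=pivot,
                  mod_springs=np.asarray(mod_springs, dtype=np.int64),
                  mod_s=np.asarray(mod_s), mod_axial=np.asarray(mod_axial),
                  mod_trans=np.asarray(mod_trans), mod_arm=np.asarray(mod_arm))


def anchor_cilium(cilium: Cilium, mesh: BodyMesh,
                  k_anchor: float = 5000.0,
                  anchored_beads: tuple[int, ...] = (0, 3)) -> Cilium:
    """Clamp the cilium to the body mesh.

    Beads 1 and 4 (indices 0 and 3, counted from the inner end) of each
    filament are connected to the surface vertex closest to the cilium base
    and to that vertex's neighbors; rest lengths are the as-built distances.
    """
    d2 = ((mesh.vertices - cilium.pivot) ** 2).sum(axis=1)
    nearest = int(np.argmin(d2))
    if np.sqrt(d2[nearest]) > mesh.mean_edge_length:
        raise ValueError("cilium base is farther than one edge length from "
                         "every surface vertex")
    targets = np.concatenate([[nearest], mesh.neighbor_lists()[nearest]])
    flat = cilium.flat_positions()
    ab, av, ar = [], [], []
    for f in range(3):
        for i in anchored_beads:
            g = f * cilium.n_beads + i
            for v in targets:
                ab.append(g)
                av.append(v)
                ar.append(float(np.linalg.norm(flat[g] - mesh.vertices[v])))
    cilium.anchor_bead = np.asarray(ab, dtype=np.int64)
    cilium.anchor_vertex = np.asarray(av, dtype=np.int64)
    cilium.anchor_rest = np.asarray(ar)
    cilium.anchor_k = np.full(len(ar), k_anchor)
    return cilium


# --------------------------------------------------------------------------
# placement
# --------------------------------------------------------------------------

def place_cilia_rings(n_eq: int, theta_r_deg: float = 0.0
                      ) -> list[tuple[float, float, float]]:
    """Three-ring cilia placement: (phi, theta, theta_r) triples in degrees.

    n_eq cilia equally spaced on the equator starting at phi=0; round(n_eq/sqrt 2)
    on each ring at theta = +-45 deg, both shifted azimuthally by
    dphi = 180/n_eq in the same direction to avoid perfect registry.
    """
    if n_eq < 1:
        raise ValueError("need at least one equatorial cilium")
    n_pol = int(round(n_eq / np.sqrt(2.0)))
    dphi = 180.0 / n_eq
    out = []
    for theta in (45.0, 0.0, -45.0):
        count = n_eq if theta == 0.0 else n_pol
        off = 0.0 if theta == 0.0 else dphi
        for i in range(count):
            out.append(((off + 360.0 * i / count) % 360.0, theta, theta_r_deg))
    return out


def place_cilia_random(n: int, R: float, min_sep: float,
                       pole_exclusion: float,
                       rng: np.random.Generator,
                       max_tries: int = 20000
                       ) -> list[tuple[float, float, float]]:
    """Random cilia placement with minimum great-circle separation.

    min_sep and pole_exclusion are arc lengths on the sphere of radius R.
    Beat directions follow the local polar direction e_theta (theta_r = 0),
    which leaves the two unavoidable singularities of a tangent field at the
    excluded poles.  Raises if the packing is infeasible after max_tries.
    """
    placed: list[np.ndarray] = []
    out: list[tuple[float, float, float]] = []
    min_ang = min_sep / R
    excl_ang = pole_exclusion / R
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} cilia with min_sep={min_sep} after "
                f"{max_tries} tries; packing infeasible")
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        theta = np.arcsin(np.clip(v[2], -1, 1))
        if np.pi / 2 - abs(theta) < excl_ang:
            continue
        if placed and np.arccos(np.clip(np.asarray(placed) @ v, -1, 1)).min() < min_ang:
            continue
        placed.append(v)
        phi = np.degrees(np.arctan2(v[1], v[0])) % 360.0
        out.append((phi, float(np.degrees(theta)), 0.0))
    return out


def mean_cilia_spacing(R: float, n: int) -> float:
    """Estimated mean anchoring distance d ~ sqrt(4 pi R^2 / N)."""
    return float(np.sqrt(4.0 * np.pi * R * R / n))


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

@dataclass
class CiliumSlots:
    """Index bookkeeping for one cilium inside an assembly."""

    bead_offset: int              # first global particle index of this cilium
    spring_offset: int            # first global spring index
    active_springs: np.ndarray    # global spring indices of active bonds
    anchor_springs: np.ndarray    # global spring indices of anchor springs
    mod_springs: np.ndarray       # global indices of curvature-modulated springs
    mod_s: np.ndarray
    mod_axial: np.ndarray
    mod_trans: np.ndarray
    mod_arm: np.ndarray
    bond_s: np.ndarray
    bond_rest: float
    side: float
    L: float
    phase_deg: float              # metachronal phase Psi
    e_r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    pivot: np.ndarray
    anchor_bead_local: np.ndarray     # as-built bead offsets from pivot
    anchor_vertex_pos: np.ndarray     # as-built vertex positions (body frame)
    base_index: int               # global index of bead 0 of the active filament
    tip_index: int                # global index of the tip bead (active filament)
    n_beads: int


@dataclass
class SwimmerAssembly:
    """Flat particle/spring arrays for the whole swimmer, body frame at build."""

    mesh: BodyMesh
    positions: np.ndarray     # (Np, 3)
    masses: np.ndarray
    spring_i: np.ndarray
    spring_j: np.ndarray
    spring_k: np.ndarray
    spring_rest: np.ndarray
    center_index: int
    polar_pair: tuple[int, int]
    marker_index: int
    cilia: list[CiliumSlots]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def axis(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        d = pos[self.polar_pair[0]] - pos[self.polar_pair[1]]
        return d / np.linalg.norm(d)

    def marker(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        n = self.axis(positions)
        m = pos[self.marker_index] - pos[self.center_index]
        m = m - (m @ n) * n
        return m / np.linalg.norm(m)


def assemble(mesh: BodyMesh, cilia: list[Cilium],
             phases_deg: list[float] | None = None) -> SwimmerAssembly:
    """Concatenate body and (anchored) cilia into flat particle/spring tables."""
    if phases_deg is None:
        phases_deg = [0.0] * len(cilia)
    ns = mesh.n_surface
    center = ns
    pos = [mesh.vertices, np.zeros((1, 3))]
    si = [mesh.edges[:, 0], np.arange(ns)]
    sj = [mesh.edges[:, 1], np.full(ns, center)]
    sk = [mesh.edge_k, mesh.radial_k]
    sr = [mesh.edge_rest, np.full(ns, mesh.R)]
    n_part = ns + 1
    n_spr = len(mesh.edges) + ns
    slots = []
    for c, psi in zip(cilia, phases_deg):
        if len(c.anchor_bead) == 0:
            raise ValueError("cilium must be anchored before assembly")
        off = n_part
        soff = n_spr
        pos.append(c.flat_positions())
        si.append(c.bonds[:, 0] + off)
        sj.append(c.bonds[:, 1] + off)
        sk.append(c.bond_k)
        sr.append(c.bond_rest0)
        active = c.active_bonds + soff
        n_spr += len(c.bonds)
        anchor = np.arange(len(c.anchor_bead)) + n_spr
        si.append(c.anchor_bead + off)
        sj.append(c.anchor_vertex)  # vertices are global already
        sk.append(c.anchor_k)
        sr.append(c.anchor_rest)
        n_spr += len(c.anchor_bead)
        flat = c.flat_positions()
        slots.append(CiliumSlots(
            bead_offset=off, spring_offset=soff, active_springs=active,
            anchor_springs=anchor, mod_springs=c.mod_springs + soff,
            mod_s=c.mod_s, mod_axial=c.mod_axial, mod_trans=c.mod_trans,
            mod_arm=c.mod_arm, bond_s=c.bond_s, bond_rest=c.bond_rest,
            side=c.side, L=c.L, phase_deg=psi, e_r=c.e_r, p=c.p, q=c.q,
            pivot=c.pivot,
            anchor_bead_local=flat[c.anchor_bead] - c.pivot,
            anchor_vertex_pos=mesh.vertices[c.anchor_vertex].copy(),
            base_index=off, tip_index=off + c.n_beads - 1,
            n_beads=c.n_beads))
        n_part += c.n_particles
    positions = np.concatenate(pos)
    # equatorial marker: surface vertex closest to the equator at phi ~ 0
    eq_score = np.abs(positions[:ns, 2]) - positions[:ns, 0]
    marker = int(np.argmin(eq_score))
    return SwimmerAssembly(
        mesh=mesh, positions=positions,
        masses=np.full(n_part, mesh.mass),
        spring_i=np.concatenate(si).astype(np.int64),
        spring_j=np.concatenate(sj).astype(np.int64),
        spring_k=np.concatenate(sk).astype(float),
        spring_rest=np.concatenate(sr).astype(float),
        center_index=center, polar_pair=mesh.polar_pair, marker_index=marker,
        cilia=slots)
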