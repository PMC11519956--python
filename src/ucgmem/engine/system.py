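"""Particle container and system builders for every simulation geometry.

All builders produce lipids as (H, T, T) bead triplets on deterministic
lattices or seeded random placements, with the bonded lists the force
calculator consumes.  Coordinates are nm, orthorhombic periodic boxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ..constants import KB
from ..forcefield import ForceFieldParams, LipidTopology

logger = logging.getLogger(__name__)

TYPE_H, TYPE_T = 0, 1
TYPE_NAMES = {TYPE_H: "H", TYPE_T: "T"}


@dataclass
class ParticleSystem:
    """Beads in an orthorhombic periodic box.

    `molecules[i]` is the molecule index of bead i; lipids own exactly
    three consecutive beads (H, T1, T2).  `geometry` tags what the system
    is (bilayer / ribbon / two_phase / gas) so estimators can refuse
    geometries they do not apply to.
    """

    positions: np.ndarray          # (N, 3) nm
    velocities: np.ndarray         # (N, 3) nm/ps
    types: np.ndarray              # (N,) int
    masses: np.ndarray             # (N,) amu
    box: np.ndarray                # (3,) nm
    molecules: np.ndarray          # (N,) int
    bonds: np.ndarray              # (nb, 2) int
    angles: np.ndarray             # (na, 3) int, central bead second
    geometry: str = "bilayer"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecules.max()) + 1 if self.n_beads else 0

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            masses=self.masses.copy(),
            box=self.box.copy(),
            molecules=self.molecules.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            geometry=self.geometry,
            meta=dict(self.meta),
        )

    def wrap_molecules(self) -> None:
        """Wrap coordinates into the box keeping each molecule whole.

        The molecule's first bead anchors the image choice; the other
        beads follow so bonds never straddle the wrap.
        """
        anchor_idx = np.searchsorted(self.molecules, np.arange(self.n_molecules))
        anchors = self.positions[anchor_idx]
        shift = np.floor(anchors / self.box) * self.box
        self.positions -= shift[self.molecules]

    def thermalize(self, temperature: float, rng: np.random.Generator) -> None:
        """Draw Maxwell-Boltzmann velocities and remove net momentum."""
        sigma = np.sqrt(KB * temperature / self.masses)[:, None]
        self.velocities = rng.standard_normal((self.n_beads, 3)) * sigma
        p = (self.masses[:, None] * self.velocities).sum(axis=0)
        self.velocities -= p / self.masses.sum()


def _assemble(
    lipid_coords: list[np.ndarray],
    box: np.ndarray,
    topology: LipidTopology,
    geometry: str,
    meta: dict | None = None,
) -> ParticleSystem:
    n_lip = len(lipid_coords)
    positions = np.concatenate(lipid_coords, axis=0)
    molecules = np.repeat(np.arange(n_lip), 3)
    types = np.tile([TYPE_H, TYPE_T, TYPE_T], n_lip)
    masses = np.full(3 * n_lip, topology.bead_mass)
    base = 3 * np.arange(n_lip)[:, None]
    bonds = np.concatenate([base + np.array([[0, 1]]), base + np.array([[0, 2]])])
    bonds = bonds[np.argsort(bonds[:, 0], kind="stable")]
    angles = base + np.array([[1, 0, 2]])
    return ParticleSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        types=types,
        masses=masses,
        box=np.asarray(box, dtype=float),
        molecules=molecules,
        bonds=bonds.astype(int),
        angles=angles.astype(int),
        geometry=geometry,
        meta=meta or {},
    )


def _lipid(
    head: np.ndarray, direction: int, topology: LipidTopology, splay_axis: int = 0
) -> np.ndarray:
    """Coordinates of one lipid with tails pointing along -direction*z.

    The two H-T bonds are at equilibrium length, splayed half the
    equilibrium angle to each side of the z axis along `splay_axis`
    (0 = x, 1 = y) so the T-H-T angle starts relaxed.
    """
    half = topology.theta0 / 2.0
    d_lat = topology.r0 * math.sin(half)
    dz = topology.r0 * math.cos(half) * direction
    offset = np.zeros(3)
    offset[splay_axis] = d_lat
    h = head
    t1 = head + offset + np.array([0.0, 0.0, -dz])
    t2 = head - offset + np.array([0.0, 0.0, -dz])
    return np.stack([h, t1, t2])


def _leaflet_grid(nx: int, ny: int, a: float) -> np.ndarray:
    """Lattice sites as rows of (ix, iy, x, y); checkerboard parity of
    (ix + iy) is used to alternate the tail splay axis so neighboring
    tails never start face-on."""
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    out = np.stack(
        [ix, iy, (ix + 0.5) * a, (iy + 0.5) * a], axis=-1
    ).reshape(-1, 4)
    return out


def _grid_shape(n: int) -> tuple[int, int]:
    nx = max(1, int(round(math.sqrt(n))))
    while n % nx:
        nx -= 1
    ny = n // nx
    if nx == 1 and n > 3:
        # prime n: fall back to the nearest rectangle-friendly count
        return _grid_shape(n + 1)
    return nx, ny


def build_bilayer(
    n_per_leaflet: int,
    apl0: float = 0.68,
    ff: ForceFieldParams | None = None,
    topology: LipidTopology | None = None,
    lz: float | None = None,
) -> ParticleSystem:
    """Flat two-leaflet bilayer on a square lattice, heads outward.

    Box area is exactly n_per_leaflet * apl0; the leaflet lattice is the
    factor pair of n_per_leaflet closest to square (a prime count is
    bumped by one and logged).
    """
    ff = ff or ForceFieldParams.optimal()
    top = topology or LipidTopology()
    nx, ny = _grid_shape(n_per_leaflet)
    n_actual = nx * ny
    if n_actual != n_per_leaflet:
        logger.warning("adjusted leaflet count %d -> %d for a rectangular lattice",
                       n_per_leaflet, n_actual)
    area = n_actual * apl0
    # keep the box area exact; the lattice constants follow the nx x ny shape
    lx = math.sqrt(area * nx / ny)
    ly = area / lx

    dz_tail = top.r0 * math.cos(top.theta0 / 2.0)
    z_head = 0.45 + dz_tail            # tail planes sit ~0.9 nm apart
    thickness = 2.0 * z_head
    lz = lz if lz is not None else max(3.0 * thickness, 2.0 * ff.r_cut + 0.5)
    z_mid = lz / 2.0

    sites = _leaflet_grid(nx, ny, lx / nx)
    sites[:, 3] *= (ly / ny) / (lx / nx)
    coords = []
    for direction, zh in ((+1, z_mid + z_head), (-1, z_mid - z_head)):
        for ix, iy, x, y in sites:
            axis = int(ix + iy) % 2
            coords.append(_lipid(np.array([x, y, zh]), direction, top, axis))
    sys_ = _assemble(coords, np.array([lx, ly, lz]), top, "bilayer",
                     meta={"n_per_leaflet": n_actual, "apl0": apl0})
    if min(lx, ly) < 2.0 * ff.r_cut:
        logger.warning("lateral box %.2f nm below twice the cutoff %.2f nm",
                       min(lx, ly), ff.r_cut)
    return sys_


def build_ribbon(
    n_lipids: int,
    apl0: float = 0.68,
    ff: ForceFieldParams | None = None,
    topology: LipidTopology | None = None,
) -> ParticleSystem:
    """Bilayer strip periodic in y with two free edges along x.

    The box leaves a vacuum margin of at least 2*r_cut on each side of
    the strip in x; the box is meant to stay fixed (no barostat).
    """
    ff = ff or ForceFieldParams.optimal()
    top = topology or LipidTopology()
    n_per_leaflet = n_lipids // 2
    a = math.sqrt(apl0)
    # strip roughly twice as long (periodic y) as wide, so the free-edge
    # fraction stays modest even for small systems
    nx = max(3, int(round(math.sqrt(n_per_leaflet / 2.0))))
    ny = n_per_leaflet // nx
    n_actual = nx * ny
    if 2 * n_actual != n_lipids:
        logger.warning("adjusted ribbon lipid count %d -> %d", n_lipids, 2 * n_actual)

    margin = 2.0 * ff.r_cut
    lx = nx * a + 2.0 * margin
    ly = ny * a
    dz_tail = top.r0 * math.cos(top.theta0 / 2.0)
    z_head = 0.45 + dz_tail
    lz = max(3.0 * 2.0 * z_head, 2.0 * ff.r_cut + 0.5)
    z_mid = lz / 2.0

    sites = _leaflet_grid(nx, ny, a)
    sites[:, 2] += margin
    coords = []
    for direction, zh in ((+1, z_mid + z_head), (-1, z_mid - z_head)):
        for ix, iy, x, y in sites:
            axis = int(ix + iy) % 2
            coords.append(_lipid(np.array([x, y, zh]), direction, top, axis))
    return _assemble(coords, np.array([lx, ly, lz]), top, "ribbon",
                     meta={"n_per_leaflet": n_actual, "apl0": apl0,
                           "strip_axis": "y", "edge_axis": "x"})


def build_two_phase(
    n_lipids: int,
    t_gel: float = 150.0,
    t_fluid: float = 315.0,
    ff: ForceFieldParams | None = None,
    seed: int = 0,
    relax_steps: int = 20_000,
    apl_gel: float = 0.50,
    apl_fluid: float = 0.68,
) -> ParticleSystem:
    """Bilayer with a gel half and a fluid half joined in one box.

    Each half is built as an independent patch and briefly relaxed with
    Langevin dynamics at its own temperature (the gel half is a quench,
    which stands in for slow cooling); the two halves are then abutted
    along x.  Starting from coexistence suppresses the nucleation barrier
    that otherwise causes hysteresis in transition-temperature scans.
    """
    from .dynamics import SimConfig, minimize, run_ld  # deferred: import cycle

    ff = ff or ForceFieldParams.optimal()
    n_half = n_lipids // 4  # per leaflet per half
    halves = []
    for idx, (t_run, apl) in enumerate(((t_gel, apl_gel), (t_fluid, apl_fluid))):
        patch = build_bilayer(n_half, apl0=apl, ff=ff)
        patch = minimize(patch, ff, max_steps=200)
        rng = np.random.default_rng((seed, idx))
        patch.thermalize(t_run, rng)
        cfg = SimConfig(temperature=t_run, n_steps=relax_steps, seed=seed + idx,
                        barostat="off", report_interval=max(relax_steps // 10, 1))
        if relax_steps > 0:
            traj = run_ld(patch, ff, cfg)
            patch = traj.final_system
        patch.wrap_molecules()
        halves.append(patch)

    gel, fluid = halves
    lz = max(gel.box[2], fluid.box[2])
    ly = min(gel.box[1], fluid.box[1])
    # clip each half laterally into a common y extent, offset fluid in x
    box = np.array([gel.box[0] + fluid.box[0], ly, lz])
    fluid_pos = fluid.positions + np.array([gel.box[0], 0.0, 0.0])
    coords = np.concatenate([gel.positions, fluid_pos])
    n_gel = gel.n_beads

    merged = ParticleSystem(
        positions=coords,
        velocities=np.concatenate([gel.velocities, fluid.velocities]),
        types=np.concatenate([gel.types, fluid.types]),
        masses=np.concatenate([gel.masses, fluid.masses]),
        box=box,
        molecules=np.concatenate([gel.molecules, fluid.molecules + gel.n_molecules]),
        bonds=np.concatenate([gel.bonds, fluid.bonds + n_gel]),
        angles=np.concatenate([gel.angles, fluid.angles + n_gel]),
        geometry="two_phase",
        meta={"gel_molecules": gel.n_molecules,
              "fluid_molecules": fluid.n_molecules,
              "t_gel": t_gel, "t_fluid": t_fluid},
    )
    merged.wrap_molecules()
    return merged


def build_random_gas(
    n_lipids: int,
    box: float | np.ndarray,
    seed: int = 0,
    topology: LipidTopology | None = None,
    min_dist: float = 0.6,
    max_tries: int = 10_000,
) -> ParticleSystem:
    """Lipids at random positions/orientations with no intermolecular overlap.

    Rejection sampling keeps every intermolecular bead pair at least
    `min_dist` nm apart (minimum image).  Deterministic per seed.
    """
    top = topology or LipidTopology()
    box = np.asarray(box, dtype=float) * np.ones(3)
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    all_beads: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_lipids:
        if tries > max_tries * n_lipids:
            raise RuntimeError("could not place lipids without overlap; box too small")
        tries += 1
        center = rng.uniform(0.0, 1.0, 3) * box
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        spin = rng.uniform(0.0, 2.0 * math.pi)
        cand = _lipid(np.zeros(3), +1, top)
        cand = cand @ _rotation_matrix(axis, spin).T + center
        if all_beads:
            existing = np.concatenate(all_beads)
            d = cand[:, None, :] - existing[None, :, :]
            d -= box * np.round(d / box)
            if np.min(np.linalg.norm(d, axis=-1)) < min_dist:
                continue
        placed.append(cand)
        all_beads.append(cand)
    sys_ = _assemble(placed, box, top, "gas", meta={"seed": seed})
    sys_.wrap_molecules()
    return sys_


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [x * x * C + c, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, y * y * C + c, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, z * z * C + c],
    ])


def count_aggregates(sys_: ParticleSystem, cutoff: float = 1.5) -> int:
    """Number of connected lipid clusters (beads within `cutoff` link them)."""
    pos = np.mod(sys_.positions, sys_.box)
    tree = cKDTree(pos, boxsize=sys_.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return sys_.n_molecules
    mi, mj = sys_.molecules[pairs[:, 0]], sys_.molecules[pairs[:, 1]]
    mask = mi != mj
    n = sys_.n_molecules
    graph = coo_matrix(
        (np.ones(mask.sum()), (mi[mask], mj[mask])), shape=(n, n)
    )
    n_comp, _ = connected_components(graph, directed=False)
    return int(n_comp)
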