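"""File formats: GRO snapshots, TSV time series, profiles, run configs.

Plain-text only, GROMACS conventions (nm, fixed-width GRO columns).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine.system import ParticleSystem, TYPE_H, TYPE_T
from .forcefield import LipidTopology
from .observables import BoxSeries, Profile1D

__all__ = [
    "write_gro",
    "read_gro",
    "write_series_tsv",
    "read_series_tsv",
    "write_profile_tsv",
    "read_profile_tsv",
    "RunConfig",
    "provenance_record",
]

_BEAD_NAMES = {TYPE_H: "H", TYPE_T: "T"}


def write_gro(sys_: ParticleSystem, path: str | Path, title: str = "ucgmem") -> Path:
    """Write a fixed-width GRO snapshot (nm; velocities if nonzero)."""
    path = Path(path)
    has_vel = bool(np.any(sys_.velocities))
    lines = [title, f"{sys_.n_beads:5d}"]
    tail_counter: dict[int, int] = {}
    for i in range(sys_.n_beads):
        mol = int(sys_.molecules[i]) + 1
        t = int(sys_.types[i])
        if t == TYPE_T:
            tail_counter[mol] = tail_counter.get(mol, 0) + 1
            name = f"T{tail_counter[mol]}"
        else:
            name = _BEAD_NAMES.get(t, f"X{t}")
        x, y, z = sys_.positions[i]
        line = f"{mol % 100000:5d}{'LIP':<5s}{name:>5s}{(i + 1) % 100000:5d}" \
               f"{x:8.3f}{y:8.3f}{z:8.3f}"
        if has_vel:
            vx, vy, vz = sys_.velocities[i]
            line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
        lines.append(line)
    lines.append("{:10.5f}{:10.5f}{:10.5f}".format(*sys_.box))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gro(path: str | Path, topology: LipidTopology | None = None) -> ParticleSystem:
    """Read a GRO snapshot of 3-bead lipids back into a ParticleSystem.

    Molecule/bond/angle lists are rebuilt assuming consecutive (H, T, T)
    triplets per residue, which is what :func:`write_gro` produces.
    """
    top = topology or LipidTopology()
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise ValueError(f"{path}: truncated GRO file")
    try:
        n = int(text[1])
    except ValueError as exc:
        raise ValueError(f"{path}:2: bad atom count line") from exc
    if len(text) < n + 3:
        raise ValueError(f"{path}: expected {n} atom lines, file too short")

    positions = np.zeros((n, 3))
    velocities = np.zeros((n, 3))
    types = np.zeros(n, dtype=int)
    molecules = np.zeros(n, dtype=int)
    mol_ids: dict[int, int] = {}
    for i in range(n):
        line = text[2 + i]
        try:
            res = int(line[0:5])
            name = line[10:15].strip()
            positions[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line) >= 68:
                velocities[i] = [float(line[44:52]), float(line[52:60]),
                                 float(line[60:68])]
        except ValueError as exc:
            raise ValueError(f"{path}:{3 + i}: malformed GRO atom line") from exc
        if res not in mol_ids:
            mol_ids[res] = len(mol_ids)
        molecules[i] = mol_ids[res]
        types[i] = TYPE_H if name.startswith("H") else TYPE_T

    box_fields = text[2 + n].split()
    if len(box_fields) < 3:
        raise ValueError(f"{path}:{3 + n}: malformed box line")
    box = np.array([float(v) for v in box_fields[:3]])

    n_mol = len(mol_ids)
    base = 3 * np.arange(n_mol)[:, None]
    bonds = np.concatenate([base + np.array([[0, 1]]), base + np.array([[0, 2]])])
    bonds = bonds[np.argsort(bonds[:, 0], kind="stable")]
    angles = base + np.array([[1, 0, 2]])
    return ParticleSystem(
        positions=positions,
        velocities=velocities,
        types=types,
        masses=np.full(n, top.bead_mass),
        box=box,
        molecules=molecules,
        bonds=bonds.astype(int),
        angles=angles.astype(int),
    )


# ---------------------------------------------------------------------------
# TSV series and profiles
# ---------------------------------------------------------------------------

def write_series_tsv(traj, path: str | Path) -> Path:
    """Energy/box/pressure records as TSV with unit-bearing headers."""
    path = Path(path)
    header = ("time_ps\tlx_nm\tly_nm\tlz_nm\tepot_kjmol\tekin_kjmol"
              "\tpxx_bar\tpyy_bar\tpzz_bar")
    rows = [header]
    for r in traj.records:
        rows.append("\t".join(
            f"{v:.8g}" for v in
            (r.time, *r.box, r.epot, r.ekin, *r.pressure)
        ))
    path.write_text("\n".join(rows) + "\n")
    return path


def read_series_tsv(path: str | Path) -> tuple[BoxSeries, np.ndarray, np.ndarray]:
    """Returns (BoxSeries, energies (n,2), pressures (n,3))."""
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    series = BoxSeries(time=data[:, 0], lx=data[:, 1], ly=data[:, 2], lz=data[:, 3])
    return series, data[:, 4:6], data[:, 6:9]


def write_profile_tsv(profile: Profile1D, path: str | Path,
                      axis_name: str = "r_nm", value_name: str = "value") -> Path:
    path = Path(path)
    rows = [f"{axis_name}\t{value_name}"]
    for c, v in zip(profile.centers, profile.values):
        rows.append(f"{c:.8g}\t{v:.8g}")
    path.write_text("\n".join(rows) + "\n")
    return path


def read_profile_tsv(path: str | Path) -> Profile1D:
    data = np.atleast_2d(np.loadtxt(path, skiprows=1))
    width = float(data[1, 0] - data[0, 0]) if len(data) > 1 else 1.0
    return Profile1D(data[:, 0], data[:, 1], width)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "forcefield": {"epsilon", "r_min", "r_shift_on", "r_cut", "k_bond", "k_angle"},
    "engine": {"dt", "temperature", "gamma", "n_steps", "report_interval",
               "traj_interval", "barostat", "p_ref", "kappa_xy", "tau_p"},
    "observables": {"rdf_dr", "density_dz", "grid", "q_max"},
    "evolve": {"pop_size", "pm", "max_iters", "threshold", "elitism", "tier"},
    "multiscale": {"cutoff", "target_mean", "target_sd"},
}


@dataclass
class RunConfig:
    """Nested run configuration with strict key validation."""

    sections: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "out"
    tier: str = "desk"

    def __post_init__(self) -> None:
        for section, keys in self.sections.items():
            if section not in _KNOWN_SECTIONS:
                raise ValueError(f"unknown config section {section!r}")
            unknown = set(keys) - _KNOWN_SECTIONS[section]
            if unknown:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(unknown)}"
                )

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"seed": self.seed, "outdir": self.outdir, "tier": self.tier,
                   **self.sections}
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        seed = payload.pop("seed", 0)
        outdir = payload.pop("outdir", "out")
        tier = payload.pop("tier", "desk")
        return cls(sections=payload, seed=seed, outdir=outdir, tier=tier)


def provenance_record(path: str | Path, seed: int, config: dict | None = None) -> Path:
    """Write a JSON provenance stamp (config hash, seed, package version)."""
    from . import __version__

    config = config or {}
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "version": __version__,
        "config": config,
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
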