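"""Mixed-resolution support: coupling a bead-resolution peptide to the
ultra-coarse-grained membrane through tabulated Lennard-Jones potentials.

The membrane model stays at its own resolution (2.5 nm cutoff, 6/0.5
potentials); peptide beads interact among themselves and with membrane
beads through 12-6 LJ tables at a 1.2 nm cutoff.  With two peptide bead
classes (hydrophilic LIC, hydrophobic BIC) and two membrane bead types
(H, T) there are four cross pairs, i.e. eight free C6/C12 coefficients —
the genome of the peptide-coupling optimization.  Its objective is the
distribution of the peptide tilt angle against the membrane normal,
scored as an Earth Mover's Distance to a Gaussian target (mean 30
degrees, sd 10 degrees).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .forcefield import (
    ForceFieldParams,
    PairTerm,
    TabulatedPotential,
    _terms_force,
    _terms_potential,
    write_tables,
)
from .observables import Profile1D, emd

__all__ = [
    "PEPTIDE_CLASSES",
    "CROSS_PAIRS",
    "CrossInteractionSet",
    "TiltDistribution",
    "lj_table",
    "tilt_angle",
    "tilt_objective",
    "emit_external_run",
]

PEPTIDE_CLASSES = ("LIC", "BIC")          # hydrophilic / hydrophobic
MEMBRANE_TYPES = ("H", "T")
CROSS_PAIRS = tuple(
    (p, m) for p in PEPTIDE_CLASSES for m in MEMBRANE_TYPES
)
LJ_CUTOFF = 1.2                            # nm, peptide-resolution cutoff


@dataclass(frozen=True)
class CrossInteractionSet:
    """C6/C12 coefficients for the four peptide-membrane pair classes.

    Units: C6 kJ/mol nm^6, C12 kJ/mol nm^12; exactly eight free
    parameters, the mixed-resolution genome.
    """

    coefficients: dict = field(default_factory=dict)
    cutoff: float = LJ_CUTOFF

    def __post_init__(self) -> None:
        for pair in CROSS_PAIRS:
            if pair not in self.coefficients:
                raise ValueError(f"missing pair class {pair}")
            c6, c12 = self.coefficients[pair]
            if c6 < 0 or c12 < 0:
                raise ValueError(f"negative LJ coefficient for {pair}")
        if len(self.coefficients) != len(CROSS_PAIRS):
            extra = set(self.coefficients) - set(CROSS_PAIRS)
            raise ValueError(f"unknown pair classes {extra}")

    @classmethod
    def from_genes(cls, genes: Sequence[float], cutoff: float = LJ_CUTOFF):
        genes = np.asarray(genes, dtype=float)
        if genes.shape != (8,):
            raise ValueError("cross-interaction genome has exactly 8 genes")
        coeffs = {
            pair: (float(genes[2 * i]), float(genes[2 * i + 1]))
            for i, pair in enumerate(CROSS_PAIRS)
        }
        return cls(coeffs, cutoff)

    def to_genes(self) -> np.ndarray:
        return np.array(
            [v for pair in CROSS_PAIRS for v in self.coefficients[pair]]
        )


def lj_table(
    c6: float,
    c12: float,
    rc: float = LJ_CUTOFF,
    r1: float | None = None,
    dr: float = 0.002,
    name: str = "LJ",
) -> TabulatedPotential:
    """Force-shifted 12-6 table, V = C12/r^12 - C6/r^6, V(rc) = F(rc) = 0.

    Dispersion goes in the g column, repulsion in h, both with unit
    coefficients (same dialect as the membrane tables); the shift onset
    defaults to 0.75*rc.  Unshifted, the minimum sits at
    r* = (2 C12/C6)^(1/6) with depth C6^2/(4 C12).
    """
    if c6 < 0 or c12 < 0:
        raise ValueError("LJ coefficients must be non-negative")
    if r1 is None:
        r1 = 0.75 * rc
    r = np.arange(0.0, rc + 0.5 + 0.5 * dr, dr)
    rr = np.maximum(r, 0.1)
    if c6 == 0.0 and c12 == 0.0:
        import warnings

        warnings.warn("both LJ coefficients zero: writing a null table")
        zero = np.zeros_like(r)
        return TabulatedPotential(
            kind="nonbonded", name=name, r=r,
            columns={"f": zero, "fp": zero, "g": zero, "gp": zero,
                     "h": zero, "hp": zero},
            coefficients={"c_attraction": 0.0, "c_repulsion": 0.0,
                          "C6": c6, "C12": c12},
        )
    disp = (PairTerm.build(1.0, 6.0, r1, rc),)
    rep = (PairTerm.build(1.0, 12.0, r1, rc),)
    g = _terms_potential(rr, disp, r1, rc)
    gp = _terms_force(rr, disp, r1, rc)
    h = _terms_potential(rr, rep, r1, rc)
    hp = _terms_force(rr, rep, r1, rc)
    zero = np.zeros_like(r)
    return TabulatedPotential(
        kind="nonbonded", name=name, r=r,
        columns={"f": zero, "fp": zero, "g": g, "gp": gp, "h": h, "hp": hp},
        # V = c_att * g + c_rep * h with the attraction sign in the coefficient
        coefficients={"c_attraction": -c6, "c_repulsion": c12,
                      "C6": c6, "C12": c12, "r1": r1, "rc": rc},
    )


@dataclass
class TiltDistribution:
    """Histogrammed peptide tilt angles (degrees from the membrane normal)."""

    profile: Profile1D
    mean: float
    sd: float
    n_samples: int
    n_skipped: int = 0


def tilt_angle(
    frames: Sequence[np.ndarray],
    first_bead: int,
    last_bead: int,
    bin_width: float = 2.0,
) -> TiltDistribution:
    """Tilt of the peptide end-to-end vector against the +z membrane normal.

    The angle is folded into [0, 90] degrees: the membrane has up-down
    symmetry, so a peptide pointing along -z is as upright as one along
    +z.  Frames with a zero-length end-to-end vector are skipped.
    """
    angles = []
    skipped = 0
    for pos in frames:
        vec = np.asarray(pos[last_bead], float) - np.asarray(pos[first_bead], float)
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            skipped += 1
            continue
        cos_t = abs(vec[2]) / norm          # fold: |cos| maps theta to [0, 90]
        angles.append(math.degrees(math.acos(min(cos_t, 1.0))))
    if not angles:
        raise ValueError("no valid frames for tilt analysis")
    angles = np.asarray(angles)
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    hist, _ = np.histogram(angles, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = Profile1D(centers, hist.astype(float), bin_width).normalize()
    return TiltDistribution(
        profile=profile,
        mean=float(angles.mean()),
        sd=float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        n_samples=len(angles),
        n_skipped=skipped,
    )


def tilt_objective(
    observed: TiltDistribution | Profile1D,
    target_mean: float = 30.0,
    target_sd: float = 10.0,
) -> float:
    """EMD between the observed tilt distribution and the Gaussian target.

    Zero iff the observed histogram equals the discretized target; for
    equal-sd Gaussians the continuum EMD is |mean_1 - mean_2| (degrees).
    """
    profile = observed.profile if isinstance(observed, TiltDistribution) else observed
    if not profile.normalized:
        import warnings

        warnings.warn("normalizing tilt distribution for the objective")
        profile = profile.normalize()
    z = (profile.centers - target_mean) / target_sd
    target = np.exp(-0.5 * z**2)
    target_profile = Profile1D(
        profile.centers, target, profile.bin_width
    ).normalize()
    return emd(profile, target_profile)


def emit_external_run(
    cross: CrossInteractionSet,
    membrane_ff: ForceFieldParams | None = None,
    outdir: str | Path = "run_bundle",
    template: dict | None = None,
) -> dict:
    """Write the full mixed-resolution run bundle for an external engine.

    Contents: the four peptide-membrane cross tables (1.2 nm cutoff),
    the five membrane tables (2.5 nm cutoff, byte-identical to
    :func:`ucgmem.forcefield.write_tables` output), a JSON manifest
    echoing all eight C6/C12 values, and a commented command script.
    Nothing is executed; the bundle documents the intended invocation.
    """
    template = dict(template or {})
    required = {"engine_command", "n_steps", "temperature"}
    defaults = {"engine_command": "gmx", "n_steps": 250_000, "temperature": 315.0}
    for key in required:
        template.setdefault(key, defaults[key])
    unknown = set(template) - required
    if unknown:
        raise ValueError(f"unknown template fields: {sorted(unknown)}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    membrane_ff = membrane_ff or ForceFieldParams.optimal()

    table_files = [p.name for p in write_tables(membrane_ff, outdir)]
    for pair in CROSS_PAIRS:
        c6, c12 = cross.coefficients[pair]
        tab = lj_table(c6, c12, rc=cross.cutoff, name=f"{pair[0]}-{pair[1]}")
        fname = f"table_{pair[0]}_{pair[1]}.xvg"
        tab.write_xvg(outdir / fname)
        table_files.append(fname)

    manifest = {
        "membrane_parameters": {
            "epsilon_kjmol": membrane_ff.epsilon,
            "r_min_nm": membrane_ff.r_min,
            "r_shift_on_nm": membrane_ff.r_shift_on,
            "r_cut_nm": membrane_ff.r_cut,
            "k_bond": membrane_ff.k_bond,
            "k_angle": membrane_ff.k_angle,
        },
        "cross_interactions": {
            f"{p}-{m}": {"C6": cross.coefficients[(p, m)][0],
                         "C12": cross.coefficients[(p, m)][1]}
            for p, m in CROSS_PAIRS
        },
        "cutoffs_nm": {"membrane": membrane_ff.r_cut, "cross": cross.cutoff},
        "tables": table_files,
        "template": template,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    script = "\n".join([
        "#!/bin/sh",
        "# Mixed-resolution membrane + peptide run (external engine).",
        "# Tabulated potentials in this directory; energy groups must map",
        "# each bead class to its table file (table_<a>_<b>.xvg).",
        f"# {template['engine_command']} grompp -f run.mdp -c system.gro -p topol.top -o run.tpr",
        f"# {template['engine_command']} mdrun -deffnm run -tableb {' '.join(table_files)}",
        f"# nsteps = {template['n_steps']}, ref_t = {template['temperature']} K",
        "echo 'bundle only: see manifest.json; no engine is invoked here'",
        "",
    ])
    (outdir / "run.sh").write_text(script)
    return manifest
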