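"""Energetics of the three-site implicit-solvent lipid model.

Each lipid is one hydrophilic head bead (H) bonded to two hydrophobic tail
beads (T) at 1 nm, with a harmonic T-H-T angle of 30 degrees.  Solvent is
implicit: the hydrophobic effect is folded into an attractive tail-tail
potential, while head-head and head-tail contacts are purely repulsive
(excluded volume only).

Nonbonded forms (r in nm, energies kJ/mol):

    U_TT(r)    = (eps/5.5) * [ 0.5 (r_min/r)^6 - 6 (r_min/r)^0.5 ]
    U_HH/HT(r) = (0.4 eps/5.5) * 0.5 (r_min/r)^6

The 1/5.5 normalisation makes the TT well depth exactly -eps at r = r_min.
Both potentials are smoothly truncated with a force-shift scheme applied
per power-law term: a term V = c / r^alpha has force alpha*c/r^(alpha+1),
which between the shift onset r1 and the cutoff rc is corrected by a cubic
polynomial c*[A (r-r1)^2 + B (r-r1)^3] chosen so the force and its first
derivative vanish at rc.  The potential is the integral of the shifted
force, offset so V(rc) = 0.  This is the tabulated-potential dialect of
force shifting used by mainstream MD engines; alpha = 6 for the repulsive
term and alpha = 0.5 for the attraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .constants import KB, kbt_to_kjmol

__all__ = [
    "ForceFieldParams",
    "LipidTopology",
    "TabulatedPotential",
    "PairTerm",
    "bonded_energy",
    "tt_potential_unshifted",
    "repulsive_potential_unshifted",
    "shift_coefficients",
    "pair_terms",
    "shifted_pair_force",
    "shifted_pair_potential",
    "make_tables",
    "write_tables",
]

#: Equilibrium bond length H-T, nm
R0_BOND = 1.0
#: Equilibrium T-H-T angle, rad (30 degrees)
THETA0 = math.radians(30.0)
#: Default bead mass, amu (POPC molar mass 760.1 g/mol split over 3 beads)
BEAD_MASS = 253.4

PAIR_KINDS = ("TT", "HH", "HT")


@dataclass(frozen=True)
class ForceFieldParams:
    """The six scalars the genetic algorithm optimises.

    epsilon    : TT well depth, kJ/mol
    r_min      : position of the unshifted TT minimum, nm
    r_shift_on : onset r1 of the force-shift region, nm
    r_cut      : nonbonded cutoff rc, nm
    k_bond     : harmonic bond constant, kJ/mol/nm^2
    k_angle    : harmonic angle constant, kJ/mol/rad^2
    """

    epsilon: float
    r_min: float
    r_shift_on: float
    r_cut: float
    k_bond: float
    k_angle: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not (0 < self.r_min < self.r_shift_on < self.r_cut):
            raise ValueError(
                "require 0 < r_min < r_shift_on < r_cut, got "
                f"({self.r_min}, {self.r_shift_on}, {self.r_cut})"
            )
        if self.k_bond <= 0 or self.k_angle <= 0:
            raise ValueError("force constants must be positive")

    @classmethod
    def optimal(cls, temperature: float = 315.0) -> "ForceFieldParams":
        """The parameter set the evolutionary optimisation converged to.

        epsilon is specified as 5.788 kB*T and converted to kJ/mol at
        `temperature` (default 315 K, the parametrization temperature).
        """
        return cls(
            epsilon=kbt_to_kjmol(5.788, temperature),
            r_min=1.095,
            r_shift_on=1.729,
            r_cut=2.500,
            k_bond=1997.0,
            k_angle=264.0,
        )

    def epsilon_kbt(self, temperature: float = 315.0) -> float:
        return self.epsilon / (KB * temperature)

    # -- plain-text (key = value) round trip ---------------------------------

    def to_config(self, path: str | Path) -> None:
        lines = [
            "# three-site lipid force field parameters",
            f"epsilon = {self.epsilon!r}      # kJ/mol",
            f"r_min = {self.r_min!r}          # nm",
            f"r_shift_on = {self.r_shift_on!r}  # nm",
            f"r_cut = {self.r_cut!r}          # nm",
            f"k_bond = {self.k_bond!r}        # kJ/mol/nm^2",
            f"k_angle = {self.k_angle!r}      # kJ/mol/rad^2",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ForceFieldParams":
        values: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
        return cls(**values)


@dataclass(frozen=True)
class LipidTopology:
    """Fixed intramolecular structure of the three-bead lipid."""

    bead_types: tuple[str, str, str] = ("H", "T", "T")
    r0: float = R0_BOND
    theta0: float = THETA0
    bead_mass: float = BEAD_MASS

    @property
    def bonds(self) -> tuple[tuple[int, int], ...]:
        # head (index 0) bonded to each tail
        return ((0, 1), (0, 2))

    @property
    def angle(self) -> tuple[int, int, int]:
        # tail - head - tail
        return (1, 0, 2)


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bonded_energy(
    r: float, theta: float, p: ForceFieldParams, topology: LipidTopology | None = None
) -> float:
    """Harmonic bond + angle energy, 0.5 k_b (r-r0)^2 + 0.5 k_a (th-th0)^2."""
    top = topology or LipidTopology()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    e = 0.5 * p.k_bond * (r - top.r0) ** 2 + 0.5 * p.k_angle * (theta - top.theta0) ** 2
    return float(e) if np.ndim(e) == 0 else e


# ---------------------------------------------------------------------------
# unshifted nonbonded forms
# ---------------------------------------------------------------------------

def _check_r(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    return r


def tt_potential_unshifted(r, p: ForceFieldParams):
    """Tail-tail 6/0.5 potential; minimum exactly -epsilon at r_min."""
    r = _check_r(r)
    x = p.r_min / r
    out = (p.epsilon / 5.5) * (0.5 * x**6 - 6.0 * np.sqrt(x))
    return float(out) if np.ndim(out) == 0 else out


def repulsive_potential_unshifted(r, p: ForceFieldParams):
    """Head-head / head-tail excluded-volume term, 0.4-scaled sixth power."""
    r = _check_r(r)
    x = p.r_min / r
    out = (0.4 * p.epsilon / 5.5) * 0.5 * x**6
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# force-shift scheme
# ---------------------------------------------------------------------------

def shift_coefficients(alpha: float, r1: float, rc: float) -> tuple[float, float]:
    """Cubic force-shift coefficients (A, B) for a 1/r^alpha potential term.

    Chosen so the shifted force is continuous at r1 and vanishes together
    with its first derivative at rc.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 < r1 < rc):
        raise ValueError(f"require 0 < r1 < rc, got r1={r1}, rc={rc}")
    d = rc - r1
    A = -((alpha + 4) * rc - (alpha + 1) * r1) / (rc ** (alpha + 2) * d**2)
    B = ((alpha + 3) * rc - (alpha + 1) * r1) / (rc ** (alpha + 2) * d**3)
    return A, B


@dataclass(frozen=True)
class PairTerm:
    """One power-law component c/r^alpha with its force-shift constants.

    The stored polynomial coefficients carry the extra factor alpha of
    the force-switch convention: the shifted force of a unit term is
    alpha/r^(alpha+1) + alpha*A (r-r1)^2 + alpha*B (r-r1)^3, which makes
    the force vanish exactly at rc (writing the correction without the
    alpha prefactor would leave a residual force at the cutoff).
    """

    coef: float       # c, signed; attraction has c < 0
    alpha: float
    A: float          # alpha-scaled
    B: float          # alpha-scaled
    v_const: float    # offset so the shifted potential vanishes at rc

    @classmethod
    def build(cls, coef: float, alpha: float, r1: float, rc: float) -> "PairTerm":
        A, B = shift_coefficients(alpha, r1, rc)
        A *= alpha
        B *= alpha
        d = rc - r1
        v_const = rc ** (-alpha) - (A / 3.0) * d**3 - (B / 4.0) * d**4
        return cls(coef, alpha, A, B, v_const)


def pair_terms(p: ForceFieldParams, pair: str) -> tuple[PairTerm, ...]:
    """Force-shifted power-law decomposition of a pair interaction.

    TT is repulsion (alpha=6) plus attraction (alpha=0.5); HH and HT share
    a single 0.4-scaled repulsive term.
    """
    if pair not in PAIR_KINDS:
        raise ValueError(f"unknown pair kind {pair!r}")
    r1, rc = p.r_shift_on, p.r_cut
    c_rep = 0.5 * p.epsilon * p.r_min**6 / 5.5
    if pair == "TT":
        c_att = -6.0 * p.epsilon * math.sqrt(p.r_min) / 5.5
        return (
            PairTerm.build(c_rep, 6.0, r1, rc),
            PairTerm.build(c_att, 0.5, r1, rc),
        )
    return (PairTerm.build(0.4 * c_rep, 6.0, r1, rc),)


def _terms_force(r: np.ndarray, terms: Iterable[PairTerm], r1: float, rc: float):
    """Scalar force magnitude f(r) = -dV/dr for a sum of shifted terms."""
    f = np.zeros_like(r)
    inside = r < rc
    d = np.where(r > r1, r - r1, 0.0)
    for t in terms:
        f += np.where(
            inside,
            t.coef * (t.alpha * r ** (-(t.alpha + 1.0)) + t.A * d**2 + t.B * d**3),
            0.0,
        )
    return f


def _terms_potential(r: np.ndarray, terms: Iterable[PairTerm], r1: float, rc: float):
    v = np.zeros_like(r)
    inside = r < rc
    d = np.where(r > r1, r - r1, 0.0)
    for t in terms:
        v += np.where(
            inside,
            t.coef
            * (r ** (-t.alpha) - (t.A / 3.0) * d**3 - (t.B / 4.0) * d**4 - t.v_const),
            0.0,
        )
    return v


def shifted_pair_force(r, p: ForceFieldParams, pair: str):
    """Force magnitude -dV/dr of the shifted pair potential (kJ/mol/nm).

    Positive values push the pair apart.  Zero for r >= r_cut; continuous
    at the shift onset and at the cutoff.
    """
    r = _check_r(r)
    out = _terms_force(np.atleast_1d(r), pair_terms(p, pair), p.r_shift_on, p.r_cut)
    return float(out[0]) if np.ndim(r) == 0 else out


def shifted_pair_potential(r, p: ForceFieldParams, pair: str):
    """Shifted pair potential (kJ/mol); V(r_cut) = 0, once differentiable."""
    r = _check_r(r)
    out = _terms_potential(np.atleast_1d(r), pair_terms(p, pair), p.r_shift_on, p.r_cut)
    return float(out[0]) if np.ndim(r) == 0 else out


# ---------------------------------------------------------------------------
# tabulated potentials
# ---------------------------------------------------------------------------

@dataclass
class TabulatedPotential:
    """Potential/force on a uniform r grid in the 7-column table dialect.

    Nonbonded tables carry the attraction in the dispersion column g and
    the repulsion in column h, both with unit coefficients, so an engine
    reconstructs V(r) = c_att_mag * g(r) + c_rep * h(r) by supplying the
    two magnitudes.  Bonded tables are 3 columns (x, V, -dV/dx).
    """

    kind: str                       # "nonbonded" | "bond" | "angle"
    name: str
    r: np.ndarray
    columns: dict = field(default_factory=dict)
    coefficients: dict = field(default_factory=dict)

    def write_xvg(self, path: str | Path) -> Path:
        path = Path(path)
        if self.kind == "nonbonded":
            cols = [
                self.r,
                self.columns["f"], self.columns["fp"],
                self.columns["g"], self.columns["gp"],
                self.columns["h"], self.columns["hp"],
            ]
        else:
            cols = [self.r, self.columns["V"], self.columns["F"]]
        data = np.column_stack(cols)
        header = (
            f"# tabulated potential: {self.name} ({self.kind})\n"
            f"# coefficients: {self.coefficients}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.10e")
        return path

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """(V, F) in kJ/mol using the stored term coefficients."""
        if self.kind != "nonbonded":
            return self.columns["V"], self.columns["F"]
        ca = self.coefficients["c_attraction"]
        cr = self.coefficients["c_repulsion"]
        V = ca * self.columns["g"] + cr * self.columns["h"]
        F = ca * self.columns["gp"] + cr * self.columns["hp"]
        return V, F


#: below this distance the tabulated power laws are frozen at their value
#: there, to keep table entries finite near r = 0 (never sampled in practice)
R_TABLE_CAP = 0.1


def _unit_term_tables(alpha: float, sign: float, r: np.ndarray, r1: float, rc: float):
    """Unit-coefficient shifted (V, F) columns for one power-law family."""
    term = (PairTerm.build(sign, alpha, r1, rc),)
    rr = np.maximum(r, R_TABLE_CAP)
    V = _terms_potential(rr, term, r1, rc)
    F = _terms_force(rr, term, r1, rc)
    return V, F


def make_tables(
    p: ForceFieldParams,
    dr: float = 0.002,
    r_margin: float = 0.5,
    topology: LipidTopology | None = None,
) -> dict[str, TabulatedPotential]:
    """Build the five tables of the model: TT, HH, HT nonbonded, bond, angle."""
    if not (0 < dr <= 0.005):
        raise ValueError("dr must be in (0, 0.005] nm")
    top = topology or LipidTopology()
    r_max = p.r_cut + r_margin
    r = np.arange(0.0, r_max + 0.5 * dr, dr)
    if r[-1] < p.r_cut:
        raise ValueError("table grid does not reach the cutoff")

    g, gp = _unit_term_tables(0.5, 1.0, r, p.r_shift_on, p.r_cut)
    h, hp = _unit_term_tables(6.0, 1.0, r, p.r_shift_on, p.r_cut)
    zero = np.zeros_like(r)

    c_rep = 0.5 * p.epsilon * p.r_min**6 / 5.5
    c_att = -6.0 * p.epsilon * math.sqrt(p.r_min) / 5.5

    tables: dict[str, TabulatedPotential] = {}
    for pair in PAIR_KINDS:
        if pair == "TT":
            coeffs = {"c_attraction": c_att, "c_repulsion": c_rep}
            gcol, gpcol = g, gp
        else:
            coeffs = {"c_attraction": 0.0, "c_repulsion": 0.4 * c_rep}
            gcol, gpcol = zero, zero
        tables[pair] = TabulatedPotential(
            kind="nonbonded",
            name=pair,
            r=r,
            columns={"f": zero, "fp": zero, "g": gcol, "gp": gpcol, "h": h, "hp": hp},
            coefficients=coeffs,
        )

    rb = np.arange(0.0, 4.0 + 0.5 * dr, dr)
    rb_safe = np.maximum(rb, 1e-12)
    tables["bond"] = TabulatedPotential(
        kind="bond",
        name="bond",
        r=rb,
        columns={
            "V": 0.5 * p.k_bond * (rb_safe - top.r0) ** 2,
            "F": -p.k_bond * (rb_safe - top.r0),
        },
        coefficients={"k_bond": p.k_bond, "r0": top.r0},
    )

    theta_deg = np.arange(0.0, 180.0 + 0.25, 0.5)
    theta = np.radians(theta_deg)
    tables["angle"] = TabulatedPotential(
        kind="angle",
        name="angle",
        r=theta_deg,
        columns={
            "V": 0.5 * p.k_angle * (theta - top.theta0) ** 2,
            # force column per degree to match the degree-valued x column
            "F": -p.k_angle * (theta - top.theta0) * math.pi / 180.0,
        },
        coefficients={"k_angle": p.k_angle, "theta0_deg": math.degrees(top.theta0)},
    )
    return tables


_TABLE_FILES = {
    "TT": "table_T_T.xvg",
    "HH": "table_H_H.xvg",
    "HT": "table_H_T.xvg",
    "bond": "table_b0.xvg",
    "angle": "table_a0.xvg",
}


def write_tables(
    p: ForceFieldParams, outdir: str | Path, dr: float = 0.002
) -> list[Path]:
    """Write all five tables as .xvg files into `outdir`; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = make_tables(p, dr=dr)
    return [tables[key].write_xvg(outdir / fname) for key, fname in _TABLE_FILES.items()]
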