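"""Force, energy, and virial evaluation with a periodic neighbor list.

Nonbonded pairs come from a periodic k-d tree built with a Verlet skin;
the list is reused until any bead has moved half the skin.  Intramolecular
pairs (1-2 and 1-3 within a lipid) are excluded from nonbonded terms.
The per-axis virial sum(r_ij,a * F_ij,a) is accumulated for the pressure
tensor, including bond and angle contributions.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..constants import PRESSURE_BAR
from ..forcefield import (
    ForceFieldParams,
    LipidTopology,
    pair_terms,
    _terms_force,
    _terms_potential,
)
from .system import ParticleSystem

MIN_PAIR_DISTANCE = 1e-6

try:  # optional acceleration; the numpy path is the reference implementation
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _pair_kernel(pos, box, pairs, kinds, coefs, alphas, As, Bs, vconsts, nterms,
                 r1, rc, forces, virial):
    """Accumulate nonbonded forces/virial; returns (epot, min pair distance)."""
    epot = 0.0
    rmin_seen = 1e30
    for idx in range(pairs.shape[0]):
        i = pairs[idx, 0]
        j = pairs[idx, 1]
        dx0 = pos[i, 0] - pos[j, 0]
        dx1 = pos[i, 1] - pos[j, 1]
        dx2 = pos[i, 2] - pos[j, 2]
        dx0 -= box[0] * round(dx0 / box[0])
        dx1 -= box[1] * round(dx1 / box[1])
        dx2 -= box[2] * round(dx2 / box[2])
        r = (dx0 * dx0 + dx1 * dx1 + dx2 * dx2) ** 0.5
        if r < rmin_seen:
            rmin_seen = r
        if r >= rc or r <= 0.0:
            continue
        k = kinds[idx]
        d = r - r1 if r > r1 else 0.0
        d2 = d * d
        d3 = d2 * d
        fmag = 0.0
        for t in range(nterms[k]):
            c = coefs[k, t]
            al = alphas[k, t]
            if al == 6.0:  # fast paths for the model's two powers
                ir2 = 1.0 / (r * r)
                ir_al = ir2 * ir2 * ir2
            elif al == 0.5:
                ir_al = 1.0 / r**0.5
            else:
                ir_al = r ** (-al)
            fmag += c * (al * ir_al / r + As[k, t] * d2 + Bs[k, t] * d3)
            epot += c * (ir_al - (As[k, t] / 3.0) * d3
                         - (Bs[k, t] / 4.0) * d3 * d - vconsts[k, t])
        s = fmag / r
        f0 = s * dx0
        f1 = s * dx1
        f2 = s * dx2
        forces[i, 0] += f0
        forces[i, 1] += f1
        forces[i, 2] += f2
        forces[j, 0] -= f0
        forces[j, 1] -= f1
        forces[j, 2] -= f2
        virial[0] += dx0 * f0
        virial[1] += dx1 * f1
        virial[2] += dx2 * f2
    return epot, rmin_seen


class SingularConfigurationError(RuntimeError):
    """Two beads closer than the overlap threshold."""


class ForceCalculator:
    """Evaluates forces for one system topology + force field.

    Holds the neighbor list state; call :meth:`compute` each step.
    """

    def __init__(
        self,
        ff: ForceFieldParams,
        topology: LipidTopology | None = None,
        skin: float = 0.3,
    ) -> None:
        self.ff = ff
        self.topology = topology or LipidTopology()
        self.skin = skin
        self._ref_positions: np.ndarray | None = None
        self._ref_box: np.ndarray | None = None
        self._pairs: np.ndarray | None = None
        self._pair_kind: np.ndarray | None = None
        # pair kind index = type_i + type_j: 0 HH, 1 HT, 2 TT
        self._terms = (
            pair_terms(ff, "HH"),
            pair_terms(ff, "HT"),
            pair_terms(ff, "TT"),
        )
        # packed term table for the jitted kernel: kind index x term slot
        max_t = max(len(t) for t in self._terms)
        self._coefs = np.zeros((3, max_t))
        self._alphas = np.ones((3, max_t))
        self._As = np.zeros((3, max_t))
        self._Bs = np.zeros((3, max_t))
        self._vconsts = np.zeros((3, max_t))
        self._nterms = np.zeros(3, dtype=np.int64)
        for k, terms in enumerate(self._terms):
            self._nterms[k] = len(terms)
            for t, term in enumerate(terms):
                self._coefs[k, t] = term.coef
                self._alphas[k, t] = term.alpha
                self._As[k, t] = term.A
                self._Bs[k, t] = term.B
                self._vconsts[k, t] = term.v_const
        self.n_rebuilds = 0

    # -- neighbor list -----------------------------------------------------

    def _needs_rebuild(self, sys_: ParticleSystem) -> bool:
        if self._pairs is None or self._ref_positions is None:
            return True
        if self._ref_positions.shape != sys_.positions.shape:
            return True
        if np.any(self._ref_box != sys_.box):
            return True
        disp = sys_.positions - self._ref_positions
        # Euclidean per-bead displacement: two beads approaching head-on may
        # close the full skin before either alone has moved half of it
        return bool(np.max((disp * disp).sum(axis=1)) > (0.5 * self.skin) ** 2)

    def _rebuild(self, sys_: ParticleSystem) -> None:
        box = sys_.box
        wrapped = np.mod(sys_.positions, box)
        # guard against positions landing exactly on the upper box face
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(self.ff.r_cut + self.skin, output_type="ndarray")
        if len(pairs):
            same_mol = sys_.molecules[pairs[:, 0]] == sys_.molecules[pairs[:, 1]]
            pairs = pairs[~same_mol]
        self._pairs = np.ascontiguousarray(pairs, dtype=np.int64)
        self._pair_kind = np.ascontiguousarray(
            sys_.types[self._pairs[:, 0]] + sys_.types[self._pairs[:, 1]], dtype=np.int64
        )
        self._ref_positions = sys_.positions.copy()
        self._ref_box = sys_.box.copy()
        self.n_rebuilds += 1

    # -- evaluation --------------------------------------------------------

    def compute(
        self, sys_: ParticleSystem
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Return (forces (N,3) kJ/mol/nm, potential kJ/mol, virial diag).

        The virial diagonal is sum over interactions of r_a * F_a per axis,
        in kJ/mol, ready for the pressure tensor.
        """
        if self._needs_rebuild(sys_):
            self._rebuild(sys_)

        pos, box = sys_.positions, sys_.box
        forces = np.zeros_like(pos)
        virial = np.zeros(3)
        epot = 0.0

        pairs = self._pairs
        if len(pairs):
            if HAVE_NUMBA:
                e_nb, r_min_seen = _pair_kernel(
                    pos, box, pairs, self._pair_kind,
                    self._coefs, self._alphas, self._As, self._Bs,
                    self._vconsts, self._nterms,
                    self.ff.r_shift_on, self.ff.r_cut, forces, virial,
                )
                if r_min_seen < MIN_PAIR_DISTANCE:
                    raise SingularConfigurationError(
                        f"bead overlap: min pair distance {r_min_seen:.2e} nm"
                    )
                epot += e_nb
            else:
                epot += self._pair_numpy(pos, box, pairs, forces, virial)

        e_b, v_b = self._bond_forces(sys_, forces)
        e_a, v_a = self._angle_forces(sys_, forces)
        epot += e_b + e_a
        virial += v_b + v_a
        return forces, epot, virial

    def _pair_numpy(self, pos, box, pairs, forces, virial) -> float:
        """Vectorized nonbonded path used when numba is unavailable."""
        dx = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dx -= box * np.round(dx / box)
        r = np.linalg.norm(dx, axis=1)
        if np.any(r < MIN_PAIR_DISTANCE):
            raise SingularConfigurationError(
                f"bead overlap: min pair distance {r.min():.2e} nm"
            )
        fmag = np.zeros_like(r)
        vpair = np.zeros_like(r)
        r1, rc = self.ff.r_shift_on, self.ff.r_cut
        for kind in (0, 1, 2):
            mask = self._pair_kind == kind
            if not np.any(mask):
                continue
            rk = r[mask]
            fmag[mask] = _terms_force(rk, self._terms[kind], r1, rc)
            vpair[mask] = _terms_potential(rk, self._terms[kind], r1, rc)
        fvec = (fmag / r)[:, None] * dx
        n = len(pos)
        for a in range(3):
            forces[:, a] += np.bincount(pairs[:, 0], weights=fvec[:, a], minlength=n)
            forces[:, a] -= np.bincount(pairs[:, 1], weights=fvec[:, a], minlength=n)
        virial += (dx * fvec).sum(axis=0)
        return float(vpair.sum())

    def _bond_forces(self, sys_: ParticleSystem, forces: np.ndarray):
        b = sys_.bonds
        if len(b) == 0:
            return 0.0, np.zeros(3)
        dx = sys_.positions[b[:, 0]] - sys_.positions[b[:, 1]]
        dx -= sys_.box * np.round(dx / sys_.box)
        r = np.linalg.norm(dx, axis=1)
        k, r0 = self.ff.k_bond, self.topology.r0
        epot = float(np.sum(0.5 * k * (r - r0) ** 2))
        fmag = -k * (r - r0)
        fvec = (fmag / r)[:, None] * dx
        np.add.at(forces, b[:, 0], fvec)
        np.subtract.at(forces, b[:, 1], fvec)
        virial = (dx * fvec).sum(axis=0)
        return epot, virial

    def _angle_forces(self, sys_: ParticleSystem, forces: np.ndarray):
        a = sys_.angles
        if len(a) == 0:
            return 0.0, np.zeros(3)
        box = sys_.box
        u = sys_.positions[a[:, 0]] - sys_.positions[a[:, 1]]
        v = sys_.positions[a[:, 2]] - sys_.positions[a[:, 1]]
        u -= box * np.round(u / box)
        v -= box * np.round(v / box)
        lu = np.linalg.norm(u, axis=1)
        lv = np.linalg.norm(v, axis=1)
        uh = u / lu[:, None]
        vh = v / lv[:, None]
        cos_t = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)

        k, t0 = self.ff.k_angle, self.topology.theta0
        epot = float(np.sum(0.5 * k * (theta - t0) ** 2))
        dU = k * (theta - t0)
        coef = (dU / sin_t)[:, None]
        f_i = coef * (vh - cos_t[:, None] * uh) / lu[:, None]
        f_k = coef * (uh - cos_t[:, None] * vh) / lv[:, None]
        np.add.at(forces, a[:, 0], f_i)
        np.add.at(forces, a[:, 2], f_k)
        np.subtract.at(forces, a[:, 1], f_i + f_k)
        virial = (u * f_i).sum(axis=0) + (v * f_k).sum(axis=0)
        return epot, virial


def brute_force_reference(
    sys_: ParticleSystem, ff: ForceFieldParams, topology: LipidTopology | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """O(N^2) double-loop nonbonded + bonded evaluation (testing oracle).

    Assembled independently of the neighbor-listed path: explicit Python
    loops over all bead pairs with minimum-image distances.
    """
    top = topology or LipidTopology()
    pos, box = sys_.positions, sys_.box
    n = len(pos)
    forces = np.zeros_like(pos)
    virial = np.zeros(3)
    epot = 0.0
    kinds = {0: "HH", 1: "HT", 2: "TT"}
    from ..forcefield import shifted_pair_force, shifted_pair_potential

    for i in range(n):
        for j in range(i + 1, n):
            if sys_.molecules[i] == sys_.molecules[j]:
                continue
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            r = float(np.linalg.norm(d))
            if r >= ff.r_cut:
                continue
            pair = kinds[int(sys_.types[i] + sys_.types[j])]
            f = shifted_pair_force(r, ff, pair)
            epot += shifted_pair_potential(r, ff, pair)
            fv = f * d / r
            forces[i] += fv
            forces[j] -= fv
            virial += d * fv

    for bi, bj in sys_.bonds:
        d = pos[bi] - pos[bj]
        d -= box * np.round(d / box)
        r = float(np.linalg.norm(d))
        epot += 0.5 * ff.k_bond * (r - top.r0) ** 2
        fv = -ff.k_bond * (r - top.r0) * d / r
        forces[bi] += fv
        forces[bj] -= fv
        virial += d * fv

    for ai, aj, ak in sys_.angles:
        u = pos[ai] - pos[aj]
        v = pos[ak] - pos[aj]
        u -= box * np.round(u / box)
        v -= box * np.round(v / box)
        lu, lv = np.linalg.norm(u), np.linalg.norm(v)
        uh, vh = u / lu, v / lv
        ct = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
        th = np.arccos(ct)
        st = max(np.sqrt(1.0 - ct * ct), 1e-8)
        epot += 0.5 * ff.k_angle * (th - top.theta0) ** 2
        dU = ff.k_angle * (th - top.theta0)
        f_i = dU / st * (vh - ct * uh) / lu
        f_k = dU / st * (uh - ct * vh) / lv
        forces[ai] += f_i
        forces[ak] += f_k
        forces[aj] -= f_i + f_k
        virial += u * f_i + v * f_k

    return forces, epot, virial


def kinetic_tensor(sys_: ParticleSystem) -> np.ndarray:
    """Per-axis kinetic energy 0.5 * sum(m v_a^2), kJ/mol."""
    return 0.5 * (sys_.masses[:, None] * sys_.velocities**2).sum(axis=0)


def pressure_tensor(
    sys_: ParticleSystem, kinetic_diag: np.ndarray, virial_diag: np.ndarray
) -> np.ndarray:
    """Diagonal pressure tensor (Pxx, Pyy, Pzz) in bar.

    P_aa = (2*KE_a + W_a) / V with KE and W in kJ/mol and V in nm^3.
    """
    vol = sys_.volume
    if vol <= 0:
        raise ValueError("zero simulation volume")
    return (2.0 * np.asarray(kinetic_diag) + np.asarray(virial_diag)) / vol * PRESSURE_BAR
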