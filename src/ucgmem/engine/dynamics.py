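"""Integrators: steepest-descent minimization and Langevin dynamics.

The Langevin integrator is the symmetric BAOAB splitting: half kick, half
drift, exact Ornstein-Uhlenbeck velocity refresh, half drift, half kick.
At zero friction it reduces to velocity Verlet, so NVE energy-conservation
checks exercise the same code path.  Semi-isotropic Berendsen pressure
coupling rescales the membrane plane (x, y) jointly toward zero surface
tension while the box height stays fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ..constants import KB
from ..forcefield import ForceFieldParams, LipidTopology
from .forces import ForceCalculator, kinetic_tensor, pressure_tensor
from .system import ParticleSystem

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Integration and coupling settings (GROMACS-style units)."""

    dt: float = 0.15                  # ps
    temperature: float = 315.0        # K
    gamma: float = 1.0                # friction, 1/ps (0 disables the thermostat)
    n_steps: int = 10_000
    seed: int = 0
    report_interval: int = 100        # steps between FrameRecords
    traj_interval: int = 0            # steps between position snapshots (0 = never)
    barostat: str = "semi-isotropic-xy"   # or "off"
    p_ref: float = 1.0                # bar, reference normal pressure
    kappa_xy: float = 1.0e-5          # 1/bar, lateral compressibility
    tau_p: float = 1.0                # ps, pressure coupling time
    mu_clamp: float = 0.02            # max fractional box scaling per step

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.barostat not in ("semi-isotropic-xy", "off"):
            raise ValueError(f"unknown barostat mode {self.barostat!r}")


@dataclass
class FrameRecord:
    step: int
    time: float                      # ps
    box: np.ndarray                  # (3,) nm
    epot: float                      # kJ/mol
    ekin: float                      # kJ/mol
    pressure: np.ndarray             # (Pxx, Pyy, Pzz) bar


@dataclass
class Trajectory:
    """Per-interval scalar records plus optional position snapshots."""

    records: list[FrameRecord] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)
    snapshot_boxes: list[np.ndarray] = field(default_factory=list)
    snapshot_times: list[float] = field(default_factory=list)
    snapshot_velocities: list[np.ndarray] = field(default_factory=list)
    final_system: ParticleSystem | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def box_series(self) -> np.ndarray:
        return np.array([r.box for r in self.records])

    @property
    def epot(self) -> np.ndarray:
        return np.array([r.epot for r in self.records])

    @property
    def ekin(self) -> np.ndarray:
        return np.array([r.ekin for r in self.records])

    @property
    def etot(self) -> np.ndarray:
        return self.epot + self.ekin

    @property
    def pressures(self) -> np.ndarray:
        return np.array([r.pressure for r in self.records])

    def enthalpy(self, p_ref_bar: float = 1.0) -> np.ndarray:
        """E_pot + E_kin + P_ref*V (kJ/mol); the PV term uses the set-point
        pressure since the instantaneous virial pressure is very noisy."""
        from ..constants import PRESSURE_BAR

        vol = np.prod(self.box_series, axis=1)
        return self.etot + p_ref_bar / PRESSURE_BAR * vol


class BlowUpError(RuntimeError):
    pass


def minimize(
    sys_: ParticleSystem,
    ff: ForceFieldParams,
    max_steps: int = 500,
    initial_step: float = 0.01,
    force_tol: float = 10.0,
    topology: LipidTopology | None = None,
) -> ParticleSystem:
    """Steepest descent with adaptive step, GROMACS-style.

    The displacement is the force direction scaled so the largest bead
    move equals the current step size; accepted steps grow the step by
    1.2x, rejected ones halve it.  Energy never increases.
    """
    out = sys_.copy()
    calc = ForceCalculator(ff, topology)
    forces, epot, _ = calc.compute(out)
    h = initial_step
    for _ in range(max_steps):
        fmax = float(np.max(np.abs(forces)))
        if fmax < force_tol or h < 1e-10:
            break
        trial = out.positions + forces * (h / fmax)
        saved = out.positions
        out.positions = trial
        f_new, e_new, _ = calc.compute(out)
        if e_new < epot:
            forces, epot = f_new, e_new
            h *= 1.2
        else:
            out.positions = saved
            h *= 0.5
    return out


def run_ld(
    sys_: ParticleSystem,
    ff: ForceFieldParams,
    cfg: SimConfig,
    topology: LipidTopology | None = None,
    calculator: ForceCalculator | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics; deterministic per cfg.seed.

    Returns a :class:`Trajectory` whose `final_system` continues the run.
    """
    out = sys_.copy()
    calc = calculator or ForceCalculator(ff, topology)
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt
    masses = out.masses[:, None]

    if cfg.gamma > 0:
        c1 = math.exp(-cfg.gamma * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
    else:
        c1, c2 = 1.0, 0.0
    sigma_v = np.sqrt(KB * cfg.temperature / out.masses)[:, None]

    forces, epot, virial = calc.compute(out)
    traj = Trajectory()
    n_clamped = 0

    for step in range(1, cfg.n_steps + 1):
        v = out.velocities
        v += 0.5 * dt * forces / masses
        out.positions += 0.5 * dt * v
        if c2 != 0.0:
            v *= c1
            v += c2 * sigma_v * rng.standard_normal(v.shape)
        out.positions += 0.5 * dt * v
        forces, epot, virial = calc.compute(out)
        v += 0.5 * dt * forces / masses

        ke_diag = kinetic_tensor(out)
        press = pressure_tensor(out, ke_diag, virial)

        if cfg.barostat == "semi-isotropic-xy":
            p_lat = 0.5 * (press[0] + press[1])
            arg = 1.0 - cfg.kappa_xy * dt / cfg.tau_p * (cfg.p_ref - p_lat)
            mu = math.sqrt(max(arg, 0.0))
            lo, hi = 1.0 - cfg.mu_clamp, 1.0 + cfg.mu_clamp
            if mu < lo or mu > hi:
                mu = min(max(mu, lo), hi)
                n_clamped += 1
            if mu != 1.0:
                out.box[0] *= mu
                out.box[1] *= mu
                out.positions[:, 0] *= mu
                out.positions[:, 1] *= mu

        if not np.isfinite(out.positions).all():
            raise BlowUpError(f"non-finite positions at step {step}")
        vmax = float(np.max(np.abs(v)))
        if vmax * dt > 0.5 * float(out.box.min()):
            raise BlowUpError(
                f"velocity explosion at step {step}: a bead crosses half "
                f"the box in one step (|v|max = {vmax:.3g} nm/ps)"
            )

        if cfg.report_interval and step % cfg.report_interval == 0:
            traj.records.append(
                FrameRecord(
                    step=step,
                    time=step * dt,
                    box=out.box.copy(),
                    epot=epot,
                    ekin=float(ke_diag.sum()),
                    pressure=press.copy(),
                )
            )
        if cfg.traj_interval and step % cfg.traj_interval == 0:
            snap = out.copy()
            snap.wrap_molecules()
            traj.snapshots.append(snap.positions)
            traj.snapshot_boxes.append(snap.box.copy())
            traj.snapshot_times.append(step * dt)
            traj.snapshot_velocities.append(out.velocities.copy())

    if n_clamped:
        logger.warning("barostat scaling clamped on %d steps", n_clamped)
    out.wrap_molecules()
    traj.final_system = out
    return traj
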