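"""Synthetic-data generators that make every estimator testable without MD.

Each generator draws from the same statistical model its estimator
inverts, so estimator tests are closure tests: generate with known
parameters, estimate, compare.  All generators are deterministic per
seed.  What these fixtures do NOT emulate: real membranes couple their
observables (undulations feed area fluctuations, protrusions bend the
q^-4 law), have correlated noise in time, and drift during equilibration;
synthetic closure only validates the estimator algebra, not the physics.
"""

from __future__ import annotations

import math

import numpy as np

# (constants imported on demand)
from .observables import BoxSeries, Profile1D

__all__ = [
    "synth_helfrich_surfaces",
    "synth_gaussian_box_series",
    "synth_step_enthalpy",
    "synth_pressure_series",
    "synth_tilt_angles",
    "reference_rdf",
    "reference_density_profile",
]


def synth_helfrich_surfaces(
    kc_kbt: float,
    box_side: float,
    grid: int,
    n_frames: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Thermal membrane height fields with a known bending modulus.

    Independent Gaussian Fourier amplitudes with variance
    <|u_q|^2> = 1 / (L^2 kc q^4) (kc in kB*T), Hermitian-symmetrized so
    the real-space fields are real; the q = 0 mode is zero.
    """
    if kc_kbt <= 0:
        raise ValueError("kc must be positive")
    rng = np.random.default_rng(seed)
    n = grid
    freqs = np.fft.fftfreq(n, d=box_side / n) * 2.0 * math.pi
    qx, qy = np.meshgrid(freqs, freqs, indexing="ij")
    q2 = qx**2 + qy**2
    s_target = np.zeros_like(q2)
    nonzero = q2 > 0
    s_target[nonzero] = 1.0 / (box_side**2 * kc_kbt * q2[nonzero] ** 2)

    fields = []
    amp = np.sqrt(s_target / 2.0)
    for _ in range(n_frames):
        a = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        a *= amp
        # Hermitian symmetrization preserves per-mode variance
        a_rev = a[np.mod(-np.arange(n), n)][:, np.mod(-np.arange(n), n)]
        a_h = (a + np.conj(a_rev)) / math.sqrt(2.0)
        u = np.fft.ifft2(a_h * n * n).real
        fields.append(u)
    return fields


def synth_gaussian_box_series(
    mean_lx: float,
    sd_lx: float,
    n: int,
    seed: int = 0,
    dt: float = 15.0,
) -> BoxSeries:
    """Uncorrelated Gaussian Lx = Ly series emulating a tensionless run."""
    rng = np.random.default_rng(seed)
    lx = rng.normal(mean_lx, sd_lx, n)
    return BoxSeries(
        time=np.arange(n) * dt, lx=lx, ly=lx.copy(), lz=np.full(n, 3.0 * mean_lx)
    )


def synth_step_enthalpy(
    temperatures,
    t_transition: float,
    gap: float,
    noise: float,
    n_per_series: int = 400,
    slope: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Enthalpy-vs-time series with a plateau jump at t_transition.

    Plateaus below and above the transition differ by `gap`; a nonzero
    `slope` adds a linear heat-capacity baseline.  Additive Gaussian
    noise of scale `noise`.
    """
    rng = np.random.default_rng(seed)
    series = []
    for t in np.asarray(temperatures, dtype=float):
        base = slope * t + (gap if t > t_transition else 0.0)
        series.append(base + rng.normal(0.0, noise, n_per_series))
    return series


def synth_pressure_series(
    mean_diag,
    sd: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """(n, 3) diagonal pressure-tensor series around `mean_diag` (bar)."""
    rng = np.random.default_rng(seed)
    return np.asarray(mean_diag, dtype=float) + rng.normal(0.0, sd, (n, 3))


def synth_tilt_angles(
    mean_deg: float, sd_deg: float, n: int, seed: int = 0
) -> np.ndarray:
    """Peptide tilt angles (degrees) drawn from a clipped Gaussian."""
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(mean_deg, sd_deg, n), 0.0, 180.0)


# ---------------------------------------------------------------------------
# parametric reference curves for EMD scoring
# ---------------------------------------------------------------------------
# Synthetic stand-ins for higher-resolution reference simulations: smooth
# sum-of-Gaussians shapes with the qualitative features of a fluid POPC
# bilayer (first RDF coordination peak near one bead diameter; bimodal
# head-group density with a peak per leaflet).  The comparison machinery
# is agnostic to where reference curves come from.

def reference_rdf(
    dr: float = 0.05,
    r_max: float = 3.0,
    peak_r: float = 1.1,
    peak_height: float = 1.9,
    peak_width: float = 0.22,
    onset: float = 0.85,
) -> Profile1D:
    """Synthetic fluid-phase lateral tail-tail RDF (dimensionless g(r))."""
    r = np.arange(0.5 * dr, r_max, dr)
    excluded = 1.0 / (1.0 + np.exp(-(r - onset) / 0.06))
    first_peak = (peak_height - 1.0) * np.exp(-0.5 * ((r - peak_r) / peak_width) ** 2)
    second = 0.25 * np.exp(-0.5 * ((r - 2.0 * peak_r) / (2.0 * peak_width)) ** 2)
    return Profile1D(r, excluded * (1.0 + first_peak + second), dr, normalized=False)


def reference_density_profile(
    dz: float = 0.1,
    half_width: float = 4.0,
    peak_z: float = 1.45,
    peak_width: float = 0.35,
) -> Profile1D:
    """Synthetic head-group mass density across the bilayer (bimodal in z)."""
    z = np.arange(-half_width + 0.5 * dz, half_width, dz)
    shape = np.exp(-0.5 * ((z - peak_z) / peak_width) ** 2) + np.exp(
        -0.5 * ((z + peak_z) / peak_width) ** 2
    )
    return Profile1D(z, shape, dz, normalized=False)
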