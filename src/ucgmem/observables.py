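"""Membrane property estimators scored by the parametrization loop.

Seven observables: area per lipid, area compressibility, line tension,
bending modulus from the undulation spectrum, gel-fluid transition
temperature, lateral radial distribution function, and the center-of-mass
centered density profile; plus the Earth Mover's Distance used to compare
the two distribution-valued observables against reference curves.

All estimators consume plain arrays (box-length series, pressure-tensor
series, position frames) so they run identically on engine output and on
synthetic fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import BAR_NM2_TO_PN, KB_SI

__all__ = [
    "BoxSeries",
    "Spectrum",
    "Profile1D",
    "PropertyReport",
    "block_stderr",
    "area_per_lipid",
    "area_compressibility",
    "line_tension",
    "height_field",
    "undulation_spectrum",
    "fit_bending_modulus",
    "detect_transition",
    "lateral_rdf",
    "density_profile",
    "emd",
]

N_BLOCKS = 5


def block_stderr(x: np.ndarray, n_blocks: int = N_BLOCKS) -> float:
    """Standard error of the mean from block averages (correlation-robust)."""
    x = np.asarray(x, dtype=float)
    n = len(x) // n_blocks
    if n < 1:
        return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    blocks = x[: n * n_blocks].reshape(n_blocks, n).mean(axis=1)
    return float(np.std(blocks, ddof=1) / math.sqrt(n_blocks))


@dataclass
class BoxSeries:
    """Per-frame box dimensions from a pressure-coupled run."""

    time: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    lz: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.ly = np.asarray(self.ly, dtype=float)
        self.lz = np.asarray(self.lz, dtype=float)
        n = {len(self.time), len(self.lx), len(self.ly), len(self.lz)}
        if len(n) != 1:
            raise ValueError("box series columns differ in length")
        if len(self.lx) and (np.any(self.lx <= 0) or np.any(self.ly <= 0)):
            raise ValueError("box lengths must be positive")

    @classmethod
    def from_trajectory(cls, traj) -> "BoxSeries":
        b = traj.box_series
        return cls(time=traj.times, lx=b[:, 0], ly=b[:, 1], lz=b[:, 2])

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Spectrum:
    """Radially binned height-fluctuation spectrum <|u_q|^2>(q)."""

    q: np.ndarray           # 1/nm, ascending
    s: np.ndarray           # nm^2
    n_frames: int
    box_side: float         # nm
    grid: int


@dataclass
class Profile1D:
    """Uniformly binned 1-D profile (RDF, density, or tilt histogram)."""

    centers: np.ndarray
    values: np.ndarray
    bin_width: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def normalize(self) -> "Profile1D":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return Profile1D(self.centers, self.values / total, self.bin_width, True)

    def resample(self, centers: np.ndarray) -> "Profile1D":
        centers = np.asarray(centers, dtype=float)
        vals = np.interp(centers, self.centers, self.values, left=0.0, right=0.0)
        width = float(centers[1] - centers[0]) if len(centers) > 1 else self.bin_width
        return Profile1D(centers, vals, width, False)


@dataclass
class PropertyReport:
    """The seven observables for one parameter set, with uncertainties."""

    apl: float = math.nan               # nm^2
    ka: float = math.nan                # mN/m
    line_tension: float = math.nan      # pN
    kc: float = math.nan                # kBT
    ptt: float = math.nan               # K
    rdf: Profile1D | None = None
    density: Profile1D | None = None
    errors: dict = field(default_factory=dict)
    tier: str = "desk"

    def scalar_properties(self) -> dict[str, float]:
        return {"apl": self.apl, "ka": self.ka, "line_tension": self.line_tension,
                "kc": self.kc, "ptt": self.ptt}


# ---------------------------------------------------------------------------
# scalar estimators
# ---------------------------------------------------------------------------

def area_per_lipid(series: BoxSeries, n_per_leaflet: int) -> tuple[float, float]:
    """<Lx*Ly> / n_per_leaflet (nm^2) with a block-averaged standard error."""
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    if len(series) == 0:
        raise ValueError("empty box series")
    area = series.lx * series.ly
    return float(area.mean()) / n_per_leaflet, block_stderr(area) / n_per_leaflet


def area_compressibility(
    series: BoxSeries, temperature: float, n_boot: int = 200, seed: int = 0
) -> tuple[float, float]:
    """K_A = kB*T / (4 * var(Lx)) from box-length fluctuations, in mN/m.

    Uncertainty by block bootstrap over contiguous fifths of the series.
    """
    lx = series.lx
    var = float(np.var(lx))
    if var == 0.0:
        raise ZeroDivisionError("zero box-length variance: K_A diverges")
    kbt_j = KB_SI * temperature                       # J
    # var in nm^2 -> m^2 carries 1e-18; J/m^2 -> mN/m carries 1e3
    ka = kbt_j / (4.0 * var * 1e-18) * 1e3

    nb = N_BLOCKS
    n = len(lx) // nb
    if n >= 2:
        rng = np.random.default_rng(seed)
        blocks = lx[: n * nb].reshape(nb, n)
        est = []
        for _ in range(n_boot):
            sample = blocks[rng.integers(0, nb, nb)].ravel()
            v = np.var(sample)
            if v > 0:
                est.append(kbt_j / (4.0 * v * 1e-18) * 1e3)
        err = float(np.std(est)) if est else math.nan
    else:
        err = math.nan
    return float(ka), err


def line_tension(
    pressures: np.ndarray,
    lx: float,
    lz: float,
    geometry: str = "ribbon",
) -> tuple[float, float]:
    """Edge line tension (pN) from ribbon pressure-tensor anisotropy.

    gamma_L = -(Lx*Lz/2) * (Pyy - (Pxx+Pzz)/2); the 1/2 accounts for the
    strip's two free edges.  Requires a fixed-box ribbon (periodic in y,
    free edges in x).
    """
    if geometry != "ribbon":
        raise ValueError(f"line tension needs a ribbon geometry, got {geometry!r}")
    p = np.asarray(pressures, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("pressures must be an (n, 3) array of (Pxx, Pyy, Pzz)")
    series = -(lx * lz / 2.0) * (p[:, 1] - 0.5 * (p[:, 0] + p[:, 2])) * BAR_NM2_TO_PN
    return float(series.mean()), block_stderr(series)


# ---------------------------------------------------------------------------
# bending modulus pipeline
# ---------------------------------------------------------------------------

def height_field(
    positions: np.ndarray,
    box: np.ndarray,
    grid: int,
    max_empty_frac: float = 0.3,
) -> np.ndarray:
    """Map beads onto an N x N membrane height grid u(x, y), mean-subtracted.

    Every bead contributes to its nearest grid node (parameter-free
    variant); empty nodes are filled by iterative averaging over their
    four periodic neighbors.
    """
    pos = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    ix = np.round(pos[:, 0] / box[0] * grid).astype(int) % grid
    iy = np.round(pos[:, 1] / box[1] * grid).astype(int) % grid
    flat = ix * grid + iy
    sums = np.bincount(flat, weights=pos[:, 2], minlength=grid * grid)
    counts = np.bincount(flat, minlength=grid * grid)
    empty = counts == 0
    n_empty = int(empty.sum())
    if n_empty > max_empty_frac * grid * grid:
        raise ValueError(
            f"{n_empty}/{grid * grid} empty height-field cells: grid too fine"
        )
    u = np.where(empty, 0.0, sums / np.maximum(counts, 1)).reshape(grid, grid)
    filled = ~empty.reshape(grid, grid)
    while not filled.all():
        neigh_sum = np.zeros_like(u)
        neigh_cnt = np.zeros_like(u)
        for shift in (1, -1):
            for axis in (0, 1):
                neigh_sum += np.roll(np.where(filled, u, 0.0), shift, axis=axis)
                neigh_cnt += np.roll(filled.astype(float), shift, axis=axis)
        newly = (~filled) & (neigh_cnt > 0)
        u[newly] = neigh_sum[newly] / neigh_cnt[newly]
        filled |= newly
    return u - u.mean()


def undulation_spectrum(fields: Sequence[np.ndarray], box_side: float) -> Spectrum:
    """Radially binned <|u_q|^2> from per-frame height grids.

    Fourier convention u(r) = sum_q u_q exp(i q.r), so u_q = FFT2(u)/N^2
    and Parseval reads sum_q |u_q|^2 = <u^2> (spatial mean square).
    q = 0 is excluded; radial bins have width 2*pi/L.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no height fields")
    n = fields[0].shape[0]
    power = np.zeros((n, n))
    for u in fields:
        a = np.fft.fft2(u) / (n * n)
        power += np.abs(a) ** 2
    power /= len(fields)

    freqs = np.fft.fftfreq(n, d=box_side / n) * 2.0 * math.pi
    qx, qy = np.meshgrid(freqs, freqs, indexing="ij")
    qmag = np.sqrt(qx**2 + qy**2)
    # average over exact-|q| shells: mixing different magnitudes in one bin
    # would bias the steep q^-4 fit (S varies 4x between dq and sqrt(2) dq)
    shells, inverse = np.unique(np.round(qmag.ravel(), 9), return_inverse=True)
    sums = np.bincount(inverse, weights=power.ravel())
    cnts = np.bincount(inverse)
    valid = shells > 0
    return Spectrum(
        q=shells[valid],
        s=(sums / cnts)[valid],
        n_frames=len(fields),
        box_side=box_side,
        grid=n,
    )


def default_q_max(spec: Spectrum) -> float:
    """Continuum-regime fit window: q <= min(0.8 nm^-1, 0.4 * q_Nyquist)."""
    q_nyq = math.pi * spec.grid / spec.box_side
    return min(0.8, 0.4 * q_nyq)


def fit_bending_modulus(
    spec: Spectrum, temperature: float | None = None, q_max: float | None = None
) -> tuple[float, float]:
    """Bending modulus kc (units of kB*T) from the q^-4 undulation regime.

    For a tensionless membrane <|u_q|^2> = kB*T / (L^2 kc q^4); with kc
    expressed in kB*T the relation is S(q) = 1 / (L^2 kc_kBT q^4), so the
    fit is a one-parameter least squares of S against x = 1/(L^2 q^4)
    restricted to q <= q_max.  `temperature` is accepted for interface
    symmetry but cancels out in kB*T units.
    """
    if q_max is None:
        q_max = default_q_max(spec)
    mask = spec.q <= q_max
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 spectrum bins below q_max={q_max:.3f}")
    x = 1.0 / (spec.box_side**2 * spec.q[mask] ** 4)
    s = spec.s[mask]
    slope = float(np.dot(s, x) / np.dot(x, x))     # slope = 1/kc
    if slope <= 0:
        raise ValueError("non-positive spectral amplitude: cannot fit kc")
    resid = s - slope * x
    dof = max(mask.sum() - 1, 1)
    slope_err = math.sqrt(float(np.dot(resid, resid)) / dof / float(np.dot(x, x)))
    kc = 1.0 / slope
    return kc, kc * slope_err / slope


# ---------------------------------------------------------------------------
# phase transition detection
# ---------------------------------------------------------------------------

def detect_transition(
    temperatures: Sequence[float],
    enthalpy_series: Sequence[np.ndarray],
    tail_fraction: float = 0.5,
    significance: float = 5.0,
) -> tuple[float | None, tuple[float, float] | None]:
    """Locate the gel-fluid transition from enthalpy-vs-T plateau jumps.

    Each series' equilibrated tail gives one enthalpy plateau; the
    transition zone is the adjacent temperature pair bracketing the
    largest plateau jump, provided it exceeds `significance` times the
    pooled plateau standard error.  Returns (midpoint, zone) or
    (None, None) when no significant jump exists.
    """
    temps = np.asarray(temperatures, dtype=float)
    order = np.argsort(temps)
    temps = temps[order]
    means, errs = [], []
    for idx in order:
        series = np.asarray(enthalpy_series[idx], dtype=float)
        tail = series[int(len(series) * (1.0 - tail_fraction)):]
        means.append(float(tail.mean()))
        errs.append(block_stderr(tail))
    means = np.asarray(means)
    pooled = math.sqrt(float(np.mean(np.square(errs)))) if len(errs) else 0.0

    jumps = np.diff(means)
    if len(jumps) == 0:
        return None, None
    j = int(np.argmax(jumps))
    if jumps[j] <= significance * pooled or jumps[j] <= 0:
        return None, None
    zone = (float(temps[j]), float(temps[j + 1]))
    return 0.5 * (zone[0] + zone[1]), zone


# ---------------------------------------------------------------------------
# distribution-valued observables
# ---------------------------------------------------------------------------

def lateral_rdf(
    frames: Sequence[tuple[np.ndarray, np.ndarray]],
    dr: float = 0.05,
    r_max: float | None = None,
) -> Profile1D:
    """2-D radial distribution function in the membrane plane.

    `frames` is a sequence of (positions, box) with positions already
    restricted to the selection (e.g. tail beads).  Lateral minimum-image
    distances; normalization g(r) = n(r, r+dr) / (rho * 2 pi r dr) with
    rho the planar number density of the selection.
    """
    if not frames:
        raise ValueError("no frames")
    if any(len(p) == 0 for p, _ in frames):
        raise ValueError("empty selection")
    if r_max is None:
        r_max = 0.5 * min(min(b[0], b[1]) for _, b in frames)
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    norm = 0.0
    for pos, box in frames:
        xy = pos[:, :2]
        n = len(xy)
        d = xy[:, None, :] - xy[None, :, :]
        d -= box[:2] * np.round(d / box[:2])
        r = np.sqrt((d**2).sum(axis=-1))
        iu = np.triu_indices(n, k=1)
        counts += np.histogram(r[iu], bins=edges)[0]
        # n_ref * rho_partner / 2: pairs counted once, partner density (n-1)/A
        norm += n * ((n - 1) / (box[0] * box[1])) / 2.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 2.0 * math.pi * centers * dr
    g = counts / (norm * shell)
    return Profile1D(centers, g, dr, normalized=False)


def density_profile(
    frames: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    dz: float = 0.1,
    half_width: float | None = None,
) -> Profile1D:
    """Mass density along z relative to the instantaneous selection COM.

    `frames` is a sequence of (positions, masses, box) for the selection.
    Returns amu/nm^3 averaged over frames, bins centered on the COM.
    """
    if not frames:
        raise ValueError("no frames")
    if any(len(p) == 0 for p, _, _ in frames):
        raise ValueError("empty selection")
    if half_width is None:
        half_width = 0.5 * max(b[2] for _, _, b in frames)
    edges = np.arange(-half_width, half_width + dz, dz)
    hist = np.zeros(len(edges) - 1)
    for pos, masses, box in frames:
        com_z = float(np.average(pos[:, 2], weights=masses))
        rel = pos[:, 2] - com_z
        area = box[0] * box[1]
        hist += np.histogram(rel, bins=edges, weights=masses)[0] / (area * dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(centers, hist / len(frames), dz, normalized=False)


def emd(pa: Profile1D, pb: Profile1D) -> float:
    """1-D Earth Mover's (Wasserstein-1) distance between two profiles.

    Profiles must share a support grid (use :meth:`Profile1D.resample`);
    non-normalized inputs are normalized first.  Equals the integral of
    the absolute CDF difference, in the units of the bin axis.
    """
    if len(pa.centers) != len(pb.centers) or not np.allclose(pa.centers, pb.centers):
        raise ValueError("profiles must share a common support grid")
    a = pa if pa.normalized else pa.normalize()
    b = pb if pb.normalized else pb.normalize()
    cdf_diff = np.cumsum(a.values - b.values)
    return float(np.sum(np.abs(cdf_diff)) * a.bin_width)
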