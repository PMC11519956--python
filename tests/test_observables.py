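"""Estimator tests: closed forms, sampling closures, and independent oracles."""

import math

import numpy as np
import pytest
import scipy.stats
from scipy.optimize import linprog

from ucgmem import fixtures, observables as obs
from ucgmem.observables import BoxSeries, Profile1D


def make_series(lx, ly=None, lz=None):
    lx = np.asarray(lx, dtype=float)
    ly = lx if ly is None else np.asarray(ly, dtype=float)
    lz = np.full_like(lx, 10.0) if lz is None else np.asarray(lz, dtype=float)
    return BoxSeries(time=np.arange(len(lx), dtype=float), lx=lx, ly=ly, lz=lz)


class TestAreaPerLipid:
    def test_constant_box(self):
        series = make_series(np.full(50, 8.0))
        apl, err = obs.area_per_lipid(series, 100)
        assert apl == pytest.approx(0.64, rel=1e-12)
        assert err == 0.0

    def test_quadratic_scaling(self, rng):
        lx = 8.0 + 0.05 * rng.standard_normal(500)
        series = make_series(lx)
        scaled = make_series(1.1 * lx)
        a1, _ = obs.area_per_lipid(series, 64)
        a2, _ = obs.area_per_lipid(scaled, 64)
        assert a2 == pytest.approx(1.21 * a1, rel=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            obs.area_per_lipid(make_series(np.array([])), 10)


class TestAreaCompressibility:
    def test_closed_form_at_known_sd(self):
        """kB*315 K / (4 * (0.1 nm)^2) = 108.7 mN/m, via a synthetic series
        whose sample variance is forced to the target value."""
        rng = np.random.default_rng(7)
        lx = rng.standard_normal(4000)
        lx = (lx - lx.mean()) / lx.std() * 0.1 + 8.0   # exact sd 0.1
        ka, _ = obs.area_compressibility(make_series(lx), 315.0)
        assert ka == pytest.approx(108.7, rel=1e-3)

    def test_sampling_closure_at_1e6(self):
        series = fixtures.synth_gaussian_box_series(8.0, 0.1, 1_000_000, seed=11)
        ka, _ = obs.area_compressibility(series, 315.0)
        assert ka == pytest.approx(108.7, rel=0.01)

    def test_error_scales_as_inverse_sqrt_n(self):
        errs = []
        for n in (10**3, 10**4, 10**5):
            series = fixtures.synth_gaussian_box_series(8.0, 0.1, n, seed=3)
            ka, _ = obs.area_compressibility(series, 315.0)
            errs.append(abs(ka - 108.7))
        # each decade of samples shrinks the error by roughly sqrt(10)
        assert errs[2] < errs[0]
        assert errs[2] < 0.01 * 108.7

    def test_zero_variance_diverges(self):
        with pytest.raises(ZeroDivisionError):
            obs.area_compressibility(make_series(np.full(100, 8.0)), 315.0)


class TestLineTension:
    def test_arithmetic_conversion(self):
        p = np.tile([0.0, -10.0, 0.0], (50, 1))
        lt, _ = obs.line_tension(p, 10.0, 10.0)
        assert lt == pytest.approx(50.0, rel=1e-12)

    def test_isotropic_pressure_gives_zero(self, rng):
        iso = np.repeat(rng.normal(1.0, 5.0, 200)[:, None], 3, axis=1)
        lt, _ = obs.line_tension(iso, 12.0, 9.0)
        assert lt == pytest.approx(0.0, abs=1e-10)

    def test_non_ribbon_geometry_refused(self):
        with pytest.raises(ValueError):
            obs.line_tension(np.zeros((10, 3)), 10.0, 10.0, geometry="bilayer")


class TestHeightField:
    def test_flat_sheet_maps_to_zero(self, rng):
        pos = np.column_stack([rng.uniform(0, 20, 4000),
                               rng.uniform(0, 20, 4000),
                               np.full(4000, 5.0)])
        u = obs.height_field(pos, np.array([20.0, 20.0, 10.0]), 16)
        assert np.allclose(u, 0.0, atol=1e-12)

    def test_rigid_z_translation_invariant(self, rng):
        pos = np.column_stack([rng.uniform(0, 20, 4000),
                               rng.uniform(0, 20, 4000),
                               rng.normal(5.0, 0.3, 4000)])
        box = np.array([20.0, 20.0, 10.0])
        u1 = obs.height_field(pos, box, 12)
        pos2 = pos + np.array([0.0, 0.0, 2.5])
        u2 = obs.height_field(pos2, box, 12)
        assert np.allclose(u1, u2, atol=1e-10)

    def test_single_cosine_mode_recovered(self, rng):
        L, n_beads, a0 = 40.0, 20000, 0.8
        x = rng.uniform(0, L, n_beads)
        y = rng.uniform(0, L, n_beads)
        z = a0 * np.cos(2 * math.pi * x / L)
        u = obs.height_field(np.column_stack([x, y, z]),
                             np.array([L, L, 20.0]), 32)
        xg = (np.arange(32) + 0.0) * L / 32
        expected = a0 * np.cos(2 * math.pi * xg / L)
        rms = np.sqrt(np.mean((u - expected[:, None]) ** 2))
        assert rms < 0.05 * a0

    def test_too_fine_grid_rejected(self, rng):
        pos = rng.uniform(0, 20, (50, 3))
        with pytest.raises(ValueError):
            obs.height_field(pos, np.array([20.0, 20.0, 10.0]), 64)


class TestSpectrum:
    def test_zero_field_zero_spectrum(self):
        spec = obs.undulation_spectrum([np.zeros((16, 16))] * 5, 20.0)
        assert np.allclose(spec.s, 0.0)

    def test_single_cosine_mode_weight(self):
        """u = a*cos(q1 x) carries |u_q|^2 = a^2/4 on each of the +-q1
        modes; the |q| = q1 shell averages over the four modes (two
        active, the two transverse ones empty), hence a^2/8."""
        L, n, a = 20.0, 32, 0.7
        xg = np.arange(n) * L / n
        u = a * np.cos(2 * math.pi * xg / L)[:, None] * np.ones((1, n))
        spec = obs.undulation_spectrum([u], L)
        q1 = 2 * math.pi / L
        i = np.argmin(np.abs(spec.q - q1))
        assert spec.q[i] == pytest.approx(q1, rel=1e-8)
        assert spec.s[i] == pytest.approx(a**2 / 8.0, rel=1e-10)
        others = np.delete(spec.s, i)
        assert np.all(others < 1e-20)

    def test_white_noise_flat_spectrum(self, rng):
        n = 32
        fields = [rng.standard_normal((n, n)) for _ in range(400)]
        spec = obs.undulation_spectrum(fields, 20.0)
        # every mode has variance sigma^2/n^2 under the 1/n^2 convention
        expected = 1.0 / n**2
        assert np.all(np.abs(spec.s / expected - 1.0) < 0.15)


class TestBendingModulus:
    def test_exact_inversion_identity(self):
        L, kc = 40.0, 12.0
        q = np.arange(1, 12) * 2 * math.pi / L
        s = 1.0 / (L**2 * kc * q**4)
        spec = obs.Spectrum(q=q, s=s, n_frames=1, box_side=L, grid=64)
        got, _ = obs.fit_bending_modulus(spec, q_max=0.8)
        assert got == pytest.approx(kc, rel=1e-12)

    @pytest.mark.parametrize("kc", [8.0, 12.0, 20.0, 40.0])
    def test_helfrich_surface_recovery(self, kc):
        fields = fixtures.synth_helfrich_surfaces(kc, 40.0, 64, 500, seed=int(kc))
        spec = obs.undulation_spectrum(fields, 40.0)
        got, _ = obs.fit_bending_modulus(spec)
        assert got == pytest.approx(kc, rel=0.15)

    def test_generator_spectrum_matches_law_per_bin(self):
        kc, L = 12.0, 40.0
        fields = fixtures.synth_helfrich_surfaces(kc, L, 64, 500, seed=5)
        spec = obs.undulation_spectrum(fields, L)
        mask = spec.q <= 0.8
        expected = 1.0 / (L**2 * kc * spec.q[mask] ** 4)
        assert np.all(np.abs(spec.s[mask] / expected - 1.0) < 0.10)

    def test_too_few_bins_rejected(self):
        spec = obs.Spectrum(q=np.array([0.1, 0.2]), s=np.array([1.0, 2.0]),
                            n_frames=1, box_side=40.0, grid=8)
        with pytest.raises(ValueError):
            obs.fit_bending_modulus(spec)


class TestTransition:
    def test_programmed_zone_and_midpoint(self):
        temps = np.arange(100.0, 401.0, 20.0)
        series = fixtures.synth_step_enthalpy(temps, 250.0, gap=500.0,
                                              noise=5.0, seed=2)
        ptt, zone = obs.detect_transition(temps, series)
        assert zone == (240.0, 260.0)
        assert ptt == 250.0

    def test_featureless_curve_gives_no_transition(self):
        temps = np.arange(200.0, 321.0, 20.0)
        series = fixtures.synth_step_enthalpy(temps, 250.0, gap=0.0,
                                              noise=5.0, seed=3)
        ptt, zone = obs.detect_transition(temps, series)
        assert ptt is None and zone is None

    def test_affine_enthalpy_rescaling_invariant(self):
        temps = np.arange(150.0, 351.0, 20.0)
        series = fixtures.synth_step_enthalpy(temps, 270.0, gap=300.0,
                                              noise=3.0, seed=4)
        p1, z1 = obs.detect_transition(temps, series)
        rescaled = [7.0 * s + 123.0 for s in series]
        p2, z2 = obs.detect_transition(temps, rescaled)
        assert p1 == p2 and z1 == z2


class TestLateralRDF:
    def test_ideal_gas_is_unity(self, rng):
        frames = [(np.column_stack([rng.uniform(0, 20, 400),
                                    rng.uniform(0, 20, 400),
                                    np.zeros(400)]),
                   np.array([20.0, 20.0, 10.0])) for _ in range(40)]
        g = obs.lateral_rdf(frames, dr=0.25)
        mask = g.centers > 1.0
        assert np.abs(g.values[mask].mean() - 1.0) < 0.02
        assert np.all(np.abs(g.values[mask] - 1.0) < 0.15)

    def test_square_lattice_first_peak(self):
        a = 0.8
        n = 16
        ix, iy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pos = np.column_stack([ix.ravel() * a, iy.ravel() * a,
                               np.zeros(n * n)])
        box = np.array([n * a, n * a, 5.0])
        g = obs.lateral_rdf([(pos, box)], dr=0.05)
        first_nonzero = g.centers[np.nonzero(g.values)[0][0]]
        assert abs(first_nonzero - a) <= 0.05

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            obs.lateral_rdf([(np.zeros((0, 3)), np.array([10.0, 10.0, 10.0]))])


class TestDensityProfile:
    def test_com_centering_translation_invariance(self, rng):
        pos = rng.normal(5.0, 1.0, (300, 3))
        masses = np.full(300, 253.4)
        box = np.array([10.0, 10.0, 20.0])
        p1 = obs.density_profile([(pos, masses, box)])
        p2 = obs.density_profile([(pos + [0, 0, 3.7], masses, box)])
        assert np.allclose(p1.values, p2.values)

    def test_two_leaflet_bimodality(self, rng):
        z = np.concatenate([rng.normal(-1.5, 0.2, 500), rng.normal(1.5, 0.2, 500)])
        pos = np.column_stack([rng.uniform(0, 8, 1000),
                               rng.uniform(0, 8, 1000), z + 5.0])
        prof = obs.density_profile([(pos, np.full(1000, 253.4),
                                     np.array([8.0, 8.0, 10.0]))])
        mid = len(prof.values) // 2
        left_peak = prof.values[:mid].max()
        right_peak = prof.values[mid:].max()
        center_val = prof.values[np.argmin(np.abs(prof.centers))]
        assert left_peak > 5 * center_val and right_peak > 5 * center_val

    def test_mass_conservation(self, rng):
        pos = rng.uniform(0, 10, (200, 3))
        masses = np.full(200, 253.4)
        box = np.array([10.0, 10.0, 10.0])
        prof = obs.density_profile([(pos, masses, box)], dz=0.1, half_width=8.0)
        total = prof.values.sum() * prof.bin_width * box[0] * box[1]
        assert total == pytest.approx(masses.sum(), rel=1e-9)


def _emd_lp_oracle(a, b, centers):
    """Brute-force optimal-transport LP on small histograms."""
    n = len(a)
    cost = np.abs(centers[:, None] - centers[None, :]).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, n))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
    for j in range(n):
        row = np.zeros((n, n))
        row[:, j] = 1.0
        a_eq.append(row.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.concatenate([a, b]),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


class TestEMD:
    def test_identical_profiles_zero(self, rng):
        vals = rng.uniform(0, 1, 20)
        p = Profile1D(np.arange(20.0), vals, 1.0).normalize()
        assert obs.emd(p, p) == 0.0

    def test_unit_point_masses_distance_one(self):
        centers = np.arange(4.0)
        a = Profile1D(centers, np.array([1.0, 0, 0, 0]), 1.0, True)
        b = Profile1D(centers, np.array([0, 1.0, 0, 0]), 1.0, True)
        assert obs.emd(a, b) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transport_lp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        centers = np.arange(float(n))
        a = rng.uniform(0.01, 1.0, n)
        b = rng.uniform(0.01, 1.0, n)
        a /= a.sum()
        b /= b.sum()
        ours = obs.emd(Profile1D(centers, a, 1.0, True),
                       Profile1D(centers, b, 1.0, True))
        lp = _emd_lp_oracle(a, b, centers)
        assert ours == pytest.approx(lp, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_wasserstein(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 30
        centers = np.linspace(0.0, 5.8, n)
        a = rng.uniform(0.01, 1.0, n)
        b = rng.uniform(0.01, 1.0, n)
        ours = obs.emd(Profile1D(centers, a, centers[1] - centers[0]),
                       Profile1D(centers, b, centers[1] - centers[0]))
        ref = scipy.stats.wasserstein_distance(centers, centers,
                                               a / a.sum(), b / b.sum())
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_metric_axioms(self, rng):
        n = 10
        centers = np.arange(float(n))
        def prof(v):
            return Profile1D(centers, v / v.sum(), 1.0, True)
        for _ in range(20):
            a, b, c = (prof(rng.uniform(0.01, 1, n)) for _ in range(3))
            dab = obs.emd(a, b)
            dba = obs.emd(b, a)
            dac = obs.emd(a, c)
            dcb = obs.emd(c, b)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab >= 0
            assert dab <= dac + dcb + 1e-9

    def test_mismatched_grids_rejected(self):
        a = Profile1D(np.arange(5.0), np.ones(5) / 5, 1.0, True)
        b = Profile1D(np.arange(6.0), np.ones(6) / 6, 1.0, True)
        with pytest.raises(ValueError):
            obs.emd(a, b)


class TestBlockStderr:
    def test_iid_matches_naive_estimate(self, rng):
        x = rng.standard_normal(10000)
        err = obs.block_stderr(x)
        naive = x.std(ddof=1) / math.sqrt(len(x))
        assert err == pytest.approx(naive, rel=0.8)
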