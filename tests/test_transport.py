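"""Transport loop: sampling laws, conservation, mode equivalences,
determinism, and kernel-vs-reference agreement."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from voxlight._kernel import hg_cos_samples, rng_stream
from voxlight.normalmap import NormalMap, SmoothingConfig, compute_normal_map
from voxlight.phantoms import LabeledVolume, Medium, MediumTable, make_slab
from voxlight.transport import (Photon, SimulationConfig, SourceSpec,
                                XorShiftRNG, cross_boundary, drop,
                                get_boundary_normal, launch, roulette, run,
                                spin, trace_photon)


def _balance(stats):
    inflow = stats["launched"] + stats["roulette_boosted"]
    outflow = (stats["deposited"] + stats["escaped"]
               + stats["roulette_killed"] + stats["lost"])
    return abs(inflow - outflow) / inflow


class TestRNG:
    def test_python_mirror_matches_kernel_stream(self):
        ref = rng_stream(123, 7, 1000)
        rng = XorShiftRNG(123, 7)
        mine = np.array([rng.random() for _ in range(1000)])
        np.testing.assert_array_equal(ref, mine)

    def test_streams_distinct_across_photons(self):
        a = rng_stream(1, 0, 100)
        b = rng_stream(1, 1, 100)
        assert not np.array_equal(a, b)

    def test_uniformity(self):
        u = rng_stream(9, 0, 100_000)
        assert sps.kstest(u, "uniform").pvalue > 0.01


class TestLaunch:
    def test_pencil_beam_starts_at_origin(self):
        src = SourceSpec((0.1, 0.1, 0.01), (0.0, 0.0, 1.0), 0.0)
        ph = launch(src, XorShiftRNG(0), dx=0.01)
        np.testing.assert_allclose(ph.pos, (10.0, 10.0, 1.0), atol=2e-6)
        assert ph.weight == 1.0

    def test_disk_radial_distribution(self):
        src = SourceSpec((0.5, 0.5, 0.01), (0.0, 0.0, 1.0), 0.2)
        rng = XorShiftRNG(5)
        n = 20_000
        r = np.empty(n)
        for i in range(n):
            ph = launch(src, rng, dx=0.01)
            r[i] = math.hypot(ph.pos[0] - 50.0, ph.pos[1] - 50.0) * 0.01
        assert r.max() <= 0.2 + 1e-9
        # uniform disk: half the photons inside r/sqrt(2)
        frac = (r <= 0.2 / math.sqrt(2)).mean()
        assert abs(frac - 0.5) < 3.0 * math.sqrt(0.25 / n)

    def test_origin_outside_grid_rejected(self):
        src = SourceSpec((1.0, 0.1, 0.01), (0.0, 0.0, 1.0), 0.0)
        with pytest.raises(ValueError, match="outside"):
            launch(src, XorShiftRNG(0), dx=0.01, shape=(10, 10, 10))


class TestSpin:
    def test_isotropic_cosine_uniform(self):
        u = rng_stream(2, 0, 100_000)
        ct = hg_cos_samples(0.0, u)
        assert sps.kstest(ct, "uniform", args=(-1.0, 2.0)).pvalue > 0.01

    def test_hg_mean_cosine_equals_g(self):
        g = 0.9
        u = rng_stream(3, 0, 1_000_000)
        ct = hg_cos_samples(g, u)
        se = ct.std() / math.sqrt(ct.size)
        assert abs(ct.mean() - g) < 3.0 * se

    def test_direction_stays_unit(self, rng):
        r = XorShiftRNG(11)
        for _ in range(2000):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ph = Photon(np.zeros(3), d)
            spin(ph, 0.8, r)
            assert abs(np.linalg.norm(ph.dir) - 1.0) < 1e-12

    def test_invalid_g_rejected(self):
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="anisotropy"):
            spin(ph, 1.0, XorShiftRNG(0))


class TestDrop:
    def test_no_absorption_no_deposit(self):
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=0.7)
        ph, dw = drop(ph, Medium(0, n=1.0, mua=0.0, mus=10.0))
        assert dw == 0.0 and ph.weight == 0.7

    def test_equal_coefficients_half_weight(self):
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=0.8)
        ph, dw = drop(ph, Medium(0, n=1.0, mua=5.0, mus=5.0))
        assert dw == pytest.approx(0.4)
        assert ph.weight == pytest.approx(0.4)


class TestRoulette:
    def test_above_threshold_untouched(self):
        cfg = SimulationConfig(n_photons=1)
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=0.5)
        roulette(ph, cfg, XorShiftRNG(0))
        assert ph.weight == 0.5 and ph.alive

    def test_survivor_weight_multiplied(self):
        cfg = SimulationConfig(n_photons=1, roulette_survival=10.0)
        w0 = 5e-5
        rng = XorShiftRNG(1)
        for _ in range(200):
            ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=w0)
            roulette(ph, cfg, rng)
            if ph.alive:
                assert ph.weight == pytest.approx(10.0 * w0)

    def test_expected_weight_preserved(self):
        cfg = SimulationConfig(n_photons=1, roulette_survival=10.0)
        w0 = 5e-5
        rng = XorShiftRNG(2)
        n = 100_000
        total = 0.0
        for _ in range(n):
            ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=w0)
            roulette(ph, cfg, rng)
            if ph.alive:
                total += ph.weight
        # binomial survival at p = 1/m with payoff m*w0
        se = w0 * math.sqrt((cfg.roulette_survival - 1.0) / n)
        assert abs(total / n - w0) < 3.0 * se


class TestCrossBoundary:
    def test_matched_always_transmits_unchanged(self):
        rng = XorShiftRNG(0)
        for _ in range(100):
            ph = Photon(np.zeros(3), np.array([0.6, 0.0, 0.8]))
            ph, reflected = cross_boundary(ph, np.array([0.0, 0.0, -1.0]),
                                           1.33, 1.33, rng)
            assert not reflected
            np.testing.assert_allclose(ph.dir, (0.6, 0.0, 0.8), atol=1e-12)

    def test_tir_always_reflects(self):
        th = math.radians(60.0)
        d = np.array([math.sin(th), 0.0, math.cos(th)])
        rng = XorShiftRNG(1)
        for _ in range(100):
            ph = Photon(np.zeros(3), d.copy())
            _, reflected = cross_boundary(ph, np.array([0.0, 0.0, -1.0]),
                                          1.33, 1.00, rng)
            assert reflected

    def test_reflected_fraction_matches_fresnel(self):
        rng = XorShiftRNG(2)
        n = 30_000
        hits = 0
        for _ in range(n):
            ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
            _, reflected = cross_boundary(ph, np.array([0.0, 0.0, -1.0]),
                                          1.00, 1.33, rng)
            hits += reflected
        r0 = ((1 - 1.33) / (1 + 1.33)) ** 2
        assert abs(hits / n - r0) < 3.0 * math.sqrt(r0 * (1 - r0) / n)


class TestBoundaryNormalModes:
    def test_slab_all_modes_axis_aligned(self, mismatch_slab):
        vol, media, nm = mismatch_slab
        ph = Photon(np.array([20.0, 20.0, 30.0]), np.array([0.0, 0.0, 1.0]))
        for mode in ("facet", "surface", "interp"):
            n = get_boundary_normal(ph, mode, vol, media, nm,
                                    axis=2, sgn=1, current_voxel=(20, 20, 29))
            np.testing.assert_allclose(n, (0.0, 0.0, -1.0), atol=1e-7)

    def test_matched_mode_is_internal_error(self, mismatch_slab):
        vol, media, nm = mismatch_slab
        ph = Photon(np.array([20.0, 20.0, 30.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(RuntimeError):
            get_boundary_normal(ph, "matched", vol, media, nm, 2, 1, (20, 20, 29))

    def test_surface_mode_requires_normal_map(self, mismatch_slab):
        vol, media, _ = mismatch_slab
        ph = Photon(np.array([20.0, 20.0, 30.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="normal map"):
            get_boundary_normal(ph, "surface", vol, media, None, 2, 1, (20, 20, 29))


class TestRunConservationAndDeterminism:
    def _run(self, volume, media, nm, mode, seed=3, n=3000):
        src = SourceSpec((0.2, 0.2, 0.01), (0.0, 0.0, 1.0), 0.05)
        cfg = SimulationConfig(n_photons=n, mode=mode, seed=seed, source=src)
        return run(volume, media, nm, cfg)

    def test_energy_conserved_every_mode(self, mismatch_slab):
        vol, media, nm = mismatch_slab
        for mode in ("matched", "facet", "surface", "interp"):
            fl, _ = self._run(vol, media, nm, mode)
            assert _balance(fl.stats) < 1e-6

    def test_seeded_runs_bitwise_identical(self, mismatch_slab):
        vol, media, nm = mismatch_slab
        fl1, esc1 = self._run(vol, media, nm, "interp")
        fl2, esc2 = self._run(vol, media, nm, "interp")
        np.testing.assert_array_equal(fl1.values, fl2.values)
        assert esc1.table.equals(esc2.table)

    def test_matched_index_modes_bitwise_equal(self):
        """With every refractive index equal, all four boundary modes must
        produce identical trajectories for the same seed."""
        media = MediumTable([
            Medium(1, n=1.33, mua=0.5, mus=10.0, g=0.7),
            Medium(2, n=1.33, mua=1.0, mus=30.0, g=0.9),
        ])
        vol = make_slab((40, 40, 60), 0.01, 0.3, media=media)
        nm = compute_normal_map(vol, media, SmoothingConfig(2.0))
        ref, ref_esc = self._run(vol, media, nm, "matched")
        for mode in ("facet", "surface", "interp"):
            fl, esc = self._run(vol, media, nm, mode)
            np.testing.assert_array_equal(ref.values, fl.values)
            assert ref_esc.table.equals(esc.table)

    def test_planar_slab_modes_bitwise_equal(self, mismatch_slab):
        """For an axis-aligned interface all three normal estimates coincide
        exactly, so whole runs must agree bitwise."""
        vol, media, nm = mismatch_slab
        ref, ref_esc = self._run(vol, media, nm, "facet")
        for mode in ("surface", "interp"):
            fl, esc = self._run(vol, media, nm, mode)
            np.testing.assert_array_equal(ref.values, fl.values)
            assert ref_esc.table.equals(esc.table)

    def test_escape_positions_on_grid_faces(self, mismatch_slab):
        vol, media, nm = mismatch_slab
        _, esc = self._run(vol, media, nm, "interp")
        assert len(esc) > 0
        pos = esc.table[["x_cm", "y_cm", "z_cm"]].to_numpy()
        extent = np.array(vol.shape) * vol.dx
        on_face = np.zeros(len(esc), dtype=bool)
        for a in range(3):
            on_face |= np.isclose(pos[:, a], 0.0, atol=1e-9)
            on_face |= np.isclose(pos[:, a], extent[a], atol=1e-9)
        assert on_face.all()

    def test_total_absorption_conservation(self):
        """A thick absorbing slab with matched indices swallows the whole
        beam: deposited weight equals the launched weight."""
        media = MediumTable([Medium(1, n=1.0, mua=500.0), Medium(2, n=1.0, mua=500.0)])
        vol = make_slab((20, 20, 40), 0.01, 0.2, media=media)
        src = SourceSpec((0.1, 0.1, 0.01), (0.0, 0.0, 1.0), 0.0)
        cfg = SimulationConfig(n_photons=2000, mode="matched", seed=1, source=src)
        fl, _ = run(vol, media, None, cfg)
        assert fl.stats["deposited"] == pytest.approx(2000.0, rel=1e-3)

    def test_missing_normal_map_rejected(self, mismatch_slab):
        vol, media, _ = mismatch_slab
        cfg = SimulationConfig(n_photons=10, mode="surface", seed=0,
                               source=SourceSpec((0.2, 0.2, 0.01), (0, 0, 1.0)))
        with pytest.raises(ValueError, match="normal map"):
            run(vol, media, None, cfg)


class TestBeerLambert:
    def test_depth_profile_exponential(self):
        """Pencil beam into a pure absorber: the deposited-weight depth
        profile follows exp(-mua z) (first-interaction depths are the free
        paths, so this exercises the hop sampling law end to end)."""
        mua = 10.0
        media = MediumTable([Medium(1, n=1.0, mua=mua), Medium(2, n=1.0, mua=mua)])
        vol = make_slab((10, 10, 300), 0.01, 1.0, media=media)
        src = SourceSpec((0.05, 0.05, 0.001), (0.0, 0.0, 1.0), 0.0)
        cfg = SimulationConfig(n_photons=100_000, mode="matched", seed=4, source=src)
        fl, _ = run(vol, media, None, cfg)
        prof = fl.raw.sum(axis=(0, 1))
        z_edges = np.arange(301) * 0.01
        cdf_emp = np.cumsum(prof) / prof.sum()
        # truncated-exponential CDF over the grid depth
        cdf_th = (1 - np.exp(-mua * z_edges[1:])) / (1 - math.exp(-mua * 3.0))
        assert np.abs(cdf_emp - cdf_th).max() < 0.01


class TestReferenceStepperAgreement:
    def test_python_trace_matches_kernel_per_photon(self, small_sphere):
        """The pure-Python stepper consumes the same stream and must land
        every photon on the kernel's exit state."""
        vol, media, nm = small_sphere
        src = SourceSpec((0.3, 0.3, 0.01), (0.0, 0.0, 1.0), 0.05)
        cfg = SimulationConfig(n_photons=40, mode="interp", seed=7, source=src)
        _, esc = run(vol, media, nm, cfg)
        table = esc.table.set_index("photon_id")
        matched = 0
        for i in range(cfg.n_photons):
            rng = XorShiftRNG(cfg.seed, i)
            ph = launch(src, rng, vol.dx, vol.shape)
            out = trace_photon(vol, media, nm, ph, cfg, rng)
            assert out["escaped"] == (i in table.index)
            if out["escaped"]:
                row = table.loc[i]
                assert out["face"] == row.face
                np.testing.assert_allclose(
                    out["photon"].dir, (row.ux, row.uy, row.uz), atol=1e-9)
                assert out["photon"].weight == pytest.approx(row.weight, abs=1e-9)
                matched += 1
        assert matched > 10


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_photons": 0},
        {"n_photons": 10, "mode": "banana"},
        {"n_photons": 10, "roulette_threshold": 0.0},
        {"n_photons": 10, "roulette_survival": 1.0},
    ])
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_bad_source_rejected(self):
        with pytest.raises(ValueError):
            SourceSpec((0, 0, 0), (0, 0, 2.0))
        with pytest.raises(ValueError):
            SourceSpec((0, 0, 0), (0, 0, 1.0), radius=-0.1)
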