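import math

import numpy as np
import pytest

from earlyflt import (DomainError, FluorophoreProps, OpticalMedium, Phantom,
                      PhotonState, ProbeGeometry, SRLink, TraversalError,
                      VoxelGrid, compute_sensitivity,
                      compute_sensitivity_multi, fluorescence_conversion,
                      launch_photon, propagate, sample_hg_cosines,
                      simulate_ftpsf, traverse_voxels)


def _slab_phantom(depth_mm=5.0, mus=1e-9, mua=0.01, n=1.0, masked=False):
    """Nearly non-scattering slab for straight-line oracles."""
    nz = int(round(depth_mm / 0.5))
    grid = VoxelGrid((10, 10, nz), 0.5, (-2.5, -2.5, 0.0))
    mask = np.full(grid.shape, masked)
    medium = OpticalMedium(mua=mua, mus=mus, g=0.0, n=n)
    fluor = FluorophoreProps(muaf=mua, gamma=0.2, tau=900.0)
    return Phantom(grid=grid, medium=medium, fluor=fluor, fluoro_mask=mask,
                   muaf_map=np.where(mask, mua, 0.0),
                   tau_map=np.where(mask, 900.0, np.nan))


class TestLaunch:
    def test_no_angle_beyond_critical(self, probe, rng):
        cr = probe.critical_angle_rad
        for _ in range(2000):
            p = launch_photon(probe, (0, 0, 0), rng)
            assert math.acos(p.direction[2]) <= cr + 1e-12

    def test_uniform_disk_mean_radius(self, probe, rng):
        n = 100_000
        radius = probe.fiber_diameter / 2.0
        rs = np.empty(n)
        for i in range(n):
            p = launch_photon(probe, (0, 0, 0), rng)
            rs[i] = math.hypot(p.position[0], p.position[1])
        # uniform disk: E[r] = 2R/3, sd[r] = R sqrt(1/2 - 4/9)
        se = radius * math.sqrt(0.5 - 4.0 / 9.0) / math.sqrt(n)
        assert abs(rs.mean() - 2.0 * radius / 3.0) < 3.0 * se

    def test_point_source_limit(self, rng):
        probe = ProbeGeometry(fiber_diameter=0.0)
        for _ in range(100):
            p = launch_photon(probe, (0.3, -0.2, 0), rng)
            assert np.allclose(p.position, [0.3, -0.2, 0.0])
        assert p.weight == 1.0 and p.elapsed_time == 0.0


class TestTraverseVoxels:
    def test_axis_aligned_unit_segment(self):
        grid = VoxelGrid((20, 20, 20), 0.1, (0, 0, 0))
        seg = traverse_voxels((0.5, 0.55, 0.2), (1.5, 0.55, 0.2), grid)
        assert len(seg) == 10
        assert np.allclose(seg.lengths, 0.1)
        assert [i for (i, _, _), _ in seg] == list(range(5, 15))

    def test_oblique_segments_match_dense_sampling(self, rng):
        grid = VoxelGrid((12, 12, 12), 0.37, (-1.0, -1.0, 0.0))
        lo = np.array([-1.0, -1.0, 0.0])
        hi = lo + 12 * 0.37
        for _ in range(15):
            p0 = rng.uniform(lo + 0.05, hi - 0.05)
            p1 = rng.uniform(lo + 0.05, hi - 0.05)
            seg = traverse_voxels(p0, p1, grid)
            total = np.linalg.norm(p1 - p0)
            # dense point-sampling oracle
            ts = (np.arange(10_000) + 0.5) / 10_000
            pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
            idx = np.floor((pts - lo) / 0.37).astype(int)
            counts = {}
            for row in map(tuple, idx):
                counts[row] = counts.get(row, 0) + 1
            oracle = {k: v * total / 10_000 for k, v in counts.items()}
            got = {tuple(i): l for (i), l in zip(map(tuple, seg.indices),
                                                 seg.lengths)}
            assert abs(sum(got.values()) - total) < 1e-9
            for k in got:
                assert abs(got[k] - oracle.get(k, 0.0)) < 1e-3 + total / 5000

    def test_degenerate_segment_empty(self):
        grid = VoxelGrid((4, 4, 4), 1.0)
        assert len(traverse_voxels((1.2, 1.2, 1.2), (1.2, 1.2, 1.2),
                                   grid)) == 0

    def test_endpoint_outside_grid_rejected(self):
        grid = VoxelGrid((4, 4, 4), 1.0)
        with pytest.raises(TraversalError):
            traverse_voxels((0.5, 0.5, 0.5), (10.0, 0.5, 0.5), grid)


class TestPropagate:
    def test_ballistic_slab_crossing_time(self, rng):
        ph = _slab_phantom(depth_mm=4.0, n=1.521)
        photon = PhotonState(position=np.array([0.0, 0.0, 0.0]),
                             direction=np.array([0.0, 0.0, 1.0]))
        events = propagate(photon, ph, rng, max_time=1000.0)
        assert events[-1]["kind"] == "escape"
        c = 0.299792458 / 1.521
        assert events[-1]["time"] == pytest.approx(4.0 / c, rel=1e-12)

    def test_beer_lambert_attenuation(self, rng):
        ph = _slab_phantom(depth_mm=5.0, mua=0.0123)
        photon = PhotonState(position=np.array([0.0, 0.0, 0.0]),
                             direction=np.array([0.0, 0.0, 1.0]))
        events = propagate(photon, ph, rng, max_time=1000.0)
        assert events[-1]["weight"] == pytest.approx(
            math.exp(-0.0123 * 5.0), abs=1e-12)

    def test_hg_mean_cosine(self):
        g = 0.62
        n = 100_000
        cosines = sample_hg_cosines(g, n, seed=42)
        # HG: E[cos] = g, Var[cos] known via second moment
        se = cosines.std() / math.sqrt(n)
        assert abs(cosines.mean() - g) < 3.0 * se

    def test_isotropic_limit_of_hg(self):
        cosines = sample_hg_cosines(0.0, 50_000, seed=1)
        assert abs(cosines.mean()) < 3.0 / math.sqrt(12.0 / 4 * 50_000)


class TestFluorescenceConversion:
    def _masked_column_phantom(self):
        grid = VoxelGrid((3, 3, 40), 0.1, (-0.15, -0.15, 0.0))
        mask = np.zeros(grid.shape, bool)
        mask[1, 1, 10:30] = True  # 2 mm fluorophore column
        medium = OpticalMedium(0.01, 2.63, 0.62, 1.521)
        fluor = FluorophoreProps(0.01, 0.2, 900.0)
        return Phantom(grid=grid, medium=medium, fluor=fluor,
                       fluoro_mask=mask,
                       muaf_map=np.where(mask, 0.01, 0.0),
                       tau_map=np.where(mask, 900.0, np.nan))

    def _straight_trajectory(self, ph, rng):
        photon = PhotonState(position=np.array([0.0, 0.0, 0.0]),
                             direction=np.array([0.0, 0.0, 1.0]))
        med = ph.medium
        slab = Phantom(grid=ph.grid,
                       medium=OpticalMedium(med.mua, 1e-9, 0.0, med.n),
                       fluor=ph.fluor, fluoro_mask=ph.fluoro_mask,
                       muaf_map=ph.muaf_map, tau_map=ph.tau_map)
        return propagate(photon, slab, rng, max_time=1000.0), slab

    def test_no_crossing_no_spawns(self, rng):
        ph = _slab_phantom(masked=False)
        photon = PhotonState(position=np.array([0.0, 0.0, 0.0]),
                             direction=np.array([0.0, 0.0, 1.0]))
        events = propagate(photon, ph, rng, max_time=1000.0)
        assert fluorescence_conversion(events, ph, rng) == []

    def test_single_history_hand_weights(self, rng):
        """A straight vertical pass through a 2-mm fluorophore column:
        every 0.1-mm voxel crossing spawns weight
        exp(−μa·(distance to chord midpoint)) · μa · 0.1."""
        ph = self._masked_column_phantom()
        events, slab = self._straight_trajectory(ph, rng)
        spawns = fluorescence_conversion(events, slab, rng,
                                         mode="sensitivity")
        assert len(spawns) == 20
        mua = ph.medium.mua
        for k, sp in enumerate(spawns):
            mid = 1.0 + (k + 0.5) * 0.1
            expect = math.exp(-mua * mid) * mua * 0.1
            assert sp.weight == pytest.approx(expect, rel=1e-9)
            assert sp.delay == 0.0
        assert spawns[0].voxel_index == (1, 1, 10)

    def test_ftpsf_mode_delay_statistics(self, rng):
        ph = self._masked_column_phantom()
        events, slab = self._straight_trajectory(ph, rng)
        delays = []
        for _ in range(150):
            spawns = fluorescence_conversion(events, slab, rng, mode="ftpsf")
            delays.extend(s.delay for s in spawns)
        delays = np.asarray(delays)  # 3000 Exponential(900) samples
        se = 900.0 / math.sqrt(len(delays))
        assert abs(delays.mean() - 900.0) < 3.0 * se
        # gamma applied in ftpsf mode
        assert spawns[0].weight == pytest.approx(
            math.exp(-0.01 * 1.05) * 0.01 * 0.1 * 0.2, rel=1e-9)


class TestSimulateFTPSF:
    def test_zero_histories_rejected(self, small_phantom, probe):
        link = SRLink((0, 0, 0), (1.1, 0, 0), 1.1, 0, 0)
        with pytest.raises(DomainError):
            simulate_ftpsf(small_phantom, link, probe, 0, 1)

    def test_max_time_below_flight_time_gives_zero_curve(self, small_phantom,
                                                         probe):
        link = SRLink((0, 0, 0), (1.1, 0, 0), 1.1, 0, 0)
        curve = simulate_ftpsf(small_phantom, link, probe, 5000, 1,
                               max_time=20.0)
        assert not curve.values.any()

    def test_detected_not_exceeding_launched(self, small_phantom, probe):
        link = SRLink((-0.55, 0, 0), (0.55, 0, 0), 1.1, 0, 0)
        curve = simulate_ftpsf(small_phantom, link, probe, 20_000, 3,
                               max_time=300.0)
        assert 0.0 < curve.meta["detected_weight"] \
            <= curve.meta["launched_weight"]

    def test_bitwise_reproducible(self, small_phantom, probe):
        link = SRLink((-0.55, 0, 0), (0.55, 0, 0), 1.1, 0, 0)
        a = simulate_ftpsf(small_phantom, link, probe, 10_000, 7,
                           max_time=250.0)
        b = simulate_ftpsf(small_phantom, link, probe, 10_000, 7,
                           max_time=250.0)
        assert np.array_equal(a.values, b.values)
        c = simulate_ftpsf(small_phantom, link, probe, 10_000, 8,
                           max_time=250.0)
        assert not np.array_equal(a.values, c.values)


class TestComputeSensitivity:
    def test_zero_gate_all_zero(self, small_phantom, probe):
        link = SRLink((0, 0, 0), (1.1, 0, 0), 1.1, 0, 0)
        vol = compute_sensitivity(small_phantom, link, probe, 0.0, 100, 1)
        assert not vol.values.any()

    def test_gate_monotonicity_same_histories(self, small_phantom, probe):
        link = SRLink((-0.55, 0, 0), (0.55, 0, 0), 1.1, 0, 0)
        v100, v200 = compute_sensitivity_multi(small_phantom, link, probe,
                                               [100.0, 200.0], 20_000, 5)
        assert np.all(v100.values <= v200.values + 1e-300)
        assert v200.values.sum() > v100.values.sum() > 0.0

    def test_single_voxel_shadow_ray_oracle(self):
        """One fluorophore voxel under a nearly non-scattering medium:
        the accumulated per-history sensitivity matches an independent
        vectorized estimator (closed-form slab crossing for the straight
        excitation ray, exact disk integral of the shadow-ray kernel for
        the detection expectation)."""
        grid = VoxelGrid((9, 9, 9), 1.0, (-4.5, -4.5, 0.0))
        mask = np.zeros(grid.shape, bool)
        mask[4, 4, 4] = True  # x, y in [-0.5, 0.5), z in [4, 5) mm
        mua, mus = 0.01, 1e-9
        medium = OpticalMedium(mua, mus, 0.0, 1.0)
        fluor = FluorophoreProps(mua, 0.2, 900.0)
        ph = Phantom(grid=grid, medium=medium, fluor=fluor,
                     fluoro_mask=mask, muaf_map=np.where(mask, mua, 0.0),
                     tau_map=np.where(mask, 900.0, np.nan))
        probe = ProbeGeometry(fiber_diameter=0.4, sr_offsets=(0.3,))
        link = SRLink((0, 0, 0), (0.3, 0, 0), 0.3, 0, 0)
        n = 60_000
        vol = compute_sensitivity(ph, link, probe, 200.0, n, 9)
        got = vol.values[4, 4, 4] / n

        # independent oracle with its own sampling route
        orng = np.random.default_rng(123)
        m = 60_000
        rr = 0.2 * np.sqrt(orng.random(m))
        aa = 2 * np.pi * orng.random(m)
        sx, sy = rr * np.cos(aa), rr * np.sin(aa)
        cr = np.deg2rad(8.2)
        th = np.abs(orng.normal(0, cr / 2.0, 3 * m))
        th = th[th <= cr][:m]
        psi = 2 * np.pi * orng.random(m)
        ux = np.sin(th) * np.cos(psi)
        uy = np.sin(th) * np.sin(psi)
        uz = np.cos(th)
        # slab-method crossing of the voxel box
        with np.errstate(divide="ignore"):
            t_enter = np.maximum(4.0 / uz, np.maximum(
                np.minimum((-0.5 - sx) / ux, (0.5 - sx) / ux),
                np.minimum((-0.5 - sy) / uy, (0.5 - sy) / uy)))
            t_exit = np.minimum(5.0 / uz, np.minimum(
                np.maximum((-0.5 - sx) / ux, (0.5 - sx) / ux),
                np.maximum((-0.5 - sy) / uy, (0.5 - sy) / uy)))
        chord = np.clip(t_exit - t_enter, 0.0, None)
        d_mid = t_enter + chord / 2.0
        px = sx + ux * d_mid
        py = sy + uy * d_mid
        pz = uz * d_mid
        w_spawn = np.exp(-mua * d_mid) * mua * chord

        xs = np.linspace(0.1, 0.5, 80)
        ys = np.linspace(-0.2, 0.2, 80)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        on_disk = ((X - 0.3) ** 2 + Y ** 2 <= 0.2 ** 2).ravel()
        dA = (xs[1] - xs[0]) * (ys[1] - ys[0])
        Xf, Yf = X.ravel()[on_disk], Y.ravel()[on_disk]
        hit = chord > 0
        pxh, pyh, pzh, wh = px[hit], py[hit], pz[hit], w_spawn[hit]
        total = 0.0
        cos_cr = np.cos(cr)
        for lo in range(0, len(pxh), 1000):  # chunked: keeps memory small
            sl = slice(lo, lo + 1000)
            dx = Xf[None, :] - pxh[sl, None]
            dy = Yf[None, :] - pyh[sl, None]
            z = pzh[sl, None]
            r2 = dx * dx + dy * dy + z * z
            r = np.sqrt(r2)
            kern = np.where(z / r >= cos_cr,
                            z / (r2 * r) * np.exp(-(mua + mus) * r), 0.0)
            per_spawn = kern.sum(axis=1) * dA / (4.0 * np.pi)
            total += float((wh[sl] * per_spawn).sum())
        oracle = total / m
        assert got == pytest.approx(oracle, rel=0.08)

    def test_bitwise_reproducible(self, small_phantom, probe):
        link = SRLink((-0.55, 0, 0), (0.55, 0, 0), 1.1, 0, 0)
        a = compute_sensitivity(small_phantom, link, probe, 200.0, 5000, 11)
        b = compute_sensitivity(small_phantom, link, probe, 200.0, 5000, 11)
        assert np.array_equal(a.values, b.values)

    def test_monte_carlo_error_scales_with_histories(self, small_phantom,
                                                     probe):
        """Quadrupling the history count roughly halves the standard
        error of the total detected weight (wide band: the std estimate
        from 12 repeats is itself noisy)."""
        link = SRLink((-0.55, 0, 0), (0.55, 0, 0), 1.1, 0, 0)

        def spread(n, seed0):
            tot = [compute_sensitivity(small_phantom, link, probe, 200.0,
                                       n, seed0 + i).values.sum()
                   for i in range(12)]
            return np.std(tot) / np.mean(tot)

        r_small = spread(2000, 100)
        r_big = spread(8000, 200)
        assert 1.2 < r_small / r_big < 3.5
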