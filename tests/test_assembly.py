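import numpy as np
import pytest

from earlyflt import (AssemblyError, ProbeGeometry, ScanPattern,
                      SensitivityVolume, SRLink, VoxelGrid, assemble,
                      build_strategy1, build_strategy2, calibrate_scalar,
                      replicate_rows, scan_links, translate_volume)

R_SET = (3.3, 2.2, 1.1)


class TestStrategy1:
    def test_reference_table(self):
        s = build_strategy1(R_SET, 200.0)
        assert [e.velocity for e in s.entries] == pytest.approx(
            [0.0165, 0.011, 0.0055])
        assert [e.expected_links for e in s.entries] == [361, 361, 361]
        for e, R in zip(s.entries, R_SET):
            assert e.used_sr_distances == (R,)
            assert e.gate_per_distance == {R: 200}

    def test_single_distance(self):
        s = build_strategy1((1.0,), 100.0)
        assert len(s.entries) == 1
        assert s.entries[0].velocity == pytest.approx(0.01)

    def test_duplicate_distances_rejected(self):
        with pytest.raises(AssemblyError):
            build_strategy1((1.0, 1.0), 100.0)


class TestStrategy2:
    def test_reference_table(self):
        s = build_strategy2(R_SET, 200.0)
        e1, e2, e3 = s.entries
        assert e1.used_sr_distances == (3.3, 2.2, 1.1)
        assert e1.gate_per_distance == {3.3: 200, 2.2: 133, 1.1: 66}
        assert e2.used_sr_distances == (2.2, 1.1)
        assert e2.gate_per_distance == {2.2: 200, 1.1: 100}
        assert e3.used_sr_distances == (3.3, 2.2)
        assert e3.gate_per_distance == {3.3: 100, 2.2: 66}
        assert s.velocities == pytest.approx([0.0165, 0.011, 0.033])
        assert [e.expected_links for e in s.entries] == [1083, 722, 722]

    def test_constant_velocity_within_entries(self):
        s = build_strategy2(R_SET, 200.0)
        for e in s.entries:
            for R in e.used_sr_distances:
                assert R / e.exact_gates[R] == pytest.approx(e.velocity,
                                                             abs=1e-12)

    def test_needs_three_distances(self):
        with pytest.raises(AssemblyError):
            build_strategy2((3.3, 2.2), 200.0)


def _toy_scan(n=2, offsets=(1.0, 2.0)):
    probe = ProbeGeometry(sr_offsets=offsets, fiber_diameter=0.4)
    pattern = ScanPattern(n_rows=n, n_cols=n, step=1.0,
                          origin=(-(n - 1) / 2, -(n - 1) / 2))
    return pattern, probe, scan_links(pattern, probe)


def _vol(grid, link, gate, value=1.0, seed=0):
    values = np.full(grid.shape, value)
    return SensitivityVolume(grid=grid, values=values, link=link, gate=gate,
                             n_histories=10, seed=seed)


class TestAssemble:
    def test_shapes_and_row_order(self):
        pattern, probe, links = _toy_scan()
        grid = VoxelGrid((4, 4, 2), 1.0, (-2, -2, 0))
        s = build_strategy1(probe.sr_offsets, 100.0, n_positions=4)
        sens = {}
        meas = {}
        for ln in links:
            gate = 100
            sens[(ln.key, gate)] = _vol(grid, ln, gate,
                                        value=ln.sr_distance)
            meas[(ln.key, gate)] = 10.0 * ln.sr_distance
        sys_ = assemble(s.entries[0], links, sens, meas, calibration=2.0)
        assert sys_.shape == (4, 32)
        assert np.allclose(sys_.g, 20.0 * 1.0)
        # zigzag order preserved from the link list
        assert [k[0][:2] for k in sys_.rows] == [
            ln.key[:2] for ln in links if ln.sr_distance == 1.0]

    def test_missing_pair_rejected(self):
        pattern, probe, links = _toy_scan()
        s = build_strategy1(probe.sr_offsets, 100.0, n_positions=4)
        with pytest.raises(AssemblyError):
            assemble(s.entries[0], links, {}, {})

    def test_single_link_system(self):
        probe = ProbeGeometry(sr_offsets=(1.0,))
        pattern = ScanPattern(n_rows=1, n_cols=1, origin=(0, 0))
        links = scan_links(pattern, probe)
        grid = VoxelGrid((2, 2, 2), 1.0)
        s = build_strategy1((1.0,), 50.0, n_positions=1)
        key = (links[0].key, 50)
        sys_ = assemble(s.entries[0], links,
                        {key: _vol(grid, links[0], 50)}, {key: 7.0},
                        calibration=3.0)
        assert sys_.shape == (1, 8)
        assert sys_.g[0] == pytest.approx(21.0)


class TestReplicateRows:
    def _vol_with_blob(self):
        grid = VoxelGrid((8, 8, 4), 0.5, (-2, -2, 0))
        values = np.zeros(grid.shape)
        values[3, 2, 1] = 5.0
        link = SRLink((0.0, -1.0, 0.0), (1.0, -1.0, 0.0), 1.0, 0, 0)
        return SensitivityVolume(grid=grid, values=values, link=link,
                                 gate=100.0, n_histories=1, seed=0)

    def test_zero_shift_identity(self):
        vol = self._vol_with_blob()
        pattern = ScanPattern(n_rows=3, n_cols=3, step=0.5, origin=(-1, -1))
        out = replicate_rows([vol], pattern, 0, 0)[0]
        assert np.array_equal(out.values, vol.values)

    def test_one_row_is_pure_translation(self):
        vol = self._vol_with_blob()
        pattern = ScanPattern(n_rows=3, n_cols=3, step=0.5, origin=(-1, -1))
        out = replicate_rows([vol], pattern, 0, 1)[0]  # 0.5 mm = 1 voxel
        assert out.values[3, 3, 1] == 5.0
        assert out.values.sum() == vol.values.sum()

    def test_mass_conserved_for_interior_shifts(self):
        vol = self._vol_with_blob()
        pattern = ScanPattern(n_rows=5, n_cols=5, step=0.5, origin=(-1, -1))
        for target in range(5):
            out = replicate_rows([vol], pattern, 2, target)[0]
            assert out.values.sum() == pytest.approx(vol.values.sum())

    def test_fractional_voxel_shift_rejected(self):
        vol = self._vol_with_blob()
        pattern = ScanPattern(n_rows=2, n_cols=2, step=0.3, origin=(0, 0))
        with pytest.raises(AssemblyError):
            replicate_rows([vol], pattern, 0, 1)
        out = replicate_rows([vol], pattern, 0, 1, nearest=True)[0]
        assert out.values.sum() == pytest.approx(vol.values.sum())


class TestSymmetricMode:
    def test_translate_volume_moves_kernel_to_link(self):
        grid = VoxelGrid((10, 10, 4), 0.5, (-2.5, -2.5, 0))
        values = np.zeros(grid.shape)
        values[4, 5, 2] = 1.0
        center_link = SRLink((-0.5, 0.0, 0.0), (0.5, 0.0, 0.0), 1.0, 0, 0)
        vol = SensitivityVolume(grid=grid, values=values, link=center_link,
                                gate=100.0, n_histories=1, seed=0)
        target = SRLink((0.0, 0.5, 0.0), (1.0, 0.5, 0.0), 1.0, 1, 1)
        out = translate_volume(vol, target)
        assert out.values[5, 6, 2] == 1.0
        assert out.values.sum() == 1.0

    def test_symmetric_mode_same_kernel_every_link(self):
        from earlyflt import symmetric_sensitivities

        grid = VoxelGrid((10, 10, 4), 0.5, (-2.5, -2.5, 0))
        values = np.zeros(grid.shape)
        values[4, 5, 2] = 2.0
        center = SRLink((-0.5, 0.0, 0.0), (0.5, 0.0, 0.0), 1.0, 0, 0)
        kern = SensitivityVolume(grid=grid, values=values, link=center,
                                 gate=100.0, n_histories=1, seed=0)
        pattern = ScanPattern(n_rows=2, n_cols=2, step=0.5,
                              origin=(-1.0, -0.5))
        probe = ProbeGeometry(sr_offsets=(1.0,))
        links = scan_links(pattern, probe)
        sens = symmetric_sensitivities({(1.0, 100): kern}, links,
                                       amplitude=3.0)
        assert len(sens) == 4
        for vol in sens.values():
            assert vol.values.sum() == pytest.approx(6.0)
            assert vol.meta["amplitude_factor"] == 3.0

    def test_distance_mismatch_rejected(self):
        grid = VoxelGrid((4, 4, 2), 0.5)
        vol = SensitivityVolume(
            grid=grid, values=np.zeros(grid.shape),
            link=SRLink((0, 0, 0), (1, 0, 0), 1.0, 0, 0),
            gate=100.0, n_histories=1, seed=0)
        other = SRLink((0, 0, 0), (2, 0, 0), 2.0, 0, 0)
        with pytest.raises(AssemblyError):
            translate_volume(vol, other)


class TestCalibration:
    def test_scalar_minimizes_misfit(self, rng):
        W = rng.random((6, 30))
        f = rng.random(30)
        g_model = W @ f
        g_raw = g_model / 4.0
        kappa = calibrate_scalar(W, g_raw, f)
        assert kappa == pytest.approx(4.0)

    def test_all_zero_measurements_rejected(self):
        with pytest.raises(AssemblyError):
            calibrate_scalar(np.ones((2, 3)), np.zeros(2), np.ones(3))
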