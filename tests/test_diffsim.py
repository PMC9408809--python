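import numpy as np
import pytest

import myodti as m

UM = 1e-3  # mm per micron


@pytest.fixture(scope="module")
def fast_cfg() -> m.SimConfig:
    # short walks keep the membrane-interaction tests quick
    return m.SimConfig(n_walkers=400, duration=2e-3, seed=3)


@pytest.fixture(scope="module")
def structure_03(fast_cfg) -> m.CellStructure:
    return m.build_cell_structure(0.3, fast_cfg, seed=5)


class TestCellStructure:
    def test_target_one_is_empty(self):
        s = m.build_cell_structure(1.0, m.SimConfig(), seed=1)
        assert s.n_cylinders == 0 and s.measured_ecv == 1.0

    def test_measured_ecv_within_band(self, fast_cfg):
        s = m.build_cell_structure(0.9, fast_cfg, seed=2)
        assert 0.85 <= s.measured_ecv <= 0.95

    def test_diameters_within_range(self, structure_03):
        d_um = 2 * structure_03.radius / UM
        assert np.all(d_um >= 9.0 - 1e-9) and np.all(d_um <= 20.0 + 1e-9)

    def test_target_out_of_range_rejected(self, fast_cfg):
        with pytest.raises(ValueError):
            m.build_cell_structure(0.1, fast_cfg, seed=1)


class TestMeasureECV:
    def test_empty_structure_exact_one(self):
        s = m.build_cell_structure(1.0, m.SimConfig(), seed=1)
        ecv, se = m.measure_ecv(s, 10_000, seed=0)
        assert ecv == 1.0 and se == 0.0

    def test_single_cylinder_closed_form(self):
        L = 0.5
        r = 0.05
        s = m.CellStructure(
            mid=np.array([[L / 2, L / 2, L / 2]]),
            axis=np.array([[1.0, 0.0, 0.0]]),
            half_len=np.array([L / 2]),
            radius=np.array([r]),
            edge_mm=L,
            target_ecv=0.9,
        )
        ecv, se = m.measure_ecv(s, 200_000, seed=1)
        expected = 1.0 - np.pi * r**2 / L**2
        assert abs(ecv - expected) <= 3 * se

    def test_sample_size_floor(self, structure_03):
        with pytest.raises(ValueError):
            m.measure_ecv(structure_03, 100, seed=0)


class TestSimulateWalkers:
    def test_free_diffusion_einstein_relation(self):
        """Empty voxel: MSD = 6 D0 t within 3 Monte-Carlo standard errors."""
        cfg = m.SimConfig(n_walkers=5000, seed=9)
        s = m.build_cell_structure(1.0, cfg, seed=1)
        w = m.simulate_walkers(s, cfg)
        sq = np.sum(w.extracellular**2, axis=1)
        expect = 6 * cfg.d0_extra * cfg.duration
        se = np.std(sq) / np.sqrt(len(sq))
        assert abs(np.mean(sq) - expect) <= 3 * se

    def test_zero_duration_zero_displacement(self):
        cfg = m.SimConfig(n_walkers=100, duration=0.0, seed=2)
        s = m.build_cell_structure(1.0, cfg, seed=1)
        w = m.simulate_walkers(s, cfg)
        assert np.all(w.displacements == 0.0)

    def test_extracellular_walkers_stay_outside(self, structure_03, fast_cfg):
        """No retained extracellular endpoint lies inside any cylinder."""
        from myodti.diffsim import _build_grid, _count_outside, _structure_arrays

        cfg = m.SimConfig(n_walkers=200, duration=2e-3, seed=4)
        w = m.simulate_walkers(structure_03, cfg)
        # recompute endpoints by rerunning seeding (positions are wrapped in-kernel),
        # so instead verify via a fresh walk that records endpoint validity:
        # endpoints = seed positions + displacements, wrapped into the cube
        from myodti.diffsim import _seed_walkers

        mid, axis, half_len, r2 = _structure_arrays(structure_03)
        cell_start, items, n_grid = _build_grid(structure_03)
        pos, comp = _seed_walkers(
            200, False, mid, axis, half_len, r2, cell_start, items, n_grid,
            structure_03.edge_mm, cfg.seed % (2**31 - 1),
        )
        endpoints = (pos + w.displacements) % structure_03.edge_mm
        n_out = _count_outside(
            endpoints, mid, axis, half_len, r2, cell_start, items, n_grid,
            structure_03.edge_mm,
        )
        assert n_out == len(endpoints)

    def test_restriction_lowers_md(self, structure_03):
        cfg = m.SimConfig(n_walkers=1500, duration=10e-3, seed=6)
        w = m.simulate_walkers(structure_03, cfg)
        inv = m.compute_invariants(m.displacements_to_tensor(w).tensor)
        assert inv.md < cfg.d0_extra
        # principal eigenvector aligns with the tree axis (x) at low ECV
        field = m.displacements_to_tensor(w)
        evals, evecs = np.linalg.eigh(field.tensor)
        e1_dir = np.abs(evecs[:, np.argmax(evals)])
        assert np.degrees(np.arccos(min(e1_dir[0], 1.0))) < 10.0

    def test_determinism_bitwise(self, structure_03):
        cfg = m.SimConfig(n_walkers=300, duration=1e-3, seed=8)
        w1 = m.simulate_walkers(structure_03, cfg)
        w2 = m.simulate_walkers(structure_03, cfg)
        assert np.array_equal(w1.displacements, w2.displacements)

    def test_reflect_mode_also_valid(self, structure_03):
        cfg = m.SimConfig(n_walkers=200, duration=1e-3, seed=8, membrane_mode="reflect")
        w = m.simulate_walkers(structure_03, cfg)
        assert np.all(np.isfinite(w.displacements))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            m.SimConfig(dt=0.0)
        with pytest.raises(ValueError):
            m.SimConfig(duration=5.5e-6)  # not a multiple of dt
        with pytest.raises(ValueError):
            m.SimConfig(membrane_mode="teleport")


class TestDisplacementReadout:
    def test_gaussian_sampling_oracle(self):
        """Displacements drawn from N(0, 2 t Lambda) recover Lambda."""
        t = 51e-3
        lam = np.array([2e-3, 1e-3, 0.5e-3])
        rng = np.random.default_rng(12)
        disp = rng.normal(0.0, np.sqrt(2 * t * lam), size=(20000, 3))
        w = m.WalkerDisplacements(disp, np.zeros(20000, np.uint8), t)
        inv = m.compute_invariants(m.displacements_to_tensor(w).tensor)
        got = np.array([inv.e1, inv.e2, inv.e3])
        # variance-of-variance SE: sqrt(2/n) per eigenvalue
        se = np.sqrt(2.0 / 20000) * lam
        assert np.all(np.abs(got - lam) <= 3 * se)

    def test_rank_one_displacements(self):
        disp = np.zeros((5000, 3))
        disp[:, 0] = np.random.default_rng(1).normal(0, 1e-2, 5000)
        w = m.WalkerDisplacements(disp, np.zeros(5000, np.uint8), 51e-3)
        inv = m.compute_invariants(m.displacements_to_tensor(w).tensor)
        assert inv.fa == pytest.approx(1.0, abs=1e-6)
        assert abs(inv.e2) < 1e-12 and abs(inv.e3) < 1e-12

    def test_degenerate_directions_rejected(self):
        w = m.WalkerDisplacements(np.zeros((10, 3)), np.zeros(10, np.uint8), 1e-3)
        coplanar = np.column_stack([np.cos(np.arange(12)), np.sin(np.arange(12)), np.zeros(12)])
        with pytest.raises(ValueError, match="degenerate"):
            m.displacements_to_tensor(w, coplanar)

    def test_nonpositive_time_rejected(self):
        w = m.WalkerDisplacements(np.zeros((10, 3)), np.zeros(10, np.uint8), 0.0)
        with pytest.raises(ValueError):
            m.displacements_to_tensor(w)


class TestSweep:
    def test_scaled_sweep_shape_and_determinism(self):
        cfg = m.SimConfig(n_walkers=200, duration=1e-3, seed=14)
        targets = np.array([0.6, 1.0])
        t1 = m.run_ecv_sweep(cfg, targets, structures_per_ecv=2, repeats=2)
        assert len(t1) == 2 * 2 * 2
        assert set(t1.columns) >= {"target_ecv", "measured_ecv", "MD", "FA", "e1", "e2", "e3", "RD"}
        t2 = m.run_ecv_sweep(cfg, targets, structures_per_ecv=2, repeats=2)
        assert t1.equals(t2)

    def test_cluster_medians_group_by_ecv_band(self):
        cfg = m.SimConfig(n_walkers=200, duration=1e-3, seed=15)
        sweep = m.run_ecv_sweep(cfg, np.array([0.6, 1.0]), 2, 2)
        med = m.cluster_medians(sweep)
        assert len(med) == 2
        assert med.n_runs.sum() == len(sweep)
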