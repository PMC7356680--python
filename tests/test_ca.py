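import math

import numpy as np
import pytest

import voxtab as vt
from voxtab.errors import ValidationError
from voxtab.synthetic import uniform_block
from voxtab.voxelize import FIRST_SPECIES_ID, LIQUID, PORE


def erosion_oracle_steps(shape):
    """Brute-force erosion-front oracle on a solid block.

    With ingress 1, resistance 1 and detachment off, every solid voxel
    with a face neighbor outside the remaining set dissolves each step;
    returns the number of steps until nothing is left.  Implemented by
    direct set enumeration, independent of the lattice engine.
    """
    solid = {
        (x, y, z)
        for x in range(shape[0])
        for y in range(shape[1])
        for z in range(shape[2])
    }
    neighbors = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    steps = 0
    while solid:
        boundary = {
            v
            for v in solid
            if any(
                (v[0] + dx, v[1] + dy, v[2] + dz) not in solid
                for dx, dy, dz in neighbors
            )
        }
        solid -= boundary
        steps += 1
    return steps


class TestErosionFrontOracle:
    @pytest.mark.parametrize("w", range(1, 8))
    def test_cube_dissolution_time_matches_oracle(self, w, soluble_component):
        grid = uniform_block((w, w, w), soluble_component(resistance=1))
        rules = vt.RuleSet(detachment_threshold=0)
        result = vt.simulate(grid, rules, seed=0)
        assert result.completion_step == erosion_oracle_steps((w, w, w))
        assert result.completion_step == math.ceil(w / 2)

    def test_rectangular_block_matches_oracle(self, soluble_component):
        shape = (5, 3, 7)
        grid = uniform_block(shape, soluble_component(resistance=1))
        rules = vt.RuleSet(detachment_threshold=0)
        result = vt.simulate(grid, rules, seed=0)
        assert result.completion_step == erosion_oracle_steps(shape)

    @pytest.mark.parametrize("resistance", [1, 3, 5])
    def test_single_voxel_released_at_resistance(self, resistance, soluble_component):
        grid = uniform_block((1, 1, 1), soluble_component(resistance=resistance))
        rules = vt.RuleSet(detachment_threshold=0, seconds_per_step=2.0)
        result = vt.simulate(grid, rules, seed=0)
        assert result.completion_step == resistance
        assert vt.disintegration_time(result) == resistance * 2.0


class TestInitialization:
    def test_counters_equal_resistance(self, soluble_component):
        grid = uniform_block((3, 3, 3), soluble_component(resistance=4))
        state = vt.initialize(grid, vt.RuleSet())
        solid = grid.states >= FIRST_SPECIES_ID
        assert (state.counters[solid] == 4).all()
        assert state.step_index == 0
        assert all(v == 0 for v in state.released_voxels.values())

    def test_all_insoluble_grid_has_no_releasable_api(self, insoluble_component):
        grid = uniform_block((3, 3, 3), insoluble_component)
        state = vt.initialize(grid, vt.RuleSet())
        assert state.api_release_pct() == {}
        assert np.isinf(state.counters[grid.states >= FIRST_SPECIES_ID]).all()

    def test_unassigned_grid_rejected(self, fixture_set):
        from voxtab.voxelize import voxelize

        grid = voxelize(fixture_set.asa_tablet, pitch_um=600.0)
        with pytest.raises(ValidationError, match="unassigned"):
            vt.initialize(grid, vt.RuleSet())


class TestConservationAndMonotonicity:
    def test_mass_ledger_balances_every_step(self, toy_grids):
        grid = toy_grids["triple_layer"]
        state = vt.initialize(grid, vt.default_rules(), seed=5)
        for _ in range(25):
            vt.step(state)
            for sid, initial in state.initial_voxels.items():
                on_grid = int((state.states == sid).sum())
                assert (
                    state.released_voxels[sid] + on_grid + state.detached_voxels[sid]
                    == initial
                )

    def test_release_monotone_and_bounded(self, toy_grids):
        for name in ("bilayer", "triple_layer"):
            result = vt.simulate(toy_grids[name], vt.default_rules(), seed=2)
            for curve in result.release_pct.values():
                assert (np.diff(curve) >= 0).all()
                assert curve[0] == 0.0
                assert (curve <= 100.0 + 1e-12).all()

    def test_insoluble_separator_never_released(self, toy_grids):
        grid = toy_grids["triple_layer"]
        state = vt.initialize(grid, vt.default_rules(), seed=7)
        pcl_ids = [
            sid
            for sid, info in grid.species_table.items()
            if info.component.name == "PCL"
        ]
        assert pcl_ids
        result = vt.run(state, max_steps=500)
        assert "PCL" not in result.release_pct
        for sid in pcl_ids:
            assert state.released_voxels[sid] == 0

    def test_all_insoluble_block_never_disintegrates(self, insoluble_component):
        grid = uniform_block((4, 4, 4), insoluble_component)
        result = vt.simulate(grid, vt.RuleSet(), seed=0, max_steps=50)
        assert not result.disintegrated
        assert all(curve.size == 1 for curve in result.release_pct.values())

    def test_full_release_on_all_soluble_tablet(self, toy_grids):
        result = vt.simulate(toy_grids["asa_tablet"], vt.default_rules(), seed=3)
        assert result.release_pct["ASA"][-1] == pytest.approx(100.0)
        assert result.disintegrated


class TestDeterminismAndDominance:
    def test_bit_identical_reruns(self, toy_grids):
        grid = toy_grids["bilayer"]
        r1 = vt.simulate(grid.copy(), vt.default_rules(), seed=11)
        r2 = vt.simulate(grid.copy(), vt.default_rules(), seed=11)
        assert np.array_equal(r1.times, r2.times)
        for name in r1.release_pct:
            assert np.array_equal(r1.release_pct[name], r2.release_pct[name])
        r3 = vt.simulate(grid.copy(), vt.default_rules(), seed=12)
        assert not all(
            np.array_equal(r1.release_pct[n], r3.release_pct[n])
            for n in r1.release_pct
        )

    def test_higher_resistance_never_accelerates(self, soluble_component):
        # common random numbers: the same seed drives both runs
        comp_fast = soluble_component(resistance=2)
        comp_slow = soluble_component(resistance=4)
        rules = vt.RuleSet(default_ingress=0.6, detachment_threshold=0)
        for seed in range(5):
            g_fast = uniform_block((8, 8, 8), comp_fast, porosity=0.35, seed=1)
            g_slow = uniform_block((8, 8, 8), comp_slow, porosity=0.35, seed=1)
            r_fast = vt.simulate(g_fast, rules, seed=seed, max_steps=300)
            r_slow = vt.simulate(g_slow, rules, seed=seed, max_steps=300)
            n = min(len(r_fast.times), len(r_slow.times))
            name = comp_fast.name
            assert (
                r_slow.release_pct[name][:n] <= r_fast.release_pct[name][:n] + 1e-9
            ).all()


class TestDisintegrationRankOrder:
    def test_bilayer_slower_than_each_single_layer(self, toy_grids):
        rules = vt.default_rules()
        t = {
            name: vt.disintegration_time(vt.simulate(toy_grids[name], rules, seed=4))
            for name in ("ma_tablet", "asa_tablet", "bilayer")
        }
        assert t["bilayer"] > t["ma_tablet"]
        assert t["bilayer"] > t["asa_tablet"]

    def test_triple_layer_slower_than_bilayer(self, toy_grids):
        rules = vt.default_rules()
        tb = vt.disintegration_time(vt.simulate(toy_grids["bilayer"], rules, seed=4))
        tt = vt.disintegration_time(
            vt.simulate(toy_grids["triple_layer"], rules, seed=4)
        )
        assert tt > tb


class TestPercolation:
    def _block_with_porosity(self, porosity, seed=0):
        comp = vt.Component("solid", 1.0, 1.5)
        return uniform_block((50, 50, 50), comp, porosity=porosity, seed=seed)

    def test_dense_block_does_not_percolate(self):
        grid = self._block_with_porosity(0.0)
        assert vt.percolation_check(grid, "block") is False

    def test_far_above_threshold_percolates(self):
        # 0.9 >> simple-cubic site threshold ~0.3116
        grid = self._block_with_porosity(0.9)
        assert vt.percolation_check(grid, "block") is True

    def test_far_below_threshold_does_not_percolate(self):
        grid = self._block_with_porosity(0.05)
        assert vt.percolation_check(grid, "block") is False

    def test_unknown_layer_rejected(self):
        grid = self._block_with_porosity(0.5)
        with pytest.raises(ValidationError, match="unknown layer"):
            vt.percolation_check(grid, "nope")


class TestCalibration:
    def test_seconds_per_step_scaling(self, toy_grids):
        rules = vt.default_rules()
        cal = vt.calibrate_seconds_per_step(
            toy_grids["asa_tablet"], rules, target_time_s=81.0,
            target_release_pct=80.0, reference_species="ASA", seed=0,
        )
        result = vt.simulate(toy_grids["asa_tablet"], cal, seed=0)
        assert result.time_to_release("ASA", 80.0) == pytest.approx(81.0, rel=1e-9)
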