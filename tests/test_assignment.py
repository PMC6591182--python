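import numpy as np
import pytest

from conftest import (
    ORACLE_AFFINES,
    hand_placed_streamlines,
    oracle_assign_one,
    region_table_df,
    simple_scene,
)
from seedconn.assignment import (
    OUT_OF_BOUNDS,
    assign,
    streamline_labels,
    voxel_indices,
    world_to_voxel,
)
from seedconn.io import LabelVolume, RegionTable


def make_volume(shape=(20, 20, 20), affine=None):
    return LabelVolume(np.zeros(shape, dtype=np.int32), affine if affine is not None else np.eye(4))


class TestWorldToVoxel:
    @pytest.mark.parametrize(
        "point,affine_scale,expected",
        [
            ((0.0, 0.0, 0.0), 1.0, (0, 0, 0)),
            ((2.6, 0.0, 0.0), 2.0, (1, 0, 0)),  # 1.3 rounds down
            ((3.0, 0.0, 0.0), 2.0, (2, 0, 0)),  # 1.5 rounds half away from zero
            ((-3.0, 0.0, 0.0), 2.0, (-2, 0, 0)),
        ],
    )
    def test_rounding(self, point, affine_scale, expected):
        affine = np.diag([affine_scale] * 3 + [1.0])
        assert world_to_voxel(point, affine) == expected

    def test_out_of_bounds_marker(self):
        assert world_to_voxel((100.0, 0.0, 0.0), np.eye(4), shape=(10, 10, 10)) == OUT_OF_BOUNDS
        assert world_to_voxel((-1.0, 0.0, 0.0), np.eye(4), shape=(10, 10, 10)) == OUT_OF_BOUNDS

    def test_singular_affine_raises(self):
        affine = np.eye(4)
        affine[0, 0] = 0.0
        with pytest.raises(np.linalg.LinAlgError):
            world_to_voxel((0.0, 0.0, 0.0), affine)

    def test_inverse_of_forward_map(self):
        rng = np.random.default_rng(0)
        affine = np.eye(4)
        # non-axis-aligned: small rotation + anisotropic scaling
        theta = 0.3
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0.0],
             [np.sin(theta), np.cos(theta), 0.0],
             [0.0, 0.0, 1.0]]
        )
        affine[:3, :3] = rot @ np.diag([1.25, 1.0, 2.0])
        affine[:3, 3] = [3.0, -2.0, 1.0]
        idx = rng.integers(0, 20, size=(50, 3))
        world = idx @ affine[:3, :3].T + affine[:3, 3]
        np.testing.assert_array_equal(voxel_indices(world, affine), idx)


class TestStreamlineLabels:
    def test_background_only_is_empty(self):
        vol = make_volume()
        s = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0]])
        assert streamline_labels(s, vol) == set()

    def test_endpoints_and_corridor(self):
        vol = make_volume()
        vol.labels[2, 10, 10] = 3
        vol.labels[17, 10, 10] = 7
        vol.labels[9, 10, 10] = 5  # on the straight corridor
        s = np.array([[2.0, 10.0, 10.0], [17.0, 10.0, 10.0]])
        assert streamline_labels(s, vol) == {3, 5, 7}

    def test_thin_wall_between_distant_vertices_is_caught(self):
        # wall 1 voxel thick at x = 10, vertices 5 voxels apart straddling it
        vol = make_volume()
        vol.labels[10, :, :] = 9
        s = np.array([[8.0, 10.0, 10.0], [13.0, 10.0, 10.0]])
        assert 9 in streamline_labels(s, vol)
        assert streamline_labels(s, vol, densify=False) == set()

    def test_out_of_bounds_samples_contribute_nothing(self):
        vol = make_volume()
        vol.labels[0, 0, 0] = 2
        s = np.array([[0.0, 0.0, 0.0], [-30.0, 0.0, 0.0]])
        assert streamline_labels(s, vol) == {2}


class TestAssign:
    def test_single_target_assigned(self):
        vol, table = simple_scene()
        s = np.array([[2.0, 10.0, 10.0], [17.0, 5.0, 10.0]])
        res = assign([s], vol, table)
        assert res.outcomes.loc[0, "outcome"] == "assigned"
        assert res.outcomes.loc[0, "label"] == 2
        assert res.target_counts[2] == 1

    def test_two_targets_discarded(self):
        vol, table = simple_scene()
        s = np.array([[17.0, 5.0, 10.0], [17.0, 15.0, 10.0]])  # 2 then 3, above excl z
        res = assign([s], vol, table)
        assert res.outcomes.loc[0, "outcome"] == "multiple_targets"

    def test_exclusion_dominates_target(self):
        vol, table = simple_scene()
        s = np.array([[2.0, 10.0, 10.0], [10.0, 15.0, 10.0], [17.0, 15.0, 10.0]])
        res = assign([s], vol, table)
        assert res.outcomes.loc[0, "outcome"] == "touches_exclusion"
        assert res.discard_counts["touches_exclusion"] == 1

    def test_no_target(self):
        vol, table = simple_scene()
        s = np.array([[2.0, 10.0, 10.0], [2.0, 2.0, 2.0]])
        res = assign([s], vol, table)
        assert res.outcomes.loc[0, "outcome"] == "no_target"

    def test_short_streamline_counted_as_invalid(self):
        vol, table = simple_scene()
        res = assign([np.array([[2.0, 10.0, 10.0]])], vol, table)
        assert res.outcomes.loc[0, "outcome"] == "invalid"
        assert res.discard_counts["invalid"] == 1
        assert res.n_assigned + res.n_discarded == 1

    def test_seed_traversal_ignored_by_default_required_in_strict_mode(self):
        vol, table = simple_scene()
        from_bg = np.array([[6.0, 5.0, 10.0], [17.0, 5.0, 10.0]])  # misses seed
        assert assign([from_bg], vol, table).outcomes.loc[0, "outcome"] == "assigned"
        res = assign([from_bg], vol, table, require_seed=True)
        assert res.outcomes.loc[0, "outcome"] == "no_seed"

    def test_partition_and_order_invariance(self):
        vol, table = simple_scene()
        rng = np.random.default_rng(5)
        sls = [
            np.cumsum(rng.uniform(-3, 3, size=(rng.integers(2, 8), 3)), axis=0) + 10.0
            for _ in range(60)
        ]
        res = assign(sls, vol, table)
        assert res.n_assigned + res.n_discarded == len(sls)
        perm = rng.permutation(len(sls))
        res_p = assign([sls[i] for i in perm], vol, table)
        assert list(res_p.outcomes["outcome"]) == [
            res.outcomes.loc[i, "outcome"] for i in perm
        ]
        assert res_p.target_counts.equals(res.target_counts)
        assert res_p.discard_counts == res.discard_counts


class TestOracleEquivalence:
    @pytest.mark.parametrize("affine_case", sorted(ORACLE_AFFINES))
    def test_matches_fine_sampling_oracle(self, affine_case):
        vol, table = simple_scene()
        affine = ORACLE_AFFINES[affine_case]
        vol = LabelVolume(vol.labels, affine)
        rng = np.random.default_rng(11)
        # waypoints defined in index space; map through the affine to world
        sls_idx = hand_placed_streamlines(rng, n=50)
        sls = [s @ affine[:3, :3].T + affine[:3, 3] for s in sls_idx]
        res = assign(sls, vol, table)
        for i, s in enumerate(sls):
            expected_outcome, expected_label = oracle_assign_one(s, vol, table)
            assert res.outcomes.loc[i, "outcome"] == expected_outcome, f"streamline {i}"
            assert res.outcomes.loc[i, "label"] == expected_label, f"streamline {i}"
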