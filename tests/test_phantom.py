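import numpy as np
import pytest

from seedconn.assignment import assign
from seedconn.density import subject_profile, summarize_group
from seedconn.phantom import (
    PhantomConfig,
    PhantomGeometryError,
    default_true_weights,
    expected_delta_norm,
    generate_cohort,
    generate_subject_tractogram,
    make_phantom_labels,
    sample_subject_weights,
    simulate_profiles,
)

SMALL = PhantomConfig(n_streamlines=300, seed=7)


class TestLabels:
    def test_roles_and_counts(self):
        cfg = PhantomConfig(n_targets_bilateral=1, n_targets_midline=1,
                            grid_shape=(40, 40, 40), target_distance=12.0,
                            bilateral_x_offset=7.0)
        volume, table = make_phantom_labels(cfg)
        roles = table.df["role"].value_counts()
        assert roles["seed"] == 1
        assert roles["target"] == 3
        assert roles["exclusion"] == 1
        assert set(np.unique(volume.labels)) == set(range(0, 6))

    def test_bilateral_mirror_symmetry(self, phantom_geometry):
        _, volume, table = phantom_geometry
        for _, left, right in table.bilateral_pairs():
            assert (volume.labels == left).sum() == (volume.labels == right).sum()
            # exact mirror about the midline plane
            flipped = volume.labels[::-1, :, :]
            np.testing.assert_array_equal(flipped == left, volume.labels == right)

    def test_rois_disjoint_by_construction(self, phantom_geometry):
        # painting is exclusive, so each voxel holds one label; verify the
        # per-ROI voxel counts sum to the labelled-voxel total
        _, volume, _ = phantom_geometry
        labs, counts = np.unique(volume.labels, return_counts=True)
        assert counts[labs != 0].sum() == (volume.labels != 0).sum()

    def test_infeasible_geometry_raises(self):
        with pytest.raises(PhantomGeometryError):
            make_phantom_labels(PhantomConfig(roi_radius=8.0))
        with pytest.raises(PhantomGeometryError):
            make_phantom_labels(PhantomConfig(grid_shape=(20, 20, 20)))


class TestSubjectWeights:
    def test_zero_sigma_recovers_truth_times_shift(self):
        cfg = PhantomConfig(subject_sigma=0.0, lateralization_shift=1.5)
        rng = np.random.default_rng(0)
        w = sample_subject_weights(cfg, rng)
        truth = cfg.weights()
        np.testing.assert_allclose(w[1::2][: cfg.n_targets_bilateral],
                                   truth[1::2][: cfg.n_targets_bilateral])
        for j in range(cfg.n_targets_bilateral):
            assert w[2 * j] == pytest.approx(1.5 * truth[2 * j])

    def test_unit_shift_keeps_pairs_symmetric_in_truth(self):
        truth = PhantomConfig(lateralization_shift=1.0).weights()
        for j in range(4):
            assert truth[2 * j] == truth[2 * j + 1]

    def test_log_weights_unbiased_monte_carlo(self):
        cfg = PhantomConfig(subject_sigma=0.4)
        rng = np.random.default_rng(123)
        truth = cfg.weights()
        draws = np.log(
            np.vstack([sample_subject_weights(cfg, rng) for _ in range(10_000)])
            / truth
        )
        se = cfg.subject_sigma / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * se)

    def test_weight_length_validation(self):
        cfg = PhantomConfig(true_weights=(1.0, 2.0))
        with pytest.raises(ValueError):
            cfg.validate()


class TestGeneration:
    def test_conservation_of_intended_counts(self, phantom_geometry):
        _, volume, table = phantom_geometry
        rng = np.random.default_rng(3)
        w = sample_subject_weights(SMALL, rng)
        _, truth = generate_subject_tractogram(volume, table, w, SMALL, rng)
        assert sum(truth.intended_counts.values()) == SMALL.n_streamlines
        assert len(truth.intended) == SMALL.n_streamlines

    def test_degenerate_single_target_weights(self, phantom_geometry):
        _, volume, table = phantom_geometry
        cfg = PhantomConfig(
            n_streamlines=100, noise_exclusion_frac=0.0,
            noise_multitarget_frac=0.0, noise_offtarget_frac=0.0,
            true_weights=(1.0,) + (0.0,) * 9,
        )
        rng = np.random.default_rng(4)
        _, truth = generate_subject_tractogram(volume, table, cfg.weights(), cfg, rng)
        assert (truth.intended["label"] == table.target_labels[0]).all()

    def test_assignment_reproduces_ground_truth(self, phantom_geometry):
        _, volume, table = phantom_geometry
        rng = np.random.default_rng(5)
        w = sample_subject_weights(SMALL, rng)
        tg, truth = generate_subject_tractogram(volume, table, w, SMALL, rng)
        res = assign(tg, volume, table)
        expected = truth.intended["label"].to_numpy()
        got = res.outcomes["label"].to_numpy()
        frac = np.mean(
            (got == expected)
            | ((expected == -1) & (res.outcomes["outcome"] != "assigned"))
        )
        assert frac >= 0.99
        reason_map = {
            "noise_exclusion": "touches_exclusion",
            "noise_multitarget": "multiple_targets",
            "noise_offtarget": "no_target",
        }
        for k, reason in reason_map.items():
            rows = truth.intended["kind"] == k
            assert (res.outcomes.loc[rows.to_numpy(), "outcome"] == reason).all()


class TestCohort:
    def test_determinism_bit_identical(self):
        cfg = PhantomConfig(n_streamlines=150, seed=42)
        a = generate_cohort(cfg, 2)
        b = generate_cohort(cfg, 2)
        for sa, sb in zip(a.subjects, b.subjects):
            assert len(sa.tractogram) == len(sb.tractogram)
            for x, y in zip(sa.tractogram.streamlines, sb.tractogram.streamlines):
                np.testing.assert_array_equal(x, y)
            assert sa.ground_truth.intended.equals(sb.ground_truth.intended)

    def test_single_subject(self):
        cohort = generate_cohort(PhantomConfig(n_streamlines=50, seed=1), 1)
        assert len(cohort.subjects) == 1

    def test_noise_free_recovery_of_true_densities(self):
        cfg = PhantomConfig(
            n_streamlines=4000, subject_sigma=0.0, lateralization_shift=1.0,
            noise_exclusion_frac=0.0, noise_multitarget_frac=0.0,
            noise_offtarget_frac=0.0, seed=11,
        )
        cohort = generate_cohort(cfg, 3)
        profiles = []
        for s in cohort.subjects:
            res = assign(s.tractogram, cohort.volume, cohort.table)
            profiles.append(subject_profile(res, cohort.volume, cohort.table))
        mean = summarize_group(profiles).table["mean_delta_norm"]
        expected = expected_delta_norm(cfg, cohort.volume, cohort.table)
        # multinomial sampling error of the pooled counts, mapped to percent
        n_total = 3 * cfg.n_streamlines
        p = expected.to_numpy() / 100.0
        se = 100.0 * np.sqrt(p * (1 - p) / n_total)
        assert np.all(np.abs(mean.to_numpy() - expected.to_numpy()) <= 3 * se + 1e-9)

    def test_cov_increases_with_subject_sigma(self):
        covs = []
        for sigma in (0.05, 0.3, 0.8):
            cfg = PhantomConfig(subject_sigma=sigma, n_streamlines=5000, seed=9)
            rng = np.random.default_rng(17)
            prof = simulate_profiles(cfg, 12, rng)
            cov = prof.std(axis=0, ddof=1) / prof.mean(axis=0)
            covs.append(cov.mean())
        assert covs[0] > 0
        assert covs[0] < covs[1] < covs[2]
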