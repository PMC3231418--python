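"""Pixel coding, labelling, class statistics, merging, and the full classifier."""

import numpy as np
import pytest

import oatfrost as of
from oatfrost.classify import ClassStats, _best_pair
from oatfrost.errors import CannotSplitError, ConfigurationError, CorruptInputError
from oatfrost.thresholding import MultilevelThresholds

from conftest import role_map_from


def thr(*levels):
    return MultilevelThresholds(tuple(levels))


class TestEncode:
    def test_interval_scheme(self):
        values = np.array([[[10, 10, 10], [40, 40, 40], [70, 70, 70]]])
        coded = of.encode_pixels(values, [thr(20, 60)] * 3)
        assert coded[0, :, 0].tolist() == [0, 1, 2]

    def test_value_equal_to_threshold_is_lower_region(self):
        values = np.array([[[20, 21, 60]]])
        coded = of.encode_pixels(values, [thr(20, 60)] * 3)
        assert coded[0, 0].tolist() == [0, 1, 1]

    def test_matches_linear_scan_oracle(self, rng):
        thresholds = (15, 90, 170)
        values = rng.integers(0, 221, size=(30, 3))

        def scan(v):
            code = 0
            for t in thresholds:
                if v > t:
                    code += 1
            return code

        coded = of.encode_pixels(values[None], [thr(*thresholds)] * 3)
        expected = np.vectorize(scan)(values)
        np.testing.assert_array_equal(coded[0], expected)

    def test_mismatched_channel_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            of.encode_pixels(np.zeros((1, 1, 3), int), [thr(10), thr(10, 20), thr(10)])


class TestLabelling:
    @pytest.mark.parametrize(
        "n, codes, expected",
        [(2, (1, 0, 1), 5), (3, (2, 1, 0), 21), (2, (0, 0, 0), 0), (3, (2, 2, 2), 26)],
    )
    def test_packing_arithmetic(self, n, codes, expected):
        labels = of.label_pixels(np.array([[codes]]), n)
        assert labels[0, 0] == expected

    def test_bijection_over_all_code_triplets(self):
        for n in (2, 3, 4):
            grid = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
            labels = of.label_pixels(grid.reshape(-1, 1, 3), n)
            assert sorted(labels.ravel().tolist()) == list(range(n**3))

    def test_one_threshold_yields_eight_possible_classes(self):
        grid = np.stack(np.meshgrid(*[np.arange(2)] * 3, indexing="ij"), axis=-1)
        labels = of.label_pixels(grid.reshape(1, -1, 3), 2)
        assert len(np.unique(labels)) == 8

    def test_code_out_of_range_rejected(self):
        with pytest.raises(CorruptInputError):
            of.label_pixels(np.array([[[2, 0, 0]]]), 2)


class TestClassStatistics:
    def test_single_pixel_class(self):
        lab = np.array([[[10.0, -5.0, 3.0]]])
        (stats,) = of.class_statistics(lab, np.zeros((1, 1), int))
        assert stats.n == 1 and stats.sigma == 0.0
        assert stats.mean == (10.0, -5.0, 3.0)

    def test_two_pixel_hand_example(self):
        # pixels (0,0,0) and (6,0,0): mean (3,0,0); sigma = (3 + 3) / (3 * 2) = 1
        lab = np.array([[[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]]])
        (stats,) = of.class_statistics(lab, np.zeros((1, 2), int))
        assert stats.mean == (3.0, 0.0, 0.0)
        assert stats.sigma == pytest.approx(1.0)

    @pytest.mark.parametrize("form", ["as_printed", "squared"])
    def test_matches_scalar_loop_oracle(self, rng, form):
        lab = rng.normal(size=(4, 5, 3)) * 10
        labels = rng.integers(0, 3, size=(4, 5))
        for stats in of.class_statistics(lab, labels, form):
            members = lab[labels == stats.label]
            mu = members.mean(axis=0)
            np.testing.assert_allclose(stats.mean, mu, atol=1e-9)
            acc = 0.0
            for px in members:
                d2 = float(((px - mu) ** 2).sum())
                acc += np.sqrt(d2) if form == "as_printed" else d2
            assert stats.sigma == pytest.approx(acc / (3 * len(members)), abs=1e-9)

    def test_permutation_invariance(self, rng):
        lab = rng.normal(size=(6, 6, 3))
        labels = rng.integers(0, 4, size=(6, 6))
        perm = rng.permutation(36)
        a = of.class_statistics(lab, labels)
        b = of.class_statistics(
            lab.reshape(36, 3)[perm].reshape(6, 6, 3), labels.ravel()[perm].reshape(6, 6)
        )
        for sa, sb in zip(a, b):
            assert sa.label == sb.label and sa.n == sb.n
            np.testing.assert_allclose(sa.mean, sb.mean)
            assert sa.sigma == pytest.approx(sb.sigma)


class TestSeparation:
    def test_identical_means_have_zero_separation(self):
        a = ClassStats(0, 5, (1.0, 2.0, 3.0), 0.1)
        b = ClassStats(1, 9, (1.0, 2.0, 3.0), 0.4)
        assert of.between_class_separation(a, b) == 0.0

    def test_hand_value_and_symmetry(self, rng):
        a = ClassStats(0, 5, (3.0, 0.0, 0.0), 0.0)
        b = ClassStats(1, 5, (0.0, 0.0, 0.0), 0.0)
        assert of.between_class_separation(a, b) == pytest.approx(3.0)
        for _ in range(5):
            ma, mb = rng.normal(size=3), rng.normal(size=3)
            sa = ClassStats(0, 1, tuple(ma), 0.0)
            sb = ClassStats(1, 1, tuple(mb), 0.0)
            assert of.between_class_separation(sa, sb) == pytest.approx(
                of.between_class_separation(sb, sa)
            )


def two_cluster_image(rng, mean_a, mean_b, spread_a, spread_b, n=200):
    lab = np.empty((2, n, 3))
    lab[0] = mean_a + rng.normal(0, spread_a, size=(n, 3))
    lab[1] = mean_b + rng.normal(0, spread_b, size=(n, 3))
    labels = np.repeat(np.arange(2), n).reshape(2, n)
    return lab, labels


class TestMerging:
    def test_distant_tight_clusters_do_not_merge(self, rng):
        lab, labels = two_cluster_image(rng, (0, 0, 0), (60, 60, 60), 0.01, 0.01)
        merged, flag = of.merge_step(labels, lab)
        assert not flag
        np.testing.assert_array_equal(merged, labels)

    def test_interleaved_clusters_merge(self, rng):
        # same mean, large spread: separation ~0 < within-class spread
        lab, labels = two_cluster_image(rng, (0, 0, 0), (0, 0, 0), 10.0, 10.0)
        merged, flag = of.merge_step(labels, lab)
        assert flag
        assert len(np.unique(merged)) == 1

    def test_merged_label_comes_from_smaller_variance_member(self, rng):
        lab, labels = two_cluster_image(rng, (0, 0, 0), (0.5, 0.5, 0.5), 0.5, 30.0)
        merged, flag = of.merge_step(labels, lab)
        assert flag
        assert np.unique(merged).tolist() == [0]  # cluster 0 has the smaller spread

    def test_single_class_is_noop(self, rng):
        lab = rng.normal(size=(3, 3, 3))
        merged, flag = of.merge_step(np.zeros((3, 3), int), lab)
        assert not flag

    def test_merge_until_stable_postcondition(self, rng):
        lab = rng.normal(size=(20, 20, 3)) * 8
        labels = rng.integers(0, 6, size=(20, 20))
        stable, _ = of.merge_until_stable(labels, lab)
        stats = of.class_statistics(lab, stable)
        pair, _ = _best_pair(stats, require_overlap=True)
        assert pair is None  # every separation exceeds both within-class spreads
        assert len(stats) <= 6

    def test_uniform_image_collapses_to_one_class(self):
        lab = np.zeros((4, 4, 3))
        labels = np.arange(16).reshape(4, 4)
        stable, _ = of.merge_until_stable(labels, lab)
        assert len(np.unique(stable)) == 1


class TestClassify:
    def test_recovers_four_class_scene(self, small_scene):
        spec, rgb, truth = small_scene
        labels, stats = of.classify(of.rgb_to_lab(rgb), target_classes=4)
        assert len(stats) == 4
        role_map = role_map_from(labels, stats)
        assert (role_map == truth).mean() >= 0.95

    def test_target_one_gives_single_class(self, small_scene):
        _, rgb, _ = small_scene
        labels, stats = of.classify(of.rgb_to_lab(rgb), target_classes=1)
        assert len(stats) == 1 and len(np.unique(labels)) == 1

    def test_unreachable_target_raises(self):
        lab = np.zeros((8, 8, 3))
        with pytest.raises(CannotSplitError):
            of.classify(lab, target_classes=4)

    def test_dynamic_mode_returns_stable_partition(self, small_scene):
        _, rgb, _ = small_scene
        labels, stats = of.classify(of.rgb_to_lab(rgb))
        assert 1 <= len(stats) <= 8  # coarsest (one threshold per channel) partition bound
        pair, _ = _best_pair(stats, require_overlap=True)
        assert pair is None


class TestSemanticMapping:
    def canonical_stats(self):
        return [
            ClassStats(3, 10, (68.5, -44.7, 37.2), 1.0),  # green
            ClassStats(5, 10, (85.5, -12.2, 38.6), 1.0),  # yellow
            ClassStats(6, 10, (71.2, 0.7, 17.1), 1.0),  # half-dried brown
            ClassStats(2, 10, (40.2, -7.2, 4.7), 1.0),  # dark ground
        ]

    def test_canonical_palette_assignment(self):
        roles = of.semantic_mapping(self.canonical_stats())
        assert roles == {3: "GO", 5: "DO", 6: "HD", 2: "SG"}

    def test_invariant_to_class_label_permutation(self):
        stats = self.canonical_stats()
        relabelled = [ClassStats(s.label + 10, s.n, s.mean, s.sigma) for s in stats]
        roles = of.semantic_mapping(relabelled)
        assert {k - 10: v for k, v in roles.items()} == of.semantic_mapping(stats)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ConfigurationError):
            of.semantic_mapping(self.canonical_stats()[:3])

    def test_tie_warns(self):
        stats = self.canonical_stats()
        stats[0] = ClassStats(3, 10, (40.2, -44.7, 37.2), 1.0)  # L* ties with SG
        with pytest.warns(UserWarning):
            of.semantic_mapping(stats)


class TestDamageReport:
    def make_map(self, fractions):
        n = 100
        labels = np.repeat(np.arange(4), [int(f * n) for f in fractions]).reshape(10, 10)
        roles = dict(enumerate(of.ROLES))
        return labels, roles

    def test_all_green_map_is_fully_usable(self):
        labels = np.zeros((5, 5), int)
        report = of.damage_report(labels, {0: "GO"}, area_per_pixel=2.0)
        assert report["usable_area"] == report["total_area"] == 50.0

    def test_fractions_sum_to_one(self):
        labels, roles = self.make_map((0.5, 0.2, 0.2, 0.1))
        report = of.damage_report(labels, roles)
        assert sum(report["fractions"].values()) == pytest.approx(1.0)

    def test_usable_area_weights_half_dried(self):
        # GO 50%, HD 20%, w = 0.5 on a 1 m^2 plot -> 0.6 m^2 usable
        labels, roles = self.make_map((0.5, 0.3, 0.2, 0.0))
        report = of.damage_report(labels, roles, area_per_pixel=0.01, hd_usable_fraction=0.5)
        assert report["usable_area"] == pytest.approx(0.6)

    def test_unknown_label_rejected(self):
        with pytest.raises(CorruptInputError):
            of.damage_report(np.array([[0, 9]]), {0: "GO"})
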