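"""Overlap colocalization, tripartite categories, neighbour statistics
and the 180°-rotation spatial null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanosyn import (
    BinaryMask,
    FrameMismatchError,
    ParameterError,
    classify_category,
    edge_edge_count,
    nearest_neighbors,
    null_comparison,
    overlap_colocalize,
    rotate_mask,
    rotate_points,
)

from oracles import brute_force_neighbors


class TestOverlapColocalize:
    def _labels(self, shape, boxes):
        lab = np.zeros(shape, int)
        for i, (r0, r1, c0, c1) in enumerate(boxes, start=1):
            lab[r0:r1, c0:c1] = i
        return lab

    def test_identical_masks_all_flagged(self):
        lab = self._labels((20, 20), [(2, 5, 2, 5), (10, 14, 10, 14)])
        mask = BinaryMask(lab > 0, 100.0)
        flags = overlap_colocalize(lab, 100.0, mask)
        assert flags == {1: True, 2: True}

    def test_disjoint_masks_none_flagged(self):
        lab = self._labels((20, 20), [(2, 5, 2, 5)])
        mask = BinaryMask(self._labels((20, 20), [(10, 14, 10, 14)]) > 0,
                          100.0)
        assert overlap_colocalize(lab, 100.0, mask) == {1: False}

    def test_single_pixel_overlap_counts(self):
        """The protocol's rule: ≥ 1 px of shared support is contact."""
        lab = self._labels((20, 20), [(2, 6, 2, 6)])
        other = np.zeros((20, 20), bool)
        other[5, 5] = True  # exactly one pixel inside the object
        assert overlap_colocalize(lab, 100.0, BinaryMask(other, 100.0)) == \
               {1: True}

    def test_min_overlap_threshold(self):
        lab = self._labels((20, 20), [(2, 6, 2, 6)])
        other = np.zeros((20, 20), bool)
        other[5, 5] = True
        flags = overlap_colocalize(lab, 100.0, BinaryMask(other, 100.0),
                                   min_overlap_px=2)
        assert flags == {1: False}

    def test_mixed_resolution_evaluated_on_finer_grid(self):
        """A coarse object against a fine mask: one fine pixel inside
        the object's physical footprint is enough."""
        lab = self._labels((10, 10), [(2, 4, 2, 4)])  # 100 nm/px
        fine = np.zeros((50, 50), bool)                # 20 nm/px
        fine[12, 12] = True  # physically at (250, 250) nm → inside object
        assert overlap_colocalize(lab, 100.0, BinaryMask(fine, 20.0)) == \
               {1: True}

    def test_frame_mismatch_rejected(self):
        lab = self._labels((10, 10), [(1, 2, 1, 2)])
        with pytest.raises(FrameMismatchError):
            overlap_colocalize(lab, 100.0, BinaryMask(np.zeros((30, 30),
                                                               bool), 100.0))


class TestClassifyCategory:
    @pytest.mark.parametrize("vglut,astro,expected", [
        (False, False, "psd_only"),
        (False, True, "psd_astro"),
        (True, False, "synapse"),
        (True, True, "tripartite"),
    ])
    def test_truth_table(self, vglut, astro, expected):
        assert classify_category(vglut, astro) == expected

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=200))
    @settings(max_examples=30, deadline=None)
    def test_categories_partition_psds(self, flags):
        cats = [classify_category(v, a) for v, a in flags]
        counts = {c: cats.count(c) for c in
                  ("psd_only", "psd_astro", "synapse", "tripartite")}
        assert sum(counts.values()) == len(flags)


class TestNearestNeighbors:
    def test_single_punctum(self):
        tables = nearest_neighbors(np.array([[1.0, 1.0]]),
                                   np.array([[3.0, 1.0]]), k=10)
        t = tables[0]
        assert t.nn_distances_um[0] == pytest.approx(2.0)
        assert all(np.isnan(t.nn_distances_um[1:]))
        assert t.padded
        assert t.count_within_radius == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            psd = rng.uniform(0, 20, (30, 2))
            astro = rng.uniform(0, 20, (50, 2))
            tables = nearest_neighbors(psd, astro, k=10, radius_um=3.0)
            oracle = brute_force_neighbors(psd, astro, k=10, radius=3.0)
            for t, (dists, count) in zip(tables, oracle):
                assert np.allclose(t.nn_distances_um, dists, equal_nan=True)
                assert t.count_within_radius == count

    def test_radius_boundary_closed(self):
        """A punctum at exactly the counting radius is included."""
        tables = nearest_neighbors(np.array([[0.0, 0.0]]),
                                   np.array([[3.0, 0.0]]), radius_um=3.0)
        assert tables[0].count_within_radius == 1

    def test_empty_astro_set(self):
        tables = nearest_neighbors(np.array([[0.0, 0.0]]),
                                   np.zeros((0, 2)), k=10)
        t = tables[0]
        assert t.count_within_radius == 0 and t.padded
        assert all(np.isnan(t.nn_distances_um))

    def test_counts_monotone_in_radius(self):
        rng = np.random.default_rng(1)
        psd = rng.uniform(0, 10, (10, 2))
        astro = rng.uniform(0, 10, (40, 2))
        counts = []
        for r in (1.0, 2.0, 3.0, 5.0):
            tabs = nearest_neighbors(psd, astro, radius_um=r)
            counts.append([t.count_within_radius for t in tabs])
        for a, b in zip(counts, counts[1:]):
            assert all(x <= y for x, y in zip(a, b))


class TestEdgeEdge:
    def test_overlapping_objects_distance_zero(self):
        psd = np.zeros((20, 20), int)
        psd[5:10, 5:10] = 1
        astro = np.zeros((20, 20), int)
        astro[8:12, 8:12] = 1
        (t,) = edge_edge_count(psd, astro, pixel_size_nm=19.97, max_nm=200)
        assert t.n_astro_within == 1

    def test_gap_within_window_counted(self):
        """Two 1-px objects 5 px apart at 19.97 nm/px ≈ 99.9 nm."""
        psd = np.zeros((10, 10), int)
        psd[5, 2] = 1
        astro = np.zeros((10, 10), int)
        astro[5, 7] = 1
        (t,) = edge_edge_count(psd, astro, pixel_size_nm=19.97, max_nm=200)
        assert t.n_astro_within == 1
        (t,) = edge_edge_count(psd, astro, pixel_size_nm=19.97, max_nm=99)
        assert t.n_astro_within == 0

    def test_object_beyond_window_not_counted(self):
        psd = np.zeros((40, 40), int)
        psd[5, 5] = 1
        astro = np.zeros((40, 40), int)
        astro[5, 25] = 1  # 20 px × 19.97 nm ≈ 399 nm away
        (t,) = edge_edge_count(psd, astro, pixel_size_nm=19.97, max_nm=200)
        assert t.n_astro_within == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(FrameMismatchError):
            edge_edge_count(np.zeros((5, 5), int), np.zeros((6, 6), int),
                            19.97)


class TestRotatedControl:
    def test_mask_rotation_is_involution(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(13, 17)) < 0.4
        assert np.array_equal(rotate_mask(rotate_mask(m)), m)

    def test_mask_histogram_conserved(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 255, (20, 30))
        assert np.array_equal(np.sort(rotate_mask(m).ravel()),
                              np.sort(m.ravel()))

    def test_mask_index_mapping(self):
        m = np.zeros((5, 7), bool)
        m[1, 2] = True
        r = rotate_mask(m)
        assert r[5 - 1 - 1, 7 - 1 - 2]

    def test_point_rotation_fixed_centre(self):
        pts = rotate_points(np.array([[5.0, 4.0]]), (10.0, 8.0))
        assert np.allclose(pts, [[5.0, 4.0]])

    def test_point_rotation_involution(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10, (25, 2))
        back = rotate_points(rotate_points(pts, (10, 10)), (10, 10))
        assert np.allclose(back, pts)


class TestNullComparison:
    def _counts(self, psd, astro, field):
        true_tabs = nearest_neighbors(psd, astro)
        rot_tabs = nearest_neighbors(psd, rotate_points(astro, field),
                                     is_rotated_control=True)
        return null_comparison(true_tabs, rot_tabs)

    def test_identical_arms_no_difference(self):
        rng = np.random.default_rng(5)
        psd = rng.uniform(0, 10, (20, 2))
        astro = rng.uniform(0, 10, (30, 2))
        tabs = nearest_neighbors(psd, astro)
        summary = null_comparison(tabs, tabs)
        assert summary["count_diff"] == 0
        assert summary["direction"] == "no_difference"

    def test_csr_placement_behaves_as_null(self):
        """Uniformly random astro puncta: |mean paired difference| over
        20 seeds stays within 2 SEM — rotation does not bias CSR."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            psd = rng.uniform(0, 20, (40, 2))
            astro = rng.uniform(0, 20, (120, 2))
            s = self._counts(psd, astro, (20, 20))
            diffs.append(s["count_diff"])
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 2 * sem

    def test_clustered_placement_detected(self):
        """Astro puncta seeded at half the PSDs: the true arm beats the
        rotated control in ≥ 19/20 seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            psd = rng.uniform(1, 39, (80, 2))
            attached = []
            for p in psd:
                if rng.uniform() < 0.5:
                    for _ in range(3):
                        attached.append(p + rng.normal(0, 0.1, 2))
            decoys = rng.uniform(0, 40, (60, 2))
            astro = np.vstack([attached, decoys])
            s = self._counts(psd, astro, (40, 40))
            wins += s["count_diff"] > 0
        assert wins >= 19

    def test_mismatched_tables_rejected(self):
        t = nearest_neighbors(np.array([[1.0, 1.0]]), np.zeros((0, 2)))
        with pytest.raises(ParameterError):
            null_comparison(t, [])
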