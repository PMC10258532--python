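import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dddthresh import (
    ROI,
    ROISet,
    Streamline,
    Tractogram,
    assign_endpoints,
    connection_score,
    connectivity_matrix,
    pair_min_streamline_length,
    streamline_distance_group,
)
from dddthresh.roi_geometry import SpaceMismatchError

from conftest import make_streamline, make_tractogram


class TestAssignEndpoints:
    def test_terminus_at_center(self, two_rois):
        t = make_tractogram([((0, 0, 0), (0, 0, 40))])
        asg = assign_endpoints(t, two_rois, search_mm=4)
        assert asg.assignments == [("A", "B")]

    @pytest.mark.parametrize("dist, expected", [(11.0, "A"), (13.0, None)])
    def test_search_zone_is_surface_referenced(self, dist, expected):
        # radius 8 + search 4 captures up to 12 mm from the centre
        rois = ROISet([ROI("A", (0, 0, 0), 8.0)])
        t = make_tractogram([((dist, 0, 0), (100, 100, 100))])
        asg = assign_endpoints(t, rois, search_mm=4)
        assert asg.assignments[0][0] == expected

    def test_tie_broken_lexicographically(self):
        rois = ROISet(
            [ROI("B", (10, 0, 0), 8), ROI("A", (-10, 0, 0), 8)], warn_overlap=False
        )
        t = make_tractogram([((0, 0, 0), (100, 100, 100))])
        asg = assign_endpoints(t, rois, search_mm=4)
        assert asg.assignments[0][0] == "A"

    def test_interior_points_ignored(self):
        # streamline passes straight through B but terminates far from it
        rois = ROISet([ROI("B", (0, 0, 20), 5.0)])
        t = make_tractogram([((0, 0, 0), (0, 0, 40))], subject_id="s")
        asg = assign_endpoints(t, rois, search_mm=4)
        assert asg.assignments == [(None, None)]

    def test_space_mismatch_rejected(self, two_rois):
        t = make_tractogram([((0, 0, 0), (0, 0, 40))], space_tag="native")
        with pytest.raises(SpaceMismatchError):
            assign_endpoints(t, two_rois)


class TestConnectionScore:
    def test_direct_count_arithmetic(self):
        # 10 streamlines touch A, 2 of them end at B; 20 touch B total
        rois = ROISet([ROI("A", (0, 0, 0), 8), ROI("B", (0, 0, 100), 8), ROI("C", (100, 0, 0), 8)])
        segments = []
        segments += [((0, 0, 0), (0, 0, 100))] * 2        # A-B
        segments += [((0, 0, 0), (100, 0, 0))] * 8        # A-C
        segments += [((0, 0, 100), (200, 200, 200))] * 18  # B only
        t = make_tractogram(segments)
        asg = assign_endpoints(t, rois, search_mm=4)
        assert connection_score(asg, "A", "B") == pytest.approx(np.mean([2 / 10, 2 / 20]))

    def test_untouched_pair_scores_zero(self, two_rois):
        asg = assign_endpoints(make_tractogram([]), two_rois)
        assert connection_score(asg, "A", "B") == 0.0

    def test_exclusive_pair_scores_one(self, two_rois):
        t = make_tractogram([((0, 0, 0), (0, 0, 40))] * 3)
        asg = assign_endpoints(t, two_rois, search_mm=4)
        assert connection_score(asg, "A", "B") == 1.0

    def test_self_connection_rejected(self, two_rois):
        asg = assign_endpoints(make_tractogram([]), two_rois)
        with pytest.raises(ValueError):
            connection_score(asg, "A", "A")


class TestConnectivityMatrix:
    def test_empty_tractogram_all_zero(self, three_rois):
        m = connectivity_matrix(make_tractogram([]), three_rois)
        assert np.all(m.values == 0)

    def test_single_streamline_scores_one(self, three_rois):
        m = connectivity_matrix(make_tractogram([((0, 0, 0), (0, 0, 40))]), three_rois)
        assert m.pair("A", "B") == 1.0
        assert m.pair("A", "C") == 0.0

    def test_permutation_relabels_rows(self, three_rois):
        segs = [((0, 0, 0), (0, 0, 40)), ((0, 0, 40), (40, 0, 0)), ((0, 0, 0), (40, 0, 0))]
        t = make_tractogram(segs)
        m1 = connectivity_matrix(t, three_rois)
        permuted = ROISet(list(reversed(list(three_rois))), space_tag=three_rois.space_tag)
        m2 = connectivity_matrix(t, permuted)
        for a in "ABC":
            for b in "ABC":
                if a != b:
                    assert m1.pair(a, b) == m2.pair(a, b)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_fuzz_symmetric_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        rois = ROISet(
            [ROI(f"r{i}", tuple(rng.uniform(0, 60, 3)), 8.0) for i in range(4)],
            warn_overlap=False,
        )
        segs = [
            (tuple(rng.uniform(0, 60, 3)), tuple(rng.uniform(0, 60, 3)))
            for _ in range(rng.integers(0, 15))
        ]
        m = connectivity_matrix(make_tractogram(segs), rois)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all((m.values >= 0) & (m.values <= 1))

    def test_removing_isolated_roi_streamlines(self, three_rois):
        # streamlines touching C touch nothing else, so dropping them
        # leaves the A-B score unchanged and zeroes C's row/column
        segs_ab = [((0, 0, 0), (0, 0, 40))] * 2
        segs_c = [((40, 0, 0), (200, 200, 200))] * 3
        m_all = connectivity_matrix(make_tractogram(segs_ab + segs_c), three_rois)
        m_no_c = connectivity_matrix(make_tractogram(segs_ab), three_rois)
        assert m_all.pair("A", "B") == m_no_c.pair("A", "B")
        i = three_rois.index("C")
        assert np.all(m_no_c.values[i] == 0)


class TestStreamlineLengths:
    def test_polyline_arc_length(self):
        s = Streamline(np.array([[0, 0, 0], [3, 4, 0], [3, 4, 12]], float))
        assert s.length == pytest.approx(5 + 12)

    def test_pair_min_length(self, two_rois):
        t = Tractogram(
            "s",
            [
                make_streamline((0, 0, 0), (0, 0, 40), n_points=2),
                Streamline(np.array([[0, 0, 0], [30, 0, 20], [0, 0, 40]], float)),
            ],
        )
        asg = assign_endpoints(t, two_rois, 4)
        assert pair_min_streamline_length(t, asg, "A", "B") == pytest.approx(40.0)

    def test_pair_min_missing(self, two_rois):
        t = make_tractogram([])
        asg = assign_endpoints(t, two_rois, 4)
        assert pair_min_streamline_length(t, asg, "A", "B") is None

    def test_arc_length_bounds_endpoint_separation(self, two_rois):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.uniform(0, 50, size=(rng.integers(2, 8), 3))
            s = Streamline(pts)
            assert s.length >= np.linalg.norm(pts[-1] - pts[0]) - 1e-9


class TestStreamlineDistanceMatrix:
    def test_group_matrix_averages_subject_minima(self, two_rois):
        from dddthresh import streamline_distance_matrix

        # subject 1 connects A-B with a 40 mm track, subject 2 with a
        # longer dog-leg (51.2 mm); the pair distance is the rounded mean
        t1 = make_tractogram([((0, 0, 0), (0, 0, 40))], subject_id="s1")
        t2 = Tractogram(
            "s2",
            [Streamline(np.array([[0, 0, 0], [16, 0, 20], [0, 0, 40]], float))],
        )
        dm = streamline_distance_matrix([t1, t2], two_rois, 4)
        expected = round((40.0 + 2 * np.hypot(16, 20)) / 2)
        assert dm.measure == "streamline"
        assert dm.pair("A", "B") == expected

    def test_unconnected_pair_is_missing(self, three_rois):
        from dddthresh import streamline_distance_matrix

        t = make_tractogram([((0, 0, 0), (0, 0, 40))], subject_id="s1")
        dm = streamline_distance_matrix([t], three_rois, 4)
        assert dm.pair("A", "B") > 0
        assert dm.pair("A", "C") == -1


class TestStreamlineDistanceGroup:
    @pytest.mark.parametrize(
        "minima, expected",
        [
            ([40.2, 39.8], 40),
            ([30, None, 50], 40),
            ([None, None], None),
            ([42.0], 42),
        ],
    )
    def test_averaging_with_missing(self, minima, expected):
        assert streamline_distance_group(minima) == expected
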