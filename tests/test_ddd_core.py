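import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dddthresh import (
    ConnectivityMatrix,
    DDDModel,
    DistanceMatrix,
    apply_ddd,
    build_bins,
    empirical_upper_quantile,
    fit_ddd,
    fit_sampling_distribution,
    group_average,
    matched_count_cutoff,
    percentile_threshold,
    threshold_at_alpha,
)

from conftest import random_connectivity


def brute_force_upper_quantile(values, alpha):
    """Independent oracle: scan all candidate thresholds directly."""
    values = np.asarray(values, float)
    n = values.size
    best = None
    for t in sorted(set(values.tolist())):
        if np.sum(values > t) / n <= alpha:
            best = t
            break
    return best


class TestSamplingDistribution:
    def test_constant_candidates(self):
        d = fit_sampling_distribution(0, [0.5], n_draws=100, rng_seed=1)
        assert np.all(d.draws == 0.5)

    def test_binomial_fraction(self):
        d = fit_sampling_distribution(0, [0.0, 1.0], n_draws=100_000, rng_seed=3)
        frac = d.draws.mean()
        sd = np.sqrt(0.25 / 100_000)
        assert abs(frac - 0.5) < 3 * sd

    def test_deterministic_given_seed(self):
        a = fit_sampling_distribution(0, [0.1, 0.2, 0.3], 1000, rng_seed=9)
        b = fit_sampling_distribution(0, [0.1, 0.2, 0.3], 1000, rng_seed=9)
        assert np.array_equal(a.draws, b.draws)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_sampling_distribution(0, [], 10, 0)


class TestThresholdAtAlpha:
    def test_all_zero_draws(self):
        d = fit_sampling_distribution(0, [0.0], 100, 0)
        for a in (0.1, 0.2, 0.3):
            assert threshold_at_alpha(d, a) == 0.0

    def test_uniform_ranks(self):
        vals = np.arange(1, 101, dtype=float)
        assert empirical_upper_quantile(vals, 0.1) == 90.0

    def test_heavy_ties_at_zero(self):
        vals = np.array([0.0] * 70 + [1.0] * 30)
        assert empirical_upper_quantile(vals, 0.3) == 0.0

    @given(
        vals=st.lists(st.integers(0, 20), min_size=1, max_size=60),
        alpha=st.sampled_from([0.05, 0.1, 0.2, 0.3, 0.5]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, vals, alpha):
        v = np.array(vals, float) / 20.0
        assert empirical_upper_quantile(v, alpha) == brute_force_upper_quantile(v, alpha)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_alpha(self, seed):
        rng = np.random.default_rng(seed)
        d = fit_sampling_distribution(0, rng.random(50), 2000, seed)
        ts = [threshold_at_alpha(d, a) for a in (0.05, 0.1, 0.2, 0.3, 0.5)]
        assert all(t1 >= t2 for t1, t2 in zip(ts, ts[1:]))


def two_bin_model(scores_a, scores_b, alphas=(0.1, 0.2, 0.3), seed=0, n_draws=20_000):
    samples = [((i, "a"), 10, s) for i, s in enumerate(scores_a)]
    samples += [((i, "b"), 50, s) for i, s in enumerate(scores_b)]
    binning = build_bins([(p, d) for p, d, _ in samples], min_samples=len(scores_a))
    return fit_ddd(binning, samples, alphas=alphas, n_draws=n_draws, seed=seed)


class TestFitDDD:
    def test_identical_candidates_equivalent_thresholds(self):
        # bins resample with bin-derived seeds, so identical candidate
        # sets give thresholds that agree up to Monte-Carlo error: both
        # must sit within the adjacent order statistics of the exact
        # candidate quantile
        rng = np.random.default_rng(0)
        scores = np.sort(rng.random(200))
        model = two_bin_model(scores, scores, n_draws=100_000)
        for a in model.alphas:
            k = int(np.floor(a * scores.size))
            i = scores.size - k - 1
            lo, hi = scores[i - 2], scores[i + 2]
            for b in (0, 1):
                assert lo <= model.threshold(b, a) <= hi

    def test_stochastically_ordered_bins(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        model = two_bin_model(scores, scores * 0.5)
        for a in model.alphas:
            assert model.threshold(1, a) <= model.threshold(0, a)

    def test_serialization_deterministic(self):
        rng = np.random.default_rng(2)
        s1, s2 = rng.random(100), rng.random(100)
        j1 = two_bin_model(s1, s2, seed=42).to_json()
        j2 = two_bin_model(s1, s2, seed=42).to_json()
        assert j1 == j2

    def test_json_round_trip(self):
        rng = np.random.default_rng(3)
        model = two_bin_model(rng.random(100), rng.random(100), seed=5)
        back = DDDModel.from_json(model.to_json())
        assert back.alphas == model.alphas
        assert back.thresholds == model.thresholds
        assert back.binning.edges() == model.binning.edges()


def small_matrix(values, ids=("A", "B", "C")):
    vals = np.asarray(values, float)
    return ConnectivityMatrix(values=vals, roi_ids=list(ids))


def small_distances(values, ids=("A", "B", "C"), measure="euclidean"):
    return DistanceMatrix(values=np.asarray(values), roi_ids=list(ids), measure=measure)


class TestApplyDDD:
    def _model(self):
        # candidate fractions sit clear of the alpha boundaries so the
        # resampled thresholds are stable: bin 0 -> 0.3/0.3/0.1,
        # bin 1 (scores x 0.1) -> 0.03/0.03/0.01
        scores_a = [0.0] * 57 + [0.1] * 15 + [0.3] * 20 + [0.5] * 8
        scores_b = [s * 0.1 for s in scores_a]
        return two_bin_model(scores_a, scores_b, n_draws=50_000)

    def test_all_zero_matrix_nothing_survives(self):
        model = self._model()
        m = small_matrix(np.zeros((3, 3)))
        dm = small_distances([[0, 10, 50], [10, 0, 50], [50, 50, 0]])
        net = apply_ddd(model, m, dm)
        assert all(net.n_surviving(a) == 0 for a in model.alphas)

    def test_tier_nesting(self):
        model = self._model()
        rng = np.random.default_rng(0)
        m = random_connectivity(6, rng, roi_ids=list("ABCDEF"))
        d = rng.integers(5, 80, (6, 6))
        d = np.triu(d, 1)
        d = d + d.T
        dm = DistanceMatrix(values=d, roi_ids=list("ABCDEF"))
        net = apply_ddd(model, m, dm)
        s1 = net.surviving_edges(0.1)
        s2 = net.surviving_edges(0.2)
        s3 = net.surviving_edges(0.3)
        assert s1 <= s2 <= s3

    def test_equal_scores_different_bins_different_tiers(self):
        model = self._model()
        vals = [[0, 0.2, 0.2], [0.2, 0, 0], [0.2, 0, 0]]
        dm = small_distances([[0, 10, 50], [10, 0, 60], [50, 60, 0]])
        net = apply_ddd(model, small_matrix(vals), dm)
        e = net.edges.set_index(["roi_a", "roi_b"])
        # 0.2 in the short bin only beats the 0.3-level threshold (0.1);
        # 0.2 in the long bin beats even the 0.1-level threshold (0.03)
        assert e.loc[("A", "B"), "tier"] == pytest.approx(0.3)
        assert e.loc[("A", "C"), "tier"] == pytest.approx(0.1)

    def test_measure_mismatch_rejected(self):
        model = self._model()
        dm = small_distances([[0, 10, 50], [10, 0, 50], [50, 50, 0]], measure="streamline")
        with pytest.raises(ValueError, match="measure"):
            apply_ddd(model, small_matrix(np.zeros((3, 3))), dm)

    def test_missing_distance_edges_excluded(self):
        model = self._model()
        dm = small_distances(
            [[0, 10, -1], [10, 0, 50], [-1, 50, 0]], measure="euclidean"
        )
        net = apply_ddd(model, small_matrix(np.zeros((3, 3))), dm)
        pairs = set(map(tuple, net.edges[["roi_a", "roi_b"]].to_numpy()))
        assert ("A", "C") not in pairs


class TestGroupAverage:
    def test_single_matrix_identity(self):
        m = small_matrix([[0, 0.4, 0.2], [0.4, 0, 0.1], [0.2, 0.1, 0]])
        g = group_average([m])
        assert np.array_equal(g.values, m.values)

    def test_mean_of_zero_and_constant(self):
        z = small_matrix(np.zeros((3, 3)))
        c = small_matrix(np.full((3, 3), 0.4) - 0.4 * np.eye(3))
        g = group_average([z, c])
        iu = np.triu_indices(3, 1)
        assert np.allclose(g.values[iu], 0.2)
        assert g.n_subjects == 2

    def test_ordering_mismatch_rejected(self):
        a = small_matrix(np.zeros((3, 3)), ids=("A", "B", "C"))
        b = small_matrix(np.zeros((3, 3)), ids=("B", "A", "C"))
        with pytest.raises(ValueError):
            group_average([a, b])

    def test_commutes_with_permutation(self):
        rng = np.random.default_rng(4)
        mats = [random_connectivity(4, rng) for _ in range(3)]
        perm = [2, 0, 3, 1]
        g = group_average(mats)
        permuted = [
            ConnectivityMatrix(
                values=m.values[np.ix_(perm, perm)],
                roi_ids=[m.roi_ids[i] for i in perm],
            )
            for m in mats
        ]
        gp = group_average(permuted)
        assert np.allclose(gp.values, g.values[np.ix_(perm, perm)])


class TestPercentileBaseline:
    def _matrix_1_to_100(self):
        # 100 unique off-diagonal scores 1..100 (scaled into [0,1])
        n = 15  # 105 pairs; use first 100 distinct, rest zero
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        scores = np.zeros(iu[0].size)
        scores[:100] = np.arange(1, 101) / 100.0
        vals[iu] = scores
        vals += vals.T
        return ConnectivityMatrix(values=vals, roi_ids=[f"r{i}" for i in range(n)])

    def test_nearest_rank_cutoff(self):
        # 105 off-diag values: five 0s plus 1..100 scaled; P=0.40 -> rank 42
        m = self._matrix_1_to_100()
        net = percentile_threshold(m, 0.4)
        vals = np.sort(m.offdiag())
        cutoff = vals[int(np.ceil(0.4 * vals.size)) - 1]
        expected = int(np.sum(m.offdiag() > cutoff))
        assert net.n_surviving(0.4) == expected

    def test_tiny_percentile_keeps_all_positive(self):
        m = self._matrix_1_to_100()
        net = percentile_threshold(m, 1e-9)
        assert net.n_surviving(1e-9) == int(np.sum(m.offdiag() > 0))

    def test_nesting_across_percentiles(self):
        rng = np.random.default_rng(5)
        m = random_connectivity(10, rng)
        nets = {p: percentile_threshold(m, p) for p in (0.05, 0.1, 0.2, 0.4)}
        s = {p: nets[p].surviving_edges(p) for p in nets}
        assert s[0.4] <= s[0.2] <= s[0.1] <= s[0.05]

    def test_matched_count_cutoff(self):
        m = self._matrix_1_to_100()
        cutoff = matched_count_cutoff(m, 10)
        net = percentile_threshold(m, 0.5, cutoff=cutoff)
        assert net.n_surviving(0.5) == 10
        assert matched_count_cutoff(m, 10_000) == -np.inf
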