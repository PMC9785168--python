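import numpy as np
import pytest
from scipy import stats

from csiscore import (
    DEFAULT_WEIGHTS,
    DegenerateDataError,
    WeightVector,
    auc_rank,
    bm_confint,
    grid_search_weights,
    iter_admissible_components,
    roc_points,
    youden_optimal_cutoff,
)
from csiscore.derivation import components_matrix

from conftest import brute_force_auc, random_labeled_instance


class TestAucRank:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 3], [1, 2], 0.875),           # one tied pair worth 1/2
            ([10, 11], [1, 2], 1.0),           # perfect separation
            ([5, 5], [5, 5], 0.5),             # all ties
            ([3, 4, 5, 6], [1, 2, 3, 4], 0.875),
        ],
    )
    def test_known_values(self, pos, neg, expected):
        scores = np.concatenate([pos, neg]).astype(float)
        labels = np.array([True] * len(pos) + [False] * len(neg))
        assert auc_rank(scores, labels) == pytest.approx(expected)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            auc_rank([1.0, 2.0], [True, True])

    def test_equals_pairwise_counting_oracle(self, rng):
        for _ in range(400):
            scores, labels, pos, neg = random_labeled_instance(rng)
            assert auc_rank(scores, labels) == pytest.approx(brute_force_auc(pos, neg))

    def test_invariant_under_strictly_increasing_transform(self, rng):
        for _ in range(50):
            scores, labels, _, _ = random_labeled_instance(rng)
            transformed = np.exp(0.3 * scores) + 7.0
            assert auc_rank(transformed, labels) == pytest.approx(auc_rank(scores, labels))


class TestBrunnerMunzelInterval:
    @staticmethod
    def _sample(rng, n=40):
        scores = np.concatenate([rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        return scores, labels

    def test_point_estimate_is_the_rank_auc(self, rng):
        scores, labels = self._sample(rng)
        est = bm_confint(scores, labels)
        assert est.auc == pytest.approx(auc_rank(scores, labels))
        assert est.ci_low <= est.auc <= est.ci_high

    def test_worked_small_sample(self):
        scores = np.array([3, 4, 5, 6, 1, 2, 3, 4], dtype=float)
        labels = np.array([True] * 4 + [False] * 4)
        est = bm_confint(scores, labels)
        assert est.auc == pytest.approx(0.875)
        assert est.ci_low < 0.875 < est.ci_high
        assert est.ci_high <= 1.0

    def test_matches_scipy_test_statistic_and_df(self, rng):
        """(auc - 1/2)/se must reproduce scipy's Brunner-Munzel statistic."""
        for _ in range(20):
            scores, labels = self._sample(rng, n=int(rng.integers(5, 40)))
            est = bm_confint(scores, labels)
            if est.std_error == 0.0:  # fully concordant draw, statistic undefined
                continue
            ref = stats.brunnermunzel(scores[~labels], scores[labels])
            w = (est.auc - 0.5) / est.std_error
            assert abs(w) == pytest.approx(abs(ref.statistic), rel=1e-10)
            p = 2.0 * stats.t.sf(abs(w), est.df)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_clamped_at_one_for_separated_groups(self):
        scores = np.array([100.0, 101.0, 102.0, 1.0, 2.0, 3.0])
        labels = np.array([True, True, True, False, False, False])
        est = bm_confint(scores, labels)
        assert est.ci_high == 1.0

    def test_near_separation_is_clamped_at_one(self):
        # one discordant pair keeps the rank variance positive; the upper
        # endpoint exceeds 1 before clamping
        scores = np.array([100.0, 101.0, 102.0, 1.0, 2.0, 100.5])
        labels = np.array([True, True, True, False, False, False])
        est = bm_confint(scores, labels)
        assert est.std_error > 0.0
        assert est.ci_high == 1.0

    def test_tiny_level_collapses_to_point(self, rng):
        scores, labels = self._sample(rng)
        est = bm_confint(scores, labels, level=1e-12)
        assert est.ci_low == pytest.approx(est.auc, abs=1e-6)
        assert est.ci_high == pytest.approx(est.auc, abs=1e-6)

    def test_all_ties_zero_variance(self):
        with pytest.raises(DegenerateDataError, match="identical"):
            bm_confint([5.0, 5.0, 5.0, 5.0], [True, True, False, False])

    def test_needs_two_per_class(self):
        with pytest.raises(DegenerateDataError):
            bm_confint([1.0, 2.0, 3.0], [True, False, False])

    def test_coverage_under_normal_shift(self, rng):
        """95% intervals cover the true AUC at roughly the nominal rate."""
        delta = np.sqrt(2.0) * stats.norm.ppf(0.75)  # true AUC = 0.75
        covered = 0
        reps = 500
        for _ in range(reps):
            pos = rng.normal(delta, 1.0, 50)
            neg = rng.normal(0.0, 1.0, 50)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
            est = bm_confint(scores, labels)
            covered += est.ci_low <= 0.75 <= est.ci_high
        assert 0.90 <= covered / reps <= 0.99


class TestRocAndYouden:
    scores = np.array([8, 9, 10, 1, 2, 8], dtype=float)
    labels = np.array([True, True, True, False, False, False])

    def test_point_at_published_style_cutoff(self):
        table = roc_points(self.scores, self.labels)
        row = table[table["cutoff"] == 8].iloc[0]
        assert row["sensitivity"] == pytest.approx(1.0)
        assert row["specificity"] == pytest.approx(2 / 3)

    def test_extreme_cutoffs(self):
        table = roc_points(self.scores, self.labels)
        lowest = table.iloc[0]
        assert lowest["cutoff"] == 1.0
        assert lowest["sensitivity"] == pytest.approx(1.0)
        assert lowest["specificity"] == pytest.approx(0.0)  # everyone called positive

    def test_sorted_ascending_one_row_per_distinct_score(self):
        table = roc_points(self.scores, self.labels)
        assert list(table["cutoff"]) == sorted(set(self.scores))

    def test_youden_tie_breaks_to_smaller_cutoff(self):
        result = youden_optimal_cutoff(self.scores, self.labels)
        assert result.cutoff == 8.0
        assert result.youden_j == pytest.approx(2 / 3)

    def test_perfect_separation(self):
        scores = np.array([10.0, 11.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        result = youden_optimal_cutoff(scores, labels)
        assert result.youden_j == pytest.approx(1.0)
        assert result.cutoff == 10.0  # smallest candidate achieving J = 1

    def test_identical_distributions_give_zero_j(self):
        result = youden_optimal_cutoff([1, 2, 1, 2], [True, True, False, False])
        assert result.youden_j == pytest.approx(0.0)

    def test_agrees_with_exhaustive_search(self, rng):
        for _ in range(300):
            scores, labels, pos, neg = random_labeled_instance(rng, integer=True)
            result = youden_optimal_cutoff(scores, labels)
            cuts = sorted(set(scores))
            js = [(pos >= c).mean() + (neg < c).mean() - 1.0 for c in cuts]
            jmax = max(js)
            best_cut = next(c for c, j in zip(cuts, js) if j >= jmax - 1e-9)
            assert result.cutoff == pytest.approx(best_cut)
            assert result.youden_j == pytest.approx(jmax)


class TestGridSearch:
    @staticmethod
    def _cohort(rng, n=200):
        profiles = list(iter_admissible_components())
        idx = rng.integers(0, len(profiles), n)
        return [profiles[i] for i in idx]

    def test_labels_from_default_score_recovered_perfectly(self, rng):
        components = self._cohort(rng)
        scores = components_matrix(components) @ np.array(DEFAULT_WEIGHTS.as_tuple())
        labels = scores >= 8
        result = grid_search_weights(components, labels, grid=range(4))
        assert result.best_auc == pytest.approx(1.0)
        assert DEFAULT_WEIGHTS in result.ties
        assert result.n_candidates == 4**6

    def test_single_candidate_grid(self, rng):
        components = self._cohort(rng, n=60)
        labels = rng.random(60) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        result = grid_search_weights(components, labels, grid=[[1], [2], [1], [2], [1], [1]])
        assert result.best_weights == DEFAULT_WEIGHTS
        assert result.n_candidates == 1
        scores = components_matrix(components) @ np.array([1, 2, 1, 2, 1, 1])
        assert result.best_auc == pytest.approx(auc_rank(scores, labels))

    def test_best_auc_bounds_every_candidate(self, rng):
        components = self._cohort(rng, n=80)
        labels = components_matrix(components)[:, 1] >= 2  # labels from c_grade alone
        result = grid_search_weights(components, labels, grid=range(3))
        for w in ([1, 1, 1, 1, 1, 1], [2, 1, 0, 2, 1, 0]):
            scores = components_matrix(components) @ np.array(w)
            assert result.best_auc >= auc_rank(scores, labels) - 1e-12

    def test_permutation_invariance_and_determinism(self, rng):
        components = self._cohort(rng, n=100)
        labels = rng.random(100) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        first = grid_search_weights(components, labels, grid=range(3))
        perm = rng.permutation(100)
        second = grid_search_weights([components[i] for i in perm], labels[perm], grid=range(3))
        assert first.best_weights == second.best_weights
        assert first.best_auc == pytest.approx(second.best_auc)
        assert first.ties == second.ties

    def test_tie_break_prefers_minimal_sum_then_lexicographic(self):
        # two patients, separable by any positive weight on c_extent
        components = [(1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0)]
        labels = np.array([True, False])
        result = grid_search_weights(components, labels, grid=range(2))
        assert result.best_auc == pytest.approx(1.0)
        # every maximizer puts weight 1 on c_extent; the minimal-sum one is chosen
        assert result.best_weights == WeightVector(1, 0, 0, 0, 0, 0)
        assert all(t.w_c_extent == 1 for t in result.ties)
        assert len(result.ties) == 2**5

    def test_single_class_cohort_is_degenerate(self, rng):
        components = self._cohort(rng, n=10)
        with pytest.raises(DegenerateDataError):
            grid_search_weights(components, np.ones(10, bool), grid=range(2))
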