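import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qex.errors import MetricError, ModelError
from qex.properties import PropertyVector
from qex.screening import (
    ScreeningRanking,
    cross_validate,
    enrichment_factor,
    evaluate_fixed_model,
    evaluate_ranking,
    qex_scorer_factory,
    ro5_pass_count,
    roc_auc,
)


def make_ranking(scores, labels):
    scores = np.asarray(scores, float)
    return ScreeningRanking(ids=[str(i) for i in range(scores.size)],
                            scores=scores, labels=np.asarray(labels, bool))


def pair_counting_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: active>inactive pairs, ties count 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    act, inact = scores[labels], scores[~labels]
    wins = sum((a > i) + 0.5 * (a == i) for a in act for i in inact)
    return wins / (act.size * inact.size)


class TestRO5:
    @pytest.mark.parametrize(
        "hba, hbd, mw, alogp, expected",
        [
            (5, 5, 499.9, 4.99, 4),   # all bounds satisfied
            (6, 6, 500.0, 5.0, 0),    # MW/logP bounds are strict '<'
            (2, 1, 600.0, 2.0, 3),    # one violation
            (11, 0, 100.0, -2.0, 3),
        ],
    )
    def test_pass_count(self, hba, hbd, mw, alogp, expected):
        props = PropertyVector(mw=mw, alogp=alogp, hbd=hbd, hba=hba,
                               psa=50.0, rotb=3, arom=1, alerts=0)
        assert ro5_pass_count(props) == expected


class TestAUC:
    def test_perfect_separation(self):
        r = make_ranking([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc_auc(r) == 1.0

    def test_all_tied_is_half(self):
        r = make_ranking([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert roc_auc(r) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc(make_ranking([0.1, 0.2], [1, 1]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        # coarse scores force plenty of ties
        scores = rng.integers(0, 6, n) / 5.0
        labels = np.zeros(n, bool)
        labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = make_ranking(scores, labels)
        assert roc_auc(r) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12)

    def test_label_swap_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        labels = rng.random(40) < 0.3
        labels[0], labels[1] = True, False
        direct = roc_auc(make_ranking(scores, labels))
        swapped = roc_auc(make_ranking(scores, ~labels))
        assert direct + swapped == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        labels = np.concatenate([np.ones(20, bool), np.zeros(40, bool)])
        a1 = roc_auc(make_ranking(scores, labels))
        a2 = roc_auc(make_ranking(np.exp(5 * scores) + 3, labels))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestEnrichmentFactor:
    def test_all_actives_in_top_half(self):
        scores = np.concatenate([np.linspace(1, 0.9, 10), np.linspace(0.4, 0, 10)])
        labels = [1] * 10 + [0] * 10
        assert enrichment_factor(make_ranking(scores, labels), 50) == pytest.approx(2.0)

    def test_full_ranking_is_one(self):
        rng = np.random.default_rng(0)
        r = make_ranking(rng.random(50), rng.random(50) < 0.4)
        assert enrichment_factor(r, 100) == pytest.approx(1.0)

    def test_uniform_interleave_near_one(self):
        # strict alternation of actives and inactives, 100 compounds
        scores = np.linspace(1, 0, 100)
        labels = np.tile([1, 0], 50)
        assert enrichment_factor(make_ranking(scores, labels), 50) == pytest.approx(
            1.0, abs=0.05)

    def test_hand_count_ten_percent(self):
        # 10 actives, 90 inactives; exactly 3 actives in the top 10
        scores = np.linspace(1.0, 0.01, 100)
        labels = np.zeros(100, bool)
        labels[[0, 4, 7]] = True   # 3 actives inside the top 10
        labels[90:97] = True       # remaining 7 actives near the bottom
        r = make_ranking(scores, labels)
        assert enrichment_factor(r, 10) == pytest.approx(3.0)

    def test_upper_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            r = make_ranking(rng.integers(0, 4, n) / 3.0,
                             np.arange(n) < rng.integers(1, n))
            for x in (5, 10, 20, 50):
                ef = enrichment_factor(r, x)
                assert 0 <= ef <= 100.0 / x + 1e-9

    def test_bad_cutoff_rejected(self):
        r = make_ranking([1.0, 0.0], [1, 0])
        with pytest.raises(MetricError):
            enrichment_factor(r, 0)
        with pytest.raises(MetricError):
            enrichment_factor(r, 101)

    def test_fractional_ties_equal_random_tie_expectation(self):
        # 10 actives among 100 all-tied compounds: top 10% holds exactly the
        # active fraction in expectation -> EF = 1
        r = make_ranking(np.full(100, 0.5), np.arange(100) < 10)
        assert enrichment_factor(r, 10) == pytest.approx(1.0, abs=1e-12)
        # stable convention instead surfaces the input-order bias
        assert enrichment_factor(r, 10, ties="stable") == pytest.approx(10.0)

    def test_tie_randomization_is_seeded(self):
        scores = np.full(50, 0.5)
        labels = np.arange(50) < 10
        r = make_ranking(scores, labels)
        a = enrichment_factor(r, 10, tie_seed=5)
        b = enrichment_factor(r, 10, tie_seed=5)
        assert a == b


class TestCrossValidate:
    def constant_factory(self, *_args):
        return lambda X: np.full(X.shape[0], 0.42)

    def test_constant_scorer_is_uninformative(self, small_benchmark):
        actives, inactives = small_benchmark
        cv = cross_validate(actives, inactives,
                            lambda train: self.constant_factory(),
                            k=5, seed=1)
        assert cv.mean.auc == pytest.approx(0.5, abs=1e-12)
        for x, ef in cv.mean.ef.items():
            # fractional tie convention: only the ceil() of the cutoff
            # deviates from exactly 1
            assert ef == pytest.approx(1.0, abs=0.05)

    def test_identical_seed_reproduces_result(self, small_benchmark):
        actives, inactives = small_benchmark
        factory = qex_scorer_factory(top=50)
        cv1 = cross_validate(actives[:150], inactives[:400], factory, k=5, seed=9)
        cv2 = cross_validate(actives[:150], inactives[:400], factory, k=5, seed=9)
        assert cv1.to_frame().equals(cv2.to_frame())

    def test_fold_sizes_differ_by_at_most_one(self, small_benchmark):
        actives, inactives = small_benchmark
        cv = cross_validate(actives[:103], inactives[:200],
                            lambda train: self.constant_factory(), k=5, seed=0)
        # fold test-set size = ranking size - inactive pool
        sizes = [21, 21, 21, 20, 20]
        assert cv.k == 5 and len(cv.folds) == 5
        from qex.screening import _fold_indices
        folds = _fold_indices(103, 5, 0)
        assert sorted(len(f) for f in folds) == sorted(sizes)

    def test_mean_equals_arithmetic_mean_of_folds(self, small_benchmark):
        actives, inactives = small_benchmark
        cv = cross_validate(actives[:100], inactives[:300],
                            lambda train: self.constant_factory(), k=4, seed=2)
        assert cv.mean.auc == pytest.approx(
            np.mean([f.auc for f in cv.folds]), abs=1e-12)
        for x in cv.mean.ef:
            assert cv.mean.ef[x] == pytest.approx(
                np.mean([f.ef[x] for f in cv.folds]), abs=1e-12)

    def test_fold_too_small_aborts(self, small_benchmark):
        actives, inactives = small_benchmark
        with pytest.raises(ModelError, match="training split"):
            cross_validate(actives[:24], inactives[:50],
                           lambda train: self.constant_factory(), k=5, seed=0)


class TestFixedModel:
    def test_mw_only_model_separates_constructed_classes(self, rig_model_factory):
        # actives sit at the rig desirability peak (x=0) in MW; inactives far off
        model = rig_model_factory([0.1] * 8, weights=[1, 0, 0, 0, 0, 0, 0, 0])
        actives = np.zeros((30, 8))
        inactives = np.full((60, 8), -100.0)
        import pandas as pd
        from qex.properties import PROPERTY_NAMES
        act = pd.DataFrame(actives, columns=list(PROPERTY_NAMES)).assign(id=range(30))
        inact = pd.DataFrame(inactives, columns=list(PROPERTY_NAMES)).assign(
            id=range(30, 90))
        report = evaluate_fixed_model(model, act, inact)
        assert report.auc > 0.5

    def test_repeated_evaluation_identical(self, small_benchmark, rig_model_factory):
        actives, inactives = small_benchmark
        model = rig_model_factory([0.3] * 8)
        r1 = evaluate_fixed_model(model, actives[:50], inactives[:100])
        r2 = evaluate_fixed_model(model, actives[:50], inactives[:100])
        assert r1.to_dict() == r2.to_dict()

    def test_training_overlap_flagged_in_provenance(self, small_benchmark,
                                                    rig_model_factory):
        actives, inactives = small_benchmark
        model = rig_model_factory([0.3] * 8)
        report = evaluate_fixed_model(model, actives[:50], inactives[:100],
                                      flag_training_overlap=True)
        assert "training" in report.provenance

    def test_fold_restricted_evaluation_mirrors_cv_folds(self, small_benchmark,
                                                         rig_model_factory):
        actives, inactives = small_benchmark
        model = rig_model_factory([0.3] * 8)
        cv = evaluate_fixed_model(model, actives[:60], inactives[:100],
                                  folds=(5, 3))
        assert cv.k == 5 and len(cv.folds) == 5
        assert cv.mean.auc == pytest.approx(
            np.mean([f.auc for f in cv.folds]), abs=1e-12)


def test_report_dict_layout(small_benchmark, rig_model_factory):
    actives, inactives = small_benchmark
    model = rig_model_factory([0.3] * 8)
    report = evaluate_fixed_model(model, actives[:40], inactives[:80])
    d = report.to_dict()
    assert set(d) == {"auc", "ef_1pct", "ef_2pct", "ef_5pct",
                      "ef_10pct", "ef_20pct", "ef_50pct"}
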