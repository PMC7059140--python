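"""Classifier training, selection, prediction and validation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kcml.annotations import AnnotationSet, CatalogEntry
from kcml.core import (
    ClassifierMetrics,
    TrainConfig,
    add_zscored_ranks,
    consensus_retrain,
    cv_fscore,
    evaluate_scores,
    forward_select,
    ks_feature_ranking,
    optimize_sigma,
    predict_genome,
    select_classifiable,
    split_and_sample,
    train_term_classifier,
    validate_new_annotations,
)
from kcml.profiles import feature_columns


def auroc_pair_oracle(pos_scores, neg_scores):
    """Fraction of correctly ordered (pos, neg) pairs; ties count half."""
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos_scores for n in neg_scores)
    return wins / (len(pos_scores) * len(neg_scores))


@pytest.fixture()
def tiny_term():
    genes = frozenset(f"g{i:03d}" for i in range(100))
    return CatalogEntry("term", genes)


@pytest.fixture()
def universe():
    return [f"g{i:03d}" for i in range(400)]


class TestSplitAndSample:
    def test_70_30_proportions(self, tiny_term, universe):
        part = split_and_sample(tiny_term, universe, TrainConfig(rng_seed=0))
        assert len(part.train_pos) == 70 and len(part.test_pos) == 30
        assert len(part.train_neg) == 70 and len(part.test_neg) == 30

    def test_same_seed_identical(self, tiny_term, universe):
        cfg = TrainConfig(rng_seed=3)
        a = split_and_sample(tiny_term, universe, cfg)
        b = split_and_sample(tiny_term, universe, cfg)
        assert a == b

    def test_negatives_never_overlap_positives(self, universe):
        rng = np.random.default_rng(0)
        for s in range(100):
            genes = frozenset(rng.choice(universe, size=50, replace=False))
            part = split_and_sample(CatalogEntry("t", genes), universe, TrainConfig(rng_seed=s))
            negs = set(part.train_neg) | set(part.test_neg)
            assert negs.isdisjoint(genes)
            assert len(negs) == 50

    def test_insufficient_negatives_is_error(self):
        term = CatalogEntry("t", frozenset(f"g{i}" for i in range(90)))
        with pytest.raises(ValueError, match="negatives"):
            split_and_sample(term, [f"g{i}" for i in range(100)], TrainConfig())


class TestKSRanking:
    def test_separating_feature_ranks_first(self, rng):
        pos = [f"p{i}" for i in range(30)]
        neg = [f"n{i}" for i in range(30)]
        x = rng.normal(size=(60, 20))
        m = pd.DataFrame(x, index=pos + neg, columns=[f"f{j:02d}" for j in range(20)])
        m.loc[pos, "f07"] += 10.0  # complete separation
        assert ks_feature_ranking(m, pos, neg)[0] == "f07"

    def test_matches_per_feature_sweep(self, rng):
        pos = [f"p{i}" for i in range(15)]
        neg = [f"n{i}" for i in range(20)]
        m = pd.DataFrame(rng.normal(size=(35, 10)), index=pos + neg,
                         columns=[f"f{j}" for j in range(10)])
        got = ks_feature_ranking(m, pos, neg)
        keyed = []
        for j, f in enumerate(m.columns):
            r = stats.ks_2samp(m.loc[pos, f], m.loc[neg, f], method="asymp")
            keyed.append((r.pvalue, -r.statistic, j, f))
        assert got == [f for *_, f in sorted(keyed)]

    def test_identical_distributions_fall_back_to_column_order(self):
        pos, neg = ["p0", "p1"], ["n0", "n1"]
        x = np.tile([[1.0], [2.0], [1.0], [2.0]], (1, 4))
        m = pd.DataFrame(x, index=pos + neg, columns=list("abcd"))
        assert ks_feature_ranking(m, pos, neg) == list("abcd")


def _labelled_data(rng, n_per_class=30, n_feats=10, informative=(0,), effect=2.0):
    x = rng.normal(size=(2 * n_per_class, n_feats))
    y = np.r_[np.ones(n_per_class), np.zeros(n_per_class)]
    for j in informative:
        x[: n_per_class, j] += effect
    cols = [f"f{j:02d}" for j in range(n_feats)]
    return pd.DataFrame(x, columns=cols), y


class TestForwardSelect:
    def test_planted_feature_recovered(self, rng):
        train, y = _labelled_data(rng, n_per_class=40, n_feats=50, informative=(3,))
        order = ks_feature_ranking(train.assign(), [i for i in range(40)], list(range(40, 80)))
        cfg = TrainConfig(rng_seed=0, cv_folds=10)
        selected, trace = forward_select(order, train, y, sigma=3.0, cfg=cfg)
        assert "f03" in selected
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_trace_nondecreasing_on_noise(self, rng):
        train, y = _labelled_data(rng, n_per_class=20, n_feats=15, informative=(), effect=0)
        order = list(train.columns)
        _, trace = forward_select(order, train, y, sigma=3.0, cfg=TrainConfig(cv_folds=5))
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_max_features_cap(self, rng):
        train, y = _labelled_data(rng, n_per_class=25, n_feats=12,
                                  informative=tuple(range(12)), effect=3.0)
        cfg = TrainConfig(cv_folds=5, max_features=3)
        selected, _ = forward_select(list(train.columns), train, y, sigma=3.0, cfg=cfg)
        assert 1 <= len(selected) <= 3

    def test_single_class_is_error(self, rng):
        train, _ = _labelled_data(rng, n_per_class=10)
        with pytest.raises(ValueError, match="single class"):
            forward_select(list(train.columns), train, np.ones(20), 1.0, TrainConfig())


class TestOptimizeSigma:
    def test_single_value_grid(self, rng):
        x, y = _labelled_data(rng)
        assert optimize_sigma(x.to_numpy(), y, [2.5], TrainConfig(cv_folds=5)) == 2.5

    def test_best_grid_value_verified_exhaustively(self, rng):
        x, y = _labelled_data(rng, n_per_class=25, informative=(0, 1), effect=2.5)
        cfg = TrainConfig(cv_folds=5)
        grid = [0.1, 1.0, 4.0, 16.0]
        best = optimize_sigma(x.to_numpy(), y, grid, cfg)
        scores = {s: cv_fscore(x.to_numpy(), y, s, cfg) for s in grid}
        assert scores[best] == max(scores.values())

    def test_deterministic(self, rng):
        x, y = _labelled_data(rng)
        cfg = TrainConfig(cv_folds=5)
        g = [0.5, 2.0, 8.0]
        assert optimize_sigma(x.to_numpy(), y, g, cfg) == optimize_sigma(x.to_numpy(), y, g, cfg)


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate_scores(np.array([2.0, 3.0]), np.array([1.0, 2.0]), np.array([-1.0, -2.0]))
        assert m.auroc == 1.0 and m.fpr == 0.0 and m.test_recall == 1.0

    def test_fscore_formula(self):
        m = ClassifierMetrics(precision=0.5, test_recall=1.0)
        assert m.fscore == pytest.approx(2 / 3)

    def test_auroc_matches_pair_counting(self, rng):
        for _ in range(20):
            pos = rng.integers(0, 5, size=12).astype(float)  # ties on purpose
            neg = rng.integers(0, 5, size=9).astype(float)
            m = evaluate_scores(np.array([1.0]), pos, neg)
            assert m.auroc == pytest.approx(auroc_pair_oracle(pos, neg))

    def test_empty_test_class_missing(self):
        m = evaluate_scores(np.array([1.0]), np.array([]), np.array([1.0]))
        assert np.isnan(m.auroc)


class TestSelectClassifiable:
    def _clf(self, fpr, test_recall, train_recall):
        m = ClassifierMetrics(precision=0.5, test_recall=test_recall,
                              train_recall=train_recall, fpr=fpr, auroc=0.7)

        class Stub:
            metrics = m
        return Stub()

    def test_threshold_semantics(self):
        cfg = TrainConfig()
        passing = self._clf(0.19, 0.31, 0.41)
        at_fpr_bound = self._clf(0.20, 0.9, 0.9)
        at_recall_bound = self._clf(0.05, 0.30, 0.9)
        out = select_classifiable([passing, at_fpr_bound, at_recall_bound], cfg)
        assert out == [passing]

    def test_empty_input(self):
        assert select_classifiable([], TrainConfig()) == []


class TestTrainAndPredict:
    def test_small_planted_term_classifiable(self, small_classifier, small_screen):
        _, _, truth = small_screen
        clf = small_classifier
        assert clf.classifiable
        assert 1 <= len(clf.selected_features) <= 100
        overlap = set(clf.selected_features) & set(truth.informative["S000"])
        assert overlap  # discriminative features found among planted ones

    def test_identical_seed_identical_metrics(self, small_screen):
        m, _, truth = small_screen
        mat = m[feature_columns(m)]
        entry = CatalogEntry("S000", frozenset(truth.positives["S000"]))
        a = train_term_classifier(entry, mat, cfg=TrainConfig(rng_seed=9))
        b = train_term_classifier(entry, mat, cfg=TrainConfig(rng_seed=9))
        assert a.metrics == b.metrics
        assert a.selected_features == b.selected_features
        assert a.sigma == b.sigma

    def test_too_few_positives_skipped(self, small_screen):
        m, _, _ = small_screen
        mat = m[feature_columns(m)]
        entry = CatalogEntry("tiny", frozenset(list(mat.index[:5])))
        assert train_term_classifier(entry, mat) is None

    def test_predict_ranks_and_invariance(self, small_classifier, small_screen):
        m, _, truth = small_screen
        mat = m[feature_columns(m)]
        preds = predict_genome(small_classifier, mat)
        assert len(preds) == len(mat)
        top = preds.loc[preds["rank"] == 1.0]
        assert top["decision_score"].iloc[0] == preds["decision_score"].max()
        # training positives mostly recovered
        tr_pos = small_classifier.partition.train_pos
        frac = preds.set_index("gene").loc[tr_pos, "predicted"].mean()
        assert frac > 0.4
        # permutation invariance
        shuffled = mat.sample(frac=1.0, random_state=1)
        preds2 = predict_genome(small_classifier, shuffled).set_index("gene")
        merged = preds.set_index("gene").join(preds2, rsuffix="_p")
        assert np.allclose(merged["decision_score"], merged["decision_score_p"])

    def test_missing_feature_is_named_error(self, small_classifier, small_screen):
        m, _, _ = small_screen
        mat = m[feature_columns(m)].drop(columns=small_classifier.selected_features[:1])
        with pytest.raises(KeyError, match=small_classifier.selected_features[0]):
            predict_genome(small_classifier, mat)

    def test_model_json_roundtrip_scores(self, small_classifier, small_screen, tmp_path):
        from kcml.core import PortableModel

        m, _, _ = small_screen
        mat = m[feature_columns(m)]
        path = tmp_path / "model.json"
        small_classifier.to_json(path)
        back = PortableModel.from_json(path)
        orig = small_classifier.decision_scores(mat)
        again = back.decision_scores(mat)
        assert np.allclose(orig, again, atol=1e-10)
        assert back.classifiable == small_classifier.classifiable

    def test_zscored_ranks(self, rng):
        df = pd.DataFrame({
            "gene": ["a", "a", "b", "b"],
            "term": ["t1", "t2", "t1", "t2"],
            "decision_score": [1.0, -1.0, 0.5, 0.5],
            "predicted": [True, False, True, True],
        })
        out = add_zscored_ranks(df)
        a = out[out["gene"] == "a"]["zscored_rank"]
        assert a.mean() == pytest.approx(0.0)
        assert (out[out["gene"] == "b"]["zscored_rank"] == 0.0).all()  # zero spread


class TestConsensus:
    def test_consensus_subset_and_determinism(self, small_classifier, small_screen):
        m, _, truth = small_screen
        mat = m[feature_columns(m)]
        entry = CatalogEntry("S000", frozenset(truth.positives["S000"]))
        cfg = TrainConfig(rng_seed=5)
        votes = consensus_retrain(small_classifier, entry, mat, cfg=cfg)
        votes2 = consensus_retrain(small_classifier, entry, mat, cfg=cfg)
        pd.testing.assert_frame_equal(votes, votes2)
        preds = predict_genome(small_classifier, mat)
        single = set(preds.loc[preds["predicted"], "gene"])
        consensus = set(votes.loc[votes["consensus"], "gene"])
        # strong planted signal: consensus is mostly contained in the
        # single-model prediction set
        assert len(consensus & single) / max(len(consensus), 1) > 0.8

    def test_required_equals_folds_is_intersection(self, small_classifier, small_screen):
        m, _, truth = small_screen
        mat = m[feature_columns(m)]
        entry = CatalogEntry("S000", frozenset(truth.positives["S000"]))
        cfg = TrainConfig(rng_seed=5, consensus_required=10)
        votes = consensus_retrain(small_classifier, entry, mat, cfg=cfg)
        assert (votes["consensus"] == (votes["votes"] == 10)).all()


class TestValidateNewAnnotations:
    def _preds(self, genes, predicted):
        return pd.DataFrame({
            "gene": genes,
            "term": "t",
            "decision_score": [1.0 if g in predicted else -1.0 for g in genes],
            "predicted": [g in predicted for g in genes],
        })

    def test_enrichment_matches_hypergeometric_enumeration(self):
        genes = [f"g{i}" for i in range(20)]
        predicted = set(genes[:5])
        new = AnnotationSet.from_pairs([(g, "t") for g in genes[:4]])
        old = AnnotationSet({})
        out = validate_new_annotations(self._preds(genes, predicted), old, new)
        # all 4 new annotations inside the 5 predicted of 20:
        # P(X >= 4), X ~ Hypergeom(N=20, K=4, n=5)
        expected = sum(
            math.comb(4, k) * math.comb(16, 5 - k) / math.comb(20, 5)
            for k in range(4, 5)
        )
        assert out["fisher_p"].iloc[0] == pytest.approx(expected)
        assert out["fraction_predicted"].iloc[0] == 1.0

    def test_independent_predictions_give_uniformish_p(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ps = []
        for s in range(200):
            r = np.random.default_rng(s)
            predicted = set(r.choice(genes, size=20, replace=False))
            new = AnnotationSet.from_pairs(
                [(g, "t") for g in r.choice(genes, size=10, replace=False)])
            out = validate_new_annotations(self._preds(genes, predicted),
                                           AnnotationSet({}), new)
            ps.append(out["fisher_p"].iloc[0])
        # under the null, right-tail p-values are super-uniform
        assert np.mean(np.array(ps) < 0.05) <= 0.08

    def test_empty_diff_skips_term(self):
        genes = [f"g{i}" for i in range(10)]
        out = validate_new_annotations(self._preds(genes, set(genes[:2])),
                                       AnnotationSet({}), AnnotationSet({}))
        assert len(out) == 0

    def test_overlapping_diff_rejected(self):
        genes = ["a", "b"]
        ann = AnnotationSet({"a": {"t"}})
        with pytest.raises(ValueError, match="disjoint"):
            validate_new_annotations(self._preds(genes, {"a"}), ann, ann)
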