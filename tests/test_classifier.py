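"""Ensemble training, evaluation metrics, thresholds and persistence."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from neuropid import classifier, feature_extraction, synth_data
from neuropid.classifier import (
    DEFAULT_THRESHOLDS,
    MODEL_NAMES,
    CatalogMismatchError,
    ModelBundle,
    auc,
    call_positive,
    confusion_metrics,
    select_minimal_features,
    train,
)


class TestConfusionMetrics:
    def test_printed_formula_example(self):
        m = confusion_metrics(tp=9, tn=8, fp=1, fn=2)
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(9 / 11)
        assert m.mcc == pytest.approx(70 / np.sqrt(9900))

    def test_perfect_classifier(self):
        m = confusion_metrics(tp=5, tn=5, fp=0, fn=0)
        assert (m.accuracy, m.precision, m.recall, m.mcc) == (1, 1, 1, 1)

    def test_undefined_precision_flagged(self):
        m = confusion_metrics(tp=0, tn=5, fp=0, fn=3)
        assert m.precision == 0.0 and m.precision_undefined

    def test_exhaustive_grid_against_exact_fraction_oracle(self):
        """Counts in [0,10]^4: agree with exact rational-arithmetic
        evaluation of the printed formulas."""
        for tp, tn, fp, fn in itertools.product(range(11), repeat=4):
            total = tp + tn + fp + fn
            if total == 0:
                with pytest.raises(ValueError):
                    confusion_metrics(tp, tn, fp, fn)
                continue
            m = confusion_metrics(tp, tn, fp, fn)
            assert m.accuracy == pytest.approx(
                float(Fraction(tp + tn, total)))
            assert m.precision == pytest.approx(
                float(Fraction(tp, tp + fp)) if tp + fp else 0.0)
            assert m.recall == pytest.approx(
                float(Fraction(tp, tp + fn)) if tp + fn else 0.0)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected_mcc = (
                0.0 if denom == 0
                else (tp * tn - fp * fn) / float(denom) ** 0.5
            )
            assert m.mcc == pytest.approx(expected_mcc)
            assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12


def pairwise_auc(scores, labels):
    """O(n^2) brute force: correctly ranked pos-neg pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_computed_pairs(self):
        assert auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 51))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            # coarse grid forces ties
            scores = rng.integers(0, 6, size=n) / 5.0
            assert auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels))


class TestCallPositive:
    def test_single_model_above_threshold_is_positive(self):
        probs = dict(zip(MODEL_NAMES, [0.85, 0.10, 0.10, 0.10]))
        calls, overall = call_positive(probs, DEFAULT_THRESHOLDS)
        assert overall and calls["random_forest"]
        assert sum(calls.values()) == 1

    def test_gradient_boosting_strict_099(self):
        probs = dict(zip(MODEL_NAMES, [0.5, 0.98, 0.5, 0.5]))
        _, overall = call_positive(probs, DEFAULT_THRESHOLDS)
        assert not overall
        probs["gradient_boosting"] = 0.991
        _, overall = call_positive(probs, DEFAULT_THRESHOLDS)
        assert overall

    def test_strict_inequality_at_08(self):
        probs = dict(zip(MODEL_NAMES, [0.8, 0.0, 0.8, 0.8]))
        calls, overall = call_positive(probs, DEFAULT_THRESHOLDS)
        assert not overall and not any(calls.values())

    def test_all_zero_is_negative(self):
        probs = dict(zip(MODEL_NAMES, [0.0] * 4))
        _, overall = call_positive(probs, DEFAULT_THRESHOLDS)
        assert not overall


class TestMinimalFeatureSelection:
    def test_planted_signal_recovered(self):
        """Only a few named columns separate the classes; they must rank
        into the selected subset."""
        rng = np.random.default_rng(0)
        names = feature_extraction.FEATURE_NAMES
        planted = ("dens_dibasic", "dens_dibasic_trim", "internal_score")
        pos = rng.normal(size=(80, 560))
        neg = rng.normal(size=(80, 560))
        for name in planted:
            pos[:, names.index(name)] += 4.0
        subset = select_minimal_features(pos, neg, k=10, seed=0)
        for name in planted:
            assert name in subset

    def test_k_equal_catalog_is_identity(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(size=(12, 560)), rng.normal(size=(12, 560))
        subset = select_minimal_features(pos, neg, k=560, seed=0)
        assert set(subset) == set(feature_extraction.FEATURE_NAMES)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            select_minimal_features(np.zeros((4, 560)), np.zeros((4, 560)),
                                    k=561)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(size=(20, 560)), rng.normal(size=(20, 560))
        assert select_minimal_features(pos, neg, k=15, seed=3) == \
            select_minimal_features(pos, neg, k=15, seed=3)


class TestTrainedEnsemble:
    def test_separable_synthetic_data_reaches_high_cv_auc(self, trained):
        _, cv = trained
        for name in MODEL_NAMES:
            assert cv[name].auc >= 0.95, name

    def test_training_errors(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 560)),
                         columns=list(feature_extraction.FEATURE_NAMES))
        with pytest.raises(ValueError):
            train(X, X.iloc[:0], seed=0)  # single-class input
        with pytest.raises(ValueError):
            train(X, X, seed=0, folds=6)  # fewer examples than folds

    def test_null_distribution_auc_near_half(self):
        """Positives and negatives from the identical distribution:
        held-out AUC hovers around chance."""
        cfg = synth_data.GeneratorConfig(n_sequences=120,
                                         negative_class="globular-like")
        import dataclasses
        a = synth_data.generate_negative(dataclasses.replace(cfg, seed=21))
        b = synth_data.generate_negative(dataclasses.replace(cfg, seed=22))
        Xa = feature_extraction.extract_matrix(a)
        Xb = feature_extraction.extract_matrix(b)
        _, cv = train(Xa, Xb, seed=7)
        for name in MODEL_NAMES:
            assert 0.4 <= cv[name].auc <= 0.6, (name, cv[name].auc)

    def test_predict_is_deterministic_and_in_unit_interval(
            self, trained, fresh_test_sets):
        bundle, _ = trained
        pos, _ = fresh_test_sets
        fv = feature_extraction.extract(pos[0])
        p1, p2 = bundle.predict(fv), bundle.predict(fv)
        assert p1 == p2
        assert all(0.0 <= p1[m] <= 1.0 for m in MODEL_NAMES)

    def test_strong_positive_scores_high_under_all_models(
            self, trained, fresh_test_sets):
        bundle, _ = trained
        pos, _ = fresh_test_sets
        probs = bundle.predict(feature_extraction.extract(pos[0]))
        assert all(probs[m] > 0.5 for m in MODEL_NAMES)

    def test_catalog_version_mismatch_refused(self, trained):
        bundle, _ = trained
        fv = feature_extraction.FeatureVector(
            values=np.zeros(560), catalog_version="other-catalog-v9")
        with pytest.raises(CatalogMismatchError):
            bundle.predict(fv)

    def test_minimal_tree_correlates_with_full_forest(
            self, trained, fresh_test_sets):
        bundle, _ = trained
        pos, neg = fresh_test_sets
        X = feature_extraction.extract_matrix((pos + neg)[:200])
        probs = bundle.predict_matrix(X)
        rho, _ = spearmanr(probs["minimal_tree"], probs["random_forest"])
        assert rho > 0

    def test_parameter_recovery_on_fresh_seed(self, trained, fresh_test_sets):
        bundle, _ = trained
        pos, neg = fresh_test_sets
        X = feature_extraction.extract_matrix(pos + neg)
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        probs = bundle.predict_matrix(X)
        pred = probs["random_forest"].to_numpy() > 0.5
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        assert confusion_metrics(tp, tn, fp, fn).mcc > 0.8

    def test_save_load_round_trip(self, trained, fresh_test_sets, tmp_path):
        import json

        bundle, _ = trained
        bundle.save(tmp_path / "bundle")
        manifest = json.loads((tmp_path / "bundle" / "manifest.json").read_text())
        assert manifest["thresholds"]["gradient_boosting"] == 0.99
        loaded = ModelBundle.load(tmp_path / "bundle")
        pos, _ = fresh_test_sets
        fv = feature_extraction.extract(pos[1])
        assert loaded.predict(fv) == bundle.predict(fv)
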