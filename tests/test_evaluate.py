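"""Metric panel against brute-force oracles, ROC/AUC concordance,
AWGN calibration, engineered features, and the robustness protocol."""

import itertools

import numpy as np
import pytest

from fatiguekit.evaluate import (add_awgn, confusion_and_metrics,
                                 engineered_features, robustness_curve,
                                 roc_ovr)


# ---------------------------------------------------------------- oracles
def brute_force_metrics(cm):
    """Independent metric computation straight from the definitions."""
    cm = np.asarray(cm, dtype=float)
    k = cm.shape[0]
    total = cm.sum()
    acc = np.trace(cm) / total
    sens, spec, prec, f1 = [], [], [], []
    for i in range(k):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        s = tp / (tp + fn) if tp + fn else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        sens.append(s)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        prec.append(p)
        f1.append(2 * p * s / (p + s) if p + s else 0.0)
    po = acc
    pe = sum(cm[i].sum() * cm[:, i].sum() for i in range(k)) / total ** 2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 0.0
    return acc, sens, spec, prec, f1, kappa


def labels_from_cm(cm):
    y_true, y_pred = [], []
    for i, j in itertools.product(range(cm.shape[0]), repeat=2):
        y_true += [i] * cm[i, j]
        y_pred += [j] * cm[i, j]
    return np.array(y_true), np.array(y_pred)


def concordance_auc(truth, scores):
    """AUC as the exhaustive pairwise concordance probability."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------------------------ tests
class TestConfusionMetrics:
    def test_perfect_two_class_prediction(self):
        y = np.repeat([0, 1], 50)
        rep = confusion_and_metrics(y, y, 2)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert rep.macro_f_score == 1.0

    def test_hand_evaluated_kappa_case(self):
        y_true, y_pred = labels_from_cm(np.array([[40, 10], [5, 45]]))
        rep = confusion_and_metrics(y_true, y_pred, 2)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.70)

    def test_constant_prediction_has_zero_kappa(self):
        y_true = np.repeat([0, 1], 30)
        rep = confusion_and_metrics(y_true, np.zeros(60, dtype=int), 2)
        assert rep.kappa == pytest.approx(0.0)

    def test_agrees_with_brute_force_on_random_matrices(self):
        """The sklearn-backed panel equals the from-definitions oracle on
        100 random confusion matrices."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            cm = rng.integers(0, 30, size=(k, k))
            cm[0, 0] += 1  # ensure non-empty
            y_true, y_pred = labels_from_cm(cm)
            rep = confusion_and_metrics(y_true, y_pred, k)
            acc, sens, spec, prec, f1, kappa = brute_force_metrics(cm)
            assert rep.accuracy == pytest.approx(acc)
            assert rep.sensitivity == pytest.approx(sens)
            assert rep.specificity == pytest.approx(spec)
            assert rep.precision == pytest.approx(prec)
            assert rep.f_score == pytest.approx(f1)
            assert rep.kappa == pytest.approx(kappa)
            assert rep.confusion.sum() == len(y_true)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([0, 5], [0, 1], 2)


class TestROC:
    def test_perfect_separation_gives_auc_1(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = roc_ovr(y, scores)
        assert out[0]["auc"] == 1.0 and out[1]["auc"] == 1.0

    def test_uninformative_scores_give_auc_half(self):
        y = np.repeat([0, 1], 10)
        scores = np.full((20, 2), 0.5)
        out = roc_ovr(y, scores)
        assert out[0]["auc"] == pytest.approx(0.5)

    def test_degenerate_class_flagged(self):
        y = np.zeros(5, dtype=int)
        scores = np.column_stack([np.full(5, 0.7), np.full(5, 0.3)])
        out = roc_ovr(y, scores)
        assert out[1]["degenerate"] and np.isnan(out[1]["auc"])

    def test_unnormalized_scores_rejected(self):
        with pytest.raises(ValueError):
            roc_ovr(np.array([0, 1]), np.array([[0.9, 0.5], [0.1, 0.5]]))

    def test_auc_equals_exhaustive_concordance_up_to_n12(self):
        rng = np.random.default_rng(1)
        for n in (4, 8, 12):
            for _ in range(20):
                truth = rng.integers(0, 2, n)
                if truth.min() == truth.max():
                    continue
                s1 = np.round(rng.random(n), 2)
                scores = np.column_stack([1 - s1, s1])
                out = roc_ovr(truth, scores)
                assert out[1]["auc"] == pytest.approx(
                    concordance_auc(truth, s1))


class TestAWGN:
    @pytest.mark.parametrize("n", [1000, 3750, 20000])
    def test_realized_snr_converges_to_target(self, n):
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 10 * np.arange(n) / 250)
        noisy = add_awgn(x, 10.0, seed=3)
        realized = 10 * np.log10(np.mean(x ** 2) / np.mean((noisy - x) ** 2))
        tol = 0.5 if n >= 3750 else 1.0
        assert realized == pytest.approx(10.0, abs=tol)

    def test_infinite_snr_returns_signal_unchanged(self):
        x = np.arange(10.0)
        assert np.array_equal(add_awgn(x, np.inf), x)

    def test_fixed_seed_reproduces_noise(self):
        x = np.ones(100)
        assert np.array_equal(add_awgn(x, 5, seed=4), add_awgn(x, 5, seed=4))

    def test_zero_power_signal_rejected(self):
        with pytest.raises(ValueError):
            add_awgn(np.zeros(10), 10)


class TestEngineeredFeatures:
    def test_sinusoid_closed_forms(self):
        # 12.5 Hz at 250 Hz puts samples exactly on the sinusoid peaks
        x = np.sin(2 * np.pi * 12.5 * np.arange(25000) / 250)
        f = engineered_features(x)
        assert f[0] == pytest.approx(0.0, abs=1e-6)           # mean
        assert f[1] == pytest.approx(np.sqrt(2), rel=1e-6)    # crest factor
        assert f[4] == pytest.approx(1.0, abs=1e-4)           # max
        assert f[5] == pytest.approx(-1.0, abs=1e-4)          # min

    def test_hand_vector(self):
        f = engineered_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f[0] == 2.5
        assert f[3] == pytest.approx(1.25)
        assert f[4] == 4.0 and f[5] == 1.0

    def test_constant_signal(self):
        f = engineered_features(np.full(10, 3.0))
        assert f[0] == 3.0 and f[3] == 0.0 and f[4] == f[5] == 3.0

    def test_zero_rms_crest_factor_flagged(self):
        with pytest.warns(UserWarning, match="crest"):
            f = engineered_features(np.zeros(10))
        assert np.isnan(f[1])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            engineered_features(np.array([1.0]))


class TestRobustnessCurve:
    def test_infinite_snr_entry_equals_clean_accuracy(self, two_class_split,
                                                      two_class_models):
        _, _, test = two_class_split
        curve = robustness_curve(two_class_models,
                                 (test.epochs, test.labels),
                                 [0.0, np.inf], replicates=2, seed=0)
        for name, clf in two_class_models.items():
            clean = clf.score(test.epochs, test.labels)
            inf_idx = curve.snr_grid_db.index(np.inf)
            assert np.all(curve.accuracy[name][inf_idx] == clean)

    def test_rerun_is_bit_identical(self, two_class_split, two_class_models):
        _, _, test = two_class_split
        kw = dict(snr_grid_db=[0.0, 10.0], replicates=3, seed=5)
        c1 = robustness_curve(two_class_models, (test.epochs, test.labels), **kw)
        c2 = robustness_curve(two_class_models, (test.epochs, test.labels), **kw)
        for name in two_class_models:
            assert np.array_equal(c1.accuracy[name], c2.accuracy[name])

    def test_empty_grid_rejected(self, two_class_models):
        with pytest.raises(ValueError):
            robustness_curve(two_class_models, (np.ones((2, 4, 10)),
                                                np.array([0, 1])), [])
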