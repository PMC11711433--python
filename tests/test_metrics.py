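"""Metric suite versus hand arithmetic, brute force and scikit-learn."""

import math

import numpy as np
import pytest
from sklearn.metrics import (cohen_kappa_score, matthews_corrcoef,
                             roc_auc_score)

from tokenmixer.metrics import (AgreementStats, ConfusionMatrix, confusion,
                                gmean, kappa, mcc, multiclass_report,
                                rate_metrics, roc_auc)


def brute_rates(tp, tn, fp, fn):
    """Independent plain-python recomputation of the five printed rates."""
    div = lambda a, b: a / b if b else 0.0
    acc = div(tp + tn, tp + tn + fp + fn)
    sens = div(tp, tp + fn)
    prec = div(tp, tp + fp)
    spec = div(tn, tn + fp)
    f1 = div(2 * prec * sens, prec + sens)
    return acc, sens, prec, spec, f1


def brute_mcc(tp, tn, fp, fn):
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / den if den else 0.0


def brute_kappa(table):
    t = np.asarray(table, float)
    n = t.sum()
    po = np.trace(t) / n
    pe = sum(t[i].sum() * t[:, i].sum() for i in range(len(t))) / n ** 2
    return po, pe, (po - pe) / (1 - pe) if pe != 1 else 0.0


def pair_counting_auc(y, s):
    """Mann-Whitney statistic with ties counted one half."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def cm_to_vectors(table):
    y_true, y_pred = [], []
    for i, row in enumerate(table):
        for j, c in enumerate(row):
            y_true.extend([i] * c)
            y_pred.extend([j] * c)
    return np.array(y_true), np.array(y_pred)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([0, 1, 2, 1], [0, 1, 2, 1], K=3)
        assert (cm.table == np.diag([1, 2, 1])).all()

    def test_binary_tally(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 0], K=2)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 2, 0)

    def test_cell_sum_conservation(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, 100)
        p = rng.integers(0, 4, 100)
        assert confusion(y, p, K=4).n == 100

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], K=2)


class TestRateMetrics:
    def test_worked_binary_example(self):
        cm = ConfusionMatrix.from_binary(tp=40, tn=45, fp=5, fn=10)
        v = rate_metrics(cm).values
        assert v["accuracy"] == pytest.approx(0.85)
        assert v["sensitivity"] == pytest.approx(0.80)
        assert v["precision"] == pytest.approx(0.8889, abs=1e-4)
        assert v["specificity"] == pytest.approx(0.90)
        assert v["f1"] == pytest.approx(0.8421, abs=1e-4)

    def test_perfect_matrix_scores_one_everywhere(self):
        v = rate_metrics(ConfusionMatrix.from_binary(30, 20, 0, 0)).values
        assert all(v[m] == 1.0 for m in v)

    def test_zero_positive_predictions_flagged(self):
        rep = rate_metrics(ConfusionMatrix.from_binary(0, 10, 0, 5))
        assert rep.values["precision"] == 0.0
        assert any("precision" in f for f in rep.flags)


class TestMccKappa:
    def test_perfect_agreement(self):
        cm = ConfusionMatrix.from_binary(25, 25, 0, 0)
        assert mcc(cm) == pytest.approx(1.0)
        assert kappa(cm).kappa == pytest.approx(1.0)

    def test_worked_example(self):
        cm = ConfusionMatrix.from_binary(tp=40, tn=45, fp=5, fn=10)
        assert mcc(cm) == pytest.approx(0.70353, abs=1e-4)
        stats = kappa(cm)
        assert stats.po == pytest.approx(0.85)
        assert stats.pe == pytest.approx(0.50)
        assert stats.kappa == pytest.approx(0.70)

    def test_single_class_predictions_give_flagged_zero(self):
        cm = ConfusionMatrix.from_binary(tp=10, tn=0, fp=10, fn=0)
        assert mcc(cm) == 0.0

    def test_chance_level_table_gives_zero_kappa(self):
        # outer product of marginals = pure chance agreement
        cm = ConfusionMatrix(np.array([[16, 24], [24, 36]]))
        assert kappa(cm).kappa == pytest.approx(0.0, abs=1e-12)


class TestGmean:
    def test_printed_formula_maximum_is_sqrt_half(self):
        g_paper, g_conv = gmean(1.0, 1.0, 1.0, 1.0)
        assert g_paper == pytest.approx(math.sqrt(0.5))
        assert g_conv == 1.0

    def test_half_rates(self):
        g_paper, _ = gmean(0.5, 0.5, 0.5, 0.5)
        assert g_paper == pytest.approx(0.5)

    def test_zero_rates_give_zero(self):
        assert gmean(0.0, 0.0, 1.0, 1.0)[0] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gmean(1.5, 0.5, 0.5, 0.5)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_anticorrelated_scores(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    def test_textbook_four_point_example(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_curve_starts_at_origin_ends_at_one_one(self):
        pts, _ = roc_auc([0, 1, 0, 1, 1], [0.3, 0.3, 0.1, 0.9, 0.5])
        assert pts[0][:2] == (0.0, 0.0)
        assert pts[-1][:2] == (1.0, 1.0)

    def test_matches_pair_counting_and_sklearn_on_random_scores(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(4, 50)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            # quantised scores force ties
            s = np.round(rng.random(n), 1)
            _, auc = roc_auc(y, s)
            assert auc == pytest.approx(pair_counting_auc(y, s), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestMulticlass:
    def test_diagonal_matrix_scores_one(self):
        rep = multiclass_report(ConfusionMatrix(np.diag([4, 5, 6])))
        assert rep.values["micro_accuracy"] == 1.0
        assert rep.values["macro_f1"] == 1.0
        assert rep.values["mcc"] == pytest.approx(1.0)

    def test_three_class_worked_example(self):
        cm = ConfusionMatrix(np.array([[2, 1, 0], [0, 3, 0], [0, 0, 4]]))
        rep = multiclass_report(cm)
        assert rep.values["micro_accuracy"] == pytest.approx(0.9)

    def test_macro_precision_is_mean_of_per_class(self):
        rng = np.random.default_rng(2)
        cm = ConfusionMatrix(rng.integers(0, 20, (4, 4)))
        rep = multiclass_report(cm)
        per = [rep.per_class[str(k)]["precision"] for k in range(4)]
        assert rep.values["macro_precision"] == pytest.approx(np.mean(per))

    def test_generalised_mcc_and_kappa_match_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            K = rng.integers(2, 6)
            cm = ConfusionMatrix(rng.integers(0, 30, (K, K)))
            if cm.n == 0 or np.trace(cm.table) == cm.n:
                continue
            y_true, y_pred = cm_to_vectors(cm.table)
            assert mcc(cm) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9)
            assert kappa(cm).kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-9)


class TestRandomSuite:
    """Brute-force agreement on a large random matrix population."""

    def test_binary_metrics_match_bruteforce_within_1e9(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 101, 4)
            cm = ConfusionMatrix.from_binary(int(tp), int(tn), int(fp), int(fn))
            if cm.n == 0:
                continue
            v = rate_metrics(cm).values
            acc, sens, prec, spec, f1 = brute_rates(tp, tn, fp, fn)
            for got, ref in zip(
                    (v["accuracy"], v["sensitivity"], v["precision"],
                     v["specificity"], v["f1"], mcc(cm), kappa(cm).kappa),
                    (acc, sens, prec, spec, f1, brute_mcc(tp, tn, fp, fn),
                     brute_kappa(cm.table)[2])):
                assert got == pytest.approx(ref, abs=1e-9)
            assert -1.0 - 1e-12 <= mcc(cm) <= 1.0 + 1e-12
            assert -1.0 - 1e-12 <= kappa(cm).kappa <= 1.0 + 1e-12
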