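"""Linear-SVM discrimination, wavenumber selection and metrics."""

import math

import numpy as np
import pytest

from mpdetect import (MP, NON_MP, ConfusionCounts, SpectraMatrix,
                      WavenumberGrid, default_grid, feature_importance,
                      gen_spectra_set, metrics_from_counts, predict,
                      reconstruct_confusion, select_wavenumbers,
                      split_train_test, train_model)
from mpdetect.svm import (DiscriminantModel, ImportanceProfile,
                          confusion_from_labels)
from mpdetect.preprocess import PreprocessSpec, snv_array, snv_spec
from mpdetect.synthetic import default_templates


class TestSplit:
    def test_paper_scale_class_sizes(self):
        """1038 MP + 1052 non-MP at 2/3 -> train (692, 701), floor policy."""
        data = gen_spectra_set(1038, 1052, 0.5, seed=1)
        train, test = split_train_test(data, 2 / 3, seed=0)
        tr = np.asarray(train.labels)
        te = np.asarray(test.labels)
        assert (tr == MP).sum() == 692 and (tr == NON_MP).sum() == 701
        assert (te == MP).sum() == 346 and (te == NON_MP).sum() == 351

    def test_partition_is_disjoint_and_complete(self, labeled_spectra):
        train, test = split_train_test(labeled_spectra, seed=5)
        assert len(train) + len(test) == len(labeled_spectra)
        stacked = np.vstack([train.X, test.X])
        assert np.array_equal(np.sort(stacked, axis=0),
                              np.sort(labeled_spectra.X, axis=0))

    def test_same_seed_identical(self, labeled_spectra):
        a = split_train_test(labeled_spectra, seed=3)
        b = split_train_test(labeled_spectra, seed=3)
        assert np.array_equal(a[0].X, b[0].X) and a[0].labels == b[0].labels

    def test_full_fraction_rejected(self, labeled_spectra):
        with pytest.raises(ValueError, match="non-empty"):
            split_train_test(labeled_spectra, train_fraction=1.0, seed=0)

    def test_tiny_class_rejected(self, grid):
        X = np.random.default_rng(0).normal(size=(3, len(grid)))
        data = SpectraMatrix(grid, X, [MP, NON_MP, NON_MP])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(data, seed=0)


def toy_separable(grid, n=20, seed=0):
    """Noise-free nylon-band vs carbonyl-band template matrix."""
    t = default_templates()
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for _ in range(n):
        rows.append(t["MP"].clean(grid.values) + rng.normal(0, 1e-6, len(grid)))
        labels.append(MP)
        rows.append(t["NONMP_TYPE1"].clean(grid.values)
                    + rng.normal(0, 1e-6, len(grid)))
        labels.append(NON_MP)
    return SpectraMatrix(grid, np.vstack(rows), labels)


class TestTrainPredict:
    def test_separable_training_ccr_100(self, grid):
        data = toy_separable(grid)
        m = train_model(data, seed=0)
        assert predict(m, data) == data.labels

    def test_single_class_rejected(self, grid):
        X = np.random.default_rng(0).normal(size=(4, len(grid)))
        with pytest.raises(ValueError, match="both MP and NON_MP"):
            train_model(SpectraMatrix(grid, X, [MP] * 4), seed=0)

    def test_heldout_ccr_full_and_reduced(self, trained_report):
        """Full-model held-out CCR is high and the reduced model is close;
        a logistic-regression oracle confirms the data are separable."""
        rep = trained_report
        assert rep.full_metrics.ccr >= 90.0
        assert abs(rep.full_metrics.ccr - rep.reduced_metrics.ccr) <= 5.0
        from sklearn.linear_model import LogisticRegression
        data = gen_spectra_set(200, 200, 0.5, seed=77)
        train, test = split_train_test(data, seed=0)
        lr = LogisticRegression(max_iter=2000).fit(
            snv_array(train.X), np.asarray(train.labels) == MP)
        acc = lr.score(snv_array(test.X), np.asarray(test.labels) == MP)
        assert acc >= 0.90

    def test_predictions_match_dot_product_oracle(self, trained_report,
                                                  labeled_spectra):
        m = trained_report.full_model
        got = predict(m, labeled_spectra)
        Z = snv_array(labeled_spectra.X)
        for i in range(0, len(labeled_spectra), 97):
            score = float(np.dot(m.weights, Z[i]) + m.bias)
            assert got[i] == (MP if score > 0 else NON_MP)

    def test_score_zero_is_nonmp(self):
        grid = WavenumberGrid(np.array([1000.0, 1100.0]))
        m = DiscriminantModel(kind="REDUCED",
                              wavenumbers_used=grid.values,
                              weights=np.array([0.0, 0.0]), bias=0.0,
                              prep=snv_spec(),
                              feature_mode="vector_snv")
        x = SpectraMatrix(grid, np.array([[1.0, 2.0]]))
        assert predict(m, x) == [NON_MP]

    def test_serialization_roundtrip_bit_identical(self, trained_report,
                                                   tmp_path):
        m = trained_report.reduced_model
        path = tmp_path / "model.json"
        m.to_json(path)
        back = DiscriminantModel.from_json(path)
        assert np.array_equal(back.weights, m.weights)
        assert back.bias == m.bias
        assert back.to_json() == m.to_json()


class TestImportanceSelection:
    def test_importance_is_absolute_weight(self):
        prof = ImportanceProfile(np.array([1.0, 2.0, 3.0]),
                                 np.abs([0.0, -3.0, 2.0]),
                                 np.array([0.0, -3.0, 2.0]))
        assert np.array_equal(prof.importance, [0.0, 3.0, 2.0])

    def test_reduced_model_has_no_profile(self, trained_report):
        with pytest.raises(ValueError, match="full"):
            feature_importance(trained_report.reduced_model)

    def test_duplicated_feature_columns_equal_importance(self):
        """Two identical discriminative columns must share importance."""
        rng = np.random.default_rng(0)
        grid = WavenumberGrid(np.array([800.0, 900.0, 1000.0, 1100.0]))
        n = 60
        col = np.r_[np.zeros(n // 2), np.ones(n // 2)] + rng.normal(0, 0.05, n)
        X = np.c_[col, col, rng.normal(size=n), np.ones(n)]
        labels = [MP] * (n // 2) + [NON_MP] * (n // 2)
        labels = labels[::-1]
        m = train_model(SpectraMatrix(grid, X, labels),
                        prep=PreprocessSpec(), seed=0)
        imp = feature_importance(m).importance
        assert imp[0] == pytest.approx(imp[1], abs=1e-6)

    def test_single_band_recovered(self, grid):
        """With one planted discriminative band, the importance argmax must
        land within +/-10 cm^-1 of its center."""
        from mpdetect.synthetic import BandModel, ClassTemplate
        import mpdetect.synthetic as syn
        t = {
            "MP": ClassTemplate("MP", (BandModel(1635.0, 8.0, 1.0),),
                                noise_sd=0.05),
            "NONMP_TYPE1": ClassTemplate("NONMP_TYPE1",
                                         (BandModel(1635.0, 8.0, 0.0001),),
                                         noise_sd=0.05),
            "NONMP_TYPE2": ClassTemplate("NONMP_TYPE2",
                                         (BandModel(1635.0, 8.0, 0.0001),),
                                         noise_sd=0.05),
        }
        data = syn.gen_spectra_set(200, 200, 0.5, seed=4, templates=t)
        m = train_model(data, seed=0)
        prof = feature_importance(m)
        argmax = prof.wavenumbers[np.argmax(prof.importance)]
        assert abs(argmax - 1635.0) <= 10.0

    def test_four_isolated_spikes_selected(self):
        wn = default_grid().values
        imp = np.zeros_like(wn)
        for c, h in [(1711.0, 4.0), (1635.0, 3.0), (1541.0, 2.0), (1077.0, 1.0)]:
            imp[np.argmin(np.abs(wn - c))] = h
        prof = ImportanceProfile(wn, imp, imp)
        assert select_wavenumbers(prof, k=4) == [1711.0, 1635.0, 1541.0, 1077.0]

    def test_k1_is_global_argmax(self):
        wn = np.array([1000.0, 1002.0, 1004.0])
        prof = ImportanceProfile(wn, np.array([0.1, 0.9, 0.4]),
                                 np.array([0.1, 0.9, 0.4]))
        assert select_wavenumbers(prof, k=1) == [1002.0]

    def test_separation_suppresses_neighbor(self):
        """Two adjacent points of one broad peak plus a distant peak:
        brute-force enumeration says one pick per peak."""
        wn = np.array([1000.0, 1002.0, 1500.0])
        imp = np.array([1.0, 0.9, 0.5])
        prof = ImportanceProfile(wn, imp, imp)
        assert select_wavenumbers(prof, k=2, min_separation=20.0) == [1000.0, 1500.0]

    def test_zero_separation_equals_topk_sort_oracle(self, rng):
        wn = default_grid().values
        imp = rng.random(wn.size)
        prof = ImportanceProfile(wn, imp, imp)
        got = select_wavenumbers(prof, k=6, min_separation=0.0)
        expected = wn[np.argsort(imp)[::-1][:6]].tolist()
        assert got == expected

    def test_infeasible_separation_errors(self):
        wn = np.array([1000.0, 1002.0])
        prof = ImportanceProfile(wn, np.array([1.0, 0.5]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="only 1"):
            select_wavenumbers(prof, k=2, min_separation=50.0)


def textbook_metrics(tp, fn, fp, tn):
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ccr = 100.0 * (tp + tn) / (tp + fn + fp + tn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return sens, spec, ccr, mcc


class TestMetrics:
    def test_reduced_model_published_counts(self):
        m = metrics_from_counts(ConfusionCounts(tp=319, fn=34, fp=28, tn=334))
        r = m.rounded()
        assert r["ccr_pct"] == 91.33
        assert r["mcc"] == 0.8266
        assert r["sensitivity"] == 0.9037
        assert r["specificity"] == 0.9227

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=10, fn=0, fp=0, tn=10))
        assert m.ccr == 100.0 and m.mcc == 1.0

    def test_empty_positive_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            metrics_from_counts(ConfusionCounts(tp=0, fn=0, fp=5, tn=5))

    def test_undefined_mcc_flagged(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fn=5, fp=0, tn=5))
        assert m.mcc is None

    def test_1000_random_matrices_match_textbook(self, rng):
        for _ in range(1000):
            tp, fn, fp, tn = rng.integers(0, 500, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = metrics_from_counts(ConfusionCounts(int(tp), int(fn),
                                                    int(fp), int(tn)))
            sens, spec, ccr, mcc = textbook_metrics(tp, fn, fp, tn)
            assert m.sensitivity == pytest.approx(sens, abs=1e-12)
            assert m.specificity == pytest.approx(spec, abs=1e-12)
            assert m.ccr == pytest.approx(ccr, abs=1e-12)
            if mcc is None:
                assert m.mcc is None
            else:
                assert m.mcc == pytest.approx(mcc, abs=1e-12)
                assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12

    def test_mcc_label_swap_invariance(self, rng):
        for _ in range(100):
            tp, fn, fp, tn = (int(v) for v in rng.integers(1, 300, size=4))
            a = metrics_from_counts(ConfusionCounts(tp, fn, fp, tn)).mcc
            b = metrics_from_counts(ConfusionCounts(tn, fp, fn, tp)).mcc
            assert a == pytest.approx(b, abs=1e-12)

    def test_confusion_from_labels(self):
        truth = [MP, MP, NON_MP, NON_MP, MP]
        pred = [MP, NON_MP, NON_MP, MP, MP]
        c = confusion_from_labels(truth, pred)
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 1)


class TestReconstructConfusion:
    def test_reduced_model_unique(self):
        c = reconstruct_confusion(fn=34, fp=28, sensitivity=0.9037,
                                  specificity=0.9227)
        assert (c.tp, c.fn, c.fp, c.tn) == (319, 34, 28, 334)

    def test_full_model_needs_ccr_tiebreak(self):
        with pytest.raises(ValueError, match="ambiguous"):
            reconstruct_confusion(fn=8, fp=97, sensitivity=0.9773,
                                  specificity=0.7320)
        c = reconstruct_confusion(fn=8, fp=97, sensitivity=0.9773,
                                  specificity=0.7320, ccr=85.31)
        assert (c.tp, c.fn, c.fp, c.tn) == (345, 8, 97, 265)

    def test_perfect_sensitivity_is_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous|unconstrained"):
            reconstruct_confusion(fn=0, fp=10, sensitivity=1.0,
                                  specificity=0.9)

    def test_bruteforce_enumeration_oracle(self):
        """Independent enumeration over P, N in [300, 400] must find the
        same unique matrix for the printed reduced-model figures."""
        found = [
            (P - 34, 34, 28, N - 28)
            for P in range(300, 401) for N in range(300, 401)
            if round((P - 34) / P, 4) == 0.9037
            and round((N - 28) / N, 4) == 0.9227
        ]
        assert found == [(319, 34, 28, 334)]
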