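"""Metric implementations against brute-force and scikit-learn oracles, the
recurrence strata, and the evaluation harnesses."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef
from sklearn.metrics import confusion_matrix as sk_confusion

import oracles
from wescnv.evaluate import (DegenerateMetricError, LocusPriorBaseline,
                             agreement_metrics, assign_stratum, confusion_matrix3,
                             locus_frequency, metric_report, one_vs_rest_metrics,
                             probability_metrics, stratified_recall)
from wescnv.train import EncodedDataset
from conftest import make_window


def random_labels(rng, n=200):
    return rng.integers(3, size=n), rng.integers(3, size=n)


class TestConfusionMatrix:
    def test_del_predicted_as_dup_convention(self):
        """A DEL called DUP lands at (1,2): one FN for DEL, one FP for DUP."""
        cm = confusion_matrix3([1], [2])
        assert cm[1, 2] == 1 and cm.sum() == 1
        m = one_vs_rest_metrics(cm + np.eye(3, dtype=int) * 5)
        # the miscall reduces DEL recall and DUP precision symmetrically
        assert m["per_class"][1]["recall"] == pytest.approx(5 / 6)
        assert m["per_class"][2]["precision"] == pytest.approx(5 / 6)

    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 1, 0])
        assert np.trace(confusion_matrix3(y, y)) == 5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        y, p = random_labels(rng)
        np.testing.assert_array_equal(confusion_matrix3(y, p),
                                      oracles.confusion_by_pair_counting(y, p))
        np.testing.assert_array_equal(confusion_matrix3(y, p),
                                      sk_confusion(y, p, labels=[0, 1, 2]))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix3([0, 3], [0, 0])


class TestOneVsRestMetrics:
    def test_diagonal_is_perfect(self):
        m = one_vs_rest_metrics(np.diag([5, 3, 2]))
        assert m["accuracy"] == 1.0
        assert all(pc["f1"] == 1.0 for pc in m["per_class"])

    def test_hand_arithmetic_example(self):
        m = one_vs_rest_metrics(np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]]))
        for pc in m["per_class"]:
            assert pc["precision"] == pytest.approx(0.8)
            assert pc["recall"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_macro_is_unweighted_mean(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 20, size=(3, 3))
        m = one_vs_rest_metrics(cm)
        assert m["macro_f1"] == pytest.approx(
            np.mean([pc["f1"] for pc in m["per_class"]]))

    def test_empty_class_zero_with_flag(self):
        cm = np.array([[5, 0, 0], [0, 4, 0], [0, 0, 0]])
        m = one_vs_rest_metrics(cm)
        assert m["per_class"][2]["recall"] == 0.0
        assert 2 in m["degenerate"]

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(2)
        y, p = random_labels(rng)
        cm = confusion_matrix3(y, p)
        for c in range(3):
            assert cm[c].sum() == (y == c).sum()       # TP + FN
            assert cm[:, c].sum() == (p == c).sum()    # TP + FP

    def test_all_zero_matrix_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            one_vs_rest_metrics(np.zeros((3, 3), dtype=int))

    def test_agrees_with_definition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            cm = rng.integers(0, 15, size=(3, 3))
            if cm.sum() == 0:
                continue
            m = one_vs_rest_metrics(cm)
            ref = oracles.ovr_metrics_by_definition(cm)
            for pc, (prec, rec, f1, spec) in zip(m["per_class"], ref):
                assert pc["precision"] == pytest.approx(prec, abs=1e-12)
                assert pc["recall"] == pytest.approx(rec, abs=1e-12)
                assert pc["f1"] == pytest.approx(f1, abs=1e-12)
                assert pc["specificity"] == pytest.approx(spec, abs=1e-12)


class TestProbabilityMetrics:
    def test_perfect_probabilities(self):
        y = np.array([0, 1, 2, 0])
        p = np.eye(3)[y]
        m = probability_metrics(y, p)
        assert m["log_loss"] == pytest.approx(0.0, abs=1e-9)
        assert m["roc_auc_macro"] == 1.0
        assert m["mean_pr_auc"] == 1.0

    def test_uniform_probabilities_log_loss(self):
        y = np.array([0, 1, 2])
        p = np.full((3, 3), 1 / 3)
        assert probability_metrics(y, p)["log_loss"] == pytest.approx(np.log(3))

    def test_aucs_match_threshold_sweep_oracles(self):
        rng = np.random.default_rng(4)
        y = rng.integers(3, size=50)
        p = rng.dirichlet(np.ones(3), size=50)
        m = probability_metrics(y, p)
        for c in range(3):
            y_bin = (y == c).astype(int)
            assert m["pr_auc_per_class"][c] == pytest.approx(
                oracles.average_precision_by_threshold_sweep(y_bin, p[:, c]),
                abs=1e-9)
        roc_ref = np.mean([
            oracles.roc_auc_by_pair_counting((y == c).astype(int), p[:, c])
            for c in range(3)
        ])
        assert m["roc_auc_macro"] == pytest.approx(roc_ref, abs=1e-9)
        assert m["log_loss"] == pytest.approx(
            oracles.log_loss_by_definition(y, p), abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            probability_metrics([0], np.array([[0.5, 0.1, 0.1]]))


class TestAgreementMetrics:
    def test_diagonal_gives_unity(self):
        k, m = agreement_metrics(np.diag([4, 4, 4]))
        assert k == pytest.approx(1.0) and m == pytest.approx(1.0)

    def test_independence_gives_chance_kappa(self):
        # expected matrix under independent truth/prediction marginals
        cm = np.outer([30, 20, 10], [25, 20, 15])
        k, _ = agreement_metrics(cm)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_and_definition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y, p = random_labels(rng, 60)
            cm = confusion_matrix3(y, p)
            kappa, mcc = agreement_metrics(cm)
            assert kappa == pytest.approx(cohen_kappa_score(y, p), abs=1e-9)
            assert mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-9)
            assert kappa == pytest.approx(oracles.kappa_by_definition(cm), abs=1e-9)
            assert mcc == pytest.approx(oracles.mcc_by_definition(cm), abs=1e-9)

    def test_single_class_degenerate(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[0, 0] = 10
        with pytest.raises(DegenerateMetricError):
            agreement_metrics(cm)


class TestLocusFrequency:
    def _windows(self, labels_by_sample):
        out = []
        for sid, lab in labels_by_sample.items():
            out.append(make_window(start=100, end=300, chrom="chr1", label=lab,
                                   sample_id=sid))
        return out

    def test_never_locus(self):
        ws = self._windows({f"S{i}": 0 for i in range(5)})
        assert locus_frequency(ws)[("chr1", 100, 300)] == 0.0

    def test_majority_locus(self):
        ws = self._windows({"A": 1, "B": 1, "C": 2, "D": 0, "E": 0})
        assert locus_frequency(ws)[("chr1", 100, 300)] == pytest.approx(0.6)

    def test_rare_single_carrier(self):
        ws = self._windows({f"S{i}": (1 if i == 0 else 0) for i in range(300)})
        f = locus_frequency(ws)[("chr1", 100, 300)]
        assert f == pytest.approx(1 / 300)
        assert assign_stratum(f) == "Rare"


class TestStrata:
    @pytest.mark.parametrize("freq,stratum", [
        (0.0, "Never"), (0.0033, "Rare"), (0.05, "Rare"), (0.0501, "Often"),
        (0.5, "Often"), (0.501, "Majority"), (1.0, "Majority"),
    ])
    def test_boundary_assignment(self, freq, stratum):
        assert assign_stratum(freq) == stratum

    def test_perfect_predictions_full_recall(self):
        ws = [make_window(start=s, end=s + 100, label=l, sample_id="T")
              for s, l in [(100, 1), (300, 2), (500, 0)]]
        freq = {("chr1", 100, 200): 0.8, ("chr1", 300, 400): 0.0}
        table = stratified_recall(ws, np.array([1, 2, 0]), freq)
        pop = table[table["n_windows"] > 0]
        assert (pop["cnv_recall"] == 1.0).all()

    def test_partition_counts(self):
        rng = np.random.default_rng(6)
        ws = []
        freq = {}
        for i in range(40):
            lab = int(rng.integers(3))
            ws.append(make_window(start=1000 + i, end=2000 + i, label=lab,
                                  sample_id="T"))
            freq[("chr1", 1000 + i, 2000 + i)] = float(rng.choice([0, 0.02, 0.3, 0.9]))
        pred = rng.integers(3, size=40)
        table = stratified_recall(ws, pred, freq)
        n_cnv = sum(1 for w in ws if w.label > 0)
        assert table["n_windows"].sum() == n_cnv

    def test_unseen_locus_counts_as_never(self):
        ws = [make_window(start=100, end=200, label=1, sample_id="T")]
        table = stratified_recall(ws, np.array([1]), {})
        assert table.set_index("stratum").loc["Never", "n_windows"] == 1

    def test_any_cnv_recall_forgives_cross_calls(self):
        ws = [make_window(start=100, end=200, label=1, sample_id="T")]
        table = stratified_recall(ws, np.array([2]), {})
        never = table.set_index("stratum").loc["Never"]
        assert never["cnv_recall"] == 0.0
        assert never["any_cnv_recall"] == 1.0


class TestLocusPriorBaseline:
    def test_features_exclude_depth_by_construction(self):
        rng = np.random.default_rng(7)
        ds = EncodedDataset(rng.random((5, 1002, 3)).astype(np.float32),
                            np.eye(24, dtype=np.float32)[:5],
                            rng.integers(3, size=5))
        x = LocusPriorBaseline.features(ds)
        assert x.shape == (5, 26)
        # perturbing depth tokens leaves the features unchanged
        ds2 = EncodedDataset(ds.channels.copy(), ds.chrom, ds.y)
        ds2.channels[:, :, 0] += 100
        np.testing.assert_array_equal(x, LocusPriorBaseline.features(ds2))


class TestMetricReport:
    def test_report_serialization(self, tmp_path):
        rng = np.random.default_rng(8)
        y, p = random_labels(rng, 100)
        rep = metric_report(y, p)
        rep.to_json(tmp_path / "rep.json")
        import json

        d = json.loads((tmp_path / "rep.json").read_text())
        assert d["accuracy"] == pytest.approx(rep.accuracy)
        assert np.asarray(d["confusion"]).sum() == 100
        assert -1 <= d["mcc"] <= 1 and -1 <= d["kappa"] <= 1

    def test_per_class_table_shape(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = metric_report(y, y)
        df = rep.per_class_table()
        assert list(df.index) == ["NO-CALL", "DEL", "DUP"]
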