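"""Confusion metrics, accuracy, Pearson, and the defection correlation."""

import numpy as np
import pytest

from taxonovel.classifier import ScoredRead
from taxonovel.errors import InputError, UndefinedMetricError
from taxonovel.evaluation import (
    ConfusionCounts,
    EvalReport,
    TaxonAbundanceRecord,
    assignment_accuracy,
    confusion,
    defection_correlation,
    metrics,
    pearson,
    read_abundance_tsv,
)
from taxonovel.readsim import KNOWN, NOVEL


def brute_force_counts(calls, labels):
    tp = sum(1 for r in labels if labels[r] == KNOWN and calls[r] == KNOWN)
    fn = sum(1 for r in labels if labels[r] == KNOWN and calls[r] == NOVEL)
    tn = sum(1 for r in labels if labels[r] == NOVEL and calls[r] == NOVEL)
    fp = sum(1 for r in labels if labels[r] == NOVEL and calls[r] == KNOWN)
    return tp, fn, tn, fp


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        labels = {"a": KNOWN, "b": NOVEL, "c": KNOWN}
        c = confusion(labels, labels)
        assert (c.fn, c.fp) == (0, 0) and (c.tp, c.tn) == (2, 1)

    def test_all_called_novel(self):
        labels = {"a": KNOWN, "b": NOVEL}
        calls = {k: NOVEL for k in labels}
        c = confusion(calls, labels)
        assert c.tp == 0 and c.fp == 0 and c.fn == 1 and c.tn == 1

    def test_hand_built_table(self):
        labels = {f"r{i}": lab for i, lab in enumerate(
            [KNOWN, KNOWN, KNOWN, NOVEL, NOVEL, NOVEL])}
        calls = {f"r{i}": lab for i, lab in enumerate(
            [KNOWN, NOVEL, KNOWN, NOVEL, KNOWN, NOVEL])}
        c = confusion(calls, labels)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 1, 2, 1)
        assert (c.tp, c.fn, c.tn, c.fp) == brute_force_counts(calls, labels)

    def test_key_mismatch_is_input_error(self):
        with pytest.raises(InputError):
            confusion({"a": KNOWN}, {"b": KNOWN})

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            labels = {f"r{i}": KNOWN if rng.random() < 0.5 else NOVEL for i in range(n)}
            calls = {f"r{i}": KNOWN if rng.random() < 0.5 else NOVEL for i in range(n)}
            c = confusion(calls, labels)
            assert (c.tp, c.fn, c.tn, c.fp) == brute_force_counts(calls, labels)


class TestMetrics:
    def test_reported_operating_point_scaled_to_counts(self):
        sens, spec, f = metrics(ConfusionCounts(tp=642, fn=358, tn=929, fp=71))
        assert sens == pytest.approx(0.642)
        assert spec == pytest.approx(0.929)
        assert f == pytest.approx(0.759, abs=5e-4)

    def test_perfect_detector(self):
        assert metrics(ConfusionCounts(10, 0, 10, 0)) == (1.0, 1.0, 1.0)

    def test_empty_class_raises_undefined_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))

    def test_random_calls_on_balanced_labels_approach_call_rate(self, rng):
        n = 20_000
        call_rate = 0.3
        labels = {f"r{i}": KNOWN if i % 2 == 0 else NOVEL for i in range(n)}
        calls = {f"r{i}": KNOWN if rng.random() < call_rate else NOVEL for i in range(n)}
        sens, spec, _ = metrics(confusion(calls, labels))
        assert sens == pytest.approx(call_rate, abs=0.02)
        assert spec == pytest.approx(1 - call_rate, abs=0.02)


class TestEvalReport:
    def test_undefined_metrics_reported_as_absent(self):
        labels = {"a": KNOWN, "b": KNOWN}
        calls = {"a": KNOWN, "b": NOVEL}
        rep = EvalReport.build("genus", 500, "bootstrap", calls, labels)
        assert rep.sensitivity == 0.5
        assert rep.specificity is None and rep.f_measure is None

    def test_search_space_reduction_identity(self):
        # known fraction 0.85, sensitivity 0.5 -> novel pool 1 - 0.85*0.5
        labels = {f"k{i}": KNOWN for i in range(1700)}
        labels.update({f"n{i}": NOVEL for i in range(300)})
        calls = {f"k{i}": KNOWN if i < 850 else NOVEL for i in range(1700)}
        calls.update({f"n{i}": NOVEL for i in range(300)})
        rep = EvalReport.build("genus", 100, "bootstrap", calls, labels)
        assert rep.known_fraction() == 0.85
        assert rep.sensitivity == 0.5
        assert rep.novel_pool_fraction() == 1 - 0.85 * 0.5

    def test_roundtrip_dict_fields(self):
        labels = {"a": KNOWN, "b": NOVEL}
        rep = EvalReport.build("genus", 250, "likelihood", {"a": KNOWN, "b": NOVEL}, labels,
                               auc=0.9, threshold=-3.2)
        d = rep.to_dict()
        assert d["tp"] == 1 and d["tn"] == 1 and d["auc"] == 0.9


class TestAssignmentAccuracy:
    @staticmethod
    def sr(rid, path):
        return ScoredRead(rid, 0, {}, tuple(path), -1.0, -1.0)

    def test_manual_fraction(self):
        truth = {f"r{i}": ("K", "P", "C", "O", "F", "G1") for i in range(5)}
        scored = [self.sr(f"r{i}", ("K", "P", "C", "O", "F", "G1" if i < 3 else "G2"))
                  for i in range(5)]
        assert assignment_accuracy(scored, truth, "genus") == pytest.approx(3 / 5)
        # at family level all 5 agree
        assert assignment_accuracy(scored, truth, "family") == 1.0

    def test_restricted_to_training_taxa(self):
        truth = {"a": ("K", "P", "C", "O", "F", "G1"),
                 "b": ("K", "P", "C", "O", "F", "G2")}
        scored = [self.sr("a", truth["a"]), self.sr("b", truth["a"])]
        paths = {("K", "P", "C", "O", "F", "G1")}  # only G1 trainable
        assert assignment_accuracy(scored, truth, "genus", paths) == 1.0

    def test_empty_eligible_set_is_undefined(self):
        truth = {"a": ("K", "P", "C", "O", "F", "G1")}
        scored = [self.sr("a", truth["a"])]
        with pytest.raises(UndefinedMetricError):
            assignment_accuracy(scored, truth, "genus", training_paths=set())


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        # textbook formula: r = cov(x,y) / (sd_x * sd_y)
        xm, ym = np.mean(x), np.mean(y)
        num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
        den = np.sqrt(sum((a - xm) ** 2 for a in x) * sum((b - ym) ** 2 for b in y))
        assert pearson(x, y) == pytest.approx(num / den)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_is_error(self):
        with pytest.raises(InputError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestDefectionCorrelation:
    def test_perfect_linearity(self):
        # construct records where predicted fraction equals observed decrease
        records = []
        for i, frac in enumerate((0.1, 0.3, 0.5, 0.7, 0.9)):
            n_half = 1000
            n_passed = int(n_half * (1 - frac))
            n_full = int(n_half * (1 - frac))
            records.append(TaxonAbundanceRecord(f"T{i}", "genus", n_half, n_passed, n_full))
        r, n = defection_correlation(records)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_printed_abundance_row_arithmetic(self):
        # a heavily novel taxon: 757 assigned, 7 pass, 646 retained under full DB
        rec = TaxonAbundanceRecord("Conexibacter", "genus", 757, 7, 646)
        x = 1 - rec.n_passed / rec.n_half
        y = (rec.n_half - rec.n_full) / rec.n_half
        assert x == pytest.approx(0.991, abs=5e-4)
        assert y == pytest.approx(0.147, abs=5e-4)

    def test_invariant_to_uniform_count_rescaling(self):
        base = [TaxonAbundanceRecord(f"T{i}", "genus", h, p, f)
                for i, (h, p, f) in enumerate(
                    [(100, 10, 60), (200, 150, 190), (400, 40, 250), (80, 70, 79)])]
        scaled = [TaxonAbundanceRecord(r.taxon_id, r.rank, r.n_half * 3,
                                       r.n_passed * 3, r.n_full * 3) for r in base]
        assert defection_correlation(base)[0] == pytest.approx(defection_correlation(scaled)[0])

    def test_min_abundance_filters_records(self):
        records = [TaxonAbundanceRecord(f"T{i}", "genus", h, h // 2, h // 2)
                   for i, h in enumerate([10, 20, 60, 70, 80])]
        with pytest.raises(InputError):
            defection_correlation(records, min_abundance=65)

    def test_invalid_passed_count_rejected(self):
        with pytest.raises(InputError):
            TaxonAbundanceRecord("T", "genus", 10, 11, 5)

    def test_abundance_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("taxon_id\trank\tn_half\tn_passed\tn_full\n"
                     "T1\tgenus\t100\t10\t60\n")
        recs = read_abundance_tsv(p)
        assert recs == [TaxonAbundanceRecord("T1", "genus", 100, 10, 60)]
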