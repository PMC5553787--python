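"""Pair-level validation: confusion counts, metrics, kappa, consensus."""

import numpy as np
import pytest

from stentminer import ProcedureRecord, ReportDocument, parse_report
from stentminer.evaluation import (
    AgreementResult,
    ConfusionCounts,
    PairSet,
    as_pair_sets,
    cohen_kappa,
    confusion_counts,
    consensus_merge,
    metrics,
    pair_universe,
    pooled_confusion,
    to_pair_set,
)

UNIVERSE = pair_universe("category")  # 4 vessels x 4 class labels = 16 slots


def _ps(rid, pairs):
    return PairSet(rid, frozenset(pairs), UNIVERSE)


class TestPairSets:
    def test_universe_size(self):
        assert len(UNIVERSE) == 16

    def test_duplicates_collapse_at_category_granularity(self, lexicon):
        doc = ReportDocument(
            "r", "p", "2011-01-01", "LAD:\n Xience 3.0/28mm and Xience 2.5/18mm"
        )
        ps = to_pair_set(parse_report(doc, lexicon))
        assert ps.pairs == {("LAD", "DES2-DP")}

    def test_empty_record_gives_empty_pair_set(self):
        ps = to_pair_set(ProcedureRecord(report_id="r"))
        assert ps.pairs == frozenset()

    def test_pairs_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            PairSet("r", frozenset({("LAD", "nonsense")}), UNIVERSE)


class TestConfusionCounts:
    def test_identity(self):
        c = confusion_counts(_ps("r", {("LAD", "DES2-DP")}), _ps("r", {("LAD", "DES2-DP")}))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 15)

    def test_label_swap_counts_fp_and_fn(self):
        c = confusion_counts(_ps("r", {("LAD", "DES2-DP")}), _ps("r", {("LAD", "DES2-BP")}))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 1, 14)

    def test_universe_mismatch_is_an_error(self):
        other = PairSet("r", frozenset(), pair_universe("brand"))
        with pytest.raises(ValueError):
            confusion_counts(_ps("r", set()), other)

    def test_pooled_total_is_universe_times_reports(self):
        pred = {"a": _ps("a", {("LAD", "DES1")}), "b": _ps("b", set())}
        gold = {"a": _ps("a", set()), "b": _ps("b", {("RCA", "BMS")})}
        counts = pooled_confusion(pred, gold)
        assert counts.total == 16 * 2
        assert (counts.fp, counts.fn) == (1, 1)


class TestMetrics:
    def test_identity_gives_all_ones(self):
        c = confusion_counts(_ps("r", {("LAD", "DES1")}), _ps("r", {("LAD", "DES1")}))
        m = metrics(c)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.f_measure) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_computed_example(self):
        m = metrics(ConfusionCounts(tp=99, fn=1, tn=900, fp=0))
        assert m.sensitivity == pytest.approx(0.99)
        assert m.specificity == 1.0
        assert m.f_measure == pytest.approx(2 * 1.0 * 0.99 / 1.99)

    def test_degenerate_counts_flag_undefined(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity == 1.0
        all_zero = metrics(ConfusionCounts())
        assert all(
            getattr(all_zero, f) is None
            for f in ("sensitivity", "specificity", "ppv", "npv", "f_measure")
        )

    def test_f_measure_is_harmonic_mean_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            m = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            assert m.f_measure == pytest.approx(
                2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity)
            )


class TestCohenKappa:
    def test_self_agreement_is_one(self):
        coll = {"a": _ps("a", {("LAD", "DES1")}), "b": _ps("b", {("RCA", "BMS")})}
        assert cohen_kappa(coll, coll) == pytest.approx(1.0)

    def test_symmetry(self):
        a = {"r": _ps("r", {("LAD", "DES1"), ("RCA", "BMS")})}
        b = {"r": _ps("r", {("LAD", "DES1"), ("LCx", "DES2-DP")})}
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))

    def test_hand_computed_kappa(self):
        """Observed agreement 0.9 with both marginals at 0.5 gives
        kappa = (0.9 - 0.5)/(1 - 0.5) = 0.8 exactly.

        Construction over 5 reports x 16 slots = 80 slots: each rater asserts
        40; they disagree on 8 slots, 4 in each direction (so both marginals
        stay 0.5 and p_o = 72/80 = 0.9).
        """
        universe = sorted(UNIVERSE)
        a, b = {}, {}
        for i in range(5):
            rid = f"r{i}"
            pa = set(universe[:8])  # first 8 of the 16 slots
            pb = set(universe[:8])
            if i == 0:
                # swap 4 slots out of A and 4 different slots into B
                pa -= set(universe[4:8])
                pa |= set(universe[8:12])
                # B keeps the original 8: disagreement on slots 4..11
            a[rid] = PairSet(rid, frozenset(pa), UNIVERSE)
            b[rid] = PairSet(rid, frozenset(pb), UNIVERSE)
        assert cohen_kappa(a, b) == pytest.approx(0.8)

    def test_independent_ratings_give_near_zero_kappa(self):
        rng = np.random.default_rng(1)
        universe = sorted(UNIVERSE)
        a, b = {}, {}
        for i in range(400):
            rid = f"r{i}"
            a[rid] = PairSet(rid, frozenset(p for p in universe if rng.random() < 0.3), UNIVERSE)
            b[rid] = PairSet(rid, frozenset(p for p in universe if rng.random() < 0.3), UNIVERSE)
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        universe = sorted(UNIVERSE)
        a, b = {}, {}
        for i in range(50):
            rid = f"r{i}"
            pa = frozenset(p for p in universe if rng.random() < 0.4)
            pb = frozenset(
                p for p in universe
                if (p in pa) != (rng.random() < 0.15)  # correlated raters
            )
            a[rid] = PairSet(rid, pa, UNIVERSE)
            b[rid] = PairSet(rid, pb, UNIVERSE)
        av = [p in a[f"r{i}"].pairs for i in range(50) for p in universe]
        bv = [p in b[f"r{i}"].pairs for i in range(50) for p in universe]
        expected = sklearn_metrics.cohen_kappa_score(av, bv)
        assert cohen_kappa(a, b) == pytest.approx(expected)

    def test_constant_raters_are_undefined(self):
        empty = {"r": _ps("r", set())}
        assert cohen_kappa(empty, empty) is None


class TestConsensus:
    def test_identical_inputs_accept_everything(self):
        coll = {"a": _ps("a", {("LAD", "DES1")}), "b": _ps("b", set())}
        out = consensus_merge(coll, coll, coll)
        assert out.accepted["a"] == {("LAD", "DES1")}
        assert out.disputed == []

    def test_two_of_three_is_disputed_not_accepted(self):
        present = {"a": _ps("a", {("LAD", "DES1")})}
        absent = {"a": _ps("a", set())}
        out = consensus_merge(present, present, absent)
        assert out.accepted["a"] == frozenset()
        assert len(out.disputed) == 1

    def test_permutation_invariance(self):
        x = {"a": _ps("a", {("LAD", "DES1")}), "b": _ps("b", {("RCA", "BMS")})}
        y = {"a": _ps("a", {("LAD", "DES1"), ("LM", "DES2-DP")}), "b": _ps("b", set())}
        z = {"a": _ps("a", set()), "b": _ps("b", {("RCA", "BMS")})}
        base = consensus_merge(x, y, z)
        for perm in ((x, z, y), (y, x, z), (z, y, x), (y, z, x), (z, x, y)):
            out = consensus_merge(*perm)
            assert out.accepted == base.accepted
            assert out.disputed == base.disputed

    def test_adjudication_roundtrip(self):
        present = {"a": _ps("a", {("LAD", "DES1"), ("RCA", "BMS")})}
        partial = {"a": _ps("a", {("LAD", "DES1")})}
        out = consensus_merge(present, present, partial)
        queue = out.disputed_frame()
        assert list(queue.columns[:4]) == ["report_id", "vessel", "stent_label", "verdict"]
        queue["verdict"] = "present"
        final = out.resolve(queue)
        assert final["a"] == {("LAD", "DES1"), ("RCA", "BMS")}
        queue["verdict"] = "absent"
        assert out.resolve(queue)["a"] == {("LAD", "DES1")}

    def test_unknown_adjudication_item_is_an_error(self):
        coll = {"a": _ps("a", {("LAD", "DES1")})}
        out = consensus_merge(coll, coll, coll)
        bogus = out.disputed_frame()
        bogus.loc[0] = ["zzz", "LAD", "DES1", "present", "", ""]
        with pytest.raises(ValueError):
            out.resolve(bogus)

    def test_as_pair_sets_wraps_plain_mappings(self):
        colls = as_pair_sets({"a": {("LAD", "DES1")}})
        assert colls["a"].universe == UNIVERSE


def test_agreement_result_is_plain_data():
    r = AgreementResult(1.0, 1.0, 1.0, 1.0, 1.0, kappa=None)
    assert r.sensitivity == 1.0
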