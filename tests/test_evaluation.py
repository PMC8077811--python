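"""Token confusion, micro-averaged P/R/F, and slot error rate."""

from itertools import permutations

import pytest
from hypothesis import given, settings, strategies as st

from medextract.evaluation import (
    ConfusionCounts,
    Slot,
    aggregate_ser,
    extract_and_align_slots,
    iob_to_slots,
    micro_prf,
    token_confusion,
)
from medextract.labels import LABELS
from medextract.text_model import AlignmentError


def tags(seq: str) -> list[str]:
    """Compact tag notation: 'O B-dosage I-dosage' -> list."""
    return seq.split()


class TestTokenConfusion:
    def test_correct_token_is_tp(self):
        c = token_confusion(["B-dosage"], ["B-dosage"])
        assert c.tp["dosage"] == 1

    def test_wrong_class_is_fp_and_fn(self):
        c = token_confusion(["B-dosage"], ["B-route"])
        assert c.fp["route"] == 1 and c.fn["dosage"] == 1

    def test_prefix_mismatch_same_class_still_tp(self):
        c = token_confusion(["B-dosage"], ["I-dosage"])
        assert c.tp["dosage"] == 1 and c.fp["dosage"] == 0

    def test_missed_token_is_fn_only(self):
        c = token_confusion(["B-duration"], ["O"])
        assert c.fn["duration"] == 1 and sum(c.fp.values()) == 0

    def test_spurious_token_is_fp_only(self):
        c = token_confusion(["O"], ["B-duration"])
        assert c.fp["duration"] == 1 and sum(c.fn.values()) == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            token_confusion(["O"], ["O", "O"])

    @given(
        pair=st.lists(
            st.tuples(
                st.sampled_from(["O", "B-dosage", "I-dosage", "B-route", "I-frequency"]),
                st.sampled_from(["O", "B-dosage", "I-dosage", "B-route", "I-frequency"]),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_per_token_tally_oracle(self, pair):
        gold = [g for g, _ in pair]
        pred = [p for _, p in pair]
        c = token_confusion(gold, pred)

        def cls(t):
            return None if t == "O" else t[2:]

        for label in LABELS:
            tp = sum(1 for g, p in pair if cls(g) == label and cls(p) == label)
            fp = sum(1 for g, p in pair if cls(p) == label and cls(g) != label)
            fn = sum(1 for g, p in pair if cls(g) == label and cls(p) != label)
            assert (c.tp[label], c.fp[label], c.fn[label]) == (tp, fp, fn)
        # token identity: every gold entity token is either TP or FN
        n_gold = sum(1 for g, _ in pair if g != "O")
        assert sum(c.tp.values()) + sum(c.fn.values()) == n_gold


class TestMicroPRF:
    def test_simple_percentages(self):
        c = ConfusionCounts()
        c.tp["dosage"], c.fp["dosage"], c.fn["dosage"] = 9, 1, 1
        rep = micro_prf(c)
        assert rep.overall.precision == pytest.approx(90.0)
        assert rep.overall.recall == pytest.approx(90.0)
        assert rep.overall.f_measure == pytest.approx(90.0)

    def test_no_predictions_is_degenerate_zero(self):
        c = ConfusionCounts()
        c.fn["dosage"] = 3
        rep = micro_prf(c)
        assert rep.overall.precision == 0.0
        assert rep.overall.f_measure == 0.0
        assert rep.overall.degenerate

    def test_f_between_p_and_r(self):
        c = ConfusionCounts()
        c.tp["dosage"], c.fp["dosage"], c.fn["dosage"] = 8, 4, 1
        rep = micro_prf(c)
        lo, hi = sorted([rep.overall.precision, rep.overall.recall])
        assert lo <= rep.overall.f_measure <= hi


class TestSlots:
    def test_slot_extraction(self):
        slots = iob_to_slots(tags("B-dosage I-dosage O B-route"))
        assert slots == [Slot(0, 2, "dosage"), Slot(3, 4, "route")]

    def test_identical_sequences_have_zero_ser(self):
        seq = tags("B-dosage I-dosage O B-route")
        rep = extract_and_align_slots(seq, seq)
        assert rep.ser == 0.0
        assert (rep.deletions, rep.insertions, rep.type_errors, rep.frontier_errors) == (0, 0, 0, 0)

    def test_worked_example_ser_030(self):
        """10 gold slots; one missed, one spurious, one mislabeled at equal
        boundaries, one clipped by a token: SER = (1 + 1 + 0.5 + 0.5)/10."""
        gold, pred = [], []
        for k in range(10):
            gold += ["B-dosage", "I-dosage", "O"]
            if k == 0:
                pred += ["O", "O", "O"]               # deletion
            elif k == 1:
                pred += ["B-route", "I-route", "O"]   # type error
            elif k == 2:
                pred += ["B-dosage", "O", "O"]        # frontier error
            elif k == 3:
                pred += ["B-dosage", "I-dosage", "B-frequency"]  # + insertion
            else:
                pred += ["B-dosage", "I-dosage", "O"]
        rep = extract_and_align_slots(gold, pred)
        assert rep.reference_slots == 10
        assert (rep.deletions, rep.insertions) == (1, 1)
        assert (rep.type_errors, rep.frontier_errors) == (1, 1)
        assert rep.ser == pytest.approx(0.30)

    def test_both_wrong_counts_type_plus_frontier(self):
        rep = extract_and_align_slots(
            tags("B-dosage I-dosage I-dosage"), tags("O B-route I-route")
        )
        assert (rep.type_errors, rep.frontier_errors) == (1, 1)
        assert rep.ser == pytest.approx(1.0)

    def test_ser_decomposition_identity(self):
        gold = tags("B-dosage O B-route I-route O B-frequency")
        pred = tags("B-dosage B-duration O I-route O B-condition")
        rep = extract_and_align_slots(gold, pred)
        lhs = rep.ser * rep.reference_slots
        rhs = rep.deletions + rep.insertions + 0.5 * (rep.type_errors + rep.frontier_errors)
        assert lhs == pytest.approx(rhs)


def _bruteforce_align(gold_slots, pred_slots):
    """Exhaustive maximal-total-overlap matching with the same tie-break
    (earlier gold, then earlier pred, pair by pair in overlap order)."""
    best = None
    n, m = len(gold_slots), len(pred_slots)
    pred_idx = list(range(m))
    for k in range(0, min(n, m) + 1):
        for g_sel in permutations(range(n), k):
            for p_sel in permutations(pred_idx, k):
                if any(
                    gold_slots[g].overlap(pred_slots[p]) == 0
                    for g, p in zip(g_sel, p_sel)
                ):
                    continue
                total = sum(
                    gold_slots[g].overlap(pred_slots[p]) for g, p in zip(g_sel, p_sel)
                )
                key = (total, )
                if best is None or total > best[0]:
                    best = (total, set(zip(g_sel, p_sel)))
    return best if best else (0, set())


def _score(gold_slots, pred_slots, matches):
    correct = type_err = frontier = 0
    for g, p in matches:
        gs, ps = gold_slots[g], pred_slots[p]
        same_class = gs.label == ps.label
        same_bounds = (gs.start, gs.end) == (ps.start, ps.end)
        if same_class and same_bounds:
            correct += 1
        elif same_bounds:
            type_err += 1
        elif same_class:
            frontier += 1
        else:
            type_err += 1
            frontier += 1
    D = len(gold_slots) - len(matches)
    I = len(pred_slots) - len(matches)
    return D, I, type_err, frontier


@st.composite
def iob_sequence(draw, max_len=18):
    n = draw(st.integers(1, max_len))
    labels = ["dosage", "route", "frequency"]
    seq = []
    while len(seq) < n:
        if draw(st.booleans()):
            lab = draw(st.sampled_from(labels))
            run = draw(st.integers(1, 3))
            seq.append(f"B-{lab}")
            seq.extend([f"I-{lab}"] * min(run - 1, n - len(seq)))
        else:
            seq.append("O")
    return seq[:n]


class TestAlignmentOracle:
    @given(gold=iob_sequence(), pred=iob_sequence())
    @settings(max_examples=150, deadline=None)
    def test_greedy_matches_bruteforce_total_overlap(self, gold, pred):
        n = min(len(gold), len(pred))
        gold, pred = gold[:n], pred[:n]
        gs, ps = iob_to_slots(gold), iob_to_slots(pred)
        if len(gs) > 6 or len(ps) > 6:
            gold = gold[:10]
            pred = pred[:10]
            gs, ps = iob_to_slots(gold), iob_to_slots(pred)
        rep = extract_and_align_slots(gold, pred)
        total_greedy = sum(g.overlap(p) for g, p in rep.matches)
        total_best, best_matches = _bruteforce_align(gs, ps)
        assert total_greedy == total_best
        assert len(rep.matches) >= len(best_matches) or total_greedy == total_best


class TestAggregateSER:
    def test_half_weight_identity_on_rates(self):
        assert aggregate_ser(0.03, 0.23, 0.02, 0.04) == pytest.approx(0.29)

    def test_linear_in_counts_or_rates(self):
        # scaling all four components scales the aggregate identically
        a = aggregate_ser(3, 23, 2, 4, ndigits=None)
        b = aggregate_ser(0.03, 0.23, 0.02, 0.04, ndigits=None)
        assert a == pytest.approx(100 * b)
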