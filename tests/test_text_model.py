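"""Standoff parsing, IOB conversion, and CoNLL round trips."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from medextract.labels import LABELS, UnknownLabelError
from medextract.preprocessing import Token, tokenize
from medextract.text_model import (
    AlignmentError,
    EntitySpan,
    MalformedAnnotationError,
    iob_to_spans,
    preprocess_document,
    read_conll,
    read_standoff,
    resolve_overlaps,
    spans_to_iob,
    write_conll,
)


def _write_pair(tmp_path, text, ann):
    txt = tmp_path / "d.txt"
    annf = tmp_path / "d.ann"
    txt.write_text(text, encoding="utf-8")
    annf.write_text(ann, encoding="utf-8")
    return txt, annf


class TestReadStandoff:
    def test_direct_parse(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "doliprane 1 g", "T1\tmedication_name 0 9\tdoliprane\n")
        doc = read_standoff(txt, ann)
        (span,) = doc.spans_for("gold")
        assert (span.char_start, span.char_end, span.label) == (0, 9, "medication_name")

    def test_empty_ann_gives_no_spans(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "doliprane 1 g", "")
        assert read_standoff(txt, ann).spans_for("gold") == []

    def test_surface_mismatch_raises(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "doliprane 1 g", "T1\tmedication_name 0 9\tkardegic\n")
        with pytest.raises(MalformedAnnotationError):
            read_standoff(txt, ann)

    def test_offsets_outside_text_raise(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "abc", "T1\tdosage 0 99\tabc\n")
        with pytest.raises(MalformedAnnotationError):
            read_standoff(txt, ann)

    def test_unknown_label_raises(self, tmp_path):
        txt, ann = _write_pair(tmp_path, "abc", "T1\tbogus 0 3\tabc\n")
        with pytest.raises(UnknownLabelError):
            read_standoff(txt, ann)

    def test_gold_offsets_projected_through_normalization(self, tmp_path):
        raw = "2.5 mg d'aspirine"
        txt, ann = _write_pair(tmp_path, raw, "T1\tmedication_name 9 17\taspirine\n")
        doc = read_standoff(txt, ann)
        (span,) = doc.spans_for("gold")
        assert doc.span_text(span) == "aspirine"


class TestSpansToIob:
    def test_multi_token_span(self):
        tokens = tokenize("pendant 3 semaines")
        iob = spans_to_iob(tokens, [EntitySpan(0, 18, "duration")])
        assert iob == ["B-duration", "I-duration", "I-duration"]

    def test_adjacent_spans_get_separate_b_tags(self):
        tokens = tokenize("1g quotidien")
        iob = spans_to_iob(
            tokens, [EntitySpan(0, 2, "dosage"), EntitySpan(3, 12, "frequency")]
        )
        assert iob == ["B-dosage", "B-frequency"]

    def test_any_char_overlap_labels_token(self):
        tokens = tokenize("doliprane matin")
        # span covers only half of the first token
        iob = spans_to_iob(tokens, [EntitySpan(0, 4, "medication_name")])
        assert iob == ["B-medication_name", "O"]

    def test_matches_bruteforce_character_overlap(self):
        # oracle: a token is labeled iff any of its characters is inside the span
        text = "prendre doliprane 500 mg le soir"
        tokens = tokenize(text)
        spans = [EntitySpan(8, 17, "medication_name"), EntitySpan(18, 24, "dosage")]
        iob = spans_to_iob(tokens, spans)
        for tok, tag in zip(tokens, iob):
            covering = [
                s
                for s in spans
                if any(s.char_start <= i < s.char_end for i in range(tok.char_start, tok.char_end))
            ]
            assert (tag != "O") == bool(covering)
            if covering:
                assert tag.endswith(covering[0].label)

    def test_span_over_no_token_is_dropped_and_counted(self):
        tokens = tokenize("abc def")
        dropped = []
        iob = spans_to_iob(tokens, [EntitySpan(3, 4, "dosage")], dropped=dropped)
        assert iob == ["O", "O"]
        assert len(dropped) == 1

    def test_overlap_resolution_prefers_longer_span(self):
        spans = [EntitySpan(0, 5, "dosage"), EntitySpan(0, 9, "frequency")]
        kept = resolve_overlaps(spans)
        assert kept == [EntitySpan(0, 9, "frequency")]


class TestIobToSpans:
    def test_run_becomes_one_span(self):
        tokens = tokenize("500 mg demain")
        spans = iob_to_spans(tokens, ["B-dosage", "I-dosage", "O"])
        assert spans == [EntitySpan(0, 6, "dosage", "model")]

    def test_orphan_inside_opens_slot_leniently(self):
        tokens = tokenize("intraveineuse")
        assert iob_to_spans(tokens, ["I-route"]) == [EntitySpan(0, 13, "route", "model")]

    def test_strict_mode_drops_orphan_inside(self):
        tokens = tokenize("intraveineuse")
        assert iob_to_spans(tokens, ["I-route"], strict=True) == []

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            iob_to_spans(tokenize("a b"), ["O"])


@st.composite
def token_aligned_document(draw):
    """A tokenized sentence plus a random set of token-aligned, non-adjacent-
    same-class spans (the class changes guarantee IOB invertibility)."""
    n_tokens = draw(st.integers(1, 12))
    words = [draw(st.text(alphabet="abcdefg123", min_size=1, max_size=6)) for _ in range(n_tokens)]
    text = " ".join(words)
    tokens = tokenize(text)
    spans = []
    i = 0
    while i < len(tokens):
        if draw(st.booleans()):
            length = draw(st.integers(1, min(3, len(tokens) - i)))
            label = draw(st.sampled_from(LABELS))
            if spans and spans[-1][1] == i and spans[-1][2] == label:
                label = LABELS[(LABELS.index(label) + 1) % len(LABELS)]
            spans.append((i, i + length, label))
            i += length
        else:
            i += 1
    entity_spans = [
        EntitySpan(tokens[a].char_start, tokens[b - 1].char_end, lab)
        for a, b, lab in spans
    ]
    return tokens, entity_spans


class TestRoundTrips:
    @given(token_aligned_document())
    @settings(max_examples=150, deadline=None)
    def test_spans_iob_identity(self, doc):
        tokens, spans = doc
        iob = spans_to_iob(tokens, spans)
        back = iob_to_spans(tokens, iob, source="gold")
        assert sorted(back) == sorted(spans)

    @given(token_aligned_document())
    @settings(max_examples=100, deadline=None)
    def test_conll_round_trip(self, doc):
        tokens, spans = doc
        document = preprocess_document(" ".join(t.text for t in tokens))
        gold = document.iob("gold")
        document.spans.extend(
            EntitySpan(s.char_start, s.char_end, s.label, "gold") for s in spans
        )
        gold = document.iob("gold")
        rule = [["O"] * len(s) for s in document.sentences]
        buf = io.StringIO()
        write_conll(document, gold, rule, buf)
        buf.seek(0)
        toks2, rule2, gold2 = read_conll(buf)
        assert toks2 == [[t.text for t in s] for s in document.sentences]
        assert gold2 == gold
        assert rule2 == rule

    def test_write_conll_shapes(self, tmp_path):
        doc = preprocess_document("doliprane 1 g")
        out = tmp_path / "x.conll"
        write_conll(doc, doc.iob("gold"), doc.iob("rule"), out)
        lines = out.read_text().split("\n")
        assert len([l for l in lines if l]) == 3  # one line per token

    def test_empty_document_writes_empty_file(self, tmp_path):
        doc = preprocess_document("")
        out = tmp_path / "x.conll"
        write_conll(doc, [], [], out)
        assert out.read_text() == ""

    def test_misaligned_sequences_raise(self):
        doc = preprocess_document("doliprane 1 g")
        with pytest.raises(AlignmentError):
            write_conll(doc, [["O"]], [["O", "O", "O"]], io.StringIO())
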