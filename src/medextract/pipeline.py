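"""End-to-end wiring: corpus -> rule layer -> features -> tagger -> metrics.

This is the orchestration used by the command-line interface and the
experiment scripts: it owns no modeling logic of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionCounts, MetricsReport, SERReport, micro_prf, token_confusion, extract_and_align_slots
from .features import EmbeddingProvider, build_inputs
from .lexicon import DrugLexicon
from .rule_engine import RuleSet, annotate_document, default_ruleset
from .tagger import TaggerModel, encode_tags
from .text_model import AnnotatedDocument

__all__ = ["SentenceExample", "prepare_documents", "make_dataset",
           "score_sequences", "evaluate_rules", "predict_documents"]


@dataclass
class SentenceExample:
    doc_id: str
    tokens: list[str]
    gold: list[str]
    rule: list[str]


def prepare_documents(
    docs: list[AnnotatedDocument],
    lexicon: DrugLexicon,
    ruleset: RuleSet | None = None,
) -> list[SentenceExample]:
    """Annotate with rules and flatten into per-sentence examples."""
    ruleset = ruleset or default_ruleset()
    examples: list[SentenceExample] = []
    for doc in docs:
        annotate_document(doc, lexicon, ruleset)
        gold_seqs = doc.iob("gold")
        rule_seqs = doc.iob("rule")
        for tokens, gold, rule in zip(doc.sentences, gold_seqs, rule_seqs):
            if tokens:
                examples.append(
                    SentenceExample(doc.doc_id, [t.text for t in tokens], gold, rule)
                )
    return examples


def make_dataset(
    examples: list[SentenceExample],
    provider: EmbeddingProvider,
    with_rule_features: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (
            build_inputs(ex.tokens, provider, ex.rule if with_rule_features else None),
            encode_tags(ex.gold),
        )
        for ex in examples
    ]


def score_sequences(
    gold: list[list[str]], pred: list[list[str]]
) -> tuple[MetricsReport, SERReport]:
    """Pooled token metrics and slot error report over parallel sequences."""
    counts = ConfusionCounts()
    ser = SERReport(0, 0, 0, 0, 0, 0)
    for g, p in zip(gold, pred):
        counts.add(token_confusion(g, p))
        ser = ser.combine(extract_and_align_slots(g, p))
    return micro_prf(counts), ser


def evaluate_rules(examples: list[SentenceExample]):
    """Score the rule layer itself against gold."""
    return score_sequences([e.gold for e in examples], [e.rule for e in examples])


def predict_documents(
    model: TaggerModel,
    examples: list[SentenceExample],
    provider: EmbeddingProvider,
    with_rule_features: bool = True,
) -> list[list[str]]:
    from .tagger import predict

    inputs = [
        build_inputs(ex.tokens, provider, ex.rule if with_rule_features else None)
        for ex in examples
    ]
    return predict(model, inputs)
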