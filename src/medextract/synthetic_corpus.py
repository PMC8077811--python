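"""Synthetic French prescription corpus with gold annotations.

Real clinical notes cannot ship with the package, so every component is
exercised on generated prescription-like documents: short sentences of the
form "<verb> <drug> <dosage> <frequency> [<duration>] [<route>]
[<condition>]" mixed with entity-free distractor sentences, plus a toy drug
lexicon covering exactly the clean drug surfaces.

The category profile follows the empirical slot distribution of French
medication corpora: medication names dominate, dosage and frequency are the
common attributes, drug classes come next, and duration / route / condition
are rare. Noise is controllable and targets specific failure modes of the
rule layer:

* **alias noise** replaces a drug surface by an out-of-lexicon alias
  (abbreviation, misspelling, alternate brand) — the dictionary anchor is
  lost and the whole sentence escapes the rule engine;
* **paraphrase noise** rewords an attribute outside the rule inventory —
  the anchor stays but the attribute is missed;
* **typo noise** perturbs characters of one word per affected sentence.

All sampled entities keep exact gold spans regardless of noise. Generated
text is its own normalized form (ASCII, comma decimals, no apostrophes), so
gold offsets are valid in both raw and normalized coordinates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import DrugLexicon, build_lexicon
from .preprocessing import tokenize
from .text_model import AnnotatedDocument, EntitySpan, preprocess_document, write_standoff

__all__ = ["GeneratorConfig", "generate_corpus", "split_corpus", "write_corpus"]


# (surface, ATC, out-of-lexicon alias)
DEFAULT_DRUGS: tuple[tuple[str, str, str], ...] = (
    ("doliprane", "N02BE01", "dolipranne"),
    ("paracetamol", "N02BE01", "paracetamole"),
    ("dafalgan", "N02BE01", "dafalgon"),
    ("efferalgan", "N02BE01", "efferalgane"),
    ("paracetamol codeine", "N02BE51", "klipal"),
    ("ibuprofene", "M01AE01", "ibuprofen"),
    ("kardegic", "B01AC06", "kardegique"),
    ("aspirine", "B01AC06", "aspirin"),
    ("acide acetylsalicylique", "B01AC06", "aas"),
    ("augmentin", "J01CR02", "augmentine"),
    ("amoxicilline", "J01CA04", "amox"),
    ("clamoxyl", "J01CA04", "clamoxil"),
    ("levothyrox", "H03AA01", "levotyrox"),
    ("ventoline", "R03AC02", "ventolin"),
    ("spasfon", "A03AX12", "spasfone"),
    ("tramadol", "N02AX02", "tramadole"),
    ("codeine", "R05DA04", "codein"),
    ("omeprazole", "A02BC01", "omeprazol"),
    ("esomeprazole", "A02BC05", "esomeprazol"),
    ("metformine", "A10BA02", "metformin"),
    ("insuline", "A10AB01", "insulin"),
    ("ramipril", "C09AA05", "ramiprile"),
    ("bisoprolol", "C07AB07", "bisoprolole"),
    ("furosemide", "C03CA01", "furosemid"),
    ("atorvastatine", "C10AA05", "atorvastatin"),
    ("prednisone", "H02AB07", "prednison"),
)

DEFAULT_CLASSES: tuple[tuple[str, str, str], ...] = (
    ("antibiotique", "J01", "antibio"),
    ("antibiotherapie", "J01", "atb"),
    ("betabloquant", "C07", "beta bloquant"),
    ("statine", "C10", "statines"),
    ("antalgique", "N02", "antalgiques"),
    ("anticoagulant", "B01", "anticoagulants"),
    ("corticoides", "H02", "cortico"),
    ("diuretique", "C03", "diuretiques"),
)

DEFAULT_DOSAGES = (
    "1 g", "500 mg", "1000 mg", "0,5 mg", "5 mg", "10 mg", "20 mg", "40 mg",
    "75 mg", "100 mg", "1 cp", "2 cp", "1 comprime", "2 comprimes",
    "2 gelules", "20 gouttes", "1 sachet", "2 bouffees", "10 ml", "4 UI",
)
DEFAULT_DOSAGE_PARAPHRASES = (
    "deux comprimes", "un comprime et demi", "500 milligrammes",
    "trois gelules", "un demi comprime",
)
DEFAULT_FREQUENCIES = (
    "3 fois par jour", "2 fois par jour", "1 fois par jour", "4 fois par jour",
    "1 fois par semaine", "toutes les 8 heures", "toutes les 6 heures",
    "toutes les 12 heures", "matin et soir", "matin midi et soir",
    "le matin", "le soir", "au coucher",
)
DEFAULT_FREQUENCY_PARAPHRASES = (
    "une prise quotidienne", "deux prises quotidiennes",
    "trois prises quotidiennes", "une prise hebdomadaire", "a chaque repas",
)
DEFAULT_DURATIONS = (
    "pendant 5 jours", "pendant 7 jours", "pendant 10 jours",
    "pendant 2 semaines", "pendant 3 semaines", "pendant 1 mois",
    "pendant 6 mois", "jusqu a la prochaine consultation",
)
DEFAULT_DURATION_PARAPHRASES = (
    "durant deux semaines", "sur une periode de dix jours", "pour un mois entier",
)
DEFAULT_ROUTES = (
    "per os", "voie orale", "voie intraveineuse", "voie intramusculaire",
    "voie sous cutanee", "IV", "IM", "SC",
)
DEFAULT_ROUTE_PARAPHRASES = (
    "par la bouche", "en injection lente", "par voie injectable",
)
DEFAULT_CONDITIONS = (
    "si douleur", "si douleurs", "si fievre", "si besoin", "si nausees",
    "si insomnie", "si toux", "si crise", "en cas de douleur",
    "en cas de fievre", "en cas de crise", "en cas de vomissements",
    "en cas de malaise",
)
DEFAULT_CONDITION_PARAPHRASES = (
    "lorsque la douleur survient", "des que necessaire", "en presence de symptomes",
)
DEFAULT_VERBS = (
    "Prendre", "Poursuivre", "Debuter", "Reprendre", "Introduire",
    "Prescription de", "Arret progressif de",
)
DEFAULT_DISTRACTORS = (
    "Le patient est apyretique",
    "Examen clinique sans particularite",
    "Tension arterielle 12/8",
    "Poids 70 kg",
    "Retour a domicile ce jour",
    "Bilan biologique normal",
    "Pas d allergie connue",
    "Suivi en consultation prevu",
    "Etat general conserve",
    "Auscultation pulmonaire libre",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic corpus.

    Attribute probabilities follow the slot profile of annotated French
    medication corpora (names >> dosage > frequency >> class > the rare
    three). Noise rates are per-mention (alias, paraphrase) or per-sentence
    (typo, distractor) probabilities in [0, 1].
    """

    n_documents: int = 320
    sentences_per_document: tuple[int, int] = (4, 10)
    alias_rate: float = 0.15
    paraphrase_rate: float = 0.15
    typo_rate: float = 0.05
    distractor_rate: float = 0.25
    class_anchor_rate: float = 0.157
    second_drug_rate: float = 0.12
    attribute_rates: tuple[tuple[str, float], ...] = (
        ("dosage", 0.55),
        ("frequency", 0.43),
        ("duration", 0.06),
        ("route", 0.07),
        ("condition", 0.05),
    )
    max_anchor_distance: int = 10
    seed: int = 0
    drugs: tuple[tuple[str, str, str], ...] = DEFAULT_DRUGS
    classes: tuple[tuple[str, str, str], ...] = DEFAULT_CLASSES
    verbs: tuple[str, ...] = DEFAULT_VERBS
    distractors: tuple[str, ...] = DEFAULT_DISTRACTORS
    inventories: dict = field(
        default_factory=lambda: {
            "dosage": (DEFAULT_DOSAGES, DEFAULT_DOSAGE_PARAPHRASES),
            "frequency": (DEFAULT_FREQUENCIES, DEFAULT_FREQUENCY_PARAPHRASES),
            "duration": (DEFAULT_DURATIONS, DEFAULT_DURATION_PARAPHRASES),
            "route": (DEFAULT_ROUTES, DEFAULT_ROUTE_PARAPHRASES),
            "condition": (DEFAULT_CONDITIONS, DEFAULT_CONDITION_PARAPHRASES),
        }
    )

    def __post_init__(self) -> None:
        for name in ("alias_rate", "paraphrase_rate", "typo_rate", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.drugs or not self.classes:
            raise ValueError("drug and class inventories must be non-empty")
        for attr, (clean, para) in self.inventories.items():
            if not clean or not para:
                raise ValueError(f"empty inventory for {attr}")


def _typo(word: str, rng: random.Random) -> str:
    """One character-level perturbation; alphabetic words of length >= 4 only."""
    if len(word) < 4 or not word.isalpha():
        return word
    kind = rng.choice(("swap", "drop", "double"))
    i = rng.randrange(1, len(word) - 1)
    if kind == "swap":
        return word[: i] + word[i + 1] + word[i] + word[i + 2 :]
    if kind == "drop":
        return word[:i] + word[i + 1 :]
    return word[: i + 1] + word[i] + word[i + 1 :]


def _phrase_tokens(phrase: str) -> int:
    return len(tokenize(phrase))


class _SentenceBuilder:
    """Accumulates (text, label) pieces and finalizes offsets."""

    def __init__(self) -> None:
        self.pieces: list[tuple[str, str | None]] = []

    def add(self, text: str, label: str | None = None) -> None:
        self.pieces.append((text, label))

    def apply_typo(self, rng: random.Random) -> None:
        candidates = [
            (i, j)
            for i, (text, _lab) in enumerate(self.pieces)
            for j, word in enumerate(text.split(" "))
            if len(word) >= 4 and word.isalpha()
        ]
        if not candidates:
            return
        pi, wj = rng.choice(candidates)
        text, lab = self.pieces[pi]
        words = text.split(" ")
        words[wj] = _typo(words[wj], rng)
        self.pieces[pi] = (" ".join(words), lab)

def _render(builder: _SentenceBuilder, offset: int) -> tuple[str, list[EntitySpan]]:
    parts: list[str] = []
    spans: list[EntitySpan] = []
    pos = offset
    for k, (text, label) in enumerate(builder.pieces):
        if k > 0:
            parts.append(" ")
            pos += 1
        if label is not None:
            spans.append(EntitySpan(pos, pos + len(text), label, "gold"))
        parts.append(text)
        pos += len(text)
    parts.append(".")
    return "".join(parts), spans


def _anchored_sentence(cfg: GeneratorConfig, rng: random.Random) -> _SentenceBuilder:
    b = _SentenceBuilder()
    b.add(rng.choice(cfg.verbs))

    def add_drug() -> None:
        if rng.random() < cfg.class_anchor_rate:
            surface, _atc, alias = rng.choice(cfg.classes)
            label = "medication_class"
        else:
            surface, _atc, alias = rng.choice(cfg.drugs)
            label = "medication_name"
        if rng.random() < cfg.alias_rate:
            surface = alias
        b.add(surface, label)

    def add_attributes() -> None:
        # Keep every attribute's first token within the rule engine's default
        # anchor window; overflowing attributes are simply not emitted.
        distance = 0
        for attr, rate in cfg.attribute_rates:
            if rng.random() >= rate:
                continue
            clean, para = cfg.inventories[attr]
            paraphrased = rng.random() < cfg.paraphrase_rate
            phrase = rng.choice(para if paraphrased else clean)
            if distance + 1 > cfg.max_anchor_distance:
                break
            b.add(phrase, attr)
            distance += _phrase_tokens(phrase)

    add_drug()
    add_attributes()
    if rng.random() < cfg.second_drug_rate:
        b.add("et")
        surface, _atc, alias = rng.choice(cfg.drugs)
        if rng.random() < cfg.alias_rate:
            surface = alias
        b.add(surface, "medication_name")
        if rng.random() < 0.5:
            clean, para = cfg.inventories["dosage"]
            paraphrased = rng.random() < cfg.paraphrase_rate
            b.add(rng.choice(para if paraphrased else clean), "dosage")
    return b


def build_toy_lexicon(cfg: GeneratorConfig | None = None) -> DrugLexicon:
    """The lexicon covering exactly the clean (non-alias) drug surfaces."""
    cfg = cfg or GeneratorConfig()
    rows = [
        {"name": surface, "atc": atc, "type": "medication_name"}
        for surface, atc, _alias in cfg.drugs
    ] + [
        {"name": surface, "atc": atc, "type": "medication_class"}
        for surface, atc, _alias in cfg.classes
    ]
    return build_lexicon(rows)


def generate_corpus(
    cfg: GeneratorConfig | None = None,
) -> tuple[list[AnnotatedDocument], DrugLexicon]:
    """Generate the corpus and its matching toy lexicon, seed-deterministic."""
    cfg = cfg or GeneratorConfig()
    rng = random.Random(cfg.seed)
    docs: list[AnnotatedDocument] = []
    lo, hi = cfg.sentences_per_document
    for d in range(cfg.n_documents):
        n_sent = rng.randint(lo, hi)
        lines: list[str] = []
        spans: list[EntitySpan] = []
        offset = 0
        for _ in range(n_sent):
            if rng.random() < cfg.distractor_rate:
                text, sent_spans = rng.choice(cfg.distractors) + ".", []
            else:
                builder = _anchored_sentence(cfg, rng)
                if rng.random() < cfg.typo_rate:
                    builder.apply_typo(rng)
                text, sent_spans = _render(builder, offset)
            lines.append(text)
            spans.extend(sent_spans)
            offset += len(text) + 1  # the joining newline
        raw = "\n".join(lines)
        doc = preprocess_document(raw, doc_id=f"synthetic-{d:04d}")
        if doc.normalized_text != raw:  # generated text must be normalization-stable
            raise AssertionError("generator emitted text altered by normalization")
        doc.spans.extend(spans)
        docs.append(doc)
    return docs, build_toy_lexicon(cfg)


def split_corpus(
    documents: list, fractions: tuple[float, ...] = (0.675, 0.075, 0.25), seed: int = 0
) -> tuple[list, ...]:
    """Disjoint, exhaustive, seed-deterministic document-level split.

    Split sizes use largest-remainder rounding, so 320 documents under the
    default fractions give the conventional 216 / 24 / 80 partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(documents)
    if n < len(fractions):
        raise ValueError(f"cannot split {n} documents into {len(fractions)} parts")
    exact = [f * n for f in fractions]
    sizes = [int(e) for e in exact]
    for i in sorted(range(len(exact)), key=lambda i: exact[i] - sizes[i], reverse=True):
        if sum(sizes) == n:
            break
        sizes[i] += 1
    order = list(range(n))
    random.Random(seed).shuffle(order)
    out: list[list] = []
    start = 0
    for size in sizes:
        out.append([documents[i] for i in sorted(order[start : start + size])])
        start += size
    return tuple(out)


def write_corpus(docs: list[AnnotatedDocument], out_dir) -> None:
    """Write each document as a standoff .txt/.ann pair (gold layer)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_standoff(doc, "gold", out / f"{doc.doc_id}.txt", out / f"{doc.doc_id}.ann")
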