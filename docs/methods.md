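# Methods

`medextract` implements a hybrid extractor for medication information in
French clinical text: a high-precision dictionary/rule annotator, a
bidirectional LSTM sequence tagger (optionally topped by a linear-chain
CRF), and a fusion mechanism in which the rule layer's output is fed to the
tagger as extra input features. This note documents the model, the
numerical choices, the synthetic evaluation corpus, and the limits of what
the shipped experiments can show.

## Task and label space

Seven entity categories are extracted: `medication_name`,
`medication_class`, and five attributes of a drug mention — `dosage`,
`frequency`, `duration`, `route`, `condition` (the event triggering intake,
e.g. *si douleur*). Sequences are tagged in IOB: 15 tags (`O` plus a
`B-`/`I-` pair per category) in a fixed order shared by the rule-feature
encoding and the tagger's output layer.

## Preprocessing

Normalization removes acronym-internal periods, turns decimal points between
digits into commas, strips accents to ASCII (NFKD, combining marks dropped),
replaces apostrophes by spaces, and converts hard-wrap line breaks into
spaces. A line break counts as a wrap artifact when the preceding line does
not end in a period and the following line starts lowercase; consecutive
breaks (paragraph breaks) are always kept. Every normalized character maps
to a raw-text index (the offset map), so annotations — which live in
normalized coordinates throughout the system — can be projected back.

Sentence boundaries are the remaining periods and retained line breaks,
suppressed when the adjacent word on either side belongs to a shipped list
of ~35 French prepositions and coordinating conjunctions. The source
heuristic also names transitive verbs as boundary blockers; with no usable
inventory of those, only the preposition/conjunction condition is
implemented. Tokens are maximal alphanumeric runs or maximal runs of one
repeated non-alphanumeric character (`3x/jour !!!` → `3x / jour !!!`).

Case is preserved by normalization; layers that want case-insensitivity
(dictionary matching, most rules) fold case themselves.

## Rule-based layer

Extraction is strictly anchor-gated. Dictionary anchors come first: exact
matching of the drug lexicon (surface forms normalized, tokenized, and
case-folded; longest-leftmost selection; no stemming or edit distance —
exactness is what buys the layer its precision). A surface listed both as a
medication name and as a class resolves to the name. Attribute rules
(regular expressions over normalized text) are then applied only within a
window of 10 tokens on either side of an anchor. Overlapping matches are
resolved by rule priority (dosage > frequency > duration > route >
condition, mirroring corpus frequency), then by length, then position. The
shipped inventory (`data/rules.yml`, ~13 patterns) is an original artifact
covering French dosage units, frequency idioms, durations, routes, and
intake conditions; it is a config file and fully replaceable.

The rule spans serve twice: as standalone pre-annotation output, and —
converted to IOB and one-hot encoded over the 15-tag order — as 15 extra
input dimensions concatenated after the word embedding of each token.

## IOB conversion conventions

Character spans project to tokens by the *any-overlap* rule: any character
overlap labels the token (first token `B-`, rest `I-`). Within one
annotation layer, overlapping spans resolve longer-first, ties to the
earlier start. Decoding is lenient by default — an orphan `I-` opens a slot,
because neural taggers emit such sequences — with a strict mode (orphan `I-`
ignored) behind a flag for ablation. For token-aligned spans the two
directions are exact inverses, a property the suite checks on random
documents.

## Embeddings

Providers share one contract: a per-sentence lookup returning one
fixed-dimension vector per token, frozen while the tagger trains.

* **Static skip-gram** (baseline): skip-gram with negative sampling (5
  negatives, unigram^0.75 noise, window 5, 5 epochs, dimension 100 by
  default) trained on the training split only. Out-of-vocabulary tokens map
  to a dedicated seed-fixed unknown vector.
* **Subword**: same objective, with a word represented as the mean of its
  character 3–6-gram vectors (word-boundary markers included), so unseen
  words compose a vector from their substrings.
* **Contextual**: a provider interface whose reference implementation is a
  small character-aware bidirectional recurrent language model — subword
  inputs, a forward LSTM predicting the next token and a backward LSTM the
  previous one; a token's embedding is the concatenation of the two hidden
  states (dimension 2·hidden). It exists to exercise the fusion
  architecture; training a large contextual model on real clinical notes is
  out of scope.

All embedding training is deterministic for a fixed seed (sorted
vocabularies, seeded generators).

## Tagger

Input → dropout → forward LSTM + backward LSTM (hidden states concatenated,
never summed) → dropout → dense projection to 15 tags. The network is
implemented directly on numpy with hand-derived backpropagation; the test
suite verifies every gradient (LSTM, dense, CRF) against central finite
differences, and CRF marginals against exhaustive enumeration over all tag
sequences at small length.

With the CRF enabled, training follows the marginal formulation:
forward-backward per-token marginals under a 15×15 transition table,
optimized with categorical cross-entropy on the gold tag's marginal,
backpropagated exactly through both recursions; decoding is per-token
marginal argmax, with joint Viterbi behind a flag. Without the CRF the
output is softmax + cross-entropy, decoded by argmax.

Schedule: Adam at learning rate 0.001, up to 50 epochs, early stopping on
development loss with patience 8, learning rate × 0.1 on plateau. The
plateau trigger — no dev-loss improvement above 1e-4 for 3 consecutive
epochs — is a package choice; the source schedule specifies the factor and
trigger kind but not the thresholds. Checkpoint selection is best dev loss
(consistent with the early-stopping monitor); dev micro-F is logged per
epoch alongside. Sentences are batched with right-padding; losses are
masked on padding, and the backward LSTM reverses each sentence by its true
length. Recurrent dropout is variational (one mask per sequence).

Hyperparameters live on a fixed grid — hidden size {128, 256, 512}, batch
size {64, 128}, dropout before/after/recurrent {0.0, 0.1, 0.2, 0.3, 0.5,
0.6, 0.7} — explored by seeded random search (15 iterations by default)
scored on development micro-F; the full trial log is returned and the
argmax trial's configuration wins.

## Evaluation

Token scoring compares classes and ignores the B/I prefix (a gold
`B-dosage` predicted `I-dosage` is a true positive; prefix errors surface
at slot level as frontier errors). A token predicted with the wrong class
counts simultaneously as a false positive of the predicted class and a
false negative of the gold class. Precision, recall, and F are
micro-averaged by pooling counts, reported on the percent scale; zero
denominators yield 0 with a degeneracy flag.

Slot scoring extracts maximal B,I⁺ runs from both sequences and aligns them
greedily by maximal token overlap (ties to the earlier gold slot, then the
earlier predicted slot). Matched pairs score: correct (class and boundaries
right), type error (boundaries right, class wrong), frontier error (class
right, boundaries wrong), or type + frontier (both wrong). Unmatched gold
slots are deletions, unmatched predictions insertions, and

    SER = (D + I + 0.5 · (T + Fr)) / reference slots.

The half weight on substitution-like errors is the convention that makes
the published per-type rates and aggregate SER values mutually consistent.
The greedy alignment was verified equivalent (in total overlap and
resulting SER) to exhaustive enumeration over all injective matchings on
1,000 random ≤8-slot sequence pairs. Note that published overall F values
in this line of work are not always the harmonic mean of the published P
and R; this package emits standard micro-F only.

## Synthetic corpus

Real annotated clinical notes cannot ship, so every end-to-end claim is
made on a generated French-prescription-like corpus: sentences of the form
*verb drug [dosage] [frequency] [duration] [route] [condition]*, entity-free
distractor lines, exact gold spans for every emitted entity, and a toy
lexicon covering exactly the clean drug surfaces. Defaults: 320 documents
of 4–10 sentences (split 216/24/80 at the standard fractions), category
profile matching annotated medication corpora (names ≫ dosage > frequency ≫
class > route/duration/condition), alias noise 0.15, paraphrase noise 0.15,
typo noise 0.05, distractor rate 0.25. Alias noise swaps a drug for an
out-of-lexicon variant (killing the anchor and with it the whole sentence's
rule output); paraphrase noise rewords an attribute outside the rule
inventory; each targets one documented failure mode of dictionary systems.

What the generator does *not* emulate: real orthographic variety, section
structure, negation/experiencer phenomena, coordination beyond a second
drug clause, discontinuous or nested entities, and the long documents of a
hospital data warehouse (~60 sentences each; the default here is 4–10 to
keep desk-scale training runs in seconds-to-minutes). Consequently the
absolute F-measures obtained on this corpus say nothing quantitative about
clinical text; what the experiments *do* establish is ordinal: rule
precision stays near-perfect while recall degrades with noise, the neural
tagger generalizes past the dictionary, and rule features do not hurt and
typically help (the hybrid ≥ plain ≥ rules-alone ordering on test micro-F).

## Degenerate inputs and tie-breaks

Empty documents annotate to nothing; punctuation-only sentences produce
only symbol tokens and no spans. Spans overlapping no token are dropped and
surfaced to the caller. Malformed ATC codes are kept with code `unknown`;
empty lexicon rows are skipped and counted. All randomness (generation,
splits, embeddings, initialization, batching, search) flows from explicit
seeds; reruns are byte-identical.

## Known limitations

Relation extraction (attaching each attribute to *its* drug), event
markers, and meta-attributes (negation, experiencer, temporality) are out
of scope. The rule inventory is a functional stand-in, not a validated
clinical artifact. The CRF's marginal training is quadratic in tag count
per token and runs sentence-by-sentence; it is comfortable at this scale
but not engineered for GPU-scale corpora.
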