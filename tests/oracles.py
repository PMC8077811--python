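"""Independent brute-force oracles used by the acceptance suite.

These deliberately avoid the library's own code paths: token tallies are
per-token dictionary counts, and slot alignment is exhaustive enumeration
over all injective matchings maximizing total overlap.
"""


def token_tally(gold: list[str], pred: list[str]):
    """Per-class (tp, fp, fn) dicts computed token by token."""
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}

    def cls(tag):
        return None if tag == "O" else tag.split("-", 1)[1]

    for g_tag, p_tag in zip(gold, pred):
        g, p = cls(g_tag), cls(p_tag)
        if g is not None and g == p:
            tp[g] = tp.get(g, 0) + 1
        else:
            if p is not None:
                fp[p] = fp.get(p, 0) + 1
            if g is not None:
                fn[g] = fn.get(g, 0) + 1
    return tp, fp, fn


def extract_slots(iob: list[str]):
    """(start, end, label) runs; orphan I- opens a run (lenient)."""
    slots = []
    open_label, start = None, 0
    for i, tag in enumerate(iob):
        prefix = None if tag == "O" else tag[0]
        label = None if tag == "O" else tag.split("-", 1)[1]
        continues = prefix == "I" and label == open_label
        if open_label is not None and not continues:
            slots.append((start, i, open_label))
            open_label = None
        if prefix == "B" or (prefix == "I" and not continues):
            open_label, start = label, i
    if open_label is not None:
        slots.append((start, len(iob), open_label))
    return slots


def _overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def exhaustive_alignments(gold_slots, pred_slots):
    """All maximal-total-overlap injective matchings, by exhaustive search.

    Returns (best_total, list of matchings); every matching is a list of
    (gold_index, pred_index) pairs with positive overlap. Slots are
    intervals, so each gold slot has only a handful of overlapping partners
    and plain recursion stays fast at the <= 8-slot scale.
    """
    candidates = [
        [p for p, ps in enumerate(pred_slots) if _overlap(g, ps) > 0]
        for g in gold_slots
    ]
    best = {"total": 0, "matchings": [[]]}

    def recurse(i, used, pairs, total):
        if i == len(gold_slots):
            if total > best["total"]:
                best["total"] = total
                best["matchings"] = [list(pairs)]
            elif total == best["total"]:
                best["matchings"].append(list(pairs))
            return
        recurse(i + 1, used, pairs, total)  # leave gold slot i unmatched
        for p in candidates[i]:
            if p not in used:
                pairs.append((i, p))
                used.add(p)
                recurse(i + 1, used, pairs, total + _overlap(gold_slots[i], pred_slots[p]))
                used.remove(p)
                pairs.pop()

    recurse(0, set(), [], 0)
    return best["total"], best["matchings"]


def slot_error_counts(gold_slots, pred_slots, pairs):
    deletions = len(gold_slots) - len(pairs)
    insertions = len(pred_slots) - len(pairs)
    type_err = frontier = 0
    for g, p in pairs:
        gs, ps = gold_slots[g], pred_slots[p]
        same_class = gs[2] == ps[2]
        same_bounds = gs[:2] == ps[:2]
        if same_class and same_bounds:
            continue
        if same_bounds:
            type_err += 1
        elif same_class:
            frontier += 1
        else:
            type_err += 1
            frontier += 1
    return deletions, insertions, type_err, frontier
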