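"""BioNLP-ST standoff reading/writing and approximate-match evaluation.

Entities live in .a1 files ("T1\tProtein 0 4\tJNK"), event triggers and
events in .a2 files ("T10\tPhosphorylation 5 19\tphosphorylates",
"E1\tPhosphorylation:T10 Theme:T2 Cause:T1"), and equivalent entity
mentions in "* Equiv T1 T2" lines.  All offsets are 0-based character
positions into the raw .txt.

Scoring follows the approximate recursive matching mode of the GE task:
two events are equal iff their types are the same, their triggers are the
same and their arguments are the same role-by-role, where a predicted span
counts as the same as a gold span iff it is entirely contained within the
gold span extended by one word to the left and to the right.  An event
whose argument belongs to an n-member equivalence class is counted n
times.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .entities import EntityMention
from .templates import Event

__all__ = [
    "GoldSet",
    "EvalResult",
    "read_standoff",
    "write_a2",
    "approx_span_match",
    "evaluate",
    "tokenize",
]

_ROLE_TO_STANDOFF = {"theme": "Theme", "agent": "Cause"}
_STANDOFF_TO_ROLE = {"Theme": "theme", "Cause": "agent"}


@dataclass
class GoldSet:
    entities: list[EntityMention]
    events: list[Event]
    equiv_classes: list[frozenset[tuple[int, int]]] = field(default_factory=list)
    text: str = ""

    def __post_init__(self):
        spans = [s for cls in self.equiv_classes for s in cls]
        if len(spans) != len(set(spans)):
            raise ValueError("equivalence classes must be disjoint")


@dataclass
class EvalResult:
    per_relation: dict[str, tuple[int, int, int]]  # relation -> (TP, FP, FN)
    tp: int
    fp: int
    fn: int

    @staticmethod
    def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    @property
    def precision(self) -> float:
        return self._prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return self._prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return self._prf(self.tp, self.fp, self.fn)[2]

    def relation_prf(self, relation: str) -> tuple[float, float, float]:
        return self._prf(*self.per_relation[relation])


_TOKEN_RE = re.compile(r"[^\s()\[\]{},.;:]+|[()\[\]{},.;:]")


def tokenize(text: str) -> list[tuple[int, int]]:
    """Word-token spans of a document (whitespace and punctuation breaks)."""
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def read_standoff(txt: str, a1: str, a2: Optional[str] = None) -> GoldSet:
    """Read a standoff-annotated document into a GoldSet.

    Dangling references raise an error naming the annotation id.  Entity
    mentions from .a1 are marked pre-annotated and typed GGP.
    """
    entities: list[EntityMention] = []
    by_id: dict[str, EntityMention] = {}

    def parse_t_line(line: str, source: str) -> tuple[str, EntityMention]:
        tid, middle, text = line.split("\t", 2)
        typ, start, end = middle.rsplit(" ", 2)
        span = (int(start), int(end))
        if txt[span[0]:span[1]] != text:
            raise ValueError(f"{tid}: span text mismatch")
        sem = "GGP" if source == "a1" else typ
        return tid, EntityMention(span, text, sem, source="preannotated",
                                  ann_id=tid)

    for raw in a1.splitlines():
        if not raw.strip():
            continue
        tid, mention = parse_t_line(raw, "a1")
        entities.append(mention)
        by_id[tid] = mention

    events: list[Event] = []
    equiv: list[frozenset[tuple[int, int]]] = []
    triggers: dict[str, tuple[str, tuple[int, int], str]] = {}
    if a2:
        event_lines = []
        for raw in a2.splitlines():
            if not raw.strip():
                continue
            if raw.startswith("T"):
                tid, mention = parse_t_line(raw, "a2")
                typ = raw.split("\t")[1].rsplit(" ", 2)[0]
                triggers[tid] = (typ, mention.span, mention.text)
                by_id.setdefault(tid, mention)
            elif raw.startswith("*"):
                parts = raw.split()
                if parts[1] != "Equiv":
                    raise ValueError(f"unknown relation line {raw!r}")
                spans = []
                for tid in parts[2:]:
                    if tid not in by_id:
                        raise ValueError(f"dangling reference {tid}")
                    spans.append(by_id[tid].span)
                equiv.append(frozenset(spans))
            elif raw.startswith("E"):
                event_lines.append(raw)
        for raw in event_lines:
            eid, body = raw.split("\t", 1)
            parts = body.split()
            etype, trig_id = parts[0].split(":")
            if trig_id not in triggers:
                raise ValueError(f"dangling reference {trig_id} in {eid}")
            _, tspan, ttext = triggers[trig_id]
            args: dict[str, list[EntityMention]] = {}
            for part in parts[1:]:
                role_name, ref = part.split(":")
                role = _STANDOFF_TO_ROLE.get(role_name.rstrip("0123456789"))
                if role is None:
                    raise ValueError(f"unknown role {role_name} in {eid}")
                if ref not in by_id:
                    raise ValueError(f"dangling reference {ref} in {eid}")
                args.setdefault(role, []).append(by_id[ref])
            events.append(Event(etype, tspan, ttext,
                                {r: tuple(ms) for r, ms in args.items()}))
    return GoldSet(entities, events, equiv, text=txt)


def write_a2(events: list[Event], next_tid: int = 1000) -> str:
    """Serialize events to .a2 content.

    Triggers get fresh T-ids (from ``next_tid``); event arguments reference
    the .a1 ids carried by their mentions.  ``read_standoff`` of the output
    (together with the matching .a1) reproduces the events.
    """
    lines: list[str] = []
    trig_ids: dict[tuple[str, tuple[int, int]], str] = {}
    tid = next_tid
    for e in events:
        key = (e.relation, e.trigger_span)
        if key not in trig_ids:
            trig_ids[key] = f"T{tid}"
            tid += 1
            lines.append(f"{trig_ids[key]}\t{e.relation} {e.trigger_span[0]} "
                         f"{e.trigger_span[1]}\t{e.trigger_text}")
    for i, e in enumerate(events, start=1):
        parts = [f"{e.relation}:{trig_ids[(e.relation, e.trigger_span)]}"]
        for role in ("theme", "agent"):
            for k, m in enumerate(e.args.get(role, ())):
                name = _ROLE_TO_STANDOFF[role]
                if role == "theme" and k > 0:
                    name = f"Theme{k + 1}"
                ref = m.ann_id or "T?"
                parts.append(f"{name}:{ref}")
        lines.append(f"E{i}\t" + " ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


def approx_span_match(pred: tuple[int, int], gold: tuple[int, int],
                      tokens: list[tuple[int, int]]) -> bool:
    """Approximate span equality of the GE task.

    The gold span is extended by one word both to the left and to the
    right (word boundaries given by ``tokens``); the predicted span
    matches iff it is entirely contained in the extension.
    """
    ext_start, ext_end = gold
    prev = [t for t in tokens if t[1] <= gold[0]]
    if prev:
        ext_start = prev[-1][0]
    nxt = [t for t in tokens if t[0] >= gold[1]]
    if nxt:
        ext_end = nxt[0][1]
    return pred[0] >= ext_start and pred[1] <= ext_end


def _expand_gold(events: list[Event],
                 equiv: list[frozenset[tuple[int, int]]]) -> list[Event]:
    """One gold copy per equivalence-class member of each argument."""
    by_span: dict[tuple[int, int], frozenset] = {}
    members: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for cls in equiv:
        for span in cls:
            by_span[span] = cls
            members[span] = sorted(cls)
    out: list[Event] = []
    for e in events:
        variants: list[dict[str, tuple[EntityMention, ...]]] = [{}]
        for role, ms in sorted(e.args.items()):
            new_variants = []
            options_per_arg: list[list[EntityMention]] = []
            for m in ms:
                if m.span in by_span:
                    options_per_arg.append([
                        EntityMention(s, m.text, m.sem_type, m.source, m.ann_id)
                        for s in members[m.span]])
                else:
                    options_per_arg.append([m])
            combos = [[]]
            for options in options_per_arg:
                combos = [c + [o] for c in combos for o in options]
            for v in variants:
                for combo in combos:
                    nv = dict(v)
                    nv[role] = tuple(combo)
                    new_variants.append(nv)
            variants = new_variants
        for v in variants:
            out.append(Event(e.relation, e.trigger_span, e.trigger_text, v))
    return out


def _events_match(pred: Event, gold: Event,
                  tokens: list[tuple[int, int]]) -> bool:
    if pred.relation != gold.relation:
        return False
    if not approx_span_match(pred.trigger_span, gold.trigger_span, tokens):
        return False
    if set(pred.args) != set(gold.args):
        return False
    for role in gold.args:
        pspans = sorted(m.span for m in pred.args[role])
        gspans = sorted(m.span for m in gold.args[role])
        if len(pspans) != len(gspans):
            return False
        # greedy one-to-one span matching within the role
        unused = list(gspans)
        for ps in pspans:
            hit = next((gs for gs in unused
                        if approx_span_match(ps, gs, tokens)), None)
            if hit is None:
                return False
            unused.remove(hit)
    return True


def evaluate(pred: list[Event], gold: GoldSet,
             tokens: Optional[list[tuple[int, int]]] = None) -> EvalResult:
    """Score predictions against a gold set (greedy one-to-one matching in
    document order), per relation and overall."""
    if tokens is None:
        tokens = tokenize(gold.text)
    gold_expanded = _expand_gold(gold.events, gold.equiv_classes)
    matched_gold: set[int] = set()
    per: dict[str, list[int]] = {}

    def bucket(rel: str) -> list[int]:
        return per.setdefault(rel, [0, 0, 0])

    for p in sorted(pred, key=lambda e: (e.trigger_span, e.relation)):
        hit = None
        for gi, g in enumerate(gold_expanded):
            if gi in matched_gold:
                continue
            if _events_match(p, g, tokens):
                hit = gi
                break
        if hit is None:
            bucket(p.relation)[1] += 1
        else:
            matched_gold.add(hit)
            bucket(p.relation)[0] += 1
    for gi, g in enumerate(gold_expanded):
        if gi not in matched_gold:
            bucket(g.relation)[2] += 1

    tp = sum(v[0] for v in per.values())
    fp = sum(v[1] for v in per.values())
    fn = sum(v[2] for v in per.values())
    return EvalResult({k: tuple(v) for k, v in per.items()}, tp, fp, fn)
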