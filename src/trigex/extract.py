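"""Pattern matching and event extraction.

For every lexico-syntactic pattern the trigger occurrence is located on
the (variant) parse tree; the template's structural constraints are then
checked around it: the consecutive verb group is resolved to its last main
verb, adverbial and adjective-nominal adjuncts between trigger and
argument are skipped, the captured NP is semantically typed and checked
against the trigger specification's slot, and lexical guards are applied.
Successful captures become <trigger, NP_i> pairs in original document
coordinates; pairs sharing a trigger occurrence are combined into events.

The document pipeline is: simplification (+ attachment alternatives) ->
per-variant extraction -> span mapping -> referential-relation linking ->
homonym disambiguation -> pair combination -> deduplication.  Only
arguments backed by pre-annotated (.a1) mentions surface in final events,
mirroring the standoff format in which event arguments reference entity
annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .entities import EntityMention, heuristic_type, np_head, satisfies
from .linking import ReferentialLink, detect_links, resolve
from .simplify import (
    SentenceVariant,
    attachment_alternatives,
    map_span,
    simplify,
    variant_from_tree,
)
from .templates import (
    Event,
    LexicoSyntacticPattern,
    TriggerArgPair,
    pairs_to_events,
)
from .trees import ParseTree, match_all, parent_map, read_bracketed, verb_group_head

log = logging.getLogger(__name__)

__all__ = [
    "Document",
    "ExtractionConfig",
    "load_document",
    "extract_sentence",
    "extract_document",
    "disambiguate_homonyms",
]

_BE_FORMS = {"be", "is", "are", "was", "were", "been", "being", "am"}
_ADJUNCT_LABELS = {"ADVP", "RB", "RBR", "RBS", "PRT", "MD"}
_UNDERGO = {"undergo", "undergoes", "underwent", "undergone", "undergoing"}
_CAUSE_VERBS = {"induce", "induces", "induced", "inducing",
                "prevent", "prevents", "prevented", "preventing",
                "cause", "causes", "caused", "causing",
                "block", "blocks", "blocked", "blocking",
                "promote", "promotes", "promoted", "promoting",
                "inhibit", "inhibits", "inhibited", "inhibiting"}
_OBSERVE_VERBS = {"observed", "detected", "seen", "found"}
_RESULT_VERBS = {"result", "results", "resulted", "resulting"}
_NP_LABELS = ("NP", "NX", "NML")


@dataclass
class Document:
    """A parsed document: raw text, sentence offsets, one tree per sentence
    (leaf spans in whole-document coordinates) and pre-annotated mentions."""

    text: str
    sentences: list[tuple[int, int]]
    trees: list[ParseTree]
    mentions: list[EntityMention] = field(default_factory=list)


@dataclass
class ExtractionConfig:
    simplify: bool = True
    attachments: bool = True
    linking: bool = True
    max_variants: int = 64


def _shift_spans(tree: ParseTree, delta: int) -> None:
    for node in tree.preorder():
        node.span = (node.span[0] + delta, node.span[1] + delta)


def load_document(text: str, parse_lines: list[str],
                  sentences: Optional[list[tuple[int, int]]] = None,
                  mentions: Optional[list[EntityMention]] = None) -> Document:
    """Build a Document from raw text and one bracketed parse per sentence.

    Without explicit sentence offsets, sentences are taken as the text's
    non-empty lines.  Unreadable parses are skipped with a warning.
    """
    if sentences is None:
        sentences = []
        pos = 0
        for line in text.split("\n"):
            if line.strip():
                start = pos + (len(line) - len(line.lstrip()))
                sentences.append((start, pos + len(line.rstrip())))
            pos += len(line) + 1
    trees: list[ParseTree] = []
    kept: list[tuple[int, int]] = []
    for (start, end), parse in zip(sentences, parse_lines):
        try:
            tree = read_bracketed(parse, text[start:end])
        except ValueError as e:
            log.warning("skipping sentence at %d-%d: %s", start, end, e)
            continue
        _shift_spans(tree, start)
        trees.append(tree)
        kept.append((start, end))
    return Document(text, kept, trees, list(mentions or []))


# ----------------------------------------------------------------------
# Structural helpers around a trigger occurrence
# ----------------------------------------------------------------------


class _Ctx:
    def __init__(self, variant: SentenceVariant, mentions: list[EntityMention]):
        self.variant = variant
        self.tree = variant.tree
        self.parents = parent_map(variant.tree)
        self.mentions = mentions
        self.token_set = {t.lower() for t in variant.tree.tokens()}

    def parent(self, node: ParseTree) -> Optional[ParseTree]:
        return self.parents.get(id(node))

    def to_original(self, span: tuple[int, int]) -> tuple[int, int]:
        return map_span(self.variant, span)

    def mention_at(self, head: Optional[ParseTree],
                   np_span: tuple[int, int], text: str) -> EntityMention:
        """Type a captured phrase: pre-annotated mention overlapping the
        head wins; a sortal head ("Y mRNA") defers to the named modifier
        right before it; otherwise the head lexicon decides."""
        try:
            orig_np = self.to_original(np_span)
        except ValueError:
            orig_np = np_span
        if head is not None:
            try:
                h = self.to_original(head.span)
            except ValueError:
                h = head.span
            for m in self.mentions:
                if m.span[0] < h[1] and h[0] < m.span[1]:
                    return m
            if head.token.lower() in ("mrna", "mrnas", "transcript",
                                      "transcripts", "gene", "genes",
                                      "protein", "proteins"):
                prev = self._preceding_leaf(head)
                if prev is not None:
                    try:
                        p = self.to_original(prev.span)
                    except ValueError:
                        p = prev.span
                    for m in self.mentions:
                        if m.span[0] < p[1] and p[0] < m.span[1]:
                            return m
        else:
            # no head leaf (sub-token captures): overlap the span itself
            for m in self.mentions:
                if m.span[0] < orig_np[1] and orig_np[0] < m.span[1]:
                    return m
        # heuristic typing on the phrase itself
        word = head.token if head is not None else \
            (text.split()[-1] if text.split() else text)
        return EntityMention(orig_np, text, heuristic_type(word),
                             source="heuristic")

    def _preceding_leaf(self, leaf: ParseTree) -> Optional[ParseTree]:
        leaves = self.tree.leaves()
        for i, lv in enumerate(leaves):
            if lv is leaf:
                return leaves[i - 1] if i > 0 else None
        return None

    # -- verb-group geometry ------------------------------------------

    def max_verb_group(self, pre: ParseTree, trig: ParseTree
                       ) -> Optional[ParseTree]:
        vp = self.parent(pre)
        if vp is None or vp.label != "VP":
            return None
        while True:
            p = self.parent(vp)
            if p is None:
                break
            candidate = None
            if p.label == "VP":
                candidate = p
            elif p.label in ("S", "SBAR"):
                gp = self.parent(p)
                if gp is not None and gp.label == "VP":
                    candidate = gp
            if candidate is None:
                break
            try:
                if verb_group_head(candidate) is trig:
                    vp = candidate
                    continue
            except ValueError:
                pass
            break
        return vp

    def clause_subject(self, vp: ParseTree) -> Optional[ParseTree]:
        node = vp
        while True:
            p = self.parent(node)
            if p is None:
                return None
            if p.label in ("S", "SINV"):
                i = next(k for k, c in enumerate(p.children) if c is node)
                for c in reversed(p.children[:i]):
                    if c.label in _NP_LABELS:
                        return c
                    if c.label not in _ADJUNCT_LABELS and c.label not in (",",):
                        return None
                return None
            if p.label == "VP":
                node = p
                continue
            return None

    def is_passive(self, pre: ParseTree, max_vp: ParseTree,
                   trig: ParseTree) -> bool:
        if pre.label != "VBN":
            return False
        for node in max_vp.preorder():
            if node.is_leaf and node.span[1] <= trig.span[0] \
                    and node.token.lower() in _BE_FORMS:
                return True
        return False

    def object_np(self, inner_vp: ParseTree, pre: ParseTree
                  ) -> Optional[ParseTree]:
        after = False
        for c in inner_vp.children:
            if c is pre:
                after = True
                continue
            if not after:
                continue
            if c.label in _ADJUNCT_LABELS:
                continue
            if c.label in _NP_LABELS:
                return c
            if c.label in (",",):
                continue
            return None
        return None

    def pp_object(self, pre: ParseTree, max_vp: ParseTree,
                  preps: set[str]) -> Optional[ParseTree]:
        """First PP headed by one of ``preps`` among the verb group's VPs,
        innermost first; returns its NP object."""
        vp = self.parent(pre)
        chain = []
        while vp is not None and vp is not self.parent(max_vp):
            if vp.label == "VP":
                chain.append(vp)
            if vp is max_vp:
                break
            vp = self.parent(vp)
        for v in chain:
            for c in v.children:
                if c.label == "PP":
                    toks = c.tokens()
                    if toks and toks[0].lower() in preps:
                        np = next((x for x in c.children
                                   if x.label in _NP_LABELS), None)
                        if np is not None:
                            return np
        return None


def _pp_of_np(host: ParseTree, preps: set[str],
              after: Optional[ParseTree] = None) -> Optional[ParseTree]:
    started = after is None
    for c in host.children:
        if c is after:
            started = True
            continue
        if started and c.label == "PP":
            toks = c.tokens()
            if toks and toks[0].lower() in preps:
                return next((x for x in c.children if x.label in _NP_LABELS),
                            None)
    return None


def _conjunct_nps(np: ParseTree) -> list[ParseTree]:
    kids = [c for c in np.children if c.label in _NP_LABELS]
    if any(c.label == "CC" for c in np.children) and len(kids) >= 2:
        out: list[ParseTree] = []
        for k in kids:
            out.extend(_conjunct_nps(k))
        return out
    return [np]


@dataclass
class _Capture:
    """A candidate argument before typing/role assignment."""
    span: tuple[int, int]                  # variant coords
    text: str
    head: Optional[ParseTree] = None
    trigger_span: Optional[tuple[int, int]] = None   # override (N8)
    deferred: Optional[str] = None          # antecedent-recovery mode


# ----------------------------------------------------------------------
# Template-specific matching
# ----------------------------------------------------------------------


def _np_capture(np: ParseTree) -> _Capture:
    return _Capture(np.span, " ".join(np.tokens()), np_head(np))


def _match_verbal(tid: str, trig: ParseTree, ctx: _Ctx) -> list[_Capture]:
    pre = ctx.parent(trig)
    if pre is None or pre.label not in ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ"):
        return []
    max_vp = ctx.max_verb_group(pre, trig)
    if max_vp is None:
        return []
    try:
        if verb_group_head(max_vp) is not trig:
            return []
    except ValueError:
        return []
    passive = ctx.is_passive(pre, max_vp, trig)
    inner = ctx.parent(pre)

    if tid in ("V1", "V7"):
        if passive:
            return []
        subj = ctx.clause_subject(max_vp)
        return [_np_capture(subj)] if subj is not None else []
    if tid == "V2":
        if passive:
            return []
        obj = ctx.object_np(inner, pre)
        return [_np_capture(obj)] if obj is not None else []
    if tid == "V3":
        if not passive:
            return []
        subj = ctx.clause_subject(max_vp)
        return [_np_capture(subj)] if subj is not None else []
    if tid == "V4":
        if not passive:
            return []
        np = ctx.pp_object(pre, max_vp, {"by"})
        return [_np_capture(np)] if np is not None else []
    if tid == "V5":
        np = ctx.pp_object(pre, max_vp, {"with", "to", "at"})
        return [_np_capture(np)] if np is not None else []
    if tid == "V6":
        if passive or ctx.object_np(inner, pre) is not None:
            return []
        subj = ctx.clause_subject(max_vp)
        if subj is None or not any(c.label == "CC" for c in subj.children):
            return []
        return [_np_capture(c) for c in _conjunct_nps(subj)]
    return []


def _nominal_anchor(trig: ParseTree, ctx: _Ctx
                    ) -> Optional[tuple[ParseTree, ParseTree, ParseTree]]:
    """(preterminal, base NP, host NP) for a nominal trigger, requiring the
    trigger to head its noun phrase."""
    pre = ctx.parent(trig)
    if pre is None or pre.label not in ("NN", "NNS", "NNP", "NNPS"):
        return None
    np = ctx.parent(pre)
    if np is None or np.label not in _NP_LABELS:
        return None
    head = np_head(np)
    if head is not trig:
        return None
    host = ctx.parent(np)
    if host is None or host.label not in _NP_LABELS:
        host = np
    return pre, np, host


def _is_bare_nominal(pre: ParseTree, np: ParseTree, host: ParseTree) -> bool:
    if _pp_of_np(host, {"of"}) is not None:
        return False
    before = True
    for c in np.children:
        if c is pre:
            before = False
        elif before and c.label in ("NN", "NNS", "NNP", "NNPS"):
            return False
    return True


def _match_nominal(tid: str, trig: ParseTree, ctx: _Ctx) -> list[_Capture]:
    anchor = _nominal_anchor(trig, ctx)
    if tid == "N8":
        return _match_hyphenated(trig, ctx)
    if anchor is None:
        return []
    pre, np, host = anchor

    if tid == "N1":
        target = _pp_of_np(host, {"of"})
        return [_np_capture(target)] if target is not None else []
    if tid == "N2":
        nouns = []
        for c in np.children:
            if c is pre:
                break
            if c.label in ("NN", "NNS", "NNP", "NNPS"):
                nouns.append(c)
        if not nouns:
            return []
        span = (nouns[0].span[0], nouns[-1].span[1])
        text = " ".join(n.children[0].token for n in nouns)
        return [_Capture(span, text, nouns[-1].children[0])]
    if tid == "N3":
        target = _pp_of_np(host, {"by"})
        return [_np_capture(target)] if target is not None else []
    if tid == "N4":
        for c in np.children:
            if c is pre:
                break
            if c.label in _NP_LABELS and c.children \
                    and c.children[-1].label == "POS":
                owners = c.children[:-1]
                if not owners:
                    return []
                span = (owners[0].span[0], owners[-1].span[1])
                text = " ".join(t for o in owners for t in o.tokens())
                hd = np_head(ParseTree("NP", [o.copy() for o in owners]))
                # head copy loses identity; find the original leaf by span
                orig_head = None
                for o in owners:
                    for leaf in o.leaves():
                        if hd is not None and leaf.span == hd.span:
                            orig_head = leaf
                return [_Capture(span, text, orig_head)]
        return []
    if tid == "N5":
        if _pp_of_np(host, {"of"}) is None:
            return []
        target = _pp_of_np(host, {"to", "with"})
        return [_np_capture(target)] if target is not None else []
    if tid == "N6":
        target = _pp_of_np(host, {"between"})
        if target is None:
            return []
        return [_np_capture(c) for c in _conjunct_nps(target)]
    if tid == "N7":
        target = _pp_of_np(host, {"to", "with"})
        return [_np_capture(target)] if target is not None else []
    if tid == "N9":
        if _pp_of_np(host, {"of"}) is None:
            return []
        target = _pp_of_np(host, {"by"})
        return [_np_capture(target)] if target is not None else []
    return []


def _match_hyphenated(trig: ParseTree, ctx: _Ctx) -> list[_Capture]:
    token = trig.token
    idx = token.rfind("-")
    if idx <= 0:
        return []
    prefix_span = (trig.span[0], trig.span[0] + idx)
    trig_span = (trig.span[0] + idx + 1, trig.span[1])
    return [_Capture(prefix_span, token[:idx], None, trigger_span=trig_span)]


def _match_adjectival(tid: str, trig: ParseTree, ctx: _Ctx) -> list[_Capture]:
    pre = ctx.parent(trig)
    if pre is None:
        return []
    if tid in ("A1", "A2", "A3"):
        if pre.label not in ("JJ", "VBN", "VBG"):
            return []
        np = ctx.parent(pre)
        if np is None or np.label not in _NP_LABELS:
            return []
        head = np_head(np)
        if head is None or head is trig or head.span[0] < trig.span[1]:
            return []
        # capture the modified nominal, excluding the adjectival trigger
        rest = [c for c in np.children if c is not pre
                and c.label not in ("DT",)]
        if not rest:
            return []
        span = (min(c.span[0] for c in rest), max(c.span[1] for c in rest))
        text_toks = [t for c in rest for t in
                     ([c.token] if c.is_leaf else c.tokens())]
        return [_Capture(span, " ".join(text_toks), head)]
    if tid == "A4":
        if pre.label not in ("JJ", "VBN"):
            return []
        adjp = ctx.parent(pre)
        if adjp is None or adjp.label != "ADJP":
            return []
        vp = ctx.parent(adjp)
        if vp is None or vp.label != "VP":
            return []
        has_be = any(c.label.startswith("VB") and c.children
                     and c.children[0].token.lower() in _BE_FORMS
                     for c in vp.children)
        if not has_be:
            return []
        subj = ctx.clause_subject(vp)
        return [_np_capture(subj)] if subj is not None else []
    return []


def _matrix_subject(node: ParseTree, ctx: _Ctx) -> Optional[ParseTree]:
    current = node
    while True:
        p = ctx.parent(current)
        if p is None:
            return None
        if p.label in ("S", "SINV"):
            for c in p.children:
                if c.label in _NP_LABELS:
                    return c
                if c.label == "VP":
                    break
            current = p
            continue
        current = p


def _match_null(tid: str, trig: ParseTree, ctx: _Ctx) -> list[_Capture]:
    anchor = _nominal_anchor(trig, ctx)
    if anchor is None:
        return []
    pre, np, host = anchor
    if not _is_bare_nominal(pre, np, host):
        return []
    pp = ctx.parent(host)
    pp = pp if pp is not None and pp.label == "PP" else None
    first_prep = pp.tokens()[0].lower() if pp is not None and pp.tokens() else None

    if tid == "Z1":
        if first_prep != "via":
            return []
        vp = ctx.parent(pp)
        if vp is None or vp.label != "VP":
            return []
        obj = next((c for c in vp.children
                    if c.label in _NP_LABELS and c.span[1] <= pp.span[0]), None)
        return [_np_capture(obj)] if obj is not None else []
    if tid == "Z2":
        if first_prep not in ("upon", "after", "following"):
            return []
        subj = _matrix_subject(pp, ctx)
        if subj is not None and subj.span != host.span:
            return [_np_capture(subj)]
        return []
    if tid == "Z3":
        vp = ctx.parent(host)
        if vp is None or vp.label != "VP":
            return []
        verb = next((c for c in vp.children if c.label.startswith("VB")
                     and c.children
                     and c.children[0].token.lower() in _UNDERGO), None)
        if verb is None:
            return []
        subj = ctx.clause_subject(vp)
        return [_np_capture(subj)] if subj is not None else []
    if tid == "Z4":
        s = ctx.parent(host)
        if s is None or s.label not in ("S", "SINV"):
            return []
        vp = next((c for c in s.children if c.label == "VP"), None)
        if vp is None:
            return []
        try:
            head = verb_group_head(vp)
        except ValueError:
            return []
        has_be = any(t.lower() in _BE_FORMS for t in vp.tokens())
        if head.token.lower() in _OBSERVE_VERBS and has_be:
            return [_Capture(host.span, " ".join(host.tokens()),
                             deferred="antecedent_theme")]
        return []
    if tid == "Z5":
        vp = ctx.parent(host)
        if vp is None or vp.label != "VP":
            return []
        verb = next((c for c in vp.children if c.label.startswith("VB")
                     and c.children
                     and c.children[0].token.lower() in _CAUSE_VERBS), None)
        if verb is None or verb.span[0] > host.span[0]:
            return []
        return [_Capture(host.span, " ".join(host.tokens()),
                         deferred="antecedent_theme")]
    if tid == "Z6":
        if pp is None or first_prep != "in":
            return []
        vp = ctx.parent(pp)
        if vp is None or vp.label != "VP":
            return []
        verb = next((c for c in vp.children if c.label.startswith("VB")
                     and c.children
                     and c.children[0].token.lower() in _RESULT_VERBS), None)
        if verb is None:
            return []
        subj = ctx.clause_subject(vp)
        return [_np_capture(subj)] if subj is not None else []
    return []


_GROUP_DISPATCH = {
    "verbal": _match_verbal,
    "nominal": _match_nominal,
    "adjectival": _match_adjectival,
    "null_argument": _match_null,
}


# ----------------------------------------------------------------------
# Sentence- and document-level extraction
# ----------------------------------------------------------------------


def extract_sentence(variant: SentenceVariant,
                     patterns: list[LexicoSyntacticPattern],
                     mentions: list[EntityMention]) -> list[TriggerArgPair]:
    """Trigger-argument pairs extracted from one sentence variant, with
    spans mapped back to original-document coordinates."""
    ctx = _Ctx(variant, mentions)
    pairs: list[TriggerArgPair] = []
    deferred: list[tuple[LexicoSyntacticPattern, tuple[int, int]]] = []

    for pattern in patterns:
        surface = pattern.form.surface.lower()
        hyphen = pattern.template.constraints.get("shape") == "hyphenated"
        if hyphen:
            if not any(t.endswith("-" + surface) for t in ctx.token_set):
                continue
        elif surface not in ctx.token_set:
            continue
        for m in match_all(pattern.tree_pattern, ctx.tree):
            trig = m.bindings["trig"]
            if not trig.is_leaf:
                continue
            captures = _GROUP_DISPATCH[pattern.template.group](
                pattern.template_id, trig, ctx)
            for cap in captures:
                tspan_local = cap.trigger_span or trig.span
                try:
                    tspan = ctx.to_original(tspan_local)
                except ValueError:
                    continue
                if cap.deferred:
                    deferred.append((pattern, tspan))
                    continue
                pair = _make_pair(pattern, tspan, cap, ctx)
                if pair is not None:
                    pairs.append(pair)

    # null-argument antecedent recovery: the elided theme is an argument
    # determined by another trigger in the same sentence
    for pattern, tspan in deferred:
        spec = pattern.spec
        slot_idx = spec.theme_slots[0] if spec.theme_slots else 1
        try:
            slot = spec.slot(slot_idx)
        except KeyError:
            continue
        for other in pairs:
            if other.trigger_span == tspan or other.role != "theme":
                continue
            if not satisfies(other.arg, slot):
                continue
            pairs.append(TriggerArgPair(
                spec.relation, tspan, pattern.form.surface, slot_idx,
                other.arg, "theme",
                provenance=f"{pattern.template_id}+antecedent",
                directional=spec.direction == "directional",
                root=spec.root,
                guard_passed=slot_idx in spec.lexical_guards))
    return _dedup_pairs(pairs)


def _make_pair(pattern: LexicoSyntacticPattern, tspan: tuple[int, int],
               cap: _Capture, ctx: _Ctx) -> Optional[TriggerArgPair]:
    spec = pattern.spec
    mention = ctx.mention_at(cap.head, cap.span, cap.text)
    slot_idx = None
    for cand in pattern.slot_candidates or (pattern.template.captured_slot,):
        if cand is None:
            continue
        try:
            slot = spec.slot(cand)
        except KeyError:
            continue
        if satisfies(mention, slot):
            slot_idx = cand
            break
    if slot_idx is None:
        log.debug("type check failed: %s %s vs %s", pattern.template_id,
                  mention.sem_type, spec.relation)
        return None
    guard_ok = False
    guard = spec.lexical_guards.get(slot_idx)
    if guard is not None:
        arg_tokens = {t.lower() for t in cap.text.split()}
        if guard.lower() not in arg_tokens:
            log.debug("guard %r failed for %s", guard, spec.relation)
            return None
        guard_ok = True
    role = spec.roles.get(slot_idx, "theme")
    prov = pattern.template_id
    if ctx.variant.provenance:
        prov += "+" + ";".join(ctx.variant.provenance)
    return TriggerArgPair(
        spec.relation, tspan, pattern.form.surface, slot_idx, mention, role,
        provenance=prov, directional=spec.direction == "directional",
        root=spec.root, guard_passed=guard_ok)


def _dedup_pairs(pairs: list[TriggerArgPair]) -> list[TriggerArgPair]:
    seen: set[tuple] = set()
    out = []
    for p in pairs:
        key = (p.relation, p.trigger_span, p.slot, p.arg.span, p.role)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def disambiguate_homonyms(pairs: list[TriggerArgPair]) -> list[TriggerArgPair]:
    """Resolve competing specifications sharing one trigger occurrence.

    Only pairs whose type checks and guards succeeded exist at this point;
    when a guarded reading fires for an occurrence (e.g. Transcription's
    "mRNA" co-occurrence for "express"), the unguarded sibling readings of
    the same root are dropped for that occurrence.  Otherwise all surviving
    relations are proposed.
    """
    guarded: dict[tuple[str, tuple[int, int]], set[str]] = {}
    for p in pairs:
        if p.guard_passed:
            guarded.setdefault((p.root, p.trigger_span), set()).add(p.relation)
    out = []
    for p in pairs:
        winners = guarded.get((p.root, p.trigger_span))
        if winners is not None and p.relation not in winners:
            continue
        out.append(p)
    return out


def _sentence_variants(tree: ParseTree, config: ExtractionConfig
                       ) -> list[SentenceVariant]:
    if not config.simplify:
        return [variant_from_tree(tree, [])]
    variants = simplify(tree, max_variants=config.max_variants)
    if config.attachments:
        for alt in attachment_alternatives(tree):
            budget = config.max_variants - len(variants)
            if budget <= 0:
                break
            # re-expand each attachment reading; its offset map already
            # points at the original sentence because surgery preserves
            # leaf spans
            sub = simplify(alt.tree, max_variants=max(1, budget))
            for v in sub:
                v.provenance = ["attach:" + (alt.attachment_choice or "?")] \
                    + v.provenance
                # compose offset maps: alt.tree spans are variant-local,
                # map them through alt's own offset map
                v.offset_map = [
                    alt.offset_map[i] if i is not None
                    and i < len(alt.offset_map) else None
                    for i in v.offset_map]
                variants.append(v)
    seen: set[str] = set()
    unique = []
    for v in variants:
        key = v.text + "|" + ";".join(v.provenance)
        if key not in seen:
            seen.add(key)
            unique.append(v)
    return unique


def extract_document(doc: Document,
                     patterns: list[LexicoSyntacticPattern],
                     config: Optional[ExtractionConfig] = None,
                     external_links: Optional[list[ReferentialLink]] = None
                     ) -> list[Event]:
    """Run the full pipeline over a document and return its events."""
    config = config or ExtractionConfig()
    all_pairs: list[TriggerArgPair] = []
    for tree in doc.trees:
        for variant in _sentence_variants(tree, config):
            all_pairs.extend(extract_sentence(variant, patterns, doc.mentions))
    all_pairs = _dedup_pairs(all_pairs)

    if config.linking:
        links = detect_links(doc.trees, doc.mentions)
        if external_links:
            links = links + list(external_links)
        slot_of = {}
        for p in patterns:
            for s in p.spec.slots:
                slot_of[(p.spec.relation, p.spec.root, s.index)] = s
        resolved: list[TriggerArgPair] = []
        for pair in all_pairs:
            slot = slot_of.get((pair.relation, pair.root, pair.slot))
            resolved.extend(resolve(pair, links, doc.mentions, slot))
        all_pairs = _dedup_pairs(resolved)

    all_pairs = disambiguate_homonyms(all_pairs)
    # only arguments backed by pre-annotated mentions surface in events
    final_pairs = [p for p in all_pairs if p.arg.informative]
    events = pairs_to_events(final_pairs)
    events.sort(key=lambda e: (e.trigger_span, e.relation, sorted(e.args)))
    return events
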