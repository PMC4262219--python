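"""Referential-relation detection and recursive argument linking.

When a pattern captures an argument that is not an informative named
entity ("the earliest genes", "the protein"), the actual target entity is
often given elsewhere through a referential relation: part-whole ("the
Prf1 locus" -> Prf1), member-collection ("adhesion molecules including
integrin alpha, ..."), hyponymy ("CD14, a membrane glycoprotein" / "acts
as"), apposition, or a relative-pronoun coreference.  General pronominal
coreference is deliberately not built in -- an external resolver's links
can be registered through the same interface.

``resolve`` rewrites a trigger-argument pair by recursively following the
detected links until informative mentions are reached, with a visited set
so arbitrary (even cyclic) link graphs terminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .entities import EntityMention, np_head, type_np
from .simplify import detect_constructs
from .templates import TriggerArgPair
from .trees import ParseTree, parent_map
from .triggers import ArgSlot

__all__ = [
    "ReferentialLink",
    "detect_links",
    "resolve",
    "register_external_coref",
    "parse_coref_file",
]

LINK_KINDS = {"part_whole", "member_collection", "hyponymy", "apposition",
              "relpronoun_coref", "coref"}

_PART_HEADS = {"locus", "loci", "promoter", "promoters", "domain", "domains",
               "residue", "residues", "site", "sites", "motif", "motifs",
               "region", "regions", "subunit", "subunits", "terminus",
               "fragment", "fragments"}
_MEMBER_CUES = ("such as", "including", "e.g.", "e.g. ,", "for example")
_HYPONYMY_VERBS = {"acts", "act", "acted", "serves", "serve", "served"}
_HYPONYMY_PPARTS = {"identified", "described", "defined", "recognized",
                    "characterized", "classified"}
_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "both",
                "its", "their", "such"}


@dataclass(frozen=True)
class ReferentialLink:
    """A typed link between two mentions of the same document.

    ``source``/``target`` follow the relation's natural direction:
    part->whole, member->collection, hyponym->hypernym, appositive->referent,
    pronoun->referent.
    """

    kind: str
    source: EntityMention
    target: EntityMention

    def __post_init__(self):
        if self.kind not in LINK_KINDS:
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.source.span == self.target.span:
            raise ValueError("a link must join two distinct spans")


def _norm_text(text: str) -> str:
    words = text.lower().split()
    while words and words[0] in _DETERMINERS:
        words = words[1:]
    return " ".join(words)


def _mention_for(np: ParseTree, mentions: list[EntityMention]) -> EntityMention:
    return type_np(np, mentions)


def _inner_named_mention(np: ParseTree, mentions: list[EntityMention],
                         exclude: Optional[ParseTree] = None
                         ) -> Optional[EntityMention]:
    lo, hi = np.span
    ex = exclude.span if exclude is not None else None
    for m in mentions:
        if lo <= m.span[0] and m.span[1] <= hi:
            if ex is not None and m.span[0] < ex[1] and ex[0] < m.span[1]:
                continue
            return m
    return None


def _conjunct_nps(np: ParseTree) -> list[ParseTree]:
    """The conjunct NPs of a coordinated NP, or the NP itself."""
    kids = [c for c in np.children if c.label == "NP"]
    if any(c.label == "CC" for c in np.children) and len(kids) >= 2:
        out = []
        for k in kids:
            out.extend(_conjunct_nps(k))
        return out
    return [np]


def detect_links(trees: list[ParseTree],
                 mentions: list[EntityMention]) -> list[ReferentialLink]:
    """All referential links found in the document's parses."""
    links: list[ReferentialLink] = []

    def add(kind: str, source: EntityMention, target: EntityMention):
        if source.span != target.span:
            links.append(ReferentialLink(kind, source, target))

    for tree in trees:
        parents = parent_map(tree)
        for node in tree.preorder():
            if node.is_leaf:
                continue

            # (i) part-whole by part-keyword heads: "the Prf1 locus"
            if node.label in ("NP", "NX", "NML"):
                head = np_head(node)
                if head is not None and head.token.lower() in _PART_HEADS:
                    whole = _inner_named_mention(node, mentions, exclude=head)
                    if whole is not None:
                        part = EntityMention(node.span, " ".join(node.tokens()),
                                             _part_type(head.token.lower()))
                        add("part_whole", part, whole)

            # (i') clause pattern NP_whole contains NP_part
            if node.label == "VP" and node.children:
                verb = node.children[0]
                word = (verb.children[0].token if verb.children else verb.token)
                if verb.label.startswith("VB") and word and \
                        word.lower() in ("contains", "contain", "comprises",
                                         "comprise", "harbors", "harbor"):
                    obj = next((c for c in node.children[1:] if c.label == "NP"),
                               None)
                    subj = _clause_subject(node, parents)
                    if obj is not None and subj is not None:
                        add("part_whole", _mention_for(obj, mentions),
                            _mention_for(subj, mentions))

            # (ii) member-collection: NP , such as / including NP(, NP)*
            if node.label in ("NP", "NX", "NML"):
                coll = None
                for i, child in enumerate(node.children):
                    if child.label in ("NP", "NX", "NML"):
                        coll = child
                    elif child.label == "PP" and coll is not None:
                        lead = " ".join(child.tokens()[:2]).lower()
                        first = child.tokens()[0].lower() if child.tokens() else ""
                        if lead.startswith("such as") or \
                                first in ("including", "e.g."):
                            inner = next((c for c in child.children
                                          if c.label == "NP"), None)
                            if inner is None:
                                continue
                            coll_m = _mention_for(coll, mentions)
                            for member in _conjunct_nps(inner):
                                add("member_collection",
                                    _mention_for(member, mentions), coll_m)
                # "one of NP / some of NP": the of-object is the collection
                head = np_head(node)
                if head is not None and head.token.lower() in (
                        "one", "some", "several", "many", "each", "most"):
                    pp = next((c for c in node.children if c.label == "PP"
                               and c.tokens() and c.tokens()[0].lower() == "of"),
                              None)
                    if pp is not None:
                        inner = next((c for c in pp.children if c.label == "NP"),
                                     None)
                        if inner is not None:
                            member = EntityMention((head.span[0], head.span[1]),
                                                   head.token, "class_noun")
                            add("member_collection", member,
                                _mention_for(inner, mentions))

            # (iii) hyponymy cues: acts as / is identified as / is a(n)
            if node.label == "VP" and node.children:
                subj = _clause_subject(node, parents)
                if subj is None:
                    continue
                hypernym_np = _hyponymy_complement(node)
                if hypernym_np is not None:
                    add("hyponymy", _mention_for(subj, mentions),
                        _mention_for(hypernym_np, mentions))

        # (iv) appositions and (v) relative-pronoun coreference
        for construct in detect_constructs(tree):
            if construct.kind == "apposition":
                add("apposition",
                    _mention_for(construct.parts[0], mentions),
                    _mention_for(construct.referent, mentions))
            elif construct.kind == "relative_clause_full":
                sbar = construct.parts[0]
                wh = next((c for c in sbar.children
                           if c.label in ("WHNP", "WHADVP")), None)
                if wh is not None:
                    pron = EntityMention(wh.span, " ".join(wh.tokens()),
                                         "other")
                    add("relpronoun_coref", pron,
                        _mention_for(construct.referent, mentions))
    return links


def _part_type(head: str) -> str:
    return "gene_part" if head in ("locus", "loci", "promoter", "promoters") \
        else "protein_part"


def _clause_subject(vp: ParseTree, parents: dict[int, ParseTree]
                    ) -> Optional[ParseTree]:
    node = vp
    while id(node) in parents:
        parent = parents[id(node)]
        if parent.label in ("S", "SINV"):
            i = next(k for k, c in enumerate(parent.children) if c is node)
            for c in reversed(parent.children[:i]):
                if c.label == "NP":
                    return c
            return None
        if parent.label != "VP":
            return None
        node = parent
    return None


def _hyponymy_complement(vp: ParseTree) -> Optional[ParseTree]:
    kids = vp.children
    verb = kids[0]
    if not verb.label.startswith("VB") or not verb.children:
        return None
    word = verb.children[0].token.lower()
    # "acts as NP"
    if word in _HYPONYMY_VERBS:
        pp = next((c for c in kids if c.label == "PP" and c.tokens()
                   and c.tokens()[0].lower() == "as"), None)
        if pp is not None:
            return next((c for c in pp.children if c.label == "NP"), None)
    # "is identified as NP" (passive participle inside the be-group)
    if word in ("is", "are", "was", "were", "be", "been"):
        inner = next((c for c in kids if c.label == "VP"), None)
        if inner is not None and inner.children and \
                inner.children[0].label == "VBN" and \
                inner.children[0].children and \
                inner.children[0].children[0].token.lower() in _HYPONYMY_PPARTS:
            pp = next((c for c in inner.children if c.label == "PP"
                       and c.tokens() and c.tokens()[0].lower() == "as"), None)
            if pp is not None:
                return next((c for c in pp.children if c.label == "NP"), None)
        # copula "is a/an NP"
        obj = next((c for c in kids if c.label == "NP"), None)
        if obj is not None and obj.children and obj.children[0].label == "DT":
            return obj
    return None


# ----------------------------------------------------------------------
# Recursive linking
# ----------------------------------------------------------------------


def _matches(arg_span: tuple[int, int], arg_norm: str,
             endpoint: EntityMention) -> bool:
    s, e = endpoint.span
    if arg_span[0] < e and s < arg_span[1]:
        return True
    return arg_norm != "" and _norm_text(endpoint.text) == arg_norm


def _overlap(span: tuple[int, int], endpoint: EntityMention) -> bool:
    s, e = endpoint.span
    return span[0] < e and s < span[1]


def _substitutions(current_span: tuple[int, int], current_norm: str,
                   links: list[ReferentialLink]) -> list[EntityMention]:
    """Mentions reachable from the current argument in one link step.

    Directions: collection->member, part->whole, hypernym->hyponym,
    apposition both ways, pronoun->referent, external coref both ways.
    An endpoint is matched by span overlap, or -- for a definite phrase
    repeated elsewhere in the document -- by surface identity after
    determiner stripping, in which case only the nearest occurrence
    counts (preferring a preceding one, as for definite anaphora).
    """
    by_overlap: list[EntityMention] = []
    by_text: list[tuple[EntityMention, EntityMention]] = []  # (endpoint, sub)

    def consider(endpoint: EntityMention, substitution: EntityMention,
                 allow_text: bool = False):
        if _overlap(current_span, endpoint):
            by_overlap.append(substitution)
        elif allow_text and current_norm \
                and _norm_text(endpoint.text) == current_norm:
            by_text.append((endpoint, substitution))

    for link in links:
        # apposition, relative pronouns, parts and collections are
        # sentence-internal: matched by overlap only.  Hyponymy and
        # external coreference may bridge a repeated definite phrase.
        if link.kind == "member_collection":
            consider(link.target, link.source)
        elif link.kind == "part_whole":
            consider(link.source, link.target)
        elif link.kind == "hyponymy":
            consider(link.target, link.source, allow_text=True)
        elif link.kind == "apposition":
            consider(link.source, link.target)
            consider(link.target, link.source)
        elif link.kind == "coref":
            consider(link.source, link.target, allow_text=True)
            consider(link.target, link.source, allow_text=True)
        elif link.kind == "relpronoun_coref":
            consider(link.source, link.target)

    out = list(by_overlap)
    if by_text:
        def distance(item):
            start = item[0].span[0]
            preceding = start < current_span[0]
            return (0 if preceding else 1, abs(current_span[0] - start))
        out.append(min(by_text, key=distance)[1])
    return out


def resolve(pair: TriggerArgPair, links: list[ReferentialLink],
            mentions: list[EntityMention],
            slot: Optional[ArgSlot] = None) -> list[TriggerArgPair]:
    """Rewrite a pair whose argument is not an informative named entity.

    Follows the link graph breadth-first from the argument, collecting
    every reachable informative mention; each is re-type-checked against
    the slot (when given) and yields one rewritten pair.  A visited set
    guarantees termination on any graph, including cycles.  If nothing
    informative is reachable the original pair is returned unchanged.
    """
    from .entities import satisfies

    if pair.arg.informative:
        return [pair]

    def snap(m: EntityMention) -> EntityMention:
        """Snap a link endpoint onto a pre-annotated mention it covers."""
        if m.informative:
            return m
        for pre in mentions:
            if pre.informative and m.span[0] <= pre.span[0] \
                    and pre.span[1] <= m.span[1]:
                return pre
        return m

    visited: set[tuple] = set()
    frontier: list[EntityMention] = [pair.arg]
    visited.add((pair.arg.span, _norm_text(pair.arg.text)))
    found: list[EntityMention] = []
    while frontier:
        current = frontier.pop(0)
        cur_norm = _norm_text(current.text)
        for nxt in _substitutions(current.span, cur_norm, links):
            nxt = snap(nxt)
            key = (nxt.span, _norm_text(nxt.text))
            if key in visited:
                continue
            visited.add(key)
            if nxt.informative:
                found.append(nxt)
            else:
                # keep searching through uninformative intermediates until
                # all possibilities are exhausted
                frontier.append(nxt)

    results: list[TriggerArgPair] = []
    for m in found:
        if slot is not None and not satisfies(m, slot):
            continue
        results.append(TriggerArgPair(
            pair.relation, pair.trigger_span, pair.trigger_form, pair.slot,
            m, pair.role, pair.provenance + "+linked", pair.directional))
    return results if results else [pair]


def register_external_coref(link_store: list[ReferentialLink],
                            links: list[ReferentialLink],
                            text_length: Optional[int] = None) -> None:
    """Merge links produced by an external anaphora resolver into the
    document link set.  Malformed spans are rejected with an error."""
    for link in links:
        for m in (link.source, link.target):
            if m.span[0] < 0 or m.span[1] <= m.span[0]:
                raise ValueError(f"malformed span {m.span}")
            if text_length is not None and m.span[1] > text_length:
                raise ValueError(f"span {m.span} outside document")
        link_store.append(link)


def parse_coref_file(content: str, doc_text: str) -> list[ReferentialLink]:
    """Tab-separated external links: source_start, source_end, target_start,
    target_end, kind."""
    links: list[ReferentialLink] = []
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 5 tab-separated fields")
        try:
            ss, se, ts, te = (int(p) for p in parts[:4])
        except ValueError:
            raise ValueError(f"line {lineno}: bad span") from None
        kind = parts[4]
        if kind not in LINK_KINDS:
            raise ValueError(f"line {lineno}: unknown kind {kind!r}")
        src = EntityMention((ss, se), doc_text[ss:se], "other")
        tgt = EntityMention((ts, te), doc_text[ts:te], "other")
        links.append(ReferentialLink(kind, src, tgt))
    return links
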