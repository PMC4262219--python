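"""Sentence simplification by parse-tree surgery.

Complex constructs -- coordinations, full and reduced relative clauses,
appositions and parenthesized elements -- are detected on the parse and
the sentence is rewritten into simpler variants: one per conjunct for a
coordination; clause-removed plus "referent + clause" for a relative
clause; referent-only plus appositive/parenthesized-content for
appositions and parentheticals.  Nested constructs expand recursively
(bounded by ``max_variants``).  Variants are produced by node deletion and
promotion on the input parse, never by re-parsing, and each variant keeps
a per-character offset map back to the original sentence so extractions
can be reported in original coordinates.

Attachment ambiguities ("NP1 of NP2 + relative clause", "NP1 and NP2 PP",
"Adj NP1 and NP2") are not resolved here: one variant per reading is
produced and the extractor's type checks select among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .trees import ParseTree, parent_map

__all__ = [
    "Construct",
    "SentenceVariant",
    "detect_constructs",
    "simplify",
    "attachment_alternatives",
    "map_span",
]

_REL_PRONOUNS = {"which", "who", "that", "whom", "whose", "where"}
_NOMINAL = {"NP", "NX", "NML", "NN", "NNS", "NNP", "NNPS"}
_VERBAL = {"VP", "VB", "VBD", "VBG", "VBN", "VBP", "VBZ"}
_PUNCT = {",", ":", ";", ".", "``", "''"}


@dataclass
class Construct:
    kind: str                      # coordination | relative_clause_full |
                                   # relative_clause_reduced | apposition |
                                   # parenthetical
    anchor: ParseTree
    parts: list[ParseTree]
    referent: Optional[ParseTree] = None

    def __post_init__(self):
        if self.kind == "coordination" and len(self.parts) < 2:
            raise ValueError("coordination requires at least two conjuncts")
        if self.kind in ("relative_clause_full", "relative_clause_reduced",
                         "apposition") and self.referent is None:
            raise ValueError(f"{self.kind} requires a referent")


@dataclass
class SentenceVariant:
    text: str
    tree: ParseTree
    offset_map: list[Optional[int]]   # variant char -> original char (None: glue)
    provenance: list[str] = field(default_factory=list)
    attachment_choice: Optional[str] = None

    def map_back(self, span: tuple[int, int]) -> tuple[int, int]:
        return map_span(self, span)


def _label_class(label: str) -> str:
    if label in _NOMINAL:
        return "N"
    if label in _VERBAL:
        return "V"
    if label in ("S", "SBAR", "SINV"):
        return "S"
    if label in ("ADJP", "JJ", "JJR", "JJS"):
        return "A"
    return label


def _first_leaf(node: ParseTree) -> Optional[ParseTree]:
    while not node.is_leaf:
        if not node.children:
            return None
        node = node.children[0]
    return node


def _is_full_relative(sbar: ParseTree) -> bool:
    if sbar.label != "SBAR":
        return False
    for child in sbar.children:
        if child.label in ("WHNP", "WHPP"):
            return True
        break
    leaf = _first_leaf(sbar)
    return leaf is not None and leaf.token.lower() in _REL_PRONOUNS


def detect_constructs(tree: ParseTree) -> list[Construct]:
    """All simplifiable constructs in the tree, in pre-order.

    Appositive detection requires the second NP to begin with a determiner
    or a number, and never fires inside a coordination.
    """
    out: list[Construct] = []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        kids = node.children
        labels = [c.label for c in kids]

        # coordination
        cc_positions = [i for i, c in enumerate(kids)
                        if c.label == "CC" and _first_leaf(c) is not None
                        and _first_leaf(c).token.lower() in ("and", "or", "but")]
        if cc_positions:
            first_cc = cc_positions[0]
            anchor_conjunct = None
            for c in reversed(kids[:first_cc]):
                if c.label not in _PUNCT and c.label != "CC":
                    anchor_conjunct = c
                    break
            if anchor_conjunct is not None:
                cls = _label_class(anchor_conjunct.label)
                conjuncts = [c for c in kids
                             if c.label not in _PUNCT and c.label != "CC"
                             and _label_class(c.label) == cls]
                if len(conjuncts) >= 2 and any(
                        kids.index(c) > first_cc for c in conjuncts):
                    out.append(Construct("coordination", node, conjuncts))

        # relative clauses and appositions attach inside an NP
        if node.label in ("NP", "WHNP", "NX", "NML"):
            has_cc = any(c.label == "CC" for c in kids)
            for i, child in enumerate(kids):
                ref = _preceding_np(kids, i)
                if child.label == "SBAR" and _is_full_relative(child) and ref is not None:
                    out.append(Construct("relative_clause_full", node,
                                         [child], ref))
                elif (child.label == "VP" and ref is not None
                      and child.children
                      and child.children[0].label in ("VBG", "VBN")):
                    out.append(Construct("relative_clause_reduced", node,
                                         [child], ref))
                elif (child.label in ("NP", "NX", "NML") and ref is not None
                      and not has_cc
                      and i >= 2 and kids[i - 1].label == ","
                      and child.children
                      and child.children[0].label in ("DT", "CD")):
                    out.append(Construct("apposition", node, [child], ref))

        # parentheticals: PRN node, or an inline -LRB- ... -RRB- stretch
        for i, child in enumerate(kids):
            if child.label == "PRN":
                content = [c for c in child.children
                           if c.label not in ("-LRB-", "-RRB-", "-LSB-",
                                              "-RSB-", "-LCB-", "-RCB-")]
                ref = _preceding_np(kids, i)
                if content:
                    out.append(Construct("parenthetical", node, content, ref))
        if "-LRB-" in labels and "-RRB-" in labels:
            lo, hi = labels.index("-LRB-"), labels.index("-RRB-")
            if hi > lo + 1:
                content = kids[lo + 1:hi]
                ref = _preceding_np(kids, lo)
                out.append(Construct("parenthetical", node, content, ref))
    return out


def _preceding_np(kids: list[ParseTree], i: int) -> Optional[ParseTree]:
    for c in reversed(kids[:i]):
        if c.label in ("NP", "NX", "NML"):
            return c
        if c.label not in _PUNCT:
            break
    return None


# ----------------------------------------------------------------------
# Variant construction
# ----------------------------------------------------------------------


def _node_path(root: ParseTree, target: ParseTree) -> Optional[list[int]]:
    if root is target:
        return []
    for i, child in enumerate(root.children):
        sub = _node_path(child, target)
        if sub is not None:
            return [i] + sub
    return None


def _at_path(root: ParseTree, path: list[int]) -> ParseTree:
    node = root
    for i in path:
        node = node.children[i]
    return node


def variant_from_tree(tree: ParseTree, provenance: list[str],
                      attachment: Optional[str] = None) -> SentenceVariant:
    """Materialize a surgered tree (leaves still carrying original spans)
    into a SentenceVariant with variant-local spans and an offset map."""
    work = tree.copy()
    chunks: list[str] = []
    offset_map: list[Optional[int]] = []
    pos = 0
    for leaf in work.leaves():
        if chunks:
            chunks.append(" ")
            offset_map.append(None)
            pos += 1
        start = pos
        orig0 = leaf.span[0]
        for k, _ch in enumerate(leaf.token):
            offset_map.append(orig0 + k if leaf.span[1] - orig0 == len(leaf.token)
                              else None)
        pos += len(leaf.token)
        chunks.append(leaf.token)
        leaf.span = (start, pos)
    work.recompute_spans()
    return SentenceVariant("".join(chunks), work, offset_map,
                           list(provenance), attachment)


def map_span(variant: SentenceVariant, span: tuple[int, int]) -> tuple[int, int]:
    """Translate a variant-coordinate span into original coordinates."""
    mapped = [variant.offset_map[i] for i in range(span[0], min(span[1], len(variant.offset_map)))
              if variant.offset_map[i] is not None]
    if not mapped:
        raise ValueError(f"span {span} covers inserted glue only")
    return (min(mapped), max(mapped) + 1)


def _strip_adjacent_punct(node: ParseTree, idx: int) -> None:
    """Remove a child together with a neighbouring comma."""
    del node.children[idx]
    if idx < len(node.children) and node.children[idx].label == ",":
        del node.children[idx]
    elif idx > 0 and node.children[idx - 1].label == ",":
        del node.children[idx - 1]


def _apply_construct(root: ParseTree, construct: Construct) -> list[tuple[ParseTree, str]]:
    """Variant trees (copies of ``root``) for one construct, with step labels."""
    results: list[tuple[ParseTree, str]] = []
    anchor_path = _node_path(root, construct.anchor)
    if anchor_path is None:
        return results
    tag = f"{construct.kind}@{construct.anchor.span[0]}-{construct.anchor.span[1]}"

    if construct.kind == "coordination":
        member_idxs = []
        for part in construct.parts:
            p = _node_path(root, part)
            if p is not None:
                member_idxs.append(p[-1])
        for keep in member_idxs:
            copy = root.copy()
            node = _at_path(copy, anchor_path)
            node.children = [
                c for j, c in enumerate(node.children)
                if j == keep or (j not in member_idxs
                                 and c.label != "CC" and c.label not in (",", ";", ":"))
            ]
            results.append((copy, f"{tag}:conjunct{keep}"))
        return results

    if construct.kind in ("relative_clause_full", "relative_clause_reduced"):
        clause = construct.parts[0]
        clause_idx = _node_path(root, clause)[-1]
        # (a) original without the clause
        copy = root.copy()
        node = _at_path(copy, anchor_path)
        _strip_adjacent_punct(node, clause_idx)
        results.append((copy, f"{tag}:removed"))
        # (b) referent as subject of the clause (subject relatives only)
        body = clause
        if construct.kind == "relative_clause_full":
            inner = [c for c in clause.children if c.label in ("S", "VP")]
            body = inner[-1] if inner else None
        if body is not None:
            body_kids = body.children if body.label == "S" else [body]
            first_np = next((c for c in body_kids if c.label == "NP"), None)
            has_vp = any(c.label == "VP" for c in body_kids)
            if first_np is None and has_vp:
                new_s = ParseTree("S", [construct.referent.copy()]
                                 + [c.copy() for c in body_kids
                                    if c.label not in _PUNCT])
                results.append((new_s, f"{tag}:clause"))
        return results

    if construct.kind == "apposition":
        appositive = construct.parts[0]
        for replacement, label in ((construct.referent, "referent"),
                                   (appositive, "appositive")):
            copy = root.copy()
            node = _at_path(copy, anchor_path)
            node.children = [replacement.copy()]
            results.append((copy, f"{tag}:{label}"))
        return results

    if construct.kind == "parenthetical":
        part_paths = [_node_path(root, p) for p in construct.parts]
        covered = {tuple(p) for p in part_paths if p is not None}
        # child indices of the anchor that belong to the parenthetical,
        # including the PRN wrapper or the bracket leaves around the content
        first = min(p[len(anchor_path)] for p in part_paths)
        last = max(p[len(anchor_path)] for p in part_paths)
        kids = construct.anchor.children
        if 0 < first and kids[first - 1].label == "-LRB-":
            first -= 1
        if last + 1 < len(kids) and kids[last + 1].label == "-RRB-":
            last += 1
        if kids[first].label == "PRN":
            last = first
        # (a) without the parenthetical
        copy = root.copy()
        node = _at_path(copy, anchor_path)
        node.children = node.children[:first] + node.children[last + 1:]
        results.append((copy, f"{tag}:removed"))
        # (b) content substituted for the preceding noun phrase
        if construct.referent is not None:
            ref_path = _node_path(root, construct.referent)
            copy = root.copy()
            node = _at_path(copy, anchor_path)
            content_copies = [p.copy() for p in construct.parts]
            ref_idx = ref_path[-1]
            new_children = []
            for j, c in enumerate(node.children):
                if j == ref_idx:
                    new_children.extend(content_copies)
                elif first <= j <= last:
                    continue
                else:
                    new_children.append(c)
            node.children = new_children
            results.append((copy, f"{tag}:content"))
        return results

    raise AssertionError(construct.kind)


def simplify(tree: ParseTree, constructs: Optional[list[Construct]] = None,
             max_variants: int = 64) -> list[SentenceVariant]:
    """Simplified sentence variants, original first.

    Constructs are applied one at a time, outermost first, and the results
    are expanded recursively, so intermediate and fully-simplified
    combinations all appear.  Deterministic; capped at ``max_variants``
    (truncation is silent beyond a stable prefix)."""
    import logging
    log = logging.getLogger(__name__)

    variants: list[SentenceVariant] = []
    seen_texts: set[str] = set()

    def push(t: ParseTree, prov: list[str]) -> Optional[SentenceVariant]:
        v = variant_from_tree(t, prov)
        if v.text in seen_texts:
            return None
        seen_texts.add(v.text)
        variants.append(v)
        return v

    push(tree, [])

    frontier: list[tuple[ParseTree, list[str]]] = [(tree, [])]
    while frontier:
        current, prov = frontier.pop(0)
        found = constructs if (constructs is not None and current is tree) \
            else detect_constructs(current)
        if not found:
            continue
        construct = found[0]
        for new_tree, step in _apply_construct(current, construct):
            if len(variants) >= max_variants:
                log.warning("variant cap (%d) reached; truncating expansion",
                            max_variants)
                return variants
            v = push(new_tree, prov + [step])
            if v is not None:
                frontier.append((new_tree, prov + [step]))
    return variants


# ----------------------------------------------------------------------
# Attachment alternatives
# ----------------------------------------------------------------------


def attachment_alternatives(tree: ParseTree) -> list[SentenceVariant]:
    """One full-sentence variant per alternative attachment reading.

    Covers: relative clause after "NP1 prep NP2" (attach to either NP);
    "NP1 and NP2 PP" (PP distributed over both conjuncts, or on the last
    conjunct only); "Adj NP1 and NP2" (adjective distributed, or on the
    first conjunct only).  Unambiguous trees yield an empty list.
    """
    out: list[SentenceVariant] = []

    for node in tree.preorder():
        if node.is_leaf or node.label != "NP":
            continue
        kids = node.children

        # NP1 prep NP2 + SBAR, clause attached high -> move it low
        for i, child in enumerate(kids):
            if child.label == "SBAR" and _is_full_relative(child):
                # the "NP1 prep NP2" complex precedes the clause either as
                # siblings or nested inside the preceding NP
                pp = next((c for c in reversed(kids[:i]) if c.label == "PP"), None)
                if pp is None:
                    prev_np = next((c for c in reversed(kids[:i])
                                    if c.label == "NP"), None)
                    if prev_np is not None:
                        pp = next((c for c in reversed(prev_np.children)
                                   if c.label == "PP"), None)
                if pp is None:
                    continue
                np2 = next((c for c in pp.children if c.label == "NP"), None)
                if np2 is None:
                    continue
                copy = tree.copy()
                host = _at_path(copy, _node_path(tree, node))
                clause = host.children[i]
                _strip_adjacent_punct(host, i)
                target = _at_path(copy, _node_path(tree, np2))
                target.children = [ParseTree("NP", target.children),
                                   clause]
                out.append(variant_from_tree(copy, ["attach"],
                                             "relclause->NP2"))
        # clause attached low inside the PP object -> move it high
        for pp in (c for c in kids if c.label == "PP"):
            inner = next((c for c in pp.children if c.label == "NP"), None)
            if inner is None:
                continue
            for j, sub in enumerate(inner.children):
                if sub.label == "SBAR" and _is_full_relative(sub):
                    copy = tree.copy()
                    inner_c = _at_path(copy, _node_path(tree, inner))
                    clause = inner_c.children[j]
                    _strip_adjacent_punct(inner_c, j)
                    host = _at_path(copy, _node_path(tree, node))
                    host.children = host.children + [clause]
                    out.append(variant_from_tree(copy, ["attach"],
                                                 "relclause->NP1"))

        # NP1 and NP2 PP
        cc_idx = [i for i, c in enumerate(kids) if c.label == "CC"]
        conj = [c for c in kids if c.label in ("NP", "NN", "NNS", "NNP")]
        if cc_idx and len(conj) >= 2 and kids and kids[-1].label == "PP":
            pp = kids[-1]
            a, b = conj[0], conj[-1]
            for keep, with_pp, label in ((a, True, "pp->both:first"),
                                         (b, True, "pp->both:last"),
                                         (a, False, "pp->last-only")):
                copy = tree.copy()
                host = _at_path(copy, _node_path(tree, node))
                new_kids = [keep.copy()]
                if with_pp:
                    new_kids.append(pp.copy())
                host.children = new_kids
                out.append(variant_from_tree(copy, ["attach"], label))

        # Adj NP1 and NP2
        jj_idx = next((i for i, c in enumerate(kids)
                       if c.label in ("JJ", "ADJP")), None)
        if jj_idx is not None and cc_idx and len(conj) >= 2 \
                and all(i > jj_idx for i in cc_idx):
            adj = kids[jj_idx]
            dets = [c for c in kids[:jj_idx] if c.label == "DT"]
            a, b = conj[0], conj[-1]
            for pieces, label in (([*dets, adj, a], "adj->both:first"),
                                  ([*dets, adj, b], "adj->both:last"),
                                  ([*dets, b], "adj->first-only")):
                copy = tree.copy()
                host = _at_path(copy, _node_path(tree, node))
                host.children = [p.copy() for p in pieces]
                out.append(variant_from_tree(copy, ["attach"], label))

    # drop alternatives identical to the original surface AND structure
    return out
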