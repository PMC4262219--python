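"""Constituency-tree data model, Penn-Treebank reader and tree-pattern matching.

Trees are consumed, never produced: the package operates on pre-parsed,
pre-tokenized sentences (one bracketed parse per sentence).  Every node
carries a character span into the source sentence so that extracted
triggers and arguments can be reported in standoff coordinates.

The pattern mini-language is a small tregex-like dialect sufficient to
express the template inventory:

    node      :=  LABEL | /regex/            (regex tested on label, and on
                                              the token for leaves)
    capture   :=  node '=' NAME
    relations :=  '<'  immediate child        '<<' descendant
                  '<:' sole child             '$'  following sibling
                  '.'  immediately precedes (surface order)
    A rel B, negation '!rel B', grouping '(...)', conjunction 'and'
    (all conjuncts anchor at the same node).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "ParseTree",
    "TreePattern",
    "TreeMatch",
    "ParseError",
    "AlignmentError",
    "PatternSyntaxError",
    "read_bracketed",
    "compile_pattern",
    "match_all",
    "verb_group_head",
]


class ParseError(ValueError):
    """Malformed bracketed parse."""


class AlignmentError(ValueError):
    """Leaf tokens could not be aligned with the sentence text."""


class PatternSyntaxError(ValueError):
    """Tree-pattern expression does not follow the mini-language grammar."""


# PTB bracket escapes -> surface characters
_PTB_UNESCAPE = {
    "-LRB-": "(", "-RRB-": ")",
    "-LSB-": "[", "-RSB-": "]",
    "-LCB-": "{", "-RCB-": "}",
}


class ParseTree:
    """A constituency-tree node with a character span.

    Leaves are word nodes: ``label`` equals the surface token and ``token``
    is set.  Pre-terminals (POS nodes) have exactly one word-node child.
    ``span`` is a 0-based half-open ``(start, end)`` interval into the
    source sentence.
    """

    __slots__ = ("label", "children", "token", "span")

    def __init__(self, label: str, children: Optional[list["ParseTree"]] = None,
                 token: Optional[str] = None, span: tuple[int, int] = (0, 0)):
        self.label = label
        self.children: list[ParseTree] = list(children) if children else []
        self.token = token
        self.span = span
        if (token is not None) and self.children:
            raise ParseError("a leaf cannot have children")

    # -- structure -----------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return self.token is not None

    def preorder(self) -> Iterator["ParseTree"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["ParseTree"]:
        return [n for n in self.preorder() if n.is_leaf]

    def tokens(self) -> list[str]:
        return [leaf.token for leaf in self.leaves()]

    def copy(self) -> "ParseTree":
        if self.is_leaf:
            return ParseTree(self.label, token=self.token, span=self.span)
        return ParseTree(self.label, [c.copy() for c in self.children], span=self.span)

    def find_all(self, label: str) -> list["ParseTree"]:
        return [n for n in self.preorder() if n.label == label]

    def recompute_spans(self) -> None:
        """Recompute internal-node spans bottom-up from leaf spans."""
        for child in self.children:
            child.recompute_spans()
        if not self.is_leaf:
            if self.children:
                self.span = (self.children[0].span[0], self.children[-1].span[1])

    def pformat(self) -> str:
        if self.is_leaf:
            return self.token
        inner = " ".join(c.pformat() for c in self.children)
        return f"({self.label} {inner})"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParseTree({self.pformat()!r}, span={self.span})"


def parent_map(root: ParseTree) -> dict[int, ParseTree]:
    """Map ``id(node) -> parent`` for every node below ``root``."""
    out: dict[int, ParseTree] = {}
    for node in root.preorder():
        for child in node.children:
            out[id(child)] = node
    return out


# ----------------------------------------------------------------------
# Bracketed-format reader
# ----------------------------------------------------------------------

_TOKENIZER = re.compile(r"\(|\)|[^\s()]+")


def read_bracketed(text: str, sentence: str) -> ParseTree:
    """Read one PTB bracketed parse and align leaf spans to ``sentence``.

    Leaf tokens must occur in ``sentence`` in order, separated only by
    whitespace.  PTB bracket escapes (``-LRB-`` etc.) are unescaped before
    alignment.
    """
    toks = _TOKENIZER.findall(text)
    if not toks:
        raise ParseError("empty parse string")
    pos = 0

    def parse_node() -> ParseTree:
        nonlocal pos
        if toks[pos] != "(":
            raise ParseError(f"expected '(' at token {pos}: {toks[pos]!r}")
        pos += 1
        if pos >= len(toks) or toks[pos] in "()":
            raise ParseError("missing node label")
        label = toks[pos]
        pos += 1
        children: list[ParseTree] = []
        while pos < len(toks) and toks[pos] != ")":
            if toks[pos] == "(":
                children.append(parse_node())
            else:
                word = _PTB_UNESCAPE.get(toks[pos], toks[pos])
                children.append(ParseTree(word, token=word))
                pos += 1
        if pos >= len(toks):
            raise ParseError("unbalanced brackets: missing ')'")
        pos += 1  # consume ')'
        return ParseTree(label, children)

    tree = parse_node()
    if pos != len(toks):
        raise ParseError("unbalanced brackets: trailing material")

    cursor = 0
    for leaf in tree.leaves():
        while cursor < len(sentence) and sentence[cursor].isspace():
            cursor += 1
        end = cursor + len(leaf.token)
        if sentence[cursor:end] != leaf.token:
            raise AlignmentError(
                f"token {leaf.token!r} does not align with sentence at offset {cursor}"
            )
        leaf.span = (cursor, end)
        cursor = end
    tree.recompute_spans()
    return tree


# ----------------------------------------------------------------------
# Pattern mini-language
# ----------------------------------------------------------------------

_RELS = ("<<", "<:", "<", "$", ".")


@dataclass(frozen=True)
class _Term:
    literal: Optional[str] = None
    regex: Optional[re.Pattern] = None

    def matches(self, node: ParseTree) -> bool:
        if self.literal is not None:
            return node.label == self.literal
        if self.regex.search(node.label):
            return True
        return node.token is not None and bool(self.regex.search(node.token))


@dataclass(frozen=True)
class _Relation:
    rel: str
    operand: "_NodeExpr"
    negated: bool = False


@dataclass(frozen=True)
class _NodeExpr:
    term: _Term
    capture: Optional[str] = None
    relations: tuple[_Relation, ...] = ()


@dataclass(frozen=True)
class TreePattern:
    """A compiled tree pattern: conjunction of node expressions anchored
    at the same node, with named captures."""

    expression: str
    conjuncts: tuple[_NodeExpr, ...] = field(repr=False)
    captures: tuple[str, ...] = ()


@dataclass(frozen=True)
class TreeMatch:
    """One match: each declared capture bound to a tree node."""

    bindings: dict[str, ParseTree] = field(hash=False)

    def span(self, name: str) -> tuple[int, int]:
        return self.bindings[name].span


_PAT_TOKEN = re.compile(
    r"\s*(<<|<:|<|\$|\.|\(|\)|!|=|and\b|/(?:[^/\\]|\\.)+/|[^\s()=!<>$.]+)"
)


def _lex(expr: str) -> list[tuple[str, int]]:
    out = []
    pos = 0
    while pos < len(expr):
        m = _PAT_TOKEN.match(expr, pos)
        if not m:
            if expr[pos:].strip() == "":
                break
            raise PatternSyntaxError(f"bad character at position {pos}: {expr[pos]!r}")
        out.append((m.group(1), m.start(1)))
        pos = m.end()
    return out


def compile_pattern(expr: str) -> TreePattern:
    """Compile a mini-language expression into a reusable :class:`TreePattern`."""
    toks = _lex(expr)
    idx = 0
    captures: list[str] = []

    def peek() -> Optional[str]:
        return toks[idx][0] if idx < len(toks) else None

    def err(msg: str):
        pos = toks[idx][1] if idx < len(toks) else len(expr)
        raise PatternSyntaxError(f"{msg} at position {pos}")

    def parse_term(in_negation: bool) -> tuple[_Term, Optional[str]]:
        nonlocal idx
        tok = peek()
        if tok is None or tok in {"(", ")", "!", "=", "and"} or tok in _RELS:
            err("expected node term")
        idx += 1
        if tok.startswith("/") and tok.endswith("/") and len(tok) > 1:
            try:
                term = _Term(regex=re.compile(tok[1:-1]))
            except re.error as e:
                err(f"bad regex ({e})")
        else:
            term = _Term(literal=tok)
        cap = None
        if peek() == "=":
            idx += 1
            name = peek()
            if name is None or name in {"(", ")", "!", "=", "and"} or name in _RELS:
                err("expected capture name")
            idx += 1
            if in_negation:
                err("captures are not allowed inside a negated relation")
            if name in captures:
                raise PatternSyntaxError(f"duplicate capture name {name!r}")
            captures.append(name)
            cap = name
        return term, cap

    def parse_node_expr(in_negation: bool) -> _NodeExpr:
        nonlocal idx
        term, cap = parse_term(in_negation)
        rels: list[_Relation] = []
        while peek() in _RELS or peek() == "!":
            neg = False
            if peek() == "!":
                neg = True
                idx += 1
            rel = peek()
            if rel not in _RELS:
                err("expected relation after '!'")
            idx += 1
            if peek() == "(":
                idx += 1
                operand = parse_node_expr(in_negation or neg)
                if peek() != ")":
                    err("expected ')'")
                idx += 1
            else:
                t, c = parse_term(in_negation or neg)
                operand = _NodeExpr(t, c)
            rels.append(_Relation(rel, operand, neg))
        return _NodeExpr(term, cap, tuple(rels))

    conjuncts = [parse_node_expr(False)]
    while peek() == "and":
        idx += 1
        conjuncts.append(parse_node_expr(False))
    if idx != len(toks):
        err("unexpected trailing material")
    return TreePattern(expr, tuple(conjuncts), tuple(captures))


class _TreeContext:
    """Per-tree indexes used by relation evaluation."""

    def __init__(self, root: ParseTree):
        self.root = root
        self.parents = parent_map(root)
        leaves = root.leaves()
        self.leaf_order = {id(leaf): i for i, leaf in enumerate(leaves)}
        self.leaves = leaves
        # nodes whose leftmost leaf is leaf i
        self.starts_at: dict[int, list[ParseTree]] = {}
        for node in root.preorder():
            lv = node
            while not lv.is_leaf:
                if not lv.children:
                    lv = None
                    break
                lv = lv.children[0]
            if lv is not None:
                self.starts_at.setdefault(self.leaf_order[id(lv)], []).append(node)

    def candidates(self, node: ParseTree, rel: str) -> list[ParseTree]:
        if rel == "<":
            return node.children
        if rel == "<:":
            return node.children if len(node.children) == 1 else []
        if rel == "<<":
            return [d for d in node.preorder() if d is not node]
        if rel == "$":
            parent = self.parents.get(id(node))
            if parent is None:
                return []
            i = next(k for k, c in enumerate(parent.children) if c is node)
            return parent.children[i + 1:]
        if rel == ".":
            lv = node
            while not lv.is_leaf:
                if not lv.children:
                    return []
                lv = lv.children[-1]
            nxt = self.leaf_order[id(lv)] + 1
            return self.starts_at.get(nxt, [])
        raise AssertionError(rel)


def _match_expr(node: ParseTree, expr: _NodeExpr, ctx: _TreeContext) -> Iterator[dict]:
    if not expr.term.matches(node):
        return
    base = {expr.capture: node} if expr.capture else {}

    def extend(binding: dict, rels: tuple[_Relation, ...]) -> Iterator[dict]:
        if not rels:
            yield binding
            return
        rel, rest = rels[0], rels[1:]
        cands = ctx.candidates(node, rel.rel)
        if rel.negated:
            if not any(_has_match(c, rel.operand, ctx) for c in cands):
                yield from extend(binding, rest)
            return
        for cand in cands:
            for sub in _match_expr(cand, rel.operand, ctx):
                merged = dict(binding)
                merged.update(sub)
                yield from extend(merged, rest)

    yield from extend(base, expr.relations)


def _has_match(node: ParseTree, expr: _NodeExpr, ctx: _TreeContext) -> bool:
    for _ in _match_expr(node, expr, ctx):
        return True
    return False


def match_all(pattern: TreePattern, tree: ParseTree) -> list[TreeMatch]:
    """All matches of ``pattern`` in ``tree``, in pre-order of the anchor node.

    Distinct binding assignments under the same anchor each yield one match;
    duplicate assignments are collapsed.
    """
    ctx = _TreeContext(tree)
    out: list[TreeMatch] = []
    seen: set[tuple] = set()
    for node in tree.preorder():
        solutions: list[dict] = [{}]
        ok = True
        for conj in pattern.conjuncts:
            new: list[dict] = []
            for binding in solutions:
                for sub in _match_expr(node, conj, ctx):
                    merged = dict(binding)
                    merged.update(sub)
                    new.append(merged)
            if not new:
                ok = False
                break
            solutions = new
        if not ok:
            continue
        for binding in solutions:
            key = (id(node), tuple(sorted((k, id(v)) for k, v in binding.items())))
            if key in seen:
                continue
            seen.add(key)
            out.append(TreeMatch(binding))
    return out


# ----------------------------------------------------------------------
# Verb-group head selection
# ----------------------------------------------------------------------

VERB_TAGS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD", "TO"}

# Auxiliaries and raising/ECM carriers skipped during head selection: the
# agent and theme relate to the last main verb of a consecutive verb group.
AUXILIARIES = {
    "be", "is", "are", "was", "were", "been", "being", "am",
    "have", "has", "had", "having",
    "do", "does", "did",
    "will", "would", "can", "could", "shall", "should", "may", "might", "must",
    "to",
    "known", "shown", "found", "demonstrated", "reported",
    "seem", "seems", "seemed", "appear", "appears", "appeared",
    "likely", "thought", "believed",
}


def _is_aux(preterminal: ParseTree) -> bool:
    if preterminal.label in ("MD", "TO"):
        return True
    word = preterminal.children[0].token if preterminal.children else preterminal.token
    return word is not None and word.lower() in AUXILIARIES


def verb_group_head(vp: ParseTree) -> ParseTree:
    """Last main-verb leaf of a consecutive verb group.

    Descends rightmost through nested verbal projections (VP, and clausal
    complements of raising/auxiliary carriers), skipping auxiliaries,
    modals and infinitival "to", and returns the word leaf of the final
    main verb.
    """
    node = vp
    if node.is_leaf:
        return node
    if node.label in VERB_TAGS and len(node.children) == 1 and node.children[0].is_leaf:
        return node.children[0]
    while True:
        if node.label == "S" or node.label == "SBAR":
            inner = [c for c in node.children if c.label in ("VP", "S")]
            if not inner:
                raise ValueError("no verb phrase found in clausal complement")
            node = inner[-1]
            continue
        verb_kids = [c for c in node.children
                     if c.label in VERB_TAGS and c.children and c.children[0].is_leaf]
        nested = [c for c in node.children if c.label in ("VP", "S")]
        main = verb_kids[-1] if verb_kids else None
        if nested and (main is None or _is_aux(main)):
            node = nested[-1]
            continue
        if main is not None:
            return main.children[0]
        raise ValueError(f"no verb leaf found under {vp.label} node")
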