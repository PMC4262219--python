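"""Parse-tree reader, tree-pattern matcher and verb-group head selection."""

import itertools
import random

import pytest

from trigex.trees import (
    AlignmentError,
    ParseError,
    PatternSyntaxError,
    ParseTree,
    compile_pattern,
    match_all,
    parent_map,
    read_bracketed,
    verb_group_head,
)

from conftest import tree


class TestReader:
    def test_spans_computed_by_leaf_alignment(self):
        t = read_bracketed(
            "(S (NP (NNP JNK)) (VP (VBZ phosphorylates) (NP (NNP NFAT4))))",
            "JNK phosphorylates NFAT4")
        assert len(t.leaves()) == 3
        assert t.span == (0, 24)
        assert [lf.span for lf in t.leaves()] == [(0, 3), (4, 18), (19, 24)]

    def test_single_leaf(self):
        t = read_bracketed("(NP (NN binding))", "binding")
        assert t.span == (0, 7)
        assert t.leaves()[0].token == "binding"

    def test_token_mismatch_raises_alignment_error(self):
        with pytest.raises(AlignmentError, match="NFAT5"):
            read_bracketed("(NP (NNP NFAT5))", "NFAT4 was seen")

    def test_unbalanced_brackets(self):
        with pytest.raises(ParseError):
            read_bracketed("(S (NP (NNP JNK))", "JNK")

    def test_ptb_escapes_unescaped(self):
        t = read_bracketed("(PRN (-LRB- -LRB-) (NP (NNP MEK1)) (-RRB- -RRB-))",
                           "( MEK1 )")
        assert t.tokens() == ["(", "MEK1", ")"]

    def test_span_reconstructs_token_yield(self):
        sent = "the kinase ( MEK1 ) was seen"
        t = read_bracketed(
            "(S (NP (NP (DT the) (NN kinase)) (PRN (-LRB- -LRB-) "
            "(NP (NNP MEK1)) (-RRB- -RRB-))) (VP (VBD was) (VP (VBN seen))))",
            sent)
        for node in t.preorder():
            covered = sent[node.span[0]:node.span[1]]
            assert covered.split() == node.tokens()


class TestPatternLanguage:
    def test_example_capture_match(self):
        t = tree("(S (NP (NNP JNK)) (VP (VBZ phosphorylates) (NP (NNP NFAT4))))")
        pat = compile_pattern(
            "VP < (VBZ=trig <: /^phosphorylat/) and VP < NP=arg")
        matches = match_all(pat, t)
        assert len(matches) == 1
        m = matches[0]
        assert m.bindings["trig"].tokens() == ["phosphorylates"]
        assert m.bindings["arg"].tokens() == ["NFAT4"]

    def test_label_only_pattern_counts_nodes(self):
        t = tree("(S (NP (NNP JNK)) (VP (VBZ phosphorylates) (NP (NNP NFAT4))))")
        assert len(match_all(compile_pattern("NP"), t)) == 2

    def test_no_match_yields_empty_list(self):
        t = tree("(NP (NN binding))")
        assert match_all(compile_pattern("VP < NP"), t) == []

    def test_negation(self):
        t = tree("(S (NP (NNP A)) (VP (VBZ binds)))")
        assert len(match_all(compile_pattern("VP !< NP"), t)) == 1
        assert match_all(compile_pattern("S !< NP"), t) == []

    def test_sibling_and_precedes(self):
        t = tree("(S (NP (NNP A)) (VP (VBZ binds) (NP (NNP B))))")
        assert len(match_all(compile_pattern("NP $ VP"), t)) == 1
        assert len(match_all(compile_pattern("VBZ . NP"), t)) == 1
        assert match_all(compile_pattern("VP . NP"), t) == []

    def test_syntax_errors_carry_position(self):
        for bad in ("VP <", "VP < (NP", "=x", "NP=arg=2"):
            with pytest.raises(PatternSyntaxError):
                compile_pattern(bad)

    def test_duplicate_capture_rejected(self):
        with pytest.raises(PatternSyntaxError):
            compile_pattern("VP < NP=x < NP=x")

    def test_multiple_binding_assignments(self):
        t = tree("(VP (VBZ binds) (NP (NNP A)) (NP (NNP B)))")
        matches = match_all(compile_pattern("VP < NP=arg"), t)
        assert {m.bindings["arg"].tokens()[0] for m in matches} == {"A", "B"}


# -- randomized equivalence with a brute-force oracle -------------------

LABELS = ["S", "NP", "VP", "PP", "NN", "A", "B"]


def random_tree(rng: random.Random, max_nodes: int = 25) -> ParseTree:
    budget = rng.randint(1, max_nodes)

    def build(depth):
        nonlocal budget
        budget -= 1
        label = rng.choice(LABELS)
        if budget <= 0 or depth > 3 or rng.random() < 0.3:
            word = rng.choice(["a", "b", "c"])
            return ParseTree(label, [ParseTree(word, token=word)])
        kids = [build(depth + 1) for _ in range(rng.randint(1, 3))]
        return ParseTree(label, kids)

    t = build(0)
    # assign token spans
    pos = 0
    for leaf in t.leaves():
        leaf.span = (pos, pos + len(leaf.token))
        pos += len(leaf.token) + 1
    t.recompute_spans()
    return t


def oracle_relation(root, a, b, rel):
    """Relation predicates computed from scratch, independently of the
    matcher's candidate enumeration."""
    parents = parent_map(root)
    if rel == "<":
        return any(c is b for c in a.children)
    if rel == "<:":
        return len(a.children) == 1 and a.children[0] is b
    if rel == "<<":
        return b is not a and any(n is b for n in a.preorder())
    if rel == "$":
        pa, pb = parents.get(id(a)), parents.get(id(b))
        if pa is None or pa is not pb:
            return False
        ia = [i for i, c in enumerate(pa.children) if c is a][0]
        ib = [i for i, c in enumerate(pa.children) if c is b][0]
        return ib > ia
    if rel == ".":
        la = a.leaves()[-1]
        lb = b.leaves()[0]
        leaves = root.leaves()
        ia = [i for i, lf in enumerate(leaves) if lf is la][0]
        ib = [i for i, lf in enumerate(leaves) if lf is lb][0]
        return ib == ia + 1
    raise AssertionError(rel)


def test_matcher_equals_bruteforce_oracle_on_random_trees():
    """Every (anchor, capture...) solution of the compiled matcher equals
    exhaustive enumeration of node tuples under the relation predicates."""
    rng = random.Random(20260926)
    rels = ["<", "<:", "<<", "$", "."]
    for _ in range(150):
        t = random_tree(rng)
        nodes = list(t.preorder())
        anchor_label = rng.choice(LABELS)
        clauses = []
        for i in range(rng.randint(1, 2)):
            clauses.append((rng.choice(rels), rng.choice(LABELS),
                            rng.random() < 0.25))
        expr = anchor_label + "=a0"
        for i, (rel, lab, neg) in enumerate(clauses):
            if neg:
                expr += f" !{rel} {lab}"
            else:
                expr += f" {rel} {lab}=c{i}"
        got = {
            tuple(sorted((k, id(v)) for k, v in m.bindings.items()))
            for m in match_all(compile_pattern(expr), t)
        }
        expected = set()
        pos_clauses = [(i, rc) for i, rc in enumerate(clauses) if not rc[2]]
        neg_clauses = [rc for rc in clauses if rc[2]]
        for anchor in nodes:
            if anchor.label != anchor_label:
                continue
            if any(any(oracle_relation(t, anchor, n, rel) and n.label == lab
                       for n in nodes)
                   for rel, lab, _ in neg_clauses):
                continue
            for combo in itertools.product(nodes, repeat=len(pos_clauses)):
                ok = all(oracle_relation(t, anchor, n, rel) and n.label == lab
                         for n, (_, (rel, lab, _n)) in zip(combo, pos_clauses))
                if ok:
                    binding = {"a0": anchor}
                    for n, (i, _) in zip(combo, pos_clauses):
                        binding[f"c{i}"] = n
                    expected.add(tuple(sorted((k, id(v))
                                              for k, v in binding.items())))
        assert got == expected


class TestVerbGroupHead:
    def test_is_known_to_bind(self):
        vp = tree("(VP (VBZ is) (VP (VBN known) (S (VP (TO to) "
                  "(VP (VB bind))))))")
        assert verb_group_head(vp).token == "bind"

    def test_single_verb_is_its_own_head(self):
        vp = tree("(VP (VBZ phosphorylates))")
        assert verb_group_head(vp).token == "phosphorylates"

    def test_long_auxiliary_chain(self):
        vp = tree("(VP (VBZ has) (VP (VBN been) (VP (VBN shown) (S (VP (TO to)"
                  " (VP (VB be) (VP (VBN phosphorylated))))))))")
        assert verb_group_head(vp).token == "phosphorylated"

    def test_no_verb_raises(self):
        with pytest.raises(ValueError):
            verb_group_head(tree("(VP (NP (NN binding)))"))
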