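"""Construct detection, variant generation and attachment alternatives."""

import pytest

from trigex.simplify import (
    attachment_alternatives,
    detect_constructs,
    map_span,
    simplify,
)

from conftest import tree

# A condensed form of the MAPK cascade sentence: verb coordination, a
# parenthetical alias, a full relative clause, and an NP coordination.
CASCADE = (
    "(S (NP (JJ Active) (NNP Raf-1)) "
    "(VP (VBZ phosphorylates) (CC and) (VBZ activates) "
    "(NP (NP (NP (DT the) (NN MAP) (NN kinase) (NN kinase) (CD 1)) "
    "(PRN (-LRB- -LRB-) (NP (NNP MEK1)) (-RRB- -RRB-))) "
    "(, ,) "
    "(SBAR (WHNP (WDT which)) "
    "(S (ADVP (RB in) (RB turn)) "
    "(VP (VBZ phosphorylates) (CC and) (VBZ activates) "
    "(NP (NP (DT the) (NN MAP) (NNS kinases)) (, ,) "
    "(NP (NP (NNP ERK1)) (CC and) (NP (NNP ERK2))))))))) "
    "(. .))"
)


class TestDetection:
    def test_cascade_sentence_constructs(self):
        kinds = [c.kind for c in detect_constructs(tree(CASCADE))]
        assert kinds.count("coordination") >= 3   # two verb groups + ERK NP
        assert "parenthetical" in kinds
        assert "relative_clause_full" in kinds

    def test_simple_sentence_has_no_constructs(self):
        t = tree("(S (NP (NNP JNK)) (VP (VBZ phosphorylates) "
                 "(NP (NNP NFAT4))) (. .))")
        assert detect_constructs(t) == []

    def test_prenominal_participle_is_not_a_reduced_relative(self):
        t = tree("(S (NP (DT the) (NN protein)) (VP (VBD was) (VP (VBN "
                 "dimerized) (PP (IN with) (NP (VBN phosphorylated) "
                 "(NNP c-Jun))))) (. .))")
        assert detect_constructs(t) == []

    def test_reduced_relative_clause(self):
        t = tree("(S (NP (NP (DT the) (NN protein)) (VP (VBN encoded) "
                 "(PP (IN by) (NP (NNP Prf1))))) (VP (VBD appeared)) (. .))")
        kinds = [c.kind for c in detect_constructs(t)]
        assert "relative_clause_reduced" in kinds

    def test_apposition_requires_determiner_or_number(self):
        with_det = tree("(S (NP (NP (NNP CD14)) (, ,) (NP (DT a) (NN membrane)"
                        " (NN glycoprotein)) (, ,)) (VP (VBD was) "
                        "(VP (VBN expressed))) (. .))")
        assert "apposition" in [c.kind for c in detect_constructs(with_det)]
        no_det = tree("(S (NP (NP (NNP CD14)) (, ,) (NP (NNP CD15))) "
                      "(VP (VBD appeared)) (. .))")
        assert "apposition" not in [c.kind for c in detect_constructs(no_det)]

    def test_conjuncts_are_not_appositives(self):
        t = tree("(NP (NP (DT a) (NN kinase)) (, ,) (NP (DT a) "
                 "(NN phosphatase)) (CC and) (NP (DT a) (NN ligase)))")
        kinds = [c.kind for c in detect_constructs(t)]
        assert "apposition" not in kinds
        assert "coordination" in kinds


class TestSimplify:
    def test_no_constructs_yields_identity_variant(self):
        t = tree("(S (NP (NNP JNK)) (VP (VBZ phosphorylates) "
                 "(NP (NNP NFAT4))) (. .))")
        variants = simplify(t)
        assert len(variants) == 1
        assert variants[0].text == "JNK phosphorylates NFAT4 ."
        assert variants[0].provenance == []

    def test_subject_coordination_splits_into_three_variants(self):
        t = tree("(S (NP (NP (NNP A)) (CC and) (NP (NNP B))) "
                 "(VP (VBD were) (VP (VBN expressed))) (. .))")
        texts = [v.text for v in simplify(t)]
        assert texts == ["A and B were expressed .",
                         "A were expressed .",
                         "B were expressed ."]

    def test_relative_clause_two_way_split(self):
        t = tree("(S (NP (PRP We)) (VP (VBD studied) (NP (NP (NNP Prf1)) "
                 "(, ,) (SBAR (WHNP (WDT which)) (S (VP (VBZ controls) "
                 "(NP (NN lysis))))))) (. .))")
        texts = {v.text for v in simplify(t)}
        assert "We studied Prf1 ." in texts
        assert "Prf1 controls lysis" in texts

    def test_apposition_two_variants(self):
        t = tree("(S (NP (NP (NNP CD14)) (, ,) (NP (DT a) (NN glycoprotein)) "
                 "(, ,)) (VP (VBD was) (VP (VBN expressed))) (. .))")
        texts = {v.text for v in simplify(t)}
        assert "CD14 was expressed ." in texts
        assert "a glycoprotein was expressed ." in texts

    def test_parenthetical_content_substitutes_for_referent(self):
        t = tree("(S (NP (NP (DT the) (NN kinase)) (PRN (-LRB- -LRB-) "
                 "(NP (NNP MEK1)) (-RRB- -RRB-))) (VP (VBD appeared)) (. .))")
        texts = {v.text for v in simplify(t)}
        assert "the kinase appeared ." in texts
        assert "MEK1 appeared ." in texts

    def test_cascade_exposes_mek1_as_subject_of_phosphorylates(self):
        variants = simplify(tree(CASCADE), max_variants=128)
        assert any(v.text.startswith("MEK1") and "phosphorylates" in v.text
                   for v in variants)
        assert any("MEK1 in turn phosphorylates the MAP kinases , ERK1"
                   == v.text for v in variants)

    def test_variant_cap_truncates(self):
        variants = simplify(tree(CASCADE), max_variants=5)
        assert len(variants) == 5

    def test_deterministic_and_order_stable(self):
        t = tree(CASCADE)
        a = [v.text for v in simplify(t, max_variants=128)]
        b = [v.text for v in simplify(t, max_variants=128)]
        assert a == b

    def test_tokens_keep_original_relative_order(self):
        t = tree(CASCADE)
        for v in simplify(t, max_variants=128):
            mapped = [o for o in v.offset_map if o is not None]
            assert mapped == sorted(mapped)


class TestOffsetMaps:
    def test_map_span_returns_original_coordinates(self):
        t = tree("(S (NP (NP (NNP A)) (CC and) (NP (NNP B))) "
                 "(VP (VBP bind)) (. .))")
        variants = simplify(t)
        v_b = next(v for v in variants if v.text == "B bind .")
        # "B" sits at offset 6 in "A and B bind ."
        assert map_span(v_b, (0, 1)) == (6, 7)
        assert v_b.map_back((2, 6)) == (8, 12)

    def test_span_over_unmapped_glue_raises(self):
        t = tree("(S (NP (NNP A)) (VP (VBP bind)) (. .))")
        (v,) = simplify(t)
        with pytest.raises(ValueError):
            map_span(v, (1, 2))  # the inter-token space


class TestAttachment:
    def test_relative_clause_reattachment_both_ways(self):
        # clause parsed high on "NP1 of NP2" -> alternative attaches low
        high = tree("(S (NP (NP (NP (DT the) (NN domain)) (PP (IN of) "
                    "(NP (NNP Prf1)))) (SBAR (WHNP (WDT which)) (S (VP "
                    "(VBZ matters))))) (VP (VBD appeared)) (. .))")
        alts = attachment_alternatives(high)
        assert [a.attachment_choice for a in alts] == ["relclause->NP2"]
        low = tree("(S (NP (NP (DT the) (NN domain)) (PP (IN of) (NP (NP "
                   "(NNP Prf1)) (SBAR (WHNP (WDT which)) (S (VP (VBZ "
                   "matters))))))) (VP (VBD appeared)) (. .))")
        alts = attachment_alternatives(low)
        assert [a.attachment_choice for a in alts] == ["relclause->NP1"]

    def test_adjective_over_coordination(self):
        t = tree("(S (NP (JJ phosphorylated) (NP (NNP Cas)) (CC and) "
                 "(NP (NNP Crk))) (VP (VBD appeared)) (. .))")
        texts = {a.text for a in attachment_alternatives(t)}
        assert "phosphorylated Cas appeared ." in texts
        assert "phosphorylated Crk appeared ." in texts
        assert "Crk appeared ." in texts

    def test_pp_after_coordination(self):
        t = tree("(S (NP (NP (NNP Cas)) (CC and) (NP (NNP Crk)) (PP (IN in) "
                 "(NP (NNS cells)))) (VP (VBD appeared)) (. .))")
        labels = {a.attachment_choice for a in attachment_alternatives(t)}
        assert {"pp->both:first", "pp->both:last", "pp->last-only"} <= labels

    def test_unambiguous_tree_yields_nothing(self):
        t = tree("(S (NP (NNP JNK)) (VP (VBZ phosphorylates) "
                 "(NP (NNP NFAT4))) (. .))")
        assert attachment_alternatives(t) == []
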