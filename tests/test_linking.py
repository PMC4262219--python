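"""Referential-relation detection and recursive argument linking."""

import pytest

from trigex.entities import EntityMention
from trigex.linking import (
    ReferentialLink,
    detect_links,
    parse_coref_file,
    register_external_coref,
    resolve,
)
from trigex.templates import TriggerArgPair
from trigex.triggers import ArgSlot

from conftest import mention, tree


def _pair(arg, relation="Transcription", role="theme"):
    return TriggerArgPair(relation, (0, 5), "trig", 1, arg, role)


def _uninformative(span, text, sem="class_noun"):
    return EntityMention(span, text, sem, source="heuristic")


class TestDetection:
    def test_part_whole_from_part_keyword(self):
        sent = "Both Eomes and Runx3 bind at the Prf1 locus ."
        t = tree("(S (NP (DT Both) (NP (NNP Eomes)) (CC and) (NP (NNP Runx3)))"
                 " (VP (VBP bind) (PP (IN at) (NP (DT the) (NNP Prf1) "
                 "(NN locus)))) (. .))", sent)
        mentions = [mention("Eomes", sent), mention("Runx3", sent),
                    mention("Prf1", sent)]
        links = [l for l in detect_links([t], mentions)
                 if l.kind == "part_whole"]
        assert len(links) == 1
        assert links[0].source.text == "the Prf1 locus"
        assert links[0].target.text == "Prf1"

    def test_member_collection_links_each_member(self):
        sent = ("expression of adhesion molecules including integrin alpha , "
                "L-selectin , ICAM-3 and H-CAM .")
        t = tree("(NP (NP (NN expression)) (PP (IN of) (NP (NP (NN adhesion) "
                 "(NNS molecules)) (PP (VBG including) (NP (NP (NN integrin) "
                 "(NN alpha)) (, ,) (NP (NNP L-selectin)) (, ,) "
                 "(NP (NNP ICAM-3)) (CC and) (NP (NNP H-CAM)))))) (. .))", sent)
        mentions = [mention("integrin alpha", sent), mention("L-selectin", sent),
                    mention("ICAM-3", sent), mention("H-CAM", sent)]
        links = [l for l in detect_links([t], mentions)
                 if l.kind == "member_collection"]
        assert len(links) == 4
        assert {l.source.text for l in links} == {
            "integrin alpha", "L-selectin", "ICAM-3", "H-CAM"}
        assert all("molecules" in l.target.text for l in links)

    def test_hyponymy_from_acts_as(self):
        sent = "Prf1 acts as a pore-forming regulator ."
        t = tree("(S (NP (NNP Prf1)) (VP (VBZ acts) (PP (IN as) (NP (DT a) "
                 "(JJ pore-forming) (NN regulator)))) (. .))", sent)
        links = [l for l in detect_links([t], [mention("Prf1", sent)])
                 if l.kind == "hyponymy"]
        assert len(links) == 1
        assert links[0].source.text == "Prf1"

    def test_apposition_and_relative_pronoun_links(self):
        sent = "CD14 , a membrane glycoprotein , which appeared ."
        t = tree("(NP (NP (NNP CD14)) (, ,) (NP (DT a) (NN membrane) "
                 "(NN glycoprotein)) (, ,) (SBAR (WHNP (WDT which)) "
                 "(S (VP (VBD appeared)))) (. .))", sent)
        kinds = {l.kind for l in detect_links([t], [mention("CD14", sent)])}
        assert "apposition" in kinds and "relpronoun_coref" in kinds

    def test_no_cues_yields_empty(self):
        t = tree("(S (NP (NNP JNK)) (VP (VBZ phosphorylates) "
                 "(NP (NNP NFAT4))) (. .))")
        assert detect_links([t], []) == []


class TestResolve:
    def test_figure2_member_then_hyponym_chain(self):
        """collection -> member -> hyponym: the generic theme "the earliest
        genes" resolves to the named gene two links away."""
        genes = _uninformative((10, 28), "the earliest genes")
        one = _uninformative((40, 43), "one", sem="other")
        tnf = EntityMention((60, 89), "tumor necrosis factor alpha", "GGP",
                            source="preannotated")
        links = [ReferentialLink("member_collection", one, genes),
                 ReferentialLink("hyponymy", tnf, one)]
        (out,) = resolve(_pair(genes), links, [tnf],
                         ArgSlot(1, frozenset({"rna", "GGP"})))
        assert out.arg is tnf
        assert out.role == "theme"

    def test_hyponymy_via_apposition(self):
        glyco = _uninformative((7, 31), "a membrane glycoprotein",
                               sem="protein")
        cd14 = EntityMention((0, 4), "CD14", "GGP", source="preannotated")
        links = [ReferentialLink("apposition", glyco, cd14)]
        (out,) = resolve(_pair(glyco, relation="Gene_expression"), links,
                         [cd14], ArgSlot(1, frozenset({"GGP"})))
        assert out.arg is cd14

    def test_preannotated_argument_is_identity(self):
        arg = EntityMention((0, 4), "CD14", "GGP", source="preannotated")
        pair = _pair(arg)
        assert resolve(pair, [ReferentialLink(
            "apposition", _uninformative((9, 12), "xxx"), arg)], [arg]) == [pair]

    def test_empty_link_list_is_identity(self):
        pair = _pair(_uninformative((3, 9), "a gene"))
        assert resolve(pair, [], []) == [pair]

    def test_termination_on_cyclic_link_graph(self):
        a = _uninformative((0, 3), "aaa")
        b = _uninformative((5, 8), "bbb")
        c = _uninformative((10, 13), "ccc")
        cycle = [ReferentialLink("apposition", a, b),
                 ReferentialLink("apposition", b, c),
                 ReferentialLink("apposition", c, a)]
        pair = _pair(a)
        assert resolve(pair, cycle, []) == [pair]

    def test_cycle_with_one_informative_mention(self):
        a = _uninformative((0, 3), "aaa")
        b = _uninformative((5, 8), "bbb")
        good = EntityMention((10, 14), "Prf1", "GGP", source="preannotated")
        cycle = [ReferentialLink("apposition", a, b),
                 ReferentialLink("apposition", b, good),
                 ReferentialLink("apposition", good, a)]
        (out,) = resolve(_pair(a), cycle, [good],
                         ArgSlot(1, frozenset({"GGP"})))
        assert out.arg is good

    def test_unreachable_informative_returns_original(self):
        a = _uninformative((0, 3), "aaa")
        far = EntityMention((50, 54), "Prf1", "GGP", source="preannotated")
        links = [ReferentialLink("hyponymy", far,
                                 _uninformative((30, 33), "zzz"))]
        pair = _pair(a)
        assert resolve(pair, links, [far]) == [pair]

    def test_type_check_filters_rewrites(self):
        coll = _uninformative((0, 10), "the agents")
        chem = EntityMention((20, 24), "NaCl", "GGP", source="preannotated")
        links = [ReferentialLink("member_collection", chem, coll)]
        pair = _pair(coll)
        # slot refuses everything -> original survives (never dropped)
        out = resolve(pair, links, [chem], ArgSlot(1, frozenset({"chemical"})))
        assert out == [pair]


class TestExternalCoref:
    def test_register_merges_and_validates(self):
        store = []
        good = ReferentialLink("coref",
                               _uninformative((0, 3), "it", sem="other"),
                               _uninformative((10, 14), "Prf1"))
        register_external_coref(store, [good], text_length=20)
        assert store == [good]
        bad = ReferentialLink("coref",
                              _uninformative((0, 3), "it", sem="other"),
                              _uninformative((18, 25), "overrun"))
        with pytest.raises(ValueError):
            register_external_coref(store, [bad], text_length=20)

    def test_parse_coref_file(self):
        doc = "The protein binds c-Fox today"
        links = parse_coref_file("0\t11\t18\t23\tcoref\n", doc)
        assert links[0].source.text == "The protein"
        assert links[0].target.text == "c-Fox"
        with pytest.raises(ValueError):
            parse_coref_file("0\t11\t18\tcoref\n", doc)
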