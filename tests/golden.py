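"""Worked examples with hand-built gold trees, shared by the unit and
acceptance suites.  Each scenario builds a one-document corpus, runs the
full pipeline and returns the extracted events (plus whatever auxiliary
objects the checks need)."""

from trigex import build_patterns
from trigex.extract import ExtractionConfig, extract_document, load_document
from trigex.linking import parse_coref_file

from conftest import mention

PHOS_SPEC = """\
trigger: phosphorylate
relation: Phosphorylation
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = agent
role: NP1 = theme
affixes: -ion
"""

BIND_SPEC = """\
trigger: bind
relation: Binding
frame: NP0/NP1
type: NP0 = GGP | protein_part | gene_part
type: NP1 = GGP | protein_part | gene_part
role: NP0 = theme
role: NP1 = theme
direction: non-directional
affixes: -ing
"""

DIMERIZE_SPEC = """\
trigger: dimerize
relation: Binding
frame: NP0/NP1
type: NP0 = GGP | protein
type: NP1 = GGP | protein
role: NP0 = theme
role: NP1 = theme
direction: non-directional
"""

EXPRESS_SPEC = """\
trigger: express
relation: Gene_expression
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP
role: NP0 = agent
role: NP1 = theme
affixes: -ion
"""

EXPRESS_HOMONYM_SPECS = """\
trigger: express
relation: Gene_expression
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = gene | GGP
role: NP0 = agent
role: NP1 = theme

trigger: express
relation: Transcription
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = rna | GGP
role: NP0 = agent
role: NP1 = theme
guard: NP1 ~ mRNA
"""


def _run(spec_text, parse, sentence, mentions, config=None, coref=None):
    doc = load_document(sentence + "\n", [parse], [(0, len(sentence))],
                        mentions)
    patterns = build_patterns(spec_text)
    external = parse_coref_file(coref, doc.text) if coref else None
    return extract_document(doc, patterns, config, external)


def args_texts(event, doc_text=None):
    return {role: sorted(m.text for m in ms)
            for role, ms in event.args.items()}


def scenario_cjun_kinase():
    """"The c-Jun amino-terminal kinase phosphorylates NFAT4." -- the full
    subject NP is the agent, NFAT4 the theme."""
    sent = "The c-Jun amino-terminal kinase phosphorylates NFAT4 ."
    parse = ("(S (NP (DT The) (NN c-Jun) (JJ amino-terminal) (NN kinase)) "
             "(VP (VBZ phosphorylates) (NP (NNP NFAT4))) (. .))")
    mentions = [mention("c-Jun amino-terminal kinase", sent, ann_id="T1"),
                mention("NFAT4", sent, ann_id="T2")]
    return _run(PHOS_SPEC, parse, sent, mentions)


def scenario_jnk(config=None):
    """"JNK phosphorylates NFAT4" -- agent and theme pairs on one trigger."""
    sent = "JNK phosphorylates NFAT4"
    parse = "(S (NP (NNP JNK)) (VP (VBZ phosphorylates) (NP (NNP NFAT4))))"
    mentions = [mention("JNK", sent, ann_id="T1"),
                mention("NFAT4", sent, ann_id="T2")]
    return _run(PHOS_SPEC, parse, sent, mentions, config)


CASCADE_SENT = ("Active Raf-1 phosphorylates and activates the MAP kinase "
                "kinase 1 ( MEK1 ) , which in turn phosphorylates and "
                "activates the MAP kinases , ERK1 and ERK2 .")
CASCADE_PARSE = (
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
    "(. .))")


def scenario_cascade(simplify=True):
    """The MAPK cascade sentence: the ERK themes of the second
    "phosphorylates" are reachable only through simplification."""
    mentions = [mention("Raf-1", CASCADE_SENT, ann_id="T1"),
                mention("MEK1", CASCADE_SENT, ann_id="T2"),
                mention("ERK1", CASCADE_SENT, ann_id="T3"),
                mention("ERK2", CASCADE_SENT, ann_id="T4")]
    config = ExtractionConfig(simplify=simplify, attachments=simplify,
                              max_variants=128)
    return _run(PHOS_SPEC, CASCADE_PARSE, CASCADE_SENT, mentions, config)


def second_phosphorylates_span():
    start = CASCADE_SENT.index("phosphorylates",
                               CASCADE_SENT.index("which"))
    return (start, start + len("phosphorylates"))


def scenario_dimerized():
    """"... the protein was dimerized with phosphorylated c-Jun", with an
    injected external coreference link the protein -> c-Fox."""
    sent = ("The stability of c-Fox was decreased when the protein was "
            "dimerized with phosphorylated c-Jun .")
    parse = ("(S (NP (NP (DT The) (NN stability)) (PP (IN of) "
             "(NP (NNP c-Fox)))) (VP (VBD was) (VP (VBN decreased) "
             "(SBAR (WHADVP (WRB when)) (S (NP (DT the) (NN protein)) "
             "(VP (VBD was) (VP (VBN dimerized) (PP (IN with) "
             "(NP (VBN phosphorylated) (NNP c-Jun))))))))) (. .))")
    mentions = [mention("c-Fox", sent, ann_id="T1"),
                mention("c-Jun", sent, ann_id="T2")]
    s = sent.index("the protein")
    t = sent.index("c-Fox")
    coref = f"{s}\t{s + len('the protein')}\t{t}\t{t + len('c-Fox')}\tcoref\n"
    return _run(DIMERIZE_SPEC + "\n" + PHOS_SPEC, parse, sent, mentions,
                coref=coref)


def scenario_prf1_locus():
    """"Both Eomes and Runx3 bind at the Prf1 locus." -- the part-whole
    link substitutes Prf1 for the locus NP."""
    sent = "Both Eomes and Runx3 bind at the Prf1 locus ."
    parse = ("(S (NP (DT Both) (NP (NNP Eomes)) (CC and) (NP (NNP Runx3))) "
             "(VP (VBP bind) (PP (IN at) (NP (DT the) (NNP Prf1) "
             "(NN locus)))) (. .))")
    mentions = [mention("Eomes", sent, ann_id="T1"),
                mention("Runx3", sent, ann_id="T2"),
                mention("Prf1", sent, ann_id="T3")]
    return _run(BIND_SPEC, parse, sent, mentions)


def scenario_adhesion_molecules():
    """"expression of adhesion molecules including integrin alpha,
    L-selectin, ICAM-3, and H-CAM" -- one event per collection member."""
    sent = ("We observed expression of adhesion molecules including "
            "integrin alpha , L-selectin , ICAM-3 and H-CAM .")
    parse = ("(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NN expression)) "
             "(PP (IN of) (NP (NP (NN adhesion) (NNS molecules)) "
             "(PP (VBG including) (NP (NP (NN integrin) (NN alpha)) (, ,) "
             "(NP (NNP L-selectin)) (, ,) (NP (NNP ICAM-3)) (CC and) "
             "(NP (NNP H-CAM)))))))) (. .))")
    mentions = [mention("integrin alpha", sent, ann_id="T1"),
                mention("L-selectin", sent, ann_id="T2"),
                mention("ICAM-3", sent, ann_id="T3"),
                mention("H-CAM", sent, ann_id="T4")]
    return _run(EXPRESS_SPEC, parse, sent, mentions)


def scenario_cd14():
    """"CD14, a membrane glycoprotein, was expressed" -- hyponymy through
    the apposition resolves the theme to CD14."""
    sent = "CD14 , a membrane glycoprotein , was expressed ."
    parse = ("(S (NP (NP (NNP CD14)) (, ,) (NP (DT a) (NN membrane) "
             "(NN glycoprotein)) (, ,)) (VP (VBD was) (VP (VBN expressed))) "
             "(. .))")
    mentions = [mention("CD14", sent, ann_id="T1")]
    return _run(EXPRESS_SPEC, parse, sent, mentions)


def scenario_mrna_routing():
    """"GATA1 expresses EpoR mRNA" -- the mRNA co-occurrence guard routes
    the homonymous trigger to Transcription, not Gene_expression."""
    sent = "GATA1 expresses EpoR mRNA ."
    parse = ("(S (NP (NNP GATA1)) (VP (VBZ expresses) (NP (NNP EpoR) "
             "(NN mRNA))) (. .))")
    mentions = [mention("GATA1", sent, ann_id="T1"),
                mention("EpoR", sent, ann_id="T2")]
    return _run(EXPRESS_HOMONYM_SPECS, parse, sent, mentions)


def scenario_plain_expression():
    """"GATA1 expresses EpoR" (no mRNA) -> Gene_expression only."""
    sent = "GATA1 expresses EpoR ."
    parse = "(S (NP (NNP GATA1)) (VP (VBZ expresses) (NP (NNP EpoR))) (. .))"
    mentions = [mention("GATA1", sent, ann_id="T1"),
                mention("EpoR", sent, ann_id="T2")]
    return _run(EXPRESS_HOMONYM_SPECS, parse, sent, mentions)


def scenario_adjunct_skipping():
    """An adverbial adjunct between trigger and argument is skipped."""
    sent = "HL-60 cells abundantly expressed GATA1 ."
    parse = ("(S (NP (NNP HL-60) (NNS cells)) (VP (ADVP (RB abundantly)) "
             "(VBD expressed) (NP (NNP GATA1))) (. .))")
    mentions = [mention("HL-60", sent, ann_id="T1"),
                mention("GATA1", sent, ann_id="T2")]
    return _run(EXPRESS_SPEC, parse, sent, mentions)


def scenario_auxiliary_chain():
    """"X is known to bind Y": the verb-group head is "bind"."""
    sent = "Eomes is known to bind Runx3 ."
    parse = ("(S (NP (NNP Eomes)) (VP (VBZ is) (VP (VBN known) (S (VP (TO to)"
             " (VP (VB bind) (NP (NNP Runx3))))))) (. .))")
    mentions = [mention("Eomes", sent, ann_id="T1"),
                mention("Runx3", sent, ann_id="T2")]
    return _run(BIND_SPEC, parse, sent, mentions)
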