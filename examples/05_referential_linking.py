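"""Referential-relation linking replaces generic arguments with the named
entities they refer to.

"expression of adhesion molecules including integrin alpha, ..." first
yields the generic theme "adhesion molecules"; member-collection links
rewrite it into one event per listed member.
"""

from trigex import build_patterns
from trigex.entities import EntityMention
from trigex.extract import ExtractionConfig, extract_document, load_document
from trigex.linking import detect_links
from trigex.trees import read_bracketed

SPEC = """\
trigger: express
relation: Gene_expression
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP
role: NP0 = agent
role: NP1 = theme
affixes: -ion
"""

SENT = ("We observed expression of adhesion molecules including "
        "integrin alpha , L-selectin , ICAM-3 and H-CAM .")
PARSE = ("(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NN expression)) "
         "(PP (IN of) (NP (NP (NN adhesion) (NNS molecules)) "
         "(PP (VBG including) (NP (NP (NN integrin) (NN alpha)) (, ,) "
         "(NP (NNP L-selectin)) (, ,) (NP (NNP ICAM-3)) (CC and) "
         "(NP (NNP H-CAM)))))))) (. .))")


def m(text, ann_id):
    s = SENT.index(text)
    return EntityMention((s, s + len(text)), text, "GGP",
                         source="preannotated", ann_id=ann_id)


mentions = [m("integrin alpha", "T1"), m("L-selectin", "T2"),
            m("ICAM-3", "T3"), m("H-CAM", "T4")]
tree = read_bracketed(PARSE, SENT)
links = detect_links([tree], mentions)
print("detected referential links:")
for link in links:
    print(f"  {link.kind}: {link.source.text!r} -> {link.target.text!r}")

doc = load_document(SENT + "\n", [PARSE], [(0, len(SENT))], mentions)
patterns = build_patterns(SPEC)
for label, cfg in [("with linking", None),
                   ("without linking", ExtractionConfig(linking=False))]:
    events = extract_document(doc, patterns, cfg)
    themes = sorted(e.args["theme"][0].text for e in events)
    print(f"{label}: {len(events)} events, themes={themes}")
print("\nWithout linking the generic collection NP cannot anchor an event; "
      "with linking each member becomes a theme.")
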