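"""Extract a phosphorylation event from a parsed sentence.

Pre-annotated gene/gene-product mentions (the .a1 layer) plus a gold
constituency parse go in; typed events with character spans come out.
"""

from trigex import build_patterns
from trigex.entities import EntityMention
from trigex.extract import extract_document, load_document

SPEC = """\
trigger: phosphorylate
relation: Phosphorylation
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = agent
role: NP1 = theme
"""

SENT = "The c-Jun amino-terminal kinase phosphorylates NFAT4 ."
PARSE = ("(S (NP (DT The) (NN c-Jun) (JJ amino-terminal) (NN kinase)) "
         "(VP (VBZ phosphorylates) (NP (NNP NFAT4))) (. .))")
MENTIONS = [
    EntityMention((4, 31), "c-Jun amino-terminal kinase", "GGP",
                  source="preannotated", ann_id="T1"),
    EntityMention((47, 52), "NFAT4", "GGP", source="preannotated",
                  ann_id="T2"),
]

doc = load_document(SENT + "\n", [PARSE], [(0, len(SENT))], MENTIONS)
events = extract_document(doc, build_patterns(SPEC))
for e in events:
    args = {r: [m.text for m in ms] for r, ms in e.args.items()}
    print(f"{e.relation} trigger={SENT[e.trigger_span[0]:e.trigger_span[1]]!r}"
          f" @ {e.trigger_span} args={args}")
print("\nThe active-subject template captured the full kinase NP as agent "
      "and the object template captured NFAT4 as theme; both pairs merged "
      "into one event on the shared trigger occurrence.")
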