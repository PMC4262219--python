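# trigex

Trigger-driven, pattern-based relation extraction for biomedical text.

Molecular-biology papers state events — phosphorylation, binding, gene
expression, transcription, protein catabolism, localization — in a
limited set of syntactic guises around a *trigger* word ("phosphorylates",
"binding", "phosphorylated"). `trigex` turns a short declarative **trigger
specification** into a full extraction system, with no annotated training
corpus and no hand-written extraction rules:

```text
trigger:   phosphorylate
relation:  Phosphorylation
frame:     NP0/NP1
type:      NP0 = GGP
type:      NP1 = GGP | protein_part
role:      NP0 = agent
role:      NP1 = theme
direction: directional
```

From the root morpheme it derives every matchable surface form
(*phosphorylates, phosphorylated, phosphorylation, hyperphosphorylated,
…*) by English inflection rules plus an exception lexicon. The frame
(`NP0/NP1` transitive, `NP0` intransitive agentive, `NP1` unaccusative)
routes the trigger to the compatible subset of a fixed inventory of **26
pattern templates** — 7 verbal, 9 nominal, 4 adjectival and 6
null-argument (elliptical) — each an element sequence β₁…βₙ with feature
constraints that captures one ⟨trigger, NPᵢ⟩ pair at a time. Pairs sharing
a trigger occurrence are merged into events, so a non-directional Binding
may carry several themes while a directional Phosphorylation splits one
event per theme.

Matching runs over constituency parses (Penn Treebank bracketed format,
consumed, never produced) through a small tree-regular-expression engine,
with consecutive verb groups resolved to their last main verb ("is known
to **bind**") and adverbial adjuncts skipped. Two recall mechanisms wrap
the matcher:

* **Sentence simplification** — coordinations, full/reduced relative
  clauses, appositions and parenthesized elements are detected on the
  parse and rewritten by tree surgery into simpler variants (with
  per-character offset maps back to the original), including alternative
  attachment readings; patterns then match the variants.
* **Referential-relation linking** — when a captured argument is not an
  informative named entity ("the earliest genes", "the protein"),
  part-whole, member-collection, hyponymy, apposition and
  relative-pronoun links (plus links injected from any external
  coreference resolver) are followed recursively until pre-annotated
  entities are reached.

Entity mentions are inputs (BioNLP-ST `.a1` standoff); events are written
as `.a2` and scored with the approximate recursive matching metric (a
predicted span counts as correct when contained in the gold span extended
by one word on each side).

## Worked example

```python
from trigex import build_patterns
from trigex.entities import EntityMention
from trigex.extract import extract_document, load_document

spec = """trigger: phosphorylate
relation: Phosphorylation
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = agent
role: NP1 = theme
"""
sent = "The c-Jun amino-terminal kinase phosphorylates NFAT4 ."
parse = ("(S (NP (DT The) (NN c-Jun) (JJ amino-terminal) (NN kinase)) "
         "(VP (VBZ phosphorylates) (NP (NNP NFAT4))) (. .))")
mentions = [EntityMention((4, 31), "c-Jun amino-terminal kinase", "GGP",
                          source="preannotated", ann_id="T1"),
            EntityMention((47, 52), "NFAT4", "GGP",
                          source="preannotated", ann_id="T2")]
doc = load_document(sent + "\n", [parse], [(0, len(sent))], mentions)
for e in extract_document(doc, build_patterns(spec)):
    print(e.relation, e.trigger_span,
          {r: [m.text for m in ms] for r, ms in e.args.items()})
```

prints

```text
Phosphorylation (32, 46) {'theme': ['NFAT4'], 'agent': ['c-Jun amino-terminal kinase']}
```

— the active-subject template captured the full kinase NP as agent, the
object template captured NFAT4 as theme, and the two pairs merged on the
shared trigger occurrence at characters 32–46. The scripts in
`examples/` walk through each capability (form derivation, pattern
generation, simplification, linking, corpus scoring) the same way.

## Command line

```bash
trigex make-fixtures --seed 1 --n 50 --out-dir bundle/
trigex extract --specs bundle/triggers.spec --text bundle/doc.txt \
    --parses bundle/doc.parses --offsets bundle/doc.offsets \
    --a1 bundle/doc.a1 --out pred/doc.a2        # add --no-simplify / --no-linking
trigex evaluate --pred-dir pred/ --gold-dir bundle/ --report
trigex simplify --text doc.txt --parses doc.parses
```

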