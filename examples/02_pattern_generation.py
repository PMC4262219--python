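"""Generate lexico-syntactic patterns from a trigger specification.

The frame routes a trigger to the compatible subset of the 26-template
inventory; instantiating each template with each compatible surface form
yields the pattern set the extractor matches.
"""

from trigex import build_patterns, list_templates

SPEC = """\
trigger: phosphorylate
relation: Phosphorylation
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = agent
role: NP1 = theme
affixes: -ion
"""

groups = {}
for t in list_templates():
    groups.setdefault(t.group, []).append(t.id)
print("template inventory (26):")
for g, ids in groups.items():
    print(f"  {g:13s} {len(ids):2d}  {' '.join(ids)}")

patterns = build_patterns(SPEC)
print(f"\n'phosphorylate' instantiates {len(patterns)} patterns, e.g.:")
for p in patterns[:8]:
    elements = " ".join(p.template.elements).replace(
        "V_tr", p.form.surface).replace("N_tr", p.form.surface).replace(
        "Adj_tr", p.form.surface)
    print(f"  {p.template_id}: {elements}")
print("\nEach pattern captures one argument at a time; pairs sharing a "
      "trigger occurrence are merged into events afterwards.")
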