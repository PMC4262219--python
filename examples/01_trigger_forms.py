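"""Derive surface trigger forms from a root morpheme.

A trigger specification names only the verb root; all inflections,
process nominals and prefixed derivatives used for matching are generated
by rule (with an exception lexicon for irregulars such as
transcribe -> transcription).
"""

from trigex import derive_trigger_forms

for root, affixes in [("phosphorylate", ["-ion", "under-", "hyper-"]),
                      ("cleave", ["-age"]),
                      ("transcribe", ["-tion"])]:
    forms = derive_trigger_forms(root, affixes)
    print(f"{root} + {affixes}:")
    for f in forms:
        flag = f" [{f.nominal_class.value}]" if f.nominal_class else ""
        print(f"  {f.surface:28s} {f.category.value:14s} {f.derivation}{flag}")
    print()

print("Each line is one matchable surface form; 'entity'-class nominals "
      "(e.g. 'transcript') are derivable but never used in patterns.")
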