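"""End-to-end run on a synthetic standoff corpus with ablations.

The fixture generator builds 200 sentences (with gold parses, .a1
entities and gold .a2 events known by construction); the pipeline is
scored with the approximate-span matching metric, and the simplification
and linking modules are switched off in turn.
"""

from trigex import build_patterns
from trigex.extract import ExtractionConfig, extract_document, load_document
from trigex.fixtures import DEFAULT_TRIGGER_SPECS, FixtureRecipe, generate
from trigex.standoff import evaluate, read_standoff

bundle = generate(FixtureRecipe(seed=1, n_sentences=200))
gold = read_standoff(bundle["txt"], bundle["a1"], bundle["a2"])
doc = load_document(bundle["txt"], bundle["parses"], bundle["sentences"],
                    gold.entities)
patterns = build_patterns(DEFAULT_TRIGGER_SPECS)

print(f"{len(doc.trees)} sentences, {len(gold.entities)} entity mentions, "
      f"{len(gold.events)} gold events, {len(patterns)} patterns\n")
for label, cfg in [
        ("full pipeline", None),
        ("no simplification", ExtractionConfig(simplify=False,
                                               attachments=False)),
        ("no linking", ExtractionConfig(linking=False))]:
    r = evaluate(extract_document(doc, patterns, cfg), gold)
    print(f"{label:18s} P={100 * r.precision:6.2f}%  "
          f"R={100 * r.recall:6.2f}%  F={100 * r.f1:6.2f}%")
print("\nOn gold parses the full pipeline recovers every gold event; the "
      "ablations lose recall but keep precision, which is the division of "
      "labour the architecture is built around.")
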