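"""Synthetic document bundles for end-to-end testing.

Each generated sentence is built compositionally: a base realization of
one pattern-template shape ("<E1> phosphorylates <E2>", "binding of <E1>
to <E2>", ...) or a complication shape that wraps an extraction inside a
coordination, relative clause, apposition, parenthetical,
member-collection or hyponymy construction.  Text, gold parse, entity
annotations and gold events are constructed jointly, so the gold standard
is known by construction and no parser or corpus is ever needed.  Entity
names are synthetic (PROT001, ...) to avoid accidental lexicon hits.

A bundle is a standoff document set: raw text (one sentence per line),
one bracketed parse per line, .a1 entity annotations and gold .a2 events.
The same seed always yields a byte-identical bundle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

__all__ = ["FixtureRecipe", "DEFAULT_TRIGGER_SPECS", "generate",
           "base_realizers", "complication_realizers"]


#: trigger specifications used by the fixture suite (also a format example)
DEFAULT_TRIGGER_SPECS = """\
trigger: phosphorylate
relation: Phosphorylation
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = agent
role: NP1 = theme
direction: directional
affixes: -ion

trigger: bind
relation: Binding
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = theme
role: NP1 = theme
direction: non-directional
affixes: -ing

trigger: interact
relation: Binding
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP
role: NP0 = theme
role: NP1 = theme
direction: non-directional
affixes: -ion

trigger: express
relation: Gene_expression
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = gene
role: NP0 = agent
role: NP1 = theme
direction: directional
affixes: -ion

trigger: express
relation: Transcription
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = rna | GGP
role: NP0 = agent
role: NP1 = theme
direction: directional
guard: NP1 ~ mRNA
affixes: -ion

trigger: degrade
relation: Protein_catabolism
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP
role: NP0 = agent
role: NP1 = theme
direction: directional
affixes: -tion

trigger: localize
relation: Localization
frame: NP1
type: NP1 = GGP
role: NP1 = theme
direction: directional
affixes: -ation
"""


@dataclass(frozen=True)
class FixtureRecipe:
    seed: int = 1
    n_sentences: int = 50
    template_mix: Optional[dict[str, float]] = None   # realizer name -> weight
    complication_ops: frozenset[str] = frozenset({
        "coordinate_theme", "wrap_relative_clause", "insert_apposition",
        "insert_parenthetical", "insert_member_collection",
        "insert_hyponymy_cue"})
    entity_vocab: tuple[str, ...] = tuple(f"PROT{i:03d}" for i in range(1, 41))


# ----------------------------------------------------------------------
# Sentence realizers
#
# Each realizer returns one or more sentence dicts:
#   parse     bracketed parse whose leaves are the sentence tokens
#   entities  token references of annotated entities
#   events    (relation, trigger token ref, [(role, entity token ref)...])
# A token reference is a token index, or (index, lo, hi) for a sub-token
# span (hyphenated compounds).
# ----------------------------------------------------------------------

Sentence = dict


def _np(name: str) -> str:
    return f"(NP (NNP {name}))"


def r_active_transitive(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ phosphorylates) {_np(b)}) (. .))",
        "entities": [0, 2],
        "events": [("Phosphorylation", 1, [("agent", 0), ("theme", 2)])],
    }]


def r_passive(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S {_np(b)} (VP (VBD was) (VP (VBN phosphorylated))) (. .))",
        "entities": [0],
        "events": [("Phosphorylation", 2, [("theme", 0)])],
    }]


def r_passive_by(ents) -> list[Sentence]:
    b, a = ents[:2]
    return [{
        "parse": f"(S {_np(b)} (VP (VBD was) (VP (VBN phosphorylated) "
                 f"(PP (IN by) {_np(a)}))) (. .))",
        "entities": [0, 4],
        "events": [("Phosphorylation", 2, [("agent", 4), ("theme", 0)])],
    }]


def r_with_pp(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ interacts) (PP (IN with) {_np(b)})) (. .))",
        "entities": [0, 3],
        "events": [("Binding", 1, [("theme", 0), ("theme", 3)])],
    }]


def r_reciprocal(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S (NP {_np(a)} (CC and) {_np(b)}) (VP (VBP interact)) (. .))",
        "entities": [0, 2],
        "events": [("Binding", 3, [("theme", 0), ("theme", 2)])],
    }]


def r_unaccusative(ents) -> list[Sentence]:
    a = ents[0]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ localizes)) (. .))",
        "entities": [0],
        "events": [("Localization", 1, [("theme", 0)])],
    }]


def r_nominal_of(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NN "
                 f"phosphorylation)) (PP (IN of) {_np(b)}))) (. .))",
        "entities": [4],
        "events": [("Phosphorylation", 2, [("theme", 4)])],
    }]


def r_nominal_compound(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NNP {b}) "
                 f"(NN phosphorylation))) (. .))",
        "entities": [2],
        "events": [("Phosphorylation", 3, [("theme", 2)])],
    }]


def r_nominal_possessive(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NNP {b}) "
                 f"(POS 's)) (NN phosphorylation))) (. .))",
        "entities": [2],
        "events": [("Phosphorylation", 4, [("theme", 2)])],
    }]


def r_nominal_of_to(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NN binding)) "
                 f"(PP (IN of) {_np(a)}) (PP (TO to) {_np(b)}))) (. .))",
        "entities": [4, 6],
        "events": [("Binding", 2, [("theme", 4), ("theme", 6)])],
    }]


def r_nominal_between(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD reported) (NP (NP (NN interaction))"
                 f" (PP (IN between) (NP {_np(a)} (CC and) {_np(b)})))) (. .))",
        "entities": [4, 6],
        "events": [("Binding", 2, [("theme", 4), ("theme", 6)])],
    }]


def r_nominal_compound_to(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S (NP (NP (NNP {a}) (NN binding)) (PP (TO to) {_np(b)})) "
                 f"(VP (VBD was) (VP (VBN reported))) (. .))",
        "entities": [0, 3],
        "events": [("Binding", 1, [("theme", 0), ("theme", 3)])],
    }]


def r_hyphenated(ents) -> list[Sentence]:
    a = ents[0]
    tok = f"{a}-binding"
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NN {tok}))) (. .))",
        "entities": [(2, 0, len(a))],
        "events": [("Binding", (2, len(a) + 1, len(tok)), [("theme", (2, 0, len(a)))])],
    }]


def r_nominal_of_by(ents) -> list[Sentence]:
    b, a = ents[:2]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NN "
                 f"phosphorylation)) (PP (IN of) {_np(b)}) (PP (IN by) "
                 f"{_np(a)}))) (. .))",
        "entities": [4, 6],
        "events": [("Phosphorylation", 2, [("agent", 6), ("theme", 4)])],
    }]


def r_participle_prenominal(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (VBN phosphorylated)"
                 f" (NNP {b}))) (. .))",
        "entities": [3],
        "events": [("Phosphorylation", 2, [("theme", 3)])],
    }]


def r_predicative(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S {_np(b)} (VP (VBZ is) (ADJP (VBN phosphorylated))) (. .))",
        "entities": [0],
        "events": [("Phosphorylation", 2, [("theme", 0)])],
    }]


def r_null_via(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ activates) {_np(b)} (PP (IN via) "
                 f"(NP (NN phosphorylation)))) (. .))",
        "entities": [0, 2],
        "events": [("Phosphorylation", 4, [("theme", 2)])],
    }]


def r_null_upon(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (PP (IN Upon) (NP (NN phosphorylation))) (, ,) {_np(b)} "
                 f"(VP (VBD translocated)) (. .))",
        "entities": [3],
        "events": [("Phosphorylation", 1, [("theme", 3)])],
    }]


def r_null_undergo(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S {_np(b)} (VP (VBZ undergoes) (NP (NN phosphorylation))) (. .))",
        "entities": [0],
        "events": [("Phosphorylation", 2, [("theme", 0)])],
    }]


def r_null_observed(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (S {_np(b)} (VP (VBD was) (VP (VBN phosphorylated)))) "
                 f"(CC and) (S (NP (NN degradation)) (VP (VBD was) "
                 f"(VP (VBN observed)))) (. .))",
        "entities": [0],
        "events": [("Phosphorylation", 2, [("theme", 0)]),
                   ("Protein_catabolism", 4, [("theme", 0)])],
    }]


def r_null_cause(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VP (VBZ phosphorylates) {_np(b)}) (CC and) "
                 f"(VP (VBZ induces) (NP (NN degradation)))) (. .))",
        "entities": [0, 2],
        "events": [("Phosphorylation", 1, [("agent", 0), ("theme", 2)]),
                   ("Protein_catabolism", 5, [("theme", 2)])],
    }]


def r_null_result(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S {_np(b)} (VP (VBD resulted) (PP (IN in) "
                 f"(NP (NN degradation)))) (. .))",
        "entities": [0],
        "events": [("Protein_catabolism", 3, [("theme", 0)])],
    }]


def r_expression(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ expresses) {_np(b)}) (. .))",
        "entities": [0, 2],
        "events": [("Gene_expression", 1, [("agent", 0), ("theme", 2)])],
    }]


def r_transcription_guard(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ expresses) (NP (NNP {b}) (NN mRNA))) (. .))",
        "entities": [0, 2],
        "events": [("Transcription", 1, [("agent", 0), ("theme", 2)])],
    }]


# -- complication realizers -------------------------------------------


def c_coordinate_theme(ents) -> list[Sentence]:
    a, b, c = ents[:3]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ phosphorylates) (NP {_np(b)} (CC and) "
                 f"{_np(c)})) (. .))",
        "entities": [0, 2, 4],
        "events": [("Phosphorylation", 1, [("agent", 0), ("theme", 2)]),
                   ("Phosphorylation", 1, [("agent", 0), ("theme", 4)])],
    }]


def c_wrap_relative_clause(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD studied) (NP (NP (NNP {b})) (, ,) "
                 f"(SBAR (WHNP (WDT which)) (S (VP (VBD was) "
                 f"(VP (VBN phosphorylated))))))) (. .))",
        "entities": [2],
        "events": [("Phosphorylation", 6, [("theme", 2)])],
    }]


def c_insert_apposition(ents) -> list[Sentence]:
    b = ents[0]
    return [{
        "parse": f"(S (NP (NP (NNP {b})) (, ,) (NP (DT a) (JJ novel) "
                 f"(NN regulator)) (, ,)) (VP (VBD was) (VP (VBN degraded))) (. .))",
        "entities": [0],
        "events": [("Protein_catabolism", 7, [("theme", 0)])],
    }]


def c_insert_parenthetical(ents) -> list[Sentence]:
    a, b = ents[:2]
    return [{
        "parse": f"(S {_np(a)} (VP (VBZ phosphorylates) (NP (NP (DT the) "
                 f"(NN target) (NN kinase)) (PRN (-LRB- -LRB-) {_np(b)} "
                 f"(-RRB- -RRB-)))) (. .))",
        "entities": [0, 6],
        "events": [("Phosphorylation", 1, [("agent", 0), ("theme", 6)])],
    }]


def c_insert_member_collection(ents) -> list[Sentence]:
    b, c = ents[:2]
    return [{
        "parse": f"(S (NP (PRP We)) (VP (VBD observed) (NP (NP (NN expression))"
                 f" (PP (IN of) (NP (NP (DT the) (NN target) (NNS molecules)) "
                 f"(, ,) (PP (JJ such) (IN as) (NP {_np(b)} (CC and) "
                 f"{_np(c)})))))) (. .))",
        "entities": [10, 12],
        "events": [("Gene_expression", 2, [("theme", 10)]),
                   ("Gene_expression", 2, [("theme", 12)])],
    }]


def c_insert_hyponymy_cue(ents) -> list[Sentence]:
    b = ents[0]
    return [
        {
            "parse": f"(S {_np(b)} (VP (VBZ acts) (PP (IN as) (NP (DT a) "
                     f"(JJ strong) (NN regulator)))) (. .))",
            "entities": [0],
            "events": [],
        },
        {
            "parse": "(S (NP (DT The) (JJ strong) (NN regulator)) "
                     "(VP (VBD was) (VP (VBN degraded))) (. .))",
            "entities": [],
            "events": [("Protein_catabolism", 4, [("theme", ("prev", 0))])],
        },
    ]


def base_realizers() -> dict[str, Callable]:
    return {
        "active_transitive": r_active_transitive,
        "passive": r_passive,
        "passive_by": r_passive_by,
        "with_pp": r_with_pp,
        "reciprocal": r_reciprocal,
        "unaccusative": r_unaccusative,
        "nominal_of": r_nominal_of,
        "nominal_compound": r_nominal_compound,
        "nominal_possessive": r_nominal_possessive,
        "nominal_of_to": r_nominal_of_to,
        "nominal_between": r_nominal_between,
        "nominal_compound_to": r_nominal_compound_to,
        "hyphenated": r_hyphenated,
        "nominal_of_by": r_nominal_of_by,
        "participle_prenominal": r_participle_prenominal,
        "predicative": r_predicative,
        "null_via": r_null_via,
        "null_upon": r_null_upon,
        "null_undergo": r_null_undergo,
        "null_observed": r_null_observed,
        "null_cause": r_null_cause,
        "null_result": r_null_result,
        "expression": r_expression,
        "transcription_guard": r_transcription_guard,
    }


def complication_realizers() -> dict[str, Callable]:
    return {
        "coordinate_theme": c_coordinate_theme,
        "wrap_relative_clause": c_wrap_relative_clause,
        "insert_apposition": c_insert_apposition,
        "insert_parenthetical": c_insert_parenthetical,
        "insert_member_collection": c_insert_member_collection,
        "insert_hyponymy_cue": c_insert_hyponymy_cue,
    }


# ----------------------------------------------------------------------
# Bundle assembly
# ----------------------------------------------------------------------


def _leaf_tokens(parse: str) -> list[str]:
    import re as _re
    toks = _re.findall(r"\(|\)|[^\s()]+", parse)
    out = []
    depth_label = False
    prev = None
    for t in toks:
        if t == "(":
            depth_label = True
        elif t == ")":
            depth_label = False
        else:
            if depth_label:
                depth_label = False  # this token is a label
            else:
                out.append(t)
        prev = t
    return out


_UNESCAPE = {"-LRB-": "(", "-RRB-": ")", "-LSB-": "[", "-RSB-": "]",
             "-LCB-": "{", "-RCB-": "}"}


def _token_spans(tokens: list[str]) -> list[tuple[int, int]]:
    spans = []
    pos = 0
    for t in tokens:
        spans.append((pos, pos + len(t)))
        pos += len(t) + 1
    return spans


def generate(recipe: FixtureRecipe) -> dict:
    """Generate a document bundle: txt, parses, sentence offsets, a1, a2.

    Deterministic per seed.  Gold events reference the .a1 annotations so
    a pipeline run against the bundle's own gold scores exactly.
    """
    rng = random.Random(recipe.seed)
    bases = base_realizers()
    comps = {k: v for k, v in complication_realizers().items()
             if k in recipe.complication_ops}
    mix = recipe.template_mix
    if mix is None:
        mix = {name: 1.0 for name in list(bases) + list(comps)}
    names = sorted(mix)
    weights = [mix[n] for n in names]

    sentences: list[dict] = []
    produced = 0
    while produced < recipe.n_sentences:
        name = rng.choices(names, weights=weights, k=1)[0]
        realizer = bases.get(name) or comps.get(name)
        if realizer is None:
            raise KeyError(f"unknown realizer {name!r} in template_mix")
        ents = rng.sample(recipe.entity_vocab, 3)
        group = realizer(ents)
        sentences.extend(group)
        produced += 1

    txt_lines: list[str] = []
    parse_lines: list[str] = []
    sent_offsets: list[tuple[int, int]] = []
    a1_entries: list[tuple[tuple[int, int], str]] = []   # (global span, text)
    gold_events: list[tuple[str, tuple[int, int], str,
                            list[tuple[str, tuple[int, int]]]]] = []
    offset = 0
    prev_entity_spans: list[tuple[int, int]] = []

    for sent in sentences:
        tokens = [_UNESCAPE.get(t, t) for t in _leaf_tokens(sent["parse"])]
        spans = _token_spans(tokens)
        text = " ".join(tokens)

        def tok_span(ref) -> tuple[int, int]:
            if isinstance(ref, tuple) and ref and ref[0] == "prev":
                return prev_entity_spans[ref[1]]
            if isinstance(ref, tuple):
                i, lo, hi = ref
                return (offset + spans[i][0] + lo, offset + spans[i][0] + hi)
            return (offset + spans[ref][0], offset + spans[ref][1])

        entity_spans_here = []
        for ref in sent["entities"]:
            span = tok_span(ref)
            a1_entries.append((span, _span_text(tokens, spans, ref)))
            entity_spans_here.append(span)
        for relation, trig_ref, args in sent["events"]:
            tspan = tok_span(trig_ref)
            ttext = _span_text(tokens, spans, trig_ref)
            gold_events.append(
                (relation, tspan, ttext,
                 [(role, tok_span(eref)) for role, eref in args]))
        txt_lines.append(text)
        parse_lines.append(sent["parse"])
        sent_offsets.append((offset, offset + len(text)))
        offset += len(text) + 1
        prev_entity_spans = entity_spans_here

    txt = "\n".join(txt_lines) + "\n"
    a1_entries.sort(key=lambda e: e[0])
    tid_of: dict[tuple[int, int], str] = {}
    a1_lines = []
    for i, (span, text) in enumerate(a1_entries, start=1):
        tid = f"T{i}"
        tid_of[span] = tid
        a1_lines.append(f"{tid}\tProtein {span[0]} {span[1]}\t{text}")

    a2_lines = []
    trig_tid: dict[tuple[str, tuple[int, int]], str] = {}
    next_t = len(a1_entries) + 1
    for relation, tspan, ttext, _args in gold_events:
        key = (relation, tspan)
        if key not in trig_tid:
            trig_tid[key] = f"T{next_t}"
            next_t += 1
            a2_lines.append(f"{trig_tid[key]}\t{relation} {tspan[0]} "
                            f"{tspan[1]}\t{ttext}")
    for i, (relation, tspan, _ttext, args) in enumerate(gold_events, start=1):
        parts = [f"{relation}:{trig_tid[(relation, tspan)]}"]
        theme_n = 0
        for role, span in args:
            if role == "theme":
                theme_n += 1
                name = "Theme" if theme_n == 1 else f"Theme{theme_n}"
            else:
                name = "Cause"
            parts.append(f"{name}:{tid_of[span]}")
        a2_lines.append(f"E{i}\t" + " ".join(parts))

    return {
        "txt": txt,
        "parses": parse_lines,
        "sentences": sent_offsets,
        "a1": "\n".join(a1_lines) + ("\n" if a1_lines else ""),
        "a2": "\n".join(a2_lines) + ("\n" if a2_lines else ""),
    }


def _span_text(tokens: list[str], spans, ref) -> str:
    if isinstance(ref, tuple) and ref and ref[0] == "prev":
        raise ValueError("cross-sentence reference has no local text")
    if isinstance(ref, tuple):
        i, lo, hi = ref
        return tokens[i][lo:hi]
    return tokens[ref]
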