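"""Trigger-specification parsing, morphological derivation and frames."""

import pytest
from hypothesis import given, settings, strategies as st

from trigex.templates import frame_template_ids, list_templates
from trigex.triggers import (
    FormCategory,
    NominalClass,
    TriggerSpecError,
    default_registry,
    derive_trigger_forms,
    parse_trigger_spec,
    process_forms,
    select_frame,
)

PHOS_SPEC = """\
trigger: phosphorylate
relation: Phosphorylation
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = GGP | protein_part
role: NP0 = agent
role: NP1 = theme
direction: directional
affixes: -ion, under-, hyper-
"""

EXPRESS_HOMONYMS = """\
trigger: express
relation: Gene_expression
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = gene
role: NP0 = agent
role: NP1 = theme

trigger: express
relation: Transcription
frame: NP0/NP1
type: NP0 = GGP
type: NP1 = rna
role: NP0 = agent
role: NP1 = theme
guard: NP1 ~ mRNA
"""


class TestSpecParsing:
    def test_phosphorylate_specification(self):
        (spec,) = parse_trigger_spec(PHOS_SPEC)
        assert spec.root == "phosphorylate"
        assert spec.relation == "Phosphorylation"
        assert spec.frame == "NP0/NP1"
        assert spec.slot(0).allowed_types == {"GGP"}
        assert spec.slot(1).allowed_types == {"GGP", "protein_part"}
        assert spec.roles == {0: "agent", 1: "theme"}
        assert spec.direction == "directional"

    def test_homonymous_roots_yield_distinct_specs(self):
        specs = parse_trigger_spec(EXPRESS_HOMONYMS)
        assert len(specs) == 2
        assert {s.relation for s in specs} == {"Gene_expression",
                                               "Transcription"}
        assert all(s.root == "express" for s in specs)
        assert specs[1].lexical_guards == {1: "mRNA"}

    def test_empty_file_gives_empty_list(self):
        assert parse_trigger_spec("") == []
        assert parse_trigger_spec("\n\n# comment\n") == []

    @pytest.mark.parametrize("bad,match", [
        ("trigger: x\nrelation: R\nframe: NPX\n", "unknown frame"),
        ("trigger: x\nrelation: R\nframe: NP0\ntype: NP0 = GGP\n"
         "role: NP3 = agent\n", "undeclared slot"),
        ("trigger: x\nrelation: R\nframe: NP0\ntype: NP0 = blob\n",
         "unknown semantic type"),
    ])
    def test_errors_name_line_numbers(self, bad, match):
        with pytest.raises(TriggerSpecError, match=match):
            parse_trigger_spec(bad)


class TestDerivation:
    def test_phosphorylate_forms(self):
        surfaces = {f.surface for f in derive_trigger_forms(
            "phosphorylate", ["-ion", "under-", "hyper-"])}
        assert {"phosphorylates", "phosphorylated", "phosphorylating",
                "phosphorylation", "phosphorylations",
                "underphosphorylation", "hyperphosphorylated"} <= surfaces

    def test_cleave_gives_cleavage(self):
        surfaces = {f.surface for f in derive_trigger_forms("cleave", ["-age"])}
        assert "cleavage" in surfaces

    def test_express_prefix_composition(self):
        surfaces = {f.surface for f in derive_trigger_forms(
            "express", ["-ion", "over-", "co-", "non-", "re-"])}
        assert {"expression", "overexpression", "coexpression",
                "reexpression", "nonexpression", "expresses",
                "expressed"} <= surfaces

    @pytest.mark.parametrize("root,affix,expected", [
        ("transcribe", "-tion", "transcription"),
        ("proteolyse", "-sis", "proteolysis"),
        ("secrete", "-ion", "secretion"),
        ("degrade", "-tion", "degradation"),
        ("localize", "-ation", "localization"),
        ("engage", "-ment", "engagement"),
        ("appear", "-ance", "appearance"),
        ("bind", "-ing", "binding"),
        ("initiate", "-tion", "initiation"),
    ])
    def test_nominalizations(self, root, affix, expected):
        forms = derive_trigger_forms(root, [affix])
        noms = [f.surface for f in forms if f.category is FormCategory.nominal]
        assert expected in noms

    def test_irregular_bind(self):
        surfaces = {f.surface for f in derive_trigger_forms("bind", [])}
        assert "bound" in surfaces
        assert "binded" not in surfaces

    def test_entity_nominals_flagged_and_excluded(self):
        forms = derive_trigger_forms("transcribe", ["-tion"])
        entity = [f for f in forms
                  if f.nominal_class is NominalClass.entity]
        assert {f.surface for f in entity} == {"transcript", "transcripts"}
        assert all(f not in process_forms(forms) for f in entity)

    def test_unknown_affix_ignored_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            forms = derive_trigger_forms("bind", ["-zzz"])
        assert "ignoring unknown affix" in caplog.text
        assert all("-zzz" not in f.derivation for f in forms)

    def test_deterministic_idempotent_no_duplicates(self):
        a = derive_trigger_forms("phosphorylate", ["-ion", "over-"])
        b = derive_trigger_forms("phosphorylate", ["-ion", "over-"])
        assert a == b
        keys = [(f.surface, f.category) for f in a]
        assert len(keys) == len(set(keys))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.sampled_from(["phosphorylate", "bind", "express", "degrade",
                            "cleave", "localize", "carry", "transcribe",
                            "ligate", "associate"]))
    def test_forms_begin_with_root_stem(self, root):
        """After stripping prefixes, every surface shares the root's stem
        under e-drop / y->ie / consonant-doubling / irregular rules."""
        from trigex.triggers import IRREGULAR_VERBS, PREFIXES
        stems = {root[:4]}
        if root in IRREGULAR_VERBS:
            stems |= {f[:4] for f in IRREGULAR_VERBS[root]}
        if root == "transcribe":
            stems.add("tran")
        forms = derive_trigger_forms(
            root, ["-ion", "-ing", "over-", "co-", "re-"])
        for f in forms:
            s = f.surface
            for p in PREFIXES:
                body = p[:-1]
                if f.derivation.startswith(p) and s.startswith(body):
                    s = s[len(body):]
            assert any(s.startswith(stem) for stem in stems), (root, f)


class TestFrames:
    def test_directional_frame_never_swaps(self):
        (spec,) = parse_trigger_spec(PHOS_SPEC)
        frame = select_frame(spec, default_registry())
        assert not frame.allows_swap

    def test_non_directional_frame_allows_swap(self):
        spec = parse_trigger_spec(
            "trigger: bind\nrelation: Binding\nframe: NP0/NP1\n"
            "type: NP0 = GGP\ntype: NP1 = GGP\nrole: NP0 = theme\n"
            "role: NP1 = theme\ndirection: non-directional\n")[0]
        frame = select_frame(spec, default_registry())
        assert frame.allows_swap
        nondir_only = {t.id for t in list_templates() if t.nondirectional_only}
        assert nondir_only <= frame.compatible_templates

    def test_np0_frame_has_no_passive_templates(self):
        passive = {t.id for t in list_templates()
                   if t.constraints.get("voice") == "passive"}
        assert frame_template_ids("NP0") & passive == set()

    def test_unregistered_frame_errors(self):
        (spec,) = parse_trigger_spec(PHOS_SPEC)
        object.__setattr__(spec, "frame", "NP9")
        with pytest.raises(KeyError):
            select_frame(spec, default_registry())

    def test_slot_arity_matches_spec_slots(self):
        reg = default_registry()
        for text in (PHOS_SPEC, EXPRESS_HOMONYMS):
            for spec in parse_trigger_spec(text):
                assert select_frame(spec, reg).slot_arity == len(spec.slots)
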