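"""Template inventory, pattern generation and pair combination."""

import re

import pytest

from trigex.entities import EntityMention
from trigex.templates import (
    TriggerArgPair,
    dump_inventory,
    generate_patterns,
    list_templates,
    pairs_to_events,
)
from trigex.triggers import (
    default_registry,
    derive_trigger_forms,
    parse_trigger_spec,
    select_frame,
)

PHOS = ("trigger: phosphorylate\nrelation: Phosphorylation\nframe: NP0/NP1\n"
        "type: NP0 = GGP\ntype: NP1 = GGP | protein_part\n"
        "role: NP0 = agent\nrole: NP1 = theme\naffixes: -ion\n")
BIND = ("trigger: bind\nrelation: Binding\nframe: NP0/NP1\n"
        "type: NP0 = GGP\ntype: NP1 = GGP\nrole: NP0 = theme\n"
        "role: NP1 = theme\ndirection: non-directional\naffixes: -ing\n")
LOC = ("trigger: localize\nrelation: Localization\nframe: NP1\n"
       "type: NP1 = GGP\nrole: NP1 = theme\naffixes: -ation\n")
INTR = ("trigger: signal\nrelation: Signaling\nframe: NP0\n"
        "type: NP0 = GGP\nrole: NP0 = agent\n")


def _patterns(spec_text):
    (spec,) = parse_trigger_spec(spec_text)
    forms = derive_trigger_forms(spec.root, list(spec.affixes))
    frame = select_frame(spec, default_registry())
    return spec, forms, generate_patterns(spec, forms, frame)


class TestInventory:
    def test_exactly_26_templates(self):
        assert len(list_templates()) == 26

    def test_group_partition(self):
        groups = {}
        for t in list_templates():
            groups[t.group] = groups.get(t.group, 0) + 1
        assert groups == {"verbal": 7, "nominal": 9, "adjectival": 4,
                          "null_argument": 6}

    def test_null_argument_subset_nonempty(self):
        assert [t for t in list_templates() if t.group == "null_argument"]

    def test_at_most_one_argument_placeholder(self):
        for t in list_templates():
            args = [e for e in t.elements if re.fullmatch(r"NP_\d+", e)]
            assert len(args) <= 1, t.id

    def test_exactly_one_trigger_placeholder(self):
        for t in list_templates():
            trig = [e for e in t.elements
                    if e in ("V_tr", "N_tr", "Adj_tr")]
            assert len(trig) == 1, t.id

    def test_stable_ids_and_serialization(self):
        ids = [t.id for t in list_templates()]
        assert len(ids) == len(set(ids))
        dump = dump_inventory()
        assert dump.splitlines()[0].endswith("v1")
        assert len(dump.strip().splitlines()) == 27  # header + 26 records
        for t in list_templates():
            assert any(line.startswith(t.id + "\t")
                       for line in dump.splitlines()[1:])


class TestGeneration:
    def test_phosphorylate_active_and_passive_realizations(self):
        _, _, pats = _patterns(PHOS)
        realized = {(p.template_id, p.form.surface) for p in pats}
        assert ("V1", "phosphorylates") in realized   # NP_0 phosphorylates
        assert ("V3", "phosphorylated") in realized   # NP_1 is phosphorylated
        assert ("N1", "phosphorylation") in realized
        assert ("A1", "phosphorylated") in realized

    def test_directional_spec_excludes_nondirectional_templates(self):
        _, _, pats = _patterns(PHOS)
        nondir_only = {t.id for t in list_templates() if t.nondirectional_only}
        assert not {p.template_id for p in pats} & nondir_only

    def test_non_directional_includes_between_and_with_templates(self):
        _, _, pats = _patterns(BIND)
        ids = {p.template_id for p in pats}
        assert {"V5", "V6", "N5", "N6", "N7"} <= ids
        # swapped-role twins: every captured pattern accepts both slots
        for p in pats:
            if p.slot_candidates and p.template.captured_slot is not None:
                assert set(p.slot_candidates) == {0, 1}

    def test_swap_closure_of_non_directional_output(self):
        _, _, pats = _patterns(BIND)
        sigs = {(p.template_id, p.form.surface,
                 frozenset(p.slot_candidates)) for p in pats}
        swapped = {(tid, s, frozenset(1 - c for c in cands))
                   for tid, s, cands in sigs}
        assert swapped == sigs

    def test_frame_np0_generates_no_passive_patterns(self):
        _, _, pats = _patterns(INTR)
        assert {p.template_id for p in pats} == {"V1"}

    def test_unaccusative_frame_has_theme_subject_template(self):
        _, _, pats = _patterns(LOC)
        ids = {p.template_id for p in pats}
        assert "V7" in ids and "V1" not in ids and "V3" not in ids

    def test_output_size_is_cross_product_and_duplicate_free(self):
        spec, forms, pats = _patterns(PHOS)
        frame = select_frame(spec, default_registry())
        from trigex.templates import _form_compatible
        expected = 0
        for t in list_templates():
            if t.id not in frame.compatible_templates or t.nondirectional_only:
                continue
            expected += sum(1 for f in forms if _form_compatible(t, f))
        assert len(pats) == expected
        keys = [(p.template_id, p.form.surface, p.form.category) for p in pats]
        assert len(keys) == len(set(keys))

    def test_entity_nominals_never_instantiate(self):
        spec = parse_trigger_spec(
            "trigger: transcribe\nrelation: Transcription\nframe: NP0/NP1\n"
            "type: NP0 = GGP\ntype: NP1 = GGP\nrole: NP0 = agent\n"
            "role: NP1 = theme\naffixes: -tion\n")[0]
        forms = derive_trigger_forms("transcribe", ["-tion"])
        pats = generate_patterns(spec, forms,
                                 select_frame(spec, default_registry()))
        assert "transcript" not in {p.form.surface for p in pats}
        assert "transcription" in {p.form.surface for p in pats}


def _m(span, text, sem="GGP"):
    return EntityMention(span, text, sem, source="preannotated")


def _pair(relation, tspan, arg, role, directional=True):
    return TriggerArgPair(relation, tspan, "trig", 1 if role == "theme" else 0,
                          arg, role, directional=directional)


class TestPairCombination:
    def test_agent_and_theme_merge_into_one_event(self):
        pairs = [_pair("Phosphorylation", (4, 18), _m((0, 3), "JNK"), "agent"),
                 _pair("Phosphorylation", (4, 18), _m((19, 24), "NFAT4"),
                       "theme")]
        (event,) = pairs_to_events(pairs)
        assert event.args["agent"][0].text == "JNK"
        assert event.args["theme"][0].text == "NFAT4"

    def test_singleton_theme_pair(self):
        (event,) = pairs_to_events(
            [_pair("Phosphorylation", (0, 4), _m((5, 10), "NFAT4"), "theme")])
        assert "agent" not in event.args

    def test_binding_collects_multiple_themes(self):
        pairs = [_pair("Binding", (2, 6), _m((10, 11), "A"), "theme", False),
                 _pair("Binding", (2, 6), _m((14, 15), "B"), "theme", False)]
        (event,) = pairs_to_events(pairs)
        assert len(event.args["theme"]) == 2

    def test_directional_trigger_splits_per_theme(self):
        pairs = [_pair("Phosphorylation", (2, 6), _m((10, 11), "A"), "agent"),
                 _pair("Phosphorylation", (2, 6), _m((14, 15), "B"), "theme"),
                 _pair("Phosphorylation", (2, 6), _m((18, 19), "C"), "theme")]
        events = pairs_to_events(pairs)
        assert len(events) == 2
        assert all(e.args["agent"][0].text == "A" for e in events)

    def test_two_agents_kept_as_alternatives_with_warning(self, caplog):
        import logging
        pairs = [_pair("Phosphorylation", (2, 6), _m((10, 11), "A"), "agent"),
                 _pair("Phosphorylation", (2, 6), _m((12, 13), "B"), "agent"),
                 _pair("Phosphorylation", (2, 6), _m((14, 15), "C"), "theme")]
        with caplog.at_level(logging.WARNING):
            events = pairs_to_events(pairs)
        assert len(events) == 2
        assert "competing agents" in caplog.text

    def test_agent_only_group_emits_no_event(self):
        assert pairs_to_events(
            [_pair("Phosphorylation", (0, 4), _m((5, 6), "A"), "agent")]) == []
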