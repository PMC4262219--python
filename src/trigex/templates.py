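"""The fixed pattern-template inventory and pattern instantiation.

A pattern template is an abstract sequence of elements -- literal words, a
trigger placeholder (V_tr / N_tr / Adj_tr), at most one argument
placeholder NP_i, and wildcards -- plus feature constraints (voice,
preposition literals, form category).  Instantiated with a concrete
trigger form it becomes a lexico-syntactic pattern whose anchor is a tree
pattern locating the trigger occurrence; the structural constraints are
enforced by the matcher.

The inventory is fixed at 26 templates: 7 verbal, 9 nominal, 4 adjectival
and 6 null-argument (elliptical) templates.  Each template captures one
argument at a time; pairs sharing a trigger occurrence are combined into
events afterwards.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .entities import EntityMention
from .trees import TreePattern, compile_pattern
from .triggers import (
    Frame,
    FormCategory,
    NominalClass,
    TriggerForm,
    TriggerSpecification,
)

log = logging.getLogger(__name__)

__all__ = [
    "PatternTemplate",
    "LexicoSyntacticPattern",
    "TriggerArgPair",
    "Event",
    "list_templates",
    "frame_template_ids",
    "generate_patterns",
    "pairs_to_events",
    "dump_inventory",
    "INVENTORY_VERSION",
]

INVENTORY_VERSION = "1"


@dataclass(frozen=True)
class PatternTemplate:
    id: str
    group: str                       # verbal | nominal | adjectival | null_argument
    elements: tuple[str, ...]        # beta_1 ... beta_n
    constraints: dict[str, str] = field(default_factory=dict, hash=False)
    captured_slot: Optional[int] = None
    directional_only: bool = False
    nondirectional_only: bool = False

    def __post_init__(self):
        trig = [e for e in self.elements if e in ("V_tr", "N_tr", "Adj_tr")]
        if len(trig) != 1:
            raise ValueError(f"{self.id}: exactly one trigger placeholder required")
        args = [e for e in self.elements if re.fullmatch(r"NP_\d+", e)]
        if len(args) > 1:
            raise ValueError(f"{self.id}: at most one argument placeholder allowed")


def _t(id, group, elements, captured_slot=None, *, dir_only=False,
       nondir_only=False, **constraints) -> PatternTemplate:
    return PatternTemplate(id, group, tuple(elements), dict(constraints),
                           captured_slot, dir_only, nondir_only)


# The inventory.  NP* is a non-captured argument wildcard; literal
# alternations are written with '|'.
_TEMPLATES: tuple[PatternTemplate, ...] = (
    # -- verbal (7) ----------------------------------------------------
    _t("V1", "verbal", ("NP_0", "V_tr"), 0, voice="active"),
    _t("V2", "verbal", ("V_tr", "NP_1"), 1, voice="active"),
    _t("V3", "verbal", ("NP_1", "be", "V_tr"), 1, voice="passive"),
    _t("V4", "verbal", ("V_tr", "by", "NP_0"), 0, voice="passive", prep="by"),
    _t("V5", "verbal", ("V_tr", "with|to|at", "NP_1"), 1, nondir_only=True,
       voice="any", prep="with|to|at"),
    _t("V6", "verbal", ("NP_1", "and", "NP*", "V_tr"), 1, nondir_only=True,
       voice="active"),
    _t("V7", "verbal", ("NP_1", "V_tr"), 1, voice="active", frame="NP1"),
    # -- nominal (9) ---------------------------------------------------
    _t("N1", "nominal", ("N_tr", "of", "NP_1"), 1, prep="of"),
    _t("N2", "nominal", ("NP_1", "N_tr"), 1, shape="compound"),
    _t("N3", "nominal", ("N_tr", "by", "NP_0"), 0, prep="by"),
    _t("N4", "nominal", ("NP_1", "'s", "N_tr"), 1, shape="possessive"),
    _t("N5", "nominal", ("N_tr", "of", "NP*", "to|with", "NP_1"), 1,
       nondir_only=True, prep="to|with"),
    _t("N6", "nominal", ("N_tr", "between", "NP_1", "and", "NP*"), 1,
       nondir_only=True, prep="between"),
    _t("N7", "nominal", ("NP*", "N_tr", "to|with", "NP_1"), 1,
       nondir_only=True, prep="to|with"),
    _t("N8", "nominal", ("NP_1", "-", "N_tr"), 1, shape="hyphenated"),
    _t("N9", "nominal", ("N_tr", "of", "NP*", "by", "NP_0"), 0, prep="by"),
    # -- adjectival (4) ------------------------------------------------
    _t("A1", "adjectival", ("Adj_tr", "NP_1"), 1, form="past-participle"),
    _t("A2", "adjectival", ("Adj_tr", "NP_0"), 0, dir_only=True,
       form="present-participle"),
    _t("A3", "adjectival", ("Adj_tr", "NP_1"), 1, nondir_only=True,
       form="present-participle"),
    _t("A4", "adjectival", ("NP_1", "be", "Adj_tr"), 1, shape="predicative"),
    # -- null argument (6): the elided theme is recovered from the
    #    surrounding clause or from another trigger's argument -----------
    _t("Z1", "null_argument", ("via", "N_tr"),
       recover="governing_verb_object"),
    _t("Z2", "null_argument", ("upon|after|following", "N_tr"),
       recover="matrix_subject"),
    _t("Z3", "null_argument", ("NP*", "undergo", "N_tr"),
       recover="matrix_subject", verbs="undergo"),
    _t("Z4", "null_argument", ("N_tr", "be", "observed|detected|seen|found"),
       recover="antecedent_theme"),
    _t("Z5", "null_argument", ("induce|prevent|cause|block|promote|inhibit",
                               "N_tr"),
       recover="antecedent_theme",
       verbs="induce|prevent|cause|block|promote|inhibit"),
    _t("Z6", "null_argument", ("result", "in", "N_tr"),
       recover="matrix_subject", verbs="result"),
)

_BY_ID = {t.id: t for t in _TEMPLATES}


def list_templates() -> list[PatternTemplate]:
    """The full fixed inventory (26 templates, stable ids and order)."""
    return list(_TEMPLATES)


def frame_template_ids(frame_name: str) -> set[str]:
    """Template ids compatible with a frame.

    The transitive frame carries everything except the unaccusative
    template; the intransitive agentive frame has the active-subject
    template only (intransitives cannot be passivized); the unaccusative
    frame carries subject/nominal/adjectival theme realizations but no
    passives and no agent templates.
    """
    if frame_name == "NP0/NP1":
        return {t.id for t in _TEMPLATES} - {"V7"}
    if frame_name == "NP0":
        return {"V1"}
    if frame_name == "NP1":
        return {"V7", "N1", "N2", "N4", "N8", "A1", "A4",
                "Z1", "Z2", "Z3", "Z4", "Z5", "Z6"}
    raise KeyError(f"unknown frame {frame_name!r}")


# trigger-form category -> template groups it can instantiate
_CATEGORY_GROUPS = {
    FormCategory.verb_finite: ("verbal",),
    FormCategory.verb_base: ("verbal",),
    FormCategory.verb_ppart: ("verbal", "adjectival"),
    FormCategory.verb_prespart: ("adjectival",),
    FormCategory.nominal: ("nominal", "null_argument"),
    FormCategory.adjectival: ("adjectival",),
}


def _form_compatible(template: PatternTemplate, form: TriggerForm) -> bool:
    if template.group not in _CATEGORY_GROUPS[form.category]:
        return False
    want = template.constraints.get("form")
    if want == "past-participle":
        return form.category is FormCategory.verb_ppart
    if want == "present-participle":
        return form.category is FormCategory.verb_prespart
    if template.id == "A4":
        return form.category in (FormCategory.verb_ppart, FormCategory.adjectival)
    return True


@dataclass(frozen=True)
class LexicoSyntacticPattern:
    """A template instantiated with one trigger form of one specification."""

    template_id: str
    spec: TriggerSpecification
    form: TriggerForm
    tree_pattern: TreePattern
    slot_candidates: tuple[int, ...] = ()

    @property
    def template(self) -> PatternTemplate:
        return _BY_ID[self.template_id]


def _anchor_expression(template: PatternTemplate, surface: str) -> str:
    esc = re.escape(surface)
    if template.constraints.get("shape") == "hyphenated":
        return f"/(?i)^[^\\s]+-{esc}$/=trig"
    return f"/(?i)^{esc}$/=trig"


def generate_patterns(spec: TriggerSpecification, forms: list[TriggerForm],
                      frame: Frame) -> list[LexicoSyntacticPattern]:
    """Cross product of the frame's templates with the compatible forms.

    Non-directional-only templates are included iff the frame allows role
    swapping; for a swapping frame every pattern additionally accepts the
    swapped slot assignment (closure under NP_0/NP_1 exchange), so that
    "A binds B" and "B binds A" yield the same relation.  Entity-class
    nominal forms never instantiate patterns.
    """
    usable = [f for f in forms
              if not (f.category is FormCategory.nominal
                      and f.nominal_class is not NominalClass.process)]
    slot_indices = {s.index for s in spec.slots}
    out: list[LexicoSyntacticPattern] = []
    for template in _TEMPLATES:
        if template.id not in frame.compatible_templates:
            continue
        if template.nondirectional_only and not frame.allows_swap:
            continue
        if template.directional_only and frame.allows_swap:
            continue
        for form in usable:
            if not _form_compatible(template, form):
                continue
            cands: tuple[int, ...] = ()
            if template.captured_slot is None:
                # null-argument templates recover the elided theme
                cands = spec.theme_slots
            else:
                primary = template.captured_slot
                if primary not in slot_indices and len(slot_indices) == 1:
                    primary = next(iter(slot_indices))
                cands = (primary,)
                if frame.allows_swap:
                    other = 1 - primary
                    if other in slot_indices:
                        cands = (primary, other)
            out.append(LexicoSyntacticPattern(
                template.id, spec, form,
                compile_pattern(_anchor_expression(template, form.surface)),
                cands,
            ))
    return out


# ----------------------------------------------------------------------
# Pair combination
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TriggerArgPair:
    """One <trigger, NP_i> capture with its role, in original coordinates."""

    relation: str
    trigger_span: tuple[int, int]
    trigger_form: str
    slot: int
    arg: EntityMention
    role: str
    provenance: str = ""
    directional: bool = True
    root: str = ""                 # trigger root, for homonym grouping
    guard_passed: bool = False     # a lexical guard applied and succeeded


@dataclass(frozen=True)
class Event:
    """A typed relation instance: trigger occurrence plus role->arguments."""

    relation: str
    trigger_span: tuple[int, int]
    trigger_text: str
    args: dict[str, tuple[EntityMention, ...]] = field(hash=False)

    def __post_init__(self):
        if not self.args.get("theme"):
            raise ValueError("an event requires at least one theme")

    def key(self) -> tuple:
        return (self.relation, self.trigger_span,
                tuple(sorted((role, tuple(sorted(m.span for m in ms)))
                             for role, ms in self.args.items())))


def pairs_to_events(pairs: list[TriggerArgPair]) -> list[Event]:
    """Combine pairs sharing a trigger occurrence into events.

    A trigger occurrence is identified by (relation, trigger span).  For a
    non-directional relation all captured themes join one event (a Binding
    may carry several themes).  For a directional relation each theme forms
    its own event and any agent attaches to each; two competing agents are
    kept as alternative events with a logged warning.  Pairs without a
    theme yield no event.
    """
    groups: dict[tuple, list[TriggerArgPair]] = {}
    order: list[tuple] = []
    for p in pairs:
        key = (p.relation, p.trigger_span)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(p)

    events: list[Event] = []
    for key in order:
        relation, tspan = key
        group = groups[key]
        trig_text = group[0].trigger_form
        themes = _unique([p.arg for p in group if p.role == "theme"])
        agents = _unique([p.arg for p in group if p.role == "agent"])
        if not themes:
            continue
        directional = all(p.directional for p in group)
        if len(agents) > 1 and directional:
            log.warning("trigger %s@%s has %d competing agents; emitting "
                        "alternative events", trig_text, tspan, len(agents))
        if directional:
            agent_options: list[Optional[EntityMention]] = agents or [None]
            for agent in agent_options:
                for theme in themes:
                    args = {"theme": (theme,)}
                    if agent is not None:
                        args["agent"] = (agent,)
                    events.append(Event(relation, tspan, trig_text, args))
        else:
            args = {"theme": tuple(themes)}
            if agents:
                args["agent"] = tuple(agents)
            if len(themes) > 2:
                log.warning("non-directional trigger %s@%s carries %d themes; "
                            "flagged for review", trig_text, tspan, len(themes))
            events.append(Event(relation, tspan, trig_text, args))
    return _dedup_events(events)


def _unique(mentions: list[EntityMention]) -> list[EntityMention]:
    seen: set[tuple[int, int]] = set()
    out = []
    for m in sorted(mentions, key=lambda m: m.span):
        if m.span not in seen:
            seen.add(m.span)
            out.append(m)
    return out


def _dedup_events(events: list[Event]) -> list[Event]:
    seen: set[tuple] = set()
    out = []
    for e in events:
        k = e.key()
        if k not in seen:
            seen.add(k)
            out.append(e)
    return out


def dump_inventory() -> str:
    """Tab-separated serialization of the inventory (one record per line)."""
    lines = [f"# pattern-template inventory v{INVENTORY_VERSION}"]
    for t in _TEMPLATES:
        flags = []
        if t.directional_only:
            flags.append("directional_only")
        if t.nondirectional_only:
            flags.append("nondirectional_only")
        cons = ";".join(f"{k}={v}" for k, v in sorted(t.constraints.items()))
        lines.append("\t".join([
            t.id, t.group, " ".join(t.elements),
            "" if t.captured_slot is None else str(t.captured_slot),
            cons, ",".join(flags),
        ]))
    return "\n".join(lines) + "\n"
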