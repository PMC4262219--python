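"""Trigger specifications, surface-form derivation and frames.

A trigger is declared by its verbal root morpheme (e.g. ``phosphorylate``)
together with the relation it signals, a subcategorization frame, per-slot
semantic-type constraints, role assignments and a directionality flag.
All surface forms used for matching -- finite verb forms, participles,
process nominals and adjectival derivatives -- are generated from the root
by a rule table (e-drop, y->ie, consonant doubling) backed by an explicit
exception lexicon for irregular derivations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

log = logging.getLogger(__name__)

__all__ = [
    "ArgSlot",
    "TriggerSpecification",
    "TriggerForm",
    "FormCategory",
    "NominalClass",
    "Frame",
    "FrameRegistry",
    "TriggerSpecError",
    "SEMANTIC_TYPES",
    "parse_trigger_spec",
    "derive_trigger_forms",
    "select_frame",
    "default_registry",
]

SEMANTIC_TYPES = {
    "GGP", "gene", "rna", "protein", "protein_part", "gene_part",
    "chemical", "class_noun", "other",
}

VOWELS = "aeiou"


class TriggerSpecError(ValueError):
    """Raised on a malformed trigger specification file (carries line number)."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class FormCategory(str, Enum):
    verb_finite = "verb_finite"
    verb_ppart = "verb_ppart"
    verb_prespart = "verb_prespart"
    verb_base = "verb_base"
    nominal = "nominal"
    adjectival = "adjectival"


class NominalClass(str, Enum):
    process = "process"   # actions/states/processes: used for pattern generation
    entity = "entity"     # result entities ("transcript"): derivable, excluded


@dataclass(frozen=True)
class ArgSlot:
    """One syntactic argument slot NP_i with its allowed semantic types."""

    index: int
    allowed_types: frozenset[str]

    def __post_init__(self):
        if not self.allowed_types:
            raise ValueError("allowed_types must be non-empty")
        unknown = set(self.allowed_types) - SEMANTIC_TYPES
        if unknown:
            raise ValueError(f"unknown semantic types: {sorted(unknown)}")


@dataclass(frozen=True)
class TriggerSpecification:
    root: str
    relation: str
    frame: str
    slots: tuple[ArgSlot, ...]
    roles: dict[int, str] = field(hash=False)
    direction: str = "directional"
    lexical_guards: dict[int, str] = field(default_factory=dict, hash=False)
    affixes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.root or self.root != self.root.lower() or " " in self.root:
            raise ValueError("root must be lowercase, non-empty, without whitespace")
        indices = {s.index for s in self.slots}
        for i in self.roles:
            if i not in indices:
                raise ValueError(f"role assigned to undeclared slot NP{i}")
        for role in self.roles.values():
            if role not in ("agent", "theme"):
                raise ValueError(f"unknown role {role!r}")
        if self.direction == "non-directional" and len(self.slots) < 2:
            raise ValueError("non-directional triggers need at least two slots")

    def slot(self, index: int) -> ArgSlot:
        for s in self.slots:
            if s.index == index:
                return s
        raise KeyError(index)

    @property
    def theme_slots(self) -> tuple[int, ...]:
        return tuple(i for i, r in sorted(self.roles.items()) if r == "theme")

    @property
    def agent_slots(self) -> tuple[int, ...]:
        return tuple(i for i, r in sorted(self.roles.items()) if r == "agent")


@dataclass(frozen=True)
class TriggerForm:
    surface: str
    category: FormCategory
    derivation: str
    nominal_class: Optional[NominalClass] = None

    def __post_init__(self):
        if not self.surface:
            raise ValueError("surface must be non-empty")
        if self.category is FormCategory.nominal and self.nominal_class is None:
            raise ValueError("nominal forms must carry a nominal-class flag")


@dataclass(frozen=True)
class Frame:
    name: str
    slot_arity: int
    compatible_templates: frozenset[str]
    allows_swap: bool = False

    def __post_init__(self):
        if not self.compatible_templates:
            raise ValueError("compatible_templates must be non-empty")


class FrameRegistry:
    """Named frames; selection honours the trigger's directionality."""

    def __init__(self):
        self._frames: dict[str, Frame] = {}

    def register(self, frame: Frame) -> None:
        self._frames[frame.name] = frame

    def get(self, name: str) -> Frame:
        if name not in self._frames:
            raise KeyError(f"unregistered frame {name!r}")
        return self._frames[name]

    def names(self) -> list[str]:
        return sorted(self._frames)


def default_registry() -> FrameRegistry:
    """The three built-in frames.

    ``NP0/NP1``: transitive (the most frequent frame); ``NP0``: intransitive
    agentive (active-subject template only -- intransitives cannot be
    passivized); ``NP1``: unaccusative, for triggers such as "localize" or
    "accumulate" whose surface subject is the theme.
    """
    from .templates import frame_template_ids  # local import: avoid cycle

    reg = FrameRegistry()
    for name, arity in (("NP0/NP1", 2), ("NP0", 1), ("NP1", 1)):
        reg.register(Frame(name, arity, frozenset(frame_template_ids(name))))
    return reg


def select_frame(spec: TriggerSpecification, registry: FrameRegistry) -> Frame:
    """Bind a specification to its frame.

    For a non-directional trigger the returned frame allows swapping of the
    two argument roles and includes the non-directional-only templates
    (between-/with-/reciprocal templates).
    """
    base = registry.get(spec.frame)
    if spec.direction == "non-directional":
        return Frame(base.name, base.slot_arity, base.compatible_templates,
                     allows_swap=True)
    return base


# ----------------------------------------------------------------------
# Morphology
# ----------------------------------------------------------------------

#: irregular verb inflections: root -> (past, past participle)
IRREGULAR_VERBS = {
    "bind": ("bound", "bound"),
    "see": ("saw", "seen"),
    "find": ("found", "found"),
    "undergo": ("underwent", "undergone"),
}

#: exception lexicon for derived forms: (root, affix) -> surface.
#: Seeded from the trigger inventory used in the evaluation corpora; it
#: plays the role of the user-confirmation step of an interactive system.
DERIVATION_EXCEPTIONS = {
    ("produce", "-ion"): "production",
    ("transcribe", "-tion"): "transcription",
    ("transcribe", "-tional"): "transcriptional",
    ("transcribe", "-tionally"): "transcriptionally",
    ("degrade", "-tion"): "degradation",
    ("degrade", "-tive"): "degradative",
    ("proteolyse", "-sis"): "proteolysis",
    ("proteolyse", "-tic"): "proteolytic",
    ("proteolyse", "-tically"): "proteolytically",
    ("initiate", "-tion"): "initiation",
    ("accumulate", "-ation"): "accumulation",
    ("localize", "-ation"): "localization",
    ("mobilize", "-ation"): "mobilization",
    ("oligomerize", "-ation"): "oligomerization",
    ("dimerize", "-ation"): "dimerization",
}

#: entity-class nominals (result nouns): derivable but never used in patterns
ENTITY_NOMINALS = {
    "transcribe": "transcript",
    "produce": "product",
}

NOMINAL_SUFFIXES = {"-ion", "-tion", "-age", "-ance", "-ment", "-sis",
                    "-ation", "-ing"}
ADJECTIVAL_SUFFIXES = {"-tive", "-tic", "-tional"}
ADVERBIAL_SUFFIXES = {"-tionally", "-tically"}  # derivable; unused in matching
PREFIXES = {"over-", "co-", "non-", "re-", "under-", "hyper-", "im-", "trans-", "cross-"}


def _ends_cvc(stem: str) -> bool:
    """Final consonant-vowel-consonant in a short stem => double the consonant."""
    if len(stem) < 3:
        return False
    a, b, c = stem[-3], stem[-2], stem[-1]
    if c in VOWELS or c in "wxy":
        return False
    if b not in VOWELS or a in VOWELS:
        return False
    # doubling applies to short (one-syllable-like) stems only
    return sum(1 for ch in stem if ch in VOWELS) <= 1


def _drop_e(stem: str) -> str:
    return stem[:-1] if stem.endswith("e") and not stem.endswith("ee") else stem


def inflect_3sg(root: str) -> str:
    if root.endswith(("s", "x", "z", "ch", "sh")):
        return root + "es"
    if root.endswith("y") and len(root) > 1 and root[-2] not in VOWELS:
        return root[:-1] + "ies"
    return root + "s"


def inflect_past(root: str) -> tuple[str, str]:
    if root in IRREGULAR_VERBS:
        return IRREGULAR_VERBS[root]
    if root.endswith("e"):
        form = root + "d"
    elif root.endswith("y") and len(root) > 1 and root[-2] not in VOWELS:
        form = root[:-1] + "ied"
    elif _ends_cvc(root):
        form = root + root[-1] + "ed"
    else:
        form = root + "ed"
    return form, form


def inflect_gerund(root: str) -> str:
    stem = _drop_e(root)
    if _ends_cvc(root):
        stem = root + root[-1]
    return stem + "ing"


def pluralize(noun: str) -> str:
    if noun.endswith("sis"):
        return noun[:-3] + "ses"
    return inflect_3sg(noun)


def _apply_suffix(root: str, affix: str) -> Optional[str]:
    if (root, affix) in DERIVATION_EXCEPTIONS:
        return DERIVATION_EXCEPTIONS[(root, affix)]
    body = affix[1:]  # strip leading '-'
    if affix in ("-ion", "-age", "-ance", "-ation"):
        return _drop_e(root) + body
    if affix == "-tion":
        # regular -tion attaches to ...ate/...te stems: initiate -> initiation
        if root.endswith("te"):
            return root[:-1] + "ion"
        return _drop_e(root) + "tion"
    if affix == "-ment":
        return root + body
    if affix == "-ing":
        # gerundive nominal ("bind" -> "binding")
        return inflect_gerund(root)
    if affix == "-sis":
        return _drop_e(root) + body
    if affix in ADJECTIVAL_SUFFIXES or affix in ADVERBIAL_SUFFIXES:
        return None  # require an exception-lexicon entry; warn upstream
    return None


def derive_trigger_forms(root: str, affixes: list[str]) -> list[TriggerForm]:
    """All surface trigger forms derivable from a root morpheme.

    Always produces the verbal inflections (base, 3sg, past, past/present
    participle).  Suffix descriptors add process nominals (singular and
    plural) or adjectival derivatives; prefix descriptors compose with every
    form derived so far.  Unknown descriptors are ignored with a warning.
    Deterministic: output order is fixed and duplicate-free.
    """
    forms: list[TriggerForm] = []
    seen: set[tuple[str, FormCategory]] = set()

    def add(surface: str, cat: FormCategory, deriv: str,
            ncls: Optional[NominalClass] = None):
        key = (surface, cat)
        if key not in seen:
            seen.add(key)
            forms.append(TriggerForm(surface, cat, deriv, ncls))

    past, ppart = inflect_past(root)
    add(root, FormCategory.verb_base, "root")
    add(inflect_3sg(root), FormCategory.verb_finite, "3sg")
    add(past, FormCategory.verb_finite, "past")
    add(ppart, FormCategory.verb_ppart, "past-participle")
    add(inflect_gerund(root), FormCategory.verb_prespart, "present-participle")

    suffix_descriptors = [a for a in affixes if a.startswith("-")]
    prefix_descriptors = [a for a in affixes if a.endswith("-") and not a.startswith("-")]
    unknown = [a for a in affixes
               if a not in NOMINAL_SUFFIXES | ADJECTIVAL_SUFFIXES | ADVERBIAL_SUFFIXES
               and a not in PREFIXES]
    for a in unknown:
        log.warning("ignoring unknown affix descriptor %r for root %r", a, root)
    suffix_descriptors = [a for a in suffix_descriptors if a not in unknown]
    prefix_descriptors = [a for a in prefix_descriptors if a not in unknown]

    for affix in suffix_descriptors:
        if affix in NOMINAL_SUFFIXES:
            nom = _apply_suffix(root, affix)
            if nom is None:
                log.warning("no derivation rule for %s + %s", root, affix)
                continue
            add(nom, FormCategory.nominal, affix, NominalClass.process)
            add(pluralize(nom), FormCategory.nominal, affix + " (plural)",
                NominalClass.process)
        else:
            adj = _apply_suffix(root, affix)
            if adj is None:
                log.warning("no derivation rule for %s + %s (needs exception entry)",
                            root, affix)
                continue
            if affix in ADJECTIVAL_SUFFIXES:
                add(adj, FormCategory.adjectival, affix)
            # adverbial derivatives are derivable but not used for matching

    if root in ENTITY_NOMINALS:
        ent = ENTITY_NOMINALS[root]
        add(ent, FormCategory.nominal, "entity-nominal", NominalClass.entity)
        add(pluralize(ent), FormCategory.nominal, "entity-nominal (plural)",
            NominalClass.entity)

    base_forms = list(forms)
    for prefix in prefix_descriptors:
        body = prefix[:-1]
        for f in base_forms:
            add(body + f.surface, f.category, f"{prefix}{f.derivation}",
                f.nominal_class)
    return forms


def process_forms(forms: list[TriggerForm]) -> list[TriggerForm]:
    """Forms usable for pattern generation (entity-class nominals excluded)."""
    return [f for f in forms
            if not (f.category is FormCategory.nominal
                    and f.nominal_class is not NominalClass.process)]


# ----------------------------------------------------------------------
# Trigger-specification file parsing
# ----------------------------------------------------------------------

_KNOWN_FRAMES = {"NP0/NP1", "NP0", "NP1"}


def parse_trigger_spec(text: str) -> list[TriggerSpecification]:
    """Parse a trigger-specification file into specifications.

    Blocks are separated by blank lines; lines are ``key: value`` pairs
    (trigger, relation, frame, type, role, direction, guard, affixes).
    Two blocks may share a root (homonymous triggers are disambiguated at
    extraction time by their type constraints and guards).
    """
    specs: list[TriggerSpecification] = []
    block: dict = {}
    block_start = None

    def flush(lineno: int):
        nonlocal block, block_start
        if not block:
            return
        for req in ("trigger", "relation", "frame"):
            if req not in block:
                raise TriggerSpecError(f"block missing {req!r} line", block_start)
        slots = tuple(ArgSlot(i, frozenset(t))
                      for i, t in sorted(block.get("types", {}).items()))
        try:
            specs.append(TriggerSpecification(
                root=block["trigger"],
                relation=block["relation"],
                frame=block["frame"],
                slots=slots,
                roles=dict(sorted(block.get("roles", {}).items())),
                direction=block.get("direction", "directional"),
                lexical_guards=block.get("guards", {}),
                affixes=tuple(block.get("affixes", ())),
            ))
        except ValueError as e:
            raise TriggerSpecError(str(e), block_start) from e
        block = {}
        block_start = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            flush(lineno)
            continue
        if block_start is None:
            block_start = lineno
        if ":" not in line:
            raise TriggerSpecError(f"expected 'key: value', got {line!r}", lineno)
        key, _, value = line.partition(":")
        key, value = key.strip().lower(), value.strip()
        if key in ("trigger", "relation", "frame", "direction") and key in block:
            raise TriggerSpecError(
                f"duplicate {key!r} in block (missing blank separator line?)",
                lineno)
        if key == "trigger":
            block["trigger"] = value
        elif key == "relation":
            block["relation"] = value
        elif key == "frame":
            if value not in _KNOWN_FRAMES:
                raise TriggerSpecError(f"unknown frame name {value!r}", lineno)
            block["frame"] = value
        elif key == "direction":
            if value not in ("directional", "non-directional"):
                raise TriggerSpecError(f"bad direction {value!r}", lineno)
            block["direction"] = value
        elif key == "type":
            idx, types = _parse_slot_line(value, lineno, sep="=")
            bad = set(types) - SEMANTIC_TYPES
            if bad:
                raise TriggerSpecError(f"unknown semantic type {sorted(bad)}", lineno)
            block.setdefault("types", {})[idx] = types
        elif key == "role":
            idx, roles = _parse_slot_line(value, lineno, sep="=")
            if len(roles) != 1 or roles[0] not in ("agent", "theme"):
                raise TriggerSpecError(f"bad role line {value!r}", lineno)
            block.setdefault("roles", {})[idx] = roles[0]
        elif key == "guard":
            if "~" not in value:
                raise TriggerSpecError(f"bad guard line {value!r}", lineno)
            left, _, word = value.partition("~")
            idx = _parse_np_index(left.strip(), lineno)
            block.setdefault("guards", {})[idx] = word.strip()
        elif key == "affixes":
            block.setdefault("affixes", []).extend(
                a.strip() for a in value.split(",") if a.strip())
        else:
            raise TriggerSpecError(f"unknown key {key!r}", lineno)
    flush(len(text.splitlines()) + 1)
    return specs


def _parse_np_index(text: str, lineno: int) -> int:
    if not text.upper().startswith("NP"):
        raise TriggerSpecError(f"expected NP<i>, got {text!r}", lineno)
    try:
        return int(text[2:])
    except ValueError:
        raise TriggerSpecError(f"bad slot index in {text!r}", lineno) from None


def _parse_slot_line(value: str, lineno: int, sep: str) -> tuple[int, list[str]]:
    if sep not in value:
        raise TriggerSpecError(f"expected '{sep}' in {value!r}", lineno)
    left, _, right = value.partition(sep)
    idx = _parse_np_index(left.strip(), lineno)
    items = [t.strip() for t in right.split("|") if t.strip()]
    if not items:
        raise TriggerSpecError(f"empty value list in {value!r}", lineno)
    return idx, items
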