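"""trigex: trigger-driven, pattern-based biomedical relation extraction.

From declarative trigger specifications alone (root morpheme, frame,
argument types, roles, directionality) the package derives surface
trigger forms, instantiates a fixed inventory of lexico-syntactic pattern
templates, matches them over constituency parses of (optionally
simplified) sentences, links arguments through referential relations, and
emits and scores events in BioNLP-ST standoff format.
"""

from .entities import EntityMention, satisfies, type_np
from .extract import (
    Document,
    ExtractionConfig,
    disambiguate_homonyms,
    extract_document,
    extract_sentence,
    load_document,
)
from .fixtures import DEFAULT_TRIGGER_SPECS, FixtureRecipe, generate
from .linking import (
    ReferentialLink,
    detect_links,
    parse_coref_file,
    register_external_coref,
    resolve,
)
from .simplify import (
    Construct,
    SentenceVariant,
    attachment_alternatives,
    detect_constructs,
    map_span,
    simplify,
)
from .standoff import (
    EvalResult,
    GoldSet,
    approx_span_match,
    evaluate,
    read_standoff,
    tokenize,
    write_a2,
)
from .templates import (
    Event,
    LexicoSyntacticPattern,
    PatternTemplate,
    TriggerArgPair,
    generate_patterns,
    list_templates,
    pairs_to_events,
)
from .trees import (
    ParseTree,
    TreeMatch,
    TreePattern,
    compile_pattern,
    match_all,
    read_bracketed,
    verb_group_head,
)
from .triggers import (
    ArgSlot,
    Frame,
    TriggerForm,
    TriggerSpecification,
    default_registry,
    derive_trigger_forms,
    parse_trigger_spec,
    select_frame,
)

__version__ = "1.0.0"


def build_patterns(spec_text: str) -> list[LexicoSyntacticPattern]:
    """Parse a trigger-specification file and generate every
    lexico-syntactic pattern for its triggers."""
    registry = default_registry()
    patterns: list[LexicoSyntacticPattern] = []
    for spec in parse_trigger_spec(spec_text):
        forms = derive_trigger_forms(spec.root, list(spec.affixes))
        frame = select_frame(spec, registry)
        patterns.extend(generate_patterns(spec, forms, frame))
    return patterns
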