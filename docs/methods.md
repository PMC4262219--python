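# Methods

## Model

`trigex` treats biomedical event extraction as lexico-syntactic pattern
matching driven entirely by *trigger specifications*. A specification
declares a verbal root morpheme, the relation it signals, a
subcategorization frame, per-slot semantic-type constraints, a role map
(agent/theme) and a directionality flag. Everything else — surface
forms, patterns, matching, simplification, linking — is derived from
linguistic regularities rather than task-specific rules, which is what
makes the system cheap to retarget to a new relation: writing one more
specification block is the entire development cost.

The core assumptions are:

1. **Argument realization is systematic.** A transitive trigger's
   arguments surface in a closed set of configurations (active subject
   and object, passive subject and by-phrase, nominalizations with
   of/by/between/with complements and compounds, participial modifiers,
   and a handful of elliptical shapes). These are frozen into 26 pattern
   templates (7 verbal, 7 of which one — the unaccusative subject —
   belongs only to the `NP1` frame; 9 nominal; 4 adjectival; 6
   null-argument). Each template captures **one** argument; combination
   into multi-argument events happens afterwards, keyed on the trigger
   occurrence (relation + character span).
2. **Syntax is given.** The package consumes pre-tokenized sentences
   with constituency parses; it never runs a parser. All development and
   testing use gold trees, so measured behaviour isolates the extraction
   logic from parser error.
3. **Entity mentions are given.** Gene/gene-product mentions arrive as
   standoff `.a1` annotations (mapped to the type `GGP`). Heuristic
   head-noun typing covers un-annotated NPs, but only `.a1`-backed
   mentions may appear as arguments of emitted events, matching the
   standoff convention that event arguments reference entity
   annotations. Heuristically-typed NPs act as intermediate pair
   arguments — the inputs to referential linking.

## Trigger-form derivation

Inflections (3sg, past, participles) and affix-driven derivations
(`-ion`, `-age`, `-ance`, `-ment`, `-sis`, `-ation`, `-tion`, `-ing`
nominals; `-tive`/`-tic`/`-tional` adjectivals; `over-`, `co-`, `non-`,
`re-`, `under-`, `hyper-`, `im-`, `trans-`, `cross-` prefixes) follow a
rule table — e-drop before vowel-initial suffixes, y→ie, CVC consonant
doubling on short stems — backed by an explicit exception lexicon
(transcribe→transcription, proteolyse→proteolysis, bind→bound, …). The
exception lexicon stands in for the user-confirmation step an
interactive deployment would have. Nominalizations are classed as
*process* ("phosphorylation") or *entity* ("transcript"); only process
nominals instantiate patterns, since the target relations are processes.
Unknown affix descriptors are ignored with a warning rather than
guessed.

## Matching

Tree patterns are expressed in a small tregex-like mini-language
(immediate child `<`, descendant `<<`, sole child `<:`, following
sibling `$`, immediate precedence `.`, conjunction, negation, named
captures); it is the smallest relation set that expresses the template
inventory. The compiled pattern anchors the trigger token; the
template's structural constraints (voice, preposition literals,
compound/possessive/predicative shape, argument position) are enforced
by a per-template check around the anchor. Two deliberate
generalizations widen matching:

* the consecutive verb group is matched as a whole and headed by its
  last main verb, with be/have/do, modals, infinitival *to* and
  raising/ECM carriers (*known, shown, found, seem, appear, likely*)
  treated as auxiliaries;
* adverbial and adjective-nominal adjuncts between trigger and argument
  are skipped.

Voice is decided by the participle tag plus a be-form inside the verb
group. Trigger matching is case-insensitive; hyphenated compounds
("DNA-binding") match token-internal hyphens, with the trigger and
argument spans carved out of the single token.

Role assignment: the captured slot's role comes from the specification;
for non-directional triggers each pattern accepts both slot assignments
(closure under NP₀/NP₁ exchange), so "A binds B" and "B binds A" yield
the same unordered theme set. Null-argument templates recover the
elided theme from the surrounding clause (matrix subject or governing
verb's object) or — for the bare-nominal subject/object shapes — from a
theme established by another trigger in the same sentence. The
cause-verb shape takes the antecedent route because its own noun phrase
*is* the matrix object; the recoverable theme must come from a sibling
predication.

Lexical guards ("express + mRNA ⇒ Transcription") are post-match
co-occurrence filters on the captured NP's tokens. When a guarded
reading fires for a trigger occurrence, unguarded readings of the same
root are suppressed for that occurrence; otherwise all type-surviving
homonym readings are proposed. A sortal head ("EpoR *mRNA*") defers its
mention identity to the named modifier directly before it, so the event
argument is the annotated entity while the type check sees the sortal.

## Simplification

Constructs detected on the parse: coordinations (conjuncts of equal
label class around *and/or/but*), full relative clauses (SBAR with a
relative pronoun), reduced relative clauses (NP-internal participial
VP), appositions (comma-separated NP whose second NP begins with a
determiner or number, never inside a coordination) and parenthesized
elements (PRN nodes or bracket token runs). Variants are produced by
node deletion/promotion on the input tree — never by re-parsing — so
fixture correctness is parser-independent and parser error does not
compound; each variant carries a monotone per-character offset map to
the original sentence, and extracted spans are always reported in
original coordinates. Nested constructs expand recursively, one
construct per step in document order, keeping intermediate variants;
expansion is capped (default 64 variants) with a logged truncation.
The "referent + clause" variant is built for subject relatives only;
object relatives contribute the clause-removed variant.
Coordination splitting leaves agreement untouched ("B were expressed"):
extraction never inspects agreement, so repair would be cosmetic.

Attachment ambiguities ("NP₁ prep NP₂ + relative clause", "NP₁ and NP₂
PP", "Adj NP₁ and NP₂") are not resolved: one variant per reading is
generated and the extractor's type checks (and event-level
informativeness filter) select among them, since the decision needs
semantic information that only the matching stage has.

## Referential linking

Link detectors: part-whole (NPs headed by part keywords — locus,
promoter, domain, residue, site, … — containing a named entity, and
"NP contains NP" clauses), member-collection ("such as", "including",
"e.g.", "one/some of"), hyponymy ("acts as", "is identified as",
copular "is a/an"), apposition, and relative-pronoun coreference — the
only built-in coreference, since general anaphora resolution is a
separate task; links from any external resolver merge through
`register_external_coref` (TSV interface).

Resolution is a breadth-first search from an uninformative argument
with a visited set (termination on cyclic graphs is guaranteed because
every step strictly grows the visited set). Substitution directions:
collection→member, part→whole, hypernym→hyponym, apposition both ways,
pronoun→referent. Endpoints match by span overlap; hyponymy and
external coreference may additionally match a repeated definite phrase
by surface identity after determiner stripping, in which case only the
nearest occurrence (preferring a preceding one) counts — the
definite-anaphora heuristic that keeps repeated descriptors in a
document from cross-linking unrelated sentences. Reached mentions snap
onto pre-annotated mentions they cover. Every reachable informative
mention yields one rewritten, re-type-checked pair (several referents ⇒
several pairs, all proposed); when at least one is found the rewrites
replace the uninformative original, and when none is found the original
pair survives unchanged — resolution never leaves a trigger with
nothing.

## Evaluation

The scorer implements approximate recursive matching: events are equal
iff relation, trigger and role-wise arguments all match, where a
predicted span equals a gold span iff it lies entirely inside the gold
span extended by one word left and right. "One word" is defined by
token boundaries; `evaluate` accepts explicit token spans (e.g. parse
leaves) and otherwise tokenizes the document text on whitespace and
punctuation. Matching is greedy first-fit in document order —
tie-breaking cannot change P/R on one-to-one gold sets. A gold event
whose argument belongs to an n-member equivalence class is expanded
into n copies (so it is counted n times in the denominators); note this
expansion makes self-evaluation of a gold set with equivalence classes
score below 1 by construction, which is why the self-consistency
invariant is stated for equivalence-free gold sets. Nested-event
decomposition is vacuous here because regulation-type events (whose
themes are other events) are out of scope; argument matching bottoms
out at entity spans.

## Synthetic corpus

The fixture generator emulates the worked-example sentence shapes: one
base realizer per template family ("\<E1\> phosphorylates \<E2\>",
"binding of \<E1\> to \<E2\>", "\<E1\> undergoes phosphorylation", …) and
one complication realizer per construct (theme coordination, relative
clause, apposition, parenthetical alias, member-collection listing, a
two-sentence hyponymy-cue pair). Text, gold tree, `.a1` mentions and
gold `.a2` events are constructed jointly, so the gold standard is
exact by construction; the same seed yields a byte-identical bundle.
Entity names are synthetic (`PROT001`…`PROT040`, fixed-width so no name
is a prefix of another) to avoid accidental head-lexicon hits. Trigger
specifications for the bundle cover the six relation types with
directional and non-directional frames, a homonymous trigger pair with
an mRNA guard, and an unaccusative frame.

Complications deliberately wrap the *theme* side of each extraction, so
an ablated pipeline yields no event for that sentence rather than a
partial one: this is what lets the ablations lower recall while leaving
precision untouched, and it mirrors the intended division of labour
(patterns give precision; simplification and linking buy recall).

What the synthetic corpus does **not** emulate: parser errors (all
trees are gold), noisy or nested entity mentions, regulation events,
cross-sentence ellipsis, and the long tail of real biomedical phrasing.
Perfect scores on it certify the extraction machinery — template
coverage, span bookkeeping, variant mapping, link traversal, metric —
not performance on real corpora, where parser quality dominates.

## Problem sizes and defaults

The acceptance run uses a 200-sentence bundle (~220–230 gold events),
uniform mix over all realizers, seed from `--seed`; it completes in a
few seconds on one CPU. Defaults that matter: variant cap 64 (128 is
ample for the deepest worked example); V5's preposition set
{with, to, at}; guard scope = captured-NP tokens; event arguments
restricted to `.a1`-backed mentions. The head-noun lexicon and the
part-keyword list are packaged tables (`trigex.entities.HEAD_LEXICON`)
and are deliberately small and editable.

## Known limitations

* Object relative clauses get no "referent + clause" variant.
* The null-argument templates cover only the exemplified sentence
  shapes; a "for"-PP elliptical shape ("targets X for degradation") is
  intentionally absent from the inventory.
* Nominal triggers must head their noun phrase (no "fragments of NP"
  generalization).
* Pronominal coreference beyond relative pronouns requires an external
  resolver.
* Coordination-boundary repair of incorrect parses is out of scope, as
  is everything downstream of a wrong parse.
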