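"""Semantic typing of noun phrases.

Pre-annotated mentions (BioNLP-ST .a1, assumed given) are authoritative and
are never re-typed.  Noun phrases without an annotation are classified by a
head-noun/suffix lexicon: part keywords ("locus", "domain", ...), protein
head nouns and the "-in"/"-ase" suffixes, generic class nouns ("genes"),
and RNA heads ("mRNA", "transcript").  Type compatibility against a
trigger-specification slot goes through a small subsumption table in which
GGP (gene or gene product) covers gene, RNA and protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .trees import ParseTree
from .triggers import ArgSlot

__all__ = ["EntityMention", "type_np", "satisfies", "np_head", "HEAD_LEXICON"]


@dataclass(frozen=True)
class EntityMention:
    """A typed text span in original-document coordinates."""

    span: tuple[int, int]
    text: str
    sem_type: str
    source: str = "heuristic"          # "preannotated" | "heuristic"
    ann_id: Optional[str] = None       # .a1 T-id for pre-annotated mentions

    def __post_init__(self):
        if self.span[1] <= self.span[0]:
            raise ValueError("mention span must be non-empty")

    @property
    def informative(self) -> bool:
        """Pre-annotated mentions are the informative named entities."""
        return self.source == "preannotated"


# head word -> semantic type (heuristic, editable)
HEAD_LEXICON: dict[str, str] = {}
for _w in ("locus", "loci", "promoter", "promoters"):
    HEAD_LEXICON[_w] = "gene_part"
for _w in ("domain", "domains", "residue", "residues", "site", "sites",
           "motif", "motifs", "terminus", "subunit", "subunits", "region",
           "regions", "fragment", "fragments"):
    HEAD_LEXICON[_w] = "protein_part"
for _w in ("protein", "kinase", "factor", "glycoprotein", "receptor",
           "phosphatase", "enzyme", "ligand", "cytokine", "antibody",
           "peptide", "chemokine"):
    HEAD_LEXICON[_w] = "protein"
for _w in ("gene", "genes", "proteins", "kinases", "factors", "receptors",
           "enzymes", "molecule", "molecules", "regulator", "regulators",
           "substrate", "substrates", "partner", "partners", "target",
           "targets"):
    HEAD_LEXICON[_w] = "class_noun"
for _w in ("mrna", "mrnas", "transcript", "transcripts", "rna", "rnas"):
    HEAD_LEXICON[_w] = "rna"
for _w in ("inhibitor", "compound", "drug", "chemical", "agonist",
           "antagonist"):
    HEAD_LEXICON[_w] = "chemical"

_HEAD_POS = {"NN", "NNS", "NNP", "NNPS", "PRP", "WDT", "WP", "CD", "FW"}
_SKIP_CHILD = {"PP", "SBAR", "PRN", "VP", "S", "ADVP", ",", ".", ":", "``", "''"}


def np_head(np: ParseTree) -> Optional[ParseTree]:
    """Head word leaf of an NP: rightmost nominal leaf of the base NP,
    descending through trailing nested NPs but not into PPs, clauses or
    parentheticals."""
    node = np
    while True:
        if node.is_leaf:
            return node
        kids = [c for c in node.children if c.label not in _SKIP_CHILD]
        cands = [c for c in kids
                 if c.label in ("NP", "NX", "NML", "WHNP")
                 or c.label in _HEAD_POS]
        if not cands:
            return None
        last = cands[-1]
        if last.label in ("NP", "NX", "NML", "WHNP"):
            node = last
            continue
        return last.children[0] if last.children else last


def _overlapping(span: tuple[int, int], mentions: list[EntityMention]
                 ) -> Optional[EntityMention]:
    best = None
    for m in mentions:
        if m.span[0] < span[1] and span[0] < m.span[1]:
            if best is None or (m.span[1] - m.span[0]) > (best.span[1] - best.span[0]):
                best = m
    return best


def type_np(np: ParseTree, preannotated: list[EntityMention]) -> EntityMention:
    """Assign a semantic type to a noun phrase.

    If the NP's head word overlaps a pre-annotated mention, that mention is
    returned unchanged; otherwise the head-noun lexicon and suffix rules
    classify the phrase (deterministic and total; unknown heads -> other).
    """
    head = np_head(np)
    probe_span = head.span if head is not None else np.span
    hit = _overlapping(probe_span, preannotated)
    if hit is not None:
        return hit
    text = " ".join(np.tokens())
    word = (head.token if head is not None else text).lower()
    return EntityMention(np.span, text, heuristic_type(word),
                         source="heuristic")


def heuristic_type(head_word: str) -> str:
    """Head-noun/suffix classification of an un-annotated phrase."""
    word = head_word.lower()
    sem = HEAD_LEXICON.get(word)
    if sem is not None:
        return sem
    if len(word) > 4 and (word.endswith("in") or word.endswith("ase")):
        return "protein"
    if word.endswith(("ins", "ases")) and len(word) > 5:
        return "class_noun"
    return "other"


_BIOMOLECULE = {"GGP", "gene", "rna", "protein"}


def satisfies(mention: EntityMention, slot: ArgSlot) -> bool:
    """Type compatibility of a mention with a trigger-specification slot.

    GGP subsumes gene/RNA/protein in both directions (a pre-annotated GGP
    may fill a gene slot; a heuristically-typed protein fills a GGP slot).
    Class nouns ("the earliest genes") are compatible with biomolecule
    slots: they denote the right kind of entity and their identity is
    recovered later by referential linking.
    """
    t = mention.sem_type
    allowed = slot.allowed_types
    if t in allowed:
        return True
    if t == "GGP" and allowed & _BIOMOLECULE:
        return True
    if t in _BIOMOLECULE and "GGP" in allowed:
        return True
    if t == "class_noun" and allowed & _BIOMOLECULE:
        return True
    return False
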