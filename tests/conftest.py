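import pytest

from trigex import build_patterns
from trigex.entities import EntityMention
from trigex.extract import load_document
from trigex.fixtures import DEFAULT_TRIGGER_SPECS
from trigex.trees import read_bracketed


def tree(parse: str, sentence: str = None):
    """Build a span-annotated tree; the sentence defaults to the parse's
    token yield joined by single spaces."""
    if sentence is None:
        import re
        toks = re.findall(r"\(|\)|[^\s()]+", parse)
        words = []
        expect_label = False
        for t in toks:
            if t == "(":
                expect_label = True
            elif t == ")":
                expect_label = False
            elif expect_label:
                expect_label = False
            else:
                words.append({"-LRB-": "(", "-RRB-": ")"}.get(t, t))
        sentence = " ".join(words)
    return read_bracketed(parse, sentence)


def mention(text: str, doc: str, sem="GGP", ann_id=None, occurrence=0):
    """Pre-annotated mention located by searching ``text`` in ``doc``."""
    start = -1
    for _ in range(occurrence + 1):
        start = doc.index(text, start + 1)
    return EntityMention((start, start + len(text)), text, sem,
                         source="preannotated", ann_id=ann_id)


def single_sentence_doc(parse: str, sentence: str, mentions):
    return load_document(sentence + "\n", [parse], [(0, len(sentence))],
                         mentions)


@pytest.fixture(scope="session")
def default_patterns():
    return build_patterns(DEFAULT_TRIGGER_SPECS)
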