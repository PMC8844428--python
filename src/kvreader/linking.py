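"""Dictionary-based entity linking and mixed-corpus construction.

Molecule mentions in text are detected by exact, case-insensitive
matching against a synonym dictionary.  Because some substances share
names with common objects ("dogs", "success"), common words are
filtered from the dictionary; exact matching then gives high precision
at the cost of recall, which is the right trade-off for unsupervised
corpus construction.  At each surviving mention site the molecule's
simplified SMILES string, wrapped in boundary markers, is inserted so
that masked-token pre-training sees structure and prose side by side.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequences import SMI_CLOSE, SMI_OPEN
from .smiles import SimplifiedSmiles, simplify_smiles

_WS = re.compile(r"\s+")


def normalize(surface: str) -> str:
    """Case-fold and collapse whitespace; applied at build and query time."""
    return _WS.sub(" ", surface.strip().casefold())


@dataclass
class MoleculeRecord:
    """One substance: identifiers, synonyms and its SMILES string."""

    id: str
    name: str
    synonyms: list[str]
    smiles: SimplifiedSmiles

    def __post_init__(self) -> None:
        if isinstance(self.smiles, str):
            self.smiles = simplify_smiles(self.smiles)
        if self.name not in self.synonyms:
            self.synonyms = [self.name] + list(self.synonyms)

    def to_json(self) -> str:
        return json.dumps({"id": self.id, "name": self.name,
                           "synonyms": self.synonyms,
                           "smiles": self.smiles.raw}, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "MoleculeRecord":
        d = json.loads(line)
        return cls(id=d["id"], name=d["name"], synonyms=list(d["synonyms"]),
                   smiles=simplify_smiles(d["smiles"]))


def read_dictionary(path) -> dict[str, MoleculeRecord]:
    records = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = MoleculeRecord.from_json(line)
                records[rec.id] = rec
    return records


def write_dictionary(records: Iterable[MoleculeRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


@dataclass
class SynonymIndex:
    """Normalized synonym string -> molecule id, with a common-word stoplist.

    Synonyms claimed by two different molecules are ambiguous and are
    dropped (recorded in ``ambiguous``).
    """

    mapping: dict[str, str]
    stoplist: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        assert not (set(self.mapping) & self.stoplist)

    def lookup(self, surface: str) -> str | None:
        return self.mapping.get(normalize(surface))

    @property
    def max_words(self) -> int:
        return max((k.count(" ") + 1 for k in self.mapping), default=1)


def build_synonym_index(records: Iterable[MoleculeRecord],
                        stoplist: Iterable[str] = ()) -> SynonymIndex:
    """Index every synonym of every record, minus stoplisted and ambiguous ones."""
    records = list(records)
    if not records:
        raise ValueError("molecule dictionary is empty")
    stop = {normalize(w) for w in stoplist}
    mapping: dict[str, str] = {}
    ambiguous: set[str] = set()
    for rec in records:
        for syn in rec.synonyms:
            key = normalize(syn)
            if not key or key in stop:
                continue
            owner = mapping.get(key)
            if owner is not None and owner != rec.id:
                ambiguous.add(key)
            elif key not in ambiguous:
                mapping[key] = rec.id
    for key in ambiguous:
        mapping.pop(key, None)
    return SynonymIndex(mapping=mapping, stoplist=stop, ambiguous=ambiguous)


def default_stoplist(sentences: Iterable[str], top_k: int = 1000,
                     extra: Iterable[str] = ()) -> set[str]:
    """The ``top_k`` most frequent corpus words plus a user-supplied list."""
    counts: Counter = Counter()
    word = re.compile(r"[A-Za-z0-9'-]+")
    for sent in sentences:
        counts.update(normalize(w) for w in word.findall(sent))
    common = [w for w, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return set(common[:top_k]) | {normalize(w) for w in extra}


@dataclass
class Mention:
    sentence: int
    start: int
    end: int
    molecule_id: str


@dataclass
class LinkedDocument:
    """Sentences plus the non-overlapping molecule mentions found in them."""

    sentences: list[str]
    mentions: list[Mention] = field(default_factory=list)


_TOKEN = re.compile(r"\S+")


def _word_spans(sentence: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _TOKEN.finditer(sentence)]


def link_mentions(sentences: Sequence[str], index: SynonymIndex) -> LinkedDocument:
    """Left-to-right longest-match scan for dictionary synonyms.

    Candidate spans are word-boundary aligned; at each start position
    the longest span (in words) whose normalized surface form — with
    trailing punctuation stripped — is an index key wins, and scanning
    resumes after it, so mentions never overlap.
    """
    max_words = index.max_words
    doc = LinkedDocument(sentences=list(sentences))
    for si, sent in enumerate(sentences):
        spans = _word_spans(sent)
        i = 0
        while i < len(spans):
            hit = None
            for width in range(min(max_words, len(spans) - i), 0, -1):
                start = spans[i][0]
                end = spans[i + width - 1][1]
                surface = sent[start:end].rstrip(".,;:!?)\"'")
                end = start + len(surface)
                if surface and index.lookup(surface) is not None:
                    hit = (start, end, index.lookup(surface), width)
                    break
            if hit is not None:
                start, end, mol, width = hit
                doc.mentions.append(Mention(si, start, end, mol))
                i += width
            else:
                i += 1
    return doc


def insert_smiles(doc: LinkedDocument,
                  records: Mapping[str, MoleculeRecord],
                  replace: bool = False) -> list[str]:
    """Insert delimited SMILES spans at each mention site.

    By default the mention text is kept and the span appended after it,
    preserving the name-structure co-occurrence that masking exploits;
    ``replace=True`` substitutes the span for the mention instead.
    """
    out = []
    by_sentence: dict[int, list[Mention]] = {}
    for m in doc.mentions:
        if m.molecule_id not in records:
            raise KeyError(f"mention refers to unknown molecule id {m.molecule_id!r}")
        by_sentence.setdefault(m.sentence, []).append(m)
    for si, sent in enumerate(doc.sentences):
        pieces = []
        pos = 0
        for m in sorted(by_sentence.get(si, []), key=lambda m: m.start):
            smiles = records[m.molecule_id].smiles.simplified
            span = f"{SMI_OPEN} {smiles} {SMI_CLOSE}"
            if replace:
                pieces.append(sent[pos:m.start])
                pieces.append(span)
            else:
                pieces.append(sent[pos:m.end])
                pieces.append(" " + span)
            pos = m.end
        pieces.append(sent[pos:])
        out.append("".join(pieces))
    return out


def strip_smiles_spans(sentence: str) -> str:
    """Remove every delimited SMILES span (inverse of insert_smiles)."""
    pattern = re.compile(r" ?" + re.escape(SMI_OPEN) + r".*?" + re.escape(SMI_CLOSE))
    return pattern.sub("", sentence)


_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+(?=[A-Z])")


def split_sentences(text: str) -> list[str]:
    """Deterministic sentence splitter: ./!/? followed by space + uppercase."""
    return [s for s in _SENT_SPLIT.split(text.strip()) if s]


# JSON-lines corpus I/O --------------------------------------------------

def read_corpus(path) -> list[dict]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(json.loads(line))
    return docs


def write_corpus(docs: Iterable[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc, sort_keys=True) + "\n")


def build_mixed_corpus(docs: Sequence[dict],
                       records: Mapping[str, MoleculeRecord],
                       index: SynonymIndex,
                       replace: bool = False) -> list[dict]:
    """Link mentions in every document and insert SMILES spans.

    Documents are dicts with ``doc_id`` and ``sentences``; the output
    adds ``mentions`` (sentence index, char span, molecule id) and
    rewrites sentences with the delimited spans.
    """
    out = []
    for doc in docs:
        linked = link_mentions(doc["sentences"], index)
        mixed = insert_smiles(linked, records, replace=replace)
        out.append({
            "doc_id": doc.get("doc_id"),
            "sentences": mixed,
            "mentions": [[m.sentence, m.start, m.end, m.molecule_id]
                         for m in linked.mentions],
        })
    return out
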