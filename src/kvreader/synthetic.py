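"""Synthetic molecules, descriptions, dictionaries and corpora.

The generator encodes the premise the whole pipeline rests on: that
sub-structures (functional groups, chains) are strong indicators of the
properties described in text.  Each synthetic molecule is a
concatenation of fragments drawn from a small grammar, and its
description contains one property sentence per fragment — so fragment
presence and sentence presence carry positive mutual information, and
shuffling the pairing destroys it.  Chemical validity is *not*
enforced: the pipeline treats SMILES as strings throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linking import MoleculeRecord
from .pairs import PairedExample
from .smiles import simplify_smiles

# fragments are chemically plausible motifs over a fixed atom alphabet
_FRAGMENTS = [
    "CCO", "C=O", "CCN", "c<ar>c<ar>c<ar>", "C=CC", "CCl", "CBr", "CCS",
    "N=O", "C#N", "COC", "CCCC", "NCC", "OC=O", "SCC", "C=NC",
    "CC=C", "NC=O", "OCO", "CSC", "CCCO", "NCN", "C#CC", "OCN",
]

_ADJECTIVES = [
    "volatile", "corrosive", "fluorescent", "hygroscopic", "carcinogenic",
    "antimicrobial", "analgesic", "anti-inflammatory", "photosensitive",
    "water-soluble", "lipophilic", "thermostable", "mutagenic", "sedative",
    "diuretic", "antipyretic", "vasodilatory", "hepatotoxic", "nephrotoxic",
    "radioactive", "chelating", "oxidizing", "reducing", "alkylating",
    "emulsifying", "crystalline", "deliquescent", "pyrophoric", "explosive",
    "bioluminescent", "antiviral", "antifungal", "anticoagulant",
    "bronchodilatory", "immunosuppressive", "neuroprotective", "osmotic",
    "surface-active", "astringent", "antioxidant", "cytotoxic", "emetic",
    "expectorant", "haemolytic", "keratolytic", "laxative", "miotic",
    "mydriatic",
]

_CONTEXTS = [
    "in aqueous solution", "at room temperature", "under ultraviolet light",
    "in clinical assays", "in animal models",
]

_NOISE = [
    "It was first catalogued in an early regional survey.",
    "Several suppliers distribute it in bulk quantities.",
    "The archival literature on it remains fragmentary.",
    "Storage guidelines for it vary between jurisdictions.",
    "It has appeared in three routine screening panels.",
    "Its market availability fluctuated during the last decade.",
]

_MENTION_PREFIXES = ["", "Notably, ", "Earlier assays confirmed that "]

_FILLERS = [
    "The assay protocol followed standard practice.",
    "Results were averaged over three replicates.",
    "No further characterization was attempted.",
    "The cohort was monitored for six weeks.",
]


@dataclass
class FragmentGrammar:
    """Fragments, their property sentences, and distractor sentences."""

    fragments: list[str]
    property_map: dict[str, list[str]]
    noise_sentences: list[str] = field(default_factory=lambda: list(_NOISE))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("grammar has no fragments")
        missing = set(self.fragments) - set(self.property_map)
        if missing:
            raise ValueError(f"fragments without property sentences: {missing}")


def default_grammar(n_fragments: int = 20,
                    sentences_per_fragment: int = 2,
                    seed: int = 0) -> FragmentGrammar:
    """A grammar of aliphatic/aromatic-style motifs with unique properties.

    Each fragment receives ``sentences_per_fragment`` sentences built
    from an adjective unique to that (fragment, slot) pair, so every
    property sentence points back to exactly one fragment.
    """
    if n_fragments > len(_FRAGMENTS):
        raise ValueError(f"at most {len(_FRAGMENTS)} fragments available")
    need = n_fragments * sentences_per_fragment
    if need > len(_ADJECTIVES):
        raise ValueError("not enough distinct adjectives for this grammar")
    rng = np.random.default_rng(seed)
    fragments = [f.replace("<ar>", "c") for f in _FRAGMENTS[:n_fragments]]
    adjectives = list(rng.permutation(_ADJECTIVES)[:need])
    property_map = {}
    for i, frag in enumerate(fragments):
        sents = []
        for j in range(sentences_per_fragment):
            adj = adjectives[i * sentences_per_fragment + j]
            ctx = _CONTEXTS[(i + j) % len(_CONTEXTS)]
            sents.append(f"It is {adj} {ctx}.")
        property_map[frag] = sents
    return FragmentGrammar(fragments=fragments, property_map=property_map,
                           seed=seed)


@dataclass
class GenerationLog:
    """Ground truth recorded during generation, for oracle tests."""

    compositions: dict[str, list[str]]          # molecule id -> fragments
    noise_flags: dict[str, list[str]]           # molecule id -> noise sentences


def gen_pairs(grammar: FragmentGrammar, n: int,
              frags_per_mol: tuple[int, int] = (2, 4),
              noise_rate: float = 0.1,
              seed: int = 0) -> tuple[list[PairedExample],
                                      dict[str, MoleculeRecord],
                                      GenerationLog]:
    """Sample molecules as fragment concatenations with matched descriptions.

    Each molecule concatenates ``k`` fragments sampled without
    replacement (``k`` uniform over ``frags_per_mol``); its description
    holds one property sentence per fragment, in shuffled order, plus a
    distractor sentence with probability ``noise_rate``.  Synonyms are
    synthetic and unique per molecule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = frags_per_mol
    if not (1 <= lo <= hi <= 6):
        raise ValueError("frags_per_mol must lie within [1, 6]")
    rng = np.random.default_rng(seed)
    pairs: list[PairedExample] = []
    records: dict[str, MoleculeRecord] = {}
    log = GenerationLog(compositions={}, noise_flags={})
    for i in range(n):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(grammar.fragments))
        idx = rng.choice(len(grammar.fragments), size=k, replace=False)
        frags = [grammar.fragments[j] for j in idx]
        smiles = "".join(frags)
        sentences = [grammar.property_map[f][rng.integers(
            len(grammar.property_map[f]))] for f in frags]
        noise = []
        if grammar.noise_sentences and rng.random() < noise_rate:
            noise = [grammar.noise_sentences[
                rng.integers(len(grammar.noise_sentences))]]
        all_sents = sentences + noise
        order = rng.permutation(len(all_sents))
        description = " ".join(all_sents[j] for j in order)
        mol_id = f"M{i:05d}"
        rec = MoleculeRecord(
            id=mol_id,
            name=f"substance-{i:05d}",
            synonyms=[f"substance-{i:05d}", f"compound-{i:05d}",
                      f"cpd {i:05d}"],
            smiles=simplify_smiles(smiles),
        )
        records[mol_id] = rec
        pairs.append(PairedExample(molecule=rec, description=description))
        log.compositions[mol_id] = frags
        log.noise_flags[mol_id] = noise
    return pairs, records, log


@dataclass
class PlantedMention:
    doc: int
    sentence: int
    start: int
    end: int
    molecule_id: str
    synonym: str


def gen_corpus(records: dict[str, MoleculeRecord],
               grammar: FragmentGrammar,
               n_docs: int = 100,
               mentions_per_doc: int = 2,
               log: GenerationLog | None = None,
               seed: int = 0) -> tuple[list[dict], list[PlantedMention]]:
    """Documents with molecule mentions planted at recorded positions.

    Each mention sentence names a molecule by a random synonym and
    states one of its fragments' properties (the sentence's "It" is
    replaced by the synonym), so that after SMILES insertion the mixed
    corpus carries a cross-modal signal.  Filler sentences carry no
    mentions.  Returned plants are the ground truth for linker
    precision/recall tests.
    """
    if not records:
        raise ValueError("molecule dictionary is empty")
    rng = np.random.default_rng(seed)
    mol_ids = sorted(records)
    docs: list[dict] = []
    plants: list[PlantedMention] = []
    for d in range(n_docs):
        sentences: list[str] = []
        for _ in range(mentions_per_doc):
            mol_id = mol_ids[rng.integers(len(mol_ids))]
            rec = records[mol_id]
            syn = rec.synonyms[rng.integers(len(rec.synonyms))]
            if log is not None and log.compositions.get(mol_id):
                frags = log.compositions[mol_id]
                frag = frags[rng.integers(len(frags))]
                prop = grammar.property_map[frag][
                    rng.integers(len(grammar.property_map[frag]))]
                # "It is <adj> <ctx>." -> "<syn> is <adj> <ctx>."
                body = prop.split(" ", 1)[1]
            else:
                body = "is described in the registry."
            prefix = _MENTION_PREFIXES[rng.integers(len(_MENTION_PREFIXES))]
            sent = f"{prefix}{syn} {body}"
            plants.append(PlantedMention(
                doc=d, sentence=len(sentences),
                start=len(prefix), end=len(prefix) + len(syn),
                molecule_id=mol_id, synonym=syn))
            sentences.append(sent)
            if rng.random() < 0.5:
                sentences.append(_FILLERS[rng.integers(len(_FILLERS))])
        if mentions_per_doc == 0:
            sentences.append(_FILLERS[rng.integers(len(_FILLERS))])
        docs.append({"doc_id": f"doc-{d:04d}", "sentences": sentences})
    return docs, plants
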