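"""Paired (molecule, description) examples and train/valid/test splits.

Each example couples one substance with a natural-language property
description.  Following the convention of the paired corpus these
descriptions emulate, every synonym of the described substance is
replaced by the word "it" so that retrieval cannot shortcut through
the name.  Splitting is done by molecule, by default in ratio 7:1:2.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .linking import MoleculeRecord, split_sentences
from .smiles import simplify_smiles


@dataclass
class PairedExample:
    """One molecule paired with one description paragraph."""

    molecule: MoleculeRecord
    description: str
    split: str = "train"

    def __post_init__(self) -> None:
        if not self.description.strip():
            raise ValueError("description must be non-empty")

    @property
    def sentences(self) -> list[str]:
        return split_sentences(self.description)

    def to_json(self) -> str:
        return json.dumps({
            "molecule_id": self.molecule.id,
            "smiles": self.molecule.smiles.raw,
            "description": self.description,
            "split": self.split,
        }, sort_keys=True)


def mask_synonyms(description: str, record: MoleculeRecord,
                  placeholder: str = "it") -> str:
    """Replace every synonym of the molecule in the text by a placeholder."""
    out = description
    for syn in sorted(record.synonyms, key=len, reverse=True):
        out = re.sub(r"\b" + re.escape(syn) + r"\b", placeholder, out,
                     flags=re.IGNORECASE)
    return out


def assign_splits(pairs: Sequence[PairedExample],
                  ratios: tuple[int, int, int] = (7, 1, 2),
                  seed: int = 0) -> list[PairedExample]:
    """Shuffle molecules and split them train/valid/test by the ratios."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    total = sum(ratios)
    n_train = round(len(pairs) * ratios[0] / total)
    n_valid = round(len(pairs) * ratios[1] / total)
    for rank, idx in enumerate(order):
        if rank < n_train:
            pairs[idx].split = "train"
        elif rank < n_train + n_valid:
            pairs[idx].split = "valid"
        else:
            pairs[idx].split = "test"
    return list(pairs)


def read_pairs(path, records: dict[str, MoleculeRecord] | None = None
               ) -> list[PairedExample]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            if records and d["molecule_id"] in records:
                mol = records[d["molecule_id"]]
            else:
                mol = MoleculeRecord(id=d["molecule_id"], name=d["molecule_id"],
                                     synonyms=[], smiles=simplify_smiles(d["smiles"]))
            pairs.append(PairedExample(molecule=mol,
                                       description=d["description"],
                                       split=d.get("split", "train")))
    return pairs


def write_pairs(pairs: Iterable[PairedExample], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(p.to_json() + "\n")
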