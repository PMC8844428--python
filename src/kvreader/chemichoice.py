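"""Four-way multiple-choice benchmark over molecule descriptions.

Questions pair a SMILES stem with four candidate property sentences,
exactly one of which comes from the stem molecule's own description.
Negatives are drawn from a *choice base*: the description sentences
that recur across the corpus (occurrence count above a threshold,
derivation-style sentences excluded), sorted lexicographically so that
similar — likely paraphrased — sentences receive nearby indices.
Requiring every negative's index to differ from the positive's
insertion index by more than a gap then suppresses false negatives.
"""

from __future__ import annotations

import bisect
import json
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .pairs import PairedExample
from .retrieval import CrossModalRetriever, cosine_score

#: default predicate for the excluded derivation-description category
_DERIVATION = re.compile(
    r"\b(derived|derivative|derivation|obtained from|prepared from)\b",
    re.IGNORECASE)


def is_derivation_sentence(sentence: str) -> bool:
    return bool(_DERIVATION.search(sentence))


@dataclass
class ChoiceBase:
    """Sorted recurring description sentences with their counts."""

    sentences: list[str]
    counts: dict[str, int]
    min_count: int

    def __len__(self) -> int:
        return len(self.sentences)

    def insertion_index(self, sentence: str) -> int:
        """Lexicographic insertion position of a (possibly absent) sentence."""
        return bisect.bisect_left(self.sentences, sentence.casefold())


@dataclass
class ChoiceQuestion:
    """One stem with four choices; ``answer`` indexes the positive."""

    qid: str
    smiles: str
    choices: list[str]
    answer: int
    provenance: dict

    def __post_init__(self) -> None:
        if len(self.choices) != 4 or len(set(self.choices)) != 4:
            raise ValueError("a question needs 4 distinct choices")
        if not 0 <= self.answer < 4:
            raise ValueError("answer index out of range")

    def to_json(self, blind: bool = False) -> str:
        d = {"qid": self.qid, "smiles": self.smiles, "choices": self.choices}
        if not blind:
            d["answer"] = self.answer
            d["provenance"] = self.provenance
        return json.dumps(d, sort_keys=True)


def build_choice_base(
    pairs: Sequence[PairedExample],
    min_count: int = 6,
    exclude: Callable[[str], bool] = is_derivation_sentence,
) -> ChoiceBase:
    """Count description sentences and keep the recurring ones, sorted.

    A sentence survives iff its corpus-wide occurrence count is at
    least ``min_count`` (the default keeps sentences occurring more
    than five times) and the exclusion predicate rejects it.  Sorting
    is case-folded lexicographic.
    """
    counts: Counter = Counter()
    for pair in pairs:
        counts.update(s.casefold() for s in pair.sentences)
    kept = sorted(s for s, c in counts.items()
                  if c >= min_count and not exclude(s))
    if not kept:
        raise ValueError("choice base is empty: no sentence passed the "
                         f"count >= {min_count} filter")
    return ChoiceBase(sentences=kept,
                      counts={s: counts[s] for s in kept},
                      min_count=min_count)


def generate_questions(
    pairs: Sequence[PairedExample],
    base: ChoiceBase,
    gap: int = 10,
    seed: int = 0,
) -> list[ChoiceQuestion]:
    """One question per molecule, with gap-constrained negative sampling.

    The positive is drawn uniformly from the molecule's own description
    sentences; the three negatives are drawn without replacement from
    base entries whose index differs from the positive's insertion
    index by more than ``gap``.  Choice order is shuffled under the
    given seed, so the same seed reproduces the file byte-for-byte.
    """
    if len(base) <= 3 + 2 * gap:
        raise ValueError(
            f"choice base of {len(base)} sentences is too small for "
            f"gap={gap}; need more than {3 + 2 * gap}")
    rng = np.random.default_rng(seed)
    questions = []
    for pair in pairs:
        sentences = pair.sentences or [pair.description]
        positive = sentences[rng.integers(len(sentences))]
        pos_idx = base.insertion_index(positive)
        legal = [i for i in range(len(base)) if abs(i - pos_idx) > gap
                 and base.sentences[i] != positive.casefold()]
        if len(legal) < 3:
            raise ValueError(
                f"cannot generate negatives for molecule {pair.molecule.id}: "
                f"only {len(legal)} base sentences clear the gap")
        neg_idx = rng.choice(len(legal), size=3, replace=False)
        negatives = [base.sentences[legal[i]] for i in neg_idx]
        choices = [positive] + negatives
        order = rng.permutation(4)
        shuffled = [choices[i] for i in order]
        answer = int(np.where(order == 0)[0][0])
        questions.append(ChoiceQuestion(
            qid=f"q-{pair.molecule.id}",
            smiles=pair.molecule.smiles.simplified,
            choices=shuffled,
            answer=answer,
            provenance={
                "molecule_id": pair.molecule.id,
                "positive_insertion_index": pos_idx,
                "negative_indices": [int(legal[i]) for i in neg_idx],
            },
        ))
    return questions


def answer_questions(
    questions: Sequence[ChoiceQuestion],
    retriever: CrossModalRetriever,
) -> tuple[list[int], float]:
    """Pick, for each stem, the choice with the highest cosine score.

    Ties break toward the lowest choice index.  Returns the chosen
    indices and the fraction answered correctly.
    """
    questions = list(questions)
    stems = retriever.embed_texts(
        [f"[SMI] {q.smiles} [/SMI]" for q in questions], kind="smiles")
    choices = retriever.embed_texts(
        [c for q in questions for c in q.choices], kind="text")
    answers = []
    correct = 0
    for i, q in enumerate(questions):
        vecs = choices[4 * i:4 * i + 4]
        scores = [cosine_score(stems[i], v) for v in vecs]
        pick = int(np.argmax(scores))  # argmax takes the first maximum
        answers.append(pick)
        correct += int(pick == q.answer)
    return answers, correct / len(questions)


def write_questions(questions: Iterable[ChoiceQuestion], path,
                    blind: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in questions:
            fh.write(q.to_json(blind=blind) + "\n")


def read_questions(path) -> list[ChoiceQuestion]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(ChoiceQuestion(
                    qid=d["qid"], smiles=d["smiles"], choices=d["choices"],
                    answer=d["answer"], provenance=d.get("provenance", {})))
    return out
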