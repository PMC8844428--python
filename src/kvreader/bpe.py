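"""Data-driven byte-pair-encoding of simplified SMILES strings.

Starting from single characters (with the two-letter element symbols
``Cl`` and ``Br`` seeded as atomic units so they are never split), the
most frequent adjacent token pair in the corpus is iteratively fused
into a new sub-structure pattern.  The surviving patterns — those whose
corpus frequency reaches a retention threshold — tend to be chemically
meaningful units such as carbon chains and functional groups.

The estimator follows the scikit-learn fit/transform convention:

>>> tok = SmilesBpeTokenizer(num_merges=2).fit(["CCO", "CCO", "CCN"])
>>> tok.transform(["CCOC"])
[['CCO', 'C']]
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .smiles import SimplifiedSmiles, simplify_smiles

#: element symbols treated as indivisible base tokens
DEFAULT_TWO_CHAR_SYMBOLS = frozenset({"Cl", "Br"})


@dataclass
class SmilesBpeVocab:
    """Learned merge rules plus the surviving sub-structure patterns.

    ``merges`` is the ordered list of (left, right) fusions; replaying it
    over the base alphabet reconstructs every pattern.  ``patterns`` maps
    each retained pattern to its corpus frequency after the final merge;
    base-alphabet tokens are always retained (encoding backs off to them)
    even when their residual frequency falls below ``min_frequency``.
    """

    merges: list[tuple[str, str]]
    patterns: dict[str, int]
    min_frequency: int
    base_alphabet: set[str] = field(default_factory=set)

    @property
    def two_char_symbols(self) -> frozenset[str]:
        return frozenset(t for t in self.base_alphabet if len(t) > 1)

    def save(self, path) -> None:
        """Write the vocabulary as plain text (bit-exact round trip)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write("#kvreader-bpe v1\n")
        buf.write(f"#min_frequency\t{self.min_frequency}\n")
        buf.write("#base\t" + " ".join(sorted(self.base_alphabet)) + "\n")
        buf.write("#merges\n")
        for left, right in self.merges:
            buf.write(f"{left} {right}\n")
        buf.write("#patterns\n")
        for pat in sorted(self.patterns):
            buf.write(f"{pat}\t{self.patterns[pat]}\n")
        return buf.getvalue()

    @classmethod
    def load(cls, path) -> "SmilesBpeVocab":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.loads(fh.read())

    @classmethod
    def loads(cls, text: str) -> "SmilesBpeVocab":
        lines = text.splitlines()
        if not lines or not lines[0].startswith("#kvreader-bpe"):
            raise ValueError("not a kvreader BPE vocabulary file")
        min_frequency = 1
        base: set[str] = set()
        merges: list[tuple[str, str]] = []
        patterns: dict[str, int] = {}
        section = None
        for line in lines[1:]:
            if not line:
                continue
            if line.startswith("#min_frequency"):
                min_frequency = int(line.split("\t")[1])
            elif line.startswith("#base"):
                payload = line.split("\t", 1)[1] if "\t" in line else ""
                base = set(payload.split()) if payload else set()
            elif line == "#merges":
                section = "merges"
            elif line == "#patterns":
                section = "patterns"
            elif section == "merges":
                left, right = line.split(" ")
                merges.append((left, right))
            elif section == "patterns":
                pat, freq = line.split("\t")
                patterns[pat] = int(freq)
        return cls(merges=merges, patterns=patterns,
                   min_frequency=min_frequency, base_alphabet=base)


def _as_simplified(s) -> str:
    if isinstance(s, SimplifiedSmiles):
        return s.simplified
    return simplify_smiles(s).simplified


def _to_symbols(s: str, two_char: frozenset[str]) -> list[str]:
    """Greedy left-to-right split into base symbols, keeping Cl/Br whole."""
    out: list[str] = []
    i = 0
    n = len(s)
    while i < n:
        if i + 1 < n and s[i:i + 2] in two_char:
            out.append(s[i:i + 2])
            i += 2
        else:
            out.append(s[i])
            i += 1
    return out


def _apply_merge(tokens: list[str], left: str, right: str) -> list[str]:
    """Fuse every non-overlapping (left, right) adjacency, left to right."""
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and tokens[i] == left and tokens[i + 1] == right:
            out.append(left + right)
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


class SmilesBpeTokenizer(TransformerMixin, BaseEstimator):
    """Learn and apply a BPE sub-structure vocabulary over SMILES strings.

    Parameters
    ----------
    num_merges : int, default=100
        Number of pair-fusion rules to learn.
    min_frequency : int, default=1
        Patterns whose corpus frequency (after the final merge) falls
        below this are dropped from the retained vocabulary; the merge
        lineage is kept so encoding backs off to shorter patterns.
    seed : int, default=0
        Accepted for interface uniformity; training is fully
        deterministic (frequency ties are broken lexicographically on
        the (left, right) pair), so the seed has no effect.
    two_char_symbols : frozenset of str
        Element symbols seeded into the base alphabet as atomic units.

    Attributes
    ----------
    vocab_ : SmilesBpeVocab
        The learned merges and retained patterns.
    """

    def __init__(self, num_merges: int = 100, min_frequency: int = 1,
                 seed: int = 0,
                 two_char_symbols: frozenset = DEFAULT_TWO_CHAR_SYMBOLS):
        self.num_merges = num_merges
        self.min_frequency = min_frequency
        self.seed = seed
        self.two_char_symbols = two_char_symbols

    def fit(self, X: Iterable, y=None) -> "SmilesBpeTokenizer":
        corpus = [_as_simplified(s) for s in X]
        if not corpus:
            raise ValueError("BPE training corpus is empty")
        if self.num_merges < 0:
            raise ValueError("num_merges must be >= 0")
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")
        two_char = frozenset(self.two_char_symbols)
        seqs = [_to_symbols(s, two_char) for s in corpus]

        base: set[str] = set()
        for seq in seqs:
            base.update(seq)

        merges: list[tuple[str, str]] = []
        for _ in range(self.num_merges):
            counts: Counter = Counter()
            for seq in seqs:
                for a, b in zip(seq, seq[1:]):
                    counts[(a, b)] += 1
            if not counts:
                break
            # most frequent pair; ties broken lexicographically
            best = min(counts, key=lambda p: (-counts[p], p))
            merges.append(best)
            seqs = [_apply_merge(seq, *best) for seq in seqs]

        freqs: Counter = Counter()
        for seq in seqs:
            freqs.update(seq)
        patterns = {t: c for t, c in freqs.items() if c >= self.min_frequency}
        for t in base:  # base tokens always survive, for back-off
            patterns.setdefault(t, freqs.get(t, 0))

        self.vocab_ = SmilesBpeVocab(
            merges=merges, patterns=patterns,
            min_frequency=self.min_frequency, base_alphabet=base,
        )
        return self

    def encode(self, s) -> list[str]:
        """Segment one (simplified) SMILES string into patterns.

        Merges are applied exhaustively in learned order; the output
        tokens concatenate back to the input exactly.  Characters
        outside the base alphabet degrade to singleton tokens.
        """
        vocab = self.vocab_
        text = _as_simplified(s)
        tokens = _to_symbols(text, vocab.two_char_symbols)
        for left, right in vocab.merges:
            tokens = _apply_merge(tokens, left, right)
        return tokens

    def transform(self, X: Sequence) -> list[list[str]]:
        return [self.encode(s) for s in X]

    @classmethod
    def from_vocab(cls, vocab: SmilesBpeVocab) -> "SmilesBpeTokenizer":
        tok = cls(num_merges=len(vocab.merges),
                  min_frequency=vocab.min_frequency,
                  two_char_symbols=vocab.two_char_symbols)
        tok.vocab_ = vocab
        return tok


def train_bpe(corpus: Sequence, num_merges: int, min_frequency: int = 1,
              seed: int = 0) -> SmilesBpeVocab:
    """Functional wrapper: learn a BPE vocabulary from a SMILES corpus."""
    tok = SmilesBpeTokenizer(num_merges=num_merges,
                             min_frequency=min_frequency, seed=seed)
    return tok.fit(corpus).vocab_


def encode_smiles(s, vocab: SmilesBpeVocab) -> list[str]:
    """Functional wrapper: segment one SMILES string with a learned vocab."""
    return SmilesBpeTokenizer.from_vocab(vocab).encode(s)
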