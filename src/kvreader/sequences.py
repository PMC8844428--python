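"""Mixed token sequences: text with embedded, delimited SMILES spans.

A corpus sentence after entity linking looks like

    ``Aspirin [SMI] CC=OOcccccC=OO [/SMI] reduces fever.``

Tokenization produces a single stream of tokens with a parallel segment
label per token (``TEXT``, ``SMILES`` or ``SPECIAL``).  In *dual* mode
(the starred model variant) SMILES spans are segmented by the learned
sub-structure tokenizer and live in their own vocabulary namespace,
disjoint from natural-language tokens; in *shared* mode the whole
string goes through the text tokenizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .bpe import SmilesBpeVocab, encode_smiles
from .text import TextTokenizer, WordTokenizer

SMI_OPEN = "[SMI]"
SMI_CLOSE = "[/SMI]"

TEXT = "TEXT"
SMILES = "SMILES"
SPECIAL = "SPECIAL"

#: maximum text positions / maximum tokens inside one SMILES span
MAX_TEXT_LEN = 128
MAX_SMILES_LEN = 64

Mode = Literal["shared", "dual"]


@dataclass
class MixedTokenSequence:
    """Token stream with per-token segment labels.

    SMILES spans are contiguous and delimited by the SPECIAL boundary
    tokens ``[SMI]`` / ``[/SMI]``; truncation never removes a boundary
    marker.
    """

    tokens: list[str]
    segments: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.segments):
            raise ValueError("tokens and segments must have equal length")
        bad = set(self.segments) - {TEXT, SMILES, SPECIAL}
        if bad:
            raise ValueError(f"unknown segment labels: {bad}")
        self._check_spans()

    def _check_spans(self) -> None:
        depth = 0
        for tok, seg in zip(self.tokens, self.segments):
            if tok == SMI_OPEN:
                if depth:
                    raise ValueError("nested SMILES span")
                depth = 1
            elif tok == SMI_CLOSE:
                if not depth:
                    raise ValueError("unmatched SMILES span close")
                depth = 0
            elif seg == SMILES and not depth:
                raise ValueError("SMILES token outside a delimited span")
        if depth:
            raise ValueError("unclosed SMILES span")

    def __len__(self) -> int:
        return len(self.tokens)


def split_smiles_spans(text: str) -> list[tuple[str, bool]]:
    """Split a marked-up string into (chunk, is_smiles) parts.

    Raises ``ValueError`` on unbalanced or nested boundary markers.
    """
    parts: list[tuple[str, bool]] = []
    pos = 0
    while True:
        start = text.find(SMI_OPEN, pos)
        if start == -1:
            tail = text[pos:]
            if SMI_CLOSE in tail:
                raise ValueError("unmatched [/SMI] marker")
            if tail:
                parts.append((tail, False))
            return parts
        head = text[pos:start]
        if SMI_CLOSE in head:
            raise ValueError("unmatched [/SMI] marker")
        if head:
            parts.append((head, False))
        end = text.find(SMI_CLOSE, start + len(SMI_OPEN))
        inner = text[start + len(SMI_OPEN):end if end != -1 else None]
        if end == -1 or SMI_OPEN in inner:
            raise ValueError("unbalanced [SMI] marker")
        parts.append((inner.strip(), True))
        pos = end + len(SMI_CLOSE)


def tokenize_mixed(
    text: str,
    mode: Mode = "dual",
    vocab: SmilesBpeVocab | None = None,
    text_tokenizer: TextTokenizer | None = None,
    max_text_len: int = MAX_TEXT_LEN,
    max_smiles_len: int = MAX_SMILES_LEN,
) -> MixedTokenSequence:
    """Tokenize a string with delimited SMILES spans into a mixed sequence.

    In ``dual`` mode SMILES spans are encoded with the sub-structure
    tokenizer (``vocab`` required) and text with ``text_tokenizer``; in
    ``shared`` mode everything goes through the text tokenizer, with
    segment labels still marking the spans.  Text positions are capped
    at ``max_text_len`` in total and each SMILES span at
    ``max_smiles_len`` tokens; boundary markers are never dropped.
    """
    if mode not in ("shared", "dual"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "dual" and vocab is None:
        raise ValueError("dual mode requires a trained SMILES BPE vocab")
    tokenizer = text_tokenizer if text_tokenizer is not None else WordTokenizer()

    tokens: list[str] = []
    segments: list[str] = []
    text_budget = max_text_len
    for chunk, is_smiles in split_smiles_spans(text):
        if is_smiles:
            if mode == "dual":
                span = encode_smiles(chunk, vocab)
            else:
                span = tokenizer.tokenize(chunk)
            span = span[:max_smiles_len]
            tokens.append(SMI_OPEN)
            segments.append(SPECIAL)
            tokens.extend(span)
            segments.extend([SMILES] * len(span))
            tokens.append(SMI_CLOSE)
            segments.append(SPECIAL)
        else:
            words = tokenizer.tokenize(chunk)
            take = words[:max(text_budget, 0)]
            text_budget -= len(take)
            tokens.extend(take)
            segments.extend([TEXT] * len(take))
    return MixedTokenSequence(tokens=tokens, segments=segments)


# ---------------------------------------------------------------------------
# integer vocabulary shared by the masking policy and the encoder

PAD, CLS, SEP, MASK, UNK = "[PAD]", "[CLS]", "[SEP]", "[MASK]", "[UNK]"
SPECIAL_TOKENS = [PAD, CLS, SEP, MASK, UNK, SMI_OPEN, SMI_CLOSE]


@dataclass
class TokenVocabulary:
    """Maps (token, segment) pairs to integer ids.

    In dual mode the TEXT and SMILES namespaces are disjoint id ranges,
    so a SMILES sub-structure pattern that happens to spell the same
    string as a word still gets its own id.  In shared mode there is a
    single namespace and SMILES-segment tokens resolve through it.
    """

    mode: Mode
    text_tokens: list[str]
    smiles_tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._special_ids = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
        off = len(SPECIAL_TOKENS)
        self._text_ids = {t: off + i for i, t in enumerate(self.text_tokens)}
        off += len(self.text_tokens)
        self._smiles_ids = {t: off + i for i, t in enumerate(self.smiles_tokens)}
        self.size = off + len(self.smiles_tokens)

    @classmethod
    def from_sequences(cls, seqs: Sequence[MixedTokenSequence],
                       mode: Mode) -> "TokenVocabulary":
        text: set[str] = set()
        smi: set[str] = set()
        for seq in seqs:
            for tok, seg in zip(seq.tokens, seq.segments):
                if seg == TEXT:
                    text.add(tok)
                elif seg == SMILES:
                    (smi if mode == "dual" else text).add(tok)
        return cls(mode=mode, text_tokens=sorted(text),
                   smiles_tokens=sorted(smi) if mode == "dual" else [])

    def id_of(self, token: str, segment: str) -> int:
        if token in self._special_ids:
            return self._special_ids[token]
        if segment == SMILES and self.mode == "dual":
            return self._smiles_ids.get(token, self._special_ids[UNK])
        return self._text_ids.get(token, self._special_ids[UNK])

    def encode(self, seq: MixedTokenSequence, add_cls: bool = True) -> np.ndarray:
        toks = zip(seq.tokens, seq.segments)
        ids = [self.id_of(t, s) for t, s in toks]
        if add_cls:
            ids = [self._special_ids[CLS]] + ids
        return np.asarray(ids, dtype=np.int64)

    def namespace_tokens(self, segment: str) -> list[str]:
        """Tokens eligible as random replacements at a given segment."""
        if segment == SMILES and self.mode == "dual":
            return self.smiles_tokens
        return self.text_tokens

    def is_smiles_id(self, idx: int) -> bool:
        off = len(SPECIAL_TOKENS) + len(self.text_tokens)
        return idx >= off

    @property
    def pad_id(self) -> int:
        return self._special_ids[PAD]

    @property
    def mask_id(self) -> int:
        return self._special_ids[MASK]

    @property
    def cls_id(self) -> int:
        return self._special_ids[CLS]
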