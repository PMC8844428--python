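"""Token corruption for masked-token pre-training.

Each non-special position is independently selected with probability
``select_prob``; selected positions are replaced by the mask token,
by a random same-namespace token, or kept unchanged, in the classic
80/10/10 split.  Random replacements respect the vocabulary namespace
of the position: a SMILES position is never corrupted with a natural-
language word (and vice versa) when the dual tokenizer is in use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import MASK, SPECIAL, MixedTokenSequence, TokenVocabulary


@dataclass
class MaskingPolicy:
    """Selection probability and mask/random/keep action split.

    ``mask_frac + random_frac + keep_frac`` must equal 1; special
    tokens (boundary markers, padding, CLS) are never selected.
    """

    select_prob: float = 0.15
    mask_frac: float = 0.8
    random_frac: float = 0.1
    keep_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.select_prob <= 1.0):
            raise ValueError("select_prob must lie in [0, 1]")
        total = self.mask_frac + self.random_frac + self.keep_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mask/random/keep fractions must sum to 1")
        if min(self.mask_frac, self.random_frac, self.keep_frac) < 0:
            raise ValueError("action fractions must be nonnegative")
        if self.select_prob == 0 and self.mask_frac == 0 and \
                self.random_frac == 0 and self.keep_frac == 0:
            raise ValueError("degenerate all-zero masking policy")


def mask_tokens(
    seq: MixedTokenSequence,
    policy: MaskingPolicy,
    vocab: TokenVocabulary,
    rng: np.random.Generator | None = None,
) -> tuple[MixedTokenSequence, dict[int, str]]:
    """Corrupt a sequence and return it with the reconstruction targets.

    Returns the corrupted sequence and a mapping from selected position
    to the original token at that position (the prediction targets).
    """
    if len(seq) == 0:
        raise ValueError("cannot mask an empty sequence")
    if rng is None:
        rng = np.random.default_rng(policy.seed)

    tokens = list(seq.tokens)
    targets: dict[int, str] = {}
    for i, (tok, segment) in enumerate(zip(seq.tokens, seq.segments)):
        if segment == SPECIAL:
            continue
        if rng.random() >= policy.select_prob:
            continue
        targets[i] = tok
        u = rng.random()
        if u < policy.mask_frac:
            tokens[i] = MASK
        elif u < policy.mask_frac + policy.random_frac:
            pool = vocab.namespace_tokens(segment)
            if pool:
                tokens[i] = pool[rng.integers(len(pool))]
        # else: keep the original token
    corrupted = MixedTokenSequence(tokens=tokens, segments=list(seq.segments))
    return corrupted, targets
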