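"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from kvreader.bpe import SmilesBpeTokenizer
from kvreader.pretrain import MaskedLanguagePretrainer
from kvreader.sequences import SMI_CLOSE, SMI_OPEN, tokenize_mixed
from kvreader.synthetic import default_grammar, gen_pairs


def random_simplified_smiles(rng: np.random.Generator, n: int,
                             alphabet: str = "CNOSc=#.+-",
                             max_len: int = 30) -> list[str]:
    """Seeded random fragment-style strings over SMILES-ish symbols."""
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len))
        out.append("".join(rng.choice(list(alphabet), size=length)))
    return out


@pytest.fixture(scope="session")
def small_world():
    """300 synthetic pairs from a 10-fragment grammar, with records/log."""
    grammar = default_grammar(n_fragments=10, seed=7)
    pairs, records, log = gen_pairs(grammar, 300, seed=7)
    return grammar, pairs, records, log


@pytest.fixture(scope="session")
def small_bpe(small_world):
    _, pairs, _, _ = small_world
    return SmilesBpeTokenizer(num_merges=40, min_frequency=2, seed=0).fit(
        [p.molecule.smiles for p in pairs])


@pytest.fixture(scope="session")
def small_pretrained(small_world, small_bpe):
    """A briefly pre-trained encoder over the small world's mixed text."""
    _, pairs, _, _ = small_world
    seqs = [
        tokenize_mixed(
            f"{SMI_OPEN} {p.molecule.smiles.simplified} {SMI_CLOSE} "
            f"{p.description}",
            mode="dual", vocab=small_bpe.vocab_)
        for p in pairs
    ]
    est = MaskedLanguagePretrainer(mode="dual", epochs=1, batch_size=32,
                                   seed=0)
    return est.fit(seqs)
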