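"""SMILES simplification, BPE training/encoding, and mixed tokenization."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kvreader.bpe import (SmilesBpeTokenizer, SmilesBpeVocab, encode_smiles,
                          train_bpe)
from kvreader.sequences import (SMILES, SPECIAL, TEXT, MixedTokenSequence,
                                tokenize_mixed)
from kvreader.smiles import simplify_smiles

from conftest import random_simplified_smiles


# ---------------------------------------------------------------------------
# an independent brute-force BPE oracle: re-counts every adjacent pair
# from scratch at every iteration, with no shared code with the package

def oracle_bpe_merges(corpus: list[str], num_merges: int,
                      two_char=("Cl", "Br")) -> list[tuple[str, str]]:
    def split(s):
        toks, i = [], 0
        while i < len(s):
            if s[i:i + 2] in two_char:
                toks.append(s[i:i + 2]); i += 2
            else:
                toks.append(s[i]); i += 1
        return toks

    seqs = [split(s) for s in corpus]
    merges = []
    for _ in range(num_merges):
        counts = Counter(p for seq in seqs for p in zip(seq, seq[1:]))
        if not counts:
            break
        top = max(counts.values())
        best = sorted(p for p, c in counts.items() if c == top)[0]
        merges.append(best)
        fused = best[0] + best[1]
        new_seqs = []
        for seq in seqs:
            out, i = [], 0
            while i < len(seq):
                if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                    out.append(fused); i += 2
                else:
                    out.append(seq[i]); i += 1
            new_seqs.append(out)
        seqs = new_seqs
    return merges


# ---------------------------------------------------------------------------
# simplification

@pytest.mark.parametrize("raw, expected", [
    ("C1=CC=CC=C1", "C=CC=CC=C"),
    ("CC(=O)O", "CC=OO"),
    ("[NH4+].[Cl-]", "NH+.Cl-"),
    ("C%12CC%12", "CCC"),
    ("C/C=C\\C", "C/C=C\\C"),   # stereo markers are kept
])
def test_simplify_removes_brackets_and_digits(raw, expected):
    assert simplify_smiles(raw).simplified == expected


@pytest.mark.parametrize("bad", ["", "   ", "\t\n"])
def test_simplify_rejects_empty_input(bad):
    with pytest.raises(ValueError):
        simplify_smiles(bad)


@given(st.text(alphabet="CNOScl()[]0123456789%=#@/\\.+-", min_size=1,
               max_size=40).filter(lambda s: simplifiable(s)))
@settings(max_examples=200, deadline=None)
def test_simplify_is_idempotent_and_subsequence(raw):
    first = simplify_smiles(raw)
    again = simplify_smiles(first.simplified)
    assert again.simplified == first.simplified
    # the simplified string is a subsequence of the raw one
    it = iter(raw.strip())
    assert all(ch in it for ch in first.simplified)


def simplifiable(s: str) -> bool:
    stripped = "".join(c for c in s.strip() if c not in set("()[]%0123456789"))
    return bool(stripped.strip())


# ---------------------------------------------------------------------------
# BPE training

def test_bpe_merges_match_worked_example():
    vocab = train_bpe(["CCO", "CCO", "CCN"], num_merges=2, min_frequency=1)
    assert vocab.merges == [("C", "C"), ("CC", "O")]


def test_bpe_frequency_filter_drops_rare_patterns_keeps_base():
    vocab = train_bpe(["CCO", "CCO", "CCN"], num_merges=2, min_frequency=2)
    assert "CCN" not in vocab.patterns
    assert vocab.patterns["CCO"] == 2
    # base-alphabet tokens survive for back-off even below the threshold
    assert {"C", "N", "O"} <= set(vocab.patterns)
    # merge lineage is retained despite the filter
    assert vocab.merges == [("C", "C"), ("CC", "O")]


def test_bpe_zero_merges_yields_base_alphabet():
    vocab = train_bpe(["CCO", "CN"], num_merges=0)
    assert set(vocab.patterns) == {"C", "N", "O"}
    assert vocab.merges == []


def test_bpe_empty_corpus_rejected():
    with pytest.raises(ValueError):
        train_bpe([], num_merges=3)


def test_two_char_element_symbols_never_split():
    vocab = train_bpe(["CClC", "CClO", "BrBr"], num_merges=3)
    assert "Cl" in vocab.base_alphabet and "Br" in vocab.base_alphabet
    assert all("l" not in (a, b) and "r" not in (a, b)
               for a, b in vocab.merges)


def test_bpe_matches_brute_force_oracle_on_random_corpora():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n_strings = int(rng.integers(2, 21))
        alphabet = "".join(rng.choice(list("CNOSc="),
                                      size=int(rng.integers(2, 7)),
                                      replace=False))
        corpus = random_simplified_smiles(rng, n_strings, alphabet=alphabet,
                                          max_len=15)
        num_merges = int(rng.integers(0, 12))
        vocab = train_bpe(corpus, num_merges=num_merges)
        assert vocab.merges == oracle_bpe_merges(corpus, num_merges)


def test_bpe_training_is_replay_deterministic():
    corpus = ["CCOCC", "CCNC", "OCCO", "CClBr"]
    a = train_bpe(corpus, num_merges=6, seed=1)
    b = train_bpe(corpus, num_merges=6, seed=2)
    assert a.merges == b.merges and a.patterns == b.patterns


# ---------------------------------------------------------------------------
# encoding

def test_encode_applies_merges_in_learned_order():
    vocab = train_bpe(["CCO", "CCO", "CCN"], num_merges=2)
    assert encode_smiles("CCOC", vocab) == ["CCO", "C"]


def test_encode_single_base_token():
    vocab = train_bpe(["CN"], num_merges=0)
    assert encode_smiles("N", vocab) == ["N"]


def test_encode_unknown_characters_degrade_to_singletons():
    vocab = train_bpe(["CCO"], num_merges=1)
    assert encode_smiles("CXQ", vocab) == ["C", "X", "Q"]


def test_encoding_round_trips_for_seeded_random_strings():
    rng = np.random.default_rng(3)
    corpus = random_simplified_smiles(rng, 200)
    tok = SmilesBpeTokenizer(num_merges=50).fit(corpus)
    probes = random_simplified_smiles(rng, 1000)
    for s in probes:
        assert "".join(tok.encode(s)) == s


def test_more_merges_never_lengthen_an_encoding():
    rng = np.random.default_rng(5)
    corpus = random_simplified_smiles(rng, 50, alphabet="CNO=")
    probes = random_simplified_smiles(rng, 20, alphabet="CNO=")
    prev = None
    for n_merges in (0, 2, 5, 10, 25, 50):
        tok = SmilesBpeTokenizer(num_merges=n_merges).fit(corpus)
        lengths = [len(tok.encode(s)) for s in probes]
        if prev is not None:
            assert all(a <= b for a, b in zip(lengths, prev))
        prev = lengths


def test_vocab_file_round_trip_is_bit_exact(tmp_path):
    vocab = train_bpe(["CCOCC", "CCNC", "OClO"], num_merges=5,
                      min_frequency=2)
    path = tmp_path / "vocab.txt"
    vocab.save(path)
    reloaded = SmilesBpeVocab.load(path)
    assert reloaded == vocab
    reloaded.save(tmp_path / "vocab2.txt")
    assert (tmp_path / "vocab.txt").read_bytes() == \
        (tmp_path / "vocab2.txt").read_bytes()


# ---------------------------------------------------------------------------
# mixed tokenization

def test_dual_mode_uses_smiles_tokenizer_inside_spans(small_bpe):
    seq = tokenize_mixed("it [SMI] CCO [/SMI] is volatile", mode="dual",
                         vocab=small_bpe.vocab_)
    open_i = seq.tokens.index("[SMI]")
    close_i = seq.tokens.index("[/SMI]")
    assert seq.segments[open_i] == SPECIAL and seq.segments[close_i] == SPECIAL
    span = seq.tokens[open_i + 1:close_i]
    assert "".join(span) == "CCO"
    assert all(s == SMILES for s in seq.segments[open_i + 1:close_i])
    assert seq.segments[0] == TEXT and seq.segments[-1] == TEXT


def test_shared_mode_routes_span_through_text_tokenizer(small_bpe):
    seq = tokenize_mixed("it [SMI] CCO [/SMI] is volatile", mode="shared")
    open_i = seq.tokens.index("[SMI]")
    close_i = seq.tokens.index("[/SMI]")
    # span tokens come from the (lower-casing) text tokenizer but still
    # carry the SMILES segment label
    assert seq.tokens[open_i + 1:close_i] == ["cco"]
    assert all(s == SMILES for s in seq.segments[open_i + 1:close_i])


def test_text_budget_truncates_long_sentences(small_bpe):
    text = " ".join(["word"] * 300) + " [SMI] CCO [/SMI]"
    seq = tokenize_mixed(text, mode="dual", vocab=small_bpe.vocab_)
    assert sum(s == TEXT for s in seq.segments) == 128
    # the SMILES span and its markers survive truncation
    assert "[SMI]" in seq.tokens and "[/SMI]" in seq.tokens


def test_smiles_span_budget_is_per_span(small_bpe):
    text = "[SMI] " + "C" * 500 + " [/SMI]"
    seq = tokenize_mixed(text, mode="dual", vocab=small_bpe.vocab_)
    assert sum(s == SMILES for s in seq.segments) <= 64
    assert seq.tokens[0] == "[SMI]" and seq.tokens[-1] == "[/SMI]"


@pytest.mark.parametrize("bad", [
    "one [SMI] CCO and no close",
    "unopened CCO [/SMI] here",
    "[SMI] C [SMI] C [/SMI]",
])
def test_unbalanced_markers_rejected(bad, small_bpe):
    with pytest.raises(ValueError):
        tokenize_mixed(bad, mode="dual", vocab=small_bpe.vocab_)


def test_mixed_sequence_validates_span_structure():
    with pytest.raises(ValueError):
        MixedTokenSequence(tokens=["C"], segments=[SMILES])
    with pytest.raises(ValueError):
        MixedTokenSequence(tokens=["a", "b"], segments=[TEXT])
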