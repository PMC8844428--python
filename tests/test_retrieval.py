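"""Cosine scoring, Max-of-Hinges loss laws, and retrieval metrics."""

from __future__ import annotations

import numpy as np
import pytest

from kvreader.pairs import PairedExample, assign_splits
from kvreader.retrieval import (CrossModalRetriever, cosine_score,
                                eval_batched_top1, eval_recall_at_k, mh_loss,
                                recall_from_scores, score_matrix,
                                top1_from_scores)


class TestCosine:
    def test_identical_vectors_score_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine_score(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert cosine_score([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_worked_example_45_degrees(self):
        assert cosine_score([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_score([0, 0], [1, 0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert cosine_score(3.7 * a, b) == pytest.approx(cosine_score(a, b))


class TestMaxOfHinges:
    def test_inactive_when_margins_satisfied(self):
        s = np.full((3, 3), 0.5)
        np.fill_diagonal(s, 0.9)
        per_pair, mean = mh_loss(s, alpha=0.2)
        assert np.allclose(per_pair, 0.0) and mean == 0.0

    def test_worked_example_with_two_active_hinges(self):
        # pair 0: hardest wrong description 0.8, hardest wrong molecule
        # 0.85, positive 0.9 -> (0.2+0.8-0.9) + (0.2+0.85-0.9) = 0.25
        s = np.array([[0.90, 0.80, 0.10],
                      [0.85, 0.90, 0.10],
                      [0.10, 0.10, 0.90]])
        per_pair, _ = mh_loss(s, alpha=0.2)
        assert per_pair[0] == pytest.approx(0.25)

    def test_constant_score_matrix_gives_two_alpha_per_pair(self):
        s = np.full((5, 5), 0.37)
        per_pair, mean = mh_loss(s, alpha=0.2)
        assert np.allclose(per_pair, 0.4) and mean == pytest.approx(0.4)

    def test_nonnegative_and_transpose_invariant_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            s = rng.uniform(-1, 1, size=(n, n))
            per_pair, mean = mh_loss(s, alpha=0.2)
            assert (per_pair >= 0).all()
            _, mean_t = mh_loss(s.T, alpha=0.2)
            assert mean_t == pytest.approx(mean)

    def test_zero_exactly_when_all_margins_met(self):
        rng = np.random.default_rng(7)
        alpha = 0.2
        for _ in range(200):
            n = int(rng.integers(2, 7))
            s = rng.uniform(-1, 1, size=(n, n))
            _, mean = mh_loss(s, alpha=alpha)
            pos = np.diag(s)
            off = ~np.eye(n, dtype=bool)
            margins_met = all(
                pos[i] - np.where(off, s, -np.inf)[i].max() >= alpha
                and pos[i] - np.where(off, s, -np.inf)[:, i].max() >= alpha
                for i in range(n))
            assert (mean == 0.0) == margins_met

    def test_unclamped_form_can_go_negative(self):
        s = np.eye(2) * 0.9 - 0.9 * (1 - np.eye(2))
        _, clamped = mh_loss(s, alpha=0.2, clamp_at_zero=True)
        _, literal = mh_loss(s, alpha=0.2, clamp_at_zero=False)
        assert clamped == 0.0 and literal < 0.0

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            mh_loss(np.array([[1.0]]), alpha=0.2)


class TestMetricCalibration:
    def test_identity_embeddings_are_perfect(self):
        s = np.eye(30)
        assert top1_from_scores(s) == (1.0, 1.0)
        assert recall_from_scores(s, k=5) == (1.0, 1.0)

    def test_ties_at_the_top_count_as_incorrect(self):
        s = np.ones((4, 4))
        assert top1_from_scores(s) == (0.0, 0.0)

    def test_worked_three_pair_matrix(self):
        s = np.array([[0.9, 0.2, 0.1],
                      [0.3, 0.8, 0.2],
                      [0.4, 0.1, 0.1]])
        s2t, t2s = top1_from_scores(s)
        assert s2t == pytest.approx(2 / 3)
        assert t2s == pytest.approx(2 / 3)

    def test_recall_at_one_with_one_swapped_pair(self):
        s = np.eye(5)
        s[[0, 1]] = s[[1, 0]]   # counterparts of pairs 0 and 1 swapped
        s2t, t2s = recall_from_scores(s, k=1)
        assert s2t == pytest.approx(3 / 5)
        assert t2s == pytest.approx(3 / 5)

    def test_random_unit_vectors_hit_chance_top1(self):
        rng = np.random.default_rng(0)
        hits = []
        for _ in range(200):
            m = rng.normal(size=(64, 32))
            d = rng.normal(size=(64, 32))
            s2t, t2s = top1_from_scores(score_matrix(m, d))
            hits.append((s2t + t2s) / 2)
        p = 1 / 64
        se = np.sqrt(p * (1 - p) / (200 * 64))
        assert abs(np.mean(hits) - p) < 3 * se

    def test_random_unit_vectors_hit_chance_recall(self):
        rng = np.random.default_rng(1)
        n, k, trials = 3000, 20, 20
        vals = []
        for _ in range(trials):
            m = rng.normal(size=(n, 16))
            d = rng.normal(size=(n, 16))
            s2t, t2s = recall_from_scores(score_matrix(m, d), k=k)
            vals.append((s2t + t2s) / 2)
        p = k / n
        se = np.sqrt(p * (1 - p) / (trials * n))
        assert abs(np.mean(vals) - p) < 3 * se

    def test_k_must_be_smaller_than_candidate_set(self):
        with pytest.raises(ValueError):
            recall_from_scores(np.eye(5), k=5)


def _toy_pairs(n: int) -> list[PairedExample]:
    from kvreader.linking import MoleculeRecord
    rng = np.random.default_rng(0)
    out = []
    for i in range(n):
        smiles = "".join(rng.choice(list("CNO"), size=6))
        rec = MoleculeRecord(id=f"T{i}", name=f"t-{i}", synonyms=[f"t-{i}"],
                             smiles=smiles)
        out.append(PairedExample(molecule=rec,
                                 description=f"It is sample number {i}."))
    return out


class TestRetrieverContracts:
    def test_embedding_is_deterministic(self, small_world, small_bpe,
                                        small_pretrained):
        _, pairs, _, _ = small_world
        r = CrossModalRetriever(small_pretrained, bpe_vocab=small_bpe.vocab_)
        seq = r._smiles_sequence(pairs[0])
        assert np.array_equal(r.embed(seq, kind="smiles"),
                              r.embed(seq, kind="smiles"))

    def test_one_token_difference_changes_the_embedding(
            self, small_bpe, small_pretrained):
        r = CrossModalRetriever(small_pretrained, bpe_vocab=small_bpe.vocab_)
        a = r.embed_texts(["It is volatile in water ."])[0]
        b = r.embed_texts(["It is corrosive in water ."])[0]
        assert not np.allclose(a, b)

    def test_empty_sequence_rejected(self, small_bpe, small_pretrained):
        from kvreader.sequences import MixedTokenSequence
        r = CrossModalRetriever(small_pretrained, bpe_vocab=small_bpe.vocab_)
        with pytest.raises(ValueError):
            r.embed(MixedTokenSequence(tokens=[], segments=[]))

    def test_fewer_than_two_molecules_rejected(self, small_bpe,
                                               small_pretrained):
        pairs = _toy_pairs(1) * 3
        r = CrossModalRetriever(small_pretrained, bpe_vocab=small_bpe.vocab_)
        with pytest.raises(ValueError):
            r.fit(pairs)

    def test_short_finetuning_run_decreases_loss(self, small_world, small_bpe,
                                                 small_pretrained):
        import copy
        _, pairs, _, _ = small_world
        r = CrossModalRetriever(copy.deepcopy(small_pretrained), epochs=6,
                                batch_size=64, bpe_vocab=small_bpe.vocab_,
                                seed=0)
        r.fit(pairs)
        assert np.isfinite(r.loss_log_).all()
        assert r.epoch_losses_[-1] < r.epoch_losses_[0]


def test_split_ratios_partition_molecules():
    pairs = _toy_pairs(100)
    assign_splits(pairs, ratios=(7, 1, 2), seed=0)
    counts = {s: sum(p.split == s for p in pairs)
              for s in ("train", "valid", "test")}
    assert counts == {"train": 70, "valid": 10, "test": 20}
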