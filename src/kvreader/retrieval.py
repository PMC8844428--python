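"""Bidirectional SMILES <-> description retrieval.

One shared encoder embeds both a molecule's segmented SMILES string and
a property description; the match score is the cosine similarity of the
two pooled representations,

    s(m, d) = f(m) . f(d) / (|f(m)| |f(d)|).

Fine-tuning minimizes the Max-of-Hinges ranking loss with margin alpha:
for each positive pair only the hardest in-batch negative in each
direction is penalized,

    L = [alpha + max_{d'} s(m, d') - s(m, d)]_+
      + [alpha + max_{m'} s(m', d) - s(m, d)]_+ .

Evaluation uses two protocols: top-1 accuracy within randomly sampled
mini-batches of 64 pairs, and recall@20 against the full candidate set,
both in both directions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .nn import AdamW, Tensor, clip_grad_norm, l2_normalize
from .pairs import PairedExample
from .pretrain import MaskedLanguagePretrainer, _pad_batch
from .sequences import (SMI_CLOSE, SMI_OPEN, MixedTokenSequence,
                        TokenVocabulary, tokenize_mixed)


# ---------------------------------------------------------------------------
# scoring primitives

def cosine_score(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two representations; errors on zero norms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine score undefined for zero-norm vector")
    return float(a @ b / (na * nb))


def score_matrix(m_vecs: np.ndarray, d_vecs: np.ndarray) -> np.ndarray:
    """All-pairs cosine scores; entry (i, j) scores molecule i vs text j."""
    mn = m_vecs / np.linalg.norm(m_vecs, axis=1, keepdims=True)
    dn = d_vecs / np.linalg.norm(d_vecs, axis=1, keepdims=True)
    return mn @ dn.T


def mh_loss(scores: np.ndarray, alpha: float = 0.2,
            clamp_at_zero: bool = True) -> tuple[np.ndarray, float]:
    """Max-of-Hinges loss per positive pair, and the batch mean.

    ``scores[i, j]`` is s(m_i, d_j); the diagonal holds the positives.
    With the clamp active the loss is nonnegative and vanishes exactly
    when every positive beats its hardest in-batch negative by at least
    ``alpha`` in both directions.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if scores.shape != (n, n) or n < 2:
        raise ValueError("score matrix must be square with size >= 2")
    if alpha <= 0:
        raise ValueError("margin alpha must be positive")
    off = ~np.eye(n, dtype=bool)
    pos = np.diag(scores)
    hardest_d = np.where(off, scores, -np.inf).max(axis=1)   # max_j!=i s(m_i, d_j)
    hardest_m = np.where(off, scores, -np.inf).max(axis=0)   # max_j!=i s(m_j, d_i)
    term_d = alpha + hardest_d - pos
    term_m = alpha + hardest_m - pos
    if clamp_at_zero:
        term_d = np.maximum(term_d, 0.0)
        term_m = np.maximum(term_m, 0.0)
    per_pair = term_d + term_m
    return per_pair, float(per_pair.mean())


# ---------------------------------------------------------------------------
# the retriever

class CrossModalRetriever(BaseEstimator):
    """Fine-tune the shared encoder for molecule-description retrieval.

    Warm-started from a :class:`MaskedLanguagePretrainer` (its encoder
    and vocabulary are adopted); fine-tuning draws mini-batches without
    molecule duplication, scores all in-batch pairs by cosine and
    back-propagates the Max-of-Hinges loss.

    Parameters
    ----------
    pretrainer : fitted MaskedLanguagePretrainer
        Supplies the encoder and token vocabulary.
    alpha : float, default=0.2
        Ranking margin.
    clamp_at_zero : bool, default=True
        Apply the hinge clamp ``[.]_+`` to each direction's term.
    pair_level : {"sentence", "paragraph"}, default="paragraph"
        Whether training aligns a molecule with a single (randomly
        drawn) description sentence or the whole paragraph.  Paragraph
        alignment is the default: with hardest-negative mining, a
        sentence that truthfully describes a *different* molecule
        sharing the same sub-structure is usually the hardest negative,
        and sentence-level training then penalizes the very signal it
        should learn.
    pooling : {"mean", "first"}, default="mean"
        How token states become one vector: masked mean over content
        positions, or the first (CLS) position's output.  At desk scale
        the first-position output is nearly input-independent at
        initialization, which starves the cosine objective of gradient,
        so the mean is the default.
    bpe_vocab : SmilesBpeVocab or None
        Sub-structure vocabulary used to tokenize SMILES spans in dual
        mode; unused in shared mode.
    """

    def __init__(self, pretrainer: MaskedLanguagePretrainer,
                 alpha: float = 0.2, clamp_at_zero: bool = True,
                 epochs: int = 10, batch_size: int = 64, lr: float = 1e-3,
                 warmup: float = 0.2, weight_decay: float = 0.0,
                 pair_level: str = "paragraph", pooling: str = "mean",
                 bpe_vocab=None, seed: int = 0):
        self.pretrainer = pretrainer
        self.bpe_vocab = bpe_vocab
        self.pooling = pooling
        self.alpha = alpha
        self.clamp_at_zero = clamp_at_zero
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.warmup = warmup
        self.weight_decay = weight_decay
        self.pair_level = pair_level
        self.seed = seed

    # -- embedding -----------------------------------------------------
    @property
    def vocab_(self) -> TokenVocabulary:
        return self.pretrainer.vocab_

    def _smiles_sequence(self, pair: PairedExample) -> MixedTokenSequence:
        marked = f"{SMI_OPEN} {pair.molecule.smiles.simplified} {SMI_CLOSE}"
        return self._tokenize(marked)

    def _tokenize(self, text: str) -> MixedTokenSequence:
        return tokenize_mixed(text, mode=self.pretrainer.mode,
                              vocab=self.bpe_vocab)

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "loss_log_")

    def _encode_batch(self, seqs: list[MixedTokenSequence]) -> Tensor:
        vocab = self.vocab_
        for s in seqs:
            if len(s) == 0:
                raise ValueError("cannot embed an empty token sequence")
        ids = _pad_batch([vocab.encode(s) for s in seqs], vocab.pad_id)
        hidden = self.pretrainer.encoder_(ids, vocab.pad_id, final_norm=False)
        B, T, D = hidden.shape
        if self.pooling == "first":
            return hidden.reshape(B * T, D).take_rows(np.arange(B) * T)
        # masked mean over content positions (pad and CLS excluded)
        weights = (ids != vocab.pad_id).astype(float)
        weights[:, 0] = 0.0
        weights /= weights.sum(axis=1, keepdims=True)
        return (hidden * Tensor(weights[:, :, None])).sum(axis=1)

    def embed(self, seq: MixedTokenSequence, kind: str = "text") -> np.ndarray:
        """Pooled fixed-width representation of one token sequence.

        After fitting, the stored per-modality mean component is
        subtracted, so representations are batch-independent.
        """
        return self._encode_batch([seq]).data[0] - self._center(kind)

    def _center(self, kind: str) -> np.ndarray:
        return getattr(self, "center_", {}).get(kind, 0.0) \
            if hasattr(self, "center_") else 0.0

    def embed_texts(self, texts: list[str], kind: str = "text",
                    batch_size: int = 256) -> np.ndarray:
        seqs = [self._tokenize(t) for t in texts]
        out = []
        for start in range(0, len(seqs), batch_size):
            out.append(self._encode_batch(seqs[start:start + batch_size]).data)
        return np.concatenate(out, axis=0) - self._center(kind)

    def embed_pairs(self, pairs: list[PairedExample],
                    level: str = "paragraph",
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Embed the SMILES side and the description side of each pair."""
        smi_seqs = [self._smiles_sequence(p) for p in pairs]
        if level == "sentence":
            assert rng is not None
            texts = [p.sentences[rng.integers(len(p.sentences))] if p.sentences
                     else p.description for p in pairs]
        else:
            texts = [p.description for p in pairs]
        m, out = [], []
        for start in range(0, len(pairs), 256):
            m.append(self._encode_batch(smi_seqs[start:start + 256]).data
                     - self._center("smiles"))
            out.append(self.embed_texts(texts[start:start + 256],
                                        kind="text", batch_size=256))
        return np.concatenate(m), np.concatenate(out)

    # -- training ------------------------------------------------------
    def fit(self, X: list[PairedExample], y=None) -> "CrossModalRetriever":
        pairs = list(X)
        if len({p.molecule.id for p in pairs}) < 2:
            raise ValueError("need at least 2 distinct molecules to fine-tune")
        rng = np.random.default_rng(self.seed)
        params = self.pretrainer.encoder_.parameters()
        steps = max(1, len(pairs) // self.batch_size) * self.epochs
        opt = AdamW(params, lr=self.lr, weight_decay=self.weight_decay,
                    warmup=self.warmup, total_steps=steps)
        self.loss_log_ = []
        self.epoch_losses_ = []
        for _ in range(self.epochs):
            order = rng.permutation(len(pairs))
            epoch = []
            for start in range(0, len(order) - self.batch_size + 1,
                               self.batch_size):
                batch_idx = self._dedupe(pairs, order, start)
                batch = [pairs[i] for i in batch_idx]
                loss = self._step(batch, rng)
                opt.zero_grad()
                loss.backward()
                clip_grad_norm(params, 1.0)
                opt.step()
                self.loss_log_.append(float(loss.data))
                epoch.append(float(loss.data))
            self.epoch_losses_.append(float(np.mean(epoch)) if epoch else np.nan)
        self._fit_center(pairs)
        return self

    def _fit_center(self, pairs: list[PairedExample]) -> None:
        """Freeze the per-modality mean components used at inference."""
        self.center_ = {}
        sums = {"smiles": np.zeros(self.pretrainer.width),
                "text": np.zeros(self.pretrainer.width)}
        count = 0
        for start in range(0, len(pairs), 256):
            chunk = pairs[start:start + 256]
            m = self._encode_batch([self._smiles_sequence(p) for p in chunk])
            d = self._encode_batch([self._tokenize(p.description)
                                    for p in chunk])
            sums["smiles"] += m.data.sum(axis=0)
            sums["text"] += d.data.sum(axis=0)
            count += len(chunk)
        self.center_ = {k: v / count for k, v in sums.items()}

    def _dedupe(self, pairs, order, start) -> list[int]:
        """Take the next batch_size indices, skipping duplicate molecules."""
        seen: set[str] = set()
        batch: list[int] = []
        for i in order[start:]:
            mol = pairs[i].molecule.id
            if mol in seen:
                continue
            seen.add(mol)
            batch.append(int(i))
            if len(batch) == self.batch_size:
                break
        return batch

    def _step(self, batch: list[PairedExample],
              rng: np.random.Generator) -> Tensor:
        smi_seqs = [self._smiles_sequence(p) for p in batch]
        if self.pair_level == "sentence":
            texts = [p.sentences[rng.integers(len(p.sentences))]
                     if p.sentences else p.description for p in batch]
        else:
            texts = [p.description for p in batch]
        txt_seqs = [self._tokenize(t) for t in texts]
        m = self._encode_batch(smi_seqs)
        d = self._encode_batch(txt_seqs)
        # remove each modality's batch-mean component before cosine: an
        # input-independent additive pathway — including one that only
        # tells the two modalities apart — cancels here, so collapsing
        # to constant or antipodal outputs cannot silence the loss
        m = l2_normalize(m - m.mean(axis=0, keepdims=True))
        d = l2_normalize(d - d.mean(axis=0, keepdims=True))
        scores = m @ d.swapaxes(-1, -2)
        return self._mh_loss_tensor(scores)

    def _mh_loss_tensor(self, scores: Tensor) -> Tensor:
        """Differentiable Max-of-Hinges over an in-batch score matrix."""
        n = scores.shape[0]
        s = scores.data
        off = ~np.eye(n, dtype=bool)
        j_star = np.where(off, s, -np.inf).argmax(axis=1)
        i_star = np.where(off, s, -np.inf).argmax(axis=0)
        flat = scores.reshape(n * n)
        pos = flat.take_rows(np.arange(n) * n + np.arange(n))
        hard_d = flat.take_rows(np.arange(n) * n + j_star)
        hard_m = flat.take_rows(i_star * n + np.arange(n))
        term_d = hard_d - pos + self.alpha
        term_m = hard_m - pos + self.alpha
        if self.clamp_at_zero:
            term_d, term_m = term_d.relu(), term_m.relu()
        return (term_d + term_m).mean()


# ---------------------------------------------------------------------------
# evaluation protocols

def top1_from_scores(scores: np.ndarray) -> tuple[float, float]:
    """Top-1 accuracy per direction from one in-batch score matrix.

    Pair i is correct iff its diagonal entry is the *strict* maximum of
    row i (SMILES -> text) / column i (text -> SMILES); ties count as
    incorrect.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    pos = np.diag(scores)
    row_ok = ((scores > pos[:, None]).sum(axis=1) == 0) & \
             ((scores == pos[:, None]).sum(axis=1) == 1)
    col_ok = ((scores > pos[None, :]).sum(axis=0) == 0) & \
             ((scores == pos[None, :]).sum(axis=0) == 1)
    return row_ok.sum() / n, col_ok.sum() / n


def recall_from_scores(scores: np.ndarray, k: int) -> tuple[float, float]:
    """Recall@k per direction; ties broken by stable candidate index."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the candidate set ({n})")

    def _recall(mat: np.ndarray) -> float:
        order = np.argsort(-mat, axis=1, kind="stable")
        rank = np.empty_like(order)
        np.put_along_axis(rank, order,
                          np.broadcast_to(np.arange(n), (n, n)), axis=1)
        return float((np.diag(rank) < k).mean())

    return _recall(scores), _recall(scores.T)


def eval_batched_top1(pairs: list[PairedExample],
                      retriever: CrossModalRetriever,
                      batch_size: int = 64,
                      seed: int = 0) -> dict[str, float]:
    """Top-1 accuracy within randomly sampled mini-batches of pairs.

    A pair is correct iff its diagonal score is the strict maximum of
    its row (SMILES -> text) or column (text -> SMILES); the trailing
    partial batch is dropped.
    """
    rng = np.random.default_rng(seed)
    m_vecs, d_vecs = retriever.embed_pairs(pairs, level="paragraph")
    order = rng.permutation(len(pairs))
    s2t = t2s = total = 0
    for start in range(0, len(order) - batch_size + 1, batch_size):
        idx = order[start:start + batch_size]
        scores = score_matrix(m_vecs[idx], d_vecs[idx])
        r, c = top1_from_scores(scores)
        s2t += r * batch_size
        t2s += c * batch_size
        total += batch_size
    if total == 0:
        raise ValueError("need at least one full batch of pairs")
    return {"s2t_top1": s2t / total, "t2s_top1": t2s / total, "n": total}


def eval_recall_at_k(pairs: list[PairedExample],
                     retriever: CrossModalRetriever,
                     k: int = 20) -> dict[str, float]:
    """Recall@k against the full candidate set, both directions.

    Candidates are ranked by score with ties broken by stable candidate
    index; a pair is correct iff its true counterpart lands in the top k.
    """
    n = len(pairs)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the candidate set ({n})")
    m_vecs, d_vecs = retriever.embed_pairs(pairs, level="paragraph")
    s2t, t2s = recall_from_scores(score_matrix(m_vecs, d_vecs), k)
    return {"s2t_recall@k": s2t, "t2s_recall@k": t2s, "n": n, "k": k}


def train_retrieval(pairs: list[PairedExample],
                    pretrainer: MaskedLanguagePretrainer,
                    **kwargs) -> CrossModalRetriever:
    """Functional wrapper around :class:`CrossModalRetriever`."""
    return CrossModalRetriever(pretrainer, **kwargs).fit(pairs)
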