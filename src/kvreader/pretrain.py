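"""Masked-token pre-training over mixed SMILES/text sequences.

The encoder sees sentences in which molecule mentions are followed by
their delimited, segmented SMILES strings.  A fraction of tokens —
drawn from both the structure and the text side — is corrupted, and
the encoder is trained to reconstruct them from context.  Because a
sub-structure pattern and the words describing its properties co-occur
in the same sentences, reconstruction pressure aligns the two
vocabularies without any labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .masking import MaskingPolicy, mask_tokens
from .nn import (AdamW, Dense, EncoderConfig, Tensor, TransformerEncoder,
                 clip_grad_norm, cross_entropy, softmax)
from .sequences import MixedTokenSequence, Mode, TokenVocabulary


def _pad_batch(id_lists: list[np.ndarray], pad_id: int) -> np.ndarray:
    width = max(len(ids) for ids in id_lists)
    out = np.full((len(id_lists), width), pad_id, dtype=np.int64)
    for i, ids in enumerate(id_lists):
        out[i, :len(ids)] = ids
    return out


class MaskedLanguagePretrainer(BaseEstimator):
    """Self-supervised pre-training of the shared encoder.

    Parameters mirror the usual masked-modeling setup: 15% of
    non-special positions are selected, of which 80% are masked, 10%
    replaced by a random same-namespace token and 10% kept.  The
    optimizer is Adam with decoupled weight decay and a linear warmup
    over the first ``warmup`` proportion of steps.

    Attributes
    ----------
    vocab_ : TokenVocabulary
        Joint (or dual-namespace) integer vocabulary.
    encoder_ : TransformerEncoder
        The pre-trained encoder.
    loss_log_ : list of float
        Per-step training loss.
    """

    def __init__(self, mode: Mode = "dual", layers: int = 2, width: int = 64,
                 heads: int = 4, ff_width: int = 256,
                 select_prob: float = 0.15, mask_frac: float = 0.8,
                 random_frac: float = 0.1, keep_frac: float = 0.1,
                 epochs: int = 3, batch_size: int = 32, lr: float = 1e-3,
                 warmup: float = 0.2, weight_decay: float = 0.01,
                 seed: int = 0):
        self.mode = mode
        self.layers = layers
        self.width = width
        self.heads = heads
        self.ff_width = ff_width
        self.select_prob = select_prob
        self.mask_frac = mask_frac
        self.random_frac = random_frac
        self.keep_frac = keep_frac
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.warmup = warmup
        self.weight_decay = weight_decay
        self.seed = seed

    # ------------------------------------------------------------------
    def _mlm_step(self, batch: list[MixedTokenSequence],
                  policy: MaskingPolicy,
                  rng: np.random.Generator) -> tuple[Tensor, int]:
        vocab = self.vocab_
        corrupted_ids, target_pos, target_ids = [], [], []
        for b, seq in enumerate(batch):
            corrupted, targets = mask_tokens(seq, policy, vocab, rng=rng)
            ids = vocab.encode(corrupted)
            corrupted_ids.append(ids)
            for pos, tok in targets.items():
                # +1 for the prepended CLS position
                target_pos.append((b, pos + 1))
                target_ids.append(vocab.id_of(tok, seq.segments[pos]))
        ids = _pad_batch(corrupted_ids, vocab.pad_id)
        hidden = self.encoder_(ids, vocab.pad_id)
        if not target_pos:
            return Tensor(0.0), 0
        B, T, D = hidden.shape
        flat = hidden.reshape(B * T, D)
        rows = np.array([b * T + t for b, t in target_pos])
        picked = flat.take_rows(rows)
        logits = self.head_(picked)
        return cross_entropy(logits, np.asarray(target_ids)), len(rows)

    def fit(self, X: list[MixedTokenSequence], y=None) -> "MaskedLanguagePretrainer":
        seqs = list(X)
        if not seqs:
            raise ValueError("pre-training corpus is empty")
        rng = np.random.default_rng(self.seed)
        self.vocab_ = TokenVocabulary.from_sequences(seqs, self.mode)
        config = EncoderConfig(layers=self.layers, width=self.width,
                               heads=self.heads, ff_width=self.ff_width,
                               vocab_size=self.vocab_.size)
        self.encoder_ = TransformerEncoder(config, seed=self.seed)
        head_rng = np.random.default_rng(self.seed + 1)
        self.head_ = Dense(head_rng, self.width, self.vocab_.size)
        policy = MaskingPolicy(select_prob=self.select_prob,
                               mask_frac=self.mask_frac,
                               random_frac=self.random_frac,
                               keep_frac=self.keep_frac, seed=self.seed)
        params = self.encoder_.parameters() + self.head_.parameters()
        steps_per_epoch = max(1, len(seqs) // self.batch_size)
        opt = AdamW(params, lr=self.lr, weight_decay=self.weight_decay,
                    warmup=self.warmup,
                    total_steps=self.epochs * steps_per_epoch)
        self.loss_log_ = []
        self.epoch_losses_ = []
        order = np.arange(len(seqs))
        for _ in range(self.epochs):
            rng.shuffle(order)
            epoch = []
            for start in range(0, len(order) - self.batch_size + 1,
                               self.batch_size):
                batch = [seqs[i] for i in order[start:start + self.batch_size]]
                loss, n = self._mlm_step(batch, policy, rng)
                if n == 0:
                    continue
                opt.zero_grad()
                loss.backward()
                clip_grad_norm(params, 1.0)
                opt.step()
                self.loss_log_.append(float(loss.data))
                epoch.append(float(loss.data))
            self.epoch_losses_.append(float(np.mean(epoch)) if epoch else np.nan)
        return self

    # ------------------------------------------------------------------
    def predict_token_probs(self, seq: MixedTokenSequence,
                            position: int) -> np.ndarray:
        """Vocabulary distribution the model predicts at one position.

        The caller typically places a ``[MASK]`` token at ``position``
        first; the position index refers to the sequence *before* the
        CLS token is prepended.
        """
        vocab = self.vocab_
        ids = vocab.encode(seq)[None, :]
        hidden = self.encoder_(ids, vocab.pad_id)
        logits = self.head_(hidden.take_rows(np.array([0]))
                            .reshape(ids.shape[1], self.width)
                            .take_rows(np.array([position + 1])))
        return softmax(logits, axis=-1).data[0]


def save_checkpoint(est: MaskedLanguagePretrainer, directory) -> None:
    """Persist encoder weights, MLM head, vocabulary and hyperparameters."""
    import hashlib
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    est.encoder_.save(directory)
    np.savez(directory / "head.npz", W=est.head_.W.data, b=est.head_.b.data)
    vocab_payload = json.dumps({
        "mode": est.vocab_.mode,
        "text_tokens": est.vocab_.text_tokens,
        "smiles_tokens": est.vocab_.smiles_tokens,
    }, sort_keys=True)
    (directory / "vocab.json").write_text(vocab_payload, encoding="utf-8")
    (directory / "meta.json").write_text(json.dumps({
        "params": est.get_params(),
        "vocab_sha256": hashlib.sha256(vocab_payload.encode()).hexdigest(),
    }, sort_keys=True), encoding="utf-8")


def load_checkpoint(directory) -> MaskedLanguagePretrainer:
    """Reload a checkpoint; evaluation is bit-identical on fixed input."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    est = MaskedLanguagePretrainer(**meta["params"])
    v = json.loads((directory / "vocab.json").read_text(encoding="utf-8"))
    est.vocab_ = TokenVocabulary(mode=v["mode"], text_tokens=v["text_tokens"],
                                 smiles_tokens=v["smiles_tokens"])
    est.encoder_ = TransformerEncoder.load(directory)
    head_rng = np.random.default_rng(0)
    est.head_ = Dense(head_rng, est.width, est.vocab_.size)
    with np.load(directory / "head.npz") as head:
        est.head_.W.data = np.asarray(head["W"], dtype=np.float64)
        est.head_.b.data = np.asarray(head["b"], dtype=np.float64)
    est.loss_log_ = []
    return est


def pretrain(corpus: list[MixedTokenSequence], mode: Mode = "dual",
             epochs: int = 3, seed: int = 0,
             **kwargs) -> MaskedLanguagePretrainer:
    """Functional wrapper around :class:`MaskedLanguagePretrainer`."""
    est = MaskedLanguagePretrainer(mode=mode, epochs=epochs, seed=seed,
                                   **kwargs)
    return est.fit(corpus)
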