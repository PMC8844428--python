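"""End-to-end pipeline: simulate -> tokenize -> build-corpus ->
pretrain -> finetune-retrieval -> make-choices -> evaluate.

Every stage writes a manifest (parameters, derived seed, SHA-256 of its
inputs) into the artifact directory so a run can be replayed stage by
stage.  A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])``, so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bpe import SmilesBpeTokenizer
from .chemichoice import (answer_questions, build_choice_base,
                          generate_questions, write_questions)
from .linking import (build_mixed_corpus, build_synonym_index, write_corpus,
                      write_dictionary)
from .pairs import assign_splits, write_pairs
from .pretrain import MaskedLanguagePretrainer, save_checkpoint
from .retrieval import (CrossModalRetriever, eval_batched_top1,
                        eval_recall_at_k)
from .sequences import SMI_CLOSE, SMI_OPEN, tokenize_mixed
from .synthetic import default_grammar, gen_corpus, gen_pairs

_STAGES = ["simulate", "tokenize", "build-corpus", "pretrain",
           "finetune-retrieval", "make-choices", "evaluate"]


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's defaults."""

    workdir: str = "artifacts"
    mode: str = "dual"
    seed: int = 0
    # simulate
    n_pairs: int = 2000
    n_fragments: int = 20
    frags_per_mol: tuple[int, int] = (2, 4)
    noise_rate: float = 0.1
    n_docs: int = 500
    mentions_per_doc: int = 2
    split_ratios: tuple[int, int, int] = (7, 1, 2)
    # tokenize
    num_merges: int = 80
    min_frequency: int = 2
    # pretrain
    pretrain_epochs: int = 3
    pretrain_batch: int = 32
    # finetune
    alpha: float = 0.2
    finetune_epochs: int = 10
    batch_size: int = 64
    lr: float = 1e-3
    warmup: float = 0.2
    pair_level: str = "paragraph"
    shuffle_pairs: bool = False   # negative control: break the pairing
    # choices / evaluation
    min_count: int = 6
    gap: int = 10
    recall_k: int = 20
    stoplist: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.mode not in ("shared", "dual"):
            raise ValueError("mode must be 'shared' or 'dual'")
        if self.alpha <= 0:
            raise ValueError("margin alpha must be positive")
        if self.batch_size < 2:
            raise ValueError("retrieval batch size must be >= 2")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        if self.min_count < 1 or self.gap < 0:
            raise ValueError("invalid choice-base parameters")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, workdir: Path):
        self.workdir = workdir

    def write(self, stage: str, seed: int, params: dict,
              inputs: list[Path], outputs: list[Path]) -> None:
        payload = {
            "stage": stage,
            "seed": seed,
            "params": params,
            "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }
        (self.workdir / f"manifest-{stage}.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1), encoding="utf-8")


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute every stage and return the metrics dictionary.

    Artifacts (dictionary, pairs, corpus, vocabulary, checkpoint,
    questions, metrics and per-stage manifests) are written under
    ``config.workdir``.
    """
    config.validate()
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(work)
    t0 = time.time()

    def log(msg: str) -> None:
        if verbose:
            import sys
            print(f"[{time.time() - t0:7.1f}s] {msg}", file=sys.stderr)

    # -- simulate ------------------------------------------------------
    seed = stage_seed(config.seed, "simulate")
    grammar = default_grammar(n_fragments=config.n_fragments, seed=seed)
    pairs, records, gen_log = gen_pairs(
        grammar, config.n_pairs, frags_per_mol=config.frags_per_mol,
        noise_rate=config.noise_rate, seed=seed)
    docs, _plants = gen_corpus(records, grammar, n_docs=config.n_docs,
                               mentions_per_doc=config.mentions_per_doc,
                               log=gen_log, seed=seed + 1)
    assign_splits(pairs, ratios=config.split_ratios, seed=seed + 2)
    dict_path, pairs_path = work / "dictionary.jsonl", work / "pairs.jsonl"
    corpus_path = work / "corpus.jsonl"
    write_dictionary(records.values(), dict_path)
    write_pairs(pairs, pairs_path)
    write_corpus(docs, corpus_path)
    manifest.write("simulate", seed,
                   {"n_pairs": config.n_pairs,
                    "n_fragments": config.n_fragments,
                    "noise_rate": config.noise_rate},
                   [], [dict_path, pairs_path, corpus_path])
    log(f"simulated {len(pairs)} pairs, {len(docs)} documents")

    # -- tokenize ------------------------------------------------------
    seed = stage_seed(config.seed, "tokenize")
    bpe = SmilesBpeTokenizer(num_merges=config.num_merges,
                             min_frequency=config.min_frequency, seed=seed)
    bpe.fit([p.molecule.smiles for p in pairs])
    vocab_path = work / "smiles-vocab.txt"
    bpe.vocab_.save(vocab_path)
    manifest.write("tokenize", seed,
                   {"num_merges": config.num_merges,
                    "min_frequency": config.min_frequency},
                   [pairs_path], [vocab_path])
    log(f"learned {len(bpe.vocab_.merges)} merges, "
        f"{len(bpe.vocab_.patterns)} patterns")

    # -- build-corpus --------------------------------------------------
    seed = stage_seed(config.seed, "build-corpus")
    index = build_synonym_index(records.values(), stoplist=config.stoplist)
    mixed_docs = build_mixed_corpus(docs, records, index)
    mixed_path = work / "mixed-corpus.jsonl"
    write_corpus(mixed_docs, mixed_path)
    manifest.write("build-corpus", seed, {"stoplist": list(config.stoplist)},
                   [dict_path, corpus_path], [mixed_path])
    n_mentions = sum(len(d["mentions"]) for d in mixed_docs)
    log(f"linked {n_mentions} mentions in {len(mixed_docs)} documents")

    # -- pretrain ------------------------------------------------------
    seed = stage_seed(config.seed, "pretrain")
    sequences = [
        tokenize_mixed(sent, mode=config.mode, vocab=bpe.vocab_)
        for doc in mixed_docs for sent in doc["sentences"]
    ]
    # the paired corpus is unlabeled text too: include the training-split
    # pairs as mixed sentences so the vocabulary covers both sides
    train_pairs = [p for p in pairs if p.split == "train"]
    sequences.extend(
        tokenize_mixed(
            f"{SMI_OPEN} {p.molecule.smiles.simplified} {SMI_CLOSE} "
            f"{p.description}",
            mode=config.mode, vocab=bpe.vocab_)
        for p in train_pairs)
    pretrainer = MaskedLanguagePretrainer(
        mode=config.mode, epochs=config.pretrain_epochs,
        batch_size=config.pretrain_batch, lr=config.lr,
        warmup=config.warmup, seed=seed)
    pretrainer.fit(sequences)
    ckpt_dir = work / "checkpoint"
    save_checkpoint(pretrainer, ckpt_dir)
    manifest.write("pretrain", seed,
                   {"epochs": config.pretrain_epochs, "mode": config.mode,
                    "sequences": len(sequences)},
                   [mixed_path, vocab_path],
                   [ckpt_dir / "weights.npz", ckpt_dir / "vocab.json"])
    log(f"pre-trained on {len(sequences)} sequences; "
        f"epoch losses {['%.3f' % e for e in pretrainer.epoch_losses_]}")

    # -- finetune-retrieval --------------------------------------------
    seed = stage_seed(config.seed, "finetune-retrieval")
    if config.shuffle_pairs:
        rng = np.random.default_rng(seed + 77)
        descs = [p.description for p in train_pairs]
        for p, d in zip(train_pairs, rng.permutation(descs)):
            p.description = str(d)
    retriever = CrossModalRetriever(
        pretrainer, alpha=config.alpha, epochs=config.finetune_epochs,
        batch_size=config.batch_size, lr=config.lr, warmup=config.warmup,
        pair_level=config.pair_level, bpe_vocab=bpe.vocab_, seed=seed)
    retriever.fit(train_pairs)
    manifest.write("finetune-retrieval", seed,
                   {"alpha": config.alpha, "epochs": config.finetune_epochs,
                    "batch_size": config.batch_size,
                    "shuffle_pairs": config.shuffle_pairs},
                   [pairs_path], [])
    log(f"fine-tuned retrieval; epoch losses "
        f"{['%.3f' % e for e in retriever.epoch_losses_]}")

    # -- make-choices --------------------------------------------------
    seed = stage_seed(config.seed, "make-choices")
    test_pairs = [p for p in pairs if p.split == "test"]
    base = build_choice_base(pairs, min_count=config.min_count)
    questions = generate_questions(test_pairs, base, gap=config.gap,
                                   seed=seed)
    questions_path = work / "questions.jsonl"
    write_questions(questions, questions_path)
    manifest.write("make-choices", seed,
                   {"min_count": config.min_count, "gap": config.gap,
                    "base_size": len(base)},
                   [pairs_path], [questions_path])
    log(f"generated {len(questions)} questions from a base of {len(base)}")

    # -- evaluate ------------------------------------------------------
    seed = stage_seed(config.seed, "evaluate")
    top1 = eval_batched_top1(test_pairs, retriever,
                             batch_size=config.batch_size, seed=seed)
    recall = eval_recall_at_k(test_pairs, retriever, k=config.recall_k)
    _, choice_acc = answer_questions(questions, retriever)
    metrics = {
        "s2t_top1": top1["s2t_top1"],
        "t2s_top1": top1["t2s_top1"],
        "s2t_recall@k": recall["s2t_recall@k"],
        "t2s_recall@k": recall["t2s_recall@k"],
        "chemichoice_accuracy": choice_acc,
        "n_test": len(test_pairs),
        "n_questions": len(questions),
        "k": config.recall_k,
        "seed": config.seed,
    }
    metrics_path = work / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, sort_keys=True, indent=1),
                            encoding="utf-8")
    manifest.write("evaluate", seed,
                   {"batch_size": config.batch_size, "k": config.recall_k},
                   [questions_path], [metrics_path])
    log(f"metrics: {metrics}")
    return metrics
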