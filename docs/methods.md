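# Methods

## Overview

`kvreader` treats a molecule's SMILES serialization as a second
language and learns one encoder over both languages. The pipeline has
five stages: (1) simplify and BPE-segment SMILES strings; (2) link
molecule mentions in text by exact synonym matching and insert the
segmented SMILES after each mention; (3) pre-train a transformer
encoder with masked-token reconstruction over the mixed stream; (4)
fine-tune for bidirectional retrieval with a cosine / Max-of-Hinges
objective; (5) generate and answer four-way multiple-choice questions
about molecular properties. Everything runs at desk scale on synthetic
data whose generative structure matches the pipeline's core premise:
sub-structures indicate properties.

## SMILES simplification and sub-structure BPE

Simplification deletes `(`, `)`, `[`, `]`, all decimal digits and the
`%` two-digit ring-closure prefix; all other characters, including
stereo markers (`@`, `/`, `\`), are kept in order. This discards
branching/ring topology on purpose — the tokenizer then sees a linear
sequence of atom and bond symbols. Simplification is idempotent and
the output is a subsequence of the input.

BPE starts from single characters, with the two-letter element symbols
`Cl` and `Br` seeded as atomic units (splitting them would create
chemically meaningless symbols). Training iteratively fuses the most
frequent adjacent pair; frequency ties break lexicographically on the
(left, right) pair, so training is replay-deterministic and the `seed`
parameter exists only for interface uniformity. The retention filter
(`min_frequency`, applied to final corpus frequencies) prunes rare
patterns but keeps (a) the full merge list and (b) all base-alphabet
tokens, so encoding always backs off to shorter patterns and
round-trips exactly. Characters never seen in training become
singleton unknown-typed tokens rather than errors, since SMILES
dialects vary. Encoding applies merges exhaustively in learned order;
adding merges can only coarsen a segmentation, never lengthen it.

## Entity linking and mixed-corpus construction

Mentions are found by left-to-right, longest-match scanning of
word-boundary-aligned spans against a normalized (case-folded,
whitespace-collapsed) synonym index. Synonyms claimed by two molecules
are dropped as ambiguous; a stoplist removes substance names that
collide with common words, built by default from the corpus's most
frequent words plus a user list. Exact matching trades recall for
precision, which is the right trade for unsupervised corpus
construction: a missed mention costs one training sentence, a wrong
link plants a false cross-modal association.

At each mention the molecule's simplified SMILES, wrapped in the
reserved markers `[SMI] … [/SMI]`, is inserted *after* the mention by
default (the mention text is kept, preserving the name–structure
co-occurrence that masking exploits); `replace=True` substitutes it.
Deleting all marked spans restores the original sentence byte-for-byte.

Mixed sequences carry a per-token segment label (TEXT / SMILES /
SPECIAL). Text positions are capped at 128 per sequence and each
SMILES span at 64 tokens; truncation never removes a boundary marker.
In dual mode the SMILES patterns get an id range disjoint from the
word vocabulary; in shared mode one word-level tokenizer handles both.
The text tokenizer is pluggable (anything with `tokenize(str)`); the
default lower-cases and splits on non-alphanumerics, which is lossless
for a closed synthetic vocabulary but would need a subword tokenizer
for open text.

## Encoder and masked-token pre-training

The encoder is a pre-norm transformer: learned token + position
embeddings, then `layers` blocks of multi-head self-attention and a
GELU feedforward with residuals, with a final LayerNorm feeding the
masked-token prediction head. Desk-scale defaults: 2 layers, width 64,
4 heads, feedforward 256, max 264 positions (128 text + two delimited
64-token spans + specials). The architecture is size-agnostic; these
defaults exist so the whole study runs in minutes on one CPU. Token
embeddings initialize near unit norm and positions at 0.02 scale so
that token content, not shared positional structure, dominates early
representations.

Masking selects each non-special position independently with
probability 0.15 and applies the classic 80/10/10 mask/random/keep
split. Random replacements are drawn from the position's own
vocabulary namespace — a SMILES position is never corrupted with a
word, and vice versa, in dual mode. The optimizer is Adam with
decoupled weight decay (0.01), linear warmup over the first 20% of
steps and linear decay after, gradient-norm clipping at 1.0, and
learning rate 1e-3 (appropriate for this parameter count; the
full-scale counterpart of this recipe uses 5e-5 at 110M parameters).
All gradients come from a built-in reverse-mode autodiff engine whose
every operation is checked against central finite differences in the
test suite.

## Retrieval fine-tuning

The same encoder embeds both sides; the score is the cosine of pooled
representations and the loss is Max-of-Hinges with margin α = 0.2,
mean over the batch's positive pairs, mini-batches of 64 drawn without
molecule duplication. The hinge clamp `[·]₊` is applied by default
(the unclamped literal form is available via `clamp_at_zero=False` but
is unbounded below). Three pooling/scoring choices matter at this
scale and were selected after observing the failure modes they fix;
all are configurable:

- **Pooling** defaults to a masked mean over content positions taken
  from the pre-LayerNorm residual stream. First-position (CLS) pooling
  is available, but at this scale the first position's output is
  nearly input-independent at initialization; cosine differences then
  sit in a narrow band, the margin objective gets almost no gradient,
  and training settles into the loss plateau at 2α where all scores
  are equal. Pooling the raw residual stream keeps a direct gradient
  path into the token embeddings.
- **Per-modality centering.** Before cosine scoring, each side's
  batch-mean vector is subtracted during training, and a frozen
  training-corpus mean per modality is subtracted at inference. Any
  input-independent additive pathway in the encoder (output biases,
  shared tokens — including one that merely *tells the modalities
  apart*) cancels under this centering; without it the encoder can
  silence the loss by emitting constant or modality-antipodal outputs
  (in practice it does: all cross-modal cosines converge to −1). The
  center is a fixed statistic of the trained model, not a learned
  projection head.
- **Pair level** defaults to `paragraph`: training aligns a molecule
  with its whole description. Sentence-level alignment is supported
  but interacts badly with hardest-negative mining on compositional
  data — a sentence that truthfully describes a *shared* sub-structure
  of another in-batch molecule is usually the hardest negative, so the
  objective actively penalizes the signal it should learn; measured at
  the default study size this keeps held-out accuracy at chance,
  whereas paragraph alignment reaches ~0.86.

Fine-tuning uses no weight decay (decay pulls the representation
spread back toward the collapse plateau) and the same warmup/decay
schedule and learning rate as pre-training.

Evaluation embeds full paragraphs. Batched top-1 samples disjoint
64-pair batches (trailing partial batch dropped) and counts a pair
correct only when its diagonal score is the strict maximum of its row
(structure→text) or column (text→structure); ties are failures, which
keeps the metric reproducible. Recall@20 ranks all candidates with
ties broken by stable candidate index.

## CHEMIchoice question generation

The choice base is the set of description sentences occurring at least
`min_count = 6` times corpus-wide (i.e. more than five), minus
derivation-style sentences (pluggable predicate; the default matches
derived/derivative/obtained-from phrasing), sorted case-folded
lexicographically so near-paraphrases get adjacent indices. Each test
molecule yields one question: the positive is drawn uniformly from its
own description sentences; its *insertion index* is the lexicographic
position where it would enter the sorted base; the three negatives are
drawn without replacement from base entries whose index differs from
the insertion index by more than `gap = 10`, which suppresses
paraphrase false negatives. Choice order is shuffled under the stated
seed, making question files byte-reproducible. Answering embeds the
SMILES stem and the four sentences and takes the argmax cosine, ties
toward the lowest index.

## Synthetic data generator

The generator encodes the premise the method relies on. A grammar of
up to 24 chemically plausible fragments (chains, carbonyl-like and
aromatic motifs over C/N/O/S/c, bonds, halogens) assigns each fragment
property sentences of the form "It is *adjective* *context*." with an
adjective unique to the (fragment, slot) pair, so fragment presence
and sentence presence carry positive mutual information by
construction — shuffling the pairing destroys it, which is exactly
what the negative-control run measures. Descriptions use "it"
throughout, mirroring the convention of masking the substance's own
name in paired corpora.

Defaults for the study: 2,000 molecules of 2–4 fragments sampled
without replacement from a 20-fragment grammar; one sentence per
fragment in shuffled order; a distractor sentence appended with
probability 0.1 (emulating description sentences untied to structure);
7:1:2 train/valid/test split by molecule; a 500-document corpus with 2
planted mentions per document, each mention naming a molecule by a
random synonym inside a property sentence, with character-exact
positions recorded as ground truth for the linker tests.

What the generator does *not* emulate: real lexical diversity
(paraphrase, negation, hedging), chemically valid SMILES syntax
(strings are fragment concatenations; the pipeline treats SMILES as
strings throughout), long-document discourse, and noisy or partial
synonym dictionaries. Passing tests therefore demonstrate that the
machinery is correct and that the training signal is learnable when
present — not that the desk-scale model reads real chemistry text.

## Reproducibility and numerical choices

A single global seed fans out to per-stage seeds via
`numpy.random.SeedSequence([seed, stage_index])`; each stage writes a
manifest with its parameters, derived seed and SHA-256 of inputs and
outputs, so any stage replays in isolation. Training is deterministic
given the seed up to floating-point accumulation order (exact under a
fixed BLAS thread count). Checkpoints reload bit-identically.
Numerical details: float64 throughout; cosine normalization adds 1e-12
to norms (zero-norm vectors are errors at the public scoring API);
attention masks use −1e9 additive bias on padding; the degenerate
all-equal score matrix yields exactly 2α loss per pair, which is also
the plateau the collapse diagnostics watch for.

## Known limitations

- The desk-scale encoder cannot represent subtle compositional
  chemistry; it learns a soft bag-of-fragments to bag-of-sentences
  alignment, which is sufficient for the synthetic study's mapping.
- CHEMIchoice accuracy on synthetic data is ceiling-limited below 1.0:
  a sampled negative may truthfully describe another fragment of the
  stem molecule (the gap constraint orders sentences lexically, not
  semantically), so some questions have two defensible answers.
- Sentence-level contrastive training remains available but is
  ill-conditioned under hardest-negative mining at this scale (see
  above); use paragraph level unless batches are screened for shared
  fragments.
- The linker does no statistical NER, abbreviation resolution or
  coreference; recall on real text would be correspondingly low,
  which the upstream design accepts in exchange for precision.
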