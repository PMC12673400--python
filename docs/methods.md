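# Methods

This note records what the package computes, the assumptions behind each
stage, the default parameter values and why they were chosen, what the
synthetic corpora do and do not emulate, and the numerical conventions that
make runs reproducible. It makes no empirical claims beyond what the test
suite and `scripts/acceptance.py` compute at runtime.

## 1. Problem statement and model

The package implements a generative design funnel for short peptide binders.
A recurrent language model is trained on protein sequences, sampled to
produce a large pool of novel peptides, and the pool is reduced by
physicochemical screening and a sequence-novelty filter.

### 1.1 Sequence representation

Sequences use the 20 canonical amino acids in alphabetical one-letter order,
`ACDEFGHIKLMNPQRSTVWY`; a residue's integer index is its position in that
string (A = 0, …, Y = 19). There is no padding or wildcard token: training
examples are taken only from positions where a full context exists, so the
vocabulary stays exactly 20 symbols and the softmax never has to assign mass
to a non-residue. Sequences shorter than the window contribute no examples
and are skipped with a warning rather than padded.

### 1.2 Next-residue model

The model is an autoregressive next-residue predictor

> P(x_t | x_{t−34}, …, x_{t−1})

realised as a stacked bidirectional LSTM:

* input: one-hot encoding of a 34-residue context window;
* 2 bidirectional LSTM layers, 256 units per direction (default);
  dropout 0.2 is applied after each recurrent layer during training;
* the final hidden state is the concatenation of the forward direction's
  last state and the backward direction's first state;
* 2 fully connected ReLU layers of width 128, then a softmax over the
  20 residues;
* categorical cross-entropy loss, Adam optimiser at learning rate 1e-3.

Both directions read the same 34-residue *past* context, so the model remains
strictly autoregressive at generation time — the backward pass adds a second
view of the context, not access to the future.

The network is implemented directly in NumPy (forward pass, backpropagation
through time, and Adam), because the recurrent architecture is the core of
the method rather than an interchangeable commodity. Gradients were verified
against central finite differences during development.

### 1.3 Two-phase training

Training runs in two phases with separate epoch/batch settings:

1. **base**: full-length proteins, default 150 epochs, mini-batch 30;
2. **fine-tune**: peptides of at most 100 residues, default 45 epochs,
   mini-batch 62.

The fine-tuning corpus defines the target distribution (short binder-like
peptides); the base corpus teaches general sequence statistics. Fine-tuning
continues from the base weights and Adam state is retained.

Reported per-epoch accuracy/loss are running minibatch statistics with
dropout active; `score()`/`evaluate()` recompute them in inference mode
(dropout off), which is what quality checks use.

### 1.4 Generation

Peptides are generated greedily:

* a seed is a contiguous 34-residue window drawn uniformly over all
  (sequence, offset) pairs of the seed corpus (by default the fine-tuning
  records), so longer sequences contribute proportionally more windows;
* the target length is drawn uniformly from [80, 100] residues;
* decoding is greedy argmax; ties resolve to the lowest residue index;
* the seed window is not included in the emitted sequence (configurable);
* the default pool size is 1000 sequences.

All sequences in a pool are decoded in lock-step batches for speed; this is
mathematically identical to decoding them one at a time, which the test
suite verifies directly.

### 1.5 Two-stage funnel screen

The pool is split into 5 contiguous batches (when the pool size is not
divisible by the batch count, earlier batches get the remainder). Within
each batch:

* **Stage 1** ranks every peptide by three properties — Shannon entropy
  (descending: more diverse composition is better), GRAVY (ascending: more
  hydrophilic is better), instability index (ascending: more stable is
  better) — using 1-based ordinal ranks with ties broken by generation
  order, sums the three ranks into a composite, and keeps the 10 best
  composites per batch.
* **Stage 2** computes the Euclidean distance in raw (GRAVY, instability)
  units from each stage-1 survivor to the centroid of the fine-tuning
  reference peptides and keeps the 5 closest per batch.

With defaults this reduces 1000 → 50 → 25. Distances are taken in raw units
by default (an optional z-scored mode exists) because the two properties'
native scales are part of the published screening recipe; standardising
would change which peptides survive.

### 1.6 Sequence-property definitions

* **Shannon entropy**: base-2 entropy of the residue frequency distribution,
  in bits; range [0, log2 20 ≈ 4.32].
* **GRAVY**: mean Kyte–Doolittle hydropathy over all residues.
* **Instability index**: Guruprasad's I = (10/L) · Σ DIWV(x_i, x_{i+1}) over
  consecutive residue pairs; a protein is called stable iff I ≤ 40. Defined
  only for length ≥ 2.

The Kyte–Doolittle scale and the 20×20 DIWV dipeptide table are embedded in
the source verbatim as published constants. The test suite checks both
metrics against Biopython's ProtParam implementation as an independent
oracle (agreement to 1e-6 over random peptides).

### 1.7 Novelty shortlist

Each funnel survivor is globally aligned (Needleman–Wunsch with affine gaps)
against every fine-tuning reference using BLOSUM62, gap-open 10 and
gap-extension 0.5 (a gap of length k costs open + (k−1)·extend). Percent
identity is 100 × (identical aligned columns) / (alignment length including
gap columns). A candidate qualifies if its ranking statistic (default: its
*maximum* identity over all references) is strictly below the novelty
ceiling of 60 %; qualifying candidates are sorted by the statistic in
descending order (most reference-like novel sequences first) and the top 11
are kept, with ties broken by id.

When several alignments are co-optimal the aligner reports one of them;
percent identity can then differ slightly between equivalent inputs. The
test oracle therefore checks membership in the co-optimal identity set, and
the symmetry test allows 0.5 percentage points of slack.

## 2. Parameters, defaults, and rationale

| Parameter | Default | Rationale |
|---|---|---|
| context window | 34 (+1 target = 35) | long enough to span typical binding motifs several times over; training examples per sequence = L − 34 |
| recurrent layers × units | 2 × 256/direction | production scale for real corpora; capacity for long-range residue statistics |
| dense layers × units | 2 × 128 | a modest bottleneck between the 512-wide pooled recurrent state and the 20-way softmax |
| dropout | 0.2 | regularises the recurrent layers without starving the small fine-tuning corpus |
| learning rate | 1e-3 (Adam) | standard Adam default; stable for this architecture in our runs |
| base epochs / batch | 150 / 30 | enough passes for a handful of full-length proteins; small batches give more updates per epoch |
| fine-tune epochs / batch | 45 / 62 | shorter adaptation phase; larger batch smooths updates on the small peptide corpus |
| generation pool | 1000, lengths U[80, 100] | wide funnel mouth; length band matches the intended peptide product |
| funnel | 5 batches, keep 10 then 5 | 1000 → 50 → 25; batching decorrelates the survivor set from global ranking quirks |
| novelty | ceiling 60 %, keep 11 | excludes near-copies of the references while retaining family resemblance |

The **worked example** in the README, the tests, and the acceptance script
use deliberately scaled-down settings (24 recurrent units, 32 dense units,
25 base + 10 fine-tune epochs, or 60 epochs on the exact-oracle corpus).
These are this package's own desk-scale configuration: they exercise every
code path and reach the checked quality bars in seconds to minutes on a CPU.
The full-size defaults remain available unchanged for real corpora.

## 3. Synthetic corpora: what they emulate, and what they do not

`pepfunnel.synthetic` provides two programmatic corpora so the pipeline can
be exercised without any external data.

* **Motif corpus** (`motif_corpus`): random-residue "proteins"
  (default 7 base sequences of 230–1019 residues, 6 fine-tuning peptides of
  40–100 residues) with a short motif (default `KLVFF`, the amyloid-β core
  recognition element) planted by overwriting at a Binomial-distributed
  number of positions (default rate 2 plantings per 100 residues). This
  emulates the *shape* of a real training setup — a small base corpus of
  long sequences, a handful of short reference binders, and a learnable
  local signal. It does **not** emulate real protein statistics: residue
  usage outside the motif is uniform, there is no secondary structure,
  domain grammar, or realistic composition bias, and nothing about actual
  binding is represented.
* **Successor corpus** (`deterministic_successor_corpus`): each sequence
  follows a fixed random permutation of the alphabet (every residue's
  successor is determined). The next residue is therefore an exact function
  of the previous one, which gives training an exact oracle: a correct
  implementation can reach perfect next-residue accuracy, and the planted
  permutation can be read back from the trained model's argmax.

Conclusions about real peptide design cannot be drawn from these corpora;
they validate the machinery, not the biology.

## 4. Numerical and reproducibility choices

* **Determinism.** All randomness flows from `numpy.random.SeedSequence`
  spawned into separate initialisation, training and generation streams.
  Seeds derived from a user seed are reduced modulo 2^31. The same seed
  yields byte-identical artifacts (FASTA, TSV, JSON), which is tested.
* **Tie-breaking** is total and explicit everywhere: stage-1 ranks and
  stage-2 distances break ties by generation index; greedy decoding breaks
  probability ties toward the lowest residue index; the shortlist breaks
  statistic ties by candidate id. No ordering depends on hash order or
  sort instability (sorts use stable mergesort keys).
* **Softmax and sigmoid** use the standard max-subtraction / branch-free
  stable forms; Adam uses bias correction with ε = 1e-7.
* **Checkpoints** are NumPy `.npz` archives holding weights, Adam state and
  a JSON metadata block (format version, configuration, training history).
  Loading verifies the format version and raises `IOError` on truncation.
* **Entropy** uses log base 2 (bits); `evaluate()` reports cross-entropy in
  nats (so the uniform-model baseline is ln 20 ≈ 2.996).
* **Percent identity denominator** is the full alignment length including
  gap columns, making identity monotone-decreasing in indels.

## 5. Known limitations

* Training is plain batched BPTT on CPU in NumPy; it is intended for small
  and mid-size corpora, not for large-scale pretraining.
* Greedy decoding yields the mode of the model's conditional at every step;
  pool diversity comes entirely from seed-window and length randomisation.
  A stochastic (temperature) sampler is a natural extension and is not
  implemented.
* The screen uses three bulk physicochemical properties; it does not model
  structure, aggregation propensity, protease stability or toxicity.
* The instability index's stable/unstable call (threshold 40) is a published
  heuristic for proteins and is applied here to short peptides, where it is
  at best indicative.
* When alignments are co-optimal the reported identity is one valid value
  among possibly several (see §1.7).
* The early-stopping option monitors training loss, not held-out loss;
  there is no built-in validation split.
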