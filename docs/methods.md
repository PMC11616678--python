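# Methods

## The problem

Protein structures can be written as strings: each residue is assigned one of
twenty structure tokens (the "3Di" alphabet of structural states) describing
its local tertiary geometry, so a 3D structure becomes a 1D sequence over a
20-letter alphabet. Once both modalities are strings, translation between
them is a sequence-to-sequence problem: amino acids → structure tokens
("folding" into the token representation) and structure tokens → amino acids
(inverse folding). `pro3di` implements this translation loop at desk scale —
tokenization, data curation, two-phase training, a full sampling stack,
roundtrip-filtered generation, and the evaluation machinery for
remote-homology search and embedding-based annotation transfer — against a
seeded synthetic bilingual proteome, so the entire method is exercised on one
CPU in minutes with no external data.

## Dual-alphabet tokenization

Amino acids are the 20 upper-case letters (ambiguous codes B/Z/U/O/J are read
as X); structure tokens are the same letters lower-cased, which keeps the two
alphabets disjoint inside one shared vocabulary. Two special prefix tokens,
`<AA2fold>` and `<fold2AA>`, are prepended to the encoder input to select the
translation direction. A block of sentinel tokens (128 by default, 16 in the
toy models used here) supports span corruption. Tokenization is strictly
character-level: one token per residue, no subwords. The vocabulary
serializes to JSON next to each checkpoint.

## The synthetic bilingual world

The generator produces paired (AA, structure-token) records with the
statistical properties the method relies on:

* **Local determinism.** The structure token at position *i* is a fixed
  function g of the amino-acid window `aa[i-w .. i+w]` (window 3 by default).
  g reads the *physicochemical class* pattern of the window — hydrophobic,
  aromatic, polar, positive, negative, small/special, plus a boundary class —
  giving 7³ = 343 window keys. Keys are ordered by a fixed 64-bit avalanche
  hash (seed-independent) and partitioned into contiguous blocks sized by a
  geometric token prior (mass ∝ skew^i, skew 0.78), each token receiving at
  least one key. The map is therefore surjective onto all 20 tokens,
  pseudo-random with respect to content, exactly recomputable from any
  sequence, and — because it reads residue classes rather than identities —
  representable by a small network. Class patterns rather than identities
  also reflect how local backbone geometry depends on residue character.
* **Run smoothing.** Raw tokens pass a majority vote over each 3-window
  (ties keep the centre), creating secondary-structure-like runs.
* **Class imbalance.** Under the skewed prior plus smoothing, the three most
  common tokens cover slightly more than half of all residues, matching the
  strong imbalance of real structure-token data; this is asserted
  empirically in the tests.
* **Noise dial.** Each position is independently resampled uniformly with
  probability `noise_rate`. 0 gives a deterministic map (Bayes token accuracy
  1.0); 1 destroys all sequence dependence (the negative control).
* **Hierarchy and clusters.** Sequences descend from prototypes mutated
  top-down: fold → superfamily → family → cluster → protein with per-level
  substitution rates (0.35, 0.25, 0.15, 0.08). Four folds × 3 superfamilies ×
  3 families and 108 clusters by default. This makes within-family identity
  highest and cross-fold identity near chance, so homology search and
  annotation transfer have graded signal across all three levels.
* **Quality scores.** Per-protein pLDDT-like scores are drawn from a two-band
  Beta(2,2) mixture over [40,70) and [70,100], with 12% of proteins expected
  below the quality-filter threshold of 70.

What the generator does **not** emulate: physically realistic structures or
energetics, realistic length distributions (lengths are uniform on 30–60),
sequence-composition biases of real proteomes, domain architecture, and the
vector-quantized geometry encoder that produces real 3Di strings. Passing
tests therefore demonstrate that the machinery is correct and that the
method behaves as designed when its assumptions hold — not that the toy model
would reach any particular accuracy on real proteins.

## Curation and splits

Three filters, applied in order with strict thresholds (equality survives):
remove proteins with quality score < 70, length < 30, or more than 95% of
residues assigned to a single structure token. A record failing several rules
is counted under the first failing rule. Splitting moves whole clusters into
validation/test until the requested sizes accumulate (seeded cluster order),
so no cluster ever straddles splits; each val/test cluster designates its
highest-scoring member as representative for redundancy-free views. Cluster
capping selects at most k members by greedy max-min diversity (start at the
representative, repeatedly add the member with the largest minimum distance
to the selected set); the distance is pluggable and defaults to one minus
positional identity.

## Model and training

The translation model is a pre-norm transformer encoder-decoder with a shared
token embedding tied to the output projection, learned relative-position
attention biases, and a conventional pad-token decoder start. Toy dimensions:
1 encoder + 1 decoder layer, width 64, 4 heads, feed-forward 128 — small
enough to train on one CPU in a few minutes while keeping the architecture
class (bidirectional encoder, causal decoder with cross-attention).

The relative-position bias tables are initialized with per-head local peaks
(encoder heads around offsets ±1–2; decoder self-attention on the recent
past; cross-attention at +1, compensating the direction prefix that shifts
the encoder by one position). This is an inductive-bias choice: translation
here is a nearly monotone residue-to-residue mapping, and starting attention
near the diagonal shortens optimization dramatically without constraining
what the heads can learn.

Training has two phases, mirroring the full-scale recipe in shape:

1. **Span denoising on both modalities**, alternating AA and structure-token
   batches per step, so the model learns the new lower-case tokens without
   forgetting the other alphabet. Corruption rate 0.15, geometric span
   lengths with mean 3; the i-th masked span is replaced by sentinel i and
   the target lists each sentinel followed by its hidden tokens — the
   corruption is exactly invertible. Both modalities' validation denoising
   losses are reported at the end of the phase.
2. **Bidirectional translation**, alternating direction per batch, under a
   growing max-length schedule (800 steps at 48, then 500 at 64 residues).

Toy learning rates are 1e-3 for both phases with Adam, linear warmup and
global-norm clipping at 1.0. The published full-scale values (1e-3 denoising,
1e-5 translation, lengths 256→512 over 100K+600K steps, batch 16 with
gradient accumulation) are recorded in `full_scale_train_config()`; the toy
schedule scales them to minutes while preserving the two-phase structure.
All randomness flows from a single config seed.

The package's neural-network core is a compact reverse-mode autodiff engine
over numpy float32 arrays (broadcast arithmetic, batched matmul, embedding
gather, fused softmax/layer-norm/cross-entropy). Its gradients are verified
against central finite differences in float64 in the test suite.

## Decoding

Next-token distributions pass a fixed processing order: repetition penalty
(positive logits of already-generated tokens divided by the penalty, negative
multiplied), temperature, top-k truncation, nucleus truncation keeping the
minimal prefix whose cumulative probability reaches top-p (boundary token
included), an optional target-alphabet mask, then softmax. The order follows
the convention of the generation framework the published configurations come
from; reordering changes the sampled distribution. When the alphabet
constraint is active, `translate` additionally masks disallowed tokens
*before* processing so the top-k/top-p budgets are spent inside the target
alphabet — otherwise a barely-trained model can drive every candidate out of
the truncated set.

Two published sampling configurations ship as defaults: sequence → structure
tokens (`do_sample`, 3 beams, top-p 0.95, temperature 1.2, top-k 6,
repetition penalty 1.2) and structure tokens → sequence (top-p 0.85,
temperature 1.0, top-k 3, repetition penalty 1.2). The latter does not
specify a beam count; 1 (the framework default) is used. Beams with sampling
are interpreted as *stochastic beam search*: each beam extends by sampling
from its processed distribution, beams are ranked by length-normalized
log-probability (normalization exponent 1), ties break to the lower beam
index, finished beams are frozen, and the best finished beam is returned.
Generated amino-acid sequences never contain X: it is a reading convention
for ambiguous input, not a residue to design.

## Fast structure-token prediction

The fast inference path drops the decoder: a two-layer 1-D CNN
(kernel 7, 32 hidden channels, ReLU, dropout 0.1) classifies each residue
into one of the 20 structure tokens directly from the frozen encoder's
last-layer embeddings. The exact CNN hyperparameters of the full-scale
reference are inherited by citation only, so these values are declared
defaults, config-exposed. A confidence threshold on the per-residue max
probability trades coverage (low threshold) against precision (high
threshold); below-threshold residues are emitted as the placeholder `x` so
output stays length-aligned, with per-residue confidences available as a
sidecar table.

## Alignment and roundtrip filtering

The global aligner is a Gotoh-style Needleman-Wunsch with affine gaps
(open charged for the first gap residue, default −10; extend for each
further one, default −1) over an arbitrary symmetric substitution matrix.
Traceback is fully deterministic: ties prefer diagonal, then up, then left,
both within and across the three DP states. PIDE is percentage identity over
alignment columns including gap columns (the conservative denominator;
switchable to the shorter sequence length for sensitivity analyses);
similarity is the percentage of aligned pairs with positive substitution
score — both are reported since either reading of "sequence similarity" is
defensible. The packaged default structure-token matrix (+6 match / −2
mismatch) is a synthetic stand-in; any Foldseek-format matrix file loads via
`read_substitution_matrix`.

Roundtrip accuracy scores a generated amino-acid sequence by translating it
back to structure tokens and aligning against the native token string:
`pide(native, AA→3Di(3Di→AA(native)))`. Roundtrip-filtered generation samples
candidates until one reaches 70% roundtrip identity or ten attempts are
exhausted, keeping the candidate with the maximal roundtrip accuracy (or
reporting the best effort with no acceptance). Per-attempt seeds derive
deterministically from the config seeds.

KL naturalness is the Kullback–Leibler divergence (nats) between the pooled
amino-acid composition of generated sequences and a strictly positive
reference composition; the synthetic study uses the training set's
composition as reference.

## Evaluation machinery

**Sensitivity to the first false positive.** For each query's ranked hits:
a hit sharing the query's hierarchy label at the evaluated level is a true
positive; a hit from a different fold (the coarsest level) is a false
positive and terminates the walk; same-fold hits differing at the evaluated
level are neutral. The query's sensitivity is TPs found before the first FP
divided by all possible TPs at that level; queries with zero possible TPs are
excluded from that level's mean and reported. The aggregate is the mean over
queries, which equals the area under the descending sorted per-query
sensitivity curve (the statistic printed as "ROC-AUC" in structure-search
benchmarks is realized here as this mean; the exact upstream computation is
inherited by citation and not restated, so the statistic is declared, not
asserted identical).

**Embedding-based annotation transfer (EAT).** Proteins are embedded by
average-pooling the encoder's last-layer residue embeddings into one
fixed-length vector. Each query receives the full hierarchy label of its
Euclidean nearest neighbour in the lookup set (ties break to the earlier
entry). Per-level accuracy is hierarchical: a level counts as correct only if
all coarser levels are also correct, so the accuracy vector is non-increasing
from coarse to fine by construction. The analytic baseline is the hierarchical
accuracy of always predicting the modal lookup label.

## Numerical and engineering choices

* float32 throughout training; float64 only in gradient-check tests.
* Attention masking uses additive −1e9; the decoder start position is
  explicitly kept attendable (it shares the pad id).
* The backward pass releases the autodiff graph eagerly (closures form
  reference cycles that would otherwise hold every intermediate array).
* The aligner's DP fill is a numba kernel; all tie-breaks are explicit.
* Nucleus truncation uses a 1e-9 tolerance so exact-boundary cumulative
  sums are not pushed out by floating-point rounding.
* Hit lists reject self-hits and duplicate targets at construction; score
  ties in hit ranking break by target order for determinism.

## Problem sizes of the packaged study

The end-to-end study (the acceptance script and the heavyweight tests) uses
6,500 generated proteins (→ ~5,700 after filtering; ≥5,000 train), whole-
cluster validation/test splits of ≥250 records each, a 1,300-step phase-2
schedule, a CNN head trained on 3,000 proteins, 40 roundtrip queries with a
10-attempt budget, a 160-protein all-against-all homology benchmark on
CNN-predicted tokens, and 80 EAT queries against a 300-protein lookup. These
sizes were chosen so the full pipeline runs in roughly ten minutes on one
CPU core.

## Known limitations

* The decoder recomputes the full prefix each generation step (no
  incremental state); fine at toy lengths, quadratic in general.
* The synthetic world's structure tokens are a function of local sequence
  alone; real structure tokens depend on long-range tertiary contacts, which
  is precisely why the real problem needs a large model. Inverse-folding
  "success" here means roundtrip consistency, not designability.
* Structural similarity metrics of generated sequences (lDDT/TM-score/RMSD)
  require 3D structure predictors and are out of scope; sequence-level
  metrics (PIDE, KL naturalness, roundtrip accuracy) are implemented.
* Beam search with sampling is one interpretation of the published hybrid
  configuration; the underlying framework's semantics are not restated in
  print.
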