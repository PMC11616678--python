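# pro3di

Bilingual protein sequence / structure-token modelling at desk scale.

Protein structures can be written as strings: the 3Di structural alphabet
assigns each residue one of twenty tokens describing its local tertiary
geometry, so a 3D structure becomes a 1D lower-case string aligned with the
upper-case amino-acid sequence. `pro3di` implements the complete translation
loop between those two languages for people who want to study, teach or
extend the method without GPUs or external databases:

* a dual-alphabet character tokenizer (amino acids upper-case, structure
  tokens lower-case, direction prefixes `<AA2fold>` / `<fold2AA>`, denoising
  sentinels);
* a seeded synthetic bilingual proteome in which each structure token is a
  local windowed function of the sequence, with realistic token imbalance,
  pLDDT-like quality scores, clusters and a fold/superfamily/family hierarchy;
* the dataset curation filters (pLDDT < 70, length < 30, >95% single-token
  strings) and whole-cluster train/val/test splitting;
* two-phase training of a small transformer encoder-decoder — span denoising
  on both alphabets, then bidirectional translation — on a compact numpy
  autodiff engine;
* the full sampling stack (temperature, top-k, nucleus, repetition penalty,
  stochastic beams) with both published generation configurations;
* a two-layer CNN fast path predicting structure tokens per residue from
  encoder embeddings, with confidence thresholding;
* affine-gap Needleman-Wunsch over custom substitution matrices, PIDE /
  similarity / KL-naturalness metrics, and roundtrip-filtered inverse folding
  (keep a generated sequence only if its back-translation matches the native
  token string at ≥70% identity within ten attempts);
* the remote-homology benchmark statistic (per-query sensitivity up to the
  first false positive at three hierarchy levels) and embedding-based
  annotation transfer (EAT) with hierarchical accuracy.

## The core model

The translator is a T5-class encoder-decoder over a shared character
vocabulary: a bidirectional self-attention encoder reads
`<AA2fold> M K L … </s>` (or `<fold2AA> v v d … </s>`), and a causal decoder
with cross-attention emits the other alphabet token by token. Given a native
structure-token string *s*, inverse folding samples amino-acid candidates
*a ~ p(a | s)* and scores each by **roundtrip accuracy**
`PIDE(s, AA→3Di(a))` under global alignment with a structure-token
substitution matrix — the model auditing its own generations.

## Worked example

```python
import numpy as np
from pro3di import (
    WorldConfig, generate_world, CurationConfig, apply_filters, cluster_split,
    TrainConfig, train, fold2aa_config, aa2fold_config,
    generate_with_roundtrip, default_tdi_matrix,
)
from pro3di.seq2seq import evaluate_translation

records = generate_world(WorldConfig(n_proteins=6500, noise_rate=0.0, seed=1))
curation = CurationConfig(val_size=250, test_size=250, seed=1)
kept, report = apply_filters(records, curation)
kept = cluster_split(kept, curation)

result = train(kept, TrainConfig(seed=1))          # ~4 min on one CPU core
val = [r for r in kept if r.split == "val"]
loss, acc = evaluate_translation(result.model, val, result.vocab, "AA2fold")
print(f"val AA->3Di token accuracy: {acc:.3f}")

rec = next(r for r in kept if r.split == "test")
rt = generate_with_roundtrip(
    rec.tdi_seq, result.model,
    fold2aa_config(seed=7, max_new_tokens=rec.length + 10),
    aa2fold_config(seed=8, max_new_tokens=rec.length + 10),
    default_tdi_matrix(), result.vocab, threshold=70.0, budget=10,
)
print(f"roundtrip identity {rt.best[1]:.1f}% after {rt.n_attempts} attempt(s)")
```

On this run the validation token accuracy prints as `0.965` — the model has
essentially learned the sequence-to-structure-token map of the synthetic
world — and the roundtrip line prints an identity above the 70% acceptance
threshold (e.g. `89.5% after 1 attempt(s)`), meaning the first sampled
amino-acid sequence already re-folds (in token space) to the requested
structure. With `noise_rate=1.0` the same pipeline collapses to chance
(~0.05), confirming the model learns the mapping rather than artifacts.

A command-line interface mirrors the library:

```bash
pro3di generate-data --n-proteins 6500 --seed 1 --out-dir world/
pro3di curate --aa world/aa.fasta --tdi world/tdi.fasta \
       --metadata world/metadata.tsv --val-size 250 --test-size 250 \
       --seed 1 --out-dir curated/
pro3di train --data-dir curated/ --out-dir ckpt/
pro3di train-head --data-dir curated/ --model ckpt/ --out-dir head/
pro3di translate -i query.fasta -o query_3di.fasta --model ckpt/ --direction AA2fold
pro3di predict-3di -i query.fasta -o fast_3di.fasta --model ckpt/ --head head/ --half 0
```

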