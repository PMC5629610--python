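# mednorm

Biomedical entity normalization: map disease/disorder mentions in text to
concepts of a knowledge base, or to "CUI-less" (NIL) when no concept
applies.

The system has two stages:

1. **Tiered candidate generation** — handcrafted rules at three priority
   tiers: exact match (CI); exact match after one morphological rewriting
   (CII: abbreviation expansion, word-order swap, numeral rewriting,
   hyphenation, suffix alternation, word-level synonyms, stemming,
   coordinated-phrase splitting); partial word-overlap match (CIII). The
   highest non-empty tier forms the candidate set; with NIL handling
   enabled, a NIL candidate joins CIII sets so "no concept" competes in
   ranking like any other label. Singleton sets are selected directly with
   score 1.0.
2. **CNN pair ranking** — mention and candidate are encoded by a
   convolutional layer (ReLU, filter widths 2 and 3) with 1-max pooling;
   the encodings, a learned bilinear similarity `v_m^T M v_y`, and two
   morphological features (shared-word proportion and an
   inverse-mention-frequency-weighted cosine) feed a fully connected ReLU
   layer and a two-class softmax. The positive-class probability ranks the
   candidates. Training is pairwise: every (mention, candidate) pair is a
   binary example optimized with seeded SGD on cross-entropy.

The network is implemented in numpy with analytic gradients (verified
against finite differences in the test suite); no GPU or tensor framework
is required.

## Data formats

- **KB**: UTF-8 TSV, `concept_id<TAB>preferred_name<TAB>syn|syn|...`
- **Corpus**: PubTator (`pmid|t|`, `pmid|a|`, tab-separated annotation
  lines with 0-based half-open offsets into `title + " " + abstract`;
  gold id `-1`/`CUI-less` means NIL), or a plain TSV mention list
  `doc_id  start  end  text  gold_id`.
- **Embeddings**: text, one `word v1 ... vt` per line.

## CLI

```sh
# deterministic synthetic dataset (kb.tsv, corpus.pubtator, embeddings.txt, spec.json)
mednorm fixtures make --spec spec.json --out-dir data/

# train ranking parameters (config is flat "key = value"; see TrainConfig)
mednorm train --kb data/kb.tsv --corpus data/corpus.pubtator \
    --embeddings data/embeddings.txt --config train.cfg --out model.npz

# normalize a corpus -> TSV [doc_id, start, end, mention, predicted_id, score, tier]
mednorm normalize --kb data/kb.tsv --corpus data/corpus.pubtator \
    --ckpt model.npz --train-corpus data/corpus.pubtator --out pred.tsv

# accuracy against a gold mention TSV
mednorm evaluate --pred pred.tsv --gold gold.tsv

# 10-fold cross-validated grid search (grid.json: {"t": [50,100], ...})
mednorm cv --kb data/kb.tsv --corpus data/corpus.pubtator --grid grid.json
```

Default network settings: embedding size t=50, filter widths {2, 3} with
50 filters each, hidden width 100, 10 cross-validation folds, symmetric
uniform [-0.25, 0.25] embedding initialization (overridable per word by a
pre-trained embedding file, then fine-tuned).

## Library

```python
from mednorm import (load_kb, load_pubtator_corpus, build_training_lexicon,
                     generate_candidates, build_pairs, train,
                     normalize_corpus, evaluate, GenConfig, TrainConfig)
```

`evaluate` returns accuracy, candidate recall (the fraction of mentions
whose gold concept appears in the candidate set — the ceiling on ranking
accuracy), the ambiguity rate, a per-tier breakdown and an error list.

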