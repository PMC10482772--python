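# contextsim

Contextual semantic similarity measures for reading-time research.

When people read naturalistic text, words that are semantically close to
their recent context are fixated for less time.  Quantifying that closeness
requires a per-token score: how similar is *this* word, here, to the words
that just preceded it?  `contextsim` computes six such scores from a plain
word-embedding table and exports tidy per-token tables ready for
mixed-model analysis of eye-tracking data (e.g. GAMMs with participant
random effects, fitted in external software such as `mgcv`).  It is aimed
at psycholinguists and cognitive modellers working with token-level
reading-time corpora.

## The measures

Let $w^t$ be the target word's embedding and $w^{t-1}, w^{t-2}, \dots$ the
embeddings of its preceding words.  Three families, each in two variants:

| measure | context window | value |
|---|---|---|
| `dynamic_full` | 3 preceding words, any class | sum of all $\binom{k+1}{2}$ pairwise Pearson correlations among $\{w^{t-3},w^{t-2},w^{t-1},w^t\}$ (the strictly-lower triangle of the window's correlation matrix) |
| `dynamic_simpler` | 3 preceding words, any class | sum of the target's correlations with each context word only: $\sum_{i=1}^{3} r(w^t, w^{t-i})$ |
| `cosine_content` | up to 3 preceding **content** words, same sentence | $\cos(A, w^t)$ with $A=\sum_i w^{t-i}$ |
| `cosine_all` | 3 preceding words, any class | same cosine, function words included |
| `euclidean_sentence` | all preceding words in the sentence | $1/\lVert w^t - \bar{B}\rVert_2$ with $\bar{B}$ the mean context vector |
| `euclidean_fixed` | 3 preceding words, any class | same reciprocal distance, fixed window |

Pearson correlations are taken *across embedding dimensions* between two
word vectors.  The dynamic measures are interpretable cell by cell: each
summed entry is the correlation between one pair of words in the window.

Windows that cannot be formed (sentence-initial targets, too few
in-vocabulary predecessors for a fixed-k window) and degenerate vectors
yield MISSING — exported as empty CSV fields, never zeros.

## Worked example

The sentence "We invade the smart watch space." with the bundled
fixture embeddings, whose sample correlations among "the", "smart",
"watch", "space" are exactly 0.17/0.18/0.65/0.42/0.31/0.25:

```python
from contextsim import MeasureId, compute_measure, fig3_embeddings, tokenize

table = fig3_embeddings()
passage = tokenize("We invade the smart watch space.")
for measure in MeasureId:
    sv = compute_measure(passage, 5, measure, k=3, table=table)
    print(f"{measure.value:<18} {sv.value:+.3f}")
```

prints

```
cosine_content     -0.073
cosine_all         +0.438
euclidean_sentence +0.186
euclidean_fixed    +1.053
dynamic_full       +1.980
dynamic_simpler    +0.980
```

`dynamic_full` is the sum of all six pairwise correlations in the window
(0.17 + 0.18 + 0.65 + 0.42 + 0.31 + 0.25 = 1.98); `dynamic_simpler` keeps
only the target row (0.42 + 0.31 + 0.25 = 0.98).  The cosine and Euclidean
values depend on the full fixture vectors, not only on their correlations.

## Command line

```bash
# score a stimulus file against a .vec embedding table
contextsim compute --embeddings vectors.vec --text passages.txt \
    --measures all --window 3 --dataset 2 --freq counts.csv --out scores.csv

# join with eye-tracking records (passage_id, token_index, participant,
# first_fixation_ms, total_fixation_ms) and estimate the similarity effect
contextsim export --scores scores.csv --fixations fixations.csv --out analysis.csv
contextsim recover --table analysis.csv --measure dynamic_full --response first

# or generate a fully synthetic dataset end to end
contextsim simulate --n-passages 55 --participants 20 --beta-sim -10 \
    --seed 1 --out-scores scores.csv --out-fixations fixations.csv
```

`--dataset 1` keeps content-word targets only; `--dataset 2` scores every
token.  Embedding tables are read in the word2vec/fastText text dialect
(header `count dim`, then one word and `dim` floats per line).

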