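"""Synthetic embeddings, passages, and fixation data for end-to-end testing.

Real inputs to the similarity workflow — a pretrained embedding table, a
passage corpus, and per-participant eye-tracking records — are large
downloads.  This module generates statistically controlled stand-ins:

* a latent-factor embedding sampler whose expected pairwise Pearson
  correlation between two words is the dot product of their (unit) factor
  loadings, attenuated by the idiosyncratic-noise share, so correlation
  structure can be dialled in;
* a passage sampler shaped like short naturalistic reading stimuli
  (defaults: 55 passages of ~50 words and ~2.5 sentences, mixing function
  and content words);
* a fixation-duration simulator with word-length and log-frequency
  effects, a participant random intercept, and a (negative) linear
  similarity effect — the structure a mixed-model analysis of reading
  times assumes;
* the exact worked-example window ("We invade the smart watch space")
  together with its printed correlation matrix and an embedding table
  whose sample correlations reproduce that matrix to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .embedding_io import EmbeddingTable
from .similarity_measures import CorrMatrix
from .text_context import FUNCTION_WORDS, Passage, Token, tokenize

__all__ = [
    "LatentEmbeddingSpec",
    "FixationSimSpec",
    "make_embeddings",
    "make_passages",
    "make_frequency_table",
    "simulate_fixations",
    "fig3_fixture",
    "fig3_embeddings",
    "FIG3_SENTENCE",
]

# The worked-example window: target "space", three preceding words.
FIG3_SENTENCE = "We invade the smart watch space."
_FIG3_LABELS = ["the", "smart", "watch", "space"]
_FIG3_CORR = np.array(
    [
        [1.00, 0.17, 0.18, 0.42],
        [0.17, 1.00, 0.65, 0.31],
        [0.18, 0.65, 1.00, 0.25],
        [0.42, 0.31, 0.25, 1.00],
    ]
)

# Function words seeded into generated vocabularies, most frequent first.
_COMMON_FUNCTION_WORDS = (
    "the of and a to in is was he for it with as his on be at by i this had "
    "not are but from or have an they which one you were her all she there "
    "would their we him been has when who will more no if out so what up its "
    "about into than them can only"
).split()


@dataclass(frozen=True)
class LatentEmbeddingSpec:
    """Parameters of the latent-factor embedding sampler.

    Each word w gets loadings l_w on ``n_factors`` latent axes and the
    vector  v_w = L @ l_w + noise_scale * eps_w  with L a d x m matrix and
    eps_w a d-vector, both standard normal.  Across dimensions the
    expected Pearson correlation of two words with unit loadings is
    l_w . l_u / (1 + noise_scale^2), so zero noise gives the loading dot
    product directly.
    """

    vocab_size: int = 1200
    dimension: int = 300
    n_factors: int = 8
    noise_scale: float = 0.5
    seed: int = 0
    n_function_words: int = 60

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2 for Pearson to be defined")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if self.n_factors < 1 or self.noise_scale < 0:
            raise ValueError("invalid factor/noise specification")


_ONSETS = "b c d f g h j k l m n p r s t v w z br cl dr fl gr pl st tr".split()
_VOWELS = "a e i o u".split()
_CODAS = ["", "n", "r", "t", "l", "s", "nd", "st"]


def _pseudo_word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 4))
    parts = []
    for _ in range(n_syll):
        parts.append(
            _ONSETS[rng.integers(len(_ONSETS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            + _CODAS[rng.integers(len(_CODAS))]
        )
    return "".join(parts)


def _default_vocabulary(spec: LatentEmbeddingSpec, rng: np.random.Generator) -> list[str]:
    n_func = min(spec.n_function_words, len(_COMMON_FUNCTION_WORDS), spec.vocab_size // 2)
    words = list(_COMMON_FUNCTION_WORDS[:n_func])
    seen = set(words)
    while len(words) < spec.vocab_size:
        w = _pseudo_word(rng)
        if w not in seen and w not in FUNCTION_WORDS:
            seen.add(w)
            words.append(w)
    return words


def make_embeddings(
    spec: LatentEmbeddingSpec,
    vocabulary: Optional[list[str]] = None,
    loadings: Optional[np.ndarray] = None,
) -> EmbeddingTable:
    """Sample a seeded, reproducible embedding table from a latent spec.

    Parameters
    ----------
    vocabulary : optional
        Explicit word list; defaults to common function words plus
        generated pronounceable pseudo-words (content class).
    loadings : optional
        Explicit per-word loadings of shape (|V|, n_factors); defaults to
        random unit loadings.
    """
    rng = np.random.default_rng(spec.seed)
    if vocabulary is None:
        vocabulary = _default_vocabulary(spec, rng)
    if len(set(vocabulary)) != len(vocabulary):
        raise ValueError("vocabulary contains duplicates")

    n = len(vocabulary)
    if loadings is None:
        loadings = rng.standard_normal((n, spec.n_factors))
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    else:
        loadings = np.asarray(loadings, dtype=np.float64)
        if loadings.shape != (n, spec.n_factors):
            raise ValueError("loadings shape must be (|V|, n_factors)")

    factor_axes = rng.standard_normal((spec.dimension, spec.n_factors))
    noise = rng.standard_normal((n, spec.dimension))
    vectors = loadings @ factor_axes.T + spec.noise_scale * noise
    # A constant row would make Pearson undefined; probability ~0, but jitter
    # deterministically if it ever happens.
    flat = vectors.std(axis=1) == 0.0
    if np.any(flat):
        vectors[flat, 0] += 1e-6
    return EmbeddingTable.from_items(dict(zip(vocabulary, vectors)))


def make_passages(
    table: EmbeddingTable,
    n_passages: int = 55,
    mean_words: float = 50.0,
    mean_sentences: float = 2.5,
    function_word_rate: float = 0.4,
    seed: int = 0,
) -> list[Passage]:
    """Sample reading-stimulus passages from a table's vocabulary.

    Word classes are assigned by the generator (function words drawn from
    the closed-class list present in the vocabulary) so downstream counts
    have a ground truth.  Defaults mirror short naturalistic stimuli:
    55 passages of ~50 words in ~2.5 sentences.
    """
    if len(table) < 2:
        raise ValueError("vocabulary must contain at least 2 words")
    if not 0.0 <= function_word_rate < 1.0:
        raise ValueError("function_word_rate must be in [0, 1)")
    if mean_words < 1 or mean_sentences < 1:
        raise ValueError("means must be >= 1")

    func_pool = sorted(w for w in table.vocabulary if w in FUNCTION_WORDS)
    cont_pool = sorted(w for w in table.vocabulary if w not in FUNCTION_WORDS)
    if function_word_rate > 0 and not func_pool:
        raise ValueError("function_word_rate > 0 but vocabulary has no function words")
    if not cont_pool:
        raise ValueError("vocabulary has no content words")

    rng = np.random.default_rng(seed)
    passages = []
    for p in range(n_passages):
        n_words = max(2, int(rng.poisson(mean_words)))
        n_sent = max(1, min(n_words, int(round(rng.normal(mean_sentences, 0.6)))))
        # spread words across sentences
        bounds = np.sort(rng.choice(np.arange(1, n_words), size=n_sent - 1, replace=False)) if n_sent > 1 else np.array([], dtype=int)
        sent_of = np.zeros(n_words, dtype=int)
        for b in bounds:
            sent_of[b:] += 1

        tokens = []
        for i in range(n_words):
            if func_pool and rng.random() < function_word_rate:
                word = func_pool[rng.integers(len(func_pool))]
                cls = "function"
            else:
                word = cont_pool[rng.integers(len(cont_pool))]
                cls = "content"
            tokens.append(
                Token(
                    surface=word,
                    norm=word,
                    passage_id=f"p{p:03d}",
                    sentence_index=int(sent_of[i]),
                    token_index=i,
                    word_class=cls,
                )
            )
        passages.append(Passage(id=f"p{p:03d}", tokens=tokens, n_sentences=int(sent_of[-1]) + 1))
    return passages


def make_frequency_table(
    words: list[str] | EmbeddingTable,
    seed: int = 0,
    total_count: int = 1_000_000,
    zipf_exponent: float = 1.05,
) -> dict[str, int]:
    """Assign Zipf-distributed corpus counts to words (rank order shuffled)."""
    if isinstance(words, EmbeddingTable):
        words = sorted(words.vocabulary, key=words.vocabulary.__getitem__)
    rng = np.random.default_rng(seed)
    ranks = rng.permutation(len(words)) + 1
    weights = ranks.astype(float) ** (-zipf_exponent)
    counts = np.maximum(1, np.round(total_count * weights / weights.sum())).astype(int)
    return {w: int(c) for w, c in zip(words, counts)}


@dataclass(frozen=True)
class FixationSimSpec:
    """Generative model for per-token, per-participant fixation durations.

    duration = beta0 + beta_len * length + beta_freq * logfreq
             + beta_sim * similarity + u_participant + eps

    with u ~ N(0, sigma_u^2), eps ~ N(0, sigma_eps^2), truncated below at
    1 ms.  Total fixation duration uses the same linear predictor shifted
    by ``total_offset_ms`` (refixations lengthen total reading time) with
    independent residual noise.  The negative default ``beta_sim`` encodes
    the expectation that words semantically closer to their context are
    read faster.
    """

    beta0: float = 214.0
    beta_len: float = 5.0
    beta_freq: float = -8.0
    beta_sim: float = -10.0
    sigma_u: float = 30.0
    sigma_eps: float = 50.0
    n_participants: int = 20
    total_offset_ms: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_eps < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_participants < 1:
            raise ValueError("at least one participant is required")


def simulate_fixations(
    scores: pd.DataFrame,
    spec: FixationSimSpec,
    measure: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate fixation durations for every (token, participant) pair.

    Parameters
    ----------
    scores : DataFrame
        Token score table with columns ``passage_id, token_index,
        word_length, log_freq`` and the named measure column; rows with a
        MISSING measure value are skipped.
    measure : str
        Name of the similarity column driving the effect.

    Returns
    -------
    (fixations, u) : the long-format fixation table with columns
        ``passage_id, token_index, participant, first_fixation_ms,
        total_fixation_ms``, and the realized participant intercepts.
    """
    if measure not in scores.columns:
        raise KeyError(f"measure column {measure!r} not in score table")
    rows = scores.dropna(subset=[measure])
    if rows.empty:
        raise ValueError(f"no tokens with a defined {measure!r} value")

    rng = np.random.default_rng(spec.seed)
    u = rng.normal(0.0, spec.sigma_u, size=spec.n_participants)

    n_tok = len(rows)
    base = (
        spec.beta0
        + spec.beta_len * rows["word_length"].to_numpy(dtype=float)
        + spec.beta_freq * rows["log_freq"].to_numpy(dtype=float)
        + spec.beta_sim * rows[measure].to_numpy(dtype=float)
    )
    # token-major blocks: all participants for token 0, then token 1, ...
    mu = np.repeat(base, spec.n_participants) + np.tile(u, n_tok)
    eps_first = rng.normal(0.0, spec.sigma_eps, size=mu.size)
    eps_total = rng.normal(0.0, spec.sigma_eps, size=mu.size)
    first = np.maximum(1.0, mu + eps_first)
    total = np.maximum(1.0, mu + spec.total_offset_ms + eps_total)

    out = pd.DataFrame(
        {
            "passage_id": np.repeat(rows["passage_id"].to_numpy(), spec.n_participants),
            "token_index": np.repeat(rows["token_index"].to_numpy(), spec.n_participants),
            "participant": np.tile(np.arange(spec.n_participants), n_tok),
            "first_fixation_ms": first,
            "total_fixation_ms": total,
        }
    )
    return out, u


def fig3_fixture() -> tuple[Passage, CorrMatrix]:
    """The worked-example passage and its printed correlation matrix.

    The target word is "space"; the matrix rows/columns are ordered
    ["the", "smart", "watch", "space"], and the strictly-lower-triangle
    entries are 0.17, 0.18, 0.65, 0.42, 0.31, 0.25 (summing to 1.98; the
    target row alone sums to 0.98).
    """
    passage = tokenize(FIG3_SENTENCE, passage_id="fig3")
    matrix = CorrMatrix(labels=list(_FIG3_LABELS), values=_FIG3_CORR.copy())
    return passage, matrix


def fig3_embeddings(dimension: int = 300, seed: int = 7) -> EmbeddingTable:
    """An embedding table reproducing the worked-example correlations.

    The vectors for "the", "smart", "watch", "space" are constructed (via
    Cholesky against orthonormalized centered noise) so that their sample
    Pearson correlations equal the printed matrix to machine precision;
    "we" and "invade" get arbitrary random vectors so the full sentence is
    in vocabulary.
    """
    if dimension < 6:
        raise ValueError("dimension must exceed the window size + 1")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((dimension, 4))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    chol = np.linalg.cholesky(_FIG3_CORR)
    exact = q @ chol.T  # columns: centered, unit-norm, Gram == _FIG3_CORR
    items = {w: exact[:, i] for i, w in enumerate(_FIG3_LABELS)}
    for w in ("we", "invade"):
        items[w] = rng.standard_normal(dimension)
    return EmbeddingTable.from_items(items)
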