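"""Tokenization, content/function word classification, and context-window
extraction for contextual semantic similarity.

A target word's similarity to its context depends on which preceding words
count as context.  Three window policies are supported, matching the three
families of measures:

* ``FIXED_K_ALL`` — the k most recent in-vocabulary preceding tokens of any
  word class, allowed to cross sentence boundaries within a passage but
  never passage boundaries.  Requires a full k-token context; otherwise the
  window is undefined, so every defined window yields the same number of
  word pairs and values are comparable across tokens.
* ``FIXED_K_CONTENT_SENT`` — up to the k most recent in-vocabulary content
  words within the current sentence.
* ``ALL_PRECEDING_SENT`` — all in-vocabulary preceding tokens within the
  current sentence, any class.

Out-of-vocabulary tokens are skipped with extended lookback rather than
zero-filled: a zero vector has no defined Pearson correlation and would
distort context sums and means.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .embedding_io import (
    DEFAULT_NORMALIZATION,
    EmbeddingTable,
    NormalizationPolicy,
    normalize_word,
)

__all__ = [
    "Token",
    "Passage",
    "ContextWindow",
    "WindowPolicy",
    "FUNCTION_WORDS",
    "tokenize",
    "classify_word",
    "annotate_vocabulary",
    "extract_window",
    "read_passages_text",
    "read_tokens_csv",
    "load_function_words",
]

# Closed-class English word list: determiners, prepositions, conjunctions,
# pronouns, auxiliaries/modals, particles, wh-words.  Overridable by file via
# load_function_words(); everything not on the list is treated as content.
FUNCTION_WORDS: frozenset[str] = frozenset(
    """
    a an the this that these those some any each every either neither no
    another such both all half several enough much many more most few fewer
    little less least
    of in on at by for with from to into onto upon about above below under
    over between among through during before after since until across along
    around behind beside besides beyond despite except inside outside near
    off out up down toward towards via within without against amid
    and or but nor so yet if because although though while whereas unless
    whether as than once
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves yourselves themselves one oneself somebody someone something
    anybody anyone anything everybody everyone everything nobody nothing
    this that who whom whose which what whatever whoever whichever
    be am is are was were been being have has had having do does did doing
    will would shall should can could may might must ought need dare
    not n't to
    when where why how there here then
    """.split()
)

_WORD_RE = re.compile(r"[^\W\d_]+(?:[-'’][^\W\d_]+)*|\d+(?:[.,]\d+)*", re.UNICODE)
# Sentence terminators: . ! ? (possibly repeated), then closing quotes/brackets.
_SENT_RE = re.compile(r"[.!?]+[\"'”’»)\]]*")


@dataclass
class Token:
    """One word token of a stimulus passage."""

    surface: str
    norm: str
    passage_id: str
    sentence_index: int
    token_index: int
    word_class: str = "content"  # "content" | "function"
    in_vocab: bool = True

    def __len__(self) -> int:
        return len(self.surface)


@dataclass
class Passage:
    """An ordered sequence of tokens with sentence structure."""

    id: str
    tokens: list[Token]
    n_sentences: int

    def __post_init__(self) -> None:
        if self.n_sentences < 1:
            raise ValueError("a passage must contain at least one sentence")
        for i, tok in enumerate(self.tokens):
            if tok.token_index != i:
                raise ValueError("token_index must be 0-based and consecutive")
        sent = [t.sentence_index for t in self.tokens]
        if any(b < a for a, b in zip(sent, sent[1:])):
            raise ValueError("sentence_index must be non-decreasing")

    def __len__(self) -> int:
        return len(self.tokens)


class WindowPolicy(Enum):
    """Context-window extraction policies (see module docstring)."""

    FIXED_K_ALL = "fixed_k_all"
    FIXED_K_CONTENT_SENT = "fixed_k_content_sent"
    ALL_PRECEDING_SENT = "all_preceding_sent"


@dataclass
class ContextWindow:
    """A target token plus its ordered preceding-context tokens.

    Context tokens are earliest-first; all are in-vocabulary and strictly
    precede the target.
    """

    target: Token
    context: list[Token]
    policy: WindowPolicy
    k: int

    def __post_init__(self) -> None:
        if not self.context:
            raise ValueError("a defined window must have at least one context token")
        idx = [t.token_index for t in self.context]
        if any(b <= a for a, b in zip(idx, idx[1:])) or idx[-1] >= self.target.token_index:
            raise ValueError("context tokens must strictly precede the target in order")
        if not all(t.in_vocab for t in self.context) or not self.target.in_vocab:
            raise ValueError("window tokens must be in-vocabulary")


def classify_word(norm: str, function_list: frozenset[str] | set[str] = FUNCTION_WORDS) -> str:
    """Classify a normalized form as ``"function"`` or ``"content"``."""
    return "function" if norm in function_list else "content"


def load_function_words(path: str | Path) -> frozenset[str]:
    """Load an override function-word list: one word per line, '#' comments."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.append(normalize_word(line))
    return frozenset(words)


def tokenize(
    text: str,
    passage_id: str = "p0",
    function_list: frozenset[str] | set[str] = FUNCTION_WORDS,
    normalization: NormalizationPolicy = DEFAULT_NORMALIZATION,
) -> Passage:
    """Deterministically segment raw passage text into a :class:`Passage`.

    Sentences end at terminal punctuation (``. ! ?`` plus closing quotes);
    words are maximal alphabetic runs, hyphenated words kept whole,
    standalone punctuation discarded.
    """
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty or whitespace-only text")

    # Segment into sentences by terminator positions, then extract words.
    sentences: list[str] = []
    last = 0
    for m in _SENT_RE.finditer(text):
        seg = text[last : m.end()]
        if _WORD_RE.search(seg):
            sentences.append(seg)
        last = m.end()
    tail = text[last:]
    if _WORD_RE.search(tail):
        sentences.append(tail)
    if not sentences:
        raise ValueError("no word tokens found in text")

    tokens: list[Token] = []
    for s_idx, sent in enumerate(sentences):
        for m in _WORD_RE.finditer(sent):
            surface = m.group(0)
            norm = normalize_word(surface, normalization)
            if not norm:
                continue
            tokens.append(
                Token(
                    surface=surface,
                    norm=norm,
                    passage_id=passage_id,
                    sentence_index=s_idx,
                    token_index=len(tokens),
                    word_class=classify_word(norm, function_list),
                )
            )
    return Passage(id=passage_id, tokens=tokens, n_sentences=len(sentences))


def annotate_vocabulary(passage: Passage, table: EmbeddingTable) -> Passage:
    """Return a copy of the passage with ``in_vocab`` set against a table."""
    tokens = [replace(t, in_vocab=t.norm in table.vocabulary) for t in passage.tokens]
    return Passage(id=passage.id, tokens=tokens, n_sentences=passage.n_sentences)


def extract_window(
    passage: Passage,
    target_index: int,
    policy: WindowPolicy,
    k: int = 3,
    table: Optional[EmbeddingTable] = None,
) -> Optional[ContextWindow]:
    """Extract the preceding-context window for a target token.

    Returns ``None`` (the window is undefined) when the policy cannot
    supply a usable context: the target is out of vocabulary, FIXED_K_ALL
    finds fewer than k in-vocabulary preceding tokens in the passage, or a
    sentence-bounded policy finds no eligible in-sentence predecessor.

    If ``table`` is given, ``in_vocab`` flags are refreshed against it
    first; otherwise the flags already on the tokens are trusted.
    """
    if target_index < 0 or target_index >= len(passage.tokens):
        raise IndexError(f"target_index {target_index} out of range")
    if policy in (WindowPolicy.FIXED_K_ALL, WindowPolicy.FIXED_K_CONTENT_SENT) and k < 1:
        raise ValueError("k must be >= 1 for fixed-k policies")

    if table is not None:
        passage = annotate_vocabulary(passage, table)
    target = passage.tokens[target_index]
    if not target.in_vocab:
        return None

    preceding = passage.tokens[:target_index]

    if policy is WindowPolicy.FIXED_K_ALL:
        picked: list[Token] = []
        for tok in reversed(preceding):
            if tok.in_vocab:
                picked.append(tok)
                if len(picked) == k:
                    break
        if len(picked) < k:
            return None
        context = picked[::-1]
    elif policy is WindowPolicy.FIXED_K_CONTENT_SENT:
        picked = []
        for tok in reversed(preceding):
            if tok.sentence_index != target.sentence_index:
                break
            if tok.in_vocab and tok.word_class == "content":
                picked.append(tok)
                if len(picked) == k:
                    break
        if not picked:
            return None
        context = picked[::-1]
    elif policy is WindowPolicy.ALL_PRECEDING_SENT:
        context = [
            tok
            for tok in preceding
            if tok.sentence_index == target.sentence_index and tok.in_vocab
        ]
        if not context:
            return None
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown policy {policy}")

    return ContextWindow(target=target, context=context, policy=policy, k=k)


def read_passages_text(
    path: str | Path,
    function_list: frozenset[str] | set[str] = FUNCTION_WORDS,
    normalization: NormalizationPolicy = DEFAULT_NORMALIZATION,
) -> list[Passage]:
    """Read a plain-text stimulus file: passages separated by blank lines."""
    text = Path(path).read_text(encoding="utf-8")
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    if not blocks:
        raise ValueError(f"no passages found in {path}")
    return [
        tokenize(block, passage_id=f"p{i}", function_list=function_list,
                 normalization=normalization)
        for i, block in enumerate(blocks)
    ]


def read_tokens_csv(
    path: str | Path,
    function_list: frozenset[str] | set[str] = FUNCTION_WORDS,
    normalization: NormalizationPolicy = DEFAULT_NORMALIZATION,
) -> list[Passage]:
    """Read pre-tokenized stimuli from CSV.

    Required columns: ``passage_id, sentence_index, token_index, surface``.
    """
    required = {"passage_id", "sentence_index", "token_index", "surface"}
    rows: list[dict] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"pre-tokenized CSV must have columns {sorted(required)}"
            )
        rows = list(reader)
    if not rows:
        raise ValueError(f"no token rows in {path}")

    by_passage: dict[str, list[dict]] = {}
    for row in rows:
        by_passage.setdefault(row["passage_id"], []).append(row)

    passages = []
    for pid, prows in by_passage.items():
        prows.sort(key=lambda r: int(r["token_index"]))
        tokens = []
        for row in prows:
            norm = normalize_word(row["surface"], normalization)
            tokens.append(
                Token(
                    surface=row["surface"],
                    norm=norm,
                    passage_id=pid,
                    sentence_index=int(row["sentence_index"]),
                    token_index=len(tokens),
                    word_class=classify_word(norm, function_list),
                )
            )
        n_sent = tokens[-1].sentence_index + 1 if tokens else 1
        passages.append(Passage(id=pid, tokens=tokens, n_sentences=n_sent))
    return passages
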