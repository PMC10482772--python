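"""Reading and querying word-embedding tables in the word2vec/fastText text dialect.

The ``.vec`` plain-text format is a one-line header ``"<count> <dim>"``
followed by one line per word: the surface key and ``dim`` decimal floats,
single-space separated, UTF-8.  Pretrained distributions in this format
(e.g. the fastText English vectors trained on Wikipedia + UMBC + news)
contain occasional malformed lines, which are skipped and counted rather
than treated as fatal.
"""

from __future__ import annotations

import string
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "NormalizationPolicy",
    "EmbeddingTable",
    "normalize_word",
    "read_vec_text",
    "write_vec_text",
    "lookup",
]

_STRIP_CHARS = string.punctuation + "‘’“”–—…"


@dataclass(frozen=True)
class NormalizationPolicy:
    """How raw word forms are mapped to vocabulary keys.

    Defaults: Unicode NFC, case-fold to lower, strip leading/trailing
    punctuation.  Lower-casing maximizes the hit rate of stimulus surface
    forms against word2vec-style vocabularies, which are dominated by
    lower-case entries.
    """

    nfc: bool = True
    casefold: bool = True
    strip_punctuation: bool = True


DEFAULT_NORMALIZATION = NormalizationPolicy()


def normalize_word(raw: str, policy: NormalizationPolicy = DEFAULT_NORMALIZATION) -> str:
    """Normalize a raw surface form to an embedding-table key."""
    word = raw
    if policy.nfc:
        word = unicodedata.normalize("NFC", word)
    if policy.casefold:
        word = word.casefold()
    if policy.strip_punctuation:
        word = word.strip(_STRIP_CHARS)
    return word


@dataclass
class EmbeddingTable:
    """A vocabulary of fixed-dimension real word vectors.

    Attributes
    ----------
    vocabulary : dict
        Normalized word form -> row index into ``vectors``.
    vectors : ndarray of shape (|V|, d)
    dimension : int
        Vector dimensionality d.
    source_meta : tuple
        ``(declared_count, declared_dimension)`` from the file header
        (equal to the observed values for tables built in memory).
    n_skipped : int
        Lines rejected because their float count mismatched the header.
    n_collisions : int
        Raw words whose normalized key was already present (first wins).
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray
    dimension: int
    source_meta: tuple[int, int]
    n_skipped: int = 0
    n_collisions: int = 0
    normalization: NormalizationPolicy = field(default=DEFAULT_NORMALIZATION)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.dimension:
            raise ValueError(
                f"vector matrix shape {self.vectors.shape} inconsistent with "
                f"dimension {self.dimension}"
            )
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vocabulary size does not match vector row count")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding table contains non-finite entries")

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, form: str) -> bool:
        return form in self.vocabulary

    @classmethod
    def from_items(
        cls,
        items: dict[str, np.ndarray],
        normalization: NormalizationPolicy = DEFAULT_NORMALIZATION,
    ) -> "EmbeddingTable":
        """Build a table from an in-memory mapping word -> vector."""
        words = list(items)
        mat = np.asarray([items[w] for w in words], dtype=np.float64)
        vocab = {w: i for i, w in enumerate(words)}
        return cls(
            vocabulary=vocab,
            vectors=mat,
            dimension=mat.shape[1],
            source_meta=(len(words), mat.shape[1]),
            normalization=normalization,
        )


class VecFormatError(ValueError):
    """Raised for unreadable files, malformed headers, or empty tables."""


def read_vec_text(
    path: str | Path,
    normalization: NormalizationPolicy = DEFAULT_NORMALIZATION,
) -> EmbeddingTable:
    """Read a ``.vec`` text file into an :class:`EmbeddingTable`.

    Lines whose float count mismatches the header dimension are skipped
    and counted in ``n_skipped``.  When two raw words normalize to the
    same key the first occurrence wins and ``n_collisions`` increments.

    Raises
    ------
    VecFormatError
        If the file cannot be read, the header does not parse as two
        positive integers, or no line is accepted.
    """
    path = Path(path)
    try:
        fh = path.open("r", encoding="utf-8")
    except OSError as exc:
        raise VecFormatError(f"cannot read embedding file {path}: {exc}") from exc

    with fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise VecFormatError(f"malformed .vec header in {path}: {header!r}")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise VecFormatError(f"malformed .vec header in {path}: {header!r}") from exc
        if count <= 0 or dim <= 0:
            raise VecFormatError(f"non-positive count/dimension in {path} header")

        vocab: dict[str, int] = {}
        rows: list[np.ndarray] = []
        n_skipped = 0
        n_collisions = 0
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                n_skipped += 1
                continue
            try:
                vec = np.array(parts[1:], dtype=np.float64)
            except ValueError:
                n_skipped += 1
                continue
            if not np.all(np.isfinite(vec)):
                n_skipped += 1
                continue
            key = normalize_word(parts[0], normalization)
            if not key:
                n_skipped += 1
                continue
            if key in vocab:
                n_collisions += 1
                continue
            vocab[key] = len(rows)
            rows.append(vec)

    if not rows:
        raise VecFormatError(f"no well-formed vector lines in {path}")
    return EmbeddingTable(
        vocabulary=vocab,
        vectors=np.vstack(rows),
        dimension=dim,
        source_meta=(count, dim),
        n_skipped=n_skipped,
        n_collisions=n_collisions,
        normalization=normalization,
    )


def write_vec_text(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table back out in ``.vec`` text format.

    Floats are rendered with ``repr`` precision so a read/write round trip
    reproduces vector values to well below 1e-6 per entry.
    """
    path = Path(path)
    order = sorted(table.vocabulary, key=table.vocabulary.__getitem__)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(order)} {table.dimension}\n")
        for word in order:
            row = table.vectors[table.vocabulary[word]]
            fh.write(word + " " + " ".join(repr(float(x)) for x in row) + "\n")


def lookup(table: EmbeddingTable, token_form: str) -> Optional[np.ndarray]:
    """Return the stored vector for a normalized form, or None if absent.

    Never raises for out-of-vocabulary forms; ``None`` is the MISSING
    sentinel used throughout the package.
    """
    idx = table.vocabulary.get(token_form)
    if idx is None:
        return None
    return table.vectors[idx]
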