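"""The six contextual semantic similarity measures.

Three families, each in two variants:

* **dynamic** — stack the target word's vector with its k preceding words'
  vectors, compute the (k+1)x(k+1) Pearson correlation matrix across
  embedding dimensions, and sum either the whole strictly-lower triangle
  (``dynamic_full``: one correlation per unordered word pair) or only the
  target's row against each context word (``dynamic_simpler``).
* **cosine** — cosine of the angle between the target vector and the *sum*
  of the context vectors; the classical variant uses up to the three
  preceding in-sentence content words, the modified variant the three
  preceding words of any class.
* **euclidean** — reciprocal of the Euclidean distance between the target
  vector and the *mean* of the context vectors; the classical variant uses
  all preceding in-sentence words, the modified variant a fixed window of
  three.

Degenerate inputs (constant vectors, zero-norm context sums) yield MISSING
(``None``) rather than a numeric sentinel: zero is a meaningful similarity
value and must not encode failure.  The one exception is the documented
Euclidean saturation — when target and context mean coincide to within
1e-12 the value is reported as 1e12 with ``saturated=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .embedding_io import EmbeddingTable, lookup
from .text_context import ContextWindow, Passage, WindowPolicy, extract_window

__all__ = [
    "MeasureId",
    "MEASURE_POLICY",
    "CorrMatrix",
    "SimilarityValue",
    "DegenerateVectorError",
    "pearson",
    "cosine_vec",
    "correlation_matrix",
    "dynamic_full",
    "simpler_dynamic",
    "cosine_measure",
    "euclidean_measure",
    "compute_measure",
]

EUCLIDEAN_SATURATION_DISTANCE = 1e-12
EUCLIDEAN_SATURATION_VALUE = 1e12


class DegenerateVectorError(ValueError):
    """A vector is constant or zero-norm; the measure is undefined for it."""


class MeasureId(Enum):
    """The six measures, each bound to one window policy."""

    COSINE_CONTENT = "cosine_content"
    COSINE_ALL = "cosine_all"
    EUCLIDEAN_SENTENCE = "euclidean_sentence"
    EUCLIDEAN_FIXED = "euclidean_fixed"
    DYNAMIC_FULL = "dynamic_full"
    DYNAMIC_SIMPLER = "dynamic_simpler"


MEASURE_POLICY: dict[MeasureId, WindowPolicy] = {
    MeasureId.COSINE_CONTENT: WindowPolicy.FIXED_K_CONTENT_SENT,
    MeasureId.COSINE_ALL: WindowPolicy.FIXED_K_ALL,
    MeasureId.EUCLIDEAN_SENTENCE: WindowPolicy.ALL_PRECEDING_SENT,
    MeasureId.EUCLIDEAN_FIXED: WindowPolicy.FIXED_K_ALL,
    MeasureId.DYNAMIC_FULL: WindowPolicy.FIXED_K_ALL,
    MeasureId.DYNAMIC_SIMPLER: WindowPolicy.FIXED_K_ALL,
}


@dataclass
class CorrMatrix:
    """Pairwise Pearson correlations over a window's word vectors.

    Labels are ordered context-first, target last; ``values`` is the
    symmetric (k+1)x(k+1) matrix with unit diagonal.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape must match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    def entry(self, a: str, b: str) -> float:
        """Correlation between two labelled words."""
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class SimilarityValue:
    """Per-token outcome of one measure: a value or MISSING."""

    measure: MeasureId
    value: Optional[float]
    passage_id: str
    token_index: int
    k: int
    saturated: bool = False

    @property
    def missing(self) -> bool:
        return self.value is None


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two word vectors across embedding dimensions.

    r = sum((u_i - u_bar)(v_i - v_bar)) / sqrt(sum((u_i - u_bar)^2) * sum((v_i - v_bar)^2))

    Raises :class:`DegenerateVectorError` if either vector is constant.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("pearson requires two equal-length vectors of size >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt(du @ du) * np.sqrt(dv @ dv)
    if denom == 0.0:
        raise DegenerateVectorError("constant vector has no defined correlation")
    return float(np.clip((du @ dv) / denom, -1.0, 1.0))


def cosine_vec(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors.

    Raises :class:`DegenerateVectorError` on zero-norm input.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateVectorError("zero-norm vector has no defined cosine")
    return float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))


def _window_vectors(window: ContextWindow, table: EmbeddingTable) -> tuple[np.ndarray, np.ndarray]:
    """(context matrix |C| x d, target vector). All lookups must succeed."""
    ctx = []
    for tok in window.context:
        vec = lookup(table, tok.norm)
        if vec is None:
            raise KeyError(f"context token {tok.norm!r} not in embedding table")
        ctx.append(vec)
    tgt = lookup(table, window.target.norm)
    if tgt is None:
        raise KeyError(f"target token {window.target.norm!r} not in embedding table")
    return np.vstack(ctx), tgt


def correlation_matrix(window: ContextWindow, table: EmbeddingTable) -> CorrMatrix:
    """Correlation matrix over a window's vectors, context first, target last.

    Raises :class:`DegenerateVectorError` if any vector is constant.
    """
    ctx, tgt = _window_vectors(window, table)
    mat = np.vstack([ctx, tgt])
    if np.any(mat.std(axis=1) == 0.0):
        raise DegenerateVectorError("constant word vector in window")
    values = np.corrcoef(mat)
    np.fill_diagonal(values, 1.0)
    labels = [t.norm for t in window.context] + [window.target.norm]
    return CorrMatrix(labels=labels, values=np.clip(values, -1.0, 1.0))


def dynamic_full(m: CorrMatrix) -> float:
    """Sum of the strictly-lower-triangle correlations (one per word pair)."""
    return float(np.tril(m.values, k=-1).sum())


def simpler_dynamic(m: CorrMatrix) -> float:
    """Sum of the target's correlations with each context word.

    The target is the last label; this is the last row excluding the
    diagonal, i.e. dynamic_full minus the context-context pair sum.
    """
    return float(m.values[-1, :-1].sum())


def cosine_measure(window: ContextWindow, table: EmbeddingTable) -> float:
    """Cosine between the target vector and the summed context vectors."""
    ctx, tgt = _window_vectors(window, table)
    return cosine_vec(ctx.sum(axis=0), tgt)


def euclidean_measure(window: ContextWindow, table: EmbeddingTable) -> tuple[float, bool]:
    """1 / Euclidean distance between target and mean context vector.

    Returns ``(value, saturated)``; when the distance is below 1e-12 the
    value saturates at 1e12 and the flag is set.
    """
    ctx, tgt = _window_vectors(window, table)
    dist = float(np.linalg.norm(tgt - ctx.mean(axis=0)))
    if dist < EUCLIDEAN_SATURATION_DISTANCE:
        return EUCLIDEAN_SATURATION_VALUE, True
    return 1.0 / dist, False


def compute_measure(
    passage: Passage,
    target_index: int,
    measure: MeasureId,
    k: int = 3,
    table: EmbeddingTable | None = None,
) -> SimilarityValue:
    """Compute one measure for one target token.

    Extracts the measure's policy-bound window and applies the measure.
    Undefined windows and degenerate vectors yield MISSING, never a crash.
    """
    if table is None:
        raise ValueError("an embedding table is required")
    policy = MEASURE_POLICY[measure]
    pid = passage.id
    window = extract_window(passage, target_index, policy, k=k, table=table)
    if window is None:
        return SimilarityValue(measure, None, pid, target_index, k)

    try:
        if measure in (MeasureId.DYNAMIC_FULL, MeasureId.DYNAMIC_SIMPLER):
            m = correlation_matrix(window, table)
            val = dynamic_full(m) if measure is MeasureId.DYNAMIC_FULL else simpler_dynamic(m)
            return SimilarityValue(measure, val, pid, target_index, k)
        if measure in (MeasureId.COSINE_CONTENT, MeasureId.COSINE_ALL):
            return SimilarityValue(measure, cosine_measure(window, table), pid, target_index, k)
        val, saturated = euclidean_measure(window, table)
        return SimilarityValue(measure, val, pid, target_index, k, saturated=saturated)
    except DegenerateVectorError as exc:
        warnings.warn(
            f"{measure.value} at {pid}[{target_index}]: {exc}; value set to MISSING",
            RuntimeWarning,
            stacklevel=2,
        )
        return SimilarityValue(measure, None, pid, target_index, k)
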