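"""Tidy per-token score tables, eye-tracking joins, and a linear
similarity-effect recovery check.

The heavy statistical machinery applied to reading times in practice —
generalized additive mixed models with tensor smooths and participant
random effects, and their quantile-regression counterparts — lives in
dedicated smooth-model software and consumes a tidy table.  This module
produces that table (per-token measure values plus word length,
log frequency and word class, optionally joined with per-participant
fixation durations) and offers a deliberately simple in-repo estimator:
ordinary least squares on participant-mean-centered durations with length
and log-frequency covariates.  Centering absorbs the participant random
intercept exactly under the additive generative model, so the OLS slope on
the similarity column is a consistent estimate of the linear similarity
effect in ms per similarity unit.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .embedding_io import EmbeddingTable
from .similarity_measures import MeasureId, compute_measure
from .text_context import Passage, annotate_vocabulary

__all__ = [
    "compute_token_table",
    "join_eyetracking",
    "recover_similarity_effect",
    "FIXATION_COLUMNS",
]

FIXATION_COLUMNS = (
    "passage_id",
    "token_index",
    "participant",
    "first_fixation_ms",
    "total_fixation_ms",
)

_RESPONSE_COLUMN = {"first": "first_fixation_ms", "total": "total_fixation_ms"}


def compute_token_table(
    passages: Sequence[Passage],
    table: EmbeddingTable,
    measures: Iterable[MeasureId] = tuple(MeasureId),
    k: int = 3,
    freq_table: Optional[dict[str, int]] = None,
    dataset: int = 2,
) -> pd.DataFrame:
    """Score every token of every passage with the requested measures.

    One row per (passage, token) with columns ``passage_id, token_index,
    norm, word_length, log_freq, log_freq_imputed, word_class`` and one
    column per measure (NaN where the measure is MISSING).

    ``dataset=1`` keeps content-word targets only; ``dataset=2`` keeps all
    targets.  Words absent from ``freq_table`` receive its minimum count
    (flagged in ``log_freq_imputed``); if coverage falls below 90% a
    warning is emitted.
    """
    passages = list(passages)
    if not passages:
        raise ValueError("empty passage list")
    if dataset not in (1, 2):
        raise ValueError("dataset must be 1 (content targets) or 2 (all targets)")
    measures = list(measures)

    if freq_table:
        min_count = min(freq_table.values())
    else:
        freq_table, min_count = {}, 1

    records = []
    n_tokens = 0
    n_covered = 0
    for passage in passages:
        passage = annotate_vocabulary(passage, table)
        for tok in passage.tokens:
            n_tokens += 1
            count = freq_table.get(tok.norm)
            covered = count is not None
            n_covered += covered
            rec = {
                "passage_id": passage.id,
                "token_index": tok.token_index,
                "norm": tok.norm,
                "word_length": len(tok.surface),
                "log_freq": float(np.log(count if covered else min_count)),
                "log_freq_imputed": not covered,
                "word_class": tok.word_class,
            }
            for measure in measures:
                sv = compute_measure(passage, tok.token_index, measure, k=k, table=table)
                rec[measure.value] = np.nan if sv.value is None else sv.value
            records.append(rec)

    if freq_table and n_covered < 0.9 * n_tokens:
        warnings.warn(
            f"frequency table covers only {n_covered}/{n_tokens} tokens "
            "(< 90%); uncovered words imputed at the minimum count",
            RuntimeWarning,
            stacklevel=2,
        )

    out = pd.DataFrame.from_records(records)
    if dataset == 1:
        out = out[out["word_class"] == "content"].reset_index(drop=True)
    return out


def join_eyetracking(
    scores: pd.DataFrame,
    fixations: pd.DataFrame | str | Path,
) -> pd.DataFrame:
    """Inner-join token scores with per-participant fixation durations.

    The fixation table must carry ``passage_id, token_index, participant,
    first_fixation_ms, total_fixation_ms``.  Unmatched fixation rows are
    counted in ``result.attrs["n_unmatched"]``; a key match rate below 95%
    triggers a warning.
    """
    if not isinstance(fixations, pd.DataFrame):
        fixations = pd.read_csv(fixations)
    missing = [c for c in FIXATION_COLUMNS if c not in fixations.columns]
    if missing:
        raise ValueError(f"fixation table missing required columns: {missing}")

    keys = ["passage_id", "token_index"]
    merged = fixations.merge(scores, on=keys, how="inner")
    n_unmatched = len(fixations) - len(merged)
    if n_unmatched:
        rate = len(merged) / len(fixations)
        msg = f"{n_unmatched} fixation rows had no matching token (match rate {rate:.1%})"
        if rate < 0.95:
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    merged.attrs["n_unmatched"] = n_unmatched
    return merged


def recover_similarity_effect(
    table: pd.DataFrame,
    measure: MeasureId | str,
    response: str = "first",
) -> tuple[float, float]:
    """Estimate the linear similarity effect on fixation duration.

    Participant-mean-centers the response (absorbing the participant
    random intercept), then fits OLS of the centered duration on the
    measure value, word length and log frequency.  Returns ``(slope, se)``
    in ms per similarity unit.

    Requires at least 2 participants and 100 complete records.
    """
    col = measure.value if isinstance(measure, MeasureId) else str(measure)
    if col not in table.columns:
        raise KeyError(f"measure column {col!r} not in table")
    if response not in _RESPONSE_COLUMN:
        raise ValueError("response must be 'first' or 'total'")
    ycol = _RESPONSE_COLUMN[response]

    data = table.dropna(subset=[col, ycol, "word_length", "log_freq"]).copy()
    if data.empty:
        raise ValueError(f"no complete records for measure {col!r}")
    if data["participant"].nunique() < 2:
        raise ValueError("at least 2 participants are required")
    if len(data) < 100:
        raise ValueError("at least 100 complete records are required")

    y = data[ycol] - data.groupby("participant")[ycol].transform("mean")
    X = sm.add_constant(data[[col, "word_length", "log_freq"]].astype(float))
    fit = sm.OLS(y.to_numpy(dtype=float), X).fit()
    return float(fit.params[col]), float(fit.bse[col])
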