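"""Independent brute-force reimplementation of the six measures.

Everything here is written from the measure definitions with plain Python
loops and ``math`` — no numpy, no imports from the package's numeric code —
so it can serve as an independent oracle for elementwise comparison.
"""

from __future__ import annotations

import math

FUNCTION = "function"


def o_pearson(u, v):
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = math.sqrt(sum((a - mu) ** 2 for a in u))
    dv = math.sqrt(sum((b - mv) ** 2 for b in v))
    if du == 0.0 or dv == 0.0:
        return None
    return num / (du * dv)


def o_cosine(u, v):
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    if nu == 0.0 or nv == 0.0:
        return None
    return sum(a * b for a, b in zip(u, v)) / (nu * nv)


def _vec(table, word):
    idx = table.vocabulary.get(word)
    return None if idx is None else [float(x) for x in table.vectors[idx]]


def _in_vocab(table, tok):
    return tok.norm in table.vocabulary


def o_window(passage, i, policy, k, table):
    """Context token list (earliest first) or None, from the policy definitions."""
    toks = passage.tokens
    target = toks[i]
    if not _in_vocab(table, target):
        return None
    if policy == "fixed_k_all":
        picked = []
        j = i - 1
        while j >= 0 and len(picked) < k:
            if _in_vocab(table, toks[j]):
                picked.append(toks[j])
            j -= 1
        return picked[::-1] if len(picked) == k else None
    if policy == "fixed_k_content_sent":
        picked = []
        j = i - 1
        while j >= 0 and toks[j].sentence_index == target.sentence_index and len(picked) < k:
            if _in_vocab(table, toks[j]) and toks[j].word_class != FUNCTION:
                picked.append(toks[j])
            j -= 1
        return picked[::-1] if picked else None
    if policy == "all_preceding_sent":
        picked = [
            toks[j]
            for j in range(i)
            if toks[j].sentence_index == target.sentence_index and _in_vocab(table, toks[j])
        ]
        return picked or None
    raise ValueError(policy)


def o_dynamic(passage, i, k, table, simpler):
    ctx = o_window(passage, i, "fixed_k_all", k, table)
    if ctx is None:
        return None
    vecs = [_vec(table, t.norm) for t in ctx] + [_vec(table, passage.tokens[i].norm)]
    total = 0.0
    for a in range(len(vecs)):
        for b in range(a):
            if simpler and a != len(vecs) - 1:
                continue
            r = o_pearson(vecs[a], vecs[b])
            if r is None:
                return None
            total += max(-1.0, min(1.0, r))
    return total


def o_cosine_measure(passage, i, k, table, content_only):
    policy = "fixed_k_content_sent" if content_only else "fixed_k_all"
    ctx = o_window(passage, i, policy, k, table)
    if ctx is None:
        return None
    tgt = _vec(table, passage.tokens[i].norm)
    summed = [0.0] * len(tgt)
    for tok in ctx:
        for d, x in enumerate(_vec(table, tok.norm)):
            summed[d] += x
    val = o_cosine(summed, tgt)
    return None if val is None else max(-1.0, min(1.0, val))


def o_euclidean_measure(passage, i, k, table, fixed):
    policy = "fixed_k_all" if fixed else "all_preceding_sent"
    ctx = o_window(passage, i, policy, k, table)
    if ctx is None:
        return None
    tgt = _vec(table, passage.tokens[i].norm)
    mean = [0.0] * len(tgt)
    for tok in ctx:
        for d, x in enumerate(_vec(table, tok.norm)):
            mean[d] += x
    mean = [x / len(ctx) for x in mean]
    dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(tgt, mean)))
    if dist < 1e-12:
        return 1e12
    return 1.0 / dist


def o_all_measures(passage, i, k, table):
    """All six measure values for one target token (None = MISSING)."""
    return {
        "cosine_content": o_cosine_measure(passage, i, k, table, content_only=True),
        "cosine_all": o_cosine_measure(passage, i, k, table, content_only=False),
        "euclidean_sentence": o_euclidean_measure(passage, i, k, table, fixed=False),
        "euclidean_fixed": o_euclidean_measure(passage, i, k, table, fixed=True),
        "dynamic_full": o_dynamic(passage, i, k, table, simpler=False),
        "dynamic_simpler": o_dynamic(passage, i, k, table, simpler=True),
    }
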