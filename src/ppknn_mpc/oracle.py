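"""Plaintext brute-force references for every protocol in the package.

These oracles live in the shipped package (not only in the tests) so the
CLI ``selftest`` can cross-check the MPC stack anywhere:

* ``plaintext_topk``  — sort-based top-k with the index-augmentation tie
  rule, the defining property PE-FTK must reproduce.
* ``plaintext_knn``   — squared-Euclidean kNN voting with the same tie
  rule, the defining property the full classifier must reproduce.
* ``trace_pe_ftk``    — the PE-FTK control flow run on plaintext integers,
  producing the identical public transcript (Cnt sequence, step labels,
  alpha, termination round) at negligible cost.  This is what makes the
  1000-datum bit-round experiments desk-scale.
* ``bench_bitrounds`` — the bit-round experiment: repeated random datasets
  through ``trace_pe_ftk``, reporting the termination-round distribution.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError, TieError
from .field import min_width
from .knn import classify
from .peftk import INDEX_AUGMENT, PEFTKTrace, RoundRecord, STRICT

_NO_COST: dict = {}


def augment_values(values: list[int], n: int | None = None) -> list[int]:
    """The plaintext image of index augmentation: v*2^w + (n - i)."""
    n = len(values) if n is None else n
    w = min_width(n)
    return [(v << w) + (n - i) for i, v in enumerate(values)]


def plaintext_topk(
    values: list[int], k: int, tie_mode: str = INDEX_AUGMENT
) -> list[int]:
    """Indices of the k largest values; ties break toward the lower index
    under index augmentation, and are an error in strict mode."""
    n = len(values)
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    if tie_mode == STRICT and len(set(values)) != n:
        raise TieError("strict mode requires distinct values")
    keyed = augment_values(list(values))
    order = sorted(range(n), key=lambda i: keyed[i], reverse=True)
    return sorted(order[:k])


def plaintext_knn(
    query: list[int],
    features: list[list[int]],
    labels: list[int],
    k: int,
    v: int,
) -> tuple[list[int], int]:
    """kNN class histogram and majority class, with the augmentation tie
    rule (nearer wins; equal distance -> lower record index wins)."""
    dists = [
        sum((int(q) - int(x)) ** 2 for q, x in zip(query, feat))
        for feat in features
    ]
    # smaller distance == larger similarity; reuse the top-k tie rule on
    # negated order by selecting on complemented distances
    max_d = max(dists) if dists else 0
    sims = [max_d - d for d in dists]
    chosen = plaintext_topk(sims, k)
    scores = [0] * v
    for i in chosen:
        scores[labels[i] - 1] += 1
    return scores, classify(scores)


def trace_pe_ftk(
    values: list[int],
    k: int,
    width_l: int | None = None,
    tie_mode: str = INDEX_AUGMENT,
) -> tuple[list[int], PEFTKTrace]:
    """Run the PE-FTK control flow on plaintext integers.

    Returns the selected indices and a trace identical (Cnt sequence, step
    labels, alpha, termination round) to the one the MPC run produces on
    the same inputs.
    """
    n = len(values)
    if n == 0:
        raise ParameterError("empty dataset")
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    if width_l is None:
        width_l = max(1, max(int(v) for v in values).bit_length())
    if max(values) >= 1 << width_l:
        raise ParameterError(f"values do not fit in {width_l} bits")

    vals = list(values)
    if tie_mode == INDEX_AUGMENT:
        vals = augment_values(vals)
        width_l += min_width(n)

    arr = np.asarray(vals, dtype=np.int64)
    res = np.zeros(n, dtype=bool)
    can: np.ndarray | None = None
    trace = PEFTKTrace(mode="plaintext", tie_mode=tie_mode, width_l=width_l,
                       n_data=n, k=k)
    done = False

    for j in range(width_l):
        bit = (arr >> (width_l - 1 - j)) & 1
        if can is None:
            hits = (~res) & (bit == 1)
            cnt = int(res.sum() + hits.sum())
            if cnt == k:
                res |= hits
                step, done = "2-2", True
            elif cnt < k:
                res |= hits
                step = "2-3"
            else:
                can = hits
                step = "2-1"
            part = 1
        else:
            t = can & (bit == 1)
            cnt = int(res.sum() + t.sum())
            if cnt == k:
                res |= t
                step, done = "5-1", True
            elif cnt > k:
                can = t
                step = "5-2"
            else:
                res |= t
                can = can & ~t
                step = "5-3"
            part = 2
        trace.rounds.append(RoundRecord(bit_round=j + 1, part=part, cnt=cnt,
                                        step=step, cost=_NO_COST))
        if done:
            break

    if not done:
        raise TieError(
            "bit positions exhausted before selecting exactly k items"
        )
    return [int(i) for i in np.flatnonzero(res)], trace


def bench_bitrounds(
    n_data: int,
    width_l: int,
    k: int,
    trials: int,
    seed: int = 0,
) -> dict:
    """Termination bit-round distribution on uniform random data.

    Each trial draws ``n_data`` uniform integers in [0, 2^width_l) (with
    index augmentation, so the rare collision is harmless), runs the
    plaintext control-flow trace, and records the termination bit-round
    and the part-1 execution count alpha.
    """
    if trials < 1:
        raise ParameterError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    rounds, alphas = [], []
    for _ in range(trials):
        values = [
            int(x) for x in
            rng.integers(0, 1 << width_l, size=n_data, dtype=np.int64)
        ]
        _, trace = trace_pe_ftk(values, k, width_l=width_l)
        rounds.append(trace.termination_round)
        alphas.append(trace.alpha)
    return {
        "n_data": n_data, "width_l": width_l, "k": k, "trials": trials,
        "seed": seed,
        "bit_rounds": rounds,
        "mean": float(np.mean(rounds)),
        "min": int(np.min(rounds)),
        "max": int(np.max(rounds)),
        "alpha_mean": float(np.mean(alphas)),
    }
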