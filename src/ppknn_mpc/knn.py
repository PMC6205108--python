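"""Privacy-preserving k-nearest-neighbor classification over shared data.

Pipeline (all on shares, no server ever sees plaintext):

1. similarity     — squared Euclidean distance between the shared query
                    and every shared record, one batched multiplication
                    round (n*m invocations).
2. bit conversion — each distance is bit-decomposed and complemented
                    bitwise, mapping distance d to (2^l_sim - 1) - d: a
                    strictly order-reversing transform, so the k *largest*
                    similarities are exactly the k *nearest* records.
3. selection      — PE-FTK marks the k nearest records with shared flags.
4. aggregation    — ck_ij = Res_i * c_ij (one batched round, n*v
                    invocations); scr_j = sum_i ck_ij counts, per class j,
                    how many of the k nearest records carry class j.

The per-class score shares are handed to the inquirer role, the only role
that reconstructs them; the servers never open the scores among
themselves, and every record's shares are touched identically regardless
of the query (uniform access pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import MPCEngine
from .errors import EngineError, ParameterError, RangeError
from .field import min_width
from .peftk import INDEX_AUGMENT, PUBLIC_CNT, PEFTKTrace, TopKFlags, pe_ftk
from .primitives import bit_decompose
from .sharing import BitwiseSharedInt, ShareVector, reconstruct


@dataclass
class SharedRecord:
    """One medical record as the servers see it: m shared symptom features
    plus a shared one-hot class vector (class labels are 1-based; the
    alpha-th bit is 1, all others 0)."""

    features: list[ShareVector]
    class_onehot: list[ShareVector]

    @property
    def m(self) -> int:
        return len(self.features)

    @property
    def v(self) -> int:
        return len(self.class_onehot)


@dataclass
class SharedQuery:
    """The inquirer's shared symptom vector."""

    features: list[ShareVector]

    @property
    def m(self) -> int:
        return len(self.features)


@dataclass
class ScoreVector:
    """The inquirer's reconstructed diagnosis output.

    ``scores[j-1]`` counts how many of the k nearest records carry class j;
    the scores sum to k.  ``predicted_class`` is the (1-based) argmax, ties
    broken toward the lower class index.
    """

    scores: list[int]
    predicted_class: int


def classify(scores: list[int]) -> int:
    """Majority vote: 1-based argmax with lowest-index tie-break."""
    best = max(scores)
    return scores.index(best) + 1


def similarity_width(m: int, feature_bits: int) -> int:
    """Bit width l_sim that holds any squared distance: m*(2^b - 1)^2."""
    return min_width(m * ((1 << feature_bits) - 1) ** 2)


def compute_similarity(
    engine: MPCEngine, query: SharedQuery, record: SharedRecord
) -> ShareVector:
    """Shared squared Euclidean distance sum_j (q_j - d_j)^2.

    One batched multiplication round of m invocations.
    """
    if query.m != record.m:
        raise EngineError(
            f"dimension mismatch: query has {query.m} features, "
            f"record has {record.m}"
        )
    diffs = [engine.sub(q, d) for q, d in zip(query.features, record.features)]
    squares = engine.mul_batch([(d, d) for d in diffs])
    return engine.sum(squares)


def compute_similarities(
    engine: MPCEngine, query: SharedQuery, dataset: list[SharedRecord]
) -> list[ShareVector]:
    """All n distances in a single batched round (n*m invocations)."""
    diffs_per_record = []
    for rec in dataset:
        if rec.m != query.m:
            raise EngineError("dimension mismatch in dataset")
        diffs_per_record.append(
            [engine.sub(q, d) for q, d in zip(query.features, rec.features)]
        )
    flat = [(d, d) for diffs in diffs_per_record for d in diffs]
    squares = engine.mul_batch(flat)
    m = query.m
    return [
        engine.sum(squares[i * m:(i + 1) * m]) for i in range(len(dataset))
    ]


def distance_to_similarity_bits(
    engine: MPCEngine, dist: ShareVector, l_sim: int
) -> BitwiseSharedInt:
    """Bit-decompose a distance and complement every bit.

    The result's value is (2^l_sim - 1) - dist: order-reversing, so
    top-k selection on these similarities yields the k nearest records.
    """
    bits = bit_decompose(engine, dist, l_sim)
    flipped = tuple(engine.const_minus(1, b) for b in bits.bits)
    return BitwiseSharedInt(bits=flipped, width_l=l_sim)


def inquirer_reconstruct(
    engine: MPCEngine, score_shares: list[ShareVector]
) -> list[int]:
    """The inquirer role combines the per-server score shares.

    Modeled as direct reconstruction from the shares the servers hand
    over — not an engine opening, so nothing enters the servers'
    transcript.
    """
    return [reconstruct(sv, engine.field) for sv in score_shares]


@dataclass
class PPkNNResult:
    score_vector: ScoreVector
    flags: TopKFlags
    trace: PEFTKTrace
    report: dict


def ppknn(
    engine: MPCEngine,
    query: SharedQuery,
    dataset: list[SharedRecord],
    k: int,
    l_sim: int,
    mode: str = PUBLIC_CNT,
    tie_mode: str = INDEX_AUGMENT,
) -> PPkNNResult:
    """Full privacy-preserving kNN classification.

    ``l_sim`` is the bit width of the squared distances (use
    :func:`similarity_width`).  Raises :class:`ParameterError` for k out of
    range and propagates PE-FTK's tie error in strict mode.
    """
    n = len(dataset)
    if n == 0:
        raise ParameterError("empty dataset")
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    v = dataset[0].v
    if any(rec.v != v for rec in dataset):
        raise EngineError("records disagree on the number of classes")

    access_log: dict[str, list[int]] = {}

    with engine.phase("similarity"):
        distances = compute_similarities(engine, query, dataset)
    access_log["similarity"] = [rec.m for rec in dataset]

    with engine.phase("bit_decomposition"):
        sims = [
            distance_to_similarity_bits(engine, d, l_sim) for d in distances
        ]
    access_log["bit_decomposition"] = [l_sim] * n

    with engine.phase("pe_ftk"):
        flags, trace = pe_ftk(engine, sims, k, mode=mode, tie_mode=tie_mode)
    # every record participates in every bit-round batch by construction
    access_log["pe_ftk"] = [trace.termination_round] * n

    with engine.phase("aggregation"):
        pairs = [
            (flags.res[i], dataset[i].class_onehot[j])
            for i in range(n)
            for j in range(v)
        ]
        ck = engine.mul_batch(pairs)
        scr_shares = [
            engine.sum([ck[i * v + j] for i in range(n)]) for j in range(v)
        ]
    access_log["aggregation"] = [rec.v for rec in dataset]

    scores = inquirer_reconstruct(engine, scr_shares)
    if sum(scores) != k:
        raise RangeError(
            f"score vector sums to {sum(scores)}, expected k={k}"
        )
    sv = ScoreVector(scores=scores, predicted_class=classify(scores))

    report = {
        "n_data": n, "m": query.m, "v": v, "k": k, "l_sim": l_sim,
        "mode": mode, "tie_mode": tie_mode,
        "phases": engine.phase_report(),
        "counters": engine.counters.snapshot(),
        "per_record_touches": access_log,
    }
    return PPkNNResult(score_vector=sv, flags=flags, trace=trace,
                       report=report)
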