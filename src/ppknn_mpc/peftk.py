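"""PE-FTK: deterministic privacy-preserving selection of the k largest
bitwise-shared values.

The protocol scans all data synchronously from the most significant bit to
the least significant ("bit-rounds").  Each round it forms the shared
counter Cnt = (number of data already selected) + (number of still-eligible
data showing a 1 at the current position) and compares it with the public
parameter k:

part 1 (every datum still eligible):
    Cnt < k   step 2-3: select the data showing a 1; next bit-round.
    Cnt == k  step 2-2: select them and terminate.
    Cnt > k   step 2-1: the data showing a 1 become the candidate set;
              proceed to part 2.

part 2 (only candidates can still be selected):
    Cnt == k  step 5-1: select the candidates showing a 1; terminate.
    Cnt > k   step 5-2: drop candidates showing a 0.
    Cnt < k   step 5-3: select candidates showing a 1; keep those showing 0.

In ``public_cnt`` mode part 1 opens Cnt itself (the documented leakage:
how many data lead at each prefix, never which ones).  In ``private_cnt``
mode part 1 opens only the comparison and equality bits against k.  Part 2
always keeps Cnt and the less-than bit shared and opens only the equality
bit — the minimal public termination signal; the result flags Res_i stay
shared throughout, so no server learns which records were selected.

The selection is deterministic: on distinct inputs the flags mark exactly
the k largest values, with no error probability.  Ties (or an all-zero
value that can never reveal a 1-bit) are the one degenerate case; the
default ``index_augment`` tie mode appends ceil(log2(n+1)) public low-order
index bits to every datum, making all values distinct and strictly
positive with ties broken toward the lower index, while ``strict`` mode
raises :class:`TieError` if the scan exhausts all positions without
selecting exactly k.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .engine import MPCEngine
from .errors import ParameterError, TieError, WidthError
from .field import min_width
from .primitives import bit_decompose, cnt_width, equality, less_than
from .sharing import BitwiseSharedInt, ShareVector

PUBLIC_CNT = "public_cnt"
PRIVATE_CNT = "private_cnt"
STRICT = "strict"
INDEX_AUGMENT = "index_augment"


@dataclass
class TopKFlags:
    """Shared 0/1 indicators [Res_i]; on success exactly k reconstruct to 1."""

    res: list[ShareVector]
    k: int

    def reconstruct(self, engine: MPCEngine) -> list[int]:
        """Audit-side plaintext flags (simulation view, not a server view)."""
        return [engine.audit_reconstruct(sv) for sv in self.res]

    def selected_indices(self, engine: MPCEngine) -> list[int]:
        return [i for i, b in enumerate(self.reconstruct(engine)) if b == 1]


@dataclass
class RoundRecord:
    """Per-bit-round trace row: the Table-style public transcript plus the
    simulation-side audit of the shared counter."""

    bit_round: int  # 1-based
    part: int  # 1 or 2
    cnt: int  # audit value; public in part 1 of public_cnt mode
    step: str  # 2-1 / 2-2 / 2-3 / 5-1 / 5-2 / 5-3
    cost: dict  # engine counter deltas for this round


@dataclass
class PEFTKTrace:
    """Public transcript plus audit trail of one PE-FTK run."""

    rounds: list[RoundRecord] = dc_field(default_factory=list)
    mode: str = PUBLIC_CNT
    tie_mode: str = INDEX_AUGMENT
    width_l: int = 0  # width actually scanned (incl. augmentation bits)
    n_data: int = 0
    k: int = 0

    @property
    def cnt_sequence(self) -> list[int]:
        return [r.cnt for r in self.rounds]

    @property
    def step_labels(self) -> list[str]:
        return [r.step for r in self.rounds]

    @property
    def alpha(self) -> int:
        """Number of part-1 bit-rounds executed."""
        return sum(1 for r in self.rounds if r.part == 1)

    @property
    def part2_rounds(self) -> int:
        return sum(1 for r in self.rounds if r.part == 2)

    @property
    def termination_round(self) -> int:
        return len(self.rounds)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tie_mode": self.tie_mode,
            "n_data": self.n_data,
            "k": self.k,
            "width_l": self.width_l,
            "alpha": self.alpha,
            "part2_rounds": self.part2_rounds,
            "termination_round": self.termination_round,
            "rounds": [
                {"bit_round": r.bit_round, "part": r.part, "cnt": r.cnt,
                 "step": r.step, "cost": r.cost}
                for r in self.rounds
            ],
        }


def augment_for_ties(
    engine: MPCEngine, data: list[BitwiseSharedInt]
) -> list[BitwiseSharedInt]:
    """Append public low-order index bits so all values become distinct.

    Datum i gains w = ceil(log2(n+1)) trailing bits encoding n - i: the map
    v -> v * 2^w + (n - i) preserves the order of distinct values, breaks
    ties toward the lower index, and makes every value strictly positive
    (so everything is selectable).  The appended bits are public constants
    — they encode only the already-public record position.
    """
    n = len(data)
    w = min_width(n)
    out = []
    for i, d in enumerate(data):
        code = n - i
        tail = tuple(
            engine.constant((code >> j) & 1) for j in range(w - 1, -1, -1)
        )
        out.append(
            BitwiseSharedInt(bits=d.bits + tail, width_l=d.width_l + w)
        )
    return out


def pe_ftk(
    engine: MPCEngine,
    data: list[BitwiseSharedInt],
    k: int,
    mode: str = PUBLIC_CNT,
    tie_mode: str = INDEX_AUGMENT,
) -> tuple[TopKFlags, PEFTKTrace]:
    """Select the k largest of n bitwise-shared values.

    Returns the shared result flags and the run trace.  Raises
    :class:`TieError` in strict mode if the scan exhausts every bit
    position without the counter ever hitting k exactly.
    """
    n = len(data)
    if n == 0:
        raise ParameterError("empty dataset")
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    if mode not in (PUBLIC_CNT, PRIVATE_CNT):
        raise ParameterError(f"unknown mode {mode!r}")
    if tie_mode not in (STRICT, INDEX_AUGMENT):
        raise ParameterError(f"unknown tie mode {tie_mode!r}")
    widths = {d.width_l for d in data}
    if len(widths) != 1:
        raise WidthError(f"data widths differ: {sorted(widths)}")

    if tie_mode == INDEX_AUGMENT:
        data = augment_for_ties(engine, data)
    l = data[0].width_l
    w_cnt = cnt_width(n)

    res = [engine.constant(0) for _ in range(n)]
    can: list[ShareVector] | None = None  # None while in part 1
    trace = PEFTKTrace(mode=mode, tie_mode=tie_mode, width_l=l,
                       n_data=n, k=k)
    done = False

    for j in range(l):
        before = engine.counters.snapshot()
        bit_round = j + 1
        bits_j = [d.bits[j] for d in data]

        if can is None:
            # ---- part 1: hit_i = Active_i * bit_ij, one batched round ----
            active = [engine.const_minus(1, r) for r in res]
            hits = engine.mul_batch(list(zip(active, bits_j)))
            cnt_sv = engine.add(engine.sum(res), engine.sum(hits))

            if mode == PUBLIC_CNT:
                cnt = engine.open(cnt_sv, "peftk.part1.cnt")
                lt_pub, eq_pub = cnt < k, cnt == k
            else:
                cnt_bits = bit_decompose(engine, cnt_sv, w_cnt)
                lt_sv = less_than(engine, cnt_bits, k)
                eq_sv = equality(engine, cnt_bits, k)
                lt_pub = engine.open(lt_sv, "peftk.part1.lt") == 1
                eq_pub = engine.open(eq_sv, "peftk.part1.eq") == 1
                cnt = engine.audit_reconstruct(cnt_sv)

            if eq_pub:
                res = [engine.add(r, h) for r, h in zip(res, hits)]
                step, done = "2-2", True
            elif lt_pub:
                res = [engine.add(r, h) for r, h in zip(res, hits)]
                step = "2-3"
            else:
                can = hits
                step = "2-1"
        else:
            # ---- part 2: only the equality bit is ever opened ------------
            t_i = engine.mul_batch(list(zip(can, bits_j)))
            cnt_sv = engine.add(engine.sum(res), engine.sum(t_i))
            cnt = engine.audit_reconstruct(cnt_sv)

            cnt_bits = bit_decompose(engine, cnt_sv, w_cnt)
            lt_sv = less_than(engine, cnt_bits, k)
            eq_sv = equality(engine, cnt_bits, k)
            eq_pub = engine.open(eq_sv, "peftk.part2.eq")

            if eq_pub == 1:
                res = [engine.add(r, t) for r, t in zip(res, t_i)]
                step, done = "5-1", True
            else:
                gt_sv = engine.sub(engine.const_minus(1, lt_sv), eq_sv)
                can_minus_t = [engine.sub(c, t) for c, t in zip(can, t_i)]
                batch = (
                    [(lt_sv, t) for t in t_i]
                    + [(lt_sv, cmt) for cmt in can_minus_t]
                    + [(gt_sv, t) for t in t_i]
                )
                prods = engine.mul_batch(batch)
                inc = prods[:n]
                keep = prods[n:2 * n]
                drop = prods[2 * n:]
                res = [engine.add(r, x) for r, x in zip(res, inc)]
                can = [engine.add(a, b) for a, b in zip(keep, drop)]
                # 5-2 (drop zeros) vs 5-3 (include ones, keep zeros) is not
                # public here; the trace labels it from the audited counter.
                step = "5-2" if cnt > k else "5-3"

        cost = {key: engine.counters.snapshot()[key] - before[key]
                for key in before}
        trace.rounds.append(RoundRecord(bit_round=bit_round,
                                        part=1 if step.startswith("2") else 2,
                                        cnt=cnt, step=step, cost=cost))
        if done:
            break

    if not done:
        # Exhausted every bit position without Cnt ever hitting k.  Under
        # index augmentation this cannot happen (all values distinct, > 0).
        raise TieError(
            "bit positions exhausted before selecting exactly k items; "
            "inputs tie at the selection boundary or an unselectable "
            "all-zero value sits in the top-k (use index_augment tie mode)"
        )

    return TopKFlags(res=res, k=k), trace
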