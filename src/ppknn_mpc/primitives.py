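"""Data-oblivious comparison, equality, and bit decomposition over shares.

These are the building blocks the top-k protocol leans on when it compares
a shared counter against the public parameter k.  The constructions here
are the standard statistically-masked ones:

``bit_decompose``
    Mask the shared secret with a jointly random value (width_l genuine
    shared bits for the low positions plus an arithmetic kappa-bit-per-party
    high mask), open the masked sum — the only opening, and it is within
    statistical distance ~2^-kappa of secret-independent — then recover the
    secret's shared bits with an oblivious binary borrow-subtraction
    circuit against the public masked value.

``less_than`` / ``equality``
    Shared value vs PUBLIC bound, computed on bitwise shares.  Because the
    bound's bits are public, the per-bit match terms are linear; only the
    prefix products (and, for less_than, the final position terms) cost
    multiplications.  Nothing is opened.

``complexity_formulas``
    The reference MPC library's stated costs for comparison and equality as
    functions of the data length l.  These are reporting formulas for
    analytic cost accounting — they describe the cited construction, not
    this module's own instrumentation counters, which the engine reports
    separately.
"""

from __future__ import annotations

from typing import NamedTuple

from .engine import MPCEngine
from .errors import RangeError
from .field import min_width
from .sharing import BitwiseSharedInt, ShareVector


class ComplexityFormulas(NamedTuple):
    cmp_mults: int
    cmp_rounds: int
    eq_mults: int
    eq_rounds: int


def complexity_formulas(l: int) -> ComplexityFormulas:
    """Stated costs of the reference comparison/equality protocols.

    Comparison: 24l + 5 multiplications in 2l + 10 rounds.
    Equality:   l + 1 multiplications in l rounds.
    """
    if l < 1:
        raise RangeError("data length l must be >= 1")
    return ComplexityFormulas(
        cmp_mults=24 * l + 5,
        cmp_rounds=2 * l + 10,
        eq_mults=l + 1,
        eq_rounds=l,
    )


def bit_decompose(
    engine: MPCEngine, a: ShareVector, width_l: int
) -> BitwiseSharedInt:
    """Decompose an arithmetic sharing into shared bits (MSB first).

    Requires reconstruct(a) < 2^width_l and a field large enough to hold
    the masked sum (see :meth:`FieldConfig.check_maskable_width`).
    """
    field = engine.field
    field.check_maskable_width(width_l)
    p = field.p

    # Low mask: width_l jointly random shared bits; high mask: per-party
    # kappa-bit uniform draws.  r = r_low + 2^l * r_high.
    r_bits_lsb = engine.random_shared_bits(width_l)  # index j = weight 2^j
    r_low = engine.constant(0)
    for j, rb in enumerate(r_bits_lsb):
        r_low = engine.add(r_low, engine.const_mul(1 << j, rb))
    r_high = engine.random_bounded_value(field.kappa)

    masked = engine.add(engine.add(a, r_low),
                        engine.const_mul(1 << width_l, r_high))
    c = engine.open(masked, "bd.masked_open", kind="masked")

    # a = c - r exactly over the integers, so the low width_l bits of a are
    # the low bits of (c - r_low) mod 2^width_l: an oblivious borrow
    # subtractor over the low width_l positions, LSB upward.  Public c bits
    # keep every step linear except the r_j * borrow product.
    bits_lsb: list[ShareVector] = []
    borrow: ShareVector | None = None
    for j in range(width_l):
        cj = (c >> j) & 1
        rj = r_bits_lsb[j]
        if borrow is None:
            x = rj  # r_j XOR borrow with borrow = 0
            new_borrow = rj if cj == 0 else engine.constant(0)
        else:
            rb = engine.mul(rj, borrow)
            # x = r_j XOR borrow
            x = engine.sub(engine.add(rj, borrow), engine.const_mul(2, rb))
            if cj == 1:
                new_borrow = rb  # r_j AND borrow
            else:
                new_borrow = engine.sub(engine.add(rj, borrow), rb)  # OR
        diff = engine.const_minus(1, x) if cj == 1 else x  # c_j XOR x
        bits_lsb.append(diff)
        borrow = new_borrow

    return BitwiseSharedInt(bits=tuple(reversed(bits_lsb)), width_l=width_l)


def _as_bits(
    engine: MPCEngine,
    a: ShareVector | BitwiseSharedInt,
    width_l: int | None,
) -> BitwiseSharedInt:
    if isinstance(a, BitwiseSharedInt):
        return a
    if width_l is None:
        raise RangeError(
            "width_l is required when comparing an arithmetic sharing"
        )
    return bit_decompose(engine, a, width_l)


def _match_terms(
    engine: MPCEngine, bits: BitwiseSharedInt, b: int
) -> list[ShareVector]:
    """Per-position agreement bits against a public bound (MSB first).

    match_i = a_i when b_i = 1, else 1 - a_i; linear because b is public.
    """
    l = bits.width_l
    out = []
    for idx, a_bit in enumerate(bits.bits):  # idx 0 = MSB
        b_bit = (b >> (l - 1 - idx)) & 1
        out.append(a_bit if b_bit == 1 else engine.const_minus(1, a_bit))
    return out


def _product_tree(engine: MPCEngine, terms: list[ShareVector]) -> ShareVector:
    """Multiply shared bits in a logarithmic-depth tree of batched rounds."""
    layer = list(terms)
    while len(layer) > 1:
        pairs = [(layer[i], layer[i + 1]) for i in range(0, len(layer) - 1, 2)]
        prods = engine.mul_batch(pairs)
        if len(layer) % 2:
            prods.append(layer[-1])
        layer = prods
    return layer[0] if layer else engine.constant(1)


def equality(
    engine: MPCEngine,
    a: ShareVector | BitwiseSharedInt,
    b: int,
    width_l: int | None = None,
) -> ShareVector:
    """Shared bit [a == b] for a public bound b; nothing is opened."""
    bits = _as_bits(engine, a, width_l)
    if not 0 <= b <= (1 << bits.width_l):
        raise RangeError(f"bound {b} outside [0, 2^{bits.width_l}]")
    if b == 1 << bits.width_l:
        return engine.constant(0)  # a < 2^l always
    return _product_tree(engine, _match_terms(engine, bits, b))


def less_than(
    engine: MPCEngine,
    a: ShareVector | BitwiseSharedInt,
    b: int,
    width_l: int | None = None,
) -> ShareVector:
    """Shared bit [a < b] for a public bound b; nothing is opened.

    a < b iff at some position j the bound has a 1 where a has a 0 and all
    more significant positions agree.  Prefix agreement products are built
    sequentially; the position terms are combined in one batched round.
    """
    bits = _as_bits(engine, a, width_l)
    l = bits.width_l
    if not 0 <= b <= (1 << l):
        raise RangeError(f"bound {b} outside [0, 2^{l}]")
    if b == 0:
        return engine.constant(0)
    if b == 1 << l:
        return engine.constant(1)

    matches = _match_terms(engine, bits, b)
    # prefix[idx] = product of matches for positions strictly above idx
    prefix: list[ShareVector] = [engine.constant(1)]
    for idx in range(1, l):
        prefix.append(engine.mul(prefix[-1], matches[idx - 1]))

    term_pairs = []
    for idx in range(l):  # idx 0 = MSB
        if (b >> (l - 1 - idx)) & 1:
            not_a = engine.const_minus(1, bits.bits[idx])
            term_pairs.append((prefix[idx], not_a))
    terms = engine.mul_batch(term_pairs)
    return engine.sum(terms)


def cnt_width(n_data: int) -> int:
    """Smallest bit width holding a counter in [0, n_data]."""
    return min_width(n_data)
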