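"""Shamir secret sharing: the input-sharing and output-reconstruction phases.

A secret s in Z_p is hidden in a random polynomial f_s of degree <= t with
f_s(0) = s; party i holds f_s(alpha_i).  Any t shares are jointly uniform
(independent of s); any t+1 determine s.  A ``BitwiseSharedInt`` is simply
one such sharing per bit of an integer, most significant bit first — the
representation the bit-scanning top-k protocol consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSharesError, RangeError, WidthError
from .field import FieldConfig, lagrange_coefficients


@dataclass(frozen=True)
class ShareVector:
    """All parties' shares of one secret, with the polynomial degree bound.

    ``shares[i]`` is f(alpha_{i+1}); ``degree_bound`` is the largest degree
    the sharing polynomial may have, which determines how many shares a
    reconstruction needs (degree_bound + 1).
    """

    shares: tuple[int, ...]
    degree_bound: int

    @property
    def n_parties(self) -> int:
        return len(self.shares)


@dataclass(frozen=True)
class BitwiseSharedInt:
    """A width_l-bit integer shared bit by bit, most significant bit first."""

    bits: tuple[ShareVector, ...]
    width_l: int

    def __post_init__(self):
        if len(self.bits) != self.width_l:
            raise WidthError(
                f"got {len(self.bits)} bit sharings for width {self.width_l}"
            )


def _eval_poly(coeffs: list[int], x: int, p: int) -> int:
    """Horner evaluation of sum_i coeffs[i] * x^i (mod p)."""
    acc = 0
    for c in reversed(coeffs):
        acc = (acc * x + c) % p
    return acc


def share(
    secret: int,
    t: int,
    field: FieldConfig,
    rng: np.random.Generator,
) -> ShareVector:
    """Share ``secret`` with a fresh random polynomial of degree <= t."""
    n = field.n_parties
    if not 0 <= secret < field.p:
        raise RangeError(f"secret {secret} outside [0, p)")
    if not 0 <= t <= n - 1:
        raise RangeError(f"threshold t={t} outside [0, n_parties-1]")
    coeffs = [secret % field.p]
    if t > 0:
        coeffs += [int(c) for c in rng.integers(0, field.p, size=t)]
    shares = tuple(_eval_poly(coeffs, a, field.p) for a in field.eval_points)
    return ShareVector(shares=shares, degree_bound=t)


def reconstruct(
    sv: ShareVector,
    field: FieldConfig,
    subset: tuple[int, ...] | list[int] | None = None,
) -> int:
    """Interpolate the sharing polynomial at 0 from a subset of parties.

    ``subset`` holds 0-based party indices; by default all parties
    contribute.  Offering fewer than degree_bound + 1 shares raises
    :class:`InsufficientSharesError` — a threshold violation must never
    produce a wrong value silently.
    """
    idx = tuple(range(sv.n_parties)) if subset is None else tuple(subset)
    if len(set(idx)) != len(idx):
        raise InsufficientSharesError("duplicate party indices in subset")
    if len(idx) < sv.degree_bound + 1:
        raise InsufficientSharesError(
            f"{len(idx)} shares cannot reconstruct a degree-"
            f"{sv.degree_bound} sharing (need {sv.degree_bound + 1})"
        )
    points = tuple(field.eval_points[i] for i in idx)
    lam = lagrange_coefficients(points, 0, field.p)
    return sum(l * sv.shares[i] for l, i in zip(lam, idx)) % field.p


def share_bitwise(
    secret: int,
    width_l: int,
    t: int,
    field: FieldConfig,
    rng: np.random.Generator,
) -> BitwiseSharedInt:
    """Share each bit of ``secret`` separately (MSB first)."""
    if not 0 <= secret < (1 << width_l):
        raise WidthError(f"secret {secret} does not fit in {width_l} bits")
    bits = tuple(
        share((secret >> j) & 1, t, field, rng)
        for j in range(width_l - 1, -1, -1)
    )
    return BitwiseSharedInt(bits=bits, width_l=width_l)


def reconstruct_bitwise(bsi: BitwiseSharedInt, field: FieldConfig) -> int:
    """Recombine a bitwise sharing into the plaintext integer (audit aid)."""
    value = 0
    for bit_sv in bsi.bits:
        b = reconstruct(bit_sv, field)
        if b not in (0, 1):
            raise RangeError(f"bit share reconstructed to non-bit value {b}")
        value = (value << 1) | b
    return value
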