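"""Prime-field arithmetic and Lagrange interpolation.

Everything above this layer — Shamir sharing, the multiplication protocol's
degree reduction, output reconstruction — reduces to evaluating and
interpolating polynomials over Z_p.  The field is deliberately boring:
elements are plain Python integers in [0, p), the default modulus is the
Mersenne prime 2^61 - 1 (large enough to statistically mask every bit width
the protocols use at desk scale, small enough that arithmetic stays fast),
and party i evaluates at alpha_i = i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import sympy

from .errors import FieldConfigError

#: Default prime modulus.  2^61 - 1 is prime and congruent to 3 (mod 4),
#: so modular square roots (needed for joint random-bit generation) are a
#: single exponentiation.
DEFAULT_PRIME = 2**61 - 1

#: Default statistical masking parameter, in bits.  Masked openings inside
#: bit decomposition are within statistical distance ~2^-kappa of a
#: distribution independent of the secret.
DEFAULT_KAPPA = 40


@dataclass(frozen=True)
class FieldConfig:
    """A prime field plus the public evaluation points of the parties.

    Parameters
    ----------
    p:
        Prime modulus.
    eval_points:
        Distinct nonzero field elements alpha_1..alpha_n, one per party.
    kappa:
        Statistical masking parameter in bits (see :mod:`.primitives`).
    """

    p: int = DEFAULT_PRIME
    eval_points: tuple[int, ...] = dc_field(default_factory=tuple)
    kappa: int = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if not sympy.isprime(self.p):
            raise FieldConfigError(f"modulus {self.p} is not prime")
        if self.kappa < 1:
            raise FieldConfigError("kappa must be positive")
        pts = tuple(int(a) for a in self.eval_points)
        if len(set(pts)) != len(pts):
            raise FieldConfigError("evaluation points must be distinct")
        for a in pts:
            if not 0 < a < self.p:
                raise FieldConfigError(
                    f"evaluation point {a} outside (0, p); points must be "
                    "nonzero field elements"
                )
        object.__setattr__(self, "eval_points", pts)

    @classmethod
    def for_parties(
        cls, n_parties: int, p: int = DEFAULT_PRIME, kappa: int = DEFAULT_KAPPA
    ) -> "FieldConfig":
        """Canonical configuration: alpha_i = i for i = 1..n_parties."""
        return cls(p=p, eval_points=tuple(range(1, n_parties + 1)), kappa=kappa)

    @property
    def n_parties(self) -> int:
        return len(self.eval_points)

    def check_maskable_width(self, width_l: int) -> None:
        """Ensure ``p`` can hold a masked ``width_l``-bit opening.

        The masked sum inside bit decomposition is bounded by
        ``2^l * (2 + n * 2^kappa)`` (low random bits, the secret itself, and
        an n-party sum of kappa-bit uniform draws), which must stay below p
        so the opening is an exact integer, not a field wraparound.
        """
        bound = (1 << width_l) * (2 + self.n_parties * (1 << self.kappa))
        if bound >= self.p:
            raise FieldConfigError(
                f"width {width_l} with kappa={self.kappa} and "
                f"{self.n_parties} parties needs a prime > {bound}; "
                f"p={self.p} is too small"
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"prime": self.p, "eval_points": list(self.eval_points),
                "kappa": self.kappa}

    @classmethod
    def from_dict(cls, d: dict) -> "FieldConfig":
        return cls(p=int(d["prime"]),
                   eval_points=tuple(int(a) for a in d["eval_points"]),
                   kappa=int(d.get("kappa", DEFAULT_KAPPA)))


def lagrange_coefficients(
    points: tuple[int, ...] | list[int], target: int, p: int
) -> tuple[int, ...]:
    """Interpolation coefficients (the public recombination vector).

    Returns c_1..c_m such that for every polynomial f of degree < m,
    sum_j c_j * f(points_j) == f(target) in Z_p.  With target = 0 this is
    the recombination vector lambda used for reconstruction and for the
    degree-reduction step of share multiplication.
    """
    pts = [x % p for x in points]
    if len(set(pts)) != len(pts):
        raise FieldConfigError("duplicate interpolation points")
    tgt = target % p
    coeffs = []
    for j, xj in enumerate(pts):
        num, den = 1, 1
        for i, xi in enumerate(pts):
            if i == j:
                continue
            num = num * ((tgt - xi) % p) % p
            den = den * ((xj - xi) % p) % p
        coeffs.append(num * pow(den, p - 2, p) % p)
    return tuple(coeffs)


def sqrt_mod(a: int, p: int) -> int:
    """A square root of a quadratic residue a modulo the prime p."""
    a %= p
    if a == 0:
        return 0
    if p % 4 == 3:
        return pow(a, (p + 1) // 4, p)
    root = sympy.ntheory.sqrt_mod(a, p)
    if root is None:
        raise ValueError(f"{a} is not a quadratic residue mod {p}")
    return int(root)


def min_width(value: int) -> int:
    """Number of bits needed to represent values in [0, value]."""
    return max(1, math.ceil(math.log2(value + 1)))
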