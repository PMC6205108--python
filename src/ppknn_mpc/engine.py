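"""Simulated n-server MPC engine: the computation phase.

All n_parties cloud servers live inside one process.  Linear operations
(addition, subtraction, multiplication by public constants) are local and
free of communication.  Multiplying two sharings costs one communication
round: each party locally multiplies its shares, reshares the product with
a fresh degree-t polynomial, and everyone recombines with the public
Lagrange recombination vector — the classic degree-reduction step, which
requires 2t + 1 <= n_parties.

Instrumentation is first-class: the engine counts multiplication
invocations, multiplication rounds (a batch of independent products costs
one round), openings, sharings, and simulated point-to-point messages, and
records every opened public value in an ordered transcript.  Transcript
entries are classified by what the value can reveal:

``output``
    A protocol-level public value (a reconstructed counter, an opened
    equality bit).  The leakage audits operate on this class.
``masked``
    A value opened under a statistical mask (bit decomposition's masked
    sum); its distribution is independent of the secret up to ~2^-kappa.
``preprocessing``
    Input-independent randomness-generation openings (the r^2 opening of
    joint random-bit generation).

This is a protocol-correctness artifact, not a hardened deployment: there
are no sockets, no TLS, and no attempt at constant-time arithmetic.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import EngineError, RandomnessError
from .field import FieldConfig, lagrange_coefficients, sqrt_mod
from .sharing import ShareVector, share, reconstruct

_MAX_BIT_RETRIES = 64


@dataclass(frozen=True)
class TranscriptEntry:
    label: str
    value: int
    kind: str  # "output" | "masked" | "preprocessing"
    index: int  # position in the transcript


@dataclass
class Counters:
    mult_invocations: int = 0
    mult_rounds: int = 0
    openings: int = 0
    sharings: int = 0
    messages: int = 0

    def snapshot(self) -> dict:
        return {
            "mult_invocations": self.mult_invocations,
            "mult_rounds": self.mult_rounds,
            "openings": self.openings,
            "sharings": self.sharings,
            "messages": self.messages,
        }


@dataclass
class _Phase:
    name: str
    start: dict
    end: dict | None = None

    @property
    def delta(self) -> dict:
        end = self.end or self.start
        return {k: end[k] - self.start[k] for k in self.start}


class MPCEngine:
    """n_parties simulated servers sharing one field configuration.

    One master seed expands (via ``numpy.random.SeedSequence``) into one
    dealer generator (used for input sharing) plus one generator per party
    (used for resharing and joint randomness), so every run is reproducible
    from the seed alone.
    """

    def __init__(
        self,
        n_parties: int = 5,
        threshold: int | None = None,
        field: FieldConfig | None = None,
        seed: int = 0,
    ):
        if n_parties < 2:
            raise EngineError("need at least 2 parties")
        t = (n_parties - 1) // 2 if threshold is None else threshold
        if t < 0 or 2 * t + 1 > n_parties:
            raise EngineError(
                f"threshold t={t} incompatible with n={n_parties}: "
                "multiplication degree reduction needs 2t+1 <= n"
            )
        self.n_parties = n_parties
        self.t = t
        self.field = field or FieldConfig.for_parties(n_parties)
        if self.field.n_parties != n_parties:
            raise EngineError(
                "field has evaluation points for "
                f"{self.field.n_parties} parties, engine has {n_parties}"
            )
        children = np.random.SeedSequence(seed).spawn(n_parties + 1)
        self._dealer_rng = np.random.default_rng(children[0])
        self._party_rngs = [np.random.default_rng(c) for c in children[1:]]
        self.counters = Counters()
        self.transcript: list[TranscriptEntry] = []
        self._phases: list[_Phase] = []
        # recombination vector over all parties, target 0 (public)
        self._lambda = lagrange_coefficients(self.field.eval_points, 0, self.field.p)

    # -- constants and input sharing --------------------------------------
    def constant(self, c: int) -> ShareVector:
        """The trivial degree-0 sharing of a public constant."""
        c %= self.field.p
        return ShareVector(shares=(c,) * self.n_parties, degree_bound=0)

    def share_secret(self, value: int, t: int | None = None) -> ShareVector:
        """Dealer-side input sharing using the engine's dealer randomness."""
        t = self.t if t is None else t
        sv = share(value, t, self.field, self._dealer_rng)
        self.counters.sharings += 1
        self.counters.messages += self.n_parties
        return sv

    # -- local linear operations (no communication) ------------------------
    def _check(self, *svs: ShareVector) -> None:
        for sv in svs:
            if sv.n_parties != self.n_parties:
                raise EngineError(
                    f"share vector for {sv.n_parties} parties fed to an "
                    f"engine with {self.n_parties}"
                )

    def add(self, a: ShareVector, b: ShareVector) -> ShareVector:
        self._check(a, b)
        p = self.field.p
        return ShareVector(
            shares=tuple((x + y) % p for x, y in zip(a.shares, b.shares)),
            degree_bound=max(a.degree_bound, b.degree_bound),
        )

    def sub(self, a: ShareVector, b: ShareVector) -> ShareVector:
        self._check(a, b)
        p = self.field.p
        return ShareVector(
            shares=tuple((x - y) % p for x, y in zip(a.shares, b.shares)),
            degree_bound=max(a.degree_bound, b.degree_bound),
        )

    def add_const(self, a: ShareVector, c: int) -> ShareVector:
        self._check(a)
        p = self.field.p
        c %= p
        return ShareVector(
            shares=tuple((x + c) % p for x in a.shares),
            degree_bound=a.degree_bound,
        )

    def const_mul(self, c: int, a: ShareVector) -> ShareVector:
        self._check(a)
        p = self.field.p
        c %= p
        return ShareVector(
            shares=tuple(c * x % p for x in a.shares),
            degree_bound=a.degree_bound,
        )

    def const_minus(self, c: int, a: ShareVector) -> ShareVector:
        """Sharing of c - a for public c (used for NOT on shared bits)."""
        return self.sub(self.constant(c), a)

    def sum(self, svs: list[ShareVector]) -> ShareVector:
        if not svs:
            return self.constant(0)
        acc = svs[0]
        for sv in svs[1:]:
            acc = self.add(acc, sv)
        return acc

    # -- multiplication (one communication round per batch) ----------------
    def mul_batch(
        self, pairs: list[tuple[ShareVector, ShareVector]]
    ) -> list[ShareVector]:
        """Multiply independent share pairs in a single parallel round.

        Each party multiplies locally, reshares its product point with a
        fresh degree-t polynomial, and recombines the received shares with
        the public recombination vector.  Accounting: one multiplication
        round per batch, one invocation per pair.
        """
        if not pairs:
            return []
        n, t, p = self.n_parties, self.t, self.field.p
        if 2 * t >= n:
            raise EngineError("degree overflow: 2t >= n_parties")
        lam = self._lambda
        results = []
        for a, b in pairs:
            self._check(a, b)
            if a.degree_bound > t or b.degree_bound > t:
                raise EngineError(
                    "multiplication operands must have degree <= t "
                    f"(got {a.degree_bound}, {b.degree_bound})"
                )
            # party j's local product, reshared among all parties
            reshares = [
                share(a.shares[j] * b.shares[j] % p, t, self.field,
                      self._party_rngs[j]).shares
                for j in range(n)
            ]
            new_shares = tuple(
                sum(lam[j] * reshares[j][i] for j in range(n)) % p
                for i in range(n)
            )
            results.append(ShareVector(shares=new_shares, degree_bound=t))
        self.counters.mult_invocations += len(pairs)
        self.counters.mult_rounds += 1
        self.counters.sharings += n * len(pairs)
        self.counters.messages += n * (n - 1) * len(pairs)
        return results

    def mul(self, a: ShareVector, b: ShareVector) -> ShareVector:
        return self.mul_batch([(a, b)])[0]

    # -- openings -----------------------------------------------------------
    def open(self, sv: ShareVector, label: str, kind: str = "output") -> int:
        """All parties exchange shares and reconstruct a public value.

        The value joins the transcript under ``label`` with the given
        leakage class.
        """
        if kind not in ("output", "masked", "preprocessing"):
            raise EngineError(f"unknown transcript kind {kind!r}")
        self._check(sv)
        value = sum(l * s for l, s in zip(self._lambda, sv.shares)) % self.field.p
        self.counters.openings += 1
        self.counters.messages += self.n_parties * (self.n_parties - 1)
        self.transcript.append(
            TranscriptEntry(label=label, value=value, kind=kind,
                            index=len(self.transcript))
        )
        return value

    def audit_reconstruct(self, sv: ShareVector) -> int:
        """Reconstruct a value outside the protocol (simulation-side audit).

        This models the experimenter's God's-eye view of the simulation,
        not a message any server ever sees; it leaves no transcript entry
        and touches no counter.
        """
        return reconstruct(sv, self.field)

    # -- joint randomness ----------------------------------------------------
    def random_shared_values(self, count: int) -> list[ShareVector]:
        """Uniform random shared field elements unknown to every party.

        Each party shares a uniform draw; the sum is uniform as long as at
        least one party is honest.
        """
        n, p = self.n_parties, self.field.p
        out = []
        for _ in range(count):
            acc = None
            for j in range(n):
                contrib = share(
                    int(self._party_rngs[j].integers(0, p)),
                    self.t, self.field, self._party_rngs[j],
                )
                acc = contrib if acc is None else ShareVector(
                    shares=tuple((x + y) % p
                                 for x, y in zip(acc.shares, contrib.shares)),
                    degree_bound=self.t,
                )
            out.append(acc)
        self.counters.sharings += n * count
        self.counters.messages += n * (n - 1) * count
        return out

    def random_bounded_value(self, bits: int) -> ShareVector:
        """A shared random integer, each party contributing a uniform
        ``bits``-bit draw (sum < n * 2^bits).  Used as the statistical high
        mask in bit decomposition."""
        n = self.n_parties
        acc = None
        for j in range(n):
            contrib = share(
                int(self._party_rngs[j].integers(0, 1 << bits)),
                self.t, self.field, self._party_rngs[j],
            )
            acc = contrib if acc is None else self.add(acc, contrib)
        self.counters.sharings += n
        self.counters.messages += n * (n - 1)
        return acc

    def random_shared_bits(self, count: int) -> list[ShareVector]:
        """Jointly generated uniform shared bits, unknown to every party.

        Classic construction: share a random r, open r^2 (input-independent
        preprocessing), and set b = (r / sqrt(r^2) + 1) / 2, which is 0 or 1
        with equal probability.  Degenerate r = 0 draws are retried.
        """
        p = self.field.p
        inv2 = pow(2, p - 2, p)
        bits: list[ShareVector] = []
        attempts = 0
        while len(bits) < count:
            attempts += 1
            if attempts > _MAX_BIT_RETRIES:
                raise RandomnessError(
                    "random bit generation kept drawing degenerate values"
                )
            need = count - len(bits)
            rs = self.random_shared_values(need)
            squares = self.mul_batch([(r, r) for r in rs])
            for r, sq in zip(rs, squares):
                r2 = self.open(sq, "rand.square", kind="preprocessing")
                if r2 == 0:
                    continue
                s_inv = pow(sqrt_mod(r2, p), p - 2, p)
                # r * s^-1 is +/-1; map to {0,1}
                pm1 = self.const_mul(s_inv, r)
                bits.append(self.const_mul(inv2, self.add_const(pm1, 1)))
        return bits

    def random_shared_bit(self) -> ShareVector:
        return self.random_shared_bits(1)[0]

    # -- instrumentation ------------------------------------------------------
    @contextlib.contextmanager
    def phase(self, name: str):
        """Record counter deltas attributed to a named protocol phase."""
        ph = _Phase(name=name, start=self.counters.snapshot())
        self._phases.append(ph)
        try:
            yield
        finally:
            ph.end = self.counters.snapshot()

    def phase_report(self) -> dict:
        report: dict[str, dict] = {}
        for ph in self._phases:
            if ph.name not in report:
                report[ph.name] = {k: 0 for k in ph.start}
            for k, v in ph.delta.items():
                report[ph.name][k] += v
        return report

    def transcript_dump(self) -> list[dict]:
        """Transcript as JSON-serializable records."""
        return [
            {"index": e.index, "label": e.label, "value": e.value,
             "kind": e.kind}
            for e in self.transcript
        ]
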