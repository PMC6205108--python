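# Methods

This note documents the models, protocol realizations, numerical choices,
and limitations behind `ppknn_mpc`. Notation: n servers, corruption
threshold t, prime field Z_p, data bit width l, dataset size n_data,
feature count m, class count v.

## Security model and what the simulation is

The stack simulates semi-honest n-party MPC over Shamir shares inside one
process. "Communication" is explicit share exchange between simulated
party objects, with message, round, and invocation counters, so protocol
costs and the public transcript are auditable; there is no networking,
no malicious-adversary protection, and no constant-time arithmetic. The
simulation is a protocol-correctness and leakage-accounting artifact, not
a hardened deployment.

Roles: data owners (hospitals) share their records and never interact
with each other; servers compute only on shares; the inquirer shares the
query and is the only role that reconstructs the score vector — the
servers hand over score *shares* and never open them among themselves.

## Field and sharing layer

* Default modulus p = 2^61 − 1 (Mersenne, ≡ 3 mod 4 so square roots are
  one `pow`); evaluation points α_i = i. Elements are Python ints in
  [0, p) — unambiguous serialization, no balanced representation.
* Default threshold t = ⌊(n−1)/2⌋, the largest for which one-round
  multiplication (degree reduction 2t → t via the public Lagrange
  recombination vector) is possible.
* Bitwise sharings store the most significant bit first, matching the
  scan direction of the selection protocol; share CSVs document this.
* Reconstruction with fewer than degree_bound+1 shares raises — a
  threshold violation is a visible error, never a silently wrong value.

## Round and invocation accounting

One multiplication *round* = one `mul_batch` call (any number of
independent products in parallel); sequential dependent products cost
additional rounds. Openings are counted separately. The accounting is
what the instrumentation reports; the analytic formulas below are not
asserted against it.

`complexity_formulas(l)` returns the reference comparison/equality
library costs — (24l+5 multiplications, 2l+10 rounds) and
(l+1 multiplications, l rounds) — used for analytic cost reporting.
This package's own primitives are deliberately simpler constructions
with different (unoptimized) counts; reproducing the cited library's
exact counts is a non-goal.

## Primitive realizations

**Joint random bits** — each party shares a uniform value; the sum r is
uniform. Open r² (input-independent), take the canonical square root s,
and b = (r·s^(−1) + 1)/2 is a uniform shared bit. r = 0 draws are
retried, bounded at 64 attempts.

**Bit decomposition** (width l, masking parameter κ, default 40) —
generate l joint random shared bits r_0..r_{l−1} and an arithmetic high
mask R as the sum of per-party uniform κ-bit draws; open
c = a + Σ 2^j r_j + 2^l R. Since a < 2^l, the low l bits of a equal the
low l bits of (c − Σ 2^j r_j), recovered by an oblivious borrow
subtractor: with c's bits public, each position costs one multiplication
(r_j·borrow). The single opening is within statistical distance ~n·2^(−κ)
of a secret-independent distribution. Feasibility requires
p > 2^l·(2 + n·2^κ), enforced at call time; with the defaults this allows
widths up to 16 bits, ample for distance values and counters at desk
scale (and the selection protocol itself never decomposes its l-bit
inputs — only counters of width ⌈log2(n_data+1)⌉).

**Comparison/equality against a public bound** — computed on bitwise
shares. The bound's bits are public, so per-position match terms are
linear; equality is one log-depth product tree, less-than is a sequential
prefix-product chain plus one batched round of boundary terms. Nothing is
opened. An arithmetic operand is first bit-decomposed at the smallest
sufficient width.

## PE-FTK control flow

Part 1, per bit-round j (MSB→LSB), with Active_i = 1 − Res_i:

    [hit_i] = [Active_i]·[bit_{i,j}]          (one batch, n invocations)
    [Cnt]   = Σ[Res_i] + Σ[hit_i]
    Cnt < k  → fold hits into Res, continue      (step 2-3)
    Cnt == k → fold hits into Res, terminate     (step 2-2)
    Cnt > k  → Can := hits, enter part 2         (step 2-1)

Part 2, per bit-round:

    [t_i]  = [Can_i]·[bit_{i,j}] ;  [Cnt] = Σ[Res_i] + Σ[t_i]
    [lt] = [Cnt < k], [eq] = [Cnt == k] ; open eq only
    eq = 1 → Res_i += t_i, terminate             (step 5-1)
    else, obliviously with [gt] = 1 − [lt] − [eq]:
        Res_i += [lt]·[t_i]
        Can_i  = [lt]·([Can_i] − [t_i]) + [gt]·[t_i]

Design choices that were genuinely open:

* **Part-2 branch secrecy.** Only the equality bit is opened — the
  minimal public termination signal; the less-than bit stays shared and
  drives the oblivious updates. Consequently the 5-2/5-3 step labels in
  the trace are filled from the simulation-side audit reconstruction of
  Cnt, not from anything a server sees.
* **Per-element part-2 cost.** This formulation uses 4 multiplication
  invocations per element per bit-round (t, lt·t, lt·(Can−t), gt·t) in
  3 dependent rounds plus the comparison/equality primitives; the counts
  are reported by instrumentation, not asserted to match any external
  figure.
* **Private-counter variant.** Part 1 can avoid opening Cnt: one
  comparison and one equality per bit-round, opening only the two
  relation bits. Selection output is identical; only the transcript
  changes.
* **Ties and zeros.** A value with no 1-bit can never be selected, and a
  tie at the selection boundary would exhaust the scan. Default
  `index_augment` mode appends w = ⌈log2(n+1)⌉ public low-order bits
  encoding n − i: all values become distinct, strictly positive, and
  order-preserving with ties broken toward the lower index. `strict` mode
  instead raises a tie error that names no values. Exhaustion is detected
  from already-public information (the final branch outcome), so the
  error itself leaks nothing new.

## Leakage accounting

Transcript entries carry a class: `output` (protocol-level public
values), `masked` (the single statistically masked opening per bit
decomposition), `preprocessing` (input-independent r² openings). The
documented leakage of a selection run is exactly: part-1 counters (public
mode) or part-1 relation bits (private mode), part-2 equality bits, and
the public termination round. The audit tests assert the `output` class
equals this set, and a chi-square test checks empirically that the masked
openings are distributed independently of the secret. Access-pattern
privacy is structural — every record participates in every batch of every
phase — and is asserted on the per-record touch counts in the run report.

## kNN pipeline choices

* **Similarity orientation.** The selection protocol takes the *largest*
  values; nearest neighbors have the *smallest* distance. Distances of
  width l_sim = ⌈log2(m·(2^b−1)² + 1)⌉ are bit-decomposed and every bit
  complemented, i.e. d ↦ 2^l_sim − 1 − d: exact order reversal with zero
  extra arithmetic width.
* **Tie rules.** Boundary ties inherit index augmentation (lower record
  id wins); the final argmax breaks ties toward the lower class index.
  Both rules exist for determinism and are mirrored exactly in the
  plaintext oracle.
* Features are non-negative integers (quantized); real-valued features
  must be pre-scaled by the user. Labels are 1-based, record ids 0-based.

## Synthetic data generator

`SynthConfig` emulates a small multi-hospital case library: per-class
cluster centers in symptom space (default: evenly spaced along the
feature range), integer-rounded Gaussian noise with spread 1 quantization
step, clipped to [0, 2^b); labels assigned round-robin then shuffled so
every class is populated. Defaults (n=30, m=4, v=3, b=4) keep full MPC
runs fast while exercising multi-class voting. What it does **not**
model: correlated symptoms, class imbalance, measurement noise structure,
or realistic feature scales — passing tests show protocol correctness
(MPC output ≡ plaintext kNN on the same data), not clinical accuracy on
real records.

## Problem sizes used in the checks

The exhaustive selection sweep covers every 5-element subset of [0,16)
at every k (21 840 full MPC runs); the end-to-end classifier check runs
50 seeded synthetic libraries at k ∈ {1,3,5}; the bit-round experiment
uses the plaintext control-flow trace (provably transcript-identical to
the MPC run, and tested as such) at n_data = 1000, l = 33, k = 100 over
30 trials, spot-checked by one full MPC run at n_data = 50, l = 12,
k = 5. These sizes were chosen so the entire suite runs on a laptop in a
couple of minutes while still covering the protocol exhaustively at
small scale.

## Known limitations

* Semi-honest only; no verifiable sharing, no proactive refresh, no
  Beaver-triple preprocessing mode (the engine's randomness layer is the
  natural place to add one).
* The default 61-bit field caps maskable bit decomposition at 16-bit
  widths with κ = 40; larger widths need a larger configured prime.
* Single-process simulation: timing results are meaningless by design;
  cost claims are made in rounds/invocations only.
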