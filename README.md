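# ppknn-mpc

Privacy-preserving k-nearest-neighbor diagnosis over secret-shared medical
records — a desk-scale, fully tested simulation of an e-health cloud built
on Shamir-secret-sharing multiparty computation (MPC).

## The problem

Case-based diagnosis works by kNN: given a patient's symptom vector
**q** = (q_1, …, q_m), find the k records in a case library
{(**d**_i, c_i)} with the smallest squared Euclidean distance
Σ_j (q_j − d_{i,j})² and report the per-disease score vector
**scr** = (scr_1, …, scr_v), where scr_j counts how many of the k nearest
records carry diagnosis class j; the diagnosis is argmax_j scr_j.
Hospitals, however, cannot hand their case libraries to a cloud in
plaintext, and a patient cannot reveal symptoms or receive a diagnosis in
the open. This package computes the kNN score vector across *multiple
mutually untrusting data owners* so that no cloud server learns the
dataset, the query, the result, or which records were touched — only the
inquirer can reconstruct **scr**.

## How it works

* **Input sharing.** Every value is Shamir-shared: a secret s becomes
  evaluations of a random degree-t polynomial f_s with f_s(0) = s at
  public points α_1..α_n, one share per server. Any t shares are jointly
  uniform; t+1 reconstruct. Integers that must be bit-scanned are shared
  *bitwise*: [s]_B = {[s_{l−1}], …, [s_0]}.
* **Computation.** Additions and constant multiplications are local;
  products [a]·[b] cost one communication round (local multiply, reshare,
  recombine with the public Lagrange vector λ — hence 2t+1 ≤ n).
* **PE-FTK**, the selection core: a deterministic protocol that finds the
  k largest of n bitwise-shared values by scanning all data from the most
  significant bit down ("bit-rounds"). Each round it forms the shared
  counter [Cnt] = #(already selected) + #(eligible data showing a 1) and
  compares it with the public k: while Cnt ≤ k the leaders are folded
  into the shared result flags [Res_i] (part 1); once Cnt > k the leaders
  become a candidate set [Can_i] that is obliviously narrowed (part 2),
  where only the *equality* bit [Cnt = k] is ever opened — the minimal
  public termination signal. The output is exact, with no error
  probability, and the flags never leave shared form.
* **PPkNN** end-to-end: batched shared squared distances → bit
  decomposition and bitwise complement (mapping distance d to
  2^l − 1 − d, so top-k similarity = k nearest) → PE-FTK →
  [ck_{i,j}] = [Res_i]·[c_{i,j}] and scr_j = Σ_i ck_{i,j}, reconstructed
  only by the inquirer.

Ties are handled by appending ⌈log2(n+1)⌉ public index bits to every
value (lower record index wins), which also makes every value selectable.
A plaintext oracle suite (sort-based top-k, plaintext kNN, and an exact
control-flow trace of PE-FTK) ships inside the package for cross-checks
at any scale.

## Worked example

The canonical dataset {16, 12, 11, 10, 9} with k = 3, shared bitwise
(l = 5) among 5 simulated servers with threshold t = 2:

```bash
$ ppknn-mpc trace --values 16,12,11,10,9 --k 3
Bit-round    (Cnt, k)  Step  Result
        1       1 < 3   2-3
        2       5 > 3   2-1
        3       2 < 3   5-3
        4       4 > 3   5-2
        5      3 == 3   5-1
selected indices: [0, 1, 2] (values [16, 12, 11])
alpha=2 termination_round=5
```

Reading the table: at bit-round 1 only 16 shows a leading 1 (Cnt = 1 < 3,
it is selected); at round 2 all remaining values show a 1 (Cnt = 5 > 3),
so {12, 11, 10, 9} become candidates and the protocol enters part 2;
rounds 3–5 narrow the candidates until Cnt = k = 3 fires the equality
branch and {16, 12, 11} are flagged. `run-peftk` runs the same selection
through the actual MPC stack (sharing, batched share multiplications,
masked bit decompositions) and prints the identical trace:

```bash
$ ppknn-mpc run-peftk --values examples/worked_example.csv --k 3 --tie strict
top-3 record ids: [0, 1, 2]
top-3 values:     [16, 12, 11]
terminated at bit-round 5 (alpha=2)
```

A full diagnosis run on a synthetic 30-record case library (4 four-bit
symptom features, 3 disease classes), querying the class-2 cluster
center:

```bash
$ ppknn-mpc gen-data --n 30 --m 4 --v 3 --bits 4 --seed 11 \
      --out cases.csv --queries-out centers.csv
$ ppknn-mpc run-ppknn --dataset cases.csv --query query.csv \
      --v 3 --feature-bits 4 --k 5 --seed 11
scores: [0, 5, 0]
predicted class: 2
```

All 5 nearest cases carry class 2, so the score vector (which always sums
to k) is (0, 5, 0) and the diagnosis is class 2. Other subcommands:
`share` (write per-server share CSVs), `bench-bitrounds` (termination
distribution on random data), `selftest` (MPC vs plaintext-oracle
cross-checks).

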