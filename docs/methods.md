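# Methods

## The model

Complex tandem repeats (TRs) are nucleotide strings built from consecutive
copies of several different repeat units, e.g. `(AAAG)3(AG)2(AAAG)5` over
the unit set `U = {AAAG, AG}`. During DNA replication, slippage duplicates
or deletes whole units, so two alleles at the same locus typically differ by
unit-count changes as much as by point mutations. The natural distance is
therefore the **edit distance with duplication and contraction (EDDC)**: the
minimum summed cost of a sequence of edit operations transforming one string
into the other, where the operations are

| operation           | effect                              | default cost |
|---------------------|-------------------------------------|--------------|
| substitution        | one base replaced                   | 1            |
| insertion           | one base inserted                   | 1            |
| deletion            | one base deleted                    | 1            |
| unit duplication    | `…α… → …αα…` for a unit `α ∈ U`     | `|α|/2`      |
| unit contraction    | `…αα… → …α…` for a unit `α ∈ U`     | `|α|/2`      |

Duplication and contraction apply to **any substring occurrence** of a unit
in the current string, not only to occurrences aligned with a unit
decomposition: the operations are defined on raw strings. This matters: the
pair `(AAAG)3(AG)2(AAAG)5` vs `(AAAG)5(AG)5(AAAG)3` can be converted by two
`AAAG` duplications, three `AG` duplications and two `AAAG` contractions
(cost 11), but the true EDDC is 5 — an optimal script duplicates the `AG`
that occurs *inside* an `AAAG` run and finishes with three single-base
edits. Both the exact oracle and the estimator in this package find 5.

Unit operations cost `|α|/2` by default (half the cost of the equivalent
run of single-base indels) because slippage events are considered at least
as frequent as point mutations in TRs. Costs are user-configurable but must
be nonnegative exact half-integers; all arithmetic is carried in integer
half-units so comparisons (including the rule-pruning equalities below) are
exact. `unit_op_cost(α) ≤ |α|` is enforced so a duplication is never dearer
than writing the unit base by base.

## Decomposition

`decompose(S, U)` compresses `S` into the unit-symbol sequence `S̄` whose
decoded concatenation minimises the Levenshtein distance to `S` (the
*residue*). The DP matches `S` against the regular language `(u1|…|uk)*`
with states (position in `S`, unit, offset), free jumps from any unit end to
any unit start, and unit transitions for match (0), mismatch/indel (1); it
runs in `O(|S| · Σ|u|)`. The empty concatenation is accepted, so degenerate
and empty inputs are handled.

Co-optimal decompositions are real (the worked 21-bp example matches both
`(AAAG)5` and `(AAAG)2(AG)2(AAAG)2` at residue 1). The implementation
breaks ties deterministically: fewest unit symbols, then lowest unit index,
then match > substitution > deletion > insertion in the traceback. A
`prefer="most"` switch selects the opposite extreme, which localises
discrepancies into the shortest spans. Flanking partial unit copies are not
emitted as symbols; their cost is absorbed into the residue, because the
downstream recursion requires `S̄` to be a sequence over `U`.

The residue is **excluded** from the reported distance by default — the
estimator measures the distance between the optimal complex TRs, not the
raw strings — and is exposed separately (an `add_residue` option exists as
an extension).

## The exact oracle

The oracle computes EDDC exactly by bidirectional best-first (A*) search
over string states. The move set is closed under inversion (duplication ↔
contraction, insertion ↔ deletion), so one frontier grows from each
endpoint and the search stops, provably at the optimum, once the best
meeting cost is at most the larger of the two frontiers' minimum
f-values; at each step the frontier likelier to exhaust first is advanced.
Two admissible, consistent lower bounds guide the search:

- an *alignment bound*: the weighted Levenshtein distance to the goal with
  substitution weight 2 and indel weight 1 (half-cost units), which equals
  `|W| + |goal| − 2·LCS(W, goal)` and is evaluated with a bit-parallel LCS;
  no single edit changes it by more than that edit's cost;
- a *composition bound*: relaxing every operation to its effect on the
  (A, C, G, T) count vector gives a min-cost program whose LP value, by
  duality, is a maximum of finitely many linear functions of the count
  difference — the dual polytope's vertices are precomputed once per cost
  setting, so the bound costs one dot product per vertex at run time.

When every half-cost is even (as with the defaults) all path costs are
even, so odd bounds round up by one. Search is bounded above by the
weighted Levenshtein distance (always achievable) and by the best meeting
found so far; intermediate strings are capped at `|s| + |t| +
2·max_unit_len` by default, and node and state budgets are enforced
(configurable; exceeding any budget raises a loud error, never a silent
approximation). The oracle is deliberately independent of the estimator's
code paths and is cross-validated in the tests against a plain
uniform-cost enumeration on tiny strings.

The oracle is exponential in the worst case and is intended for strings of
a few dozen bases — enough for unit cost tables and the scaled-down
benchmark. It is not a replacement for a polynomial exact algorithm.

## Unit cost tables and rule pruning

The estimator consumes tables of exact EDDC values between units:
`cost(x→z)` and `cost(xy→z)` for `x, y ∈ U` and `z ∈ U ∪ {ε}`, computed
with the oracle. A conversion rule `xy→z` is *redundant* when some other
pair `(p, q) ≠ (x, y)` achieves
`cost(x→p) + cost(y→q) + cost(pq→z) ≤ cost(xy→z)`.
With exact tables the right-hand side is itself an achievable script, so
the inequality can only hold with equality or not at all; pruning removes
exactly the redundant rules and provably leaves every dynamic-programming
value unchanged (asserted in the tests).

## The estimator

With `S̄ = u0…u(n−1)` and `T̄ = v0…v(m−1)`:

- `f(w, b, e, z)`: minimum table-derived cost of converting the unit
  interval `w[b, e)` into the single target `z ∈ U ∪ {ε}`; base cases are
  the empty interval (0 for `z = ε`, impossible otherwise) and the
  singleton (`cost(w[b]→z)`); longer intervals split at an interior point
  `b < k < e` into left → `x`, right → `y`, then `cost(xy→z)`. Restricting
  the split to interior points is essential: allowing `k = e` against a
  zero-cost empty suffix would inject a phantom unit for free and break the
  upper-bound guarantee.
- `dp(i, j)`: distance between the prefixes `u[0,i)` and `v[0,j)`; each
  aligned block pair is routed through a common unit `x`, paying
  `f(u, p, i, x) + f(v, q, j, x)`, with the leading-prefix base cases
  `f(·, 0, ·, ε)`.

Both published complexity reductions are implemented: the inner minimum
`min_y f(w,k,e,y) + cost(xy→z)` is precomputed per (interval, x, z), and
`dp` is evaluated through `g(p, j, x) = min_{q<j} dp(p,q) + f(v,q,j,x)`,
filled with `j` ascending so every `dp(·, q<j)` precedes it. Equality with
a directly-coded naive evaluation of the triple-minimum recursions is
asserted on randomized instances.

Every `dp` derivation corresponds to an achievable edit script (convert
both blocks to the common unit and compose via the triangle inequality),
so the estimate is an upper bound on the true EDDC; it equals it on all
pure benchmark pairs measured here. Distances are reported raw (exact
rationals) and normalized by `max(1,|S|) · max(1,|T|)` — the guards keep
alleles with all copy numbers zero (empty strings) finite, a case the
uniform 0-based copy-count distribution does produce.

## Unit-variant discovery

Impure TRs often carry recurrent unit variants (e.g. `AAG` next to `AAAG`
runs); adding them to `U` can make alleles pure and sharpens the estimate.
From each decomposition span whose substring differs from its assigned
unit, the discovery procedure strips flanks that are exact unit
concatenations (already explained by `U`) and keeps the core closest in
Levenshtein distance to the assigned unit (then shortest, then
lexicographically first). Primitive cores recurring in at least
`min_count` records are appended, ranked by count, length, and spelling,
capped at `max_added` — the cap exists because every added unit enlarges
the `cost(xy→z)` tables cubically. On the worked 21-bp example this
recovers exactly the variant `AAG`. Discovery is off by default.

## Synthetic benchmark

The generator emulates the diversity of a complex-TR locus across a
population: copy numbers per block drawn uniformly and independently from
[0, 50], then point sequencing errors at rates 0/1/3/5/10% (one event at
most per original position; kind uniform over substitution/insertion/
deletion by default — the kind mix is a maximum-entropy choice, exposed in
the model). One top-level seed drives counter-derived per-record
substreams, so generation is bit-reproducible and order-independent. It
does **not** emulate read-level artifacts (quality, homopolymer error
profiles, strand effects) or locus-specific copy-number distributions, so
passing benchmarks demonstrate estimator fidelity under idealised noise,
not performance on any particular sequencing platform.

The correlation experiment scores all unordered pairs per dataset with
both the estimator and the exact oracle, skips identical-sequence pairs
(both methods return 0 there, adding no information), normalizes by
`|S|·|T|`, and reports the per-dataset Pearson correlation. Because the
oracle is search-based, the shipped experiment runs at reduced scale:
pattern `(AAAG)i(AG)j`, copy counts 0–6, 12 repeats per dataset, error
rates 0% and 3% — sizes chosen so pairs stay inside the oracle's reach.
Very rarely, a record draws far more point errors than the 3% expectation
and its pairings with dissimilar records fall outside the search oracle's
certification budget (the lower bounds that keep the search narrow lose
power on heavily mutated, structurally impure strings). The experiment
runner excludes such a pair from the correlation, counts it in the
per-dataset report, and logs it — the reported correlation is over all
pairs whose exact distance the oracle certified: typically every pair, and
in the worst dataset observed during development 3 of 63. The
library-level `run_correlation` default is stricter: an oracle budget
overrun flags the whole dataset. The error-free dataset correlates at or
near 1.0 (the estimator matches the oracle exactly on pure pairs); the
3%-error dataset varies with the seed, around 0.96–0.997 in development
sweeps — the scaled-down copy-number range compresses between-pair
variance, so the correlation sits a little below the full-scale figure on
some seeds.

## Numerical choices and degenerate inputs

- All distance arithmetic is integer (half-units); no floating point
  enters a comparison. Normalized values are rendered to 10 significant
  digits only at output boundaries.
- Empty strings: decomposition of `""` is the empty symbol sequence with
  residue 0; `max(1, ·)` guards the normalization denominator.
- Neighbor joining runs on the normalized matrix (the tree method itself
  is a free choice; NJ is the default, UPGMA is behind a flag); negative
  branch lengths are clamped to zero with a warning.
- Deterministic tie-breaks everywhere (decomposer preferences, search heap
  ordering, variant ranking) make identical inputs give byte-identical
  outputs.

## Known limitations

- The oracle's cap on intermediate string length (`|s|+|t|+2q`) is a
  conservative assumption, not a proven bound on optimal scripts; it is
  configurable, and the default has never been observed binding.
- The estimator is restricted to conversions through units of `U`; with a
  poorly chosen unit set the estimate can exceed the true EDDC
  substantially. Choosing an optimal unit set is out of scope.
- Pairwise computation scales quadratically in the number of alleles and
  the dp cubically in compressed length; thousands of long alleles call
  for pre-clustering, which this package does not provide.
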