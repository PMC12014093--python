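# heddc

Edit distances between **complex tandem repeats** under unit duplication
and contraction.

Tandem repeats (TRs) built from several different units — e.g.
`(ACAG)6(AGGC)19(AC)22` in a disease-associated intron — diverge between
individuals mostly through replication slippage, which duplicates or drops
whole units. Comparing such alleles with the plain Levenshtein distance
misprices a slippage event as `|unit|` independent base edits. The right
yardstick is the **edit distance with duplication and contraction (EDDC)**:
substitutions, insertions and deletions at cost 1, plus duplication
(`…α… → …αα…`) and contraction (`…αα… → …α…`) of any unit `α ∈ U` at cost
`|α|/2`. Exact EDDC computation is polynomial but far too slow for the
allele collections produced by population-scale long-read sequencing.

This package provides:

- an **exact EDDC oracle** for short strings (admissible best-first search
  with branch-and-bound) — the ground truth used for unit cost tables and
  validation;
- a **decomposer** compressing a string `S` into the unit sequence `S̄`
  that matches it with minimum Levenshtein residue (wraparound DP over
  `(u1|…|uk)*`);
- the fast **estimator**: a dynamic program over `S̄` and `T̄` that
  converts unit intervals through precomputed tables `cost(x→z)` and
  `cost(xy→z)`,

  ```
  dp(i,j) = min_{x∈U} min_{p<i} ( f(u,p,i,x) + g(v,p,j,x) ),
  f(w,b,e,z) = min_{b<k<e} min_{x} ( f(w,b,k,x) + min_y { f(w,k,e,y) + cost(xy→z) } ),
  ```

  an upper bound on (and in practice near-equal to) the exact EDDC;
- **rule pruning** for the cubic `cost(xy→z)` tables and discovery of
  recurrent **unit variants** worth adding to `U`;
- a **synthetic benchmark** (five complex-TR patterns, uniform copy
  numbers, point-error injection) correlating estimator against oracle;
- a **pipeline CLI**: pairwise raw and `|S|·|T|`-normalized distance
  matrices (TSV/PHYLIP) and neighbor-joining trees (Newick).

See `docs/methods.md` for the model, the tie-breaking and base-case
choices, and known limitations.

## Worked example

```python
from heddc import (UnitSet, build_cost_tables, decompose, exact_eddc,
                   heddc_distance, parse_repeat_notation)
from heddc.decomposer import decomposition_notation

U = UnitSet(["AAAG", "AG"])

# an impure allele: one base short of a pure repeat
S = "AAAGAAAGAAGAGAAAGAAAG"
d = decompose(S, U)
print(d.residue, decomposition_notation(d, U))   # -> 1 (AAAG)5

# with the recurrent variant AAG added, the allele is pure
U3 = UnitSet(["AAAG", "AG", "AAG"])
d3 = decompose(S, U3)
print(d3.residue, decomposition_notation(d3, U3))  # -> 0 (AAAG)2(AAG)1(AG)1(AAAG)2

# estimator vs exact oracle on a pure pair
A = parse_repeat_notation("(AAAG)3(AG)2(AAAG)5")
B = parse_repeat_notation("(AAAG)5(AG)5(AAAG)3")
table = build_cost_tables(U)
est = heddc_distance(A, B, U, table=table)
print(est.raw, est.normalized)        # -> 5 5/1512
print(exact_eddc(A, B, U)[0])         # -> 5
```

The obvious conversion script (two `AAAG` duplications, three `AG`
duplications, two `AAAG` contractions) costs 11, but the optimal script
costs 5: it duplicates the `AG` occurring *inside* an `AAAG` run twice and
finishes with one substitution and two insertions. Estimator and oracle
agree. `5/1512` is the raw distance divided by `|A|·|B| = 36·42`, the
normalization that makes alleles of different lengths comparable.

From the shell:

```
heddc decompose --units AAAG,AG alleles.fasta
heddc dist --units AAAG,AG alleles.fasta -o dist.tsv --phylip dist.phy
heddc tree --units AAAG,AG alleles.fasta -o tree.nwk
heddc benchmark --pattern p1 --m 20 --seed 1 --outdir bench/
```

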