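# phylodiv

Exact phylogenetic diversity indices on weighted **cluster systems** and
**split systems** — the general objects behind rooted and unrooted
phylogenetic trees — for researchers in phylogenetics and conservation
prioritization who want evolutionary-distinctiveness scores that do not
depend on committing to a single tree topology.

## The indices

Let `X` be a set of taxa. A rooted tree with branch lengths is a weighted
*hierarchy* of clusters (each edge contributes the cluster of leaves below
it); an unrooted tree is a weighted *compatible* system of splits `A|B`;
split networks give *circular* systems. On an arbitrary weighted cluster
system `(C, ω)` the package computes

- **fair proportion** `FP(ω)(x) = Σ_{C ∋ x} ω(C)/|C|`,
- **equal splits** `ES(ω)(x) = Σ_C m_x(C)·ω(C)`, where `m_x(C)` divides a
  cluster's weight equally among its child clusters and uncovered taxa,
  recursively,
- the **Shapley value** of the phylogenetic diversity game
  `PD_ω(M) = Σ_{C∩M≠∅} ω(C)` (which provably equals `FP(ω)`), and the
  dimension `|C|` of the span of these games;

and on a weighted split system `(S, λ)`

- the **split Shapley value** `SV(x) = Σ_{A|B: x∈A} |B|/(|X|·|A|)·λ(A|B)`,
- the **unrooted fair proportion** `FP_u(x) = Σ_{A|B: x∈A} λ(A|B)/(2|A|)`,
- arbitrary **lifted indices** `Ψ_τ(Φ) = Φ ∘ τ`, where `τ` maps split
  weightings to cluster weightings on the part system `C(S)` (Shapley-style
  `|B|/|X|` shares or an even/uneven `p : 1-p` division),
- **Pauplin-type indices** `Ψ_R` on circular systems, built from any right
  inverse `R` of the split–pair incidence matrix `M(S)` (with `d_λ = λ·M`
  the induced distances), including the unique closed-form inverse for full
  interval systems and the two canonical restrictions `Ψ₁`, `Ψ₂` for
  non-full circular systems.

Axiom checkers report completeness, neutrality, descendant diversity,
downward continuity, and Pareto efficiency of a given index matrix. All
arithmetic is exact (`fractions.Fraction`); completeness identities hold as
equalities of rationals.

## Worked example

The running example is the five-taxon rooted tree
`((a:3,b:2):4,(c:6,(d:1,e:4):2):3);` with total branch length 25:

```python
>>> from phylodiv import fair_proportion, unrooted_fair_proportion
>>> from phylodiv.io import read_newick, tree_to_clusters, tree_to_splits
>>> from phylodiv.datasets import example_newick
>>> tree = read_newick(example_newick())
>>> fp = fair_proportion(tree_to_clusters(tree))
>>> fp.as_tuple()
(Fraction(5, 1), Fraction(4, 1), Fraction(7, 1), Fraction(3, 1), Fraction(6, 1))
>>> fpu = unrooted_fair_proportion(tree_to_splits(tree))
>>> fpu["e"], fpu.total()
(Fraction(31, 6), Fraction(25, 1))
```

The rooted scores `(5, 4, 7, 3, 6)` split each branch's length evenly among
the species below it (taxon `c` is the most distinctive); both vectors sum
to 25, the tree's total branch length, because both indices are complete.
The same numbers from the shell:

```sh
$ phylodiv fixtures --name rooted-example > clusters.tsv
$ phylodiv fp clusters.tsv
a	5
b	4
c	7
d	3
e	6
#total	25
```

Other verbs: `es`, `shapley`, `fp-unrooted`, `psi-tau`, `psi-r`, `check`,
`restrict`, `compatible-subsets`, `distances`, `clusters`, `splits`.

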