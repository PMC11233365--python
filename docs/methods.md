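# Methods

## Objects and conventions

All computations take place over a fixed finite taxon set `X`, stored in
lexicographic order; that order fixes the column order of every index
matrix, the order of index-vector output, and the lexicographic order of
the 2-subset columns of pair-incidence matrices, so outputs and file
round trips are byte-stable. A cluster system is any non-empty set of
non-empty subsets of `X`; a split system is any non-empty set of
bipartitions, canonicalized so the part containing the smallest taxon
comes first. Weightings are maps into the rationals with *no* sign or
support restriction: zero-weight members remain structural members of a
system (they still shape the child relation `ch(C)`), and deleting a
cluster is a separate, explicit restriction operation.

Every quantity is computed in exact rational arithmetic
(`fractions.Fraction`). This is not cosmetic: the package's central
claims — completeness (`Σ_x Φ(ω)(x) = Σ_C ω(C)`), the coincidence of the
Shapley value with fair proportion on PD games, and the equality of the
closed-form circular Γ with an explicit matrix inverse — are identities
of rationals, and the tests assert them with `==`, never with a numeric
tolerance.

## Cluster indices

Fair proportion distributes each cluster's weight uniformly over its
members. Equal splits divides a cluster's weight equally among its
*children* (inclusion-maximal proper sub-clusters within the system) and
its *uncovered* members, recursively down the containment order. The
recursion is memoized over clusters in increasing size — every child is
strictly smaller, so size is a valid topological order, with ties broken
by the canonical cluster order (tie order is immaterial: same-size
clusters cannot be children of one another). On non-hierarchies the
defining recursion is applied verbatim: overlapping children each
contribute their coefficient, with no renormalization. The denominator
`|ch(C)| + |cl(C)|` is always positive (a childless cluster has
`cl(C) = C ≠ ∅`).

Both indices are linear, so each is carried by a `|C|×|X|` matrix Γ.
The axioms are checked on Γ directly: completeness as unit row sums;
neutrality as constant rows over the members of childless clusters;
descendant diversity as completeness plus non-negativity plus vanishing
off the cluster. Downward continuity is checked *structurally* — for a
linear index the limit as one weight tends to zero is exactly the map
with that row deleted, so the checker compares the row-deleted Γ with
the reduced system's Γ entrywise; this is exact and avoids numeric
limits entirely. Equal splits genuinely fails this check on chain
systems (deleting a middle cluster changes `ch` of its parent), which
the suite asserts by construction.

## Games and the Shapley value

The PD game of a weighted cluster system is evaluated lazily from the
weighting; the Shapley value is computed from its defining
weighted-marginal sum with precomputed factorials, materializing the
2^n table of game values once. The computation is guarded at 15 taxa;
the test oracle (average marginal contribution over all n! player
orders) is kept in the test suite, independent of the implementation
path. The dimension of the PD-game span is the exact rank (sympy, over
the rationals) of the cluster-versus-coalition intersection matrix; it
always equals the number of clusters because distinct unit games are
linearly independent.

Games are required to vanish on the empty coalition — the only
convention consistent with PD games and unit games — and the Shapley
evaluator accepts any such game; membership of a game in the PD span is
a separate rank question rather than a constructor restriction.

## The split–cluster bridge

A split system `S` projects to the cluster system `C(S)` of its parts.
Both τ maps are per-split; when two splits share a part their
contributions to that cluster are *summed* — the only choice under which
τ is a well-defined linear map, and the tests confirm that all
identities survive such collisions. The Shapley τ assigns `|B|/|X|` of a
split's weight to part `A`; composing fair proportion with it reproduces
the split Shapley closed form exactly. The even τ assigns `p : 1-p`
(default `p = 1/2`, one global `p`, applied to the canonical first part)
and preserves total weight for every `p`, so lifting any complete
cluster index yields a complete split index. The unrooted fair
proportion closed form is implemented independently of the composition
route and the two are asserted equal.

## Circular systems and right-inverse indices

The full interval system `S_θ` of a cyclic ordering has a square,
invertible pair-incidence matrix `M`. Its inverse is built directly in
the sparse closed form (at most four entries of ±1/2 per column, on the
pairs straddling the interval boundary, skipping degenerate coincident
pairs); because the index bookkeeping here is the classic off-by-one
trap, the `RightInverse` constructor *always* verifies `M·R = I`
exactly and raises otherwise — a convention bug cannot propagate
silently. The resulting Γ has the three-case closed form (1/2 on a
singleton part, 1/4 on a cyclic endpoint of a larger part, 0 interior),
implemented separately and asserted equal to the right-inverse route and
to an explicit sympy inversion.

For a circular system that is not full, two canonical indices are
provided: Ψ₁ restricts the full system's Γ rows, Ψ₂ restricts the full
inverse's columns (re-verified as a right inverse of the smaller `M`).
Arbitrary user-supplied right inverses are accepted through the same
validated constructor; the full affine family of inverses is not
parametrized symbolically — it is reachable by supplying any member.
Entries of Ψ_R matrices can be negative; non-negativity is reported,
not enforced.

## I/O

Newick parsing is delegated to dendropy; branch lengths arrive as floats
and are converted through `Fraction(Decimal(repr(x)))`, which is exact
for decimal literals that survive shortest-repr round-tripping (all
realistic branch-length notations, including scientific notation).
Cluster decomposition takes one cluster per edge; duplicate clusters
from unresolved degree-2 chains merge with summed weights and a warning.
Unrooting needs no special case: both child edges of a degree-2 root
induce the same canonical split, so their weights merge automatically.
TSV files carry exact fraction strings and round-trip losslessly; the
NEXUS reader/writer speaks the SplitsTree dialect (TAXA + SPLITS blocks,
1-based indices, optional CYCLE and WEIGHTS), validating a declared
cycle against the splits. PHYLIP distance export is decimal
(lossy by design — it feeds external distance tools).

## Synthetic data

The generators emulate the regimes in which the identities are stated:
hierarchies as pruned random binary merge trees, compatible systems as
random tree splits, circular systems as samples from a random ordering's
interval splits, arbitrary systems as uniform subset draws, and
weightings as small rationals (numerators in ±9, denominators up to 6,
zeros and negative weights included, since the theory imposes no sign
restriction). They are deterministic per seed. What they do *not*
emulate is any feature of real data — branch-length scale, taxon-sampling
bias, or estimation noise in split weights — so passing tests establish
the combinatorial/algebraic identities, not robustness of rankings on
empirical systems. Problem sizes (3–8 taxa, up to ~100 sampled systems
per identity) were chosen because the identities are size-uniform
algebraic statements: exercising them exactly at small n over many
random systems is the informative regime, and brute-force oracles
(2^n subset tables, n! permutation averages, explicit matrix inversion)
stay exact there.

## Known limitations

- Circularity recognition without a supplied ordering is exhaustive
  ((n−1)!/2 orders, guarded at n ≤ 8); efficient recognition is out of
  scope.
- `maximal_compatible_subsystems` enumerates maximal cliques and is
  guarded at 20 splits.
- The Shapley evaluator is exponential by design (guarded at 15 taxa);
  the closed forms serve as the polynomial-time routes where they exist.
- Split systems derived *from* cluster systems (the reverse bridge) and
  weak hierarchies are not implemented.
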