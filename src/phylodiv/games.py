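"""Cooperative games on taxon sets and the Shapley value.

A weighted cluster system induces the phylogenetic diversity game
``PD_ω(M) = Σ_{C: C∩M ≠ ∅} ω(C)``; a weighted split system induces
``PD_λ(M) = Σ_{A|B: A∩M ≠ ∅ ≠ B∩M} λ(A|B)``.  The Shapley value of a
game distributes the grand-coalition gain over the players by averaging
marginal contributions; on PD games it coincides with the fair
proportion index (cluster case) and admits a per-split closed form
(split case).  The PD games of a cluster system span a subspace of the
space of all games whose dimension is exactly the number of clusters.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial
from typing import Iterable, Iterator, Mapping

import sympy

from .indices import ClusterWeighting, IndexVector, as_rational, format_rational
from .systems import Cluster, Split, SplitSystem, TaxonSet, make_cluster

__all__ = [
    "Game",
    "SplitWeighting",
    "pd_clusters",
    "pd_splits",
    "pd_game",
    "pd_split_game",
    "unit_game",
    "shapley",
    "shapley_splits",
    "pd_space_dimension",
    "check_pareto",
]


class SplitWeighting:
    """A weighting λ ∈ L(S): one exact rational per split of a system."""

    __slots__ = ("system", "_w")

    def __init__(self, system: SplitSystem, weights: Mapping[Split, object]):
        w = {s: as_rational(v) for s, v in weights.items()}
        if set(w) != set(system.splits):
            raise ValueError("weighting domain must equal the system's splits")
        self.system = system
        self._w = w

    def weight(self, s: Split) -> Fraction:
        return self._w[s]

    def items(self) -> Iterator[tuple[Split, Fraction]]:
        for s in self.system.ordered:
            yield s, self._w[s]

    def total(self) -> Fraction:
        return sum(self._w.values(), Fraction(0))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SplitWeighting)
            and self.system == other.system
            and self._w == other._w
        )

    def __repr__(self) -> str:
        shown = ", ".join(f"{s!r}:{format_rational(v)}" for s, v in self.items())
        return f"SplitWeighting({shown})"


class Game:
    """A set function g: P(X) → Q with g(∅) = 0.

    The evaluator is called lazily; no 2^n table is stored unless the
    Shapley computation materializes one.
    """

    __slots__ = ("taxa", "_evaluate")

    def __init__(self, taxa: TaxonSet, evaluate):
        self.taxa = taxa
        self._evaluate = evaluate
        if as_rational(evaluate(frozenset())) != 0:
            raise ValueError("games must satisfy g(empty set) = 0")

    def __call__(self, coalition: Iterable[str]) -> Fraction:
        m = frozenset(coalition)
        unknown = m - self.taxa.as_set()
        if unknown:
            raise ValueError(f"unknown taxa in coalition: {sorted(unknown)}")
        return as_rational(self._evaluate(m))


def _validate_subset(taxa: TaxonSet, m: Iterable[str]) -> frozenset:
    ms = frozenset(m)
    unknown = ms - taxa.as_set()
    if unknown:
        raise ValueError(f"unknown taxa in subset: {sorted(unknown)}")
    return ms


def pd_clusters(omega: ClusterWeighting, m: Iterable[str]) -> Fraction:
    """PD_ω(M): total weight of clusters intersecting M."""
    ms = _validate_subset(omega.system.taxa, m)
    total = Fraction(0)
    for c, w in omega.items():
        if c & ms:
            total += w
    return total


def pd_splits(lam: SplitWeighting, m: Iterable[str]) -> Fraction:
    """PD_λ(M): total weight of splits with both sides meeting M."""
    ms = _validate_subset(lam.system.taxa, m)
    total = Fraction(0)
    for s, w in lam.items():
        if (s.part_a & ms) and (s.part_b & ms):
            total += w
    return total


def pd_game(omega: ClusterWeighting) -> Game:
    """The game M ↦ PD_ω(M)."""
    return Game(omega.system.taxa, lambda m: pd_clusters(omega, m))


def pd_split_game(lam: SplitWeighting) -> Game:
    """The game M ↦ PD_λ(M)."""
    return Game(lam.system.taxa, lambda m: pd_splits(lam, m))


def unit_game(taxa: TaxonSet, c: Iterable[str]) -> Game:
    """g_C: worth 1 to any coalition meeting C, 0 otherwise.

    The PD game of a weighting decomposes as PD_ω = Σ_C ω(C)·g_C, and
    these unit games are linearly independent.
    """
    cs = make_cluster(taxa, c)
    return Game(taxa, lambda m: Fraction(1) if cs & m else Fraction(0))


def _all_subsets(labels: tuple[str, ...]) -> Iterator[frozenset]:
    for r in range(len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            yield frozenset(combo)


def shapley(game: Game, max_taxa: int = 15) -> IndexVector:
    """The Shapley value by its defining weighted-marginal sum.

    SV(g)(x) = (1/n!)·Σ_{M ∋ x} (|M|-1)!(n-|M|)!·(g(M) - g(M\\{x}));
    exact rationals throughout.  The full 2^n table of game values is
    materialized, so the computation is guarded at ``max_taxa`` players.
    """
    n = len(game.taxa)
    if n > max_taxa:
        raise ValueError(f"shapley is guarded at {max_taxa} taxa (got {n})")
    labels = game.taxa.labels
    table = {m: game(m) for m in _all_subsets(labels)}
    fact = [factorial(k) for k in range(n + 1)]
    n_fact = fact[n]
    values = {}
    for x in labels:
        acc = Fraction(0)
        for m, gm in table.items():
            if x not in m:
                continue
            k = len(m)
            acc += fact[k - 1] * fact[n - k] * (gm - table[m - {x}])
        values[x] = acc / n_fact
    return IndexVector(game.taxa, values)


def shapley_splits(lam: SplitWeighting) -> IndexVector:
    """Closed form of the Shapley value on a split PD game:
    SV(x) = Σ over splits A|B with x ∈ A of |B|/(n·|A|)·λ(A|B)."""
    taxa = lam.system.taxa
    n = len(taxa)
    values = {x: Fraction(0) for x in taxa}
    for s, w in lam.items():
        for part in s.parts:
            coeff = Fraction(len(s.other(part)), n * len(part)) * w
            for x in part:
                values[x] += coeff
    return IndexVector(taxa, values)


def pd_space_dimension(cs, max_taxa: int = 12) -> int:
    """Dimension of span{g_C : C in the system} inside the game space.

    Computed as the exact rank of the |C| × (2^n - 1) incidence matrix
    whose (C, M) entry is 1 iff C ∩ M ≠ ∅; always equals |C| because the
    unit games are linearly independent.
    """
    n = len(cs.taxa)
    if n > max_taxa:
        raise ValueError(f"pd_space_dimension is guarded at {max_taxa} taxa (got {n})")
    labels = cs.taxa.labels
    cols = [m for m in _all_subsets(labels) if m]
    rows = [[1 if c & m else 0 for m in cols] for c in cs.ordered]
    return sympy.Matrix(rows).rank()


def check_pareto(phi: IndexVector, game: Game) -> bool:
    """Pareto efficiency: the scores sum to the grand coalition's worth."""
    if phi.taxa != game.taxa:
        raise ValueError("index vector and game are on different taxon sets")
    return phi.total() == game(game.taxa.labels)
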