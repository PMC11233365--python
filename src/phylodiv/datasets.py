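"""Worked-example fixtures and seeded random system generators.

The running example is a five-taxon rooted tree and its unrooted
counterpart: clusters {a}:3, {b}:2, {c}:6, {d}:1, {e}:4, {a,b}:4,
{d,e}:2, {c,d,e}:3 (total weight 25) and the corresponding seven tree
splits (the two root-incident branches merge into the split ab|cde of
weight 7).  A small three-cluster system whose index matrix satisfies
neutrality and descendant diversity without being the fair proportion
matrix is also provided; it witnesses that those two axioms alone do not
pin down fair proportion on a single fixed system.

Random generators draw modest systems (defaults: 3–8 taxa, small
integer-over-small-denominator rational weights, signs allowed) — the
regime in which the package's exact identities are exercised.  All
generators are deterministic per seed.
"""

from __future__ import annotations

import random
from fractions import Fraction

from .indices import ClusterWeighting, IndexMatrix
from .games import SplitWeighting
from .systems import (
    CircularOrdering,
    ClusterSystem,
    Split,
    SplitSystem,
    TaxonSet,
    make_cluster_system,
    make_split_system,
)
from .circular import full_circular_system

__all__ = [
    "example_newick",
    "example_cluster_weighting",
    "example_split_weighting",
    "neutrality_counterexample",
    "taxon_labels",
    "random_hierarchy",
    "random_cluster_system",
    "random_compatible_split_system",
    "random_circular_split_system",
    "random_cluster_weighting",
    "random_split_weighting",
]


def example_newick() -> str:
    """The five-taxon rooted example tree, edge weights totalling 25."""
    return "((a:3,b:2):4,(c:6,(d:1,e:4):2):3);"


def example_cluster_weighting() -> ClusterWeighting:
    """The example tree's eight weighted clusters (a hierarchy)."""
    weights = {
        frozenset("a"): 3,
        frozenset("b"): 2,
        frozenset("c"): 6,
        frozenset("d"): 1,
        frozenset("e"): 4,
        frozenset("ab"): 4,
        frozenset("de"): 2,
        frozenset("cde"): 3,
    }
    system = make_cluster_system("abcde", weights.keys())
    return ClusterWeighting(system, weights)


def example_split_weighting() -> SplitWeighting:
    """The example tree's seven weighted splits (total weight 25)."""
    taxa = TaxonSet("abcde")
    parts = {
        frozenset("a"): 3,
        frozenset("b"): 2,
        frozenset("c"): 6,
        frozenset("d"): 1,
        frozenset("e"): 4,
        frozenset("ab"): 7,
        frozenset("de"): 2,
    }
    full = taxa.as_set()
    weights = {Split(p, full - p): w for p, w in parts.items()}
    system = SplitSystem(taxa, weights.keys())
    return SplitWeighting(system, weights)


def neutrality_counterexample() -> tuple[ClusterSystem, IndexMatrix]:
    """A chain system and a complete, neutral, descendant-diversity
    index matrix that is *not* the fair proportion matrix."""
    system = make_cluster_system("abcde", [frozenset("ab"), frozenset("abcd"), frozenset("abcde")])
    rows = {
        frozenset("ab"): {
            "a": Fraction(1, 2), "b": Fraction(1, 2), "c": 0, "d": 0, "e": 0,
        },
        frozenset("abcd"): {
            "a": Fraction(1, 4), "b": Fraction(1, 4),
            "c": Fraction(1, 4), "d": Fraction(1, 4), "e": 0,
        },
        frozenset("abcde"): {
            "a": Fraction(2, 5), "b": Fraction(2, 5),
            "c": Fraction(1, 15), "d": Fraction(1, 15), "e": Fraction(1, 15),
        },
    }
    entries = {(c, x): rows[c][x] for c in system.clusters for x in system.taxa}
    return system, IndexMatrix(system.ordered, system.taxa, entries)


def taxon_labels(n: int) -> list[str]:
    """n zero-padded labels whose lexicographic order equals their index order."""
    width = len(str(n - 1)) if n > 1 else 1
    return [f"t{i:0{width}d}" for i in range(n)]


def _random_fraction(rng: random.Random, lo: int = -9, hi: int = 9, max_den: int = 6) -> Fraction:
    return Fraction(rng.randint(lo, hi), rng.randint(1, max_den))


def _random_merge_tree(labels: list[str], rng: random.Random) -> set[frozenset]:
    """Clusters of a random binary merge tree: singletons + internal nodes."""
    blocks = [frozenset([x]) for x in labels]
    clusters = set(blocks)
    while len(blocks) > 1:
        i, j = rng.sample(range(len(blocks)), 2)
        merged = blocks[i] | blocks[j]
        blocks = [b for k, b in enumerate(blocks) if k not in (i, j)] + [merged]
        clusters.add(merged)
    return clusters


def random_hierarchy(n: int, seed: int, keep: float = 0.8) -> ClusterSystem:
    """A random hierarchy: clusters of a random binary merge tree, each
    kept with probability ``keep`` (a subset of a hierarchy is one too)."""
    rng = random.Random(seed)
    labels = taxon_labels(n)
    clusters = _random_merge_tree(labels, rng)
    kept = {c for c in clusters if rng.random() < keep}
    if not kept:
        kept = {frozenset(labels)}
    return make_cluster_system(labels, kept)


def random_cluster_system(n: int, k: int, seed: int) -> ClusterSystem:
    """k distinct non-empty subsets of n taxa, uniform over subsets."""
    if k > 2**n - 1:
        raise ValueError("cannot draw more distinct clusters than non-empty subsets")
    rng = random.Random(seed)
    labels = taxon_labels(n)
    chosen: set[frozenset] = set()
    while len(chosen) < k:
        mask = rng.randrange(1, 2**n)
        chosen.add(frozenset(x for i, x in enumerate(labels) if mask >> i & 1))
    return make_cluster_system(labels, chosen)


def random_compatible_split_system(n: int, seed: int) -> SplitSystem:
    """The splits of a random binary tree on n ≥ 2 taxa (pairwise compatible)."""
    rng = random.Random(seed)
    labels = taxon_labels(n)
    full = frozenset(labels)
    parts = {c for c in _random_merge_tree(labels, rng) if c != full}
    return SplitSystem(TaxonSet(labels), {Split(p, full - p) for p in parts})


def random_circular_split_system(
    n: int, k: int, seed: int
) -> tuple[SplitSystem, CircularOrdering]:
    """k splits sampled from the full interval system of a random cyclic
    ordering of n ≥ 3 taxa; returns the system and the ordering."""
    rng = random.Random(seed)
    labels = taxon_labels(n)
    order = labels[:]
    rng.shuffle(order)
    theta = CircularOrdering(order)
    pool = list(full_circular_system(theta).ordered)
    if k > len(pool):
        raise ValueError(f"a circular system on {n} taxa has at most {len(pool)} splits")
    chosen = rng.sample(pool, k)
    return SplitSystem(theta.taxa, chosen), theta


def random_cluster_weighting(
    cs: ClusterSystem, seed: int, lo: int = -9, hi: int = 9
) -> ClusterWeighting:
    """Independent small rational weights (zeros and signs allowed)."""
    rng = random.Random(seed)
    return ClusterWeighting(cs, {c: _random_fraction(rng, lo, hi) for c in cs.ordered})


def random_split_weighting(
    ss: SplitSystem, seed: int, lo: int = -9, hi: int = 9
) -> SplitWeighting:
    """Independent small rational weights (zeros and signs allowed)."""
    rng = random.Random(seed)
    return SplitWeighting(ss, {s: _random_fraction(rng, lo, hi) for s in ss.ordered})
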