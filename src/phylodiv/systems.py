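"""Cluster systems and split systems on a finite taxon set.

A *cluster* is a non-empty subset of a fixed taxon set X.  Rooted
phylogenetic trees are encoded by cluster systems: each edge contributes
the cluster of leaves below it, and the resulting system is a *hierarchy*
(any two clusters are nested or disjoint).  A *split* is a bipartition
A|B of X; unrooted trees are encoded by *compatible* split systems, and
split networks more generally by *circular* ones (all splits are intervals
of one cyclic ordering of the taxa).

This module holds the combinatorial objects and predicates; diversity
indices live in :mod:`phylodiv.indices`, :mod:`phylodiv.games`,
:mod:`phylodiv.bridge` and :mod:`phylodiv.circular`.

All collections are canonically ordered (taxa lexicographically; clusters
by size then members; splits by the part containing the lexicographically
smallest taxon) so that every matrix and vector produced downstream has a
deterministic row/column order.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "TaxonSet",
    "Cluster",
    "ClusterSystem",
    "Split",
    "SplitSystem",
    "CircularOrdering",
    "make_cluster",
    "make_cluster_system",
    "make_split",
    "make_split_system",
    "is_hierarchy",
    "children",
    "cluster_free_taxa",
    "descendant_count",
    "splits_compatible",
    "is_compatible",
    "is_circular",
    "find_circular_ordering",
    "clusters_of_splits",
    "maximal_compatible_subsystems",
]

#: A cluster is represented as a frozenset of taxon labels.
Cluster = frozenset


class TaxonSet:
    """An ordered, finite, non-empty set of taxon labels.

    Labels are stored in lexicographic order; that order fixes the column
    order of every index matrix and index vector in the package.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = list(labels)
        if not labels:
            raise ValueError("taxon set must be non-empty")
        for lab in labels:
            if not isinstance(lab, str) or not lab:
                raise ValueError(f"invalid taxon label: {lab!r}")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        self.labels: tuple[str, ...] = tuple(sorted(labels))
        self._index = {x: i for i, x in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, x: object) -> bool:
        return x in self._index

    def index(self, x: str) -> int:
        """Position of ``x`` in the canonical (sorted) order."""
        return self._index[x]

    def as_set(self) -> frozenset:
        return frozenset(self.labels)

    def pairs(self) -> list[tuple[str, str]]:
        """All 2-subsets of X, lexicographic, as sorted pairs."""
        return list(itertools.combinations(self.labels, 2))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"


def _cluster_key(c: Cluster) -> tuple:
    return (len(c), tuple(sorted(c)))


def make_cluster(taxa: TaxonSet, members: Iterable[str]) -> Cluster:
    """Validate ``members`` against ``taxa`` and return a cluster."""
    c = frozenset(members)
    if not c:
        raise ValueError("a cluster must be non-empty")
    unknown = c - taxa.as_set()
    if unknown:
        raise ValueError(f"unknown taxon labels in cluster: {sorted(unknown)}")
    return c


class ClusterSystem:
    """A non-empty set of distinct clusters on a taxon set.

    Membership is structural: a cluster that later receives weight 0 is
    still a member and still shapes the child relation ``ch``.
    """

    __slots__ = ("taxa", "clusters", "_ordered")

    def __init__(self, taxa: TaxonSet, clusters: Iterable[Iterable[str]]):
        cs = frozenset(make_cluster(taxa, c) for c in clusters)
        if not cs:
            raise ValueError("cluster system must contain at least one cluster")
        self.taxa = taxa
        self.clusters: frozenset = cs
        self._ordered = tuple(sorted(cs, key=_cluster_key))

    @property
    def ordered(self) -> tuple[Cluster, ...]:
        """Clusters in canonical order (by size, then members)."""
        return self._ordered

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self._ordered)

    def __contains__(self, c: object) -> bool:
        return c in self.clusters

    def without(self, c: Cluster) -> "ClusterSystem":
        """The system with cluster ``c`` removed (taxa unchanged)."""
        if c not in self.clusters:
            raise KeyError(f"cluster not in system: {sorted(c)}")
        if len(self.clusters) == 1:
            raise ValueError("cannot remove the last cluster of a system")
        return ClusterSystem(self.taxa, self.clusters - {c})

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ClusterSystem)
            and self.taxa == other.taxa
            and self.clusters == other.clusters
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.clusters))

    def __repr__(self) -> str:
        shown = ", ".join("{" + ",".join(sorted(c)) + "}" for c in self._ordered)
        return f"ClusterSystem({shown})"


def make_cluster_system(taxa, clusters) -> ClusterSystem:
    """Build a :class:`ClusterSystem`; ``taxa`` may be labels or a TaxonSet."""
    if not isinstance(taxa, TaxonSet):
        taxa = TaxonSet(taxa)
    return ClusterSystem(taxa, clusters)


class Split:
    """An unordered bipartition ``A|B`` of the taxon set.

    Canonical form: the part containing the lexicographically smallest
    taxon is stored as :attr:`part_a`.
    """

    __slots__ = ("part_a", "part_b")

    def __init__(self, part_a: Iterable[str], part_b: Iterable[str]):
        a, b = frozenset(part_a), frozenset(part_b)
        if not a or not b:
            raise ValueError("both parts of a split must be non-empty")
        if a & b:
            raise ValueError("split parts must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        self.part_a = a
        self.part_b = b

    @property
    def parts(self) -> tuple[Cluster, Cluster]:
        return (self.part_a, self.part_b)

    def side_containing(self, x: str) -> Cluster:
        if x in self.part_a:
            return self.part_a
        if x in self.part_b:
            return self.part_b
        raise KeyError(f"taxon {x!r} not in split")

    def other(self, part: Cluster) -> Cluster:
        if part == self.part_a:
            return self.part_b
        if part == self.part_b:
            return self.part_a
        raise KeyError("not a part of this split")

    def separates(self, x: str, y: str) -> bool:
        """True iff x and y lie on different sides."""
        return (x in self.part_a) != (y in self.part_a)

    @property
    def is_trivial(self) -> bool:
        return len(self.part_a) == 1 or len(self.part_b) == 1

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Split)
            and self.part_a == other.part_a
            and self.part_b == other.part_b
        )

    def __hash__(self) -> int:
        return hash((self.part_a, self.part_b))

    def __repr__(self) -> str:
        a = ",".join(sorted(self.part_a))
        b = ",".join(sorted(self.part_b))
        return f"Split({a}|{b})"


def _split_key(s: Split) -> tuple:
    return (_cluster_key(s.part_a), _cluster_key(s.part_b))


def make_split(taxa: TaxonSet, part: Iterable[str]) -> Split:
    """The split ``part | X - part``; ``part`` must be a proper subset."""
    a = make_cluster(taxa, part)
    b = taxa.as_set() - a
    if not b:
        raise ValueError("a split part must be a proper subset of the taxa")
    return Split(a, b)


class SplitSystem:
    """A non-empty set of distinct splits of a taxon set."""

    __slots__ = ("taxa", "splits", "_ordered")

    def __init__(self, taxa: TaxonSet, splits: Iterable[Split]):
        ss = frozenset(splits)
        if not ss:
            raise ValueError("split system must contain at least one split")
        full = taxa.as_set()
        for s in ss:
            if not isinstance(s, Split):
                raise TypeError("SplitSystem expects Split objects; use make_split_system for raw parts")
            if s.part_a | s.part_b != full:
                raise ValueError(f"split {s!r} is not a bipartition of the taxon set")
        self.taxa = taxa
        self.splits: frozenset = ss
        self._ordered = tuple(sorted(ss, key=_split_key))

    @property
    def ordered(self) -> tuple[Split, ...]:
        return self._ordered

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self) -> Iterator[Split]:
        return iter(self._ordered)

    def __contains__(self, s: object) -> bool:
        return s in self.splits

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SplitSystem)
            and self.taxa == other.taxa
            and self.splits == other.splits
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits))

    def __repr__(self) -> str:
        return f"SplitSystem({', '.join(repr(s) for s in self._ordered)})"


def make_split_system(taxa, parts: Iterable[Iterable[str]]) -> SplitSystem:
    """Build a split system from one listed part per split (complement implied)."""
    if not isinstance(taxa, TaxonSet):
        taxa = TaxonSet(taxa)
    return SplitSystem(taxa, [make_split(taxa, p) for p in parts])


class CircularOrdering:
    """A cyclic ordering x_0, ..., x_{n-1} of the taxa (indices mod n)."""

    __slots__ = ("order", "taxa", "_pos")

    def __init__(self, order: Iterable[str]):
        self.order: tuple[str, ...] = tuple(order)
        self.taxa = TaxonSet(self.order)  # validates non-empty / distinct
        self._pos = {x: i for i, x in enumerate(self.order)}

    def position(self, x: str) -> int:
        return self._pos[x]

    def __len__(self) -> int:
        return len(self.order)

    def __iter__(self) -> Iterator[str]:
        return iter(self.order)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CircularOrdering) and self.order == other.order

    def __hash__(self) -> int:
        return hash(self.order)

    def __repr__(self) -> str:
        return f"CircularOrdering({list(self.order)!r})"


# ---------------------------------------------------------------------------
# predicates and structure maps
# ---------------------------------------------------------------------------

def is_hierarchy(cs: ClusterSystem) -> bool:
    """True iff every pair of clusters is nested or disjoint."""
    clusters = cs.ordered
    for c1, c2 in itertools.combinations(clusters, 2):
        inter = c1 & c2
        if inter and inter != c1 and inter != c2:
            return False
    return True


def children(cs: ClusterSystem, c: Cluster) -> frozenset:
    """ch(C): the maximal proper sub-clusters of ``c`` within the system.

    Computed by pairwise subset tests; quadratic in the system size, which
    is fine at the scale this package targets.
    """
    if c not in cs:
        raise KeyError(f"cluster not in system: {sorted(c)}")
    proper = [d for d in cs.clusters if d < c]
    return frozenset(
        d for d in proper if not any(d < e for e in proper)
    )


def cluster_free_taxa(cs: ClusterSystem, c: Cluster) -> frozenset:
    """cl(C): members of ``c`` covered by no child of ``c``."""
    ch = children(cs, c)
    covered = frozenset().union(*ch) if ch else frozenset()
    return c - covered


def descendant_count(cs: ClusterSystem, c: Cluster) -> int:
    """desc(C) = |union of ch(C)|."""
    ch = children(cs, c)
    return len(frozenset().union(*ch)) if ch else 0


def splits_compatible(s1: Split, s2: Split) -> bool:
    """Two splits A|B, C|D are compatible iff one of the four cross
    intersections A∩C, A∩D, B∩C, B∩D is empty."""
    a, b = s1.parts
    c, d = s2.parts
    return not (a & c) or not (a & d) or not (b & c) or not (b & d)


def is_compatible(ss: SplitSystem) -> bool:
    """True iff every pair of splits is compatible (tree-like system)."""
    for s1, s2 in itertools.combinations(ss.ordered, 2):
        if not splits_compatible(s1, s2):
            return False
    return True


def _is_cyclic_interval(positions: frozenset, n: int) -> bool:
    """True iff the position set is contiguous on the n-cycle."""
    if len(positions) in (0, n):
        return True
    # a non-empty proper subset is a cyclic interval iff exactly one
    # member has its successor outside the set
    boundary = sum(1 for p in positions if (p + 1) % n not in positions)
    return boundary == 1


def is_circular(ss: SplitSystem, ordering: Optional[CircularOrdering] = None) -> bool:
    """True iff ss ⊆ S_θ for the given (or some) cyclic ordering θ.

    A split belongs to S_θ iff one of its parts is an interval of θ, or
    equivalently iff both parts are cyclic intervals.  Without a supplied
    ordering, all (n-1)!/2 cyclic orders are searched; this is guarded at
    n ≤ 8 since efficient circularity recognition is out of scope.
    """
    if ordering is None:
        return find_circular_ordering(ss) is not None
    if ordering.taxa != ss.taxa:
        raise ValueError("ordering is not a permutation of the system's taxa")
    n = len(ordering)
    for s in ss:
        pos = frozenset(ordering.position(x) for x in s.part_a)
        if not _is_cyclic_interval(pos, n):
            return False
    return True


def find_circular_ordering(ss: SplitSystem, max_taxa: int = 8) -> Optional[CircularOrdering]:
    """Search all cyclic orders (up to rotation and reflection) for one
    that makes ``ss`` circular; return it, or None."""
    labels = ss.taxa.labels
    n = len(labels)
    if n > max_taxa:
        raise ValueError(
            f"exhaustive circularity search is limited to {max_taxa} taxa (got {n})"
        )
    if n <= 2:
        return CircularOrdering(labels)
    first, rest = labels[0], labels[1:]
    for perm in itertools.permutations(rest):
        if perm[0] > perm[-1]:  # quotient reflections
            continue
        theta = CircularOrdering((first,) + perm)
        if is_circular(ss, theta):
            return theta
    return None


def clusters_of_splits(ss: SplitSystem) -> ClusterSystem:
    """C(S): the cluster system consisting of both parts of every split."""
    parts = set()
    for s in ss:
        parts.add(s.part_a)
        parts.add(s.part_b)
    return ClusterSystem(ss.taxa, parts)


def maximal_compatible_subsystems(ss: SplitSystem, max_splits: int = 20) -> list[SplitSystem]:
    """All inclusion-maximal pairwise-compatible subsets of ``ss``.

    Maximal compatible subsets are exactly the maximal cliques of the
    compatibility graph on the splits.
    """
    if len(ss) > max_splits:
        raise ValueError(
            f"maximal_compatible_subsystems is limited to {max_splits} splits (got {len(ss)})"
        )
    g = nx.Graph()
    g.add_nodes_from(ss.ordered)
    for s1, s2 in itertools.combinations(ss.ordered, 2):
        if splits_compatible(s1, s2):
            g.add_edge(s1, s2)
    cliques = [SplitSystem(ss.taxa, clique) for clique in nx.find_cliques(g)]
    cliques.sort(key=lambda sub: (-len(sub), [_split_key(s) for s in sub.ordered]))
    return cliques
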