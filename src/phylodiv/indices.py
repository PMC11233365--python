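"""Linear phylogenetic diversity indices on weighted cluster systems.

A weighting ω assigns an (arbitrary, possibly zero or negative) rational
weight to every cluster of a system; a phylogenetic diversity index maps
ω to a per-taxon score vector.  Two classical indices are implemented:

* **fair proportion** (FP): each cluster's weight is shared equally among
  its members, ``FP(ω)(x) = Σ_{C ∋ x} ω(C)/|C|``;
* **equal splits** (ES): a cluster's weight is divided equally among its
  child clusters and its uncovered taxa, recursively.

Both are linear, so each corresponds to a |C|×|X| coefficient matrix Γ
with ``Φ(ω)(x) = Σ_C ω(C)·γ_(C,x)``, and both are *complete*: the scores
sum to the total weight of the system.  The axioms used to characterize
FP — neutrality (NC), descendant diversity (DD) and downward continuity
(DC) under deletion of a cluster — are available as checkers on Γ.

All arithmetic is exact (``fractions.Fraction``): completeness and the
characterization identities are equalities of rationals, not approximate.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Optional

from .systems import (
    Cluster,
    ClusterSystem,
    TaxonSet,
    _cluster_key,
    children,
    cluster_free_taxa,
)

__all__ = [
    "as_rational",
    "ClusterWeighting",
    "IndexVector",
    "IndexMatrix",
    "PropertyReport",
    "fair_proportion",
    "equal_splits_coefficients",
    "equal_splits",
    "index_matrix",
    "restrict",
    "check_properties",
    "check_downward_continuity",
]


def as_rational(value) -> Fraction:
    """Convert ints, Fractions, Decimals, floats and strings (decimal or
    ``p/q``) to an exact Fraction.  Floats go through their shortest
    repr, so decimal literals survive exactly."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, numbers.Integral):
        return Fraction(int(value))
    if isinstance(value, float):
        return Fraction(Decimal(repr(value)))
    if isinstance(value, Decimal):
        return Fraction(value)
    if isinstance(value, str):
        s = value.strip()
        if "/" in s:
            return Fraction(s)
        return Fraction(Decimal(s))
    raise TypeError(f"cannot interpret {value!r} as a rational weight")


def format_rational(q: Fraction) -> str:
    """``5`` or ``11/4`` — the exact serialized form used everywhere."""
    q = Fraction(q)
    return str(q.numerator) if q.denominator == 1 else f"{q.numerator}/{q.denominator}"


class ClusterWeighting:
    """A weighting ω ∈ L(C): one exact rational per cluster of a system.

    The domain is exactly the system's clusters; zero and negative
    weights are allowed (the space of weightings is all of R^C).
    """

    __slots__ = ("system", "_w")

    def __init__(self, system: ClusterSystem, weights: Mapping[Cluster, object]):
        w = {frozenset(c): as_rational(v) for c, v in weights.items()}
        if set(w) != set(system.clusters):
            missing = set(system.clusters) - set(w)
            extra = set(w) - set(system.clusters)
            parts = []
            if missing:
                parts.append(f"missing weights for {sorted(map(sorted, missing))}")
            if extra:
                parts.append(f"weights for non-members {sorted(map(sorted, extra))}")
            raise ValueError("; ".join(parts))
        self.system = system
        self._w = w

    def weight(self, c: Cluster) -> Fraction:
        return self._w[frozenset(c)]

    def items(self) -> Iterator[tuple[Cluster, Fraction]]:
        for c in self.system.ordered:
            yield c, self._w[c]

    def total(self) -> Fraction:
        return sum(self._w.values(), Fraction(0))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ClusterWeighting)
            and self.system == other.system
            and self._w == other._w
        )

    def __repr__(self) -> str:
        shown = ", ".join(
            "{" + ",".join(sorted(c)) + "}:" + format_rational(v) for c, v in self.items()
        )
        return f"ClusterWeighting({shown})"


class IndexVector(Mapping):
    """A per-taxon score vector (map taxon → exact rational)."""

    __slots__ = ("taxa", "_v")

    def __init__(self, taxa: TaxonSet, values: Mapping[str, object]):
        v = {x: as_rational(q) for x, q in values.items()}
        if set(v) != set(taxa.labels):
            raise ValueError("index vector domain must equal the taxon set")
        self.taxa = taxa
        self._v = v

    def __getitem__(self, x: str) -> Fraction:
        return self._v[x]

    def __iter__(self) -> Iterator[str]:
        return iter(self.taxa.labels)

    def __len__(self) -> int:
        return len(self.taxa)

    def total(self) -> Fraction:
        return sum(self._v.values(), Fraction(0))

    def as_tuple(self) -> tuple[Fraction, ...]:
        """Values in canonical taxon order."""
        return tuple(self._v[x] for x in self.taxa.labels)

    def ranking(self) -> list[tuple[str, Fraction]]:
        """Taxa sorted by descending score; ties broken by taxon order."""
        return sorted(self._v.items(), key=lambda kv: (-kv[1], kv[0]))

    def __add__(self, other: "IndexVector") -> "IndexVector":
        if self.taxa != other.taxa:
            raise ValueError("mismatched taxon sets")
        return IndexVector(self.taxa, {x: self._v[x] + other._v[x] for x in self.taxa})

    def __rmul__(self, a) -> "IndexVector":
        a = as_rational(a)
        return IndexVector(self.taxa, {x: a * self._v[x] for x in self.taxa})

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, IndexVector)
            and self.taxa == other.taxa
            and self._v == other._v
        )

    def __repr__(self) -> str:
        shown = ", ".join(f"{x}:{format_rational(self._v[x])}" for x in self.taxa)
        return f"IndexVector({shown})"


class IndexMatrix:
    """The |rows|×|X| coefficient matrix Γ of a linear index.

    Rows are keyed by clusters (or splits, for split-based indices);
    columns follow the canonical taxon order.  ``apply`` reproduces the
    index: ``(Γω)(x) = Σ_row ω(row)·γ_(row,x)``.
    """

    __slots__ = ("rows", "taxa", "_e")

    def __init__(self, rows: Iterable, taxa: TaxonSet, entries: Mapping):
        self.rows = tuple(rows)
        self.taxa = taxa
        e = {}
        for r in self.rows:
            for x in taxa:
                e[(r, x)] = as_rational(entries[(r, x)])
        self._e = e

    def entry(self, row, x: str) -> Fraction:
        return self._e[(row, x)]

    def row(self, row) -> tuple[Fraction, ...]:
        return tuple(self._e[(row, x)] for x in self.taxa)

    def row_sum(self, row) -> Fraction:
        return sum(self.row(row), Fraction(0))

    def apply(self, weighting) -> IndexVector:
        """Multiply Γᵀ by a weighting over the same row keys."""
        values = {x: Fraction(0) for x in self.taxa}
        for r in self.rows:
            w = weighting.weight(r)
            if w == 0:
                continue
            for x in self.taxa:
                values[x] += w * self._e[(r, x)]
        return IndexVector(self.taxa, values)

    def drop_row(self, row) -> "IndexMatrix":
        if row not in self.rows:
            raise KeyError("row not present")
        kept = [r for r in self.rows if r != row]
        return IndexMatrix(
            kept, self.taxa, {(r, x): self._e[(r, x)] for r in kept for x in self.taxa}
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, IndexMatrix)
            and self.taxa == other.taxa
            and set(self.rows) == set(other.rows)
            and all(
                self._e[(r, x)] == other._e[(r, x)]
                for r in self.rows
                for x in self.taxa
            )
        )

    def __repr__(self) -> str:
        return f"IndexMatrix({len(self.rows)}x{len(self.taxa)})"


# ---------------------------------------------------------------------------
# the indices
# ---------------------------------------------------------------------------

def fair_proportion(omega: ClusterWeighting) -> IndexVector:
    """FP(ω)(x) = Σ over clusters C containing x of ω(C)/|C|."""
    taxa = omega.system.taxa
    values = {x: Fraction(0) for x in taxa}
    for c, w in omega.items():
        share = w / len(c)
        for x in c:
            values[x] += share
    return IndexVector(taxa, values)


def equal_splits_coefficients(cs: ClusterSystem) -> dict[tuple[Cluster, str], Fraction]:
    """The coefficients m_x(C) of the equal splits index.

    m_x(C) is 0 for x ∉ C; 1/(|ch(C)|+|cl(C)|) for x uncovered in C; and
    otherwise the children's coefficients for x divided by the same
    denominator.  The recursion is evaluated over clusters in increasing
    size (every child is strictly smaller, so this is a valid topological
    order); on non-hierarchies overlapping children each contribute,
    exactly as the defining recursion states, with no renormalization.
    """
    ch = {c: children(cs, c) for c in cs.clusters}
    cl = {c: cluster_free_taxa(cs, c) for c in cs.clusters}
    m: dict[tuple[Cluster, str], Fraction] = {}
    for c in sorted(cs.clusters, key=_cluster_key):
        denom = len(ch[c]) + len(cl[c])
        for x in cs.taxa:
            if x not in c:
                m[(c, x)] = Fraction(0)
            elif x in cl[c]:
                m[(c, x)] = Fraction(1, denom)
            else:
                m[(c, x)] = (
                    sum((m[(cp, x)] for cp in ch[c]), Fraction(0)) / denom
                )
    return m


def equal_splits(omega: ClusterWeighting) -> IndexVector:
    """ES(ω)(x) = Σ_C m_x(C)·ω(C)."""
    m = equal_splits_coefficients(omega.system)
    taxa = omega.system.taxa
    values = {x: Fraction(0) for x in taxa}
    for c, w in omega.items():
        if w == 0:
            continue
        for x in taxa:
            values[x] += m[(c, x)] * w
    return IndexVector(taxa, values)


def index_matrix(index_name: str, cs: ClusterSystem) -> IndexMatrix:
    """The Γ matrix of a named cluster index on ``cs``.

    ``fair_proportion``: γ_(C,x) = 1/|C| for x ∈ C, else 0.
    ``equal_splits``:    γ_(C,x) = m_x(C).
    """
    taxa = cs.taxa
    if index_name == "fair_proportion":
        entries = {
            (c, x): (Fraction(1, len(c)) if x in c else Fraction(0))
            for c in cs.ordered
            for x in taxa
        }
    elif index_name == "equal_splits":
        m = equal_splits_coefficients(cs)
        entries = {(c, x): m[(c, x)] for c in cs.ordered for x in taxa}
    else:
        raise ValueError(f"unknown index name: {index_name!r}")
    return IndexMatrix(cs.ordered, taxa, entries)


def restrict(omega: ClusterWeighting, c: Cluster) -> ClusterWeighting:
    """Delete cluster ``c`` from the system, keeping all other weights.

    Taxa are unchanged; for the equal splits index the child relation of
    the reduced system is recomputed from scratch when the index is next
    evaluated, so coefficients of remaining clusters may change.
    """
    c = frozenset(c)
    reduced = omega.system.without(c)
    return ClusterWeighting(
        reduced, {d: omega.weight(d) for d in reduced.clusters}
    )


# ---------------------------------------------------------------------------
# axiom checkers
# ---------------------------------------------------------------------------

@dataclass
class PropertyReport:
    """Outcome of the axiom checks on a linear index's Γ matrix.

    ``complete``: every row sums to 1.
    ``neutral`` (NC): rows of childless clusters are constant on members.
    ``descendant_diversity`` (DD): complete, non-negative, zero off-cluster.
    ``nonnegative``: no negative entry (reported separately; negative
    entries are legal, e.g. for some right-inverse based split indices).
    ``pareto_efficient``: filled only when a game context is supplied.
    """

    complete: bool
    neutral: bool
    descendant_diversity: bool
    nonnegative: bool
    pareto_efficient: Optional[bool] = None
    notes: list = field(default_factory=list)


def check_properties(gamma: IndexMatrix, cs: ClusterSystem) -> PropertyReport:
    """Check completeness, neutrality (NC) and descendant diversity (DD)
    of a linear index given by its matrix on ``cs``.  Violations are
    recorded with witnesses in ``notes``."""
    if set(gamma.rows) != set(cs.clusters) or gamma.taxa != cs.taxa:
        raise ValueError("matrix rows/columns do not match the cluster system")
    notes: list[str] = []

    complete = True
    for c in gamma.rows:
        s = gamma.row_sum(c)
        if s != 1:
            complete = False
            notes.append(
                f"row {{{','.join(sorted(c))}}} sums to {format_rational(s)}, not 1"
            )

    neutral = True
    for c in gamma.rows:
        if children(cs, c):
            continue
        vals = {gamma.entry(c, x) for x in c}
        if len(vals) > 1:
            neutral = False
            notes.append(
                f"childless cluster {{{','.join(sorted(c))}}} has unequal member entries"
            )

    nonnegative = True
    off_support_zero = True
    for c in gamma.rows:
        for x in gamma.taxa:
            v = gamma.entry(c, x)
            if v < 0:
                nonnegative = False
                notes.append(
                    f"negative entry {format_rational(v)} at ({{{','.join(sorted(c))}}}, {x})"
                )
            if x not in c and v != 0:
                off_support_zero = False
                notes.append(
                    f"non-zero entry for {x} outside cluster {{{','.join(sorted(c))}}}"
                )

    dd = complete and nonnegative and off_support_zero
    return PropertyReport(
        complete=complete,
        neutral=neutral,
        descendant_diversity=dd,
        nonnegative=nonnegative,
        notes=notes,
    )


def check_downward_continuity(
    gamma: IndexMatrix, gamma_star: IndexMatrix, c: Cluster
) -> bool:
    """Downward continuity (DC) for linear indices, checked structurally.

    For a linear index the limit of Φ(ω) as ω(C) → 0 is the linear map
    with Γ's row C deleted, so DC holds iff deleting row C from Γ yields
    Γ* entrywise.
    """
    c = frozenset(c)
    if c not in gamma.rows:
        raise KeyError("cluster is not a row of the larger matrix")
    if set(gamma_star.rows) != set(gamma.rows) - {c}:
        raise ValueError("reduced matrix must be indexed by the system minus the cluster")
    return gamma.drop_row(c) == gamma_star
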