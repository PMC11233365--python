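"""Pauplin-type indices on circular split systems.

A circular split system S (all splits are intervals of one cyclic taxon
ordering θ) has a split–pair incidence matrix M(S) with a 1 wherever a
split separates a pair of taxa; a weighting λ then induces pairwise
distances d_λ = λ·M.  Because the rows of M are linearly independent,
M has right inverses R (M·R = I), each of which is a linear estimator of
split weights from distances.  Every such R defines the complete linear
index

    Ψ_R(λ)(x) = 1/2 · Σ_{y ≠ x} Σ_S d_λ({x,y}) · r_({x,y},S),

a generalization of the classical Pauplin tree-length weighting scheme.

For the *full* system S_θ (all n(n-1)/2 interval splits) M is square and
its unique inverse has an explicit four-entries-per-column form (±1/2 on
the pairs straddling the interval's ends); the resulting Γ matrix has
the closed form: 1/2 on a singleton part, 1/4 on a cyclic endpoint of a
larger part, 0 on interior taxa.  For proper circular subsystems two
canonical indices are provided: Ψ₁ restricts the full system's Γ rows,
Ψ₂ restricts the full inverse's columns (which remains a right inverse
of the smaller M).

Right-inverse constructions are validated by asserting M·R = I exactly
at build time, so an index-convention mistake cannot propagate silently.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Mapping, Optional

from .games import SplitWeighting
from .indices import IndexMatrix, IndexVector, as_rational
from .systems import (
    CircularOrdering,
    Split,
    SplitSystem,
    _is_cyclic_interval,
    is_circular,
)

__all__ = [
    "full_circular_system",
    "PairIncidenceMatrix",
    "pair_incidence",
    "DistanceVector",
    "distances",
    "RightInverse",
    "full_right_inverse",
    "psi_r",
    "psi_r_matrix",
    "full_gamma_entry",
    "full_gamma_matrix",
    "restricted_psi",
]

Pair = tuple[str, str]


def _pair(x: str, y: str) -> Pair:
    if x == y:
        raise ValueError("a pair must consist of two distinct taxa")
    return (x, y) if x < y else (y, x)


def full_circular_system(theta: CircularOrdering) -> SplitSystem:
    """S_θ: all splits with one part an interval x_i..x_j, j < n-1.

    Contains exactly n(n-1)/2 distinct splits — the maximum any circular
    system can have.
    """
    n = len(theta)
    if n < 3:
        raise ValueError("full circular systems need at least 3 taxa")
    order = theta.order
    full = frozenset(order)
    splits = set()
    for i in range(n - 1):
        for j in range(i, n - 1):
            part = frozenset(order[i : j + 1])
            splits.add(Split(part, full - part))
    return SplitSystem(theta.taxa, splits)


class PairIncidenceMatrix:
    """M(S): rows = splits, columns = 2-subsets of X (lexicographic);
    entry 1 iff the split separates the pair."""

    __slots__ = ("system", "splits", "pairs", "_m")

    def __init__(self, system: SplitSystem):
        self.system = system
        self.splits = system.ordered
        self.pairs: list[Pair] = system.taxa.pairs()
        self._m = {
            (s, p): (1 if s.separates(*p) else 0)
            for s in self.splits
            for p in self.pairs
        }

    def entry(self, s: Split, pair: Pair) -> int:
        return self._m[(s, _pair(*pair))]

    def row(self, s: Split) -> tuple[int, ...]:
        return tuple(self._m[(s, p)] for p in self.pairs)

    def rank(self) -> int:
        import sympy

        return sympy.Matrix([self.row(s) for s in self.splits]).rank()


def pair_incidence(ss: SplitSystem) -> PairIncidenceMatrix:
    return PairIncidenceMatrix(ss)


class DistanceVector:
    """Pairwise distances d({x,y}) induced by a split weighting."""

    __slots__ = ("taxa", "_d")

    def __init__(self, taxa, values: Mapping[Pair, object]):
        self.taxa = taxa
        self._d = {_pair(*p): as_rational(v) for p, v in values.items()}
        if set(self._d) != set(taxa.pairs()):
            raise ValueError("distance vector must cover every 2-subset exactly once")

    def get(self, x: str, y: str) -> Fraction:
        return self._d[_pair(x, y)]

    def items(self):
        for p in self.taxa.pairs():
            yield p, self._d[p]


def distances(lam: SplitWeighting) -> DistanceVector:
    """d_λ({x,y}) = Σ_S λ(S)·m_(S,{x,y}), i.e. d_λ = λ·M."""
    taxa = lam.system.taxa
    values = {p: Fraction(0) for p in taxa.pairs()}
    for s, w in lam.items():
        if w == 0:
            continue
        for p in taxa.pairs():
            if s.separates(*p):
                values[p] += w
    return DistanceVector(taxa, values)


class RightInverse:
    """An (n choose 2) × |S| matrix R with M(S)·R = I, verified exactly.

    Rows are 2-subsets of X, columns are the splits of the system.
    Entries are stored sparsely; construction fails loudly if R is not a
    right inverse of the system's pair-incidence matrix.
    """

    __slots__ = ("system", "splits", "pairs", "_r")

    def __init__(self, system: SplitSystem, entries: Mapping[tuple[Pair, Split], object]):
        self.system = system
        self.splits = system.ordered
        self.pairs: list[Pair] = system.taxa.pairs()
        r = {}
        for (p, s), v in entries.items():
            key = (_pair(*p), s)
            if s not in system.splits:
                raise ValueError(f"entry for split not in system: {s!r}")
            r[key] = r.get(key, Fraction(0)) + as_rational(v)
        self._r = {k: v for k, v in r.items() if v != 0}
        self._verify()

    def _verify(self) -> None:
        m = PairIncidenceMatrix(self.system)
        for s_row in self.splits:
            for s_col in self.splits:
                acc = Fraction(0)
                for p in self.pairs:
                    rv = self._r.get((p, s_col))
                    if rv is not None and m.entry(s_row, p):
                        acc += rv
                expected = 1 if s_row == s_col else 0
                if acc != expected:
                    raise ValueError(
                        f"not a right inverse: (M R)[{s_row!r},{s_col!r}] = {acc}"
                    )

    def entry(self, pair: Pair, s: Split) -> Fraction:
        return self._r.get((_pair(*pair), s), Fraction(0))

    def row_total(self, pair: Pair) -> Fraction:
        """Σ_S r_(pair,S) — the only aggregate Ψ_R needs per pair."""
        p = _pair(*pair)
        return sum(
            (v for (pp, _s), v in self._r.items() if pp == p), Fraction(0)
        )

    def restrict_columns(self, subsystem: SplitSystem) -> "RightInverse":
        """Keep only the columns of the given subsystem; the result is
        re-verified as a right inverse of the subsystem's M."""
        if not subsystem.splits <= self.system.splits:
            raise ValueError("subsystem is not contained in this inverse's system")
        entries = {
            (p, s): v for (p, s), v in self._r.items() if s in subsystem.splits
        }
        return RightInverse(subsystem, entries)


def full_right_inverse(theta: CircularOrdering) -> RightInverse:
    """The unique inverse of the square matrix M(S_θ), in closed form.

    For the split with interval part {x_a,...,x_b} (positions along θ,
    avoiding x_{n-1}) the non-zero column entries sit on the four pairs
    straddling the interval boundary: +1/2 on {x_a, x_{b+1}} and
    {x_{a-1}, x_b}, -1/2 on {x_a, x_b} and {x_{a-1}, x_{b+1}} (indices
    mod n; degenerate coincident pairs are skipped).  Validated against
    M·R = I at construction.
    """
    ss = full_circular_system(theta)
    n = len(theta)
    order = theta.order
    half = Fraction(1, 2)
    entries: dict[tuple[Pair, Split], Fraction] = {}
    for s in ss:
        # the part avoiding the last element of theta is a linear interval
        part = s.part_a if order[n - 1] not in s.part_a else s.part_b
        positions = sorted(theta.position(x) for x in part)
        a, b = positions[0], positions[-1]
        candidates = (
            (a, (b + 1) % n, half),
            ((a - 1) % n, b, half),
            (a, b, -half),
            ((a - 1) % n, (b + 1) % n, -half),
        )
        for p, q, v in candidates:
            if p == q:
                continue
            key = (_pair(order[p], order[q]), s)
            entries[key] = entries.get(key, Fraction(0)) + v
    return RightInverse(ss, entries)


def psi_r(lam: SplitWeighting, r: RightInverse) -> IndexVector:
    """Ψ_R(λ)(x) = 1/2 · Σ_{y≠x} Σ_S d_λ({x,y}) · r_({x,y},S)."""
    if lam.system != r.system:
        raise ValueError("weighting and right inverse are on different systems")
    d = distances(lam)
    taxa = lam.system.taxa
    values = {}
    for x in taxa:
        acc = Fraction(0)
        for y in taxa:
            if y == x:
                continue
            acc += d.get(x, y) * r.row_total((x, y))
        values[x] = acc / 2
    return IndexVector(taxa, values)


def psi_r_matrix(ss: SplitSystem, r: RightInverse) -> IndexMatrix:
    """Γ_{Ψ_R}: γ_(S,x) = 1/2·Σ_{y≠x} Σ_{S'} m_(S,{x,y})·r_({x,y},S').

    Every row sums exactly to 1 (Ψ_R is complete for any right inverse);
    entries may be negative, which :func:`phylodiv.indices.check_properties`
    would flag on the corresponding cluster-side report.
    """
    if ss != r.system:
        raise ValueError("system and right inverse do not match")
    taxa = ss.taxa
    entries = {}
    for s in ss.ordered:
        for x in taxa:
            acc = Fraction(0)
            for y in taxa:
                if y == x or not s.separates(x, y):
                    continue
                acc += r.row_total((x, y))
            entries[(s, x)] = acc / 2
    return IndexMatrix(ss.ordered, taxa, entries)


def full_gamma_entry(theta: CircularOrdering, s: Split, x: str) -> Fraction:
    """Closed-form Γ entry for the full system S_θ.

    Let P be the part of the split containing x (a cyclic interval of θ):
    1/2 if P is a singleton, 1/4 if x is a cyclic endpoint of a larger P,
    0 if x is interior.  Equals the entry of Γ_{Ψ_R} for the unique right
    inverse of M(S_θ).
    """
    n = len(theta)
    part = s.side_containing(x)
    positions = frozenset(theta.position(z) for z in part)
    if not _is_cyclic_interval(positions, n) or not _is_cyclic_interval(
        frozenset(range(n)) - positions, n
    ):
        raise ValueError("split is not an interval split of the given ordering")
    k = theta.position(x)
    outside = sum(1 for q in ((k - 1) % n, (k + 1) % n) if q not in positions)
    return {2: Fraction(1, 2), 1: Fraction(1, 4), 0: Fraction(0)}[outside]


def full_gamma_matrix(theta: CircularOrdering) -> IndexMatrix:
    """Γ for Ψ_R on the full system S_θ, via the closed form."""
    ss = full_circular_system(theta)
    entries = {
        (s, x): full_gamma_entry(theta, s, x) for s in ss.ordered for x in ss.taxa
    }
    return IndexMatrix(ss.ordered, ss.taxa, entries)


def restricted_psi(
    ss: SplitSystem, theta: CircularOrdering, variant: str = "psi1"
) -> IndexMatrix:
    """Γ matrix of the Ψ₁/Ψ₂ index on a circular subsystem of S_θ.

    ``psi1``: rows of the full system's closed-form Γ, restricted to the
    splits of ``ss``.  ``psi2``: Ψ_{R'} where R' keeps only the columns
    of the full right inverse belonging to ``ss`` (re-verified as a right
    inverse of M(ss)).  Both indices are complete.
    """
    if not is_circular(ss, theta):
        raise ValueError("split system is not circular with respect to the ordering")
    if variant == "psi1":
        entries = {
            (s, x): full_gamma_entry(theta, s, x) for s in ss.ordered for x in ss.taxa
        }
        return IndexMatrix(ss.ordered, ss.taxa, entries)
    if variant == "psi2":
        r_full = full_right_inverse(theta)
        r_sub = r_full.restrict_columns(ss)
        return psi_r_matrix(ss, r_sub)
    raise ValueError(f"unknown variant: {variant!r} (expected 'psi1' or 'psi2')")
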