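"""The affine–projective bridge between split and cluster indices.

Every split system S yields the cluster system C(S) consisting of the
parts of its splits.  A linear map τ: L(S) → L(C(S)) turns any cluster
index Φ into the split index Ψ_τ(Φ) = Φ ∘ τ.  Two τ maps are provided:

* :func:`tau_shapley` gives part A of split A|B the weight |B|/|X|·λ(A|B);
  composing with fair proportion reproduces the Shapley value of the
  split PD game exactly.
* :func:`tau_even` splits each weight p : (1-p) between the two parts
  (default p = 1/2); it preserves total weight for any p, so lifting any
  complete cluster index yields a complete split index.

With Φ = fair proportion and the even τ, the lifted index has the closed
form ``Σ_{A|B: x∈A} λ(A|B)/(2|A|)`` — the unrooted fair proportion index.

When two splits share a part, their τ contributions to that cluster
accumulate additively (the only choice making τ a well-defined linear
map).
"""

from __future__ import annotations

from fractions import Fraction

from .indices import (
    ClusterWeighting,
    IndexVector,
    as_rational,
    equal_splits,
    fair_proportion,
)
from .games import SplitWeighting
from .systems import clusters_of_splits

__all__ = [
    "tau_shapley",
    "tau_even",
    "lift_index",
    "unrooted_fair_proportion",
]


def tau_shapley(lam: SplitWeighting) -> ClusterWeighting:
    """τ(λ)(A) = |B|/|X| · λ(A|B), accumulated over shared parts."""
    cs = clusters_of_splits(lam.system)
    n = len(lam.system.taxa)
    weights = {c: Fraction(0) for c in cs.clusters}
    for s, w in lam.items():
        for part in s.parts:
            weights[part] += Fraction(len(s.other(part)), n) * w
    return ClusterWeighting(cs, weights)


def tau_even(lam: SplitWeighting, p=Fraction(1, 2)) -> ClusterWeighting:
    """τ(λ)(A) = p·λ(A|B) and τ(λ)(B) = (1-p)·λ(A|B), 0 < p < 1.

    ``p`` applies to the canonical first part of each split (the part
    holding the lexicographically smallest taxon); total weight is
    preserved for every p since p + (1-p) = 1.
    """
    p = as_rational(p)
    if not (0 < p < 1):
        raise ValueError("p must lie strictly between 0 and 1")
    cs = clusters_of_splits(lam.system)
    weights = {c: Fraction(0) for c in cs.clusters}
    for s, w in lam.items():
        weights[s.part_a] += p * w
        weights[s.part_b] += (1 - p) * w
    return ClusterWeighting(cs, weights)


_CLUSTER_INDICES = {
    "fair_proportion": fair_proportion,
    "equal_splits": equal_splits,
}


def lift_index(
    index_name: str, tau_name: str, lam: SplitWeighting, p=Fraction(1, 2)
) -> IndexVector:
    """Ψ_τ(Φ)(λ) = Φ(τ(λ)) on C(S).

    ``index_name`` ∈ {fair_proportion, equal_splits}; ``tau_name`` ∈
    {shapley, even} (``p`` is only meaningful for the even map).  The
    cluster system C(S) and, for equal splits, its child relation are
    recomputed from scratch on every call.
    """
    try:
        phi = _CLUSTER_INDICES[index_name]
    except KeyError:
        raise ValueError(f"unknown cluster index: {index_name!r}") from None
    if tau_name == "shapley":
        omega = tau_shapley(lam)
    elif tau_name == "even":
        omega = tau_even(lam, p)
    else:
        raise ValueError(f"unknown tau variant: {tau_name!r}")
    return phi(omega)


def unrooted_fair_proportion(lam: SplitWeighting) -> IndexVector:
    """FP_u(λ)(x) = Σ over splits A|B with x ∈ A of λ(A|B)/(2·|A|).

    Direct closed form; agrees exactly with lifting fair proportion
    through the even τ at p = 1/2.
    """
    taxa = lam.system.taxa
    values = {x: Fraction(0) for x in taxa}
    for s, w in lam.items():
        for part in s.parts:
            share = w / (2 * len(part))
            for x in part:
                values[x] += share
    return IndexVector(taxa, values)
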