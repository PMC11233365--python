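"""Readers and writers: Newick trees, weighted-system TSV, NEXUS splits
blocks (SplitsTree dialect) and PHYLIP distance matrices.

Weights are serialized as exact fraction strings (``7/2``) or integers;
readers additionally accept decimal and scientific notation, converted
exactly.  All round trips are lossless on the rational values.

Trees are parsed with dendropy and immediately decomposed:

* :func:`tree_to_clusters` — one cluster per edge of the rooted tree
  (the leaves below it), weighted by the branch length;
* :func:`tree_to_splits` — one split per edge of the unrooted tree.
  A degree-2 root is suppressed implicitly: its two child edges induce
  the same bipartition, and their weights merge by summation.
"""

from __future__ import annotations

import json
import re
import warnings
from decimal import Decimal
from fractions import Fraction
from typing import Optional, TextIO, Union

import dendropy

from .circular import DistanceVector
from .games import SplitWeighting
from .indices import ClusterWeighting, IndexVector, as_rational, format_rational
from .systems import (
    CircularOrdering,
    ClusterSystem,
    Split,
    SplitSystem,
    TaxonSet,
    is_circular,
    make_split,
)

__all__ = [
    "WeightedTree",
    "read_newick",
    "tree_to_clusters",
    "tree_to_splits",
    "dumps_cluster_weighting",
    "loads_cluster_weighting",
    "dumps_split_weighting",
    "loads_split_weighting",
    "dumps_nexus_splits",
    "loads_nexus_splits",
    "dumps_phylip_distances",
    "index_vector_to_json",
]


class WeightedTree:
    """A rooted tree with exact-rational branch lengths (missing → 0)."""

    __slots__ = ("_tree", "taxa")

    def __init__(self, tree: dendropy.Tree):
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("every leaf must carry a label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        self._tree = tree
        self.taxa = TaxonSet(labels)

    @property
    def root_degree(self) -> int:
        return len(self._tree.seed_node.child_nodes())

    def edge_clusters(self) -> list[tuple[frozenset, Fraction]]:
        """(leaves-below, branch length) for every non-root node."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            length = node.edge.length
            w = Fraction(0) if length is None else as_rational(length)
            out.append((leaves, w))
        return out


def read_newick(text: str) -> WeightedTree:
    """Parse one Newick tree from a string.

    Branch lengths are converted to exact rationals via their decimal
    representation; parse failures raise ValueError.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"invalid Newick: {exc}") from exc
    return WeightedTree(tree)


def tree_to_clusters(tree: WeightedTree) -> ClusterWeighting:
    """One cluster per edge (the leaves below it), weight = branch length.

    Degree-2 chains produce duplicate clusters; these are merged with
    summed weights and a warning.
    """
    acc: dict[frozenset, Fraction] = {}
    seen_duplicate = False
    for leaves, w in tree.edge_clusters():
        if leaves in acc:
            seen_duplicate = True
        acc[leaves] = acc.get(leaves, Fraction(0)) + w
    if seen_duplicate:
        warnings.warn(
            "duplicate clusters from unresolved degree-2 chains merged with summed weights"
        )
    system = ClusterSystem(tree.taxa, acc.keys())
    return ClusterWeighting(system, acc)


def tree_to_splits(tree: WeightedTree) -> SplitWeighting:
    """One split per edge of the unrooted tree, trivial splits included.

    Both child edges of a degree-2 root induce the same bipartition, so
    suppressing the root amounts to the canonical-form merge of their
    weights; roots of degree ≥ 3 contribute one split per child as-is.
    """
    if len(tree.taxa) < 2:
        raise ValueError("splits need at least 2 leaves")
    full = tree.taxa.as_set()
    acc: dict[Split, Fraction] = {}
    for leaves, w in tree.edge_clusters():
        if leaves == full:
            continue  # degenerate edge above a subtree holding all leaves
        s = Split(leaves, full - leaves)
        acc[s] = acc.get(s, Fraction(0)) + w
    system = SplitSystem(tree.taxa, acc.keys())
    return SplitWeighting(system, acc)


# ---------------------------------------------------------------------------
# TSV: "#taxa: a,b,c,..." header, then "<members><TAB><weight>" records
# ---------------------------------------------------------------------------

def _parse_header(line: str) -> TaxonSet:
    m = re.match(r"#taxa:\s*(.+)$", line.strip())
    if not m:
        raise ValueError("first line must be '#taxa: a,b,c,...'")
    return TaxonSet([t.strip() for t in m.group(1).split(",")])


def _parse_records(text: str):
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty input")
    taxa = _parse_header(lines[0])
    records = []
    for no, ln in enumerate(lines[1:], start=2):
        if ln.lstrip().startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {no}: expected '<members><TAB><weight>'")
        members = frozenset(t.strip() for t in parts[0].split(","))
        try:
            weight = as_rational(parts[1].strip())
        except Exception as exc:
            raise ValueError(f"line {no}: bad weight {parts[1]!r}") from exc
        records.append((members, weight))
    if not records:
        raise ValueError("no records")
    return taxa, records


def dumps_cluster_weighting(omega: ClusterWeighting) -> str:
    lines = ["#taxa: " + ",".join(omega.system.taxa.labels)]
    for c, w in omega.items():
        lines.append(",".join(sorted(c)) + "\t" + format_rational(w))
    return "\n".join(lines) + "\n"


def loads_cluster_weighting(text: str) -> ClusterWeighting:
    taxa, records = _parse_records(text)
    acc: dict[frozenset, Fraction] = {}
    dup = False
    for members, w in records:
        if members in acc:
            dup = True
        acc[members] = acc.get(members, Fraction(0)) + w
    if dup:
        warnings.warn("duplicate cluster records merged with summed weights")
    system = ClusterSystem(taxa, acc.keys())
    return ClusterWeighting(system, acc)


def dumps_split_weighting(lam: SplitWeighting) -> str:
    """One part per line (the canonical part holding the smallest taxon);
    the complement is implied."""
    lines = ["#taxa: " + ",".join(lam.system.taxa.labels)]
    for s, w in lam.items():
        lines.append(",".join(sorted(s.part_a)) + "\t" + format_rational(w))
    return "\n".join(lines) + "\n"


def loads_split_weighting(text: str) -> SplitWeighting:
    taxa, records = _parse_records(text)
    acc: dict[Split, Fraction] = {}
    dup = False
    for members, w in records:
        s = make_split(taxa, members)
        if s in acc:
            dup = True
        acc[s] = acc.get(s, Fraction(0)) + w
    if dup:
        warnings.warn("duplicate split records merged with summed weights")
    system = SplitSystem(taxa, acc.keys())
    return SplitWeighting(system, acc)


# ---------------------------------------------------------------------------
# NEXUS splits block (SplitsTree dialect: TAXA + SPLITS, CYCLE, WEIGHTS)
# ---------------------------------------------------------------------------

def dumps_nexus_splits(lam: SplitWeighting, cycle: Optional[CircularOrdering] = None) -> str:
    taxa = lam.system.taxa
    n = len(taxa)
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={n};",
        "TAXLABELS " + " ".join(taxa.labels) + ";",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"DIMENSIONS NTAX={n} NSPLITS={len(lam.system)};",
        "FORMAT LABELS=NO WEIGHTS=YES;",
    ]
    if cycle is not None:
        idx = " ".join(str(taxa.index(x) + 1) for x in cycle.order)
        lines.append(f"CYCLE {idx};")
    lines.append("MATRIX")
    for s, w in lam.items():
        ids = " ".join(str(taxa.index(x) + 1) for x in sorted(s.part_a, key=taxa.index))
        lines.append(f" {format_rational(w)} {ids},")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def loads_nexus_splits(text: str) -> tuple[SplitWeighting, Optional[CircularOrdering]]:
    """Parse a TAXA + SPLITS NEXUS file; a CYCLE statement, if present,
    is returned as a CircularOrdering and validated against the splits."""
    body = re.sub(r"\[[^\]]*\]", " ", text)  # strip NEXUS comments
    if not body.lstrip().upper().startswith("#NEXUS"):
        raise ValueError("not a NEXUS file")

    m = re.search(r"TAXLABELS(.*?);", body, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError("missing TAXLABELS")
    labels = m.group(1).replace("'", " ").split()
    taxa = TaxonSet(labels)

    sb = re.search(r"BEGIN\s+SPLITS\s*;(.*?)END\s*;", body, re.IGNORECASE | re.DOTALL)
    if not sb:
        raise ValueError("missing SPLITS block")
    block = sb.group(1)

    weights_on = True
    fm = re.search(r"FORMAT([^;]*);", block, re.IGNORECASE)
    if fm and re.search(r"WEIGHTS\s*=\s*NO", fm.group(1), re.IGNORECASE):
        weights_on = False

    cycle = None
    cm = re.search(r"CYCLE([^;]*);", block, re.IGNORECASE)
    if cm:
        order = [labels[int(i) - 1] for i in cm.group(1).split()]
        cycle = CircularOrdering(order)

    mm = re.search(r"MATRIX(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mm:
        raise ValueError("missing MATRIX in SPLITS block")
    acc: dict[Split, Fraction] = {}
    dup = False
    for raw in mm.group(1).split(","):
        tokens = raw.split()
        if not tokens:
            continue
        if weights_on:
            w = as_rational(tokens[0])
            ids = tokens[1:]
        else:
            w = Fraction(1)
            ids = tokens
        members = frozenset(labels[int(i) - 1] for i in ids)
        s = make_split(taxa, members)
        if s in acc:
            dup = True
        acc[s] = acc.get(s, Fraction(0)) + w
    if not acc:
        raise ValueError("empty MATRIX in SPLITS block")
    if dup:
        warnings.warn("duplicate split records merged with summed weights")
    system = SplitSystem(taxa, acc.keys())
    lam = SplitWeighting(system, acc)
    if cycle is not None and not is_circular(system, cycle):
        raise ValueError("CYCLE ordering does not make the split system circular")
    return lam, cycle


# ---------------------------------------------------------------------------
# PHYLIP distances and JSON output
# ---------------------------------------------------------------------------

def dumps_phylip_distances(d: DistanceVector) -> str:
    """Square symmetric PHYLIP matrix (zero diagonal, decimal entries)."""
    labels = d.taxa.labels
    lines = [f"{len(labels)}"]
    for x in labels:
        row = []
        for y in labels:
            v = Fraction(0) if x == y else d.get(x, y)
            row.append(f"{float(v):.10g}")
        lines.append(f"{x:<10}" + " ".join(row))
    return "\n".join(lines) + "\n"


def index_vector_to_json(vec: IndexVector) -> str:
    """Exact-fraction JSON for an index vector, taxa in canonical order."""
    payload = {
        "values": {x: format_rational(vec[x]) for x in vec.taxa},
        "total": format_rational(vec.total()),
    }
    return json.dumps(payload, indent=2)
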