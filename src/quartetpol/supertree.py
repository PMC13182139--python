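"""Clade-quartet aggregation and exhaustive rooted clade-supertree ranking.

Retained species-quartet scores are aggregated to one median support
vector per clade-quartet.  All (2n-3)!! rooted binary trees on the
ingroup clades (the outgroup roots implicitly) are then enumerated and
each tree scored by summing, over non-empty clade-quartet summaries, the
median support of the rooted triplet topology the tree induces on that
clade-quartet.  For complete clade-quartet coverage of a binary candidate
tree this induced-topology criterion selects exactly the maximal set of
compatible quartets, so the exhaustive ranking needs no heuristics.

Trees are represented as nested 2-tuples of clade labels in a canonical
(sorted-newick) form, so structural equality is plain ``==``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .quartets import TOPOLOGY_IDS, CladeQuartet
from .filtering import RETAINED, SpeciesQuartetScore

logger = logging.getLogger(__name__)

CladeTree = object  # str leaf or 2-tuple of CladeTree

_DOUBLE_FACTORIALS = {2: 1, 3: 3, 4: 15, 5: 105, 6: 945, 7: 10395, 8: 135135}


@dataclass(frozen=True)
class CladeQuartetSummary:
    """Median per-topology support over retained quartets of one clade-quartet."""

    clade_quartet: CladeQuartet
    medians: dict[str, float] | None  # None when no quartet was retained
    n_retained: int
    n_total: int

    @property
    def empty(self) -> bool:
        return self.medians is None


@dataclass
class CladeTreeRanking:
    """All candidate rooted clade trees ordered by total compatible support."""

    trees: list[CladeTree]
    supports: np.ndarray
    newicks: list[str]

    @property
    def best(self) -> CladeTree:
        return self.trees[0]

    @property
    def second_best(self) -> CladeTree:
        return self.trees[1]

    def distances(self) -> np.ndarray:
        """Support distance of each tree to the best tree (>= 0, best = 0)."""
        return self.supports[0] - self.supports

    def rank_of(self, tree: CladeTree) -> int:
        """1-based rank of a tree (canonicalised before lookup)."""
        return self.trees.index(canonical(tree)) + 1


def aggregate_clade_quartet(
    scores: Sequence[SpeciesQuartetScore],
) -> CladeQuartetSummary:
    """Per-topology medians of normalised support over retained quartets.

    Medians are not re-normalised across topologies.  An empty retained
    set yields an empty summary that tree scoring skips with a warning.
    """
    if not scores:
        raise ValueError("no scores supplied")
    cq = scores[0].quartet.clade_quartet
    retained = [sc for sc in scores if sc.status == RETAINED and sc.informative]
    if not retained:
        logger.warning("clade-quartet %s: no retained quartet; excluded from tree scoring", cq.id)
        return CladeQuartetSummary(cq, None, 0, len(scores))
    med = {
        x: float(np.median([sc.s[x] for sc in retained])) for x in TOPOLOGY_IDS
    }
    return CladeQuartetSummary(cq, med, len(retained), len(scores))


def summarize_all(
    scores: Sequence[SpeciesQuartetScore],
) -> dict[str, CladeQuartetSummary]:
    groups: dict[str, list[SpeciesQuartetScore]] = {}
    for sc in scores:
        groups.setdefault(sc.quartet.clade_quartet.id, []).append(sc)
    return {cq_id: aggregate_clade_quartet(g) for cq_id, g in sorted(groups.items())}


# ---------------------------------------------------------------------------
# tree representation


def canonical(tree: CladeTree) -> CladeTree:
    """Canonical form: children sorted by their newick strings."""
    if isinstance(tree, str):
        return tree
    left, right = (canonical(c) for c in tree)
    return tuple(sorted((left, right), key=to_newick))


def to_newick(tree: CladeTree, suffix: str = "") -> str:
    def render(t: CladeTree) -> str:
        if isinstance(t, str):
            return t
        return "(" + ",".join(render(c) for c in t) + ")"

    return render(canonical(tree)) + suffix


def leaves(tree: CladeTree) -> frozenset[str]:
    if isinstance(tree, str):
        return frozenset([tree])
    return leaves(tree[0]) | leaves(tree[1])


def clades(tree: CladeTree) -> list[frozenset[str]]:
    """All leaf sets of internal nodes (including the root, excluding leaves)."""
    out: list[frozenset[str]] = []

    def walk(t: CladeTree) -> frozenset[str]:
        if isinstance(t, str):
            return frozenset([t])
        s = walk(t[0]) | walk(t[1])
        out.append(s)
        return s

    walk(tree)
    return out


def from_newick(text: str) -> CladeTree:
    """Parse a newick string into a canonical clade tree (lengths ignored).

    Polytomies are rejected; labels are the leaf names as written.
    """
    import dendropy

    t = dendropy.Tree.get(data=text if text.strip().endswith(";") else text + ";", schema="newick")

    def convert(node) -> CladeTree:
        children = node.child_nodes()
        if not children:
            if node.taxon is None:
                raise ValueError("unlabeled leaf in newick input")
            return node.taxon.label.replace(" ", "_")
        if len(children) != 2:
            raise ValueError("clade trees must be binary")
        return (convert(children[0]), convert(children[1]))

    return canonical(convert(t.seed_node))


def prune_to(tree: CladeTree, keep: set[str]) -> CladeTree:
    """Restrict a tree to a leaf subset, suppressing unary nodes."""
    if isinstance(tree, str):
        return tree if tree in keep else None  # type: ignore[return-value]
    kids = [prune_to(c, keep) for c in tree]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None  # type: ignore[return-value]
    if len(kids) == 1:
        return kids[0]
    return (kids[0], kids[1])


# ---------------------------------------------------------------------------
# enumeration and scoring


def enumerate_rooted_clade_trees(labels: Sequence[str]) -> list[CladeTree]:
    """All (2n-3)!! rooted binary trees on the given leaf labels.

    Built by stepwise leaf insertion into every edge (including above the
    root); results are canonicalised, deduplicated, and sorted by newick
    string.  Guarded to 2 <= n <= 8.
    """
    labels = sorted(labels)
    n = len(labels)
    if not (2 <= n <= 8):
        raise ValueError("rooted clade-tree enumeration supports 2..8 clades")

    def insert_everywhere(tree: CladeTree, leaf: str) -> list[CladeTree]:
        results: list[CladeTree] = [(tree, leaf)]  # above the current root

        def rec(t: CladeTree) -> list[CladeTree]:
            subs: list[CladeTree] = [(t, leaf)]
            if not isinstance(t, str):
                for idx in (0, 1):
                    for replaced in rec(t[idx]):
                        pair = list(t)
                        pair[idx] = replaced
                        subs.append(tuple(pair))
            return subs

        if not isinstance(tree, str):
            for idx in (0, 1):
                for replaced in rec(tree[idx]):
                    pair = list(tree)
                    pair[idx] = replaced
                    results.append(tuple(pair))
        return results

    trees: list[CladeTree] = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        trees = [t2 for t in trees for t2 in insert_everywhere(t, leaf)]
    seen: dict[str, CladeTree] = {}
    for t in trees:
        c = canonical(t)
        seen[to_newick(c)] = c
    ordered = [seen[k] for k in sorted(seen)]
    if len(ordered) != _DOUBLE_FACTORIALS[n]:
        raise AssertionError("enumeration does not match (2n-3)!!")
    return ordered


def induced_quartet_topology(tree: CladeTree, cq: CladeQuartet) -> str:
    """Rooted triplet topology a clade tree induces on a clade-quartet.

    Returns the topology id whose grouped clade pair appears together in
    some clade of the tree that excludes the third ingroup clade; every
    binary tree containing the three clades induces exactly one.
    """
    trip = set(cq.ingroups)
    missing = trip - leaves(tree)
    if missing:
        raise KeyError(f"clades absent from tree: {sorted(missing)}")
    for cl in clades(tree):
        inter = cl & trip
        if len(inter) == 2:
            pair = tuple(sorted(inter))
            for topo in TOPOLOGY_IDS:
                if tuple(sorted(cq.grouped_clades(topo))) == pair:
                    return topo
    # root clade contains all three: take the cherry-most pair via pruning
    raise AssertionError("binary tree must induce a triplet topology")


def total_tree_support(
    tree: CladeTree, summaries: Mapping[str, CladeQuartetSummary]
) -> float:
    """Sum of induced-topology median supports over non-empty summaries."""
    total = 0.0
    for summ in summaries.values():
        if summ.empty:
            continue
        topo = induced_quartet_topology(tree, summ.clade_quartet)
        total += summ.medians[topo]
    return total


def rank_trees(
    summaries: Mapping[str, CladeQuartetSummary],
    ingroup_clades: Sequence[str],
) -> CladeTreeRanking:
    """Exhaustively score and sort all rooted clade trees.

    Ties are broken by canonical newick order (and logged).
    """
    usable = {k: s for k, s in summaries.items() if not s.empty}
    if not usable:
        raise ValueError("all clade-quartet summaries are empty; nothing to rank")
    candidates = enumerate_rooted_clade_trees(ingroup_clades)
    scored = sorted(
        ((total_tree_support(t, usable), t) for t in candidates),
        key=lambda st: (-st[0], to_newick(st[1])),
    )
    supports = np.array([s for s, _ in scored])
    if len(supports) > 1 and supports[0] == supports[1]:
        logger.info("tie for best clade tree; canonical newick order used")
    trees = [t for _, t in scored]
    return CladeTreeRanking(
        trees=trees,
        supports=supports,
        newicks=[to_newick(t, ";") for t in trees],
    )


def compare_topologies(t1: CladeTree, t2: CladeTree) -> dict:
    """Canonical equality plus shared/conflicting rooted-clade breakdown."""
    if leaves(t1) != leaves(t2):
        raise ValueError("trees have different leaf sets")
    c1 = {c for c in clades(t1)}
    c2 = {c for c in clades(t2)}
    return {
        "same": canonical(t1) == canonical(t2),
        "shared_clades": sorted(tuple(sorted(c)) for c in c1 & c2),
        "conflicting_clades_1": sorted(tuple(sorted(c)) for c in c1 - c2),
        "conflicting_clades_2": sorted(tuple(sorted(c)) for c in c2 - c1),
    }
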