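"""Merging GMYC entities into MOTUs under a K2P distance threshold.

Single-locus delimitation tends to over-split; entities whose mean corrected
distance falls below a fixed cutoff (default 7.3%, a between-sister-species
mean for rodents) are merged back.  Merging respects the entity tree: only
groups that are sisters on the current (pruned) tree may fuse, so every MOTU
is a clade.  The "genetic distance" between groups is the mean pairwise K2P
distance over all original sequences, which makes means additive under
merging and the fixpoint independent of merge order (disjoint qualifying
cherries do not affect each other; merges only create new cherries above).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genetic_distance import DistanceMatrix
from .treeio import Node, UltrametricTree

__all__ = [
    "MotuPartition",
    "merge_entities",
    "composition_summary",
    "composition_totals",
    "induce_entity_tree",
]

#: between-sister-species mean K2P distance for rodents, as a proportion
DEFAULT_MERGE_THRESHOLD = 0.073


@dataclass
class MotuPartition:
    """A partition of GMYC entities into MOTUs.

    ``entity_to_motu`` maps entity id -> MOTU id; ``threshold`` is the merge
    cutoff (proportion).  MOTU ids are ``M1``, ``M2``, ... in order of first
    member entity (entity-tree tip order).
    """

    entity_to_motu: dict[str, str]
    threshold: float

    @property
    def n_entities(self) -> int:
        return len(self.entity_to_motu)

    @property
    def n_motus(self) -> int:
        return len(set(self.entity_to_motu.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ent, motu in self.entity_to_motu.items():
            out.setdefault(motu, []).append(ent)
        return out

    def histogram(self) -> dict[int, int]:
        """Number of MOTUs containing exactly k entities, keyed by k."""
        hist: dict[int, int] = {}
        for ents in self.members().values():
            hist[len(ents)] = hist.get(len(ents), 0) + 1
        return dict(sorted(hist.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entity_to_motu.items())
        return pd.DataFrame(rows, columns=["entity_id", "motu_id"])

    def to_json(self, path) -> None:
        n_entities, n_motus, hist = composition_summary(self)
        with open(path, "w") as fh:
            json.dump(
                {
                    "threshold": self.threshold,
                    "n_entities": n_entities,
                    "n_motus": n_motus,
                    "histogram": {str(k): v for k, v in hist.items()},
                    "motus": self.members(),
                },
                fh,
                indent=1,
            )


def composition_summary(p: MotuPartition) -> tuple[int, int, dict[int, int]]:
    """(number of entities, number of MOTUs, size histogram)."""
    hist = p.histogram()
    n_entities, n_motus = composition_totals(hist)
    assert n_entities == p.n_entities and n_motus == p.n_motus
    return n_entities, n_motus, hist


def composition_totals(histogram: Mapping[int, int]) -> tuple[int, int]:
    """Entity and MOTU totals implied by a size histogram
    {entities-per-MOTU: number of such MOTUs}."""
    n_entities = sum(k * v for k, v in histogram.items())
    n_motus = sum(histogram.values())
    return n_entities, n_motus


# ---------------------------------------------------------------------------


def _group_pair_sums(
    dm: DistanceMatrix, groups: Mapping[str, str]
) -> tuple[dict[str, dict[str, float]], dict[str, dict[str, int]]]:
    """Sum and count of pairwise distances between every pair of groups."""
    ids = dm.ids
    missing = [i for i in ids if i not in groups]
    if missing:
        raise ValueError(f"sequences without entity labels: {missing}")
    sums: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    glabels = sorted(set(groups[i] for i in ids))
    for g in glabels:
        sums[g] = {h: 0.0 for h in glabels}
        counts[g] = {h: 0 for h in glabels}
    for i in range(len(ids)):
        gi = groups[ids[i]]
        for j in range(i + 1, len(ids)):
            gj = groups[ids[j]]
            if gi == gj:
                continue
            d = dm.values[i, j]
            if np.isnan(d):
                raise ValueError(
                    f"undefined distance between {ids[i]} and {ids[j]}; "
                    "cannot compute group means"
                )
            sums[gi][gj] += d
            sums[gj][gi] += d
            counts[gi][gj] += 1
            counts[gj][gi] += 1
    return sums, counts


class _Group:
    __slots__ = ("name", "members")

    def __init__(self, name: str, members: tuple[str, ...]):
        self.name = name
        self.members = members


def merge_entities(
    entity_tree: UltrametricTree,
    dm: DistanceMatrix,
    threshold: float = DEFAULT_MERGE_THRESHOLD,
    *,
    groups: Optional[Mapping[str, str]] = None,
    linkage: str = "sister",
) -> MotuPartition:
    """Agglomerate GMYC entities into MOTUs.

    Parameters
    ----------
    entity_tree : UltrametricTree
        Tree whose tips are entity ids (see :func:`induce_entity_tree`).
    dm : DistanceMatrix
        Pairwise distances between the original sequences, with ``groups``
        (or the ``groups`` argument) mapping sequence id -> entity id.
    threshold : float
        Merge cutoff as a proportion (default 0.073).
    linkage : str
        "sister" (default): only sister groups on the current pruned tree
        may merge, so MOTUs are clades.  "free": tree-free agglomeration of
        the closest pair of groups while its mean distance is below the
        threshold.

    At each step the qualifying pair with the smallest mean distance merges;
    iteration continues to fixpoint.
    """
    if groups is None:
        groups = dm.groups
    if not groups:
        raise ValueError("distance matrix carries no entity (group) labels")
    entity_ids = entity_tree.tip_labels
    have = set(groups[i] for i in dm.ids)
    missing = sorted(set(entity_ids) - have)
    if missing:
        raise ValueError(f"entities on the tree without sequences: {missing}")

    sums, counts = _group_pair_sums(dm, groups)

    def mean(a: _Group, b: _Group) -> float:
        s = sum(sums[x][y] for x in a.members for y in b.members)
        n = sum(counts[x][y] for x in a.members for y in b.members)
        if n == 0:
            raise ValueError(f"no sequence pairs between {a.name} and {b.name}")
        return s / n

    if linkage == "sister":
        merged = _merge_sister(entity_tree, mean, threshold)
    elif linkage == "free":
        merged = _merge_free(entity_ids, mean, threshold)
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    # MOTU ids in entity-tree tip order of the first member
    rank = {e: i for i, e in enumerate(entity_ids)}
    merged.sort(key=lambda ms: min(rank[e] for e in ms))
    entity_to_motu: dict[str, str] = {}
    for k, members in enumerate(merged, start=1):
        for e in sorted(members, key=rank.get):
            entity_to_motu[e] = f"M{k}"
    return MotuPartition(entity_to_motu, float(threshold))


def _merge_sister(entity_tree, mean, threshold) -> list[tuple[str, ...]]:
    # mutable copy of the topology: node -> children, leaves carry groups
    class T:
        __slots__ = ("children", "parent", "group")

        def __init__(self):
            self.children: list["T"] = []
            self.parent: Optional["T"] = None
            self.group: Optional[_Group] = None

    def build(node: Node) -> T:
        t = T()
        if node.is_leaf:
            t.group = _Group(node.label, (node.label,))
        else:
            for c in node.children:
                ct = build(c)
                ct.parent = t
                t.children.append(ct)
        return t

    root = build(entity_tree.root)

    def cherries(t: T, acc: list[T]) -> list[T]:
        if t.children and all(c.group is not None for c in t.children):
            acc.append(t)
        for c in t.children:
            cherries(c, acc)
        return acc

    while True:
        best = None
        best_d = None
        for ch in cherries(root, []):
            a, b = ch.children[0].group, ch.children[1].group
            d = mean(a, b)
            if d < threshold and (best_d is None or d < best_d):
                best, best_d = ch, d
        if best is None:
            break
        a, b = best.children[0].group, best.children[1].group
        best.group = _Group(a.name, a.members + b.members)
        best.children = []

    out: list[tuple[str, ...]] = []

    def collect(t: T) -> None:
        if t.group is not None:
            out.append(t.group.members)
        for c in t.children:
            collect(c)

    collect(root)
    return out


def _merge_free(entity_ids, mean, threshold) -> list[tuple[str, ...]]:
    active = [_Group(e, (e,)) for e in entity_ids]
    while len(active) > 1:
        best = None
        best_d = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                d = mean(active[i], active[j])
                if d < threshold and (best_d is None or d < best_d):
                    best, best_d = (i, j), d
        if best is None:
            break
        i, j = best
        a, b = active[i], active[j]
        active = [g for k, g in enumerate(active) if k not in (i, j)]
        active.append(_Group(a.name, a.members + b.members))
    return [g.members for g in active]


# ---------------------------------------------------------------------------


def induce_entity_tree(
    tree: UltrametricTree, tip_to_entity: Mapping[str, str]
) -> UltrametricTree:
    """Collapse each entity (which must be a clade) to a single tip.

    The entity tip inherits the clade root's position and is extended to the
    present, so the induced tree stays ultrametric; internal structure above
    the entity roots is preserved.
    """
    members: dict[str, list[str]] = {}
    for tip, ent in tip_to_entity.items():
        members.setdefault(ent, []).append(tip)
    missing = sorted(set(tree.tip_labels) - set(tip_to_entity))
    if missing:
        raise ValueError(f"tips without an entity assignment: {missing}")

    roots: dict[int, str] = {}
    for ent, tips in members.items():
        node = tree.mrca(tips)
        if sorted(tree.clade_tips(node)) != sorted(tips):
            raise ValueError(f"entity {ent!r} is not a clade on the tree")
        roots[node.index] = ent

    def rec(node: Node) -> str:
        if node.index in roots:
            label = roots[node.index]
            if node.parent is None:
                raise ValueError("single entity spans the whole tree")
            return f"{label}:{format(node.parent.age, '.12g')}"
        if node.is_leaf:
            raise ValueError(f"tip {node.label!r} not inside any entity")
        inner = ",".join(rec(c) for c in node.children)
        if node.parent is None:
            return f"({inner})"
        return f"({inner}):{format(node.length, '.12g')}"

    return UltrametricTree.from_newick(rec(tree.root) + ";")
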