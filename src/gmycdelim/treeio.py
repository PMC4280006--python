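"""Rooted ultrametric time-trees.

The tree container used throughout the package: a strictly bifurcating rooted
tree whose branch lengths are in time units, with every tip at age 0 (the
present) and node ages increasing toward the root.  Node ages are the
substrate of the mixed Yule/coalescent likelihood and of the trait CTMC, so
they are computed once at parse time and validated against ultrametricity.

Newick parsing and writing are delegated to dendropy; this module adds age
bookkeeping, lineage-through-time queries and tabular metadata I/O.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "UltrametricTree",
    "TreeError",
    "NonUltrametricError",
    "PolytomyError",
    "read_newick",
    "read_tip_table",
]

#: relative tolerance on tip ages (fraction of root age)
ULTRAMETRIC_RTOL = 1e-6

#: relative length of branches inserted when resolving polytomies
POLYTOMY_EPS = 1e-8


class TreeError(ValueError):
    """Invalid tree input."""


class NonUltrametricError(TreeError):
    """Tips are not contemporaneous within tolerance."""


class PolytomyError(TreeError):
    """Tree contains a multifurcation and resolution was not requested."""


class Node:
    """A node of an :class:`UltrametricTree`.

    Attributes
    ----------
    label : str
        Tip label, or a generated internal id (``N1``, ``N2``, ...).
    parent : Node or None
        ``None`` for the root.
    children : list of Node
        Empty for tips, exactly two entries for internal nodes.
    length : float
        Branch length to the parent (0.0 for the root).
    age : float
        Time before present; 0 at the tips (within tolerance).
    index : int
        Position in the tree's postorder node list.
    """

    __slots__ = ("label", "parent", "children", "length", "age", "index")

    def __init__(self, label: str = "", length: float = 0.0):
        self.label = label
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.length = length
        self.age = 0.0
        self.index = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else "node"
        return f"<{kind} {self.label!r} age={self.age:.6g}>"


class UltrametricTree:
    """Rooted, binary, ultrametric tree with node ages.

    Construct via :meth:`from_newick` (or the module-level :func:`read_newick`).
    Node lists are cached in postorder; tips appear in input (Newick) order.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()
        self._validate()

    # ------------------------------------------------------------------ build

    @classmethod
    def from_newick(
        cls,
        text: str,
        *,
        resolve_polytomies: bool = False,
        rng: Optional[np.random.Generator] = None,
        rtol: float = ULTRAMETRIC_RTOL,
    ) -> "UltrametricTree":
        """Parse a Newick string into an ultrametric tree.

        Parameters
        ----------
        text : str
            Plain Newick with branch lengths on every non-root edge.
        resolve_polytomies : bool
            If True, multifurcations are resolved randomly by inserting
            branches of length ``1e-8 * root age`` (with a warning);
            otherwise a :class:`PolytomyError` is raised.
        rng : numpy Generator, optional
            Source of randomness for polytomy resolution (seeded default
            otherwise, so resolution is deterministic).
        rtol : float
            Relative ultrametricity tolerance (fraction of root age).
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick: {exc}") from exc

        droot = dtree.seed_node
        # suppress a unifurcating root (e.g. "((A:1,B:1):1);")
        while len(droot.child_nodes()) == 1:
            droot = droot.child_nodes()[0]

        def convert(dnode, is_root: bool) -> Node:
            if dnode.is_leaf():
                if dnode.taxon is None or not dnode.taxon.label:
                    raise TreeError("tip without a label")
                node = Node(label=str(dnode.taxon.label))
            else:
                node = Node(label=str(dnode.label) if dnode.label else "")
            if not is_root:
                if dnode.edge.length is None:
                    who = node.label or "an internal node"
                    raise TreeError(f"missing branch length on the edge above {who}")
                node.length = float(dnode.edge.length)
            for dchild in dnode.child_nodes():
                child = convert(dchild, False)
                child.parent = node
                node.children.append(child)
            return node

        root = convert(droot, True)
        _check_duplicate_labels(root)
        _assign_ages(root, rtol=rtol)
        if _has_polytomy(root):
            if not resolve_polytomies:
                raise PolytomyError(
                    "tree contains a polytomy; pass resolve_polytomies=True "
                    "to resolve randomly with near-zero branches"
                )
            if rng is None:
                rng = np.random.default_rng(0)
            _resolve_polytomies(root, rng)
            _assign_ages(root, rtol=rtol)
        return cls(root)

    def _index(self) -> None:
        self.nodes: list[Node] = list(_postorder(self.root))
        for i, node in enumerate(self.nodes):
            node.index = i
        self.tips: list[Node] = [n for n in _preorder(self.root) if n.is_leaf]
        self.internal_nodes: list[Node] = [n for n in self.nodes if not n.is_leaf]
        # stable ids for unlabeled internal nodes, assigned in preorder
        # (skipping any N<k> names already present in the input)
        used = {n.label for n in self.nodes if n.label}
        k = 0
        for node in _preorder(self.root):
            if not node.is_leaf and not node.label:
                k += 1
                while f"N{k}" in used:
                    k += 1
                node.label = f"N{k}"
                used.add(node.label)

    def _validate(self) -> None:
        if self.root.is_leaf or self.root.age <= 0:
            raise TreeError("tree must have at least two tips and positive root age")
        for node in self.internal_nodes:
            if len(node.children) != 2:
                raise PolytomyError(
                    f"internal node {node.label!r} has {len(node.children)} children"
                )
        labels = [t.label for t in self.tips]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")

    # ------------------------------------------------------------ properties

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    def internal_ages(self, *, distinct: bool = False) -> np.ndarray:
        """Ages of internal nodes, ascending; optionally deduplicated."""
        ages = np.sort(np.array([n.age for n in self.internal_nodes]))
        if distinct:
            ages = np.unique(ages)
        return ages

    # ------------------------------------------------------------ operations

    def lineages_at(self, t: float) -> int:
        """Number of branches alive at time ``t`` before present.

        A branch (parent -> child) crosses ``t`` iff
        ``child.age <= t < parent.age`` (half-open, tipward-closed), giving
        deterministic behaviour when ``t`` coincides with a node age.
        At ``t = 0`` this is the tip count.
        """
        if not (0 <= t <= self.root_age):
            raise ValueError(
                f"t={t} outside the tree's time span [0, {self.root_age}]"
            )
        return sum(
            1
            for node in self.nodes
            if node.parent is not None and node.age <= t < node.parent.age
        )

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the given tips."""
        want = set(labels)
        tipsets: dict[int, set[str]] = {}
        for node in self.nodes:  # postorder
            if node.is_leaf:
                tipsets[node.index] = {node.label}
            else:
                tipsets[node.index] = set().union(
                    *(tipsets[c.index] for c in node.children)
                )
            if want <= tipsets[node.index]:
                return node
        raise TreeError(f"tips not in tree: {sorted(want - set(self.tip_labels))}")

    def clade_tips(self, node: Node) -> list[str]:
        """Labels of tips descending from (or equal to) ``node``, in tip order."""
        if node.is_leaf:
            return [node.label]
        out = []
        for n in _preorder(node):
            if n.is_leaf:
                out.append(n.label)
        return out

    def to_newick(self, *, precision: int = 12) -> str:
        """Serialize to Newick with branch lengths (root has none)."""

        def fmt(x: float) -> str:
            return format(x, f".{precision}g")

        def quote(label: str) -> str:
            if any(c in label for c in " \t(),:;'[]"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def rec(node: Node) -> str:
            if node.is_leaf:
                s = quote(node.label)
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.parent is not None:
                s += ":" + fmt(node.length)
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<UltrametricTree {self.n_tips} tips, root age {self.root_age:.6g}>"


# ---------------------------------------------------------------------------
# helpers


def _postorder(node: Node) -> Iterator[Node]:
    for child in node.children:
        yield from _postorder(child)
    yield node


def _preorder(node: Node) -> Iterator[Node]:
    yield node
    for child in node.children:
        yield from _preorder(child)


def _check_duplicate_labels(root: Node) -> None:
    seen: set[str] = set()
    for node in _postorder(root):
        if node.is_leaf:
            if node.label in seen:
                raise TreeError(f"duplicate tip label {node.label!r}")
            seen.add(node.label)


def _assign_ages(root: Node, *, rtol: float) -> None:
    """Compute node ages from branch lengths and enforce ultrametricity."""
    depth: dict[int, float] = {}

    def down(node: Node, d: float) -> None:
        depth[id(node)] = d
        for child in node.children:
            down(child, d + child.length)

    down(root, 0.0)
    tips = [n for n in _postorder(root) if n.is_leaf]
    root_age = max(depth[id(t)] for t in tips)
    if root_age <= 0:
        raise TreeError("root age must be positive (zero-length tree)")
    tol = rtol * root_age
    for tip in tips:
        age = root_age - depth[id(tip)]
        if abs(age) > tol:
            raise NonUltrametricError(
                f"tree is not ultrametric: tip {tip.label!r} sits at age "
                f"{age:.6g} (tolerance {tol:.3g})"
            )
    for node in _postorder(root):
        node.age = root_age - depth[id(node)]
        if node.is_leaf:
            node.age = max(node.age, 0.0)


def _has_polytomy(root: Node) -> bool:
    return any(len(n.children) > 2 for n in _postorder(root))


def _resolve_polytomies(root: Node, rng: np.random.Generator) -> None:
    """Randomly resolve multifurcations, inserting branches of length
    ``POLYTOMY_EPS * root age`` so GMYC interval logic keeps positive-length
    intervals."""
    root_age = max(n.age for n in _postorder(root))
    eps = POLYTOMY_EPS * root_age
    warnings.warn(
        "resolving polytomies randomly with branches of length "
        f"{eps:.3g}",
        stacklevel=3,
    )
    for node in list(_postorder(root)):
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a = node.children[i]
            b = node.children[j]
            new = Node(length=eps)
            new.parent = node
            for child in (a, b):
                node.children.remove(child)
                child.parent = new
                child.length = max(child.length - eps, 0.0)
                new.children.append(child)
            node.children.append(new)


# ---------------------------------------------------------------------------
# module-level conveniences


def read_newick(text: str, **kwargs) -> UltrametricTree:
    """Parse a Newick string (see :meth:`UltrametricTree.from_newick`)."""
    return UltrametricTree.from_newick(text, **kwargs)


def read_tip_table(path) -> pd.DataFrame:
    """Read a tip metadata TSV (columns ``tip_id`` plus e.g. ``group``,
    ``trait``); ``tip_id`` values must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "tip_id" not in df.columns:
        raise ValueError("tip table must have a 'tip_id' column")
    if df["tip_id"].duplicated().any():
        dups = df.loc[df["tip_id"].duplicated(), "tip_id"].tolist()
        raise ValueError(f"duplicate tip_id entries: {dups}")
    return df
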