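"""Rooted time trees stored as flat arrays.

A :class:`TimeTree` is a rooted, binary-or-multifurcating tree whose nodes
are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``).  Internal
node ages are in Ma; tips are extant (age 0) unless stated otherwise.
Branch lengths are derived as age differences, so the object is always
internally consistent (no separate branch-length storage to drift out of
sync with the ages).

Newick I/O goes through dendropy; branch lengths written are age
differences in Ma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy


@dataclass
class TimeTree:
    taxon_names: list[str]          # length n_tips, node i < n_tips is tip i
    parent: np.ndarray              # int array, length n_nodes; root -> -1
    ages: np.ndarray                # float array (Ma), tips typically 0

    children: list[list[int]] = field(init=False, repr=False)
    root: int = field(init=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)
        n = len(self.parent)
        self.children = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self.validate()

    # -- basic structure -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.taxon_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, i: int) -> bool:
        return i < self.n_tips

    @property
    def internal_nodes(self) -> list[int]:
        return list(range(self.n_tips, self.n_nodes))

    def validate(self) -> None:
        # ties allowed (zero-length branches occur in substitution-scaled
        # trees); strict ordering is enforced by the time prior where it
        # matters
        for i, p in enumerate(self.parent):
            if p >= 0 and self.ages[p] < self.ages[i] - 1e-9:
                raise ValueError(
                    f"parent {p} (age {self.ages[p]}) younger than "
                    f"child {i} (age {self.ages[i]})"
                )
        for i in range(self.n_tips):
            if self.children[i]:
                raise ValueError(f"tip index {i} has children")

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def branch_length(self, i: int) -> float:
        p = self.parent[i]
        if p < 0:
            raise ValueError("root has no branch")
        return float(self.ages[p] - self.ages[i])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0.0 slot at root)."""
        b = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                b[i] = self.ages[p] - self.ages[i]
        return b

    # -- queries ----------------------------------------------------------
    def tip_index(self, name: str) -> int:
        try:
            return self.taxon_names.index(name)
        except ValueError:
            raise KeyError(f"taxon {name!r} not in tree") from None

    def tips_below(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def mrca(self, name_a: str, name_b: str) -> int:
        """Most recent common ancestor of two named tips (node index)."""
        a, b = self.tip_index(name_a), self.tip_index(name_b)
        anc = set()
        v = a
        while v >= 0:
            anc.add(v)
            v = self.parent[v]
        v = b
        while v not in anc:
            v = self.parent[v]
        return int(v)

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] >= 0:
            node = self.parent[node]
            d += 1
        return d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.ages[: self.n_tips]) <= tol))

    # -- copies / edits ---------------------------------------------------
    def with_ages(self, new_internal_ages: np.ndarray) -> "TimeTree":
        ages = self.ages.copy()
        ages[self.n_tips:] = new_internal_ages
        return TimeTree(list(self.taxon_names), self.parent.copy(), ages)

    def scaled(self, factor: float) -> "TimeTree":
        return TimeTree(list(self.taxon_names), self.parent.copy(),
                        self.ages * factor)

    # -- Newick I/O -------------------------------------------------------
    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for v in self.postorder():
            if self.is_tip(v):
                label = self.taxon_names[v]
            else:
                label = ""
            if self.children[v]:
                inner = ",".join(parts[c] for c in self.children[v])
                label = f"({inner}){label}"
            p = self.parent[v]
            if p >= 0:
                label += f":{self.ages[p] - self.ages[v]:.10g}"
            parts[v] = label
        return parts[self.root] + ";"

    @classmethod
    def from_newick(cls, newick: str, force_ultrametric: bool = False) -> "TimeTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt, force_ultrametric=force_ultrametric)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree,
                      force_ultrametric: bool = False) -> "TimeTree":
        """Convert a dendropy tree with branch lengths to a TimeTree.

        Node ages are root-to-tip distances subtracted from the maximum
        root-to-tip distance; with ``force_ultrametric`` small negative tip
        ages from rounding are clamped to zero.
        """
        nodes = list(dt.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {}
        names = []
        for i, nd in enumerate(tips):
            index[id(nd)] = i
            names.append(nd.taxon.label if nd.taxon else f"tip{i}")
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j

        depth = {id(dt.seed_node): 0.0}
        for nd in nodes:
            if nd is dt.seed_node:
                continue
            el = nd.edge.length if nd.edge.length is not None else 0.0
            depth[id(nd)] = depth[id(nd.parent_node)] + el
        h = max(depth[id(nd)] for nd in tips)
        ages = np.zeros(len(nodes))
        parent = np.full(len(nodes), -1, dtype=int)
        for nd in nodes:
            i = index[id(nd)]
            ages[i] = h - depth[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        if force_ultrametric:
            ages[: len(tips)] = 0.0
        return cls(names, parent, ages)


def write_newick(tree: TimeTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path, force_ultrametric: bool = False) -> TimeTree:
    with open(path) as fh:
        return TimeTree.from_newick(fh.read(), force_ultrametric=force_ultrametric)
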