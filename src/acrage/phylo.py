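"""Dated species tree, MRCA-based age categories, and clade membership.

The evolutionary age of a genomic region is used *categorically*: each
category is a node on the path from the designated reference species to the
root of an ultrametric (dated) species tree.  The age in million years (MY)
attached to a category is the split time of that node and serves only for
ordering and reporting; no computation weights by absolute time.

The youngest category is the reference species itself (age 0): a region with
no similar sequence in any other analyzed species is reference-specific.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import pandas as pd

STRICT = "strict"
SECONDARY_LOSS = "secondary_loss"


@dataclass(frozen=True, order=True)
class AgeCategory:
    """One evolutionary-age category: a node on the reference-to-root path.

    ``rank`` 0 is the youngest (the reference leaf, ``age`` 0); ranks increase
    toward the root.  Ordering of categories follows rank.
    """

    rank: int
    age: float
    node_id: str


class PhyloTree:
    """Ultrametric species tree with split times and a reference leaf.

    Parameters are normally supplied by :func:`parse_tree`.  The tree is
    stored as parent/child maps keyed by stable node identifiers; internal
    nodes without newick labels are named ``n1, n2, ...`` in preorder.
    """

    def __init__(
        self,
        parent: Mapping[str, str | None],
        children: Mapping[str, tuple[str, ...]],
        split_time: Mapping[str, float],
        reference: str,
        newick: str,
    ) -> None:
        self._parent = dict(parent)
        self._children = dict(children)
        self.split_time = dict(split_time)
        self.reference = reference
        self._newick = newick
        self.leaf_names = frozenset(
            n for n, ch in self._children.items() if not ch
        )
        if reference not in self.leaf_names:
            raise ValueError(f"reference {reference!r} is not a leaf of the tree")
        (self.root,) = [n for n, p in self._parent.items() if p is None]
        # leaves under every node
        self._leaves_below: dict[str, frozenset[str]] = {}
        self._fill_leaves(self.root)
        # root -> reference path defines the ordered categories
        path = [reference]
        while self._parent[path[-1]] is not None:
            path.append(self._parent[path[-1]])
        self.reference_path: tuple[str, ...] = tuple(path)  # leaf first
        self.categories: tuple[AgeCategory, ...] = tuple(
            AgeCategory(rank=i, age=(0.0 if i == 0 else self.split_time[n]), node_id=n)
            for i, n in enumerate(path)
        )
        self._category_by_node = {c.node_id: c for c in self.categories}

    def _fill_leaves(self, node: str) -> frozenset[str]:
        ch = self._children[node]
        if not ch:
            res = frozenset([node])
        else:
            res = frozenset().union(*(self._fill_leaves(c) for c in ch))
        self._leaves_below[node] = res
        return res

    # ------------------------------------------------------------------
    @property
    def nonreference_leaves(self) -> frozenset[str]:
        return self.leaf_names - {self.reference}

    def mrca_category(self, sharing_set: Iterable[str]) -> AgeCategory:
        """Age category of the MRCA of the reference and ``sharing_set``.

        An empty set yields the reference-specific category (rank 0, age 0).
        """
        sharing = frozenset(sharing_set)
        unknown = sharing - self.nonreference_leaves
        if unknown:
            raise ValueError(f"unknown or reference species in sharing set: {sorted(unknown)}")
        if not sharing:
            return self.categories[0]
        # reference-path nodes have nested leaf sets; the first one containing
        # the whole sharing set is the MRCA of reference + sharing set
        for cat in self.categories[1:]:
            if sharing <= self._leaves_below[cat.node_id]:
                return cat
        raise AssertionError("root must contain every leaf")  # pragma: no cover

    def clade_species(self, node_id: str) -> frozenset[str]:
        """Non-reference leaves descending from a reference-path node."""
        if node_id not in self._category_by_node:
            raise ValueError(f"node {node_id!r} is not on the reference path")
        return self._leaves_below[node_id] - {self.reference}

    def category_of_node(self, node_id: str) -> AgeCategory:
        return self._category_by_node[node_id]

    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        return self._newick

    def category_table(self) -> pd.DataFrame:
        """TSV-ready table: node_id, age_my, rank, member_species."""
        rows = [
            {
                "node_id": c.node_id,
                "age_my": c.age,
                "rank": c.rank,
                "member_species": ",".join(sorted(self.clade_species(c.node_id))),
            }
            for c in self.categories
        ]
        return pd.DataFrame(rows)


def parse_tree(newick_text: str, reference_name: str, rtol: float = 1e-6) -> PhyloTree:
    """Parse a dated newick tree and resolve per-node split times.

    Branch lengths are in million years.  The tree must be strictly bifurcating
    and ultrametric (all leaves equidistant from the root within ``rtol``
    relative tolerance); a non-ultrametric or single-leaf tree is rejected,
    since the age categories presume a dated species tree with outgroups.
    """
    try:
        dtree = dendropy.Tree.get(data=newick_text, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter() if lf.taxon is not None]
    if len(leaves) < 2:
        raise ValueError("tree must have at least two leaves (no outgroups present)")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names")
    if reference_name not in leaves:
        raise ValueError(f"reference {reference_name!r} not found among leaves {sorted(leaves)}")

    # assign stable identifiers and depths
    parent: dict[str, str | None] = {}
    children: dict[str, tuple[str, ...]] = {}
    depth: dict[str, float] = {}
    names: dict[int, str] = {}
    counter = 0
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
        elif node.label:
            name = str(node.label)
        else:
            counter += 1
            name = f"n{counter}"
        if name in names.values():
            raise ValueError(f"duplicate node label {name!r}")
        names[id(node)] = name
        if node.parent_node is None:
            parent[name] = None
            depth[name] = 0.0
        else:
            edge = node.edge.length
            if edge is None or edge <= 0:
                raise ValueError(f"non-positive or missing branch length above {name!r}")
            pname = names[id(node.parent_node)]
            parent[name] = pname
            depth[name] = depth[pname] + float(edge)
        kids = node.child_nodes()
        if len(kids) not in (0, 2):
            raise ValueError("tree must be strictly bifurcating (polytomies are rejected)")
        children[name] = ()
    for node in dtree.preorder_node_iter():
        kids = tuple(names[id(c)] for c in node.child_nodes())
        children[names[id(node)]] = kids

    leaf_depths = [depth[lf] for lf in leaves]
    height = max(leaf_depths)
    if height <= 0:
        raise ValueError("tree height must be positive")
    for lf, d in zip(leaves, leaf_depths):
        if abs(d - height) > rtol * height:
            raise ValueError(
                f"tree is not ultrametric: leaf {lf!r} at depth {d}, height {height}"
            )
    split_time = {
        name: height - depth[name] for name in parent if children[name]
    }
    return PhyloTree(parent, children, split_time, reference_name, newick_text.strip())


def write_tree(tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_tree(path: str, reference_name: str) -> PhyloTree:
    with open(path) as fh:
        return parse_tree(fh.read(), reference_name)
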