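"""Minimal rooted-representation phylogenetic trees.

A :class:`PhyloTree` wraps a :class:`TreeNode`; an unrooted tree (the
neighbor-joining output) is represented rooted at an internal node of
degree three, which is the standard Newick convention for unrooted
topologies. Branch lengths are in substitutions per site and live on the
edge from a node to its parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        self.children.append(child)

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every unordered pair of leaves."""
        # depth of every node plus leaf lists per subtree; combine at each
        # internal node via the LCA decomposition.
        dists: dict[tuple[str, str], float] = {}

        def rec(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, 0.0)]
            groups = [
                [(name, d + child.length) for name, d in rec(child)]
                for child in node.children
            ]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for na, da in groups[i]:
                        for nb, db in groups[j]:
                            key = (na, nb) if na <= nb else (nb, na)
                            dists[key] = da + db
            return [pair for g in groups for pair in g]

        rec(self.root)
        return dists

    def to_newick(self) -> str:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        root = self.root
        if root.is_leaf:
            return f"{root.name}:{root.length:.6f};"
        inner = ",".join(fmt(c) for c in root.children)
        return f"({inner});"
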