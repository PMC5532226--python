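"""Minimal rooted-tree structure shared by the IO and phylogeny layers."""

from __future__ import annotations

from typing import Iterator, Optional


class PhyloNode:
    """A node in a phylogenetic tree.

    Leaves carry a ``name``; every node except the root carries the length of
    the branch to its parent.
    """

    __slots__ = ("name", "length", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[list["PhyloNode"]] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[PhyloNode] = []
        self.parent: Optional[PhyloNode] = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "PhyloNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        return [n for n in self.traverse() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def traverse(self) -> Iterator["PhyloNode"]:
        """Pre-order traversal. Raises ``ValueError`` on a cyclic structure."""
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise ValueError("cyclic tree structure")
            seen.add(id(node))
            yield node
            stack.extend(reversed(node.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = self.name if self.name is not None else "<internal>"
        return f"PhyloNode({label}, length={self.length}, n_children={len(self.children)})"
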