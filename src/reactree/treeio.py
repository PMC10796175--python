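"""Rooted-tree container and Newick/NEXUS serialisation.

Nodes carry forward time (branch length = child time − parent time), a
population type, and an optional leaf label.  Degree-one nodes record
lineage type changes; by default they are suppressed on output (standard
tools reject unary nodes), with an opt-in typed mode that keeps them.
Sampled ancestors follow the usual convention of a zero-length leaf branch
hanging off a bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "TreeNode",
    "assemble_newick",
    "write_nexus",
    "tree_height",
    "total_branch_length",
    "leaf_count",
    "sampled_ancestor_count",
    "pairwise_coalescence_times",
]


@dataclass
class TreeNode:
    time: float
    population: str = ""
    label: str = ""
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> Iterator["TreeNode"]:
        return (n for n in self.walk() if n.is_leaf)

    def copy_suppressed(self) -> "TreeNode":
        """Copy with unary (type-change) nodes spliced out; branch lengths
        merge, so total length and leaf set are unchanged."""
        node = self
        while len(node.children) == 1:
            node = node.children[0]
        out = TreeNode(node.time, node.population, node.label)
        out.children = [c.copy_suppressed() for c in node.children]
        return out


def _annot(node: TreeNode, typed: bool) -> str:
    return f"[&type={node.population}]" if typed and node.population else ""


def _newick_rec(node: TreeNode, parent_time: Optional[float], typed: bool,
                parts: list[str]) -> None:
    if node.children:
        parts.append("(")
        for i, c in enumerate(node.children):
            if i:
                parts.append(",")
            _newick_rec(c, node.time, typed, parts)
        parts.append(")")
    parts.append(node.label)
    parts.append(_annot(node, typed))
    length = 0.0 if parent_time is None else node.time - parent_time
    if length < -1e-12:
        raise ValueError(
            f"negative branch length {length} at node {node.label or '<internal>'}"
        )
    parts.append(f":{max(length, 0.0):.12g}")


def assemble_newick(root: TreeNode, typed: bool = True,
                    suppress_unary: bool = True) -> str:
    """Newick string with branch lengths and ``[&type=...]`` annotations."""
    tree = root.copy_suppressed() if suppress_unary else root
    parts: list[str] = []
    _newick_rec(tree, None, typed, parts)
    parts.append(";")
    return "".join(parts)


def write_nexus(trees: list[list[TreeNode]], path, typed: bool = True,
                suppress_unary: bool = True) -> None:
    """Write one NEXUS file with a Taxa block and a Trees block.

    ``trees`` holds one forest (list of roots) per replicate; a replicate
    with several roots is emitted as one tree per root, named
    ``TREE_<rep>`` (or ``TREE_<rep>_<part>`` within a forest).  Labels are
    translated through a numeric table covering all replicates.
    """
    labels: list[str] = []
    seen: set[str] = set()
    for forest in trees:
        for root in forest:
            for leaf in sorted(root.leaves(), key=lambda n: (n.time, n.label)):
                if leaf.label and leaf.label not in seen:
                    seen.add(leaf.label)
                    labels.append(leaf.label)
    index = {lab: i + 1 for i, lab in enumerate(labels)}

    def translated(root: TreeNode) -> str:
        clone = _relabel(root, index)
        return assemble_newick(clone, typed=typed, suppress_unary=suppress_unary)

    lines = ["#NEXUS", "", "Begin taxa;", f"    Dimensions ntax={len(labels)};",
             "    Taxlabels"]
    lines += [f"        {lab}" for lab in labels]
    lines += ["        ;", "End;", "", "Begin trees;", "    Translate"]
    lines += [
        f"        {i} {lab}" + ("," if i < len(labels) else "")
        for lab, i in index.items()
    ]
    lines.append("        ;")
    for rep, forest in enumerate(trees):
        for part, root in enumerate(forest):
            name = f"TREE_{rep}" if len(forest) == 1 else f"TREE_{rep}_{part}"
            lines.append(f"tree {name} = {translated(root)}")
    lines += ["End;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _relabel(node: TreeNode, index: dict[str, int]) -> TreeNode:
    out = TreeNode(node.time, node.population,
                   str(index[node.label]) if node.label in index else node.label)
    out.children = [_relabel(c, index) for c in node.children]
    return out


# --- summary statistics used across engines and oracles -------------------

def tree_height(root: TreeNode) -> float:
    """Latest leaf time minus root time."""
    return max(n.time for n in root.walk() if n.is_leaf) - root.time


def total_branch_length(root: TreeNode) -> float:
    total = 0.0
    for node in root.walk():
        for c in node.children:
            total += c.time - node.time
    return total


def leaf_count(root: TreeNode) -> int:
    return sum(1 for _ in root.leaves())


def pairwise_coalescence_times(root: TreeNode, anchor: Optional[float] = None):
    """For every unordered pair of leaves, the time back from ``anchor``
    (default: the latest leaf) to the pair's most recent common ancestor."""
    if anchor is None:
        anchor = max(n.time for n in root.walk() if n.is_leaf)
    out: list[float] = []

    def rec(node: TreeNode) -> int:
        if node.is_leaf:
            return 1
        sizes = [rec(c) for c in node.children]
        npairs = 0
        for i in range(len(sizes)):
            for j in range(i + 1, len(sizes)):
                npairs += sizes[i] * sizes[j]
        out.extend([anchor - node.time] * npairs)
        return sum(sizes)

    rec(root)
    return out


def sampled_ancestor_count(root: TreeNode) -> int:
    """Leaves attached by a zero-length branch to an internal node with
    other descendants — the sampled-ancestor convention."""
    count = 0
    for node in root.walk():
        if len(node.children) >= 2:
            for c in node.children:
                if c.is_leaf and c.label and c.time == node.time:
                    count += 1
    return count
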