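"""Random phylogenies for transposable-element families.

Two generators are provided, mirroring the contrasting copy histories of the
two major TE classes:

* DNA transposons burst briefly and leave near-independent decaying copies, so
  their phylogeny is star-like.  The tree is grown by repeatedly attaching a
  new child (branch length uniform on [0, ``max_internal_branch``]) to a parent
  chosen uniformly among all existing nodes.
* LINEs follow the master-gene model: a single active lineage continually
  spawns dead-end copies.  The tree is grown by attaching a batch of children
  to the current master node and promoting one of them to be the next master.

After growth, every leaf branch is stretched so that all root-to-leaf path
lengths equal ``root_to_leaf_target`` — the "post-extinction" phase in which
all extant copies have decayed for the same amount of time.  Branch lengths
are abstract time units; the sequence simulator converts them to generations
via its GPUT parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhyloNode",
    "Phylogeny",
    "TreeConfig",
    "TreeGenerationError",
    "generate_dna_transposon_tree",
    "generate_master_gene_tree",
    "adjust_leaf_branches",
]

_PATH_TOL = 1e-9


class TreeGenerationError(ValueError):
    """Raised when a tree cannot satisfy its structural constraints."""


@dataclass
class PhyloNode:
    name: str
    branch_length: float | None = None  # None only at the root
    parent: "PhyloNode | None" = None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloNode({self.name!r}, bl={self.branch_length})"


class Phylogeny:
    """A rooted tree with branch lengths; leaves are extant TE copies."""

    def __init__(self, root: PhyloNode):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> list[PhyloNode]:
        out: list[PhyloNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def nodes(self) -> list[PhyloNode]:
        return self.preorder()

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- measures ----------------------------------------------------------
    def depth(self, node: PhyloNode) -> float:
        d = 0.0
        while node.parent is not None:
            d += node.branch_length
            node = node.parent
        return d

    def total_length(self) -> float:
        return sum(n.branch_length for n in self.preorder() if n.parent is not None)

    def leaf_branch_fraction(self) -> float:
        """Fraction of total tree length held in terminal branches."""
        total = self.total_length()
        leaf = sum(n.branch_length for n in self.leaves() if n.parent is not None)
        return leaf / total if total > 0 else 0.0

    def validate(self) -> None:
        seen: set[int] = set()
        for node in self.preorder():
            if id(node) in seen:
                raise TreeGenerationError("cycle detected in tree")
            seen.add(id(node))
            if node.parent is None:
                if node is not self.root:
                    raise TreeGenerationError(f"non-root node {node.name} lacks a parent")
            else:
                if node.branch_length is None or node.branch_length < 0:
                    raise TreeGenerationError(
                        f"node {node.name} has missing or negative branch length"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return _node_signature(self.root) == _node_signature(other.root)


def _node_signature(node: PhyloNode):
    bl = None if node.branch_length is None else round(node.branch_length, 9)
    return (node.name, bl, tuple(_node_signature(c) for c in node.children))


@dataclass
class TreeConfig:
    """Configuration shared by both tree generators.

    ``max_internal_branch`` defaults to 10 for the transposon model and 5 for
    the master-gene model (pass explicitly to override).  ``children_low`` /
    ``children_high`` bound the per-step batch size in the master-gene model;
    set both to the same value for a fixed batch size.
    """

    n_leaves: int = 100
    max_internal_branch: float | None = None
    root_to_leaf_target: float = 100.0
    rng_seed: int = 0
    children_low: int = 1
    children_high: int = 3

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if not 1 <= self.children_low <= self.children_high:
            raise ValueError("need 1 <= children_low <= children_high")

    def resolved_max_branch(self, default: float) -> float:
        b = default if self.max_internal_branch is None else self.max_internal_branch
        if self.root_to_leaf_target < b:
            raise ValueError("root_to_leaf_target must be >= max_internal_branch")
        return b


def adjust_leaf_branches(tree: Phylogeny, target: float) -> Phylogeny:
    """Stretch every terminal branch so all root-to-leaf paths equal ``target``.

    Mutates and returns ``tree``.  Raises :class:`TreeGenerationError` if a
    leaf's parent already lies deeper than the target (a non-negative leaf
    branch cannot be set).
    """
    for leaf in tree.leaves():
        parent = leaf.parent
        parent_depth = 0.0 if parent is None else tree.depth(parent)
        residual = target - parent_depth
        if residual < -_PATH_TOL:
            raise TreeGenerationError(
                f"leaf {leaf.name}: parent depth {parent_depth:.6f} exceeds target {target}"
            )
        leaf.branch_length = max(residual, 0.0)
    return tree


def generate_dna_transposon_tree(config: TreeConfig) -> Phylogeny:
    """Star-like random phylogeny typical of a DNA-transposon burst."""
    max_branch = config.resolved_max_branch(10.0)
    rng = np.random.default_rng(config.rng_seed)
    counter = 0
    root = PhyloNode(name="n0")
    tree = Phylogeny(root)
    nodes = [root]
    # root counts as extant while it is still a leaf
    while sum(1 for n in nodes if n.is_leaf) < config.n_leaves:
        parent = nodes[int(rng.integers(len(nodes)))]
        counter += 1
        child = PhyloNode(
            name=f"n{counter}",
            branch_length=float(rng.uniform(0.0, max_branch)),
            parent=parent,
        )
        parent.children.append(child)
        nodes.append(child)
    adjust_leaf_branches(tree, config.root_to_leaf_target)
    tree.validate()
    return tree


def generate_master_gene_tree(config: TreeConfig) -> Phylogeny:
    """Master-gene phylogeny typical of LINE families.

    At each step a batch of children is attached to the current master node
    and one of them is promoted to be the next master, so every internal node
    lies on a single root-to-tip backbone.  Branch lengths are uniform on
    ``[0, max_internal_branch]``, additionally capped by the remaining depth
    budget ``target - depth(master)``: the backbone approaches the target
    root-to-leaf time asymptotically, spawning dead-end copies at every age —
    a master lineage active across the family's whole lifespan.  Without the
    cap a ~100-step backbone would overshoot any reachable target and no
    non-negative leaf adjustment could exist.
    """
    max_branch = config.resolved_max_branch(5.0)
    rng = np.random.default_rng(config.rng_seed)
    counter = 0
    root = PhyloNode(name="n0")
    tree = Phylogeny(root)
    master = root
    master_depth = 0.0
    n_extant = 1  # the root is extant while it is a leaf
    while n_extant < config.n_leaves:
        k = int(rng.integers(config.children_low, config.children_high + 1))
        # attaching k children to a leaf master converts it to internal: net +k-1
        k = min(k, config.n_leaves - n_extant + 1)
        cap = min(max_branch, config.root_to_leaf_target - master_depth)
        batch = []
        for _ in range(k):
            counter += 1
            child = PhyloNode(
                name=f"n{counter}",
                branch_length=float(rng.uniform(0.0, cap)),
                parent=master,
            )
            master.children.append(child)
            batch.append(child)
        n_extant += k - 1
        master = batch[int(rng.integers(k))]
        master_depth += master.branch_length
    adjust_leaf_branches(tree, config.root_to_leaf_target)
    tree.validate()
    return tree
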