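"""Rooted time-trees: Newick I/O, clade machinery, and tree functionals.

Everything downstream (simulators, likelihoods, the tree-space validation
procedures) works on :class:`PhyloTree`, a rooted binary tree with branch
lengths in time units.  All generative models used here produce ultrametric
trees (every tip at the present, age 0), and validation is strict about
that by default; a non-strict mode admits non-ultrametric input so that
externally produced tree logs can still be fed to the diagnostics layer.

Clades are encoded as bitsets over the lexicographic ordering of the tip
labels, which makes Robinson--Foulds distances and clade-support tables
cheap set operations.  The Robinson--Foulds distance used throughout is the
*rooted* one: the size of the symmetric difference between the sets of
nontrivial clades (tips and the root clade excluded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Iterator

import dendropy

__all__ = [
    "PhyloTree",
    "TreeNode",
    "Clade",
    "NewickParseError",
    "TreeValidationError",
    "TaxonMismatchError",
    "parse_newick",
    "write_newick",
    "root_height",
    "tree_length",
    "tip_count",
    "cherry_count",
    "clade_set",
    "rf_distance",
    "tree_functional",
    "ULTRAMETRIC_RTOL",
]

#: Relative tolerance (w.r.t. root height) for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Tree violates a structural invariant (binarity, lengths, ultrametricity)."""


class TaxonMismatchError(ValueError):
    """Two trees that must share a taxon set do not."""


class TreeNode:
    """A node of a rooted binary tree.

    ``length`` is the branch length to the parent (``None`` on the root;
    the stem above the root is carried by ``PhyloTree.origin_age``).
    """

    __slots__ = ("parent", "children", "length", "label")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.length = length
        self.label = label

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"tip {self.label!r}" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {kind} len={self.length}>"


class PhyloTree:
    """Rooted binary time-tree with optional origin (stem) age.

    Parameters
    ----------
    root
        Root node; a single tip is a legal (degenerate) tree.
    origin_age
        Time from the origin of the process to the present, if the tree is
        conditioned on (or records) an origin.  Must be >= the root height.
    """

    def __init__(self, root: TreeNode, origin_age: float | None = None):
        self.root = root
        self.origin_age = origin_age

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def internals(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def taxa(self) -> tuple[str, ...]:
        """Tip labels in lexicographic order (the bitset ordering)."""
        return tuple(sorted(t.label for t in self.tips()))

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def depths(self) -> dict[TreeNode, float]:
        """Path length from the root to each node (root depth 0)."""
        d: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            d[node] = d[node.parent] + node.length
        return d

    def heights(self) -> dict[TreeNode, float]:
        """Node ages: time before the present (deepest tip defines 0)."""
        depths = self.depths()
        h = max(depths[t] for t in self.tips()) if depths else 0.0
        return {n: h - depth for n, depth in depths.items()}

    def set_heights(self, ages: dict[TreeNode, float]) -> None:
        """Rewrite branch lengths from a node-age assignment (root age = tree height)."""
        for node in self.preorder():
            if node is not self.root:
                node.length = ages[node.parent] - ages[node]

    def copy(self) -> "PhyloTree":
        mapping: dict[TreeNode, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(node.label, node.length)
            mapping[node] = clone
            if node.parent is not None:
                mapping[node.parent].add_child(clone)
        return PhyloTree(mapping[self.root], self.origin_age)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self, strict: bool = True) -> "PhyloTree":
        labels = [t.label for t in self.tips()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise TreeValidationError(
                    f"internal node with {len(node.children)} children (tree must be binary)"
                )
            if node is not self.root:
                if node.length is None:
                    raise TreeValidationError("missing branch length on a non-root edge")
                if node.length < 0:
                    raise TreeValidationError(f"negative branch length {node.length}")
        h = root_height(self)
        if strict:
            tol = ULTRAMETRIC_RTOL * max(h, 1.0)
            ages = self.heights()
            worst = max((abs(ages[t]) for t in self.tips()), default=0.0)
            if worst > tol:
                raise TreeValidationError(
                    f"tree is not ultrametric: tip age deviates by {worst:g} "
                    f"(tolerance {tol:g})"
                )
        if self.origin_age is not None and self.origin_age < h - ULTRAMETRIC_RTOL * max(h, 1.0):
            raise TreeValidationError(
                f"origin age {self.origin_age} is below the root height {h}"
            )
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {len(self.tips())} tips, height={root_height(self):.4g}>"


@dataclass(frozen=True, order=True)
class Clade:
    """A tip-label subset, encoded as a bitset over the lexicographic taxon order."""

    mask: int

    @classmethod
    def from_labels(cls, labels, taxa: tuple[str, ...]) -> "Clade":
        index = {t: i for i, t in enumerate(taxa)}
        mask = 0
        for lab in labels:
            mask |= 1 << index[lab]
        return cls(mask)

    def labels(self, taxa: tuple[str, ...]) -> frozenset[str]:
        return frozenset(t for i, t in enumerate(taxa) if self.mask >> i & 1)

    @property
    def size(self) -> int:
        return self.mask.bit_count()


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

def parse_newick(text: str, strict: bool = True) -> PhyloTree:
    """Parse one Newick string into a validated :class:`PhyloTree`.

    Branch lengths are mandatory on all non-root edges.  A length on the
    root edge (or on collapsed unifurcations above the root) is interpreted
    as the stem, stored as ``origin_age = root_height + stem``.  Internal
    node labels are ignored.  With ``strict=True`` the tree must be
    ultrametric to within :data:`ULTRAMETRIC_RTOL` of its height.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    stem = 0.0
    has_stem = False
    seed = dtree.seed_node
    if seed.edge.length is not None:
        stem += seed.edge.length
        has_stem = True
    # collapse unifurcations above the effective root into the stem
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]
        if seed.edge.length is not None:
            stem += seed.edge.length
            has_stem = True

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(label=label)
        else:
            node = TreeNode()
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.length = child.edge.length
                node.add_child(cnode)
        return node

    root = convert(seed)
    tree = PhyloTree(root)
    if has_stem:
        tree.origin_age = root_height(tree) + stem
    return tree.validate(strict=strict)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; inverse of :func:`parse_newick` up to float formatting."""
    buf = io.StringIO()

    def rec(node: TreeNode) -> None:
        if node.is_tip:
            buf.write(node.label)
        else:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                rec(child)
                buf.write(f":{_fmt(child.length)}")
            buf.write(")")

    rec(tree.root)
    if tree.origin_age is not None:
        stem = tree.origin_age - root_height(tree)
        buf.write(f":{_fmt(stem)}")
    buf.write(";")
    return buf.getvalue()


# ----------------------------------------------------------------------
# scalar functionals
# ----------------------------------------------------------------------

def root_height(tree: PhyloTree) -> float:
    """Maximum root-to-tip path length (the tree height / root age)."""
    depths = tree.depths()
    return max(depths[t] for t in tree.tips())


def tree_length(tree: PhyloTree) -> float:
    """Sum of branch lengths over non-root edges (the stem is excluded)."""
    return sum(n.length for n in tree.preorder() if n is not tree.root)


def tip_count(tree: PhyloTree) -> int:
    return len(tree.tips())


def cherry_count(tree: PhyloTree) -> int:
    """Number of internal nodes whose two children are both tips."""
    if tip_count(tree) < 2:
        raise TreeValidationError("cherry count is undefined for a single-tip tree")
    return sum(
        1
        for n in tree.internals()
        if len(n.children) == 2 and all(c.is_tip for c in n.children)
    )


def clade_set(tree: PhyloTree, nontrivial_only: bool = True) -> frozenset[Clade]:
    """Clades (tip-label bitsets) of the internal nodes.

    With ``nontrivial_only`` the root clade (all taxa) is excluded, which
    for a binary rooted tree with s >= 2 tips leaves exactly s - 2 clades.
    """
    taxa = tree.taxa
    index = {t: i for i, t in enumerate(taxa)}
    full = (1 << len(taxa)) - 1
    masks: dict[TreeNode, int] = {}
    out = []
    for node in tree.postorder():
        if node.is_tip:
            masks[node] = 1 << index[node.label]
        else:
            m = 0
            for child in node.children:
                m |= masks[child]
            masks[node] = m
            if nontrivial_only and m == full:
                continue
            out.append(Clade(m))
    return frozenset(out)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Rooted Robinson--Foulds distance: |clades(t1) XOR clades(t2)|, nontrivial only."""
    if t1.taxa != t2.taxa:
        raise TaxonMismatchError(
            f"taxon sets differ: {t1.taxa} vs {t2.taxa}"
        )
    return len(clade_set(t1) ^ clade_set(t2))


# ----------------------------------------------------------------------
# functional registry
# ----------------------------------------------------------------------

_FUNCTIONALS: dict[str, Callable] = {
    "root_height": root_height,
    "tree_length": tree_length,
    "tip_count": tip_count,
    "cherry_count": cherry_count,
}


def tree_functional(name: str, reference: PhyloTree | None = None) -> Callable[[PhyloTree], float]:
    """Look up a scalar tree functional by name.

    ``rf_to_reference`` requires ``reference``; any other ``(tree) -> real``
    callable can be used directly wherever a functional is accepted (the
    registry exists so configurations can name functionals as strings, and
    so other tree metrics can be plugged in later).
    """
    if name == "rf_to_reference":
        if reference is None:
            raise ValueError("rf_to_reference requires a reference tree")
        return lambda t: float(rf_distance(reference, t))
    try:
        return _FUNCTIONALS[name]
    except KeyError:
        known = sorted(_FUNCTIONALS) + ["rf_to_reference"]
        raise KeyError(f"unknown tree functional {name!r}; known: {known}") from None
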