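"""Rooted, age-calibrated phylogenies and the matrices derived from them.

A :class:`Phylogeny` is a rooted tree (polytomies permitted) whose nodes carry
ages in millions of years (Myr); branch lengths are derived as
``parent_age - child_age``.  Trees may be read topology-only and calibrated
afterwards with :func:`calibrate_bladj`, which interpolates undated node ages
evenly between dated nodes.  All downstream machinery (trait-evolution model
fitting, phylogenetic eigenvector analysis, Brownian simulation) consumes the
patristic-distance and shared-path (Brownian covariance) matrices produced
here.

Newick parsing and writing are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .errors import NewickParseError, StateError, ValidationError

__all__ = [
    "Phylogeny",
    "read_newick",
    "write_newick",
    "calibrate_bladj",
    "patristic_matrix",
    "shared_path_matrix",
    "prune_to_taxa",
]

#: tolerance (Myr) for the ultrametricity check
ULTRAMETRIC_TOL = 1e-9


class Node:
    """A tree node; ``age`` is in Myr (tips 0 for extant taxa) or None if undated."""

    __slots__ = ("label", "children", "parent", "age")

    def __init__(self, label=None, age=None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.age: float | None = age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted phylogeny with per-node ages in Myr.

    Parameters
    ----------
    root:
        Root :class:`Node` of an existing node structure.

    Notes
    -----
    Tip labels must be unique.  A tree is *calibrated* when every node has an
    age; only calibrated trees can produce distance/covariance matrices.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------------------

    def _validate(self) -> None:
        labels = [t.label for t in self.iter_tips()]
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        if any(l is None for l in labels):
            raise ValidationError("every tip must carry a label")
        if self.is_calibrated:
            for node in self.iter_preorder():
                for ch in node.children:
                    if ch.age > node.age + ULTRAMETRIC_TOL:
                        raise ValidationError(
                            f"negative branch length: child {ch.label or '<internal>'} "
                            f"(age {ch.age}) older than its parent (age {node.age})"
                        )

    # -- iteration ----------------------------------------------------------------

    def iter_preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterable[Node]:
        out = list(self.iter_preorder())
        return reversed(out)

    def iter_tips(self) -> Iterable[Node]:
        return (n for n in self.iter_preorder() if n.is_tip)

    # -- basic properties -----------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in stable (preorder) order."""
        return [t.label for t in self.iter_tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def is_calibrated(self) -> bool:
        return all(n.age is not None for n in self.iter_preorder())

    @property
    def root_age(self) -> float:
        if self.root.age is None:
            raise StateError("tree is uncalibrated: root has no age")
        return float(self.root.age)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, Myr, in ``tips`` order."""
        self._require_calibrated()
        return np.array([self.root_age - t.age for t in self.iter_tips()])

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        depths = self.tip_depths()
        return bool(np.ptp(depths) <= tol)

    def _require_calibrated(self) -> None:
        if not self.is_calibrated:
            raise StateError("operation requires a calibrated tree (all node ages set)")

    # -- internals ----------------------------------------------------------------

    def _mrca_age_matrix(self) -> np.ndarray:
        """Ages of pairwise MRCAs of tips, in ``tips`` order (diagonal = tip age)."""
        self._require_calibrated()
        tips = list(self.iter_tips())
        index = {id(t): i for i, t in enumerate(tips)}
        n = len(tips)
        M = np.zeros((n, n))
        below: dict[int, list[int]] = {}
        for node in self.iter_postorder():
            if node.is_tip:
                i = index[id(node)]
                below[id(node)] = [i]
                M[i, i] = node.age
                continue
            child_sets = [below.pop(id(c)) for c in node.children]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        M[i, child_sets[b]] = node.age
                        M[child_sets[b], i] = node.age
            below[id(node)] = [i for s in child_sets for i in s]
        return M

    def copy(self) -> "Phylogeny":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.age)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Phylogeny(rec(self.root))

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        unknown = want - set(self.tips)
        if unknown:
            raise ValidationError(f"unknown taxa: {sorted(unknown)}")
        best = None
        below: dict[int, set[str]] = {}
        for node in self.iter_postorder():
            if node.is_tip:
                below[id(node)] = {node.label}
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if want <= below[id(node)]:
                best = node
                break
        return best

    def __repr__(self) -> str:  # pragma: no cover
        cal = "calibrated" if self.is_calibrated else "uncalibrated"
        return f"<Phylogeny {self.n_tips} tips, {cal}>"


# -- Newick I/O -------------------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths, when present on every edge, are converted to node ages by
    measuring depth from the root and setting ``age = max_tip_depth - depth``
    (so the deepest tips sit at age 0).  Trees without branch lengths come
    back uncalibrated (all ages ``None``).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        loc = f" near character {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed Newick string{loc}: {exc}") from exc

    has_lengths = all(
        e.length is not None for e in dtree.preorder_edge_iter() if e.head_node.parent_node
    )

    def label_of(dnode):
        if dnode.taxon is not None:
            return dnode.taxon.label
        return dnode.label

    def rec(dnode) -> Node:
        node = Node(label=label_of(dnode))
        for dc in dnode.child_nodes():
            node.add_child(rec(dc))
        return node

    root = rec(dtree.seed_node)
    tree = Phylogeny(root)

    if has_lengths:
        dlen = {}
        for dn, n in zip(dtree.preorder_node_iter(), tree.iter_preorder()):
            dlen[id(n)] = dn.edge.length or 0.0
        depth = {id(tree.root): 0.0}
        for node in tree.iter_preorder():
            for c in node.children:
                depth[id(c)] = depth[id(node)] + dlen[id(c)]
        root_age = max(depth[id(t)] for t in tree.iter_tips())
        for node in tree.iter_preorder():
            node.age = root_age - depth[id(node)]
    return tree


def write_newick(tree: Phylogeny, include_internal_labels: bool = False) -> str:
    """Serialize to Newick; ages, when set, are encoded as branch lengths."""

    def rec(node: Node) -> str:
        if node.is_tip:
            s = node.label
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if include_internal_labels and node.label:
                s += node.label
        if node.parent is not None and node.age is not None and node.parent.age is not None:
            s += f":{node.parent.age - node.age:.10g}"
        return s

    return rec(tree.root) + ";"


# -- BLADJ-style age calibration ----------------------------------------------------


def calibrate_bladj(
    tree: Phylogeny,
    constraints: Mapping[frozenset, float] | Mapping[str, float] | None,
    root_age: float,
    tip_ages: Mapping[str, float] | None = None,
) -> Phylogeny:
    """Calibrate node ages by even interpolation between dated nodes.

    Every node whose age is fixed (root, tips, constrained internal nodes)
    anchors the interpolation; each undated node receives an age that spaces
    the nodes evenly along the path between its nearest dated ancestor and its
    nearest dated descendant (fewest intervening nodes; ties resolved toward
    the older descendant).  This mirrors the classic branch-length-adjustment
    procedure used to date supertrees against a reference chronogram.

    Parameters
    ----------
    constraints:
        Map from internal node identifier to fixed age (Myr).  A node is
        identified by the frozenset of its descendant tip labels
        (order-independent, survives re-reading) or, as a convenience, by an
        internal node label string.
    root_age:
        Age of the root, Myr.
    tip_ages:
        Optional per-tip ages (default: every tip extant at age 0).
    """
    out = tree.copy()
    tipset: dict[int, frozenset] = {}
    for node in out.iter_postorder():
        if node.is_tip:
            tipset[id(node)] = frozenset([node.label])
        else:
            tipset[id(node)] = frozenset().union(*(tipset[id(c)] for c in node.children))

    by_tipset = {tipset[id(n)]: n for n in out.iter_preorder() if not n.is_tip}
    by_label = {n.label: n for n in out.iter_preorder() if not n.is_tip and n.label}

    for node in out.iter_preorder():
        node.age = None
    out.root.age = float(root_age)
    tip_ages = tip_ages or {}
    for t in out.iter_tips():
        t.age = float(tip_ages.get(t.label, 0.0))

    for key, age in (constraints or {}).items():
        if isinstance(key, str):
            node = by_label.get(key)
            if node is None:
                raise ValidationError(f"no internal node labelled {key!r}")
        else:
            node = by_tipset.get(frozenset(key))
            if node is None:
                raise ValidationError(f"no clade with tip set {sorted(key)}")
        node.age = float(age)

    dated = {id(n) for n in out.iter_preorder() if n.age is not None}

    # reject inverted constraints before interpolating
    for node in out.iter_preorder():
        if id(node) not in dated:
            continue
        anc = node.parent
        while anc is not None and id(anc) not in dated:
            anc = anc.parent
        if anc is not None and node.age >= anc.age:
            raise ValidationError(
                f"constraint inversion: clade {sorted(tipset[id(node)])[:3]}... "
                f"(age {node.age}) is not younger than its dated ancestor (age {anc.age})"
            )

    def interpolated_age(node: Node, anc_age: float, up: int) -> float:
        # every downward path ends at its first dated node; each path proposes
        # an even-spacing age for this node, and the oldest proposal wins
        # (this reproduces even thirds along undated chains and can never
        # place the node below a dated descendant)
        best = -math.inf
        stack = [(c, 1) for c in node.children]
        while stack:
            n, hops = stack.pop()
            if id(n) in dated:
                best = max(best, anc_age - (anc_age - n.age) * up / (up + hops))
            else:
                stack.extend((c, hops + 1) for c in n.children)
        return best

    for node in out.iter_preorder():
        if id(node) in dated:
            continue
        anc, up = node.parent, 1
        while id(anc) not in dated:
            anc, up = anc.parent, up + 1
        age = interpolated_age(node, anc.age, up)
        # proposals through different subtrees may cross a parent's; clamp
        if node.parent.age is not None:
            age = min(age, node.parent.age)
        node.age = age

    result = Phylogeny(out.root)
    if not result.is_ultrametric() and not tip_ages:
        raise ValidationError("calibration failed to produce an ultrametric tree")
    return result


# -- matrices -----------------------------------------------------------------------


def patristic_matrix(tree: Phylogeny) -> np.ndarray:
    """Pairwise tip-to-tip path lengths (Myr), in ``tree.tips`` order.

    ``d_ij = depth_i + depth_j - 2 * depth(MRCA(i, j))``; on an ultrametric
    tree this is twice the MRCA age.
    """
    M = tree._mrca_age_matrix()
    ages = np.diag(M).copy()
    D = (M - ages[:, None]) + (M - ages[None, :])
    np.fill_diagonal(D, 0.0)
    return D


def shared_path_matrix(tree: Phylogeny) -> np.ndarray:
    """Root-to-MRCA shared path lengths (Myr): the Brownian covariance structure.

    ``s_ij = root_age - age(MRCA(i, j))``; the diagonal holds root-to-tip
    depths.  On ultrametric trees ``s_ij = T - d_ij / 2``.
    """
    M = tree._mrca_age_matrix()
    return tree.root_age - M


# -- pruning ------------------------------------------------------------------------


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``; unary nodes suppressed, ages preserved.

    The returned root is the MRCA of the kept taxa, so distance matrices of
    the pruned tree are exact submatrices of the originals.
    """
    keep = set(keep)
    unknown = keep - set(tree.tips)
    if unknown:
        raise ValidationError(f"unknown taxa: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValidationError("need at least 2 taxa to prune to")

    def rec(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                return Node(node.label, node.age)
            return None
        kept_children = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept_children:
            return None
        if len(kept_children) == 1:
            return kept_children[0]  # suppress unary node, child age kept
        new = Node(node.label, node.age)
        for c in kept_children:
            new.add_child(c)
        return new

    return Phylogeny(rec(tree.root))
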