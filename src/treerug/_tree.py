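"""Core rooted time-tree containers shared by every diagnostic.

A :class:`RootedTree` is a dated rooted tree whose node heights are measured
backwards in time from the latest sampled tip (height 0).  Branches may carry
float annotations (most importantly ``"rate"``, the evolutionary rate of the
subtending branch in substitutions/site/time-unit) parsed from BEAST-style
``[&key=value]`` comments.  Clades are represented throughout the package as
integer bitsets over a study-wide :class:`TaxonSet`.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional


class TaxonSet:
    """Immutable ordered set of taxon labels defining bitset positions.

    All trees and alignments of one study must reference the same TaxonSet so
    that clade bitsets are comparable across samples and chains.
    """

    __slots__ = ("labels", "index", "full_bitset")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be unique")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}
        self.full_bitset = (1 << len(labels)) - 1

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({len(self.labels)} taxa)"

    def bitset(self, labels: Iterable[str]) -> int:
        """Canonical integer bitset for a set of taxon labels."""
        b = 0
        for lab in labels:
            try:
                b |= 1 << self.index[lab]
            except KeyError:
                raise KeyError(f"taxon {lab!r} not in TaxonSet") from None
        return b

    def labels_of(self, bitset: int) -> tuple[str, ...]:
        return tuple(
            lab for i, lab in enumerate(self.labels) if bitset >> i & 1
        )


class Node:
    __slots__ = ("parent", "children", "height", "label", "length", "annotations")

    def __init__(self, label: Optional[str] = None, height: float = 0.0):
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.height: float = height
        self.label = label          # taxon label for tips, None for internals
        self.length: Optional[float] = None  # raw input branch length
        self.annotations: dict[str, float] = {}

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:
        return f"Node({self.label or 'internal'}, h={self.height:.4g})"


class RootedTree:
    """Rooted, dated tree over a :class:`TaxonSet`.

    Node heights are times before the latest sampled tip.  The tree is binary
    for all clade-based diagnostics; multifurcations are tolerated only as
    transient states (e.g. basal trifurcations of unrooted input destined for
    root-to-tip regression).
    """

    __slots__ = ("taxon_set", "root")

    def __init__(self, taxon_set: TaxonSet, root: Node):
        self.taxon_set = taxon_set
        self.root = root

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def tips(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_tip]

    def tip(self, label: str) -> Node:
        for nd in self.postorder():
            if nd.is_tip and nd.label == label:
                return nd
        raise KeyError(f"tip {label!r} not in tree")

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def is_binary(self) -> bool:
        return all(
            len(nd.children) == 2 for nd in self.postorder() if not nd.is_tip
        )

    # -- clades --------------------------------------------------------

    def node_bitsets(self) -> dict[Node, int]:
        """Bitset of descendant tips for every node (computed, not cached)."""
        out: dict[Node, int] = {}
        for nd in self.postorder():
            if nd.is_tip:
                out[nd] = 1 << self.taxon_set.index[nd.label]
            else:
                b = 0
                for c in nd.children:
                    b |= out[c]
                out[nd] = b
        return out

    def clades(self) -> frozenset[int]:
        """Nontrivial rooted clades: one bitset per non-root internal node.

        Singletons and the full taxon set are excluded; for a binary rooted
        tree on n tips this yields exactly n-2 clades.
        """
        bits = self.node_bitsets()
        full = bits[self.root]
        return frozenset(
            b
            for nd, b in bits.items()
            if not nd.is_tip and nd is not self.root and b != full
        )

    def find_clade_node(self, bitset: int) -> Optional[Node]:
        """Node whose descendant tip set equals ``bitset``, or None."""
        for nd, b in self.node_bitsets().items():
            if b == bitset:
                return nd
        return None

    # -- editing helpers ----------------------------------------------

    def copy(self) -> "RootedTree":
        mapping: dict[Node, Node] = {}
        for nd in self.postorder():
            new = Node(nd.label, nd.height)
            new.length = nd.length
            new.annotations = dict(nd.annotations)
            mapping[nd] = new
            for c in nd.children:
                new.add_child(mapping[c])
        return RootedTree(self.taxon_set, mapping[self.root])

    # -- serialization -------------------------------------------------

    def newick(
        self,
        lengths_from: str = "height",
        annotations: bool = False,
        fmt: str = "%.12g",
        translate: Optional[dict[str, str]] = None,
    ) -> str:
        """Newick string; branch lengths from heights or raw input lengths.

        With ``annotations=True`` BEAST-style ``[&key=value]`` comments are
        written between the colon and the branch length, the placement BEAST
        itself uses.
        """

        def blen(nd: Node) -> Optional[float]:
            if nd.parent is None:
                return None
            if lengths_from == "height":
                return nd.parent.height - nd.height
            return nd.length

        def comment(nd: Node) -> str:
            if not (annotations and nd.annotations):
                return ""
            inner = ",".join(
                f"{k}={fmt % v}" for k, v in sorted(nd.annotations.items())
            )
            return f"[&{inner}]"

        def rec(nd: Node) -> str:
            if nd.is_tip:
                lab = translate[nd.label] if translate else nd.label
                s = lab
            else:
                s = "(" + ",".join(rec(c) for c in nd.children) + ")"
            bl = blen(nd)
            if bl is not None:
                s += ":" + comment(nd) + (fmt % bl)
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:
        return f"RootedTree({self.n_tips} tips)"


def build_caterpillar(labels: Iterable[str], step: float = 1.0) -> RootedTree:
    """Fully imbalanced (caterpillar) ultrametric tree: ((((l0,l1),l2),...).

    Internal node heights increase by ``step`` per nesting level; all tips at
    height 0.  Used as a deterministic geometry fixture for valley analyses.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    ts = TaxonSet(labels)
    cur = Node(labels[0], 0.0)
    h = 0.0
    for lab in labels[1:]:
        h += step
        par = Node(None, h)
        par.add_child(cur)
        par.add_child(Node(lab, 0.0))
        cur = par
    return RootedTree(ts, cur)
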