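"""Tree distances, tip-relocation and NNI-path moves, topology classes,
classical MDS embedding, and landscape overlays.

The central geometric fact this module operationalizes: relocating a single
tip across k intermediate internal nodes changes 2k rooted clades (rooted RF
distance 2k) yet is one SPR move — equivalently a path of k NNIs — so a
"wide" valley in RF-based tree space can be a single tree-rearrangement step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._tree import Node, RootedTree
from .clades import as_bitset
from .treeio import TreeTrace

__all__ = [
    "DistanceMatrix",
    "MDSEmbedding",
    "rf_rooted",
    "distance_matrix",
    "relocate_tip",
    "nni_path_tip_relocation",
    "rspr_distance_small",
    "topology_classes",
    "classical_mds",
    "landscape_overlay",
    "path_profile",
]


# ---------------------------------------------------------------------------
# distances

def rf_rooted(t1: RootedTree, t2: RootedTree) -> int:
    """Rooted Robinson-Foulds distance: size of the symmetric difference of
    the two trees' nontrivial clade sets."""
    if t1.taxon_set != t2.taxon_set:
        raise ValueError("trees are over different taxon sets")
    return len(t1.clades() ^ t2.clades())


@dataclass
class DistanceMatrix:
    labels: list[tuple[str, int]]  # (chain_id, sample index within chain)
    matrix: np.ndarray
    metric: str
    density: Optional[np.ndarray] = None

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix/labels shape mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str) -> None:
        names = [f"{c}:{i}" for c, i in self.labels]
        pd.DataFrame(self.matrix, index=names, columns=names).to_csv(
            path, sep="\t", float_format="%.6g"
        )


def distance_matrix(
    traces: Sequence[TreeTrace],
    metric: str = "rf",
    max_samples: Optional[int] = None,
) -> DistanceMatrix:
    """Pairwise distances between posterior samples across chains.

    When the pooled sample count exceeds ``max_samples``, every chain is
    subsampled at a deterministic even stride (reproducible, no RNG).
    """
    if metric not in ("rf", "rspr_small"):
        raise ValueError("metric must be 'rf' or 'rspr_small'")
    ts = traces[0].taxon_set
    if any(tr.taxon_set != ts for tr in traces):
        raise ValueError("chains must share one TaxonSet")
    total = sum(len(tr) for tr in traces)
    stride = 1
    if max_samples is not None and total > max_samples:
        stride = math.ceil(total / max_samples)
    kept: list[tuple[TreeTrace, int]] = []
    labels: list[tuple[str, int]] = []
    dens: list[float] = []
    for tr in traces:
        for i in range(0, len(tr), stride):
            kept.append((tr, i))
            labels.append((tr.chain_id, i))
            dens.append(tr.density[i] if tr.density is not None else np.nan)
    m = len(kept)
    mat = np.zeros((m, m))
    if metric == "rf":
        csets = [tr.clade_sets[i] for tr, i in kept]
        for a in range(m):
            for b in range(a + 1, m):
                mat[a, b] = mat[b, a] = len(csets[a] ^ csets[b])
    else:
        if len(ts) > 10:
            raise ValueError(
                "exact rSPR is limited to <= 10 tips; use metric='rf'"
            )
        topos = [_topo_from_tree(tr.trees[i]) for tr, i in kept]
        for a in range(m):
            for b in range(a + 1, m):
                mat[a, b] = mat[b, a] = _rspr_bfs(topos[a], topos[b])
    density = np.array(dens)
    if np.all(np.isnan(density)):
        density = None
    return DistanceMatrix(labels, mat, metric, density)


# ---------------------------------------------------------------------------
# tip relocation and NNI paths

CladeLike = Union[int, Iterable[str]]


def _prune_tip_inplace(tree: RootedTree, tip_label: str) -> Node:
    """Remove a tip and suppress its parent; returns the former sibling."""
    tip = tree.tip(tip_label)
    parent = tip.parent
    if parent is None:
        raise ValueError("cannot prune the root")
    parent.children.remove(tip)
    if len(parent.children) == 1:
        sib = parent.children[0]
        gp = parent.parent
        if gp is None:
            sib.parent = None
            tree.root = sib
        else:
            gp.children[gp.children.index(parent)] = sib
            sib.parent = gp
        return sib
    return parent.children[0]


def relocate_tip(
    tree: RootedTree, tip: str, dest_branch: CladeLike
) -> RootedTree:
    """Prune a tip and regraft it onto another branch (one rooted SPR move).

    ``dest_branch`` identifies the destination branch by the clade below it,
    given over taxa *excluding* the relocated tip.  The new attachment height
    is the midpoint of the feasible interval
    [max(tip height, branch child height), branch parent height]; all other
    node heights are unchanged.
    """
    ts = tree.taxon_set
    tip_bit = 1 << ts.index[tip]
    dest = as_bitset(dest_branch, ts)
    if dest & tip_bit:
        raise ValueError("destination clade must not contain the tip itself")

    out = tree.copy()
    tip_node = out.tip(tip)
    tip_h = tip_node.height
    old_parent = tip_node.parent
    sib_bits_before = out.node_bitsets()
    old_sib = [c for c in old_parent.children if c is not tip_node]
    old_sib_clade = 0
    for c in old_sib:
        old_sib_clade |= sib_bits_before[c]
    if dest == old_sib_clade:
        raise ValueError(
            "destination equals the tip's current attachment (no-op move)"
        )

    _prune_tip_inplace(out, tip)
    bits = out.node_bitsets()
    dest_node = None
    for nd, b in bits.items():
        if b == dest:
            dest_node = nd
            break
    if dest_node is None:
        raise ValueError("destination clade not found in the pruned tree")
    if dest_node.parent is None:
        raise ValueError("cannot regraft above the root")

    lo = max(tip_h, dest_node.height)
    hi = dest_node.parent.height
    if lo > hi:
        raise ValueError(
            f"infeasible relocation: tip at height {tip_h:.4g} is younger "
            f"than the destination branch interval"
        )
    att = Node(None, (lo + hi) / 2.0)
    gp = dest_node.parent
    gp.children[gp.children.index(dest_node)] = att
    att.parent = gp
    att.add_child(dest_node)
    new_tip = Node(tip, tip_h)
    att.add_child(new_tip)
    return out


def _edge_path(tree: RootedTree, start_clade: int, dest_clade: int) -> list[int]:
    """Shortest path in the line graph (edges as vertices, adjacency =
    sharing a node) from the edge above ``start_clade`` to the edge above
    ``dest_clade``; returned as the sequence of child-clade bitsets."""
    bits = tree.node_bitsets()
    by_bits = {b: nd for nd, b in bits.items()}
    if start_clade not in by_bits or dest_clade not in by_bits:
        raise ValueError("clade not present in tree")

    def neighbors(b: int) -> list[int]:
        nd = by_bits[b]
        out = []
        if nd.parent is not None:
            p = nd.parent
            if p.parent is not None:
                out.append(bits[p])  # edge above the parent
            out.extend(bits[s] for s in p.children if s is not nd)  # siblings
        out.extend(bits[c] for c in nd.children)  # child edges
        return out

    from collections import deque

    prev: dict[int, Optional[int]] = {start_clade: None}
    q = deque([start_clade])
    while q:
        cur = q.popleft()
        if cur == dest_clade:
            path = [cur]
            while prev[cur] is not None:
                cur = prev[cur]
                path.append(cur)
            return path[::-1]
        for nb in neighbors(cur):
            if nb not in prev:
                prev[nb] = cur
                q.append(nb)
    raise ValueError("no path between branches (disconnected?)")


def nni_path_tip_relocation(
    tree: RootedTree, tip: str, dest_branch: CladeLike
) -> list[RootedTree]:
    """Decompose a tip relocation into consecutive rooted NNI moves.

    Returns ``[t0, t1, ..., tk]`` with ``t0`` the input tree, ``tk`` the
    relocate_tip output, and each consecutive pair differing by exactly one
    NNI (rooted RF distance 2).  ``k`` equals the number of internal nodes
    strictly between the old and new attachment points.
    """
    ts = tree.taxon_set
    dest = as_bitset(dest_branch, ts)
    tip_bit = 1 << ts.index[tip]

    pruned = tree.copy()
    old_sib = _prune_tip_inplace(pruned, tip)
    start = pruned.node_bitsets()[old_sib]
    edge_seq = _edge_path(pruned, start, dest)  # [start, f1, ..., dest]
    if len(edge_seq) < 2:
        raise ValueError(
            "destination equals the tip's current attachment (no-op move)"
        )
    path = [tree]
    for b in edge_seq[1:]:
        path.append(relocate_tip(path[-1], tip, b))
    return path


# ---------------------------------------------------------------------------
# exact rooted SPR distance for small instances

Topo = Union[int, tuple]


def _topo_from_tree(tree: RootedTree) -> Topo:
    idx = tree.taxon_set.index

    def rec(nd: Node) -> Topo:
        if nd.is_tip:
            return idx[nd.label]
        if len(nd.children) != 2:
            raise ValueError("exact rSPR requires binary trees")
        return _pair(rec(nd.children[0]), rec(nd.children[1]))

    return rec(tree.root)


def _min_leaf(t: Topo) -> int:
    return t if isinstance(t, int) else min(_min_leaf(t[0]), _min_leaf(t[1]))


def _pair(a: Topo, b: Topo) -> tuple:
    return (a, b) if _min_leaf(a) < _min_leaf(b) else (b, a)


def _subtrees(t: Topo) -> list[Topo]:
    out = []
    stack = list(t) if isinstance(t, tuple) else []
    while stack:
        s = stack.pop()
        out.append(s)
        if isinstance(s, tuple):
            stack.extend(s)
    return out


def _leafset(t: Topo) -> frozenset:
    return frozenset([t]) if isinstance(t, int) else (
        _leafset(t[0]) | _leafset(t[1])
    )


def _prune_topo(t: Topo, sub: Topo) -> Topo:
    a, b = t
    if a == sub:
        return b
    if b == sub:
        return a
    if _leafset(sub) <= _leafset(a):
        return _pair(_prune_topo(a, sub), b)
    return _pair(a, _prune_topo(b, sub))


def _attachments(t: Topo, sub: Topo):
    yield _pair(sub, t)
    if isinstance(t, tuple):
        a, b = t
        for na in _attachments(a, sub):
            yield _pair(na, b)
        for nb in _attachments(b, sub):
            yield _pair(a, nb)


def _spr_neighbors(t: Topo) -> set:
    out = set()
    for sub in _subtrees(t):
        rem = _prune_topo(t, sub)
        for nt in _attachments(rem, sub):
            out.add(nt)
    out.discard(t)
    return out


def _rspr_bfs(a: Topo, b: Topo) -> int:
    if a == b:
        return 0
    front_a, front_b = {a}, {b}
    seen_a, seen_b = {a: 0}, {b: 0}
    d = 0
    while front_a and front_b:
        d += 1
        if len(front_a) > len(front_b):
            front_a, front_b = front_b, front_a
            seen_a, seen_b = seen_b, seen_a
        new = set()
        for t in front_a:
            for nb in _spr_neighbors(t):
                if nb in seen_b:
                    return seen_a[t] + 1 + seen_b[nb]
                if nb not in seen_a:
                    seen_a[nb] = seen_a[t] + 1
                    new.add(nb)
        front_a = new
    raise RuntimeError("SPR graph search exhausted without meeting")


def rspr_distance_small(t1: RootedTree, t2: RootedTree) -> int:
    """Exact rooted-SPR distance by breadth-first search over topology
    classes; limited to trees with at most 10 tips."""
    if t1.taxon_set != t2.taxon_set:
        raise ValueError("trees are over different taxon sets")
    if len(t1.taxon_set) > 10:
        raise ValueError("exact rSPR limited to <= 10 tips; use rf_rooted")
    return _rspr_bfs(_topo_from_tree(t1), _topo_from_tree(t2))


# ---------------------------------------------------------------------------
# topology classes

def topology_classes(traces: Sequence[TreeTrace]) -> dict:
    """Partition pooled samples into topology classes (clade-set equality).

    Returns a mapping canonical clade set -> {"counts": per-chain counts,
    "total": pooled count, "representative": first sampled tree}.
    """
    ts = traces[0].taxon_set
    if any(tr.taxon_set != ts for tr in traces):
        raise ValueError("chains must share one TaxonSet")
    out: dict[frozenset, dict] = {}
    for tr in traces:
        for i, cs in enumerate(tr.clade_sets):
            if cs not in out:
                out[cs] = {
                    "counts": {t.chain_id: 0 for t in traces},
                    "total": 0,
                    "representative": tr.trees[i],
                }
            out[cs]["counts"][tr.chain_id] += 1
            out[cs]["total"] += 1
    return dict(
        sorted(out.items(), key=lambda kv: -kv[1]["total"])
    )


# ---------------------------------------------------------------------------
# classical MDS

@dataclass
class MDSEmbedding:
    coordinates: np.ndarray  # samples x dims
    eigenvalues: np.ndarray  # full spectrum, sorted descending
    stress: float
    labels: list = field(default_factory=list)
    density: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"mds{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        if self.labels:
            df.insert(0, "chain", [c for c, _ in self.labels])
            df.insert(1, "sample", [i for _, i in self.labels])
        if self.density is not None:
            df["density"] = self.density
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> MDSEmbedding:
    """Classical (Torgerson) MDS: eigendecomposition of the double-centered
    squared-distance Gram matrix; negative eigenvalues truncated to zero."""
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    d = dist.matrix
    n = d.shape[0]
    if dims > max(n - 1, 1):
        raise ValueError("dims must be <= samples - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(pos)
    emb_d = np.sqrt(
        np.maximum(
            np.sum(
                (coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1
            ),
            0.0,
        )
    )
    denom = float(np.sum(d ** 2))
    stress = float(np.sqrt(np.sum((emb_d - d) ** 2) / denom)) if denom else 0.0
    return MDSEmbedding(coords, evals, stress, list(dist.labels), dist.density)


# ---------------------------------------------------------------------------
# landscape overlays and valley profiles

def landscape_overlay(
    embedding: MDSEmbedding,
    density: Optional[np.ndarray] = None,
    mode: str = "heatmap",
    grid: int = 50,
    top_fraction: float = 0.01,
) -> dict:
    """Posterior-density overlay of an MDS embedding, as plot-ready data.

    ``heatmap``: mean density per occupied grid cell (``grid`` x ``grid``);
    ``top_fraction``: indices and coordinates of the highest-density samples;
    ``scatter3d``: 2-d coordinates with density attached as z.
    """
    if density is None:
        density = embedding.density
    if density is None:
        raise ValueError("no density available for overlay")
    density = np.asarray(density, dtype=float)
    coords = embedding.coordinates
    if len(density) != len(coords):
        raise ValueError("density length must match embedded samples")
    x, y = coords[:, 0], coords[:, 1]
    if mode == "heatmap":
        sums, xe, ye = np.histogram2d(x, y, bins=grid, weights=density)
        counts, _, _ = np.histogram2d(x, y, bins=grid, range=[[xe[0], xe[-1]], [ye[0], ye[-1]]])
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return {"x_edges": xe, "y_edges": ye, "mean_density": mean,
                "counts": counts}
    if mode == "top_fraction":
        k = max(1, int(round(top_fraction * len(density))))
        idx = np.argsort(density)[::-1][:k]
        idx = np.sort(idx)
        return {"indices": idx, "coordinates": coords[idx],
                "density": density[idx]}
    if mode == "scatter3d":
        return {"x": x, "y": y, "z": density}
    raise ValueError("mode must be heatmap, top_fraction or scatter3d")


def path_profile(
    trees: Sequence[RootedTree], score_series: Sequence[float]
) -> list[tuple[RootedTree, float]]:
    """Score profile along an ordered tree path (e.g. an NNI valley path)."""
    if len(trees) != len(score_series):
        raise ValueError("scores must align to trees")
    return list(zip(trees, [float(s) for s in score_series]))
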