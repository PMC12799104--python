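"""Summary trees, clade-specific variable traces, tip pruning with
re-diagnosis, problematic-tip ranking, and tree-shape summaries.

The maximum-clade-credibility (MCC) tree is the *sampled* tree maximizing
the sum of log pooled clade posterior probabilities over its nontrivial
clades; node annotations carry clade support and height summaries computed
over the trees that contain each clade.

Tip pruning reproduces the dissection workflow: remove suspected wobbling
tips from every posterior sample, suppress the resulting degree-2 nodes
(merged-branch rate = duration-weighted mean), and re-run the diagnostics
on the pruned trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._tree import Node, RootedTree, TaxonSet
from .clades import CladeTable, as_bitset, clade_frequencies
from .diagnostics import _safe_ess, _safe_psrf, sdcf
from .treeio import TreeTrace

__all__ = [
    "SummaryTree",
    "mcc_tree",
    "clade_variable_traces",
    "prune_tree",
    "prune_tips",
    "rank_problematic_tips",
    "tree_shape",
]


@dataclass
class SummaryTree:
    """A sampled tree annotated with clade posterior support and height
    summaries (mean/median/95% central interval over trees containing the
    clade)."""

    tree: RootedTree
    log_credibility: float
    clade_support: dict[int, float] = field(default_factory=dict)


def mcc_tree(traces: Sequence[TreeTrace]) -> SummaryTree:
    """Maximum-clade-credibility tree over pooled chains.

    Among sampled trees, maximizes the sum of log pooled clade posterior
    probabilities; ties broken by first occurrence in trace order.
    """
    if not traces or any(len(tr) == 0 for tr in traces):
        raise ValueError("need non-empty traces")
    table = clade_frequencies(traces)
    logp = {b: math.log(table.pooled_frequency(b)) for b in table.clades}

    best_score, best_tree, best_cs = -math.inf, None, None
    seen: set[frozenset] = set()
    for tr in traces:
        for i, cs in enumerate(tr.clade_sets):
            if cs in seen:
                continue
            seen.add(cs)
            score = sum(logp[b] for b in cs)
            if score > best_score:
                best_score, best_tree, best_cs = score, tr.trees[i], cs

    out = best_tree.copy()
    bits = out.node_bitsets()
    full = bits[out.root]
    # MRCA-height samples per clade of the chosen tree, over trees containing it
    wanted = {b for nd, b in bits.items() if not nd.is_tip}
    heights: dict[int, list[float]] = {b: [] for b in wanted}
    for tr in traces:
        for info, tree in zip(tr.clade_info, tr.trees):
            for b in wanted:
                if b == full:
                    heights[b].append(tree.root.height)
                elif b in info:
                    heights[b].append(info[b][0])
    support: dict[int, float] = {}
    for nd in out.postorder():
        if nd.is_tip:
            continue
        b = bits[nd]
        p = 1.0 if b == full else table.pooled_frequency(b)
        hs = np.array(heights[b])
        nd.annotations.update(
            {
                "posterior": p,
                "height_mean": float(hs.mean()),
                "height_median": float(np.median(hs)),
                "height_95_lower": float(np.quantile(hs, 0.025)),
                "height_95_upper": float(np.quantile(hs, 0.975)),
            }
        )
        support[b] = p
    return SummaryTree(out, best_score, support)


# ---------------------------------------------------------------------------
# clade-specific variable traces

_CLADE_VARIABLES = ("node_age", "branch_duration", "branch_rate")


def clade_variable_traces(
    traces: Sequence[TreeTrace],
    clade,
    variable: str,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-chain series of a clade-specific variable, present samples only.

    Returns (series per chain, presence mask per chain).  node_age is the
    clade MRCA height; branch_duration the parent height minus MRCA height;
    branch_rate the rate annotation on the MRCA's subtending branch.
    """
    if variable not in _CLADE_VARIABLES:
        raise ValueError(f"variable must be one of {_CLADE_VARIABLES}")
    b = as_bitset(clade, traces[0].taxon_set)
    col = {"node_age": 0, "branch_duration": 1, "branch_rate": 2}[variable]
    series, masks = [], []
    any_present = False
    for tr in traces:
        vals, mask = [], np.zeros(len(tr), dtype=bool)
        for i, info in enumerate(tr.clade_info):
            if b in info:
                mask[i] = True
                h, ph, rate = info[b]
                vals.append(
                    (h, ph - h, rate)[col]
                )
        series.append(np.array(vals, dtype=float))
        masks.append(mask)
        any_present |= bool(mask.any())
    if not any_present:
        import warnings

        warnings.warn("clade never present in any sampled tree")
    return series, masks


# ---------------------------------------------------------------------------
# tip pruning

def prune_tree(tree: RootedTree, tips: Iterable[str],
               taxon_set: Optional[TaxonSet] = None) -> RootedTree:
    """Remove tips and suppress degree-2 nodes; heights of remaining nodes
    are unchanged; a merged branch's rate is the duration-weighted mean of
    the two merged segments."""
    drop = set(tips)
    keep = [lab for lab in tree.taxon_set.labels if lab not in drop]
    if taxon_set is None:
        taxon_set = TaxonSet(keep)

    # rate segments of a (possibly repeatedly) merged branch, bottom-up:
    # list of (low_height, high_height_or_None, rate); last high is open and
    # closes at the eventual parent height.
    segs: dict[Node, list] = {}

    def conv(nd: Node) -> Optional[Node]:
        if nd.is_tip:
            if nd.label in drop:
                return None
            new = Node(nd.label, nd.height)
            new.annotations = dict(nd.annotations)
            segs[new] = [(nd.height, None, nd.annotations.get("rate"))]
            return new
        kids = [conv(c) for c in nd.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress this degree-2 node
            child = kids[0]
            lower = segs[child]
            lower[-1] = (lower[-1][0], nd.height, lower[-1][2])
            lower.append((nd.height, None, nd.annotations.get("rate")))
            return child
        new = Node(None, nd.height)
        new.annotations = dict(nd.annotations)
        segs[new] = [(nd.height, None, nd.annotations.get("rate"))]
        for k in kids:
            new.add_child(k)
        return new

    root = conv(tree.root)
    if root is None or sum(1 for _ in _iter_tips(root)) < 3:
        raise ValueError("pruning would leave fewer than 3 tips")
    while not root.is_tip and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    out = RootedTree(taxon_set, root)
    for nd in out.postorder():
        if nd.parent is None:
            nd.annotations.pop("rate", None)
            continue
        parts = segs.get(nd)
        if parts is None or len(parts) == 1:
            continue  # unmerged branch keeps its own rate
        parts = [
            (lo, hi if hi is not None else nd.parent.height, r)
            for lo, hi, r in parts
        ]
        if any(r is None for _, _, r in parts):
            nd.annotations.pop("rate", None)
            continue
        total = sum(hi - lo for lo, hi, _ in parts)
        nd.annotations["rate"] = (
            sum((hi - lo) * r for lo, hi, r in parts) / total
            if total > 0
            else float(np.mean([r for _, _, r in parts]))
        )
    return out


def _iter_tips(nd: Node):
    stack = [nd]
    while stack:
        cur = stack.pop()
        if cur.is_tip:
            yield cur
        stack.extend(cur.children)


def prune_tips(
    traces: Sequence[TreeTrace], tips: Iterable[str]
) -> list[TreeTrace]:
    """Prune tips from every sampled tree of every chain."""
    tips = list(tips)
    ts = traces[0].taxon_set
    for t in tips:
        if t not in ts:
            raise ValueError(f"tip {t!r} not in the study TaxonSet")
    keep = [lab for lab in ts.labels if lab not in set(tips)]
    if len(keep) < 3:
        raise ValueError("pruning would leave fewer than 3 taxa")
    new_ts = TaxonSet(keep)
    out = []
    for tr in traces:
        trees = [prune_tree(t, tips, new_ts) for t in tr.trees]
        out.append(
            TreeTrace(tr.chain_id, list(tr.iterations), trees, tr.density)
        )
    return out


# ---------------------------------------------------------------------------
# problematic-tip ranking

def rank_problematic_tips(
    traces: Sequence[TreeTrace],
    table: Optional[CladeTable] = None,
    max_clade_frac: float = 0.1,
) -> list[tuple[str, float, dict]]:
    """Rank tips by evidence of wobbling between attachment positions.

    score(tip) = max SDCF over nontrivial clades containing the tip of size
    at most max(3, ceil(max_clade_frac * n)) — small clades localize the
    attachment.  Tips tied at the top score (a wobbler always ties with its
    attachment-partner tips) are separated by a leave-one-out re-diagnosis:
    the drop in ASDCF when that tip alone is pruned from every sampled tree,
    which is large for the tip causing the discordance and small for
    bystanders.  Remaining ties fall back to the PSRF of the tip's pendant
    branch duration (and branch rate when annotated).  Returns
    (tip, score, evidence) descending.
    """
    if table is None:
        table = clade_frequencies(traces)
    ts = traces[0].taxon_set
    n = len(ts)
    cap = max(3, math.ceil(max_clade_frac * n))
    multi = len(traces) >= 2

    # pendant branch duration / rate per tip, per chain
    def pendant_series(tip_label: str, want_rate: bool) -> list[np.ndarray]:
        out = []
        for tr in traces:
            vals = []
            for tree in tr.trees:
                nd = tree.tip(tip_label)
                if want_rate:
                    vals.append(nd.annotations.get("rate", float("nan")))
                else:
                    vals.append(nd.parent.height - nd.height)
            out.append(np.array(vals))
        return out

    has_rates = any(
        not np.isnan(info[b][2])
        for tr in traces
        for info in tr.clade_info[:1]
        for b in info
    )

    results = []
    for i, tip_label in enumerate(ts.labels):
        bit = 1 << i
        best_sdcf, best_clades = 0.0, []
        for b in table.clades:
            if not (b & bit) or int(b).bit_count() > cap:
                continue
            s = sdcf(b, table) if multi else 0.0
            if s > best_sdcf + 1e-12:
                best_sdcf, best_clades = s, [b]
            elif abs(s - best_sdcf) <= 1e-12 and s > 0:
                best_clades.append(b)
        dur_psrf = _safe_psrf(pendant_series(tip_label, False)) if multi else float("nan")
        rate_psrf = (
            _safe_psrf(pendant_series(tip_label, True))
            if (multi and has_rates)
            else float("nan")
        )
        psrf_tiebreak = np.nanmax([dur_psrf, rate_psrf, 0.0])
        evidence = {
            "clades": [
                ("|".join(ts.labels_of(b)), sdcf(b, table) if multi else 0.0)
                for b in best_clades[:5]
            ],
            "n_max_sdcf_clades": len(best_clades),
            "pendant_duration_psrf": dur_psrf,
            "pendant_rate_psrf": rate_psrf,
        }
        results.append(
            [tip_label, float(best_sdcf), 0.0, float(psrf_tiebreak), evidence]
        )

    # leave-one-out ASDCF drop for tips contesting the top score
    if multi:
        top = max(r[1] for r in results)
        base_asdcf = _asdcf_of_clade_sets(
            [tr.clade_sets for tr in traces], None, 0
        )
        for r in results:
            if top > 0 and r[1] >= top - 1e-9:
                bit = 1 << ts.index[r[0]]
                r[2] = base_asdcf - _asdcf_of_clade_sets(
                    [tr.clade_sets for tr in traces], bit, ts.full_bitset
                )
                r[4]["loo_asdcf_drop"] = r[2]

    results.sort(key=lambda r: (-r[1], -r[2], -r[3], r[0]))
    return [(lab, score, ev) for lab, score, _, _, ev in results]


def _asdcf_of_clade_sets(chain_clade_sets, drop_bit, full_bitset):
    """ASDCF recomputed directly from per-sample clade sets, optionally
    restricting every clade to the taxa left after pruning one tip."""
    keep = ~drop_bit if drop_bit else -1
    full = full_bitset & keep
    counts: dict[int, np.ndarray] = {}
    m = len(chain_clade_sets)
    for ci, csets in enumerate(chain_clade_sets):
        for cs in csets:
            if drop_bit:
                seen = set()
                for b in cs:
                    rb = b & keep
                    if int(rb).bit_count() >= 2 and rb != full:
                        seen.add(rb)
            else:
                seen = cs
            for rb in seen:
                if rb not in counts:
                    counts[rb] = np.zeros(m)
                counts[rb][ci] += 1
    if not counts:
        return 0.0
    lens = np.array([len(cs) for cs in chain_clade_sets], dtype=float)
    sdcfs = [float(np.std(c / lens, ddof=1)) for c in counts.values()]
    return float(np.mean(sdcfs))


def ranking_to_frame(
    ranking: list[tuple[str, float, dict]]
) -> pd.DataFrame:
    rows = []
    for tip_label, score, ev in ranking:
        rows.append(
            {
                "tip": tip_label,
                "score": score,
                "pendant_duration_psrf": ev["pendant_duration_psrf"],
                "pendant_rate_psrf": ev["pendant_rate_psrf"],
                "top_clades": ";".join(c for c, _ in ev["clades"]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tree shape

def tree_shape(tree: RootedTree) -> dict:
    """Lineage-through-time step function and Colless imbalance.

    LTT: lineage counts at event times (node heights), from the root toward
    the present; ends at the number of tips sampled at height 0.  Colless:
    sum over internal nodes of |left tips - right tips| (binary trees only).
    """
    bits = tree.node_bitsets()
    colless = 0
    binary = True
    for nd in tree.postorder():
        if nd.is_tip:
            continue
        if len(nd.children) != 2:
            binary = False
            continue
        a, b = nd.children
        colless += abs(int(bits[a]).bit_count() - int(bits[b]).bit_count())
    if not binary:
        raise ValueError("Colless imbalance requires a binary tree")

    # walking from the root toward the present: a coalescence adds lineages,
    # a serially sampled tip (height > 0) terminates its lineage; tips at the
    # present (height 0) remain, so an ultrametric n-tip tree ends at n
    events = []
    for nd in tree.postorder():
        if nd.is_tip:
            if nd.height > 0:
                events.append((nd.height, -1))
        else:
            events.append((nd.height, len(nd.children) - 1))
    events.sort(key=lambda e: -e[0])
    times, counts = [], []
    n = 1
    for h, delta in events:
        n += delta
        times.append(h)
        counts.append(n)
    if not times or times[-1] != 0.0:
        times.append(0.0)
        counts.append(n)
    return {
        "ltt": (np.array(times), np.array(counts)),
        "colless": int(colless),
    }
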