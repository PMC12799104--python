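"""Fitch parsimony scores, mutation mapping, discrete-trait dispersal counts
and sequence screening scans.

The parsimony score — the minimum number of mutations required to explain an
alignment on a given topology — is a model-independent statistic of a sampled
tree: its trace across posterior samples feeds ESS/PSRF as a cheap, robust
tree diagnostic.  Sites are IUPAC state sets (gaps and '?' fully missing);
costs are uniform (Fitch, not weighted Sankoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._tree import Node, RootedTree
from .treeio import Alignment, TipMetadata, TreeTrace

__all__ = [
    "ParsimonyResult",
    "fitch_score",
    "branch_mutation_counts",
    "parsimony_trace",
    "site_score_matrix",
    "dispersal_events",
    "pairwise_difference_sites",
    "sequence_screen",
]


@dataclass
class ParsimonyResult:
    total_score: int
    site_scores: np.ndarray
    branch_counts: Optional[dict[int, int]] = None  # keyed by branch bitset
    reconstruction_policy: Optional[str] = None


def _tip_rows(tree: RootedTree, alignment: Alignment) -> None:
    for t in tree.tips():
        if t.label not in alignment:
            raise ValueError(f"tip {t.label!r} has no alignment row")


def _fitch_down(
    tree: RootedTree, alignment: Alignment
) -> tuple[dict[Node, np.ndarray], np.ndarray]:
    """Bottom-up Fitch pass: per-node state-set vectors and per-site scores."""
    _tip_rows(tree, alignment)
    sets: dict[Node, np.ndarray] = {}
    scores = np.zeros(alignment.n_sites, dtype=np.int32)
    for nd in tree.postorder():
        if nd.is_tip:
            sets[nd] = alignment.row(nd.label)
        else:
            acc = sets[nd.children[0]]
            for c in nd.children[1:]:
                inter = acc & sets[c]
                empty = inter == 0
                scores += empty
                acc = np.where(empty, acc | sets[c], inter).astype(np.uint8)
            sets[nd] = acc
    return sets, scores


def fitch_score(tree: RootedTree, alignment: Alignment) -> ParsimonyResult:
    """Alignment-wise and per-site Fitch parsimony scores on one tree."""
    _, scores = _fitch_down(tree, alignment)
    return ParsimonyResult(int(scores.sum()), scores)


def branch_mutation_counts(
    tree: RootedTree,
    alignment: Alignment,
    policy: str = "acctran",
    seed: Optional[int] = None,
) -> ParsimonyResult:
    """Map parsimonious mutations onto branches.

    A single most-parsimonious reconstruction is resolved top-down from the
    Fitch state sets: each node takes its parent's state when compatible,
    otherwise the smallest compatible state (policy ``"acctran"``,
    deterministic) or a seeded random compatible state (policy ``"random"``).
    Branch counts are keyed by the bitset of the clade below the branch and
    sum to the total parsimony score.
    """
    if policy not in ("acctran", "random"):
        raise ValueError("policy must be 'acctran' or 'random'")
    rng = np.random.default_rng(seed) if policy == "random" else None
    sets, scores = _fitch_down(tree, alignment)
    bits = tree.node_bitsets()

    def pick(mask_vec: np.ndarray) -> np.ndarray:
        if rng is None:
            return (mask_vec & (-mask_vec.astype(np.int16))).astype(np.uint8)
        out = np.empty_like(mask_vec)
        for i, m in enumerate(mask_vec):
            states = [b for b in (1, 2, 4, 8) if m & b]
            out[i] = rng.choice(states)
        return out

    assigned: dict[Node, np.ndarray] = {}
    counts: dict[int, int] = {}
    for nd in tree.preorder():
        if nd.parent is None:
            assigned[nd] = pick(sets[nd])
            continue
        par = assigned[nd.parent]
        compat = (sets[nd] & par) > 0
        assigned[nd] = np.where(compat, par, pick(sets[nd])).astype(np.uint8)
        counts[bits[nd]] = int(np.count_nonzero(assigned[nd] != par))
    return ParsimonyResult(
        int(scores.sum()), scores, counts, reconstruction_policy=policy
    )


def parsimony_trace(trace: TreeTrace, alignment: Alignment) -> np.ndarray:
    """Total parsimony score of every sampled tree (the diagnostic series)."""
    return np.fromiter(
        (fitch_score(t, alignment).total_score for t in trace.trees),
        dtype=np.int64,
        count=len(trace),
    )


def site_score_matrix(trace: TreeTrace, alignment: Alignment) -> np.ndarray:
    """Samples x sites matrix of per-site parsimony scores."""
    out = np.zeros((len(trace), alignment.n_sites), dtype=np.int32)
    for i, t in enumerate(trace.trees):
        out[i] = fitch_score(t, alignment).site_scores
    return out


# ---------------------------------------------------------------------------
# discrete-trait dispersal

def dispersal_events(
    tree: RootedTree,
    traits: Union[dict, TipMetadata],
    allow_missing: bool = False,
) -> dict:
    """Parsimony count of dispersal events for a discrete location trait.

    Fitch on the single multistate character; ambiguities resolved top-down
    (root takes the lexicographically smallest member of its state set; a
    child takes its parent's state when compatible, else its smallest).
    Returns the total number of parent-to-child state changes and the
    directed pairwise matrix (rows = origin, columns = destination).
    """
    if isinstance(traits, TipMetadata):
        traits = traits.locations
    states = sorted({v for v in traits.values() if v})
    if not states:
        raise ValueError("no locations supplied")
    full = frozenset(states)

    sets: dict[Node, frozenset] = {}
    for nd in tree.postorder():
        if nd.is_tip:
            loc = traits.get(nd.label)
            if not loc:
                if not allow_missing:
                    raise ValueError(f"tip {nd.label!r} has no location")
                sets[nd] = full
            else:
                sets[nd] = frozenset([loc])
        else:
            acc = sets[nd.children[0]]
            for c in nd.children[1:]:
                inter = acc & sets[c]
                acc = inter if inter else acc | sets[c]
            sets[nd] = acc

    mat = pd.DataFrame(0, index=states, columns=states, dtype=int)
    assigned: dict[Node, str] = {}
    total = 0
    for nd in tree.preorder():
        if nd.parent is None:
            assigned[nd] = min(sets[nd])
            continue
        par = assigned[nd.parent]
        st = par if par in sets[nd] else min(sets[nd])
        assigned[nd] = st
        if st != par:
            total += 1
            mat.loc[par, st] += 1
    return {"total": total, "pairwise": mat}


# ---------------------------------------------------------------------------
# sequence screening

def pairwise_difference_sites(
    alignment: Alignment, taxon1: str, taxon2: str
) -> list[int]:
    """Sites where the two taxa's state sets are disjoint.

    Overlapping ambiguity (e.g. 'R' vs 'A') does not count as a difference.
    """
    r1, r2 = alignment.row(taxon1), alignment.row(taxon2)
    return [int(i) for i in np.where((r1 & r2) == 0)[0]]


def sequence_screen(
    alignment: Alignment,
    taxon: str,
    reference_taxa: Sequence[str],
    frame_offset: int = 0,
    windows: Optional[Sequence[tuple[int, int]]] = None,
) -> dict:
    """Missingness and difference-density scan of one sequence.

    ``missing_by_codon_position`` is the distribution of fully missing sites
    over the three codon positions given ``frame_offset``; the Hamming
    profile is the per-site mean, over the reference taxa, of the
    disjoint-state indicator; the windowed density averages that profile over
    user windows (default: thirds of the alignment).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    if not reference_taxa:
        raise ValueError("empty reference set")
    row = alignment.row(taxon)
    n = alignment.n_sites
    missing = row == 15
    missing_fraction = float(missing.mean()) if n else 0.0

    codon_pos = (np.arange(n) - frame_offset) % 3
    m_total = int(missing.sum())
    by_codon = tuple(
        float(np.sum(missing & (codon_pos == p)) / m_total) if m_total else 0.0
        for p in range(3)
    )

    profile = np.zeros(n, dtype=float)
    for ref in reference_taxa:
        profile += (row & alignment.row(ref)) == 0
    profile /= len(reference_taxa)

    if windows is None:
        edges = [round(i * n / 3) for i in range(4)]
        windows = [(edges[i], edges[i + 1]) for i in range(3)]
    density = [
        float(profile[a:b].mean()) if b > a else 0.0 for a, b in windows
    ]
    return {
        "missing_fraction": missing_fraction,
        "missing_by_codon_position": by_codon,
        "per_site_hamming_profile": profile,
        "windowed_difference_density": density,
        "windows": list(windows),
    }
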