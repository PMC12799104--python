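"""Synthetic multimodal-posterior generator: the fixture source for every
diagnostic in the package.

A study emulates the phenomenology of rugged phylodynamic tree landscapes:
a dated coalescent base tree over a shared taxon set, a small number of
designated "wobbling" tips each alternating between two attachment branches
separated by k intermediate internal nodes, and multiple MCMC-like chains
whose sampled topology is a sticky Markov chain over the 2^m peak
combinations.  Peaks are exact topology classes; intermediate topologies are
never emitted, mirroring the unsampled valleys of real posteriors.
Pseudo log-densities are peak offsets plus noise — a diagnostics fixture,
not an inference engine.  Alignments are simulated on a chosen peak
topology with a Poisson mutation process and a full truth log of every
mutation's branch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import msprime
import numpy as np

from ._tree import Node, RootedTree, TaxonSet
from .treeio import Alignment, ParameterTrace, TipMetadata, TreeTrace
from .treespace import _edge_path

__all__ = [
    "WobbleSpec",
    "SyntheticStudy",
    "MutationLog",
    "simulate_time_tree",
    "simulate_alignment",
    "make_multimodal_trace",
    "choose_wobble_specs",
    "make_preset",
    "PRESETS",
]

_NUC = "ACGT"


def _derive_seed(seq: np.random.SeedSequence) -> int:
    # msprime wants a seed in [1, 2^32); keep below 2^31 for portability
    return int(seq.generate_state(1)[0] % (2**31 - 1)) + 1


def simulate_time_tree(
    n_tips: int,
    Ne: float,
    sampling_times: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    labels: Optional[Sequence[str]] = None,
) -> RootedTree:
    """Heterochronous constant-Ne coalescent time tree (via msprime).

    ``sampling_times`` are times before the most recent sample (defaults to
    contemporaneous sampling); with k extant lineages, coalescence occurs at
    rate C(k,2)/Ne between sampling events.  Node heights are times before
    the latest tip.
    """
    if n_tips < 3 and not (n_tips == 2):
        raise ValueError("need n_tips >= 2")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    times = list(sampling_times) if sampling_times is not None else [0.0] * n_tips
    if len(times) != n_tips:
        raise ValueError("sampling_times must have length n_tips")
    if labels is None:
        width = max(2, len(str(n_tips - 1)))
        labels = [f"t{i:0{width}d}" for i in range(n_tips)]
    ts = TaxonSet(labels)

    rseed = _derive_seed(np.random.SeedSequence(seed))
    sim = msprime.sim_ancestry(
        samples=[msprime.SampleSet(1, time=t, ploidy=1) for t in times],
        population_size=Ne,
        ploidy=1,
        random_seed=rseed,
    )
    tst = sim.first()
    t0 = min(times)
    samples = list(sim.samples())
    lab_of = {u: labels[i] for i, u in enumerate(samples)}

    def rec(u: int) -> Node:
        nd = Node(lab_of.get(u), float(tst.time(u)) - t0)
        for c in tst.children(u):
            child = rec(c)
            child.length = nd.height - child.height
            nd.add_child(child)
        return nd

    return RootedTree(ts, rec(tst.root))


@dataclass
class MutationLog:
    """Ground-truth record of every simulated mutation."""

    events: list = field(default_factory=list)  # (branch_bitset, site, from, to)
    branch_counts: dict = field(default_factory=dict)
    site_counts: Optional[np.ndarray] = None

    @property
    def total(self) -> int:
        return len(self.events)


def simulate_alignment(
    tree: RootedTree,
    model: str = "JC",
    clock_rate: float = 1e-3,
    n_sites: int = 1000,
    seed: Optional[int] = None,
    kappa: float = 2.0,
) -> tuple[Alignment, MutationLog]:
    """Simulate nucleotide sequences down a time tree.

    Mutations arrive as a Poisson process along each branch with mean
    duration * clock_rate per site (HKY weights transitions by ``kappa``);
    the truth log records each mutation's branch, enabling exact validation
    of parsimony mutation mapping.
    """
    if model not in ("JC", "HKY"):
        raise ValueError("model must be 'JC' or 'HKY'")
    if clock_rate < 0 or n_sites <= 0:
        raise ValueError("need clock_rate >= 0 and n_sites > 0")
    rng = np.random.default_rng(seed)
    bits = tree.node_bitsets()
    log = MutationLog(site_counts=np.zeros(n_sites, dtype=int))
    seqs: dict[Node, np.ndarray] = {}
    for nd in tree.preorder():
        if nd.parent is None:
            seqs[nd] = rng.integers(0, 4, n_sites).astype(np.int8)
            continue
        seq = seqs[nd.parent].copy()
        duration = nd.parent.height - nd.height
        n_mut = rng.poisson(duration * clock_rate * n_sites)
        b = bits[nd]
        log.branch_counts[b] = int(n_mut)
        for site in rng.integers(0, n_sites, n_mut):
            cur = int(seq[site])
            if model == "JC":
                new = (cur + int(rng.integers(1, 4))) % 4
            else:
                partner = cur ^ 2  # A<->G, C<->T transitions
                others = [s for s in range(4) if s != cur]
                w = np.array(
                    [kappa if s == partner else 1.0 for s in others]
                )
                new = int(rng.choice(others, p=w / w.sum()))
            log.events.append((b, int(site), cur, new))
            log.site_counts[site] += 1
            seq[site] = new
        seqs[nd] = seq
    rows = {
        nd.label: "".join(_NUC[s] for s in seqs[nd]) for nd in tree.tips()
    }
    return Alignment.from_strings(rows), log


# ---------------------------------------------------------------------------
# multimodal traces

@dataclass
class WobbleSpec:
    """One problematic tip alternating between two attachment branches.

    Attachments identify branches by the clade below them, over the study
    taxa *excluding all wobbling tips*.  ``stay_prob`` is the per-step
    probability of remaining on the current peak side.
    """

    tip: str
    attachment_a: tuple[str, ...]
    attachment_b: tuple[str, ...]
    stay_prob: float = 0.98
    density_offset_a: float = 0.0
    density_offset_b: float = 0.0

    def __post_init__(self):
        if not 0 < self.stay_prob <= 1:
            raise ValueError("stay_prob must be in (0, 1]")


@dataclass
class SyntheticStudy:
    """Complete synthetic study: chains, logs, alignment, metadata, truth."""

    seed: int
    taxon_set: TaxonSet
    base_tree: RootedTree
    specs: list[WobbleSpec]
    traces: list[TreeTrace]
    params: list[ParameterTrace]
    alignment: Alignment
    metadata: TipMetadata
    mutation_log: MutationLog
    truth: dict
    manifest: dict

    @property
    def wobblers(self) -> list[str]:
        return [s.tip for s in self.specs]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for tr in self.traces:
            for t in tr.trees:
                h.update(t.newick().encode())
            h.update(np.asarray(tr.density, dtype=float).tobytes())
        for lab in self.alignment.taxa:
            h.update(self.alignment.row(lab).tobytes())
        h.update(json.dumps(self.truth_jsonable(), sort_keys=True).encode())
        return h.hexdigest()

    def truth_jsonable(self) -> dict:
        t = dict(self.truth)
        t["peak_states"] = {
            k: [int(v) for v in arr] for k, arr in t["peak_states"].items()
        }
        return t


def _restricted_find(tree: RootedTree, clade_bits: int, mask: int) -> Node:
    """Node whose descendant set, restricted to ``mask``, equals the clade."""
    hits = [
        nd
        for nd, b in tree.node_bitsets().items()
        if (b & mask) == clade_bits and nd.parent is not None
    ]
    if not hits:
        raise ValueError("attachment clade not found")
    # innermost match: the one whose full bitset is smallest
    return min(hits, key=lambda nd: int(tree.node_bitsets()[nd]).bit_count())


def _attach_tip(
    tree: RootedTree, label: str, tip_height: float, clade_bits: int, mask: int
) -> None:
    dest = _restricted_find(tree, clade_bits, mask)
    lo = max(tip_height, dest.height)
    hi = dest.parent.height
    if lo > hi:
        raise ValueError(f"infeasible attachment for tip {label!r}")
    att = Node(None, (lo + hi) / 2.0)
    gp = dest.parent
    gp.children[gp.children.index(dest)] = att
    att.parent = gp
    att.add_child(dest)
    att.add_child(Node(label, tip_height))


def _core_and_paths(
    base_tree: RootedTree, specs: Sequence[WobbleSpec]
) -> tuple[RootedTree, int, list[list[int]]]:
    """Prune all wobblers; return the core tree, the core taxon mask, and
    each spec's edge path from attachment_a to attachment_b."""
    from .summarize import prune_tree

    ts = base_tree.taxon_set
    wob = [s.tip for s in specs]
    if len(set(wob)) != len(wob):
        raise ValueError("duplicate wobbler tips")
    core = prune_tree(base_tree, wob, taxon_set=ts)
    mask = ts.full_bitset
    for w in wob:
        mask &= ~(1 << ts.index[w])
    paths = []
    for s in specs:
        a = ts.bitset(s.attachment_a)
        b = ts.bitset(s.attachment_b)
        if (a | b) & ~mask:
            raise ValueError(
                f"attachments of {s.tip!r} must exclude all wobbling tips"
            )
        paths.append(_edge_path(core, a, b))
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            if set(paths[i]) & set(paths[j]):
                raise ValueError(
                    f"interacting specs: {specs[i].tip!r} and "
                    f"{specs[j].tip!r} share valley branches"
                )
    return core, mask, paths


def make_multimodal_trace(
    base_tree: RootedTree,
    wobble_specs: Sequence[WobbleSpec],
    n_chains: int = 4,
    n_samples: int = 500,
    init_peaks: Optional[Sequence[int]] = None,
    seed: int = 0,
    step: int = 1000,
    density_noise_sd: float = 0.25,
    model: str = "JC",
    clock_rate: float = 1e-3,
    n_sites: int = 1000,
    latest_year: float = 2020.0,
    alignment_peak: int = 0,
) -> SyntheticStudy:
    """Generate a multi-chain, multimodal synthetic posterior.

    Each chain is an independent sticky Markov chain over the
    2^len(specs) peak combinations: every spec flips sides independently
    with probability 1 - stay_prob per step.  The sampled tree places each
    wobbling tip at its current attachment; the pseudo posterior log-density
    is the sum of per-spec peak offsets plus Gaussian noise.
    """
    specs = list(wobble_specs)
    m = len(specs)
    if m == 0:
        raise ValueError("need at least one WobbleSpec")
    ts = base_tree.taxon_set
    core, mask, paths = _core_and_paths(base_tree, specs)
    tip_heights = {s.tip: base_tree.tip(s.tip).height for s in specs}

    if init_peaks is None:
        # spread initial peaks so every spec starts on both sides across
        # chains (cycling over the chain-index bits)
        chain_bits = max(1, n_chains.bit_length() - 1)
        init_peaks = [
            sum(((c >> (j % chain_bits)) & 1) << j for j in range(m))
            for c in range(n_chains)
        ]
    if len(init_peaks) != n_chains:
        raise ValueError("init_peaks must have length n_chains")

    peak_cache: dict[int, RootedTree] = {}

    def peak_tree(state: int) -> RootedTree:
        if state not in peak_cache:
            t = core.copy()
            for j, s in enumerate(specs):
                att = s.attachment_b if state >> j & 1 else s.attachment_a
                _attach_tip(
                    t, s.tip, tip_heights[s.tip], ts.bitset(att), mask
                )
            peak_cache[state] = t
        return peak_cache[state]

    root_seq = np.random.SeedSequence(seed)
    chain_seqs = root_seq.spawn(n_chains)
    align_seq, noise_seq = root_seq.spawn(2)

    traces, params = [], []
    peak_states: dict[str, np.ndarray] = {}
    noise_rng = np.random.default_rng(noise_seq)
    offsets = np.array(
        [[s.density_offset_a, s.density_offset_b] for s in specs]
    )
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seqs[c])
        state = int(init_peaks[c])
        states = np.empty(n_samples, dtype=np.int64)
        for i in range(n_samples):
            if i > 0:
                flips = rng.random(m) > np.array(
                    [s.stay_prob for s in specs]
                )
                for j in np.where(flips)[0]:
                    state ^= 1 << int(j)
            states[i] = state
        chain_id = f"chain{c + 1}"
        peak_states[chain_id] = states
        trees = [peak_tree(int(st)).copy() for st in states]
        dens = np.array(
            [
                sum(offsets[j, st >> j & 1] for j in range(m))
                for st in states
            ],
            dtype=float,
        )
        dens += noise_rng.normal(0.0, density_noise_sd, n_samples)
        iters = [i * step for i in range(n_samples)]
        traces.append(TreeTrace(chain_id, iters, trees, dens))
        params.append(
            ParameterTrace(chain_id, iters, {"posterior": dens.copy()})
        )

    alignment, mlog = simulate_alignment(
        peak_tree(alignment_peak),
        model=model,
        clock_rate=clock_rate,
        n_sites=n_sites,
        seed=_derive_seed(align_seq),
    )
    metadata = TipMetadata(
        dates={
            nd.label: latest_year - nd.height for nd in base_tree.tips()
        },
        locations={},
    )
    truth = {
        "wobblers": [s.tip for s in specs],
        "separations": {
            s.tip: len(p) - 1 for s, p in zip(specs, paths)
        },
        "peak_states": peak_states,
        "n_switches": {
            cid: int(np.sum(st[1:] != st[:-1]))
            for cid, st in peak_states.items()
        },
        "alignment_peak_state": int(alignment_peak),
    }
    manifest = {
        "seed": int(seed),
        "n_chains": n_chains,
        "n_samples": n_samples,
        "n_sites": n_sites,
        "clock_rate": clock_rate,
        "model": model,
        "stay_probs": [s.stay_prob for s in specs],
    }
    return SyntheticStudy(
        seed=int(seed),
        taxon_set=ts,
        base_tree=base_tree,
        specs=specs,
        traces=traces,
        params=params,
        alignment=alignment,
        metadata=metadata,
        mutation_log=mlog,
        truth=truth,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# automatic wobble selection and presets

def choose_wobble_specs(
    base_tree: RootedTree,
    n_wobblers: int,
    separation: int,
    rng: np.random.Generator,
    stay_prob: float = 0.98,
    max_attempts: int = 200,
) -> list[WobbleSpec]:
    """Pick wobbling tips and destination branches ``separation`` internal
    nodes away, with pairwise non-interacting valley paths.

    Both attachment branches are required to subtend small local clades
    (at most max(3, ceil(0.1 n)) taxa), emulating how problematic sequences
    wobble among alternative *local* placements rather than backbone
    branches.
    """
    from .summarize import prune_tree

    ts = base_tree.taxon_set
    tips = [nd.label for nd in base_tree.tips()]
    for _ in range(max_attempts):
        chosen = [str(t) for t in rng.choice(tips, size=n_wobblers,
                                             replace=False)]
        try:
            core = prune_tree(base_tree, chosen, taxon_set=ts)
        except ValueError:
            continue
        mask = ts.full_bitset
        for w in chosen:
            mask &= ~(1 << ts.index[w])
        specs, used = [], set()
        ok = True
        for w in chosen:
            spec = _pick_destination(
                base_tree, core, mask, w, chosen, separation, used, rng,
                stay_prob,
            )
            if spec is None:
                ok = False
                break
            specs.append(spec)
        if ok:
            return specs
    raise RuntimeError(
        "could not find non-interacting wobble specs; try fewer wobblers "
        "or smaller separation"
    )


def _pick_destination(
    base_tree, core, mask, tip_label, all_wobblers, k, used, rng, stay_prob
):
    from collections import deque

    ts = base_tree.taxon_set
    tip_h = base_tree.tip(tip_label).height
    # current attachment: the sibling clade restricted to core taxa
    from .summarize import prune_tree

    others = [w for w in all_wobblers if w != tip_label]
    pruned_others = (
        prune_tree(base_tree, others, taxon_set=ts) if others else base_tree
    )
    tip_nd = pruned_others.tip(tip_label)
    bits = pruned_others.node_bitsets()
    sib_bits = 0
    for c in tip_nd.parent.children:
        if c is not tip_nd:
            sib_bits |= bits[c]
    import math as _math

    cap = max(3, _math.ceil(0.1 * len(ts))) - 1  # local-attachment size cap
    start = sib_bits & mask
    core_bits = core.node_bitsets()
    by_bits = {b: nd for nd, b in core_bits.items()}
    if start not in by_bits or int(start).bit_count() > cap:
        return None

    # BFS to depth k in the edge line graph, tracking paths
    frontier = {start: [start]}
    seen = {start}
    for _ in range(k):
        nxt = {}
        for b, path in frontier.items():
            for nb in _edge_neighbors(core, by_bits, core_bits, b):
                if nb not in seen:
                    seen.add(nb)
                    nxt[nb] = path + [nb]
        frontier = nxt
    cands = list(frontier.items())
    rng.shuffle(cands)
    for dest, path in cands:
        nd = by_bits[dest]
        if nd.parent is None or nd.parent.height <= tip_h:
            continue  # infeasible attachment height
        if int(dest).bit_count() > cap:
            continue  # not a local attachment
        if used & set(path):
            continue
        used |= set(path)
        return WobbleSpec(
            tip=tip_label,
            attachment_a=ts.labels_of(start),
            attachment_b=ts.labels_of(dest),
            stay_prob=stay_prob,
        )
    return None


def _edge_neighbors(tree, by_bits, bits, b):
    nd = by_bits[b]
    out = []
    if nd.parent is not None:
        p = nd.parent
        if p.parent is not None:
            out.append(bits[p])
        out.extend(bits[s] for s in p.children if s is not nd)
    out.extend(bits[c] for c in nd.children)
    return out


#: Named desk-scale study conditions: (n_tips, n_wobblers, separation,
#: stay_prob, n_chains, n_samples).
PRESETS = {
    # one tip wobbling 6 nodes apart, chains stuck on their initial peak
    "lassa-like": dict(
        n_tips=30, n_wobblers=1, separation=6, stay_prob=1.0,
        n_chains=4, n_samples=300,
    ),
    # one tip wobbling 4 nodes apart, rare commutes between peaks
    "mumps-like": dict(
        n_tips=30, n_wobblers=1, separation=4, stay_prob=0.98,
        n_chains=4, n_samples=400,
    ),
    # three independently wobbling tips -> 8 combinatorial peaks
    "three-wobblers": dict(
        n_tips=20, n_wobblers=3, separation=3, stay_prob=0.9,
        n_chains=4, n_samples=500,
    ),
}


def make_preset(name: str, seed: int = 0) -> SyntheticStudy:
    """Build one of the named synthetic study presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {list(PRESETS)}")
    cfg = PRESETS[name]
    root_seq = np.random.SeedSequence(seed)
    tree_seq, pick_seq, study_seq = root_seq.spawn(3)
    n = cfg["n_tips"]
    rng = np.random.default_rng(pick_seq)
    times = np.round(rng.uniform(0.0, 10.0, n), 3)
    times[int(rng.integers(n))] = 0.0  # anchor the latest tip at the present
    base = simulate_time_tree(
        n, Ne=5.0, sampling_times=times, seed=_derive_seed(tree_seq)
    )
    specs = choose_wobble_specs(
        base,
        cfg["n_wobblers"],
        cfg["separation"],
        rng,
        stay_prob=cfg["stay_prob"],
    )
    return make_multimodal_trace(
        base,
        specs,
        n_chains=cfg["n_chains"],
        n_samples=cfg["n_samples"],
        seed=_derive_seed(study_seq),
    )
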