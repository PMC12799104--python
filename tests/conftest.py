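import numpy as np
import pytest

import treerug as tr
from treerug.treeio import TreeTrace


def make_trace(trees, chain_id="c1", density=None):
    return TreeTrace(chain_id, list(range(len(trees))), trees, density)


@pytest.fixture
def quartet():
    return tr.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def stuck_study():
    """Four chains stuck pairwise on the two peaks of a single k=6 wobbler."""
    return tr.make_preset("lassa-like", seed=1)


@pytest.fixture(scope="session")
def mixing_study():
    """Fast-switching (stay probability 0.5) two-peak study: behaves like
    i.i.d. sampling of the peak mixture, so every diagnostic should pass."""
    base = tr.simulate_time_tree(
        20, Ne=5.0,
        sampling_times=list(np.linspace(0.0, 8.0, 20)), seed=11,
    )
    specs = tr.synthetic.choose_wobble_specs(
        base, 1, 3, np.random.default_rng(4), stay_prob=0.5
    )
    return tr.make_multimodal_trace(
        base, specs, n_chains=4, n_samples=400, seed=11, n_sites=400
    )


def all_rooted_topologies(labels):
    """Every labeled rooted binary topology on the labels (as newick strings,
    unit branch lengths) -- independent enumeration for brute-force checks."""
    trees = [labels[0]]
    for lab in labels[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, lab))
        trees = nxt
    return [f"{_to_newick(t)};" for t in trees]


def _insert_everywhere(t, lab):
    out = [(lab, t)]
    if isinstance(t, tuple):
        a, b = t
        out.extend((na, b) for na in _insert_everywhere(a, lab))
        out.extend((a, nb) for nb in _insert_everywhere(b, lab))
    return out


def _to_newick(t):
    if isinstance(t, str):
        return t + ":1"
    return f"({_to_newick(t[0])},{_to_newick(t[1])}):1"
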