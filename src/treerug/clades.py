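"""Clade enumeration, occurrence traces and per-chain frequencies.

Clades are *rooted* (sets of tips descending from an internal node), not
unrooted splits; singletons and the full taxon set are excluded everywhere
because they occur in every rooted tree and carry no information about
topological convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from ._tree import RootedTree, TaxonSet
from .treeio import TreeTrace

__all__ = [
    "CladeTable",
    "extract_clades",
    "clade_occurrence_trace",
    "clade_frequencies",
    "as_bitset",
]

CladeLike = Union[int, Iterable[str]]


def as_bitset(clade: CladeLike, taxon_set: TaxonSet) -> int:
    """Coerce a clade given as labels or bitset to its canonical bitset."""
    if isinstance(clade, int):
        return clade
    return taxon_set.bitset(clade)


def extract_clades(tree: RootedTree) -> frozenset[int]:
    """Nontrivial rooted clades of a tree (n-2 of them when binary)."""
    return tree.clades()


def clade_occurrence_trace(clade: CladeLike, trace: TreeTrace) -> np.ndarray:
    """Binary series: 1 when the clade is present in the sampled tree."""
    try:
        b = as_bitset(clade, trace.taxon_set)
    except KeyError:
        return np.zeros(len(trace), dtype=np.int8)  # foreign taxa: never seen
    return np.fromiter(
        (1 if b in cs else 0 for cs in trace.clade_sets),
        dtype=np.int8,
        count=len(trace),
    )


@dataclass
class CladeTable:
    """Per-chain occurrence traces and frequencies for every observed clade."""

    taxon_set: TaxonSet
    chain_ids: list[str]
    chain_lengths: list[int]
    occurrences: dict[int, list[np.ndarray]] = field(repr=False)

    @property
    def clades(self) -> list[int]:
        return list(self.occurrences)

    def __len__(self) -> int:
        return len(self.occurrences)

    def __contains__(self, clade: int) -> bool:
        return clade in self.occurrences

    def trace(self, clade: CladeLike, chain: int) -> np.ndarray:
        return self.occurrences[as_bitset(clade, self.taxon_set)][chain]

    def chain_frequencies(self, clade: CladeLike) -> np.ndarray:
        """Mean occurrence of the clade in each chain."""
        b = as_bitset(clade, self.taxon_set)
        return np.array([tr.mean() for tr in self.occurrences[b]])

    def pooled_frequency(self, clade: CladeLike) -> float:
        """Sample-count-weighted mean of the per-chain frequencies."""
        b = as_bitset(clade, self.taxon_set)
        total = sum(self.chain_lengths)
        return float(
            sum(tr.sum() for tr in self.occurrences[b]) / total
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.occurrences:
            freqs = self.chain_frequencies(b)
            row = {
                "clade": "|".join(self.taxon_set.labels_of(b)),
                "size": int(b).bit_count(),
                "pooled_frequency": self.pooled_frequency(b),
            }
            for cid, f in zip(self.chain_ids, freqs):
                row[f"freq_{cid}"] = f
            rows.append(row)
        return pd.DataFrame(rows).sort_values(
            ["size", "clade"], ignore_index=True
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def clade_frequencies(traces: Sequence[TreeTrace]) -> CladeTable:
    """Tabulate every nontrivial clade observed in any chain.

    Per-chain frequency is the mean of the clade's binary occurrence trace;
    the pooled frequency weights chains by their sample counts.
    """
    if not traces:
        raise ValueError("need at least one chain")
    for tr in traces:
        if len(tr) == 0:
            raise ValueError(f"empty trace {tr.chain_id!r}")
    ts = traces[0].taxon_set
    if any(tr.taxon_set != ts for tr in traces):
        raise ValueError("all chains must share one TaxonSet")

    all_clades: set[int] = set()
    for tr in traces:
        for cs in tr.clade_sets:
            all_clades |= cs

    occurrences: dict[int, list[np.ndarray]] = {}
    for b in sorted(all_clades, key=lambda x: (int(x).bit_count(), x)):
        occurrences[b] = [
            np.fromiter(
                (1 if b in cs else 0 for cs in tr.clade_sets),
                dtype=np.int8,
                count=len(tr),
            )
            for tr in traces
        ]
    return CladeTable(
        ts,
        [tr.chain_id for tr in traces],
        [len(tr) for tr in traces],
        occurrences,
    )
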