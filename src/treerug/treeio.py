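"""Reading and writing posterior tree logs, parameter logs, alignments and
tip metadata.

Tree logs are NEXUS (with translate tables and BEAST-style ``[&key=value]``
branch comments, accepted before or after the branch length) or plain Newick;
dendropy does the parsing.  Parameter logs are tab-delimited with a leading
iteration column.  Alignments are FASTA/NEXUS via Biopython, stored as IUPAC
state-set bitmasks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

from ._tree import Node, RootedTree, TaxonSet

__all__ = [
    "TreeTrace",
    "ParameterTrace",
    "Alignment",
    "TipMetadata",
    "read_tree_log",
    "write_tree_log",
    "read_param_log",
    "write_param_log",
    "read_alignment",
    "read_tip_metadata",
    "parse_newick",
    "apply_burnin",
]

# IUPAC nucleotide codes as bitmasks over (A=1, C=2, G=4, T=8).
IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15, ".": 15, "X": 15,
}
MASK_CHAR = {1: "A", 2: "C", 4: "G", 8: "T", 15: "N"}


@dataclass
class TreeTrace:
    """One chain's ordered sequence of sampled trees."""

    chain_id: str
    iterations: list[int]
    trees: list[RootedTree]
    density: Optional[np.ndarray] = None
    _clade_sets: Optional[list[frozenset[int]]] = field(
        default=None, repr=False, compare=False
    )
    _clade_info: Optional[list[dict]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if len(self.iterations) != len(self.trees):
            raise ValueError("iterations and trees must align")
        if self.density is not None and len(self.density) != len(self.trees):
            raise ValueError("density must align to samples")
        if any(
            b >= a for a, b in zip(self.iterations[1:], self.iterations)
        ):
            raise ValueError("iterations must be strictly increasing")
        ts = {id(t.taxon_set) for t in self.trees}
        if len(ts) > 1 and len({t.taxon_set for t in self.trees}) > 1:
            raise ValueError("all trees in a trace must share one TaxonSet")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def taxon_set(self) -> TaxonSet:
        return self.trees[0].taxon_set

    @property
    def clade_sets(self) -> list[frozenset[int]]:
        """Per-sample nontrivial clade sets (computed once, cached)."""
        if self._clade_sets is None:
            self._clade_sets = [t.clades() for t in self.trees]
        return self._clade_sets

    @property
    def clade_info(self) -> list[dict]:
        """Per-sample map: nontrivial clade bitset -> (MRCA height, parent
        height, branch rate or NaN).  Cached; trees must not be mutated."""
        if self._clade_info is None:
            out = []
            for tree in self.trees:
                bits = tree.node_bitsets()
                full = bits[tree.root]
                info = {}
                for nd, b in bits.items():
                    if nd.is_tip or nd.parent is None or b == full:
                        continue
                    info[b] = (
                        nd.height,
                        nd.parent.height,
                        nd.annotations.get("rate", float("nan")),
                    )
                out.append(info)
            self._clade_info = out
        return self._clade_info

    def subset(self, idx: Sequence[int]) -> "TreeTrace":
        idx = list(idx)
        return TreeTrace(
            self.chain_id,
            [self.iterations[i] for i in idx],
            [self.trees[i] for i in idx],
            None if self.density is None else self.density[idx],
            None if self._clade_sets is None
            else [self._clade_sets[i] for i in idx],
            None if self._clade_info is None
            else [self._clade_info[i] for i in idx],
        )

    def truncate(self, n: int) -> "TreeTrace":
        return self.subset(range(min(n, len(self)))) if n < len(self) else self


@dataclass
class ParameterTrace:
    """Continuous logged variables of one chain, aligned to iterations."""

    chain_id: str
    iterations: list[int]
    series: dict[str, np.ndarray]

    def __post_init__(self):
        for name, s in self.series.items():
            if len(s) != len(self.iterations):
                raise ValueError(f"series {name!r} misaligned to iterations")
        if len(self.series) != len(set(self.series)):
            raise ValueError("duplicated series names")

    def __len__(self) -> int:
        return len(self.iterations)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


class Alignment:
    """Taxa x sites nucleotide matrix stored as IUPAC state-set bitmasks."""

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray):
        taxa = tuple(taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in alignment")
        if matrix.ndim != 2 or matrix.shape[0] != len(taxa):
            raise ValueError("matrix must be (n_taxa, n_sites)")
        self.taxa = taxa
        self.matrix = matrix.astype(np.uint8)
        self._row = {lab: i for i, lab in enumerate(taxa)}

    @classmethod
    def from_strings(cls, rows: dict[str, str]) -> "Alignment":
        lens = {len(s) for s in rows.values()}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")
        taxa = list(rows)
        mat = np.zeros((len(taxa), lens.pop() if lens else 0), dtype=np.uint8)
        for i, lab in enumerate(taxa):
            try:
                mat[i] = [IUPAC_MASK[c] for c in rows[lab].upper()]
            except KeyError as e:
                raise ValueError(
                    f"unknown nucleotide code {e.args[0]!r} in row {lab!r}"
                ) from None
        return cls(taxa, mat)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> np.ndarray:
        try:
            return self.matrix[self._row[label]]
        except KeyError:
            raise KeyError(f"taxon {label!r} not in alignment") from None

    def __contains__(self, label: str) -> bool:
        return label in self._row

    def to_fasta(self, path: str) -> None:
        char = {m: c for m, c in MASK_CHAR.items()}
        rev = {v: k for k, v in IUPAC_MASK.items() if k not in "U-?.X"}
        with open(path, "w") as fh:
            for lab in self.taxa:
                seq = "".join(rev.get(int(m), "N") for m in self.row(lab))
                fh.write(f">{lab}\n{seq}\n")

    def __repr__(self) -> str:
        return f"Alignment({len(self.taxa)} taxa x {self.n_sites} sites)"


@dataclass
class TipMetadata:
    """Sampling date (decimal year) and optional discrete location per tip."""

    dates: dict[str, float]
    locations: dict[str, str] = field(default_factory=dict)

    def date(self, label: str) -> float:
        return self.dates[label]


# ---------------------------------------------------------------------------
# burnin / thinning

def apply_burnin(n: int, burnin_frac: float, thin: int = 1) -> list[int]:
    """Indices retained after dropping the first ceil(b*n) samples and
    keeping every thin-th of the rest."""
    if not 0 <= burnin_frac < 1:
        raise ValueError("burnin_frac must be in [0, 1)")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    start = math.ceil(burnin_frac * n)
    return list(range(start, n, thin))


# ---------------------------------------------------------------------------
# tree logs

def _dendropy_to_rooted(
    dtree: dendropy.Tree, taxon_set: TaxonSet
) -> RootedTree:
    mapping: dict = {}
    root = None
    for dnd in dtree.preorder_node_iter():
        label = dnd.taxon.label if dnd.taxon is not None else None
        nd = Node(label)
        nd.length = dnd.edge.length
        for ann in dnd.annotations:
            try:
                nd.annotations[ann.name] = float(ann.value)
            except (TypeError, ValueError):
                warnings.warn(
                    f"skipping malformed branch annotation "
                    f"{ann.name}={ann.value!r}"
                )
        mapping[dnd] = nd
        if dnd.parent_node is None:
            root = nd
        else:
            mapping[dnd.parent_node].add_child(nd)
    tree = RootedTree(taxon_set, root)
    _set_heights_from_lengths(tree)
    return tree


def _set_heights_from_lengths(tree: RootedTree) -> None:
    """Derive node heights from branch lengths; the latest tip is height 0."""
    depth = {tree.root: 0.0}
    for nd in tree.preorder():
        if nd.parent is not None:
            bl = nd.length if nd.length is not None else 1.0
            depth[nd] = depth[nd.parent] + bl
    maxd = max(depth[t] for t in tree.tips())
    for nd in tree.preorder():
        nd.height = maxd - depth[nd]


def read_tree_log(
    path: str,
    format: str = "nexus",
    burnin_frac: float = 0.0,
    thin: int = 1,
    chain_id: Optional[str] = None,
    taxon_set: Optional[TaxonSet] = None,
) -> TreeTrace:
    """Read a posterior tree log into a :class:`TreeTrace`.

    Burnin is a fraction of samples; the first ``ceil(burnin_frac * M)``
    samples are discarded, then every ``thin``-th sample is kept.  NEXUS
    translate tables are resolved; ``[&key=value]`` branch comments become
    float branch annotations (malformed values are skipped with a warning).
    """
    if format not in ("nexus", "newick"):
        raise ValueError("format must be 'nexus' or 'newick'")
    tlist = dendropy.TreeList.get(
        path=path, schema=format, extract_comment_metadata=True
    )
    if len(tlist) == 0:
        raise ValueError(f"no trees found in {path}")

    tip_sets = [
        frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in tlist
    ]
    if len(set(tip_sets)) > 1:
        raise ValueError(f"trees in {path} have differing taxon sets")
    if taxon_set is None:
        taxon_set = TaxonSet(sorted(tip_sets[0]))
    elif frozenset(taxon_set.labels) != tip_sets[0]:
        raise ValueError("trees do not match the supplied TaxonSet")

    keep = apply_burnin(len(tlist), burnin_frac, thin)
    trees, iterations = [], []
    for j, i in enumerate(keep):
        dtree = tlist[i]
        trees.append(_dendropy_to_rooted(dtree, taxon_set))
        it = _iteration_from_label(dtree.label)
        iterations.append(it if it is not None else j)
    if any(b >= a for a, b in zip(iterations[1:], iterations)):
        iterations = list(range(len(trees)))  # labels unusable; renumber
    return TreeTrace(chain_id or path, iterations, trees)


def _iteration_from_label(label: Optional[str]) -> Optional[int]:
    # BEAST names trees STATE_<n>; MrBayes uses rep.<n>/gen.<n>.
    if not label:
        return None
    for sep in ("_", ".", " "):
        tail = label.rsplit(sep, 1)[-1]
        if tail.isdigit():
            return int(tail)
    return None


def write_tree_log(path: str, trace: TreeTrace, annotations: bool = True) -> None:
    """Write a NEXUS tree log with translate table and branch annotations."""
    labels = trace.taxon_set.labels
    translate = {lab: str(i + 1) for i, lab in enumerate(labels)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBegin taxa;\n")
        fh.write(f"\tDimensions ntax={len(labels)};\n\tTaxlabels\n")
        for lab in labels:
            fh.write(f"\t\t{_nexus_quote(lab)}\n")
        fh.write("\t\t;\nEnd;\n\nBegin trees;\n\tTranslate\n")
        fh.write(
            ",\n".join(
                f"\t\t{i + 1} {_nexus_quote(lab)}"
                for i, lab in enumerate(labels)
            )
        )
        fh.write("\n\t\t;\n")
        for it, tree in zip(trace.iterations, trace.trees):
            nwk = tree.newick(annotations=annotations, translate=translate)
            fh.write(f"tree STATE_{it} = [&R] {nwk}\n")
        fh.write("End;\n")


def _nexus_quote(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`+<>-"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(
    s: str, taxon_set: Optional[TaxonSet] = None
) -> RootedTree:
    """Parse a single Newick string (taxon order is sorted labels unless a
    TaxonSet is supplied)."""
    dtree = dendropy.Tree.get(
        data=s, schema="newick", extract_comment_metadata=True
    )
    labels = sorted(lf.taxon.label for lf in dtree.leaf_node_iter())
    if taxon_set is None:
        taxon_set = TaxonSet(labels)
    elif not set(labels) <= set(taxon_set.labels):
        raise ValueError("newick tips not covered by the supplied TaxonSet")
    return _dendropy_to_rooted(dtree, taxon_set)


# ---------------------------------------------------------------------------
# parameter logs

_ITER_NAMES = {"state", "sample", "iteration", "iter", "gen", "generation"}


def read_param_log(
    path: str, burnin_frac: float = 0.0, chain_id: Optional[str] = None
) -> ParameterTrace:
    """Read a tab-delimited parameter log (BEAST/MrBayes style).

    The first column must be the iteration counter (named e.g. "state").
    Remaining columns are returned as float series, post-burnin.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected iteration column plus variables")
    first = str(df.columns[0])
    if first.lower() not in _ITER_NAMES:
        raise ValueError(
            f"{path}: first column {first!r} is not an iteration column "
            f"(expected one of {sorted(_ITER_NAMES)})"
        )
    keep = apply_burnin(len(df), burnin_frac)
    df = df.iloc[keep]
    iterations = [int(v) for v in df.iloc[:, 0]]
    series = {}
    for col in df.columns[1:]:
        try:
            series[str(col)] = pd.to_numeric(df[col], errors="raise").to_numpy(
                dtype=float
            )
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            ) from None
    return ParameterTrace(chain_id or path, iterations, series)


def write_param_log(path: str, trace: ParameterTrace) -> None:
    df = pd.DataFrame({"state": trace.iterations})
    for name, s in trace.series.items():
        df[name] = s
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# alignments and metadata

def read_alignment(path: str, format: str = "fasta") -> Alignment:
    """Read a FASTA or NEXUS alignment into bitmask form.

    IUPAC ambiguity codes expand to state sets; gaps and '?' are treated as
    fully missing ({A,C,G,T}).
    """
    if format not in ("fasta", "nexus"):
        raise ValueError("format must be 'fasta' or 'nexus'")
    aln = AlignIO.read(path, format)
    rows = {}
    for rec in aln:
        if rec.id in rows:
            raise ValueError(f"duplicate taxon label {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq)
    return Alignment.from_strings(rows)


def read_tip_metadata(path: str) -> TipMetadata:
    """Read a TSV with columns taxon, date (decimal year) and optionally
    location."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols or "date" not in cols:
        raise ValueError(f"{path}: need 'taxon' and 'date' columns")
    dates = dict(
        zip(df[cols["taxon"]].astype(str), df[cols["date"]].astype(float))
    )
    locations = {}
    if "location" in cols:
        locations = dict(
            zip(df[cols["taxon"]].astype(str), df[cols["location"]].astype(str))
        )
    return TipMetadata(dates, locations)


def write_tip_metadata(path: str, meta: TipMetadata) -> None:
    rows = []
    for lab, d in meta.dates.items():
        row = {"taxon": lab, "date": d}
        if meta.locations:
            row["location"] = meta.locations.get(lab, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
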