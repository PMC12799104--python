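"""Scalar, clade-level and tree-level MCMC diagnostics.

The toolkit flags tree-sampling problems with the field's conventional
cutoffs: effective sample size (ESS) below 200, potential scale reduction
factor (PSRF, rank-normalized split-R-hat) above 1.1, average standard
deviation of clade frequencies (ASDCF) above 0.01 (0.02 as a lenient
alternative), and per-clade SDCF above 0.1 for "nonconverging" clades.

Tree-level mixing is summarized by a pseudo-ESS (median ESS of
distance-to-reference traces) and a tree PSRF (max PSRF of per-chain
distance traces over pooled reference trees), both using the rooted
Robinson-Foulds metric by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf as _acf

from .clades import CladeTable, clade_frequencies
from .treeio import Alignment, ParameterTrace, TreeTrace

__all__ = [
    "DiagnosticThresholds",
    "DiagnosticsReport",
    "ess",
    "psrf",
    "sdcf",
    "asdcf",
    "clade_ess",
    "tree_pseudo_ess",
    "tree_psrf",
    "diagnose",
]

MAX_LAG = 2000


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Pass/fail cutoffs for the aggregated report."""

    ess_min: float = 200.0
    psrf_max: float = 1.1
    asdcf_max: float = 0.01  # 0.02 as the lenient alternative
    sdcf_nonconverged: float = 0.1

    def __post_init__(self):
        if min(self.ess_min, self.psrf_max, self.asdcf_max,
               self.sdcf_nonconverged) <= 0:
            raise ValueError("thresholds must be positive")
        if self.asdcf_max >= 1:
            raise ValueError("asdcf_max must be < 1")


# ---------------------------------------------------------------------------
# scalar diagnostics

def ess(series: Sequence[float]) -> float:
    """Effective sample size of a single-chain series.

    ESS = N / (1 + 2 * sum of autocorrelations rho(k)), with the sum
    truncated by the initial-positive-sequence rule: stop at the first k
    where rho(2k) + rho(2k+1) <= 0.  Lags are capped at min(N-1, 2000).
    The result is clipped to [1, N]; a zero-variance series yields NaN
    (reported downstream as "undefined", never as a pass).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1-d series of length >= 10")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    if np.ptp(x) == 0:
        warnings.warn("zero-variance series: ESS undefined")
        return float("nan")
    nlags = min(n - 1, MAX_LAG)
    rho = _acf(x, nlags=nlags, fft=True)  # rho[k] is lag k; rho[0] = 1
    cutoff = nlags
    m = 1
    while 2 * m + 1 <= nlags:
        if rho[2 * m] + rho[2 * m + 1] <= 0:
            cutoff = 2 * m - 1
            break
        m += 1
    s = float(np.sum(rho[1 : cutoff + 1]))
    val = n / (1.0 + 2.0 * s)
    return float(np.clip(val, 1.0, n))


def _rank_normalize(chains: list[np.ndarray]) -> list[np.ndarray]:
    pooled = np.concatenate(chains)
    r = stats.rankdata(pooled, method="average")
    z = stats.norm.ppf((r - 3.0 / 8.0) / (len(pooled) + 1.0 / 4.0))
    out, i = [], 0
    for c in chains:
        out.append(z[i : i + len(c)])
        i += len(c)
    return out


def psrf(
    series_per_chain: Sequence[Sequence[float]],
    rank_normalized: bool = True,
) -> float:
    """Rank-normalized split-R-hat across chains.

    Chains are truncated to a common length and split in half; the pooled
    samples are rank-transformed to normal scores (skipped when
    ``rank_normalized=False``); the classical R-hat
    sqrt(((n-1)/n * W + B/n) / W) is computed over the 2m half-chains.
    """
    chains = [np.asarray(c, dtype=float) for c in series_per_chain]
    if len(chains) < 2:
        raise ValueError("PSRF needs at least 2 chains")
    n_min = min(len(c) for c in chains)
    if n_min < 10:
        raise ValueError("each chain needs length >= 10")
    half = n_min // 2
    halves = []
    for c in chains:
        c = c[:n_min]
        halves.append(c[:half])
        halves.append(c[half : 2 * half])
    if rank_normalized:
        halves = _rank_normalize(halves)
    halves_arr = np.asarray(halves)
    w = float(np.mean(np.var(halves_arr, axis=1, ddof=1)))
    if w == 0:
        warnings.warn("zero within-chain variance: PSRF undefined")
        return float("nan")
    b_over_n = float(np.var(np.mean(halves_arr, axis=1), ddof=1))
    n = half
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# clade diagnostics

def sdcf(clade, table: CladeTable) -> float:
    """SD (denominator m-1) of the clade's per-chain frequencies."""
    freqs = table.chain_frequencies(clade)
    if len(freqs) < 2:
        raise ValueError("SDCF needs at least 2 chains")
    return float(np.std(freqs, ddof=1))


def asdcf(table: CladeTable) -> float:
    """Mean SDCF over all clades in the table."""
    if len(table) == 0:
        return 0.0
    return float(np.mean([sdcf(b, table) for b in table.clades]))


def clade_ess(occurrence_trace: Sequence[int]) -> float:
    """ESS of a clade's binary occurrence trace; NaN when the clade is
    absent or present in every sample (skipped, frequency 0 or 1)."""
    x = np.asarray(occurrence_trace, dtype=float)
    if np.ptp(x) == 0:
        return float("nan")
    return ess(x)


# ---------------------------------------------------------------------------
# tree-level diagnostics

MetricLike = Union[str, Callable]


def _rf_series(trace: TreeTrace, ref: frozenset) -> np.ndarray:
    return np.fromiter(
        (len(cs ^ ref) for cs in trace.clade_sets),
        dtype=float,
        count=len(trace),
    )


def tree_pseudo_ess(
    trace: TreeTrace,
    metric: MetricLike = "rf",
    n_refs: int = 5,
    seed: Optional[int] = None,
) -> float:
    """Pseudo-ESS of a tree trace.

    ``n_refs`` reference trees are drawn uniformly (seeded) from the trace;
    for each, the ESS of the rooted-RF-distance-to-reference series is
    computed; the median over references is returned.  NaN when all sampled
    topologies are identical (the distance traces carry no signal).
    """
    if metric != "rf":
        raise ValueError("only the rooted RF metric is supported here")
    if len(trace) < 10:
        raise ValueError("need at least 10 samples")
    if len(set(trace.clade_sets)) == 1:
        return float("nan")
    rng = np.random.default_rng(seed)
    refs = rng.choice(len(trace), size=min(n_refs, len(trace)), replace=False)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in refs:
            d = _rf_series(trace, trace.clade_sets[i])
            vals.append(ess(d) if np.ptp(d) > 0 else float("nan"))
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmedian(vals))


def tree_psrf(
    traces: Sequence[TreeTrace],
    metric: MetricLike = "rf",
    n_refs: int = 5,
    seed: Optional[int] = None,
) -> float:
    """Tree PSRF: max over pooled reference trees of the PSRF of the
    per-chain distance-to-reference traces."""
    if metric != "rf":
        raise ValueError("only the rooted RF metric is supported here")
    if len(traces) < 2:
        raise ValueError("tree PSRF needs at least 2 chains")
    n_min = min(len(tr) for tr in traces)
    traces = [tr.truncate(n_min) for tr in traces]
    pooled = [(ci, si) for ci, tr in enumerate(traces) for si in range(len(tr))]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pooled), size=min(n_refs, len(pooled)), replace=False)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in idx:
            ci, si = pooled[i]
            ref = traces[ci].clade_sets[si]
            series = [_rf_series(tr, ref) for tr in traces]
            vals.append(psrf(series))
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmax(vals))


# ---------------------------------------------------------------------------
# aggregated report

@dataclass
class DiagnosticsReport:
    """Aggregated per-variable / per-clade / per-site / tree diagnostics."""

    thresholds: DiagnosticThresholds
    n_chains: int
    n_samples: int
    variables: Optional[pd.DataFrame] = None
    clade_table: Optional[CladeTable] = field(default=None, repr=False)
    clades: Optional[pd.DataFrame] = None
    clade_variables: Optional[pd.DataFrame] = None
    sites: Optional[pd.DataFrame] = None
    tree: dict = field(default_factory=dict)
    parsimony: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        """True when every defined flag passes (undefined flags do not pass)."""
        return all(v is True for v in self.flags.values())

    def summary(self) -> str:
        def show(v):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return "undefined"
            if isinstance(v, bool):
                return "pass" if v else "FAIL"
            return f"{v:.4g}" if isinstance(v, float) else str(v)

        lines = [
            f"Diagnostics over {self.n_chains} chain(s), "
            f"{self.n_samples} samples each (after truncation)",
            "-" * 60,
        ]
        for k, v in {**self.tree, **self.parsimony}.items():
            lines.append(f"{k:32s} {show(v)}")
        for k, v in self.fractions.items():
            lines.append(f"{k:32s} {show(v)}")
        lines.append("-" * 60)
        for k, v in self.flags.items():
            lines.append(f"{k:32s} {show(v)}")
        lines.append(f"{'overall':32s} {'pass' if self.passed else 'FAIL'}")
        return "\n".join(lines)

    def to_json(self, path: str) -> None:
        def clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return None
            return v

        payload = {
            "thresholds": vars(self.thresholds)
            if not isinstance(self.thresholds, dict)
            else self.thresholds,
            "n_chains": self.n_chains,
            "n_samples": self.n_samples,
            "tree": {k: clean(v) for k, v in self.tree.items()},
            "parsimony": {k: clean(v) for k, v in self.parsimony.items()},
            "fractions": {k: clean(v) for k, v in self.fractions.items()},
            "flags": {k: clean(v) for k, v in self.flags.items()},
            "passed": self.passed,
        }
        payload["thresholds"] = {
            "ess_min": self.thresholds.ess_min,
            "psrf_max": self.thresholds.psrf_max,
            "asdcf_max": self.thresholds.asdcf_max,
            "sdcf_nonconverged": self.thresholds.sdcf_nonconverged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, prefix: str) -> None:
        for name in ("variables", "clades", "clade_variables", "sites"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(
                    f"{prefix}.{name}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.6g",
                )


def _nanmean(values) -> float:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0 or np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def _safe_ess(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(x) < 10 or np.ptp(x) == 0:
            return float("nan")
        return ess(x)


def _safe_psrf(chains: list[np.ndarray]) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(chains) < 2 or min(len(c) for c in chains) < 10:
            return float("nan")
        return psrf(chains)


def _flag(value: float, ok: Callable[[float], bool]) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return bool(ok(value))


def diagnose(
    traces: Sequence[TreeTrace],
    params: Optional[Sequence[ParameterTrace]] = None,
    alignment: Optional[Alignment] = None,
    thresholds: Optional[DiagnosticThresholds] = None,
    n_refs: int = 5,
    seed: int = 0,
    clade_var_min_freq: float = 0.1,
) -> DiagnosticsReport:
    """Compute the full diagnostics report from the available inputs.

    Chains are truncated to the shortest length before any cross-chain
    statistic.  Clade-specific variable diagnostics (node age, branch
    duration, branch rate) are evaluated for clades with pooled frequency
    at least ``clade_var_min_freq``.  A fraction summary counts, among the
    units actually evaluated, those failing the thresholds.
    """
    from .summarize import clade_variable_traces  # local: avoids cycle

    thr = thresholds or DiagnosticThresholds()
    if not traces:
        raise ValueError("need at least one chain of trees")
    n_min = min(len(tr) for tr in traces)
    traces = [tr.truncate(n_min) for tr in traces]
    multi = len(traces) >= 2
    report = DiagnosticsReport(thr, len(traces), n_min)

    # --- continuous variables -------------------------------------------
    if params:
        p_min = min(len(p) for p in params)
        common = set.intersection(*(set(p.series) for p in params))
        rows = []
        for name in sorted(common):
            chains = [p[name][:p_min] for p in params]
            esss = [_safe_ess(c) for c in chains]
            row = {
                "variable": name,
                "ess_mean": _nanmean(esss),
                "psrf": _safe_psrf(chains) if multi else np.nan,
            }
            for p, e in zip(params, esss):
                row[f"ess_{p.chain_id}"] = e
            rows.append(row)
        report.variables = pd.DataFrame(rows)

    # --- clades ----------------------------------------------------------
    table = clade_frequencies(traces)
    report.clade_table = table
    clade_rows = []
    for b in table.clades:
        freqs = table.chain_frequencies(b)
        ess_per_chain = [clade_ess(table.trace(b, i)) for i in range(len(traces))]
        defined = [e for e in ess_per_chain if not np.isnan(e)]
        clade_rows.append(
            {
                "clade": "|".join(table.taxon_set.labels_of(b)),
                "bitset": int(b),
                "size": int(b).bit_count(),
                "pooled_frequency": table.pooled_frequency(b),
                "sdcf": sdcf(b, table) if multi else np.nan,
                "ess_mean": float(np.mean(defined)) if defined else np.nan,
            }
        )
    report.clades = pd.DataFrame(clade_rows)

    asdcf_val = asdcf(table) if multi else float("nan")

    # --- tree-level ------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pseudo = [
            tree_pseudo_ess(tr, n_refs=n_refs, seed=seed + i)
            if len(tr) >= 10
            else float("nan")
            for i, tr in enumerate(traces)
        ]
    from .treespace import topology_classes

    n_classes = len(topology_classes(traces))
    report.tree = {
        "tree_pseudo_ess_mean": _nanmean(pseudo),
        "tree_psrf": tree_psrf(traces, n_refs=n_refs, seed=seed)
        if multi
        else float("nan"),
        "asdcf": asdcf_val,
        "n_topology_classes": n_classes,
    }

    # --- parsimony scores ------------------------------------------------
    if alignment is not None:
        from .parsimony import parsimony_trace, site_score_matrix

        totals = [parsimony_trace(tr, alignment) for tr in traces]
        report.parsimony = {
            "parsimony_ess_mean": _nanmean(
                _safe_ess(t.astype(float)) for t in totals
            ),
            "parsimony_psrf": _safe_psrf([t.astype(float) for t in totals])
            if multi
            else float("nan"),
        }
        mats = [site_score_matrix(tr, alignment) for tr in traces]
        pooled = np.vstack(mats)
        varying = np.where(np.ptp(pooled, axis=0) > 0)[0]
        site_rows = []
        for j in varying:
            chains = [m[:, j].astype(float) for m in mats]
            site_rows.append(
                {
                    "site": int(j),
                    "ess_mean": _nanmean(_safe_ess(c) for c in chains),
                    "psrf": _safe_psrf(chains) if multi else np.nan,
                }
            )
        report.sites = pd.DataFrame(site_rows)

    # --- clade-specific variables ---------------------------------------
    has_rates = any(
        nd.annotations.get("rate") is not None
        for nd in traces[0].trees[0].postorder()
        if nd.parent is not None
    )
    cv_rows = []
    variables = ["node_age", "branch_duration"] + (
        ["branch_rate"] if has_rates else []
    )
    for b in table.clades:
        if table.pooled_frequency(b) < clade_var_min_freq:
            continue
        for var in variables:
            series, masks = clade_variable_traces(traces, b, var)
            esss = [_safe_ess(s) for s in series if len(s)]
            nonempty = [s for s in series if len(s) >= 10]
            cv_rows.append(
                {
                    "clade": "|".join(table.taxon_set.labels_of(b)),
                    "bitset": int(b),
                    "variable": var,
                    "presence": float(
                        np.mean([m.mean() for m in masks])
                    ),
                    "ess_mean": _nanmean(esss),
                    "psrf": _safe_psrf(nonempty)
                    if multi and len(nonempty) >= 2
                    else np.nan,
                }
            )
    report.clade_variables = pd.DataFrame(cv_rows)

    # --- fractions -------------------------------------------------------
    report.fractions = _fractions(report, thr, multi)
    report.flags = _flags(report, thr, multi)
    return report


def _fractions(
    report: DiagnosticsReport, thr: DiagnosticThresholds, multi: bool
) -> dict:
    out = {}
    cl = report.clades
    if cl is not None and len(cl):
        bad = pd.Series(False, index=cl.index)
        if multi:
            bad |= cl["sdcf"] > thr.sdcf_nonconverged
        bad |= cl["ess_mean"].notna() & (cl["ess_mean"] < thr.ess_min)
        out["frac_poor_clades"] = float(bad.mean())
        if multi:
            out["n_nonconverging_clades"] = int(
                (cl["sdcf"] > thr.sdcf_nonconverged).sum()
            )
    if report.sites is not None and len(report.sites):
        st = report.sites
        bad = st["ess_mean"].notna() & (st["ess_mean"] < thr.ess_min)
        if multi:
            bad |= st["psrf"].notna() & (st["psrf"] > thr.psrf_max)
        out["frac_poor_sites"] = float(bad.mean())
    cv = report.clade_variables
    if cv is not None and len(cv):
        br = cv[cv["variable"].isin(["branch_duration", "branch_rate"])]
        if len(br):
            bad = br["ess_mean"].notna() & (br["ess_mean"] < thr.ess_min)
            if multi:
                bad |= br["psrf"].notna() & (br["psrf"] > thr.psrf_max)
            out["frac_poor_branches"] = float(bad.mean())
    return out


def _flags(
    report: DiagnosticsReport, thr: DiagnosticThresholds, multi: bool
) -> dict:
    flags = {}
    if report.variables is not None and len(report.variables):
        e = report.variables["ess_mean"]
        flags["variables_ess_ok"] = bool((e.dropna() >= thr.ess_min).all())
        if multi:
            p = report.variables["psrf"].dropna()
            flags["variables_psrf_ok"] = bool((p <= thr.psrf_max).all())
    t = report.tree
    f = _flag(t.get("tree_pseudo_ess_mean"), lambda v: v >= thr.ess_min)
    if f is not None:
        flags["tree_ess_ok"] = f
    if multi:
        f = _flag(t.get("tree_psrf"), lambda v: v <= thr.psrf_max)
        if f is None:
            # undefined between-chain tree variance: trivially converged when
            # every chain sampled one and the same topology, else not a pass
            f = t.get("n_topology_classes") == 1
        flags["tree_psrf_ok"] = f
        f = _flag(t.get("asdcf"), lambda v: v <= thr.asdcf_max)
        flags["asdcf_ok"] = f if f is not None else False
        if report.clades is not None and len(report.clades):
            flags["no_nonconverging_clades"] = bool(
                (report.clades["sdcf"].dropna() <= thr.sdcf_nonconverged).all()
            )
    pa = report.parsimony
    if pa:
        f = _flag(pa.get("parsimony_ess_mean"), lambda v: v >= thr.ess_min)
        if f is not None:
            flags["parsimony_ess_ok"] = f
        if multi:
            f = _flag(pa.get("parsimony_psrf"), lambda v: v <= thr.psrf_max)
            if f is not None:
                flags["parsimony_psrf_ok"] = f
    return flags
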