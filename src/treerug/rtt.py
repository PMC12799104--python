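"""Root-to-tip (RTT) regression: temporal-signal screening of a tree with
substitution-scaled branch lengths.

The tree is rooted at the point (any position on any branch) minimizing the
residual sum of squares of the OLS regression of root-to-tip genetic
distance on sampling date.  On each branch the RSS is an exactly quadratic
function of root position, so the global optimum is found analytically per
branch.  The slope estimates the clock rate (substitutions/site/year), the
x-intercept the origin date, and internally studentized residuals flag
suspect sequences (metadata errors, assembly problems).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from ._tree import Node, RootedTree
from .treeio import TipMetadata

__all__ = ["RttFit", "rtt_fit", "rtt_outliers"]


@dataclass
class RttFit:
    branch_clade: tuple[str, ...]  # tips below the optimal root branch
    branch_index: int
    position: float  # distance from the branch's child end, in subs/site
    branch_length: float
    slope: float
    intercept: float
    x_intercept: float
    r_squared: float
    rss: float
    tips: list[str]
    dates: np.ndarray
    distances: np.ndarray  # root-to-tip at the optimal rooting
    residuals: pd.Series

    def summary(self) -> str:
        return (
            f"RTT fit: rate {self.slope:.4g} subs/site/yr, "
            f"origin {self.x_intercept:.2f}, R^2 {self.r_squared:.3f}, "
            f"root on branch above {{{','.join(self.branch_clade[:4])}"
            f"{',...' if len(self.branch_clade) > 4 else ''}}} "
            f"at {self.position:.4g}/{self.branch_length:.4g}"
        )


def rtt_fit(
    tree: RootedTree, dates: Union[dict, TipMetadata]
) -> RttFit:
    """Optimal RMS-residual rooting and clock regression.

    Branch lengths must be in substitutions/site (the raw parsed lengths);
    every tip must have a decimal-year sampling date with at least two
    distinct values.
    """
    if isinstance(dates, TipMetadata):
        dates = dates.dates
    tips = [nd.label for nd in tree.tips()]
    missing = [t for t in tips if t not in dates]
    if missing:
        raise ValueError(f"tips without dates: {missing[:5]}")
    x = np.array([dates[t] for t in tips], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all dates equal: no temporal signal possible")

    nodes = [nd for nd in tree.postorder()]
    for nd in nodes:
        if nd.parent is not None:
            if nd.length is None:
                raise ValueError("tree has no branch lengths")
            if nd.length < 0:
                raise ValueError("negative branch length")

    # undirected adjacency for per-branch distance sweeps
    adj: dict[Node, list[tuple[Node, float]]] = {nd: [] for nd in nodes}
    for nd in nodes:
        if nd.parent is not None:
            adj[nd].append((nd.parent, nd.length))
            adj[nd.parent].append((nd, nd.length))
    tip_index = {nd: i for i, nd in enumerate(tree.tips())}

    def dists_from(src: Node) -> np.ndarray:
        d = np.full(len(tips), np.nan)
        stack = [(src, None, 0.0)]
        while stack:
            cur, prev, acc = stack.pop()
            if cur in tip_index:
                d[tip_index[cur]] = acc
            for nb, ln in adj[cur]:
                if nb is not prev:
                    stack.append((nb, cur, acc + ln))
        return d

    bits = tree.node_bitsets()
    ts = tree.taxon_set
    xbar = x.mean()
    xc = x - xbar
    sxx = float(xc @ xc)

    candidates = [nd for nd in tree.postorder() if nd.parent is not None]
    best = None  # (rss, branch_index, t, node, dc, s)
    for bi, nd in enumerate(candidates):
        L = nd.length
        dc = dists_from(nd)
        below = np.array(
            [bool(bits[nd] >> ts.index[t] & 1) for t in tips]
        )
        s = np.where(below, 1.0, -1.0)
        dcc = dc - dc.mean()
        sc = s - s.mean()
        s_dcdc = float(dcc @ dcc)
        s_dcs = float(dcc @ sc)
        s_ss = float(sc @ sc)
        s_xdc = float(xc @ dcc)
        s_xs = float(xc @ sc)
        # RSS(t) = A t^2 + 2 B t + C on [0, L]
        A = s_ss - s_xs**2 / sxx
        B = s_dcs - s_xdc * s_xs / sxx
        C = s_dcdc - s_xdc**2 / sxx
        cand_t = [0.0, L]
        if A > 1e-30:
            tstar = -B / A
            if 0.0 < tstar < L:
                cand_t.append(tstar)
        for t in cand_t:
            rss = A * t * t + 2 * B * t + C
            if best is None or rss < best[0] - 1e-15:
                best = (rss, bi, t, nd, dc, s)

    rss, bi, t, nd, dc, s = best
    rss = max(rss, 0.0)
    y = dc + t * s
    yc = y - y.mean()
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * xbar)
    syy = float(yc @ yc)
    r2 = 1.0 - rss / syy if syy > 0 else 1.0
    resid = y - (intercept + slope * x)
    return RttFit(
        branch_clade=ts.labels_of(bits[nd]),
        branch_index=bi,
        position=float(t),
        branch_length=float(nd.length),
        slope=slope,
        intercept=intercept,
        x_intercept=float(-intercept / slope) if slope != 0 else float("nan"),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        rss=float(rss),
        tips=tips,
        dates=x,
        distances=y,
        residuals=pd.Series(resid, index=tips),
    )


def rtt_outliers(fit: RttFit, cutoff: float = 3.0) -> list[str]:
    """Tips whose internally studentized RTT residual exceeds ``cutoff``."""
    n = len(fit.tips)
    if n < 4:
        raise ValueError("outlier detection needs at least 4 tips")
    x = fit.dates
    xc = x - x.mean()
    sxx = float(xc @ xc)
    h = 1.0 / n + xc**2 / sxx
    mse = fit.rss / (n - 2)
    if mse <= 0:
        return []
    with np.errstate(divide="ignore", invalid="ignore"):
        r = fit.residuals.to_numpy() / np.sqrt(mse * (1.0 - h))
    return [t for t, v in zip(fit.tips, r) if np.isfinite(v) and abs(v) > cutoff]
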