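# Methods

This note documents the statistical procedures implemented in `treerug`,
their assumptions, the defaults that matter, what the synthetic generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Objects and conventions

All diagnostics operate on rooted, dated, binary trees over a fixed ordered
`TaxonSet`. Node heights are times before the latest sampled tip (height 0);
tip dates are decimal years. A *clade* is the tip set below a non-root
internal node, encoded as an integer bitset in `TaxonSet` order; singletons
and the full taxon set are excluded everywhere (they are present in every
rooted tree and would dilute ASDCF without carrying information). Topology
identity is clade-set equality; the rooted Robinson–Foulds (RF) distance is
the size of the symmetric difference of the two clade sets — clades, not
unrooted splits, because the trees are rooted time trees and root placement
is part of the inference.

Burnin is a fraction of samples (CLI default 0.1; the worked examples use 0
because the generator emits post-burnin-like chains), applied before
thinning as `drop ceil(b*M), keep every thin-th`. Chains are truncated to a
common length before any cross-chain statistic.

## Single-chain ESS

`ess` implements the classical spectral estimator
`N / (1 + 2 Σ ρ̂(k))` with the sum truncated by the initial-positive-sequence
rule — stop at the first k where `ρ̂(2k) + ρ̂(2k+1) ≤ 0` — with lags capped at
`min(N−1, 2000)`, and the result clipped to `[1, N]`. Autocorrelations come
from `statsmodels` (FFT). This is the family of estimator used by the
standard MCMC trace tools; we validate it against analytic limits rather
than bit-matching any one implementation: for i.i.d. input ESS ≈ N, for an
AR(1) process with ρ = 0.9 the integrated autocorrelation time is
(1+ρ)/(1−ρ) = 19 so ESS ≈ N/19, and for a sticky two-state chain with stay
probability p the lag-1 autocorrelation is 2p−1. A zero-variance series has
no defined ESS; it is reported as *undefined*, never as a pass.

## PSRF (rank-normalized split-R̂)

`psrf` truncates chains to a common length, splits each in half,
rank-transforms the pooled samples to normal scores
(`z = Φ⁻¹((r − 3/8)/(S + 1/4))`), and computes the classical
`R̂ = sqrt(((n−1)/n·W + B/n)/W)` over the 2m half-chains. Rank
normalization makes the statistic invariant under monotone (hence affine)
transformations and robust to heavy tails. `rank_normalized=False` gives the
original-scale split-R̂. When every chain is constant the within-chain
variance is zero and the value is undefined. Note that chains that are
*constant within but different between* (exact two-peak sticking) drive W
toward the tie-broken rank floor and produce astronomically large R̂ values;
these are honest "diverged" signals, not numerical errors.

## Clade diagnostics

Each observed nontrivial clade yields a per-chain binary occurrence trace.
SDCF is the sample SD (denominator m−1) of the m per-chain frequencies;
ASDCF is the unweighted mean over *all* observed clades (no low-frequency
filter by default — a minimum-frequency filter is an explicit option).
Clade ESS applies `ess` to the occurrence trace and is skipped (undefined)
for clades at pooled frequency 0 or 1; such clades still contribute to
ASDCF. Clade-specific continuous variables — node age (MRCA height), branch
duration (parent height − MRCA height), branch rate (the `rate` annotation
on the MRCA's subtending branch) — are extracted from the samples that
contain the clade; ESS is computed per chain on these present-only series
and PSRF on the per-chain series truncated to the shortest, with the
presence fraction reported. This present-only convention is a documented
choice; the alternative (imputing absent samples) would mix topology
uncertainty into parameter traces.

## Tree-level diagnostics

*Tree pseudo-ESS*: draw `n_refs = 5` reference trees uniformly (seeded) from
the chain, compute the ESS of each RF-distance-to-reference series, report
the median. *Tree PSRF*: draw references from the pooled chains, apply
`psrf` to the per-chain distance series, report the maximum. The
distance-to-reference construction is a documented stand-in for the several
non-equivalent tree-ESS constructions in the literature; its analytic
behavior (≈N for i.i.d. topology draws, matching the peak-indicator ESS for
two-point mixtures, >1.1 for stuck chains, ≈1 for well-mixed ones) is what
the tests pin down. When every chain samples one and the same topology, the
tree PSRF is undefined but topological convergence is trivially satisfied;
the aggregated report passes the flag in exactly that case (single pooled
topology class) and reports the statistic itself as undefined.

## Parsimony diagnostics

`fitch_score` runs the set-based Fitch pass over IUPAC state-set bitmasks
(vectorized across sites); gaps and `?` are fully missing `{A,C,G,T}`, not a
fifth state. The per-tree total feeds `ess`/`psrf` as the parsimony-score
diagnostic; per-site scores give per-site diagnostics (sites whose score
never varies are not evaluable and are excluded from the denominator of the
poorly-sampled-site fraction). `branch_mutation_counts` resolves a single
most-parsimonious reconstruction top-down from the Fitch sets — a node takes
its parent's state when compatible, else its smallest compatible state
("acctran" policy, deterministic; a seeded random resolution is available) —
and counts per-branch state changes, which sum exactly to the total score.
Discrete-trait dispersal events use the same machinery on the single
location character, with the root resolved to the lexicographically smallest
member of its state set; the pairwise event matrix is directed under this
deterministic resolution, and its entries sum to the total. Sequence screens
report disjoint-state difference sites (overlapping ambiguity is not a
difference), missingness overall and by codon position, and mean per-site
Hamming profiles against a reference set with windowed densities (default:
thirds of the alignment).

## Valley geometry

`relocate_tip` prunes a tip and regrafts it on a destination branch
(identified by the clade below it, over taxa excluding the tip), placing the
new attachment at the midpoint of the feasible height interval
`[max(tip height, child height), parent height]` — the move is topological;
any feasible height serves the diagnostics, and infeasible moves (tip older
than the entire destination branch) raise. `nni_path_tip_relocation`
decomposes the same move into k rooted NNIs by walking the unique edge path
(edges adjacent when sharing a node) between the old and new attachment;
k is the number of internal nodes strictly between them. Each NNI changes
exactly 2 rooted clades, so RF = 2k and the RF/2 lower bound proves the path
minimal. `rspr_distance_small` is an exact bidirectional BFS over topology
classes (≤ 10 tips) used as a test oracle — large-instance rSPR is out of
scope.

## MDS landscapes

`classical_mds` is the Torgerson construction: double-center the squared
distance matrix, eigendecompose, scale the top eigenvectors by the square
roots of their (non-negativized) eigenvalues. It is exact on Euclidean
input; on RF matrices negative eigenvalues are truncated to zero and the
residual stress is reported. Subsampling for large traces is an even
deterministic stride per chain (no RNG, reproducible). Density overlays
return plot-ready data (50×50 cell-mean heatmap by default, top-density
fraction default 1%, or density-as-z scatter); rendering is a thin optional
matplotlib layer in the CLI so the core stays render-agnostic.

## Summaries, pruning, attribution

The MCC tree is the *sampled* tree maximizing the sum of log pooled clade
posterior probabilities, ties broken by first occurrence; node annotations
carry clade support and the mean/median/95% central interval of the clade's
MRCA height over the trees containing it (sampled heights are kept on the
tree itself — annotation conventions differ across tools and this one is
explicit and tested). `prune_tips` removes tips from every sampled tree,
suppresses degree-2 nodes, and sets a merged branch's rate to the
duration-weighted mean of its segments (preserving expected substitutions on
the merged path); heights of untouched nodes are unchanged exactly.

`rank_problematic_tips` formalizes the semi-manual attribution workflow:
score(tip) = max SDCF over clades containing the tip of size ≤
max(3, ⌈0.1 n⌉) (small clades localize the attachment). A wobbling tip
always ties with its attachment-partner tips at the top score, so tips
contesting the maximum are separated by a leave-one-out re-diagnosis — the
drop in ASDCF when that tip alone is pruned (computed directly on restricted
clade sets, no tree surgery) — which is large for the tip causing the
discordance and small for bystanders. Remaining ties fall back to the PSRF
of the pendant branch duration (and rate when annotated), then to label
order for determinism.

## Root-to-tip regression

`rtt_fit` searches every branch for the root position minimizing the OLS
residual sum of squares of root-to-tip distance (substitutions/site) on
sampling date. Along a branch, every tip distance is linear in the root
position with slope ±1, so the RSS is exactly quadratic and is minimized
analytically per branch (interior critical point and both endpoints); the
global minimum is taken, ties resolved by branch enumeration order. Outliers
are tips with |internally studentized residual| > 3 by default — the
threshold is this package's choice, standard for regression screening.
Under strict-clock simulations (rate 2·10⁻³ subs/site/yr, 40 tips sampled
over 10 years, 15 kb genome, Ne = 10 yr — chosen as a mumps-like condition)
the slope is recovered within ±20% in every replicate with mean absolute
error ≈ 4%, and the true root branch is found in ≈ 94% of replicates; in
the remainder the optimum lands on an adjacent deep branch, an inherent
ambiguity of RMS rooting when finite-sites noise exceeds the RSS contrast
between neighboring deep branches.

## Synthetic studies

The generator emulates the *phenomenology* of rugged phylodynamic
posteriors, not the inference: a heterochronous constant-Ne coalescent base
tree (msprime; lineages merge at rate C(k,2)/Ne), 1–3 designated wobbling
tips each alternating between two attachment branches separated by k
internal nodes (presets use k = 3–6, within the empirically observed 3–10
range), and per chain an independent sticky Markov chain over the 2^m peak
combinations: each spec flips sides with probability 1−p per step
(p = 1.0 stuck, 0.98 rare commutes, 0.9 frequent). Default init-peak
assignment spreads sides so every spec starts on both sides across chains.
Peaks are exact topology classes — intermediate topologies are never
emitted, mirroring the unsampled valleys of real posteriors — and the
pseudo log-density is the sum of per-spec peak offsets plus Gaussian noise
(sd 0.25), a diagnostics fixture rather than a model likelihood. Attachment
branches are restricted to small local clades (≤ max(3, ⌈0.1 n⌉) taxa),
emulating problematic sequences wobbling among alternative local
placements. Alignments are simulated on a chosen peak topology (JC or HKY,
Poisson mutations along branches, default 1000 sites at 10⁻³
subs/site/yr) with a full truth log of every mutation's branch, enabling
exact validation of the parsimony mapping. One root seed drives
per-component spawned RNG streams; identical seeds give bit-identical
studies.

What passing tests on these fixtures do **not** show: behavior under
within-peak topological jitter, model misspecification, recombination, or
rate variation across branches; the generator's peaks are cleaner than real
posteriors (within-chain variance of clade variables can be exactly zero,
which is why several within-chain diagnostics report *undefined* on fully
stuck synthetic chains — real chains would show small jitter instead).

## Problem sizes and numerical choices

Tests and the acceptance battery run on desk-scale problems chosen to make
each check sharp: 12-tip caterpillars for valley geometry, ≤ 7 tips for
exhaustive parsimony oracles (4^(n−1) assignments), ≤ 10 tips for exact
rSPR BFS, 20–50-taxon studies with 120–500 samples per chain for
diagnostics and ranking, 50 replicates for RTT recovery. Heights compare at
1e-9 (I/O round trips) and 1e-12 (pruning invariance); MDS exactness at
1e-9; NaN propagation is explicit everywhere ("undefined", never silently
pass/fail); all randomness flows from user-supplied seeds.

## Known limitations

No approximate large-n rSPR; no CCD/HIPSTR-style summary trees; no
stationarity tests (Geweke etc.); no likelihood-based ancestral
reconstruction or weighted Sankoff costs; RTT assumes a single strict clock
and flags but does not model rate outliers; the generator does not simulate
the inference process itself (no proposal/acceptance dynamics), only its
sampled output.
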