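# treerug

**Diagnosing and dissecting tree-sampling problems in Bayesian phylodynamic
MCMC output.**

Bayesian phylodynamic analyses (BEAST-style) sample time-calibrated pathogen
phylogenies by MCMC. Continuous parameters usually mix well, but the *tree*
often does not: the posterior over topologies can be rugged, with multiple
peaks separated by valleys that standard tree moves rarely cross. Chains then
stick to different peaks for billions of iterations, and conclusions that
depend on topology — clade ages, branch rates, dispersal histories — silently
inherit the problem. Remarkably often, the ruggedness is caused by just a few
*wobbling* sequences, each alternating between two attachment positions
several nodes apart.

`treerug` is a toolkit for practitioners of phylodynamics who want to detect
that situation, localize its cause, and fix it:

- **Detect** — tree-aware MCMC diagnostics: per-variable ESS and
  rank-normalized split-R̂ (PSRF), clade-occurrence ESS and SDCF/ASDCF,
  tree pseudo-ESS and tree PSRF on rooted Robinson–Foulds (RF) distance
  traces, and model-independent parsimony-score diagnostics
  (alignment-wise, per-site, per-branch via Fitch mutation mapping).
- **Visualize** — classical MDS embeddings of posterior tree space with
  posterior-density overlays (heatmap / top-density fraction / 3-D scatter),
  and explicit valley geometry: a tip relocation across k intermediate
  nodes has rooted RF distance 2k yet is a single SPR move (a k-step NNI
  path), which is why RF-wide valleys can be one rearrangement wide.
- **Dissect & fix** — problematic-tip ranking from clade-level diagnostics
  with leave-one-out re-diagnosis, pruning of wobbling tips from every
  posterior sample with exact re-diagnosis, MCC summary trees, parsimony
  dispersal-event counts, sequence screens (difference sites, missingness),
  and root-to-tip (RTT) regression with analytic RMS-residual rooting.
- **Test** — a synthetic multimodal-posterior generator (heterochronous
  coalescent base trees, designated wobbling tips with tunable peak
  stickiness, sequence simulation with a ground-truth mutation log) so the
  entire workflow is verifiable at desk scale.

## The statistics at the core

For chains $c = 1,\dots,m$, each clade $K$ (set of tips below an internal
node of the rooted tree) yields a binary occurrence trace with per-chain
frequency $\hat f_c(K)$. Then

- $\mathrm{SDCF}(K) = \mathrm{sd}_{c}\,\hat f_c(K)$ (denominator $m-1$), and
  $\mathrm{ASDCF} = \mathrm{mean}_K\, \mathrm{SDCF}(K)$ over all observed
  nontrivial clades;
- $\mathrm{ESS} = N / (1 + 2\sum_k \hat\rho(k))$ with Geyer
  initial-positive-sequence truncation; clade ESS applies this to occurrence
  traces, tree pseudo-ESS to RF-distance-to-reference traces (median over
  5 seeded reference trees);
- PSRF is the rank-normalized split-$\hat R$; tree PSRF applies it to
  per-chain RF distance traces and takes the maximum over pooled references;
- the parsimony score of a sampled tree is the Fitch minimum mutation count
  of the alignment on that topology — a model-independent per-tree statistic
  whose ESS/PSRF diagnose topology mixing directly.

Conventional cutoffs flag trouble: ESS < 200, PSRF > 1.1, ASDCF > 0.01
(0.02 as a lenient alternative), per-clade SDCF > 0.1.

## Worked example

Simulate a rugged posterior — one tip wobbling between two attachments six
nodes apart, four chains stuck pairwise on the two peaks — then diagnose,
attribute, prune, and re-diagnose:

```bash
treerug simulate --preset lassa-like --seed 1 --out study
# wrote 4 chains of 300 samples to study (wobblers: t03)

treerug diagnose --burnin-frac 0 \
    --trees study/chain1.trees --trees study/chain2.trees \
    --trees study/chain3.trees --trees study/chain4.trees \
    --alignment study/alignment.fasta --out report
```

```
Diagnostics over 4 chain(s), 300 samples each (after truncation)
------------------------------------------------------------
tree_pseudo_ess_mean             undefined
tree_psrf                        6.471e+15
asdcf                            0.2038
n_topology_classes               2
parsimony_ess_mean               undefined
parsimony_psrf                   6.471e+15
frac_poor_clades                 0.3529
n_nonconverging_clades           12
frac_poor_sites                  1
frac_poor_branches               0
------------------------------------------------------------
tree_psrf_ok                     FAIL
asdcf_ok                         FAIL
no_nonconverging_clades          FAIL
parsimony_psrf_ok                FAIL
overall                          FAIL
```

ASDCF (0.20) is far above the 0.01 cutoff, the tree and parsimony-score
PSRFs diverge (each chain's distance/score trace is constant but chains
disagree — within-chain variance is essentially zero), twelve clades are
nonconverging (SDCF > 0.1), and the pooled samples split into exactly two
topology classes. Within-chain mixing diagnostics are *undefined* (each
chain never moves), reported as such rather than passed or failed.

```bash
treerug rank-tips --burnin-frac 0 --trees study/chain1.trees \
    --trees study/chain2.trees --trees study/chain3.trees \
    --trees study/chain4.trees --out rank.tsv
# top-ranked tips: t03 (0.577), t05 (0.577), t26 (0.577); full table in rank.tsv
```

The true wobbler `t03` ranks first (its attachment partners tie on maximal
SDCF, 0.577 = sd of frequencies {1,1,0,0}, but the leave-one-out ASDCF drop
separates the causer). Prune it and re-diagnose:

```bash
treerug prune --burnin-frac 0 --tips t03 --trees study/chain*.trees --out pruned
treerug diagnose --burnin-frac 0 --trees pruned/chain*.trees --out report2
```

```
tree_psrf                        undefined
asdcf                            0
n_topology_classes               1
...
overall                          pass
```

After pruning a single sequence the landscape is unimodal: one topology
class across all chains, ASDCF exactly 0, every flag passes. The same
workflow is available as library calls (`treerug.diagnose`,
`treerug.rank_problematic_tips`, `treerug.prune_tips`, …), and
`treerug mds --trees ... --log ... --out m` writes the tree-space embedding
with the posterior density attached for landscape plots.

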