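# Methods

`fcnet` implements the graph-theoretic group analysis commonly applied to
resting-state functional brain networks, together with a synthetic cohort
generator rich enough to exercise every stage of the chain. This note
records the model, the defaults and why they are set where they are, the
numerical conventions, and what the synthetic validation does and does not
establish.

## The analysis chain

For each subject, the n×n functional connectivity matrix holds the pairwise
Pearson correlations r_ij between region time courses, with the diagonal
fixed to 0 and two-sided p-values from the exact t transform
t = r√((T−2)/(1−r²)) on T−2 degrees of freedom. Binary undirected networks
are formed at a connection density d by keeping the round(d·n(n−1)/2)
strongest edges. Ranking is by signed r by default (strong positive
coupling defines an edge; after global-signal-style preprocessing negative
correlations exist and are conventionally not treated as edges); ranking by
|r| is available (`ranking="absolute"`). Rounding is half-away-from-zero,
and ties at the cutoff break by ascending (i, j) order — ties have measure
zero on real data, but the convention makes runs bit-reproducible.

Because any single density is arbitrary, metrics are computed over an
inclusive density grid (default 24.5%–30% in steps of 0.5%, 12 points) and
summarized per subject by the trapezoidal area under the metric-vs-density
curve (AUC). The endpoints can also be derived from the data:

* **minimum density** — the smallest grid density at which every subject's
  network is a single connected component (scanning the grid upward;
  implemented by finding, per subject, the shortest top-k edge prefix that
  connects the graph via union-find);
* **maximum density** — per subject, Benjamini–Hochberg at q=0.05 over the
  n(n−1)/2 correlation p-values gives a significant-edge fraction; the
  *minimum* of these fractions across subjects is the largest density at
  which every retained edge is FDR-significant for *every* subject, and it
  is floored to the step grid. The minimum is the only aggregation that
  gives a cohort-wide guarantee; alternatives (mean, median) would leave
  some subjects with non-significant retained edges.

### Metrics

Four metrics, on each sweep network:

* nodal degree k_i (row sums);
* nodal clustering C_i = 2T_i/(k_i(k_i−1)) with T_i the triangles through
  node i; degree-<2 nodes contribute 0; the global C is the mean over all
  nodes *including* those zeros;
* characteristic path length L, the mean BFS distance over unordered node
  pairs. Disconnected graphs get the reachable-pair mean plus a warning
  rather than an error — the sweep's minimum-density rule exists precisely
  so this does not occur in a production run, but exploratory densities
  should not crash;
* nodal local efficiency, the Latora–Marchiori form: with S the neighbors
  of the node and distances measured inside the subgraph induced by S
  (paths may not leave it), E_loc = (1/(|S|(|S|−1))) Σ_{j≠h∈S} 1/d_S(j,h),
  with 1/∞ = 0. The harmonic form is used because neighbor subgraphs are
  routinely disconnected at these densities, where the alternative reading
  "1/mean(d)" is undefined; that variant is available
  (`variant="inverse_mean"`) for sensitivity analysis.

All-pairs distances use a dense matrix-power BFS (float32 BLAS matmuls):
with thousands of ≤90-node graphs per run, per-call overhead dominates
sparse-graph routines, and one matmul per diameter increment is faster and
exactly equivalent. Equivalence with networkx is asserted over random
graphs in the test suite.

### Null normalization

C_nor = C/⟨C_rand⟩ and L_nor = L/⟨L_rand⟩ over an ensemble (default 1000)
of Maslov–Sneppen degree-preserving double-edge-swap randomizations of the
same network (default budget 10·|E| attempted swaps; failed proposals are
skipped and counted). Degree-matched nulls are the field standard behind
these ratios; an Erdős–Rényi null with matched n and |E| only is available
(`null_model="erdos_renyi"`). Connectivity is *not* enforced on ensemble
members — resampling until connected would bias the null — so disconnected
members contribute their reachable-pair L and are tallied in the log.
Normalization uses the ensemble mean (not median).

### Inference

Group differences in AUC are tested with a label permutation test:
statistic = difference of group means, each repetition reassigning the
pooled subjects into groups of the original sizes (default 10 000
repetitions), two-tailed p by the add-one estimator
p = (1+#{|null| ≥ |obs|})/(1+n_perm), which cannot return 0 and matches the
percentile-position definition up to 1/(n_perm+1). An exact variant
enumerates all C(n, n_a) assignments when the pooled sample is small.
Nodal p-values are corrected with Benjamini–Hochberg at q=0.05, one
90-node family per metric (degree and local efficiency corrected
separately; whether they should form one 180-test family is a judgment
call — the per-metric family is the default and the q level is
configurable). The four global metrics form their own small BH family.

At nodes showing significant group differences, Pearson correlations
between the nodal AUC and the behavioral score are computed within each
group, reported uncorrected at p<0.05 with a BH-corrected flag alongside —
brain–behavior correlations at realistic effect sizes rarely survive
correction, and both views are reported.

Seeds split per stage from a root seed by a counter scheme
(`default_rng([seed, stage, unit])`), so any stage can be rerun
independently and whole runs are byte-reproducible from the config.

## The synthetic cohort generator

The generator emulates a two-group developmental cohort (trained mental
arithmetic vs control): 90 regions × 175 timepoints (180 scans minus 5
discarded), 72 subjects per group. Region signals are i.i.d.
multivariate-normal timepoints with a block correlation structure:
rho_within (default 0.35) inside modules, rho_between (default 0.10)
across, unit diagonal; the default partition is an 8-region planted module
plus ~10-region modules. The trained group's planted module is raised by
delta (default 0.25). Each subject additionally gets an own planted-module
level shifted by N(0, delta_sd²) (default 0.12, both groups, clipped to
[rho_between, 0.97]) — the between-subject connectivity variability that
real cohorts always show. Validity (symmetric, unit-diagonal, positive
definite) is checked by Cholesky factorization, and violations are
rejected with the offending minimum eigenvalue.

Behavioral scores match the reference math-test summaries (trained
56.97 ± 8.01, control 48.16 ± 8.30). For trained subjects, the score
couples to the subject's *realized* (sample) planted-module mean
correlation, z-scored across the trained group, with slope
behavior_coupling (default 2.16 score units, i.e. a population
brain–behavior correlation of coupling/SD ≈ 0.27); noise is scaled so the
marginal SD still matches. The cohort-level z-scoring lives in
`generate_cohort`; `sample_subject` in isolation takes an explicit
`(mean, sd)` reference or omits the coupling term with a warning.

**Why delta_sd exists.** With a single population matrix per group, every
trained subject's planted edges sit at the same correlation, far above the
density cutoff; the only between-subject variation in realized
connectivity is sampling noise of r̂ (≈0.05/√pairs), which never changes
which edges survive thresholding. A score coupled to that variation is
therefore uncorrelated with every thresholded network metric — measured
r ≈ 0 across seeds. Subject-level heterogeneity in connectivity is the
minimal mechanism that makes the planted brain–behavior correlation
expressible in the networks, and it is also what real cohorts look like.
With delta_sd = 0 the generator reduces exactly to the homogeneous model.

### What the generator does not emulate

No temporal autocorrelation, hemodynamic filtering, motion artifacts,
physiological noise, or spatial structure beyond the block pattern; scores
are continuous reals rather than integerized composite norms (downstream
Pearson correlation is scale-free). Consequently, passing tests establish
that the *pipeline* recovers planted statistical structure with calibrated
error rates — not that any particular claim about real imaging cohorts
holds. In particular the i.i.d.-timepoint choice is deliberate: Pearson r
is the only statistic consumed downstream, and the FDR-based
maximum-density rule relies on the exact t p-values of r, which
autocorrelation would invalidate.

## Validation problem sizes

The statistical validation runs at reduced sizes chosen to keep the full
suite in the minutes range while leaving the estimates well resolved:

* type-I calibration: 200 null cohorts (delta=0, no coupling), 30 regions,
  20 subjects/group, 1000 permutations; the per-node rejection rate at
  α=0.05 must fall in [0.02, 0.09] (observed ≈ 0.05);
* planted recovery: 30 regions (8 planted), 72 subjects/group,
  rho_within=0.3, rho_between=0.1, delta=0.30, delta_sd=0.15,
  coupling=0.85·8.01 — sized by power analysis for ≥90% per-node power —
  with the pipeline required to flag ≥6/8 planted and ≤2/22 other nodes
  and to recover the trained-only behavior correlation in ≥80% of ten
  seeds;
* null-model self-consistency: a degree-matched random input must give
  C_nor, L_nor within 3 SD-based tolerances of 1 (the input is a single
  draw from the null family, so the single-draw ensemble SD, not the SE of
  the ensemble mean, sets the tolerance).

`scripts/acceptance.py` reruns the recovery conditions end to end
(ensemble 30, 10 000 permutations) plus the two t statistics recomputable
from the reference group summaries, and writes all values as JSON.

## Known limitations

* Exact numerical parity with any specific historical analysis cannot be
  claimed where conventions were unstated (edge-budget rounding, tie
  breaks, the aggregation behind the FDR density bound, handling of
  disconnected neighbor subgraphs); every such choice is documented above
  and exposed in configuration.
* The permutation statistic is the difference of group means; a
  t-statistic variant would weight variances differently (not currently
  implemented).
* Rewiring mixes by attempted-swap budget, not by a mixing-time
  diagnostic; 10·|E| is a standard heuristic and configurable.
* The generator's behavior model is linear with Gaussian noise; nonlinear
  brain–behavior relationships are out of scope.
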