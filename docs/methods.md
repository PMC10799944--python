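# Methods

## Overview

`covnet` implements group-level structural covariance network (SCN) analysis
of regional cortical morphometry. The pipeline, per morphometric measure
(cortical thickness, CT, in mm; cortical surface area, CSA, in mm²) and per
timepoint:

1. validate per-subject regional tables on the 68-region Desikan–Killiany
   parcellation and regress out subject covariates (age, sex, CUDIT, AUDIT,
   age at first cannabis use) by per-region OLS on the pooled two-group
   sample;
2. correlate residuals between every pair of regions across subjects
   (Pearson), Fisher-transform, and binarize the 68×68 association matrix at
   proportional thresholds 6–40% in 1% steps (35 nested unweighted,
   undirected graphs);
3. compute integration measures (characteristic path length `L`, global and
   nodal efficiency), segregation measures (clustering coefficient `C`, local
   efficiency), betweenness centrality and degree; normalize `C` and `L` by
   degree-preserving random references to get `gamma = C/C_rand`,
   `lambda = L/L_rand` and small-worldness `sigma = gamma/lambda`;
4. condense every metric's threshold dependence into its trapezoidal area
   under the curve (AUC) over the density grid, and test group AUC
   differences with a subject-relabelling permutation scheme plus
   Benjamini–Hochberg FDR within families.

## Covariate adjustment

Each region is fit by OLS on an intercept plus the selected covariates,
pooling both groups of a timepoint in a single fit, and replaced by its
residuals. Pooling preserves between-group differences in the residual
*covariance* — the object of inference — while removing covariate-driven
variance common to both groups. Residuals are label-independent, so the
permutation test never refits the model. A covariate with missing entries in
the selected subjects (typically onset age, undefined for controls) is
dropped with a warning rather than imputed; with ~20 subjects per group, any
imputation would distort the covariance being analyzed, so missing regional
values are fatal. A rank-deficient design is fatal and names the collinear
columns.

## Network construction

Association strength is the Pearson correlation of residuals across
subjects; the Fisher transform `z = atanh(r)` is applied for scale
comparability. Because binarization keeps the top-k edges and `atanh` is
strictly monotone, thresholding on `r` or `z` yields identical graphs (a
tested invariant). Edge counts at density `d` are `round(d·n(n−1)/2)` with
half-away-from-zero rounding (at `n = 68`: 137 edges at 6%, 911 at 40%).
Edges are ranked by **signed** value — the usual SCN convention at
thresholds ≤ 40%, where negative correlations never reach the cut; an
`absolute` option ranks by |z| for sensitivity analyses. Ties at the cut are
broken by lexicographic node-pair order, making every graph, and hence every
permutation replicate, deterministic. Graphs below the minimum connected
density are kept (with a warning) rather than discarded, since the fixed
6–40% grid is applied to all groups; `min_connected_density` reports where
full connectivity is first reached.

## Graph measures

Conventions follow the Brain Connectivity Toolbox:

* clustering of a node with degree < 2 is 0;
* characteristic path length averages shortest-path distances over ordered
  pairs within the largest connected component when the graph is
  disconnected (logged);
* nodal efficiency `E_i = mean_j 1/d(i,j)` treats unreachable pairs as 0 and
  needs no disconnection special-casing; global efficiency is its node mean;
* local efficiency of a node is the global efficiency of the subgraph
  induced by its neighbours (0 for degree < 2);
* betweenness is raw (unnormalized) Brandes centrality with each unordered
  pair counted once — the permutation test is scale-invariant, so
  normalization would not change any p-value.

All shortest-path work runs on bitset adjacency rows (one `uint64` word per
64 nodes) with level-synchronous BFS, compiled with numba. This is what
makes the permutation studies (millions of 68-node graph evaluations)
tractable on one CPU; the kernels are validated against brute-force
Floyd–Warshall/path-enumeration oracles to 1e-12 on random small graphs and
against networkx.

### Random references and small-worldness

`gamma` and `lambda` are normalized by the mean over `n_null`
degree-preserving Maslov–Sneppen randomizations (double-edge swaps that
reject self-loops and multi-edges). The single-graph API
(`normalized_global_metrics`) defaults to 100 references with 10 swap
attempts per edge. Inside a density sweep the references are maintained
*incrementally*: each reference starts as a fully rewired copy of the
sparsest graph; at every subsequent density it receives the same newly
added edges — with a degree-preserving repair when an edge already exists in
the rewired reference — followed by swap attempts proportional to the new
edges. The reference degree sequence then matches the observed graph exactly
at every density (a tested invariant), total randomization effort stays
proportional to the final edge count, and the resulting gamma/lambda curves
agree with independent full re-randomization to within a few percent.
Degenerate normalizations (a zero null mean, possible only in edgeless or
triangle-free corners) fall back to a ratio of 1 inside the sweep and are a
hard error in the single-graph API.

## AUC and permutation inference

The AUC of a metric curve over the 0.06:0.01:0.40 grid is its trapezoidal
integral (a constant curve `c` integrates to `0.34·c`). The group statistic
is `AUC(A) − AUC(B)`; its null distribution comes from pooling all subjects
and drawing random repartitions into the original group sizes, recomputing
the entire pipeline per repartition. Whole subjects are reassigned, never
individual regions — required for the covariance null to be exchangeable.
All metrics share one partition stream. P-values are two-tailed with the
add-one estimator `p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`, which cannot
return 0 (a deliberate departure from the literal "fraction exceeded" rule).
FDR families: the five global metrics together per measure/timepoint, and
each nodal metric across the 68 regions.

Two exactness properties are engineered in rather than approximate:
identical groups give exactly zero differences, and swapping the group
arguments negates every difference and preserves every p-value bit for bit.
Reference-randomization seeds are derived from a checksum of each group's
data matrix (not from call order), and permutation partitions are drawn in a
canonical group orientation with a sign flip at the end.

## Synthetic cohorts

The generator emulates the post-FreeSurfer stage of a longitudinal
case–control study: two groups (default 20 vs 22 subjects) at baseline and a
3-year follow-up (ages advanced 3.25 years), with age, sex, CUDIT, AUDIT and
onset-age covariates drawn at realistic scales (onset age 16.2 ± 2.4 years
in the user group, undefined for controls). Regional values follow a
block-modular one-factor-per-module model over 68 regions in 4 contiguous
modules:

    value(s, j) = mu_j + sd_j · (beta·x_s + L_g·f_{s,m(j)} + noise_sd·eps_{s,j})

with standard-normal factors and noise, CT-like profiles (means 2.0–3.0 mm,
sd 0.15 mm) or CSA-like profiles (log-spaced means 300–4000 mm², sd 10% of
the mean), and small age/sex effects (−0.3 and +0.2 sd units). The implied
population correlation is `L²/(L² + noise_sd²)` within a module and exactly
0 across modules (`ground_truth_correlation` returns it analytically).

Group differences are injected **only** through the loadings — the
covariance topology — never through regional means, mirroring a study design
in which regional mean comparisons are null while network topology differs.
Defaults encode a baseline-different / follow-up-convergent pattern:
loadings 0.8 vs 0.3 at BL, 0.5 vs 0.5 at FU, noise_sd 1 (so within-module
r ≈ 0.39 vs 0.08 at BL). With equal loadings the groups are exchangeable
draws from one distribution — an exact null for calibrating the permutation
test. Generation is a pure function of the seed.

What the generator does *not* emulate: anatomically realistic (non-block)
covariance, distance- or hemisphere-dependent correlation structure,
longitudinal within-subject dependence between BL and FU, heavy-tailed
morphometric noise, and site/scanner effects. Passing calibration and power
checks on these cohorts therefore validates the statistical machinery, not
the anatomical interpretation of any real dataset.

## Problem sizes and numerical choices

The repeated simulation studies (type-I calibration over 200 null cohorts;
power over 50 effect cohorts) use 200 permutations per test and a
scaled-down normalization — one sweep-maintained reference per graph, 3
swap attempts per edge, global metrics only — chosen so the full studies
run in minutes on a single core. Calibration is insensitive to the number
of references (any fixed rule is exchangeable under the null), and measured
power for local efficiency is unchanged between 1 and 20 references. The
end-to-end study emulation (`scripts/acceptance.py`) uses 1000 permutations
with 5 references and 5 swaps per edge, including all nodal metrics.

Under the default alternative (loadings 0.8 vs 0.3) the local-efficiency
AUC difference is detected essentially always, while small-worldness is
detected only in a minority of runs: the block-factor alternative raises
normalized clustering and normalized path length together, and their ratio
cancels most of the contrast. This is a property of the sigma statistic
under this class of alternatives (confirmed with up to 20 references, so it
is not Monte-Carlo normalization noise), worth knowing when interpreting
sigma findings.

Other numerical choices: correlations are clipped to [−1, 1] against
rounding before the Fisher transform; |r| = 1 off the diagonal is fatal
(infinite z indicates duplicated regions); zero-variance regions are fatal
and named; component ties for the largest-component path length break
toward the component containing the smallest node index; `n_perm < 100` is
rejected (p-resolution); all RNG streams (cohort generation, partitions,
rewiring) derive from explicit seeds and reproduce bit-identically.

## Limitations

* Inference is cross-sectional per timepoint; no paired BL↔FU test is
  provided.
* Weighted, directed and individual-subject (jackknife) covariance networks
  are out of scope, as are modularity/rich-club statistics.
* The incremental reference scheme trades exact independence of references
  across densities for speed; its residual correlation slightly increases
  the Monte-Carlo variance of gamma/lambda AUCs at small `n_null` (it can
  be raised in `PipelineConfig` when precision matters more than runtime).
* With ~20 subjects per group, sample correlation matrices are rank-deficient
  (rank < 68); proportional thresholding and the permutation null handle
  this correctly, but individual edge weights are noisy and should not be
  interpreted in isolation.
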