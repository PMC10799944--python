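# covnet

Structural covariance network (SCN) analysis of regional cortical
morphometry: from per-subject regional cortical thickness (CT) and cortical
surface area (CSA) tables to group-level covariance graphs, graph-theoretic
integration/segregation measures across a density sweep, and permutation
inference on their between-group differences.

## The problem

In a group of subjects, the across-subject correlation of a morphometric
measure between two cortical regions ("structural covariance") reflects
coordinated maturation and connectivity. Treating the 68 regions of the
Desikan–Killiany parcellation as nodes and strong interregional
correlations as edges yields a group-level brain network whose topology —
small-worldness, efficiency, clustering — can differ between clinical
groups even when no single region's mean differs. `covnet` is for
researchers who have region-averaged FreeSurfer output (not raw MRI) for
two groups, possibly at multiple timepoints, and want a reproducible,
statistically calibrated network comparison.

## The method

Per group, with covariates (age, sex, clinical scores) regressed out of
each region on the pooled sample:

* `R[i,j]` = Pearson correlation of regions *i, j* across subjects, Fisher
  transformed to `z = atanh(r)`;
* the 68×68 matrix is binarized at proportional thresholds
  `d = 0.06, 0.07, …, 0.40` by keeping the `round(d·2278)` strongest edges,
  giving 35 nested unweighted graphs;
* per graph: clustering coefficient `C`, characteristic path length `L`,
  global/local/nodal efficiency, degree, betweenness; `γ = C/C_rand` and
  `λ = L/L_rand` against degree-preserving Maslov–Sneppen references, and
  small-worldness `σ = γ/λ`;
* each metric's curve over the grid is condensed to its trapezoidal AUC,
  and the group difference `AUC(A) − AUC(B)` is tested by pooling subjects
  and rebuilding both networks under random relabellings
  (`p = (1 + #{|null| ≥ |obs|})/(1 + n_perm)`, two-tailed), with
  Benjamini–Hochberg FDR within metric families.

A synthetic-cohort generator with a block-modular factor model (known
analytic correlation structure, group differences injected through
covariance topology only) makes the whole pipeline testable end to end;
see `docs/methods.md` for the model and its limits.

## Worked example

```python
from covnet import (SyntheticSpec, generate_cohort, residualize_pair,
                    permutation_test, PipelineConfig)
from covnet.simulate import GROUP_A, GROUP_B

cohort = generate_cohort(SyntheticSpec(seed=42))      # 20 HCU vs 22 controls
ra, rb = residualize_pair(cohort.table(GROUP_A, "BL"),
                          cohort.table(GROUP_B, "BL"),
                          cohort.covariates["BL"])
cfg = PipelineConfig(n_null=2, swaps_per_edge=5, include_nodal=True)
ptr = permutation_test(ra, rb, n_perm=100, seed=7, config=cfg)
for name in ("small_worldness", "local_efficiency", "global_efficiency"):
    r = ptr.result(name)
    print(f"{name}: obs={r.observed_diff:+.4f} p={r.p:.3f} q={r.q:.3f}")
```

prints

```
small_worldness: obs=+0.1786 p=0.109 q=0.109
local_efficiency: obs=+0.0391 p=0.010 q=0.050
global_efficiency: obs=-0.0133 p=0.020 q=0.050
```

The baseline cohort was generated with stronger covariance modules in the
first group (loadings 0.8 vs 0.3), so its networks are more segregated:
the local-efficiency AUC is higher in group A (+0.039, permutation
p = 0.010, FDR q = 0.050 across the five global metrics), global efficiency
is slightly lower, and small-worldness trends higher without reaching
significance at 100 permutations. Regional mean t-tests on the same cohort
flag nothing — the signal is purely in the covariance topology.

The same pipeline is scriptable from the shell:

```bash
covnet simulate --seed 3 --out cohort/
covnet permtest cohort/CT_HCU_BL.csv cohort/CT_control_BL.csv \
    --covariates cohort/covariates_BL.csv --out results.csv --n-perm 1000
```

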