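"""Group inference on covariance networks: permutation AUC tests and t-tests.

The group-difference statistic for every network measure is the difference
in its area under the metric-vs-density curve, AUC(A) − AUC(B).  Its null
distribution is built by subject relabelling: all subjects are pooled and
repeatedly repartitioned at random into two pseudo-groups of the original
sizes; the full pipeline — interregional correlation, density sweep, graph
metrics, AUC — is recomputed for every repartition.  Whole subjects (their
complete regional vectors) are reassigned, never individual regions, which
is what makes the covariance structure exchangeable under the null.

P-values are two-tailed with the add-one estimator
p = (1 + #{|null| ≥ |observed|}) / (1 + n_perm), which cannot return an
exact zero.  Benjamini–Hochberg FDR is applied within families: the five
global metrics together, and each nodal metric across regions.

Covariates must be regressed out once on the pooled sample *before* testing
(see ``morpho.residualize_pair``): residuals do not depend on group labels,
so permutations never refit the covariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .build import density_grid, edges_at_density
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    data_seed,
)
from .morpho import MorphometryTable
from . import _kernels as K

__all__ = [
    "PipelineConfig",
    "PermutationResult",
    "PermutationTestResult",
    "observed_auc_difference",
    "permutation_test",
    "fdr_correct",
    "regional_ttests",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the network pipeline shared by observed and permuted runs.

    ``n_null`` degree-preserving references (with ``swaps_per_edge``
    double-edge swaps per edge) normalize clustering and path length;
    ``include_nodal`` switches the three nodal metric families on;
    ``absolute`` ranks edges by |association| instead of signed value.
    """

    density_min: float = 0.06
    density_max: float = 0.40
    density_step: float = 0.01
    n_null: int = 20
    swaps_per_edge: int = 10
    include_nodal: bool = True
    absolute: bool = False
    keep_density_nulls: bool = False

    def grid(self) -> np.ndarray:
        return density_grid(self.density_min, self.density_max, self.density_step)


@dataclass(frozen=True)
class PermutationResult:
    """Permutation test outcome for one metric (global or one region)."""

    metric: str
    scope: str
    observed_diff: float
    null_diffs: np.ndarray
    p: float
    q: float
    n_perm: int


@dataclass(frozen=True)
class PermutationTestResult:
    """Full set of permutation results plus the curves behind them."""

    results: tuple[PermutationResult, ...]
    densities: np.ndarray
    n_perm: int
    seed: int
    config: PipelineConfig
    observed_curve_diffs: dict = field(default_factory=dict)
    null_curve_diffs: dict = field(default_factory=dict)

    def result(self, metric: str, scope: str = "global") -> PermutationResult:
        for r in self.results:
            if r.metric == metric and r.scope == scope:
                return r
        raise KeyError(f"no result for metric={metric!r}, scope={scope!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": r.metric,
                    "scope": r.scope,
                    "observed_diff": r.observed_diff,
                    "p": r.p,
                    "q": r.q,
                    "significant": r.q < 0.05,
                }
                for r in self.results
            ]
        )


def _curves_for_values(values: np.ndarray, cfg: PipelineConfig, base_seed: int):
    """Global (and nodal) metric curves for one group's residualized values."""
    n_regions = values.shape[1]
    stds = values.std(axis=0)
    if np.any(stds == 0):
        raise ValueError(
            f"region index {int(np.argmax(stds == 0))} has zero variance; "
            "correlations are undefined"
        )
    corr = np.corrcoef(values, rowvar=False)
    iu = np.triu_indices(n_regions, 1)
    v = corr[iu]
    if cfg.absolute:
        v = np.abs(v)
    order = np.argsort(-v, kind="stable")
    oi = iu[0][order].astype(np.int64)
    oj = iu[1][order].astype(np.int64)
    grid = cfg.grid()
    ks = np.array(
        [edges_at_density(n_regions, d) for d in grid], dtype=np.int64
    )
    raw, norm, deg_c, eff_c, btw_c = K.ensemble_curves(
        oi,
        oj,
        ks,
        n_regions,
        cfg.n_null,
        cfg.swaps_per_edge,
        data_seed(values, base_seed),
        cfg.include_nodal,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = norm[0] / norm[1]
    global_curves = {
        "normalized_path_length": norm[1],
        "global_efficiency": raw[2],
        "normalized_clustering": norm[0],
        "local_efficiency": raw[3],
        "small_worldness": sigma,
        "clustering": raw[0],
        "path_length": raw[1],
    }
    nodal_curves = (
        {"degree": deg_c, "nodal_efficiency": eff_c, "betweenness": btw_c}
        if cfg.include_nodal
        else None
    )
    return grid, global_curves, nodal_curves


def _auc_difference(
    values_a: np.ndarray,
    values_b: np.ndarray,
    cfg: PipelineConfig,
    base_seed: int,
):
    """AUC(a) − AUC(b) per metric; also returns the global curve differences."""
    grid, ga, na = _curves_for_values(values_a, cfg, base_seed)
    _, gb, nb = _curves_for_values(values_b, cfg, base_seed)
    global_diffs = np.array(
        [
            np.trapezoid(ga[name], grid) - np.trapezoid(gb[name], grid)
            for name in GLOBAL_METRIC_NAMES
        ]
    )
    curve_diffs = {name: ga[name] - gb[name] for name in GLOBAL_METRIC_NAMES}
    nodal_diffs = None
    if cfg.include_nodal:
        nodal_diffs = np.empty((len(NODAL_METRIC_NAMES), values_a.shape[1]))
        for k, name in enumerate(NODAL_METRIC_NAMES):
            nodal_diffs[k] = np.trapezoid(
                na[name], grid, axis=0
            ) - np.trapezoid(nb[name], grid, axis=0)
    return global_diffs, nodal_diffs, curve_diffs


def _check_pair(a: MorphometryTable, b: MorphometryTable) -> None:
    if a.atlas.region_ids != b.atlas.region_ids:
        raise ValueError("groups use different atlases")
    if a.measure != b.measure or a.timepoint != b.timepoint:
        raise ValueError("groups must share measure and timepoint")
    if set(a.subjects) & set(b.subjects):
        raise ValueError("duplicate subject ids across groups")
    if not (a.residualized and b.residualized):
        warnings.warn(
            "groups are not covariate-residualized; correlations will include "
            "covariate-driven variance",
            stacklevel=3,
        )


def observed_auc_difference(
    table_a: MorphometryTable,
    table_b: MorphometryTable,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC(group a) − AUC(group b) for every global and nodal metric."""
    cfg = config or PipelineConfig()
    _check_pair(table_a, table_b)
    gd, nd, _ = _auc_difference(table_a.values, table_b.values, cfg, seed)
    rows = [
        {"metric": name, "scope": "global", "observed_diff": float(gd[i])}
        for i, name in enumerate(GLOBAL_METRIC_NAMES)
    ]
    if nd is not None:
        labels = table_a.atlas.region_ids
        for k, name in enumerate(NODAL_METRIC_NAMES):
            rows.extend(
                {
                    "metric": name,
                    "scope": labels[r],
                    "observed_diff": float(nd[k, r]),
                }
                for r in range(len(labels))
            )
    return pd.DataFrame(rows)


def fdr_correct(p_values: Sequence[float], family: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one family of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError(f"empty p-value family {family!r}")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def permutation_test(
    table_a: MorphometryTable,
    table_b: MorphometryTable,
    n_perm: int = 1000,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> PermutationTestResult:
    """Subject-relabelling permutation test of all AUC differences.

    One stream of random partitions is shared by every metric.  Internally
    the two groups are processed in a canonical order (lexicographic by
    subject ids) and the sign flipped back afterwards, so exchanging the
    argument order negates every difference and leaves every p-value
    unchanged.
    """
    cfg = config or PipelineConfig()
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a p-value resolution")
    _check_pair(table_a, table_b)
    flip = table_a.subjects > table_b.subjects  # canonical orientation
    first, second = (table_b, table_a) if flip else (table_a, table_b)
    sign = -1.0 if flip else 1.0

    obs_gd, obs_nd, obs_curves = _auc_difference(
        first.values, second.values, cfg, seed
    )
    n1 = first.n_subjects
    pooled = np.vstack([first.values, second.values])
    n = pooled.shape[0]
    n_nodal = (
        len(NODAL_METRIC_NAMES) * pooled.shape[1] if cfg.include_nodal else 0
    )
    n_stats = len(GLOBAL_METRIC_NAMES) + n_nodal
    observed = np.concatenate(
        [obs_gd, obs_nd.ravel() if obs_nd is not None else np.empty(0)]
    )
    null = np.empty((n_stats, n_perm))
    null_curves = (
        {name: np.empty((n_perm, len(cfg.grid()))) for name in GLOBAL_METRIC_NAMES}
        if cfg.keep_density_nulls
        else {}
    )
    rng = np.random.default_rng(seed)
    for b in range(n_perm):
        perm = rng.permutation(n)
        gd, nd, curves = _auc_difference(
            pooled[perm[:n1]], pooled[perm[n1:]], cfg, seed
        )
        null[: len(GLOBAL_METRIC_NAMES), b] = gd
        if nd is not None:
            null[len(GLOBAL_METRIC_NAMES):, b] = nd.ravel()
        for name in null_curves:
            null_curves[name][b] = curves[name]

    exceed = (np.abs(null) >= np.abs(observed)[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + n_perm)

    labels = table_a.atlas.region_ids
    metrics = [(name, "global") for name in GLOBAL_METRIC_NAMES]
    if cfg.include_nodal:
        for name in NODAL_METRIC_NAMES:
            metrics.extend((name, lab) for lab in labels)

    # FDR families: the global metrics together; each nodal metric across regions
    q = np.empty(n_stats)
    ng = len(GLOBAL_METRIC_NAMES)
    q[:ng] = fdr_correct(p[:ng], family="global")
    if cfg.include_nodal:
        nreg = len(labels)
        for k, name in enumerate(NODAL_METRIC_NAMES):
            lo = ng + k * nreg
            q[lo : lo + nreg] = fdr_correct(p[lo : lo + nreg], family=name)

    results = tuple(
        PermutationResult(
            metric=metric,
            scope=scope,
            observed_diff=float(sign * observed[i]),
            null_diffs=sign * null[i],
            p=float(p[i]),
            q=float(q[i]),
            n_perm=n_perm,
        )
        for i, (metric, scope) in enumerate(metrics)
    )
    return PermutationTestResult(
        results=results,
        densities=cfg.grid(),
        n_perm=n_perm,
        seed=seed,
        config=cfg,
        observed_curve_diffs={k: sign * v for k, v in obs_curves.items()},
        null_curve_diffs={k: sign * v for k, v in null_curves.items()},
    )


def regional_ttests(
    table_a: MorphometryTable, table_b: MorphometryTable
) -> pd.DataFrame:
    """Pooled-variance two-sample t-test per region, BH-corrected across regions.

    The supplementary check that regional means (as opposed to covariance
    topology) do not differ between groups.
    """
    if table_a.atlas.region_ids != table_b.atlas.region_ids:
        raise ValueError("groups use different atlases")
    if table_a.measure != table_b.measure:
        raise ValueError("groups hold different measures")
    a, b = table_a.values, table_b.values
    na, nb = a.shape[0], b.shape[0]
    if min(na, nb) < 2:
        raise ValueError("each group needs at least 2 subjects")
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1))
    if np.any(pooled_var == 0):
        region = table_a.atlas.region_ids[int(np.argmax(pooled_var == 0))]
        raise ValueError(f"zero pooled variance in region {region!r}")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    q = fdr_correct(p, family="regions")
    return pd.DataFrame(
        {
            "region": list(table_a.atlas.region_ids),
            "t": t,
            "df": na + nb - 2,
            "p": p,
            "q": q,
            "significant": q < 0.05,
        }
    )
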