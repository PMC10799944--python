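"""Synthetic two-group, two-timepoint cohorts with known covariance structure.

The generator emulates the post-FreeSurfer stage of a longitudinal
case–control morphometry study: per-subject regional values for two groups
(default n = 20 heavy cannabis users, n = 22 controls) at baseline (BL) and
a 3-year follow-up (FU), plus age/sex/CUDIT/AUDIT/onset-age covariates.

Regional values follow a modular one-factor-per-module model.  Regions are
split into contiguous covariance modules; for subject ``s`` and region ``j``
in module ``m`` of group ``g``:

    value = mu_j + sd_j * (beta' x_s + L_g * f_sm + noise_sd * eps_sj)

with standard-normal module factors ``f`` and noise ``eps``, per-region
profile mean ``mu_j`` and scale ``sd_j``, covariate effects ``beta`` (age,
sex) and a group loading ``L_g`` in [0, 1).  The implied population
correlation is ``L_g^2 / (L_g^2 + noise_sd^2)`` within a module and exactly
0 across modules, so downstream network inference has an analytic ground
truth.  Group differences are injected purely through the loadings — the
covariance topology — and never through regional means, isolating exactly
what covariance-network inference is supposed to detect (group mean
differences are a separate, routine t-test question).

With equal loadings the two groups are exchangeable draws from one
distribution, giving an exact null for calibrating the permutation test.
Generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import synthetic_atlas
from .build import AssociationMatrix
from .morpho import CovariateTable, MorphometryTable

__all__ = ["SyntheticSpec", "Cohort", "generate_cohort", "ground_truth_correlation"]

GROUP_A = "HCU"
GROUP_B = "control"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 20 vs 22 subjects, 68 regions in 4
    covariance modules, group covariance differing at baseline
    (loadings 0.8 vs 0.3) and converged at follow-up (0.5 vs 0.5).
    """

    n_group_a: int = 20
    n_group_b: int = 22
    n_regions: int = 68
    n_modules: int = 4
    within_loading_a: float = 0.8
    within_loading_b: float = 0.3
    within_loading_a_fu: float | None = 0.5
    within_loading_b_fu: float | None = 0.5
    noise_sd: float = 1.0
    measure: str = "CT"
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": -0.3, "sex": 0.2}
    )
    timepoints: tuple[str, ...] = ("BL", "FU")
    followup_years: float = 3.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_loading_a",
            "within_loading_b",
            "within_loading_a_fu",
            "within_loading_b_fu",
        ):
            val = getattr(self, name)
            if val is not None and not (0 <= val < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {val}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (1 <= self.n_modules <= self.n_regions):
            raise ValueError("n_modules must lie in [1, n_regions]")
        if min(self.n_group_a, self.n_group_b) < 3:
            raise ValueError("groups need at least 3 subjects")
        if self.measure not in ("CT", "CSA"):
            raise ValueError("measure must be 'CT' or 'CSA'")

    def loading(self, group: str, timepoint: str) -> float:
        bl = self.within_loading_a if group == GROUP_A else self.within_loading_b
        if timepoint == "BL":
            return bl
        fu = (
            self.within_loading_a_fu
            if group == GROUP_A
            else self.within_loading_b_fu
        )
        return bl if fu is None else fu

    def module_of(self) -> np.ndarray:
        """Contiguous module index per region (remainder in the last block)."""
        block = self.n_regions // self.n_modules
        mod = np.minimum(np.arange(self.n_regions) // block, self.n_modules - 1)
        return mod

    def profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-region (mean, sd) profile for the chosen measure.

        CT-like: means spread over 2.0–3.0 mm with sd 0.15 mm; CSA-like:
        log-spaced means over 300–4000 mm² with sd at 10% of the mean.
        """
        if self.measure == "CT":
            means = np.linspace(2.0, 3.0, self.n_regions)
            sds = np.full(self.n_regions, 0.15)
        else:
            means = np.geomspace(300.0, 4000.0, self.n_regions)
            sds = 0.1 * means
        return means, sds


@dataclass(frozen=True)
class Cohort:
    """Generated morphometry tables keyed by (group, timepoint) + covariates."""

    tables: dict[tuple[str, str], MorphometryTable]
    covariates: dict[str, CovariateTable]
    spec: SyntheticSpec

    def table(self, group: str, timepoint: str) -> MorphometryTable:
        return self.tables[(group, timepoint)]


def _draw_covariates(rng: np.random.Generator, spec: SyntheticSpec) -> pd.DataFrame:
    """Subject covariates emulating a matched case–control cohort of young adults."""
    na, nb = spec.n_group_a, spec.n_group_b
    n = na + nb
    subjects = [f"hcu{i + 1:02d}" for i in range(na)] + [
        f"ctl{i + 1:02d}" for i in range(nb)
    ]
    group = np.array([GROUP_A] * na + [GROUP_B] * nb)
    age = rng.normal(21.5, 2.5, n)
    sex = rng.integers(0, 2, n).astype(float)
    cudit = np.where(
        group == GROUP_A,
        np.clip(rng.normal(17.0, 5.0, n), 0, 40),
        np.clip(rng.normal(1.0, 1.0, n), 0, 40),
    )
    audit = np.where(
        group == GROUP_A,
        np.clip(rng.normal(7.0, 4.0, n), 0, 40),
        np.clip(rng.normal(4.0, 3.0, n), 0, 40),
    )
    onset = np.where(group == GROUP_A, rng.normal(16.2, 2.38, n), np.nan)
    return pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": sex,
            "cudit": cudit,
            "audit": audit,
            "onset_age": onset,
        },
        index=pd.Index(subjects, name="subject"),
    )


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw a full synthetic cohort; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    atlas = synthetic_atlas(spec.n_regions)
    means, sds = spec.profile()
    mod = spec.module_of()
    base = _draw_covariates(rng, spec)

    covariates: dict[str, CovariateTable] = {}
    tables: dict[tuple[str, str], MorphometryTable] = {}
    for tp_idx, tp in enumerate(spec.timepoints):
        cov = base.copy()
        cov["age"] = base["age"] + tp_idx * spec.followup_years
        covariates[tp] = CovariateTable(data=cov)
        # standardized covariate scores with fixed (population) centring so
        # that generation stays a pure function of the seed
        zage = (cov["age"].to_numpy() - 21.5) / 2.5
        zsex = cov["sex"].to_numpy() - 0.5
        zscores = {"age": zage, "sex": zsex}
        for g in (GROUP_A, GROUP_B):
            sel = cov["group"].to_numpy() == g
            n_g = int(sel.sum())
            load = spec.loading(g, tp)
            factors = rng.standard_normal((n_g, spec.n_modules))
            eps = rng.standard_normal((n_g, spec.n_regions))
            signal = load * factors[:, mod] + spec.noise_sd * eps
            covterm = np.zeros((n_g, spec.n_regions))
            for name, beta in spec.covariate_effects.items():
                covterm += beta * zscores[name][sel][:, None]
            values = means[None, :] + sds[None, :] * (covterm + signal)
            tables[(g, tp)] = MorphometryTable(
                values=values,
                subjects=tuple(cov.index[sel]),
                atlas=atlas,
                measure=spec.measure,
                group=g,
                timepoint=tp,
            )
    return Cohort(tables=tables, covariates=covariates, spec=spec)


def ground_truth_correlation(
    spec: SyntheticSpec, group: str = GROUP_A, timepoint: str = "BL"
) -> AssociationMatrix:
    """Analytic population correlation matrix of covariate-adjusted values.

    Within a module r = L²/(L² + noise_sd²); exactly 0 across modules
    (independent factors).  The diagonal is stored as 0, matching the
    association-matrix convention.
    """
    load = spec.loading(group, timepoint)
    r_within = load**2 / (load**2 + spec.noise_sd**2)
    mod = spec.module_of()
    same = mod[:, None] == mod[None, :]
    values = np.where(same, r_within, 0.0)
    np.fill_diagonal(values, 0.0)
    atlas = synthetic_atlas(spec.n_regions)
    return AssociationMatrix(
        values=values,
        scale="pearson_r",
        labels=atlas.region_ids,
        measure=spec.measure,
        group=group,
        timepoint=timepoint,
    )
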