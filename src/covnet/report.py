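"""Human-readable outputs: difference bands, significance tables, plots.

The difference band mirrors the standard presentation of permutation-based
network comparisons: the observed between-group difference of a metric at
each density, against the empirical 2.5–97.5% envelope of the permutation
null, with densities flagged where the observed curve escapes the envelope.
Cortical-surface rendering is out of scope; regional results are emitted as
labelled tidy tables for external plotting tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .inference import PermutationResult, PermutationTestResult

__all__ = ["DifferenceBand", "difference_band", "significance_table", "plot_difference_band"]


@dataclass(frozen=True)
class DifferenceBand:
    """Observed per-density difference with its permutation null envelope."""

    metric: str
    densities: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    flagged: np.ndarray  # densities where observed falls outside the envelope

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.densities,
                "observed": self.observed,
                "null_mean": self.null_mean,
                "lower": self.lower,
                "upper": self.upper,
                "outside": self.flagged,
            }
        )


def difference_band(
    ptr: PermutationTestResult, metric: str, coverage: float = 0.95
) -> DifferenceBand:
    """Empirical null envelope of a global metric's difference curve.

    Requires the test to have been run with ``keep_density_nulls=True``.
    """
    if metric not in ptr.null_curve_diffs:
        raise ValueError(
            f"no per-density null distribution stored for {metric!r}; rerun "
            "the permutation test with keep_density_nulls=True"
        )
    nulls = ptr.null_curve_diffs[metric]  # (n_perm, n_densities)
    observed = ptr.observed_curve_diffs[metric]
    alpha = (1.0 - coverage) / 2.0
    lower = np.nanquantile(nulls, alpha, axis=0)
    upper = np.nanquantile(nulls, 1.0 - alpha, axis=0)
    return DifferenceBand(
        metric=metric,
        densities=ptr.densities,
        observed=observed,
        null_mean=np.nanmean(nulls, axis=0),
        lower=lower,
        upper=upper,
        flagged=(observed < lower) | (observed > upper),
    )


def significance_table(
    results: Iterable[PermutationResult],
    measure: str = "",
    timepoint: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy table of permutation results with FDR significance flags."""
    rows = [
        {
            "measure": measure,
            "timepoint": timepoint,
            "metric": r.metric,
            "scope": r.scope,
            "observed_diff": r.observed_diff,
            "p": r.p,
            "q": r.q,
            "significant": r.q < alpha,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def plot_difference_band(band: DifferenceBand, path: str | Path) -> Path:
    """Static difference-band figure (observed curve vs null envelope)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        band.densities, band.lower, band.upper, alpha=0.3, label="null 95% envelope"
    )
    ax.plot(band.densities, band.null_mean, "k:", label="null mean")
    ax.plot(band.densities, band.observed, "r-", label="observed difference")
    if band.flagged.any():
        ax.plot(
            band.densities[band.flagged],
            band.observed[band.flagged],
            "r*",
            markersize=9,
        )
    ax.set_xlabel("network density")
    ax.set_ylabel(f"group difference in {band.metric}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
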