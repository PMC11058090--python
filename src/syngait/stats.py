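"""Effect sizes and multiple-comparison adjustment for synergy contrasts.

Cohen's d on the pooled standard deviation quantifies perturbation effects
(0.2 <= |d| < 0.5 small, 0.5 <= |d| < 0.8 moderate, |d| >= 0.8 large), and
Benjamini–Hochberg step-up adjustment controls the false discovery rate
across the family of post hoc contrasts. Mixed-effects modeling and
statistical parametric mapping are deliberately out of scope: the pipeline
exports tidy tables that off-the-shelf tools consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cohens_d",
    "effect_magnitude",
    "benjamini_hochberg",
    "ComparisonResult",
    "perturbation_contrasts",
]


def cohens_d(group_x, group_y) -> float:
    """(mean_x - mean_y) / s_pooled with df-weighted sample variances."""
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = x.size, y.size
    s2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if s2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def effect_magnitude(d: float) -> str:
    """Magnitude class of |d|: none < 0.2 <= small < 0.5 <= moderate < 0.8 <= large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    if a >= 0.2:
        return "small"
    return "none"


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """One post hoc contrast with effect size and adjusted p-value."""

    contrast: str
    d: float
    p_raw: float
    p_adjusted: float

    @property
    def magnitude(self) -> str:
        return effect_magnitude(self.d)


def perturbation_contrasts(
    metrics: pd.DataFrame,
    perturbed_cycle: int,
    n_unperturbed: int = 3,
    value_columns: tuple[str, ...] = ("cs_patterns", "cs_weights", "fwhm_points", "coa_rad"),
) -> pd.DataFrame:
    """Contrast perturbed/recovery cycles against the unperturbed baseline.

    For every synergy label and metric column, compares the values of the
    unperturbed cycles (indices < ``n_unperturbed``) with those at and after
    ``perturbed_cycle`` via Welch's t-test and Cohen's d; raw p-values are
    Benjamini–Hochberg adjusted across the whole family.
    """
    rows = []
    for label, g in metrics.groupby("label"):
        base = g[g["cycle"] < n_unperturbed]
        pert = g[g["cycle"] >= perturbed_cycle]
        for col in value_columns:
            x = pert[col].dropna().to_numpy()
            y = base[col].dropna().to_numpy()
            if x.size < 2 or y.size < 2:
                continue
            try:
                d = cohens_d(x, y)
            except ValueError:
                continue
            t, p = sps.ttest_ind(x, y, equal_var=False)
            rows.append(
                dict(contrast=f"{label}:{col}", label=label, metric=col, d=d, p_raw=p)
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = benjamini_hochberg(out["p_raw"].to_numpy())
        out["magnitude"] = [effect_magnitude(d) for d in out["d"]]
    return out
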