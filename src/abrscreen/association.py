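"""Candidate-gene window association on quantitative hearing thresholds.

Raw audiometric thresholds (dB) are natural-log transformed and adjusted for
covariates (sex, nuisance codes, childhood conductive-loss indicators) by
residualisation; each marker's minor-allele count (0/1/2) is then tested for
an additive per-allele effect on the adjusted trait with a 1-df slope test.
Genes are scanned over two scopes — the gene interval itself and the
interval extended by a 0.1-Mb flank on each side — and significance is
Bonferroni-corrected for genes x traits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "log_adjust_trait",
    "per_allele_test",
    "MarkerWindow",
    "GeneScanResult",
    "window_scan",
    "assoc_significance",
]

DEFAULT_FLANK_BP = 100_000


def log_adjust_trait(
    raw_thresholds: np.ndarray, covariates: pd.DataFrame | np.ndarray | None = None
) -> np.ndarray:
    """Natural-log transform and residualise on covariates.

    Categorical covariate columns are dummy-coded; an intercept is always
    included, so residuals are exactly orthogonal to every covariate.
    """
    y = np.asarray(raw_thresholds, dtype=float)
    if np.any(y <= 0):
        raise ValueError("raw thresholds must be strictly positive")
    log_y = np.log(y)
    if covariates is None:
        return log_y - log_y.mean()
    if isinstance(covariates, pd.DataFrame):
        x = pd.get_dummies(covariates, columns=list(covariates.select_dtypes(exclude="number")), drop_first=True)
        x = x.astype(float).to_numpy()
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    design = sm.add_constant(x, has_constant="add")
    return np.asarray(sm.OLS(log_y, design).fit().resid)


def per_allele_test(allele_counts: np.ndarray, adjusted_trait: np.ndarray) -> float:
    """1-df per-allele (additive trend) test: two-sided p of the regression
    slope of the adjusted trait on minor-allele count.

    Returns NaN for a monomorphic marker (zero genotype variance).
    """
    g = np.asarray(allele_counts, dtype=float)
    y = np.asarray(adjusted_trait, dtype=float)
    if g.size != y.size:
        raise ValueError("genotype and trait lengths differ")
    if g.size < 10:
        raise ValueError("degenerate fit: need n >= 10")
    if not np.all(np.isin(g, (0.0, 1.0, 2.0))):
        raise ValueError("allele counts must be 0, 1 or 2")
    if np.ptp(g) == 0.0:
        return float("nan")  # monomorphic marker: p undefined
    res = stats.linregress(g, y)
    return float(res.pvalue)


@dataclass(frozen=True)
class MarkerWindow:
    """A gene interval (1-based, inclusive) with a symmetric flank."""

    gene_id: str
    gene_start_bp: int
    gene_end_bp: int
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.gene_start_bp > self.gene_end_bp:
            raise ValueError("gene_start_bp must be <= gene_end_bp")
        if self.gene_start_bp < 1 or self.flank_bp < 0:
            raise ValueError("coordinates must be positive, flank non-negative")

    @property
    def window_start_bp(self) -> int:
        return max(self.gene_start_bp - self.flank_bp, 1)

    @property
    def window_end_bp(self) -> int:
        return self.gene_end_bp + self.flank_bp


@dataclass
class GeneScanResult:
    gene_id: str
    min_p_in_gene: float | None
    best_marker_in_gene: str | None
    min_p_in_window: float | None
    best_marker_in_window: str | None
    significant: bool = False


def window_scan(
    positions_bp: np.ndarray,
    p_values: np.ndarray,
    window: MarkerWindow,
    marker_ids: list[str] | None = None,
) -> GeneScanResult:
    """Lowest p-value within the gene and within gene ± flank (inclusive
    bounds).  Markers with undefined p (monomorphic) are ignored; an empty
    scope reports missing (None)."""
    pos = np.asarray(positions_bp)
    pv = np.asarray(p_values, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted")
    if marker_ids is None:
        marker_ids = [f"m{i + 1}" for i in range(pos.size)]

    def best(lo: int, hi: int) -> tuple[float | None, str | None]:
        mask = (pos >= lo) & (pos <= hi) & ~np.isnan(pv)
        if not mask.any():
            return None, None
        idx = np.flatnonzero(mask)
        j = idx[int(np.argmin(pv[idx]))]
        return float(pv[j]), marker_ids[j]

    pg, mg = best(window.gene_start_bp, window.gene_end_bp)
    pw, mw = best(window.window_start_bp, window.window_end_bp)
    return GeneScanResult(window.gene_id, pg, mg, pw, mw)


def assoc_significance(
    min_p: float, n_genes: int = 37, n_traits: int = 2, alpha: float = 0.05
) -> bool:
    """Significance against the Bonferroni threshold alpha/(genes x traits)."""
    if n_genes < 1 or n_traits < 1 or not (0.0 < alpha < 1.0):
        raise ValueError("invalid multiplicity parameters")
    return min_p <= alpha / (n_genes * n_traits)
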