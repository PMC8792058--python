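"""Statistics comparing loss/stable/gain cells on terrain and velocity covariates.

The cell-covariate table holds, for every cell in a range-change category,
the category label plus elevation, TRI, TCI and the two CCV surfaces.  The
comparisons follow standard nonparametric practice: a Pearson correlation
matrix across the whole study area, a Kruskal-Wallis test among categories
per covariate, pairwise two-sided Mann-Whitney tests with Bonferroni
correction, and a subsampling robustness procedure (10% / 1% of cells per
category, or a 1000-cell cap, repeated 1000 times, counting significant
Kruskal-Wallis replicates at alpha = 0.05) to blunt pseudo-replication from
spatially autocorrelated rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import RasterGrid
from .range_dynamics import Category

__all__ = [
    "CellCovariateTable",
    "RobustnessReport",
    "build_cell_table",
    "pearson_matrix",
    "kruskal_wallis",
    "pairwise_mann_whitney",
    "randomization_robustness",
]

CATEGORY_LABELS = {Category.LOSS: "loss", Category.STABLE: "stable", Category.GAIN: "gain"}


@dataclass
class RobustnessReport:
    """Count of significant Kruskal-Wallis replicates under subsampling."""

    scheme: str
    replicates: int
    alpha: float
    significant: int
    seed: int

    @property
    def fraction(self) -> float:
        return self.significant / self.replicates


def build_cell_table(
    category_map: RasterGrid, covariates: dict[str, RasterGrid]
) -> pd.DataFrame:
    """One row per loss/stable/gain cell with its covariate values.

    Unsuitable cells are excluded; rows with any missing covariate drop out.
    """
    for name, g in covariates.items():
        category_map.require_congruent(g, f"category map and {name}")
    cat = category_map.data.ravel()
    keep = np.isin(cat, [int(c) for c in CATEGORY_LABELS])
    data = {"category": [CATEGORY_LABELS[Category(int(c))] for c in cat[keep]]}
    for name, g in covariates.items():
        data[name] = g.data.ravel()[keep]
    df = pd.DataFrame(data)
    return df.dropna().reset_index(drop=True)


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the numeric columns.

    Constant columns yield NaN entries (flagged with a warning).
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 complete rows")
    constant = [c for c in num.columns if num[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlation undefined")
    return num.corr(method="pearson")


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_mann_whitney(
    values: np.ndarray, categories: np.ndarray, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Two-sided rank-sum p per category pair, Bonferroni-adjusted.

    Adjusted p = raw p x number of comparisons, capped at 1.  Pairs with an
    empty group are NaN.
    """
    values = np.asarray(values, float)
    categories = np.asarray(categories)
    labels = sorted(pd.unique(categories))
    if len(labels) < 2:
        raise ValueError("need at least 2 categories")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    m = len(pairs)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in pairs:
        va, vb = values[categories == a], values[categories == b]
        if len(va) == 0 or len(vb) == 0:
            continue
        both = np.concatenate([va, vb])
        if np.all(both == both[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        if correction == "bonferroni":
            p = min(1.0, p * m)
        elif correction not in (None, "none"):
            raise ValueError(f"unknown correction {correction!r}")
        out.loc[a, b] = out.loc[b, a] = p
    np.fill_diagonal(out.values, 1.0)
    return out


def randomization_robustness(
    table: pd.DataFrame,
    variable: str,
    scheme: str = "frac10",
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> RobustnessReport:
    """Subsampled Kruskal-Wallis robustness count.

    Schemes: ``frac10`` / ``frac01`` sample 10% / 1% of each category's cells
    without replacement; ``cap1000`` samples min(n, 1000) per category.  A
    category too small for its scheme keeps all its cells (with a warning).
    Each replicate reruns the Kruskal-Wallis test across categories and the
    report counts replicates with p <= alpha.
    """
    fractions = {"frac10": 0.10, "frac01": 0.01}
    if scheme not in fractions and scheme != "cap1000":
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    groups = {
        lab: sub[variable].to_numpy(float) for lab, sub in table.groupby("category")
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 categories present")
    sizes = {}
    for lab, vals in groups.items():
        if scheme == "cap1000":
            k = min(len(vals), 1000)
        else:
            k = max(1, int(round(fractions[scheme] * len(vals))))
            if len(vals) < 10:
                warnings.warn(f"category {lab!r} too small for {scheme}; using all cells")
                k = len(vals)
        sizes[lab] = k
    significant = 0
    for _ in range(reps):
        sample = [
            vals[rng.choice(len(vals), size=sizes[lab], replace=False)]
            for lab, vals in groups.items()
        ]
        _, p = kruskal_wallis(sample)
        if p <= alpha:
            significant += 1
    return RobustnessReport(
        scheme=scheme, replicates=reps, alpha=alpha, significant=significant, seed=seed
    )


@dataclass
class CellCovariateTable:
    """Thin named wrapper around the cell-covariate DataFrame."""

    table: pd.DataFrame
    covariate_names: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_maps(
        cls, category_map: RasterGrid, covariates: dict[str, RasterGrid]
    ) -> "CellCovariateTable":
        return cls(build_cell_table(category_map, covariates), tuple(covariates))
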