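"""Five-family species distribution model ensemble on the two climate axes.

Families: GLM (logistic regression with linear+quadratic axis terms), GAM
(logistic regression on additive spline bases), GBM (gradient-boosted trees),
RF (random forest) and CTA (a single decision tree).  Presence data are
complemented with uniformly sampled pseudo-absences — by default 10 000 in 3
replicate sets for the regression families and as many as the presences in 10
sets for the tree families.  Each pseudo-absence set is evaluated by 10
repeats of a stratified 70/30 split-sample validation with AUC and TSS on the
held-out 30%.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grid import RasterGrid

__all__ = [
    "FAMILIES",
    "ModelRunSpec",
    "EvaluationRecord",
    "default_model_specs",
    "sample_pseudo_absences",
    "make_estimator",
    "fit_predict",
    "cross_validate",
    "auc",
    "tss",
    "extract_axis_values",
]

FAMILIES = ("GLM", "GAM", "GBM", "RF", "CTA")
_REGRESSION_FAMILIES = ("GLM", "GAM")


def stable_seed(*parts) -> int:
    """Deterministic sub-seed from arbitrary labels (process-independent)."""
    return zlib.crc32("|".join(map(str, parts)).encode()) % 2**31


@dataclass
class ModelRunSpec:
    """Sampling and validation settings for one model family."""

    family: str
    pa_count: int | None = None  # None: 10000 (regression) / n presences (trees)
    pa_sets: int = 3
    cv_repeats: int = 10
    holdout_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.cv_repeats < 1 or self.pa_sets < 1:
            raise ValueError("cv_repeats and pa_sets must be >= 1")

    def resolved_pa_count(self, n_presences: int) -> int:
        if self.pa_count is not None:
            return self.pa_count
        return 10_000 if self.family in _REGRESSION_FAMILIES else n_presences


def default_model_specs(seed: int = 0, pa_cap: int | None = None) -> dict[str, ModelRunSpec]:
    """Per-family defaults: 10 000 PAs x 3 sets for GLM/GAM, n-presence PAs x
    10 sets for GBM/RF/CTA (the Barbet-Massin-style recommendations).
    ``pa_cap`` optionally caps the regression-family count on small grids."""
    specs = {}
    for fam in FAMILIES:
        if fam in _REGRESSION_FAMILIES:
            count = 10_000 if pa_cap is None else min(10_000, pa_cap)
            specs[fam] = ModelRunSpec(fam, pa_count=count, pa_sets=3, seed=seed)
        else:
            specs[fam] = ModelRunSpec(fam, pa_count=None, pa_sets=10, seed=seed)
    return specs


@dataclass
class EvaluationRecord:
    family: str
    pa_set: int
    repeat: int
    auc: float
    tss: float
    cutoffs: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based AUC (midranks for ties) = normalized Mann-Whitney U."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS needs at least one observed positive and one negative")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

def extract_axis_values(
    points: pd.DataFrame, pc1: RasterGrid, pc2: RasterGrid
) -> np.ndarray:
    """(n, 2) matrix of PC1/PC2 values at point locations; NaN off-grid."""
    row, col = pc1.cell_index(points["x"].to_numpy(), points["y"].to_numpy())
    inside = (row >= 0) & (row < pc1.n_rows) & (col >= 0) & (col < pc1.n_cols)
    out = np.full((len(points), 2), np.nan)
    out[inside, 0] = pc1.data[row[inside], col[inside]]
    out[inside, 1] = pc2.data[row[inside], col[inside]]
    return out


def sample_pseudo_absences(
    domain: RasterGrid, presences: pd.DataFrame, spec: ModelRunSpec, pa_set: int = 0
) -> pd.DataFrame:
    """Uniform pseudo-absence points from non-presence, non-nodata cells.

    Distinct ``pa_set`` ids give distinct (but seeded, reproducible) draws.
    Points are placed at cell centers.
    """
    n_pa = spec.resolved_pa_count(len(presences))
    candidate = ~np.isnan(domain.data)
    if len(presences):
        row, col = domain.cell_index(presences["x"].to_numpy(), presences["y"].to_numpy())
        inside = (row >= 0) & (row < domain.n_rows) & (col >= 0) & (col < domain.n_cols)
        candidate[row[inside], col[inside]] = False
    flat = np.flatnonzero(candidate.ravel())
    if flat.size < n_pa:
        raise ValueError(
            f"only {flat.size} candidate cells for {n_pa} pseudo-absences"
        )
    rng = np.random.default_rng([spec.seed, stable_seed("pa", spec.family), pa_set])
    chosen = rng.choice(flat, size=n_pa, replace=False)
    rows, cols = np.unravel_index(chosen, domain.shape)
    x = domain.x0 + (cols + 0.5) * domain.cell_m
    y = domain.y0 - (rows + 0.5) * domain.cell_m
    return pd.DataFrame({"x": x, "y": y})


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

def make_estimator(family: str, seed: int = 0):
    """A scikit-learn classifier with fixed, documented hyperparameters."""
    if family == "GLM":
        return make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False),
            StandardScaler(),
            LogisticRegression(C=np.inf, max_iter=2000),  # unpenalized
        )
    if family == "GAM":
        return make_pipeline(
            SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(C=1.0, max_iter=2000),
        )
    if family == "GBM":
        return GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed
        )
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=seed, n_jobs=1
        )
    if family == "CTA":
        return DecisionTreeClassifier(
            max_depth=8, min_samples_leaf=5, random_state=seed
        )
    raise ValueError(f"unknown family {family!r}")


def fit_predict(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    predict_stack: tuple[RasterGrid, RasterGrid],
    seed: int = 0,
) -> RasterGrid:
    """Fit one family on labelled (PC1, PC2) points and map suitability.

    Returns continuous per-cell suitability in [0, 1]; nodata propagates.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = make_estimator(family, seed)
    est.fit(X, y)
    pc1, pc2 = predict_stack
    pc1.require_congruent(pc2, "prediction axes")
    flat = np.column_stack([pc1.data.ravel(), pc2.data.ravel()])
    good = ~np.isnan(flat).any(axis=1)
    suit = np.full(flat.shape[0], np.nan)
    if good.any():
        suit[good] = est.predict_proba(flat[good])[:, 1]
    return pc1.like(suit.reshape(pc1.shape))


def _fit_model(family: str, X: np.ndarray, y: np.ndarray, seed: int):
    est = make_estimator(family, seed)
    est.fit(X, y)
    return est


def cross_validate(
    family: str,
    datasets: list[tuple[np.ndarray, np.ndarray]],
    spec: ModelRunSpec,
) -> list[EvaluationRecord]:
    """Repeated split-sample validation: ``cv_repeats`` stratified 70/30
    splits per pseudo-absence set; AUC/TSS on the held-out 30%.

    Threshold cutoffs (all three ROC rules) are derived from the *training*
    scores of each split and stored on the record; TSS is evaluated at the
    training max-sens-spec cutoff.
    """
    from .binarization_consensus import THRESHOLD_METHODS, find_cutoff

    records: list[EvaluationRecord] = []
    for pa_set, (X, y) in enumerate(datasets):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("each pseudo-absence set needs both classes")
        for rep in range(spec.cv_repeats):
            split_seed = stable_seed("cv", spec.seed, family, pa_set, rep)
            for attempt in range(10):
                Xtr, Xte, ytr, yte = train_test_split(
                    X,
                    y,
                    test_size=spec.holdout_fraction,
                    random_state=split_seed + attempt,
                    stratify=y,
                )
                if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
                    break
            else:
                raise ValueError("could not obtain a split with both classes in both parts")
            est = _fit_model(family, Xtr, ytr, split_seed)
            train_scores = est.predict_proba(Xtr)[:, 1]
            test_scores = est.predict_proba(Xte)[:, 1]
            cutoffs = {
                m: find_cutoff(train_scores, ytr, m).cutoff for m in THRESHOLD_METHODS
            }
            cut = cutoffs["max_sens_spec"]
            pred = test_scores >= cut
            tp = int(np.sum(pred & (yte == 1)))
            fn = int(np.sum(~pred & (yte == 1)))
            tn = int(np.sum(~pred & (yte == 0)))
            fp = int(np.sum(pred & (yte == 0)))
            records.append(
                EvaluationRecord(
                    family=family,
                    pa_set=pa_set,
                    repeat=rep,
                    auc=auc(test_scores, yte),
                    tss=tss(tp, fn, tn, fp),
                    cutoffs=cutoffs,
                )
            )
    return records
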