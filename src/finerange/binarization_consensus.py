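"""Binarization of suitability maps and majority consensus.

Three ROC threshold-selection rules convert each continuous suitability map
into a presence/absence projection: (i) equal training sensitivity and
specificity, (ii) maximum sensitivity + specificity (max TSS), (iii) minimum
distance to the (0, 1) corner of the ROC plot.  With 5 algorithms, 3
thresholds, 5 GCMs and 2 emission scenarios this yields 15 baseline + 165
total binary projections per species.  A cell belongs to the consensus range
when at least 50% of the projections vote presence; the carbonate-geology
mask is applied afterwards (it commutes with the vote).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid

__all__ = [
    "THRESHOLD_METHODS",
    "ThresholdRule",
    "BinaryProjection",
    "find_cutoff",
    "binarize",
    "enumerate_projections",
    "majority_consensus",
    "apply_geology_mask",
]

THRESHOLD_METHODS = ("equal_sens_spec", "max_sens_spec", "min_roc_distance")


@dataclass(frozen=True)
class ThresholdRule:
    method: str
    cutoff: float


@dataclass
class BinaryProjection:
    """One binarized suitability map with its provenance tags."""

    grid: RasterGrid
    algorithm: str
    threshold: str
    scenario: str  # "baseline" or the rcp_gcm tag
    gcm: str | None = None
    rcp: str | None = None


def _sens_spec_at(cutoffs: np.ndarray, scores: np.ndarray, labels: np.ndarray):
    """Sensitivity and specificity of the >=cutoff rule at each candidate."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # fraction of positives >= cutoff / negatives < cutoff
    sens = (pos[None, :] >= cutoffs[:, None]).mean(axis=1)
    spec = (neg[None, :] < cutoffs[:, None]).mean(axis=1)
    return sens, spec


def find_cutoff(scores, labels, method: str) -> ThresholdRule:
    """Optimal binarization cutoff under one of the three ROC rules.

    Candidates are the distinct observed scores plus 0 and 1; among equally
    optimal candidates the smallest is returned (deterministic).
    """
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method {method!r}")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("cutoff selection needs both classes")
    cand = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    sens, spec = _sens_spec_at(cand, scores, labels)
    if method == "equal_sens_spec":
        objective = np.abs(sens - spec)
    elif method == "max_sens_spec":
        objective = -(sens + spec)
    else:  # min_roc_distance
        objective = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
    best = objective.min()
    cutoff = cand[objective <= best + 1e-12][0]
    return ThresholdRule(method, float(cutoff))


def binarize(suitability: RasterGrid, rule: ThresholdRule) -> RasterGrid:
    """Presence where suitability >= cutoff (boundary counts as presence)."""
    if not 0 <= rule.cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    out = np.where(suitability.data >= rule.cutoff, 1.0, 0.0)
    out[np.isnan(suitability.data)] = np.nan
    return suitability.like(out)


def enumerate_projections(
    n_algorithms: int, n_thresholds: int, n_gcms: int, n_rcps: int
) -> dict[str, int]:
    """Projection inventory counts: baseline, per-rcp and total."""
    if min(n_algorithms, n_thresholds, n_gcms, n_rcps) <= 0:
        raise ValueError("all counts must be positive")
    baseline = n_thresholds * n_algorithms
    per_rcp = n_thresholds * n_algorithms * n_gcms
    return {
        "baseline": baseline,
        "per_rcp": per_rcp,
        "total": baseline + per_rcp * n_rcps,
    }


def majority_consensus(projections: list[BinaryProjection | RasterGrid]) -> RasterGrid:
    """Cell = 1 iff at least 50% of the non-nodata votes are presences."""
    if not projections:
        raise ValueError("consensus needs at least one projection")
    grids = [p.grid if isinstance(p, BinaryProjection) else p for p in projections]
    first = grids[0]
    for g in grids[1:]:
        first.require_congruent(g, "consensus projections")
    stack = np.stack([g.data for g in grids])
    votes = np.nansum(stack, axis=0)
    n_votes = np.sum(~np.isnan(stack), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(votes / n_votes >= 0.5, 1.0, 0.0)
    out[n_votes == 0] = np.nan
    return first.like(out)


def apply_geology_mask(consensus: RasterGrid, mask: RasterGrid) -> RasterGrid:
    """Restrict a binary range to carbonate bedrock: output = consensus AND mask."""
    consensus.require_congruent(mask, "consensus and geology mask")
    mvals = mask.data[~np.isnan(mask.data)]
    if not np.isin(mvals, (0.0, 1.0)).all():
        raise ValueError("geology mask must be binary")
    out = consensus.data * mask.data
    return consensus.like(out)
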