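"""Range accounting between baseline and future binary projections.

Per-cell categories: a cell suitable now but not in the future is *loss*,
newly suitable is *gain*, suitable in both is *stable*, suitable in neither
is *unsuitable*.  Headline percentages relative to the present range PR
(stable + loss cells):

    RC = 100 * (RG - RL) / PR        (full-dispersal range change)
    RL% = 100 * RL / PR              (no-dispersal scenario: loss magnitude)
    RG% = 100 * RG / PR

so the signed identity RC = RG% - RL% holds exactly.  Means and sample
standard deviations are reported across algorithm x GCM x threshold
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .grid import RasterGrid

__all__ = ["Category", "RangeChangeResult", "classify_cells", "range_change", "summarize_combinations"]


class Category(IntEnum):
    UNSUITABLE = 0
    LOSS = 1
    STABLE = 2
    GAIN = 3


@dataclass
class RangeChangeResult:
    """Counts, percentages and the per-cell category map for one comparison."""

    PR: int
    RL: int
    RG: int
    RC_pct: float
    RL_pct: float
    RG_pct: float
    category_map: RasterGrid
    per_combination: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def classify_cells(baseline: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Per-cell loss/stable/gain/unsuitable categories (see ``Category``)."""
    baseline.require_congruent(future, "baseline and future projections")
    b, f = baseline.data, future.data
    for name, arr in (("baseline", b), ("future", f)):
        vals = arr[~np.isnan(arr)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"{name} projection is not binary")
    cat = np.full(b.shape, np.nan)
    ok = ~np.isnan(b) & ~np.isnan(f)
    cat[ok & (b == 1) & (f == 0)] = Category.LOSS
    cat[ok & (b == 1) & (f == 1)] = Category.STABLE
    cat[ok & (b == 0) & (f == 1)] = Category.GAIN
    cat[ok & (b == 0) & (f == 0)] = Category.UNSUITABLE
    return baseline.like(cat)


def range_change(PR: int, RL: int, RG: int) -> tuple[float, float, float]:
    """(RC%, RL%, RG%) from present-range, loss and gain cell counts."""
    if PR <= 0:
        raise ValueError("species has no baseline range")
    return (100.0 * (RG - RL) / PR, 100.0 * RL / PR, 100.0 * RG / PR)


def result_from_maps(baseline: RasterGrid, future: RasterGrid, **meta) -> RangeChangeResult:
    """Full accounting for one baseline/future pair of binary maps."""
    cat = classify_cells(baseline, future)
    rl = int(np.nansum(cat.data == Category.LOSS))
    st = int(np.nansum(cat.data == Category.STABLE))
    rg = int(np.nansum(cat.data == Category.GAIN))
    pr = rl + st
    rc_pct, rl_pct, rg_pct = range_change(pr, rl, rg)
    return RangeChangeResult(
        PR=pr, RL=rl, RG=rg, RC_pct=rc_pct, RL_pct=rl_pct, RG_pct=rg_pct,
        category_map=cat, meta=meta,
    )


def summarize_combinations(per_combination: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample sd (ddof=1; 0 for n=1) of RC/RL/RG% across combinations.

    Expects columns rc_pct, rl_pct, rg_pct (extra id columns are ignored).
    """
    if per_combination.empty:
        raise ValueError("no combinations to summarize")
    rows = {}
    for col in ("rc_pct", "rl_pct", "rg_pct"):
        vals = per_combination[col].to_numpy(float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows[col] = {"mean": float(np.mean(vals)), "sd": sd, "n": len(vals)}
    return pd.DataFrame(rows).T
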