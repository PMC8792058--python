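"""Climate-scenario stacks: 19 bioclimatic layers plus scenario metadata.

The layer ordering convention used throughout the package: indices 0-6 are
temperature-like variables (units K/degC), 7-14 precipitation-like (mm), and
15-18 derived mixtures of the two.  ``TEMP_WEIGHTS`` records, per layer, how
strongly a uniform warming offset propagates into that layer (1 for pure
temperature layers, 0 for pure precipitation, intermediate for mixtures); it
is also the vector used to orient the first principal component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid

__all__ = ["ClimateScenario", "N_BIOCLIM", "TEMP_LIKE", "TEMP_WEIGHTS", "BIOCLIM_NAMES"]

N_BIOCLIM = 19

#: indices of the temperature-like layers
TEMP_LIKE = tuple(range(7))

#: mixture coefficients (temperature share) used when a warming offset is applied
TEMP_WEIGHTS = np.array([1.0] * 7 + [0.0] * 8 + [0.6, 0.5, 0.4, 0.3])

BIOCLIM_NAMES = [f"bio{i + 1:02d}" for i in range(N_BIOCLIM)]


@dataclass
class ClimateScenario:
    """A labelled stack of 19 bioclimatic rasters on one (coarse) grid.

    ``rcp`` and ``gcm`` are None for the baseline scenario.
    """

    tag: str
    layers: list[RasterGrid]
    rcp: str | None = None
    gcm: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layers) != N_BIOCLIM:
            raise ValueError(
                f"scenario {self.tag!r} has {len(self.layers)} layers, expected {N_BIOCLIM}"
            )
        first = self.layers[0]
        for lyr in self.layers[1:]:
            first.require_congruent(lyr, f"bioclim layers of {self.tag!r}")

    @property
    def grid(self) -> RasterGrid:
        return self.layers[0]

    @property
    def is_baseline(self) -> bool:
        return self.rcp is None

    def stack(self) -> np.ndarray:
        """(n_cells, 19) matrix of layer values, row-major cell order."""
        return np.column_stack([lyr.data.ravel() for lyr in self.layers])
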