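"""Shared raster grid on the stereotaxic (AP, DV) plane.

All overlap statistics are computed on one common grid (10 um cells by
default) so functional masks from different animals and the atlas raster
are directly comparable; the discretization error is far below the
hundreds-of-micrometre effects being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely


@dataclass(frozen=True)
class AnalysisGrid:
    """Regular cell grid over an (AP, DV) window, cell centres labelled.

    Rows index DV (increasing ventral), columns AP (increasing, i.e.
    toward anterior); ``step_mm`` is the cell edge (default 10 um).
    """

    ap_min: float = -4.4
    ap_max: float = -1.0
    dv_min: float = 0.8
    dv_max: float = 4.4
    step_mm: float = 0.01

    def __post_init__(self):
        if self.step_mm <= 0 or self.ap_max <= self.ap_min or self.dv_max <= self.dv_min:
            raise ValueError("invalid grid window or step")

    @property
    def ap_centers(self) -> np.ndarray:
        n = int(round((self.ap_max - self.ap_min) / self.step_mm))
        return self.ap_min + (np.arange(n) + 0.5) * self.step_mm

    @property
    def dv_centers(self) -> np.ndarray:
        n = int(round((self.dv_max - self.dv_min) / self.step_mm))
        return self.dv_min + (np.arange(n) + 0.5) * self.step_mm

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.dv_centers), len(self.ap_centers))

    @property
    def cell_area_mm2(self) -> float:
        return self.step_mm**2

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.ap_centers, self.dv_centers)

    def rasterize(self, geometry) -> np.ndarray:
        """Boolean image of cells whose centres fall inside the geometry."""
        out = np.zeros(self.shape, dtype=bool)
        if geometry is None or geometry.is_empty:
            return out
        minx, miny, maxx, maxy = geometry.bounds
        ap = self.ap_centers
        dv = self.dv_centers
        c0, c1 = np.searchsorted(ap, [minx - self.step_mm, maxx + self.step_mm])
        r0, r1 = np.searchsorted(dv, [miny - self.step_mm, maxy + self.step_mm])
        if c0 >= c1 or r0 >= r1:
            return out
        aps, dvs = np.meshgrid(ap[c0:c1], dv[r0:r1])
        inside = shapely.contains_xy(geometry, aps.ravel(), dvs.ravel())
        out[r0:r1, c0:c1] = inside.reshape(aps.shape)
        return out
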