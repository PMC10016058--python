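"""Topographical (AP, DV) surface map of atlas auditory areas.

The brain atlas delineates three auditory subdivisions — primary Au1
flanked by dorsal AuD and ventral AuV — on coronal sections. Given a
table of the dorsal and ventral DV edges of each area on each section,
this module connects the edges across sections (linear interpolation
along AP) into closed surface polygons, optionally patches a known
single-section discontinuity by bisecting Au1, and rasterizes the result
onto the shared analysis grid for overlap statistics.

The real published border coordinates are copyrighted and are not
shipped; ``synthetic_atlas_table`` loads a clearly-labelled synthetic
table with the same schema and qualitative geometry (17 sections between
AP -1.67 and -3.63 mm with an AuV gap at -1.91 mm), and user-supplied
tables of real measurements are read with ``load_section_table``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .grid import AnalysisGrid

ATLAS_AREAS = ("AuD", "Au1", "AuV")

REQUIRED_COLUMNS = ("ap_mm", "area", "dorsal_dv_mm", "ventral_dv_mm")

#: AP (mm) of the section where the published AuV map is discontinuous.
DISCONTINUITY_AP_MM = -1.91


def load_section_table(source) -> pd.DataFrame:
    """Read a per-section border-edge table (CSV; '#' comments allowed)."""
    df = pd.read_csv(source, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"atlas table is missing columns {missing}")
    validate_section_table(df)
    return df


def synthetic_atlas_table() -> pd.DataFrame:
    """The synthetic stand-in border table shipped with the package."""
    with resources.files("tonomap.data").joinpath("synthetic_atlas.csv").open() as fh:
        return load_section_table(fh)


def validate_section_table(table: pd.DataFrame) -> None:
    bad = table[table.ventral_dv_mm <= table.dorsal_dv_mm]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"edge crossing: {row.area} at AP = {row.ap_mm} mm has "
            "ventral edge dorsal of its dorsal edge"
        )
    dup = table.duplicated(subset=["ap_mm", "area"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(f"duplicate section entry: {row.area} at AP = {row.ap_mm}")


@dataclass
class AtlasSurfaceMap:
    """Closed 2-D polygons of the atlas areas on the (AP, DV) plane."""

    polygons: dict  # area -> shapely Polygon
    source: str = ""
    patched: bool = False
    section_ap_mm: np.ndarray = field(default_factory=lambda: np.empty(0))

    def area_mm2(self, area: str) -> float:
        return self.polygons[area].area

    def overlap_area_mm2(self) -> float:
        """Total pairwise-overlap area (0 for a consistent map)."""
        names = list(self.polygons)
        total = 0.0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                total += self.polygons[names[i]].intersection(
                    self.polygons[names[j]]
                ).area
        return total


def build_surface_map(table: pd.DataFrame, source: str = "") -> AtlasSurfaceMap:
    """Connect per-section edges along AP into one polygon per area.

    Per area, the dorsal edges are traversed in ascending AP order and the
    ventral edges back in descending order, closing the outline; between
    sections the edges are linearly interpolated (straight polygon sides).
    Sections must have strictly distinct AP values.
    """
    validate_section_table(table)
    polygons = {}
    for area, sub in table.groupby("area"):
        sub = sub.sort_values("ap_mm")
        if len(sub) < 2:
            raise ValueError(f"{area}: need at least 2 sections")
        if sub.ap_mm.duplicated().any():
            raise ValueError(f"{area}: duplicate or unordered sections")
        ap = sub.ap_mm.to_numpy()
        dorsal = sub.dorsal_dv_mm.to_numpy()
        ventral = sub.ventral_dv_mm.to_numpy()
        ring = list(zip(ap, dorsal)) + list(zip(ap[::-1], ventral[::-1]))
        poly = Polygon(ring)
        if not poly.is_valid:
            poly = poly.buffer(0)
        polygons[area] = poly
    return AtlasSurfaceMap(
        polygons=polygons,
        source=source,
        section_ap_mm=np.sort(table.ap_mm.unique()),
    )


def patch_discontinuity(
    table: pd.DataFrame,
    ap_mm: float = DISCONTINUITY_AP_MM,
    rule: str = "split-equal",
) -> pd.DataFrame:
    """Repair the single-section AuV gap by bisecting Au1 at that section.

    At the affected section the atlas draws no AuV and an over-tall Au1;
    the ``split-equal`` rule divides that Au1 span equally, the dorsal
    half staying Au1 and the ventral half becoming AuV, restoring a smooth
    transition. Total DV coverage at the section is unchanged. Applying
    the patch to a section that already has AuV raises (already patched).
    """
    if rule != "split-equal":
        raise ValueError(f"unknown patch rule {rule!r}")
    at = table[np.isclose(table.ap_mm, ap_mm)]
    if len(at) == 0:
        raise ValueError(f"no atlas section at AP = {ap_mm} mm")
    if (at.area == "AuV").any():
        raise ValueError(f"section at AP = {ap_mm} mm already has AuV (already patched)")
    au1 = at[at.area == "Au1"]
    if len(au1) != 1:
        raise ValueError(f"section at AP = {ap_mm} mm has no unique Au1 row")
    row = au1.iloc[0]
    mid = (row.dorsal_dv_mm + row.ventral_dv_mm) / 2.0
    out = table.copy()
    out.loc[au1.index, "ventral_dv_mm"] = mid
    new_row = pd.DataFrame(
        [{"ap_mm": row.ap_mm, "area": "AuV",
          "dorsal_dv_mm": mid, "ventral_dv_mm": row.ventral_dv_mm}]
    )
    out = pd.concat([out, new_row], ignore_index=True)
    return out.sort_values(["ap_mm", "area"], ascending=[False, True]).reset_index(
        drop=True
    )


def rasterize_atlas(
    surface_map: AtlasSurfaceMap, grid: AnalysisGrid | None = None
) -> tuple[np.ndarray, dict]:
    """Label image of the atlas on the analysis grid.

    Cells are labelled by the area containing their centre; 0 means
    "outside" every atlas area. Returns ``(labels, code_map)`` where
    ``code_map`` maps area name -> integer label.
    """
    grid = grid or AnalysisGrid()
    labels = np.zeros(grid.shape, dtype=np.uint8)
    codes = {}
    for i, (area, poly) in enumerate(surface_map.polygons.items(), start=1):
        codes[area] = i
        labels[grid.rasterize(poly)] = i
    return labels, codes


def atlas_rasters(
    surface_map: AtlasSurfaceMap, grid: AnalysisGrid | None = None
) -> dict:
    """Boolean raster per atlas area on the analysis grid."""
    grid = grid or AnalysisGrid()
    return {area: grid.rasterize(poly) for area, poly in surface_map.polygons.items()}
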