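"""Population statistics on registered functional maps.

Everything here operates on masks and centroids already expressed in one
common stereotaxic coordinate system and rasterized on one shared grid:
overlap fractions between functional and atlas parcels, classification
and targeting accuracy, cross-animal mask overlap, centroid variability
and its comparison with human marking error, probability contour maps,
within-map geography metrics, ANOVA-based variance decomposition of
centroid positions, and rank-sum group comparisons.

Classification accuracy (e.g. A1 -> Au1) is the chance that an event in a
functional area is attributed to the right atlas parcel; targeting
accuracy (e.g. Au1 -> A1) is the chance that an atlas-guided manipulation
hits the intended functional area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import fftconvolve
from skimage.measure import find_contours

from .grid import AnalysisGrid

logger = logging.getLogger(__name__)

TONOTOPIC_AREAS = ("A1", "VAF", "AAF", "A2")
PRIMARY_AREAS = ("A1", "VAF", "AAF")
ATLAS_AREAS = ("Au1", "AuD", "AuV")

#: Frequency domains used for centroid-variability and cortex-centroid
#: statistics.
VARIABILITY_DOMAINS = (("A1", 3.0), ("A1", 30.0), ("AAF", 3.0), ("A2", 3.0))


@dataclass
class MouseRecord:
    """One animal's registered functional map on the shared grid."""

    mouse_id: str
    area_rasters: dict  # area name -> bool image on the grid
    centroids_mm: dict  # (area, freq) -> (AP, DV)
    area_polygons: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class PopulationMaps:
    """A registered population: shared grid, coordinate system, mice."""

    grid: AnalysisGrid
    mice: list  # of MouseRecord
    system: str = "bl_normalized"

    def __len__(self) -> int:
        return len(self.mice)


# ----------------------------------------------------------------------
# overlap fractions
# ----------------------------------------------------------------------

def overlap_fraction(mask_a: np.ndarray, mask_b: np.ndarray,
                     denominator: str = "a") -> float:
    """``|A intersect B| / |denominator mask|`` on a common raster grid."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks are on different grids")
    denom = mask_a if denominator == "a" else mask_b
    n = int(denom.sum())
    if n == 0:
        raise ValueError("empty denominator mask")
    return float((mask_a & mask_b).sum() / n)


def overlap_fraction_polygon(poly_a, poly_b, denominator: str = "a") -> float:
    """Exact polygon-kernel counterpart of :func:`overlap_fraction`."""
    denom = poly_a if denominator == "a" else poly_b
    if denom.is_empty or denom.area == 0:
        raise ValueError("empty denominator polygon")
    return poly_a.intersection(poly_b).area / denom.area


def map_functional_onto_atlas(
    mouse: MouseRecord, atlas_rasters: dict,
    functional_areas=TONOTOPIC_AREAS,
) -> pd.DataFrame:
    """Fraction of each functional area inside each atlas area.

    One row per functional area with columns Au1/AuD/AuV/outside; rows sum
    to 1 ("outside" absorbs functional mass beyond the atlas parcels).
    Absent functional areas yield NaN rows.
    """
    cols = list(atlas_rasters) + ["outside"]
    rows = {}
    for area in functional_areas:
        mask = mouse.area_rasters.get(area)
        if mask is None or not mask.any():
            rows[area] = {c: np.nan for c in cols}
            continue
        fracs = {
            name: overlap_fraction(mask, amask, "a")
            for name, amask in atlas_rasters.items()
        }
        fracs["outside"] = 1.0 - sum(fracs.values())
        rows[area] = fracs
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def map_atlas_onto_functional(
    mouse: MouseRecord, atlas_rasters: dict,
    functional_areas=TONOTOPIC_AREAS + ("DP", "CTR"),
) -> pd.DataFrame:
    """Fraction of each atlas area inside each functional area (+ outside)."""
    cols = list(functional_areas) + ["outside"]
    rows = {}
    for atlas_area, amask in atlas_rasters.items():
        if not amask.any():
            rows[atlas_area] = {c: np.nan for c in cols}
            continue
        covered = np.zeros_like(amask)
        fracs = {}
        for area in functional_areas:
            mask = mouse.area_rasters.get(area)
            if mask is None:
                fracs[area] = 0.0
                continue
            # count each atlas cell once even where A1/VAF overlap
            new = mask & ~covered
            fracs[area] = overlap_fraction(amask, new, "a")
            covered |= mask
        fracs["outside"] = 1.0 - sum(fracs.values())
        rows[atlas_area] = fracs
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def classification_accuracy(mouse: MouseRecord, atlas_rasters: dict) -> dict:
    """Per-mouse fractions A1 -> Au1 and A2 -> AuV."""
    out = {}
    pairs = {"A1->Au1": ("A1", "Au1"), "A2->AuV": ("A2", "AuV")}
    for name, (farea, aarea) in pairs.items():
        mask = mouse.area_rasters.get(farea)
        out[name] = (
            np.nan if mask is None or not mask.any()
            else overlap_fraction(mask, atlas_rasters[aarea], "a")
        )
    return out


def targeting_accuracy(mouse: MouseRecord, atlas_rasters: dict) -> dict:
    """Per-mouse fractions Au1 -> A1, Au1 -> primary, AuV -> A2.

    Primary is the union of A1, VAF and AAF, so Au1 -> primary is always
    at least Au1 -> A1.
    """
    au1 = atlas_rasters["Au1"]
    auv = atlas_rasters["AuV"]
    zeros = np.zeros_like(au1)
    a1 = mouse.area_rasters.get("A1", zeros)
    a2 = mouse.area_rasters.get("A2", zeros)
    primary = zeros.copy()
    for area in PRIMARY_AREAS:
        m = mouse.area_rasters.get(area)
        if m is not None:
            primary |= m
    return {
        "Au1->A1": overlap_fraction(au1, a1, "a"),
        "Au1->primary": overlap_fraction(au1, primary, "a"),
        "AuV->A2": overlap_fraction(auv, a2, "a"),
    }


def pairwise_population_overlap(pop: PopulationMaps, area: str) -> dict:
    """Mean cross-animal overlap of one area over ordered mouse pairs.

    For each ordered pair (i, j), ``|mask_i intersect mask_j| / |mask_i|``;
    n mice with the area present give n(n-1) ordered pairs (41 mice ->
    1,640). Mice lacking the area are skipped (logged).
    """
    masks = []
    for m in pop.mice:
        mk = m.area_rasters.get(area)
        if mk is None or not mk.any():
            logger.info("mouse %s lacks area %s; skipped", m.mouse_id, area)
            continue
        masks.append(mk)
    if len(masks) < 2:
        raise ValueError(f"need >= 2 mice with area {area}")
    fracs = [
        overlap_fraction(masks[i], masks[j], "a")
        for i, j in permutations(range(len(masks)), 2)
    ]
    return {
        "mean": float(np.mean(fracs)),
        "sem": float(np.std(fracs, ddof=1) / np.sqrt(len(fracs))),
        "n_pairs": len(fracs),
        "fractions": np.asarray(fracs),
    }


# ----------------------------------------------------------------------
# centroid variability and human error
# ----------------------------------------------------------------------

def centroid_pairwise_distances(
    pop: PopulationMaps, domains=VARIABILITY_DOMAINS
) -> dict:
    """Per-axis |distance| between corresponding domain centroids across mice.

    For every unordered mouse pair and each listed frequency domain, the
    absolute AP and DV offsets; pairs where either mouse lacks the domain
    are dropped, so the realized pair count is reported alongside the
    theoretical maximum ``len(domains) * C(n, 2)``.
    """
    ap, dv = [], []
    n = len(pop.mice)
    for dom in domains:
        pts = [m.centroids_mm.get(dom) for m in pop.mice]
        for i, j in combinations(range(n), 2):
            if pts[i] is None or pts[j] is None:
                continue
            d = np.abs(np.asarray(pts[i]) - np.asarray(pts[j]))
            ap.append(d[0])
            dv.append(d[1])
    ap = np.asarray(ap)
    dv = np.asarray(dv)
    return {
        "ap_mm": ap,
        "dv_mm": dv,
        "n_pairs": len(ap),
        "max_pairs": len(domains) * (n * (n - 1)) // 2,
        "mean_ap_mm": float(ap.mean()) if len(ap) else np.nan,
        "mean_dv_mm": float(dv.mean()) if len(dv) else np.nan,
    }


def human_error_metric(marks_mm_a: np.ndarray, marks_mm_b: np.ndarray) -> dict:
    """Inter-experimenter marking error for one animal.

    Both inputs are the three reference marks registered into mm by the
    same transform chain; the per-axis |difference| is averaged across the
    three marks, giving one AP and one DV error value per animal.
    """
    a = np.asarray(marks_mm_a, dtype=float)
    b = np.asarray(marks_mm_b, dtype=float)
    if a.shape != (3, 2) or b.shape != (3, 2):
        raise ValueError("expected 3 (AP, DV) marks per experimenter")
    d = np.abs(a - b).mean(axis=0)
    return {"ap_mm": float(d[0]), "dv_mm": float(d[1])}


def auditory_cortex_centroid(mouse: MouseRecord) -> np.ndarray:
    """Centre of the four reference domain centroids (A1 3k/30k, AAF 3k, A2 3k)."""
    pts = []
    for dom in VARIABILITY_DOMAINS:
        p = mouse.centroids_mm.get(dom)
        if p is None:
            raise ValueError(f"missing domain centroid {dom[0]} {dom[1]:g} kHz")
        pts.append(np.asarray(p, dtype=float))
    return np.mean(pts, axis=0)


# ----------------------------------------------------------------------
# probability contours
# ----------------------------------------------------------------------

def _disk_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.ceil(radius_cells))
    ys, xs = np.mgrid[-r:r + 1, -r:r + 1]
    k = (xs**2 + ys**2 <= radius_cells**2).astype(float)
    return k / k.sum()


def probability_map(
    pop: PopulationMaps, area: str, filter_radius_um: float = 100.0
) -> np.ndarray:
    """Fraction-of-mice image for one area, circular-mean filtered."""
    if not pop.mice:
        raise ValueError("empty population")
    count = np.zeros(pop.grid.shape, dtype=float)
    n = 0
    for m in pop.mice:
        mask = m.area_rasters.get(area)
        if mask is not None:
            count += mask
            n += 1
    if n == 0:
        raise ValueError(f"no mouse has area {area}")
    frac = count / n
    radius_cells = filter_radius_um / (pop.grid.step_mm * 1000.0)
    if radius_cells > 0:
        frac = fftconvolve(frac, _disk_kernel(radius_cells), mode="same")
    return np.clip(frac, 0.0, 1.0)


def probability_contours(
    pop: PopulationMaps, area: str,
    filter_radius_um: float = 100.0, step: float = 0.1,
) -> dict:
    """Nested probability contours at ``step`` increments (10%, 20%, ...).

    Returns the filtered fraction image and, per level, the marching-
    squares contour paths in (AP, DV) mm.
    """
    frac = probability_map(pop, area, filter_radius_um)
    grid = pop.grid
    levels = np.round(np.arange(step, 1.0, step), 10)
    contours = {}
    for level in levels:
        paths = []
        for c in find_contours(frac, level):
            ap = grid.ap_min + (c[:, 1] + 0.5) * grid.step_mm
            dv = grid.dv_min + (c[:, 0] + 0.5) * grid.step_mm
            paths.append(np.column_stack([ap, dv]))
        contours[float(level)] = paths
    return {"fraction": frac, "contours": contours, "levels": levels}


# ----------------------------------------------------------------------
# geography of the map
# ----------------------------------------------------------------------

@dataclass
class GeographyMetrics:
    """Within-animal geometry of the tonotopic map."""

    ap_extent_mm: float
    dv_extent_mm: float
    alpha_rad: float
    beta_rad: float
    a1_aaf_border_distance_mm: float
    area_mm2: dict


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate axis for angle computation")
    return float(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))


def geography_metrics(mouse: MouseRecord, grid: AnalysisGrid) -> GeographyMetrics:
    """Cortex dimensions, inter-axis angles, A1-AAF gap, per-area areas.

    alpha is the angle between the A1 3 kHz -> AAF 3 kHz axis and the A1
    tonotopic (3 -> 30 kHz) axis; beta replaces the second axis with A1
    3 kHz -> A2 3 kHz. The A1-AAF border distance (0 when the areas touch)
    indicates whether a tone low-responsive centre region fits between
    them.
    """
    union = np.zeros(grid.shape, dtype=bool)
    areas_mm2 = {}
    for area in TONOTOPIC_AREAS:
        mask = mouse.area_rasters.get(area)
        if mask is None or not mask.any():
            raise ValueError(f"missing area mask {area}")
        union |= mask
        areas_mm2[area] = float(mask.sum() * grid.cell_area_mm2)
    rows, cols = np.nonzero(union)
    ap_extent = (cols.max() - cols.min() + 1) * grid.step_mm
    dv_extent = (rows.max() - rows.min() + 1) * grid.step_mm

    c = {}
    for dom in (("A1", 3.0), ("A1", 30.0), ("AAF", 3.0), ("A2", 3.0)):
        p = mouse.centroids_mm.get(dom)
        if p is None:
            raise ValueError(f"missing centroid {dom[0]} {dom[1]:g} kHz")
        c[dom] = np.asarray(p, dtype=float)
    base = c[("AAF", 3.0)] - c[("A1", 3.0)]
    alpha = _angle_between(base, c[("A1", 30.0)] - c[("A1", 3.0)])
    beta = _angle_between(base, c[("A2", 3.0)] - c[("A1", 3.0)])

    pa = mouse.area_polygons.get("A1")
    pb = mouse.area_polygons.get("AAF")
    if pa is not None and pb is not None:
        border = float(pa.distance(pb))
    else:  # raster fallback: minimum distance between mask cells
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(~mouse.area_rasters["AAF"]) * grid.step_mm
        border = float(dist[mouse.area_rasters["A1"]].min())
    return GeographyMetrics(
        ap_extent_mm=float(ap_extent),
        dv_extent_mm=float(dv_extent),
        alpha_rad=alpha,
        beta_rad=beta,
        a1_aaf_border_distance_mm=border,
        area_mm2=areas_mm2,
    )


# ----------------------------------------------------------------------
# variance decomposition and group tests
# ----------------------------------------------------------------------

def variance_decomposition(
    data: pd.DataFrame,
    value: str,
    categorical: tuple = ("strain", "sex"),
    continuous: tuple = ("age",),
    ss_type: int = 1,
) -> dict:
    """Percent of centroid-position variance explained by animal factors.

    Fixed-effects N-way ANOVA of ``value`` on strain, sex (categorical)
    and age (continuous); each factor's share is its sum of squares over
    the total, in percent, with the residual reported as ``unexplained``.
    Shares plus unexplained sum to 100 for sequential (Type I) SS.
    Factors constant in the sample are kept with a 0 share rather than
    raising. Perfectly aliased factors raise.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.copy()
    terms, dropped = [], []
    for f in categorical:
        if df[f].nunique() >= 2:
            terms.append(f"C({f})")
        else:
            dropped.append(f)
    for f in continuous:
        if df[f].nunique() >= 2:
            terms.append(f)
        else:
            dropped.append(f)
    shares = {f: 0.0 for f in dropped}
    total_ss = float(((df[value] - df[value].mean()) ** 2).sum())
    if total_ss == 0:
        raise ValueError("response has zero variance")
    if terms:
        model = smf.ols(f"{value} ~ " + " + ".join(terms), data=df).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise ValueError("confounded design: aliased factors")
        table = sm.stats.anova_lm(model, typ=ss_type)
        resid_ss = float(table.loc["Residual", "sum_sq"])
        for term in table.index:
            if term == "Residual":
                continue
            name = term.replace("C(", "").replace(")", "")
            shares[name] = 100.0 * float(table.loc[term, "sum_sq"]) / total_ss
        if ss_type == 1:
            unexplained = 100.0 * resid_ss / total_ss
        else:
            unexplained = 100.0 - sum(shares.values())
    else:
        unexplained = 100.0
    shares["unexplained"] = unexplained
    return shares


def group_comparison(samples_a, samples_b, corrections: int = 1) -> float:
    """Two-sided rank-sum p-value with Bonferroni multiplication.

    Exact null enumeration for small tie-free samples, normal
    approximation otherwise; the corrected p is capped at 1.
    """
    if corrections < 1:
        raise ValueError("corrections must be >= 1")
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(min(1.0, p * corrections))
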