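"""End-to-end orchestration: session -> maps -> parcels -> registered record.

Ties the stages together for both synthetic and real sessions: process the
per-frequency trial stacks into response maps, fit the stereotaxic
transform from the skull marks, propose or accept seed ROIs, run the
parcellation, and express the resulting masks and centroids in a chosen
coordinate system on the shared analysis grid. Also provides the
synthetic-population driver used by the validation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage.measure import find_contours

from . import imaging, metrics, segmentation, synthetic
from .coords import StereotaxicTransform
from .grid import AnalysisGrid
from .registration import ReferenceMarks, fit_transform


def process_layout_maps(
    layout: synthetic.GroundTruthLayout,
    config: synthetic.AcquisitionConfig,
    seed: int | np.random.Generator = 0,
    rl_iterations: int = 60,
) -> dict:
    """Render and process one synthetic session, one frequency at a time.

    Trial stacks are rendered, reduced to response maps, and released
    immediately, so peak memory stays at a single frequency's stack.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    px_scale = np.sqrt(layout.scale_ap_um * layout.scale_dv_um)
    maps = {}
    for f in synthetic.FREQUENCIES_KHZ:
        field_img = synthetic.render_response_field(layout, f, config)
        stack = synthetic.render_trial_stack(field_img, config, rng, frequency_khz=f)
        maps[f] = imaging.process_stack(
            stack,
            response_window_s=config.response_window_s,
            deconv_sigma_um=config.blur_sigma_um,
            px_scale_um=px_scale,
            deconv_iterations=rl_iterations,
        )
        del stack
    return maps


@dataclass
class SessionAnalysis:
    """Everything derived from one session."""

    transform: StereotaxicTransform
    segmentation: segmentation.SegmentationResult
    maps: dict = field(default_factory=dict)
    record: metrics.MouseRecord | None = None


def mask_to_polygon(mask: np.ndarray, transform: StereotaxicTransform):
    """Sub-pixel outline of a mask mapped into stereotaxic mm.

    Each closed 0.5-level contour becomes a polygon (the pixel -> mm map
    is affine, so straight contour segments stay straight); multiple
    components are unioned. Holes inside components are rare after the
    morphological closing and are filled.
    """
    polys = []
    padded = np.pad(mask.astype(float), 1)
    for contour in find_contours(padded, 0.5):
        if len(contour) < 3:
            continue
        px = contour[:, ::-1] - 1.0  # (row, col) -> (x, y), un-pad
        mm = transform.px_to_mm(px)
        poly = Polygon(mm)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if not poly.is_empty:
            polys.append(poly)
    if not polys:
        return Polygon()
    return unary_union(polys)


def build_mouse_record(
    seg: segmentation.SegmentationResult,
    transform: StereotaxicTransform,
    grid: AnalysisGrid,
    system: str = "bl_normalized",
    mouse_id: str = "mouse",
    meta: dict | None = None,
) -> metrics.MouseRecord:
    """Express a parcellation in one coordinate system on the shared grid."""
    t = transform.with_system(system)
    polygons = {}
    rasters = {}
    for name, am in seg.all_area_masks().items():
        poly = mask_to_polygon(am.mask, t)
        polygons[name] = poly
        rasters[name] = grid.rasterize(poly)
    centroids = {
        key: np.asarray(t.px_to_mm(dom.centroid_px))
        for key, dom in seg.domains.items()
    }
    return metrics.MouseRecord(
        mouse_id=mouse_id,
        area_rasters=rasters,
        centroids_mm=centroids,
        area_polygons=polygons,
        meta=meta or {},
    )


def analyze_session(
    maps: dict,
    marks: ReferenceMarks,
    seed_rois: dict | None = None,
    seg_params: segmentation.SegmentationParams | None = None,
    grid: AnalysisGrid | None = None,
    system: str = "bl_normalized",
    mouse_id: str = "mouse",
    meta: dict | None = None,
) -> SessionAnalysis:
    """Parcellate processed response maps and register them.

    ``maps`` maps frequency (kHz) to a :class:`~tonomap.imaging.ResponseMap`.
    If no seed ROIs are given they are proposed automatically from the
    response peaks and the expected area geometry.
    """
    transform = fit_transform(marks)
    magnitude = {f: m.magnitude for f, m in maps.items()}
    px_scale = np.sqrt(transform.scale_ap_um * transform.scale_dv_um)
    if seg_params is None:
        seg_params = segmentation.SegmentationParams.for_pixel_scale(px_scale)
    if seed_rois is None:
        seed_rois = segmentation.propose_seed_rois(magnitude, transform)
    seg = segmentation.run_segmentation(
        magnitude, seed_rois, seg_params, transform=transform
    )
    grid = grid or AnalysisGrid()
    record = build_mouse_record(seg, transform, grid, system, mouse_id, meta)
    return SessionAnalysis(
        transform=transform, segmentation=seg, maps=maps, record=record
    )


# ----------------------------------------------------------------------
# synthetic population driver
# ----------------------------------------------------------------------

@dataclass
class RecoveryEvaluation:
    """Ground-truth comparison for one synthetic mouse."""

    mouse_id: str
    n_rendered: int
    n_detected: int
    centroid_errors_um: dict  # (area, freq) -> error for detected domains
    rotation_error_rad: float
    scale_errors_frac: tuple


@dataclass
class PopulationRun:
    """Synthetic population with per-mouse ground-truth evaluations."""

    population: metrics.PopulationMaps
    layouts: list
    evaluations: list

    @property
    def detection_rate(self) -> float:
        rendered = sum(e.n_rendered for e in self.evaluations)
        detected = sum(e.n_detected for e in self.evaluations)
        return detected / rendered if rendered else np.nan

    def detection_rate_within(self, tol_um: float) -> float:
        rendered = sum(e.n_rendered for e in self.evaluations)
        good = sum(
            sum(1 for err in e.centroid_errors_um.values() if err < tol_um)
            for e in self.evaluations
        )
        return good / rendered if rendered else np.nan

    @property
    def rotation_errors_rad(self) -> np.ndarray:
        return np.array([e.rotation_error_rad for e in self.evaluations])

    @property
    def centroid_errors_um(self) -> np.ndarray:
        return np.concatenate(
            [list(e.centroid_errors_um.values()) for e in self.evaluations]
        ) if self.evaluations else np.empty(0)


def evaluate_recovery(
    layout: synthetic.GroundTruthLayout,
    analysis: SessionAnalysis,
    mouse_id: str = "mouse",
) -> RecoveryEvaluation:
    """Score recovered domains and transform against a layout's truth.

    Centroid errors are measured by mapping the true rendered centre and
    the recovered centroid through the SAME fitted transform, so a
    coherent mark-placement offset (which shifts all absolute coordinates
    together) does not contaminate the segmentation error.
    """
    t = analysis.transform
    errors = {}
    for key, center_mm in layout.centers_mm.items():
        dom = analysis.segmentation.domains.get(key)
        if dom is None:
            continue
        true_px = layout.transform.mm_to_px(center_mm)
        err_mm = np.asarray(t.px_to_mm(dom.centroid_px)) - np.asarray(
            t.px_to_mm(true_px)
        )
        errors[key] = float(np.linalg.norm(err_mm) * 1000.0)
    rot_err = float(t.theta_rad - layout.rotation_rad)
    scale_err = (
        t.scale_ap_um / layout.scale_ap_um - 1.0,
        t.scale_dv_um / layout.scale_dv_um - 1.0,
    )
    return RecoveryEvaluation(
        mouse_id=mouse_id,
        n_rendered=len(layout.centers_mm),
        n_detected=len(errors),
        centroid_errors_um=errors,
        rotation_error_rad=rot_err,
        scale_errors_frac=scale_err,
    )


def run_synthetic_population(
    n_mice: int,
    seed: int = 0,
    params: synthetic.PopulationParams | None = None,
    config: synthetic.AcquisitionConfig | None = None,
    human_error_sd_um: float = 100.0,
    rl_iterations: int = 60,
    grid: AnalysisGrid | None = None,
    system: str = "bl_normalized",
) -> PopulationRun:
    """Generate, image, parcellate and register a synthetic population."""
    params = params or synthetic.PopulationParams()
    config = config or synthetic.AcquisitionConfig()
    grid = grid or AnalysisGrid()
    root = np.random.SeedSequence(seed)
    layout_rng = np.random.default_rng(root.spawn(1)[0])
    layouts = synthetic.sample_population_layouts(params, n_mice, layout_rng, config)
    mouse_seeds = root.spawn(n_mice + 1)[1:]

    mice, evaluations = [], []
    for i, (layout, ss) in enumerate(zip(layouts, mouse_seeds)):
        rng = np.random.default_rng(ss)
        mouse_id = f"m{i:03d}"
        maps = process_layout_maps(layout, config, rng, rl_iterations)
        placement = synthetic.place_reference_marks(layout, human_error_sd_um, rng)
        marks = ReferenceMarks(pixels=placement.pixels, bldist_mm=layout.bldist_mm)
        analysis = analyze_session(
            maps, marks, grid=grid, system=system, mouse_id=mouse_id,
            meta={
                "strain": layout.strain, "sex": layout.sex,
                "age_wk": layout.age_wk, "bldist_mm": layout.bldist_mm,
            },
        )
        mice.append(analysis.record)
        evaluations.append(evaluate_recovery(layout, analysis, mouse_id))
    return PopulationRun(
        population=metrics.PopulationMaps(grid=grid, mice=mice, system=system),
        layouts=layouts,
        evaluations=evaluations,
    )
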