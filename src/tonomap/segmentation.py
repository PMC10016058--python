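"""Semiautomated parcellation of response maps into auditory areas.

For each tone frequency, a seed region of interest (ROI) marks the coarse
location of a frequency domain in each of the four tonotopic areas. The
domain centroid is the mean of the peak-response pixel and the
amplitude-weighted centre of mass within the seed ROI; the domain mask is
the connected component, around that centroid, of pixels exceeding 60% of
the ROI peak amplitude. Same-frequency masks of different areas that
overlap are split by a dividing line whose distances to the two centroids
are proportional to the peak amplitudes (the 3 kHz domains of A1 and VAF,
which converge at their low-frequency poles, are exempt). Per-area masks
are the union of their frequency-domain masks smoothed by morphological
opening and closing (disk radii 30 and 150 px at the reference pixel
scale); remaining inter-area overlaps are removed with a dividing line
through the two boundary intersection points (A1/VAF again exempt).
Tone low-responsive cortex is extracted the same way at a 20% threshold,
and split into the dorsoposterior field (DP) and the centre region (CTR)
by geometric rules expressed in stereotaxic axes.

Seed ROIs are drawn manually in the real workflow; for unattended runs
:func:`propose_seed_rois` matches response peaks against the expected
area geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import linear_sum_assignment
from shapely.geometry import LineString
from skimage.feature import peak_local_max
from skimage.measure import find_contours, label
from skimage.morphology import convex_hull_image

logger = logging.getLogger(__name__)

#: Pixel scale (um/px) at which the default 30/150 px disk radii are defined.
REFERENCE_PIXEL_SCALE_UM = 3.21

TONOTOPIC_AREAS = ("A1", "VAF", "AAF", "A2")

#: Area pairs whose masks are allowed to overlap (A1 and VAF converge at
#: their low-frequency poles).
ALLOWED_OVERLAP = frozenset({frozenset({"A1", "VAF"})})


@dataclass
class SegmentationParams:
    """Thresholds and morphology radii for the parcellation.

    ``threshold_frac`` is the peak-relative level defining frequency-domain
    masks (0.60 default, 0.40 for the permissive variant);
    ``low_threshold_frac`` (0.20) defines tone low-responsive pixels.
    Disk radii are in pixels of the current image grid; use
    :meth:`for_pixel_scale` to rescale the reference 30/150 px radii to a
    different resolution.
    """

    threshold_frac: float = 0.60
    low_threshold_frac: float = 0.20
    open_radius_px: float = 30.0
    close_radius_px: float = 150.0
    connectivity: int = 2  # 8-connectivity

    def __post_init__(self):
        for frac in (self.threshold_frac, self.low_threshold_frac):
            if not 0 < frac < 1:
                raise ValueError("threshold fractions must be in (0, 1)")
        if self.open_radius_px <= 0 or self.close_radius_px <= 0:
            raise ValueError("morphology radii must be positive")

    @classmethod
    def for_pixel_scale(cls, px_scale_um: float, **kwargs) -> "SegmentationParams":
        """Parameters with disk radii rescaled to ``px_scale_um`` um/px."""
        f = REFERENCE_PIXEL_SCALE_UM / px_scale_um
        return cls(
            open_radius_px=max(1.0, 30.0 * f),
            close_radius_px=max(1.0, 150.0 * f),
            **kwargs,
        )


@dataclass
class FrequencyDomain:
    """One area's response patch for one tone frequency."""

    area: str
    frequency_khz: float
    centroid_px: np.ndarray  # (x, y)
    peak_amplitude: float
    mask: np.ndarray  # bool (H, W)
    seed_roi: np.ndarray | None = None


@dataclass
class AreaMask:
    """Binary mask of one cortical area after merging and smoothing."""

    area: str
    mask: np.ndarray
    frequencies: tuple = ()
    peak_amplitude: float = 0.0

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ----------------------------------------------------------------------
# disk morphology via Euclidean distance transforms
# ----------------------------------------------------------------------
# Erosion by a disk of radius r keeps pixels whose distance to the nearest
# background pixel exceeds r; dilation adds pixels within r of the
# foreground. Exact for disk elements and fast even at the 150 px closing
# radius. The image border counts as background.

def erode_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    dist = distance_transform_edt(padded)
    return (dist > radius)[1:-1, 1:-1]


def dilate_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    dist = distance_transform_edt(~mask)
    return dist <= radius


def open_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    return dilate_disk(erode_disk(mask, radius), radius)


def close_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    # pad so the intermediate dilation is not clipped by the frame, which
    # would make the subsequent erosion eat into the original shape
    r = int(np.ceil(radius)) + 1
    padded = np.pad(mask, r, constant_values=False)
    closed = erode_disk(dilate_disk(padded, radius), radius)
    return closed[r:-r, r:-r]


# ----------------------------------------------------------------------
# frequency domains
# ----------------------------------------------------------------------

def disk_roi(shape: tuple[int, int], center_px, radius_px: float) -> np.ndarray:
    """Convenience: a disk-shaped seed ROI mask."""
    h, w = shape
    cx, cy = np.asarray(center_px, dtype=float)
    ys, xs = np.ogrid[:h, :w]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px**2


def compute_domain_centroid(
    magnitude: np.ndarray, seed_roi: np.ndarray
) -> tuple[np.ndarray, float]:
    """Domain centroid and peak amplitude within a seed ROI.

    The centroid is the mean of two locations: the peak-amplitude pixel and
    the amplitude-weighted centre of mass, both restricted to the ROI. The
    result is largely independent of the exact ROI outline as long as the
    ROI contains the response peak.
    """
    mag = np.asarray(magnitude, dtype=float)
    roi = np.asarray(seed_roi, dtype=bool)
    if mag.shape != roi.shape:
        raise ValueError("magnitude and ROI shapes differ")
    if not roi.any():
        raise ValueError("empty seed: ROI contains no pixels")
    vals = np.where(roi, mag, -np.inf)
    peak_flat = int(np.argmax(vals))
    py, px_ = np.unravel_index(peak_flat, mag.shape)
    peak_amp = float(mag[py, px_])
    if peak_amp <= 0:
        raise ValueError("empty seed: no positive response in ROI")
    ys, xs = np.nonzero(roi)
    w = np.clip(mag[ys, xs], 0.0, None)
    com = np.array([np.sum(w * xs), np.sum(w * ys)]) / w.sum()
    centroid = (np.array([px_, py], dtype=float) + com) / 2.0
    return centroid, peak_amp


def extract_domain_mask(
    magnitude: np.ndarray,
    centroid_px,
    peak_amplitude: float,
    threshold_frac: float = 0.60,
    connectivity: int = 2,
) -> np.ndarray:
    """Peak-relative threshold mask: the component around the centroid.

    Thresholds the whole map at ``threshold_frac * peak_amplitude`` and
    keeps the connected component containing the centroid pixel; the mask
    may extend beyond the seed ROI.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold fraction must be in (0, 1)")
    mag = np.asarray(magnitude, dtype=float)
    binary = mag >= threshold_frac * peak_amplitude
    cx, cy = np.asarray(centroid_px, dtype=float)
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < mag.shape[0] and 0 <= ix < mag.shape[1]) or not binary[iy, ix]:
        raise ValueError("centroid is not above the threshold")
    labels = label(binary, connectivity=connectivity)
    return labels == labels[iy, ix]


def dividing_distance(amp_a: float, amp_b: float, separation: float) -> float:
    """Distance from centroid a to the amplitude-weighted dividing line.

    The line sits so its distances to the two centroids are proportional
    to the respective peak amplitudes: ``separation * amp_a / (amp_a+amp_b)``.
    """
    return separation * amp_a / (amp_a + amp_b)


def split_overlapping_domains(
    domain_a: FrequencyDomain, domain_b: FrequencyDomain
) -> tuple[FrequencyDomain, FrequencyDomain]:
    """Split overlapping same-frequency masks with an amplitude-weighted line.

    The dividing line is perpendicular to the centroid-centroid segment;
    each mask is clipped to its own side. Non-overlapping inputs are
    returned unchanged.
    """
    if not np.any(domain_a.mask & domain_b.mask):
        return domain_a, domain_b
    ca, cb = domain_a.centroid_px, domain_b.centroid_px
    sep = float(np.linalg.norm(cb - ca))
    if sep < 1e-9:
        raise ValueError("degenerate split: coincident centroids")
    u = (cb - ca) / sep
    cut = dividing_distance(domain_a.peak_amplitude, domain_b.peak_amplitude, sep)
    h, w = domain_a.mask.shape
    ys, xs = np.ogrid[:h, :w]
    proj = (xs - ca[0]) * u[0] + (ys - ca[1]) * u[1]
    new_a = domain_a.mask & (proj <= cut)
    new_b = domain_b.mask & (proj > cut)
    out_a = FrequencyDomain(domain_a.area, domain_a.frequency_khz,
                            domain_a.centroid_px, domain_a.peak_amplitude,
                            new_a, domain_a.seed_roi)
    out_b = FrequencyDomain(domain_b.area, domain_b.frequency_khz,
                            domain_b.centroid_px, domain_b.peak_amplitude,
                            new_b, domain_b.seed_roi)
    return out_a, out_b


def merge_domains_to_area(
    domains: list[FrequencyDomain], params: SegmentationParams
) -> AreaMask | None:
    """Join a single area's frequency-domain masks and smooth the outline.

    Union of the binary masks, then morphological opening and closing with
    the configured disk radii. Areas lacking clear responses to some tones
    contribute only their responsive domains; an empty input returns
    ``None`` (absent area), not an error.
    """
    domains = [d for d in domains if d is not None]
    if not domains:
        return None
    union = np.zeros_like(domains[0].mask, dtype=bool)
    for d in domains:
        union |= d.mask
    smoothed = close_disk(open_disk(union, params.open_radius_px),
                          params.close_radius_px)
    if not smoothed.any():
        return None
    return AreaMask(
        area=domains[0].area,
        mask=smoothed,
        frequencies=tuple(sorted(d.frequency_khz for d in domains)),
        peak_amplitude=max(d.peak_amplitude for d in domains),
    )


# ----------------------------------------------------------------------
# inter-area overlap removal
# ----------------------------------------------------------------------

def _mask_boundary(mask: np.ndarray):
    """Sub-pixel outline(s) of a binary mask as shapely LineStrings (x, y)."""
    lines = []
    for contour in find_contours(mask.astype(float), 0.5):
        if len(contour) >= 2:
            lines.append(LineString(contour[:, ::-1]))  # (row,col) -> (x,y)
    return lines


def boundary_intersection_points(
    mask_a: np.ndarray, mask_b: np.ndarray, merge_tol_px: float = 2.0
) -> np.ndarray:
    """Points where the outlines of two masks cross, merged within a tolerance."""
    pts = []
    for la in _mask_boundary(mask_a):
        for lb in _mask_boundary(mask_b):
            inter = la.intersection(lb)
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Point":
                    pts.append([g.x, g.y])
                else:  # line-shaped intersection: use representative endpoints
                    pts.extend(np.asarray(g.coords))
    if not pts:
        return np.empty((0, 2))
    pts = np.asarray(pts)
    merged: list[np.ndarray] = []
    for p in pts:
        for i, q in enumerate(merged):
            if np.linalg.norm(p - q) < merge_tol_px:
                merged[i] = (p + q) / 2.0
                break
        else:
            merged.append(p)
    return np.asarray(merged)


def _clip_by_line(mask, p1, p2, keep_positive: bool):
    h, w = mask.shape
    d = p2 - p1
    ys, xs = np.ogrid[:h, :w]
    cross = d[0] * (ys - p1[1]) - d[1] * (xs - p1[0])
    return mask & ((cross >= 0) if keep_positive else (cross < 0))


def resolve_area_overlaps(area_masks: list[AreaMask]) -> list[AreaMask]:
    """Remove pairwise overlaps between area masks.

    For each overlapping pair (A1/VAF exempt) a dividing line through the
    two outline intersection points splits the overlap and each mask keeps
    its own side. When the outlines cross at more than two points, the
    amplitude-weighted perpendicular split is used instead (logged). A
    mask fully nested inside another cannot be resolved and is an error.
    """
    masks = [AreaMask(m.area, m.mask.copy(), m.frequencies, m.peak_amplitude)
             for m in area_masks]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            a, b = masks[i], masks[j]
            if frozenset({a.area, b.area}) in ALLOWED_OVERLAP:
                continue
            overlap = a.mask & b.mask
            if not overlap.any():
                continue
            if (a.mask & ~b.mask).sum() == 0 or (b.mask & ~a.mask).sum() == 0:
                raise ValueError(
                    f"containment unresolved: {a.area} and {b.area} are nested"
                )
            pts = boundary_intersection_points(a.mask, b.mask)
            if len(pts) == 2:
                p1, p2 = pts
                d = p2 - p1
                # which side of the line holds A's exclusive territory?
                ys, xs = np.nonzero(a.mask & ~b.mask)
                cross = d[0] * (ys - p1[1]) - d[1] * (xs - p1[0])
                a_side = bool(np.median(np.sign(cross)) >= 0)
                a.mask = _clip_by_line(a.mask, p1, p2, a_side)
                b.mask = _clip_by_line(b.mask, p1, p2, not a_side)
            else:
                logger.info(
                    "%d boundary intersections between %s and %s; using "
                    "amplitude-weighted fallback split",
                    len(pts), a.area, b.area,
                )
                ca = _mask_centroid(a.mask)
                cb = _mask_centroid(b.mask)
                sep = float(np.linalg.norm(cb - ca))
                if sep < 1e-9:
                    raise ValueError("degenerate split: coincident mask centroids")
                u = (cb - ca) / sep
                cut = dividing_distance(a.peak_amplitude or 1.0,
                                        b.peak_amplitude or 1.0, sep)
                h, w = a.mask.shape
                ys, xs = np.ogrid[:h, :w]
                proj = (xs - ca[0]) * u[0] + (ys - ca[1]) * u[1]
                a.mask = a.mask & (proj <= cut)
                b.mask = b.mask & (proj > cut)
    return masks


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([xs.mean(), ys.mean()])


# ----------------------------------------------------------------------
# tone low-responsive cortex: DP and CTR
# ----------------------------------------------------------------------

def detect_tone_low_responsive(
    magnitude_maps: dict,
    domains: list[FrequencyDomain],
    area_masks: list[AreaMask],
    params: SegmentationParams,
) -> np.ndarray:
    """Marginal cortex responding above 20% but below the area thresholds.

    Re-extracts every frequency domain at the low (20%) threshold, joins
    all of them, smooths the combined outline with the same opening and
    closing, and removes the four tonotopic area masks.
    """
    union = None
    for d in domains:
        if d is None:
            continue
        mag = magnitude_maps[d.frequency_khz]
        try:
            m = extract_domain_mask(
                mag, d.centroid_px, d.peak_amplitude,
                params.low_threshold_frac, params.connectivity,
            )
        except ValueError:
            continue
        union = m if union is None else (union | m)
    if union is None:
        shape = next(iter(magnitude_maps.values())).shape
        return np.zeros(shape, dtype=bool)
    smoothed = close_disk(open_disk(union, params.open_radius_px),
                          params.close_radius_px)
    for am in area_masks:
        if am is not None:
            smoothed &= ~am.mask
    return smoothed


def identify_dp(low_mask: np.ndarray, a1_mask: np.ndarray, transform) -> AreaMask:
    """Dorsoposterior field: low-responsive cortex dorsal to A1's most
    posterior point and posterior to A1's most dorsal point.

    Dorsal/posterior are evaluated in stereotaxic axes via the session
    transform (posterior = more negative AP, dorsal = smaller DV).
    """
    if not a1_mask.any():
        raise ValueError("A1 mask is empty")
    ap, dv = transform.pixel_grid_mm(low_mask.shape)
    a1_ap = np.where(a1_mask, ap, np.inf)
    a1_dv = np.where(a1_mask, dv, np.inf)
    iy, ix = np.unravel_index(np.argmin(a1_ap), ap.shape)
    dv_at_most_posterior = dv[iy, ix]
    iy, ix = np.unravel_index(np.argmin(a1_dv), dv.shape)
    ap_at_most_dorsal = ap[iy, ix]
    mask = low_mask & (dv < dv_at_most_posterior) & (ap < ap_at_most_dorsal)
    return AreaMask("DP", mask)


def fit_tonotopic_axis(points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through domain centroids: (point, direction)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if len(pts) < 2:
        raise ValueError("axis unfittable: need at least 2 centroids")
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean)
    return mean, vt[0]


def identify_ctr(
    low_mask: np.ndarray,
    area_masks: dict,
    aaf_centroids_px: np.ndarray,
    transform,
) -> AreaMask:
    """Centre region: low-responsive cortex enclosed by the tonotopic areas.

    Bounded by (1) the A1/VAF/A2/AAF borders (approximated by the convex
    hull of their union), (2) the iso-DV line through A1's most dorsal
    point, and (3) the total-least-squares fit to the AAF tonotopic axis
    (keeping the A1 side). An empty CTR is a valid result.
    """
    aaf_pts = np.atleast_2d(np.asarray(aaf_centroids_px, dtype=float))
    if len(aaf_pts) < 2:
        raise ValueError("axis unfittable: AAF needs >= 2 frequency domains")
    a1 = area_masks["A1"].mask
    if not a1.any():
        raise ValueError("A1 mask is empty")
    union = np.zeros_like(low_mask)
    for name in TONOTOPIC_AREAS:
        am = area_masks.get(name)
        if am is not None:
            union |= am.mask
    hull = convex_hull_image(union) if union.any() else union
    ap, dv = transform.pixel_grid_mm(low_mask.shape)
    dv_top_a1 = dv[a1].min()

    mean, direction = fit_tonotopic_axis(transform.px_to_mm(aaf_pts))
    signed = (ap - mean[0]) * direction[1] - (dv - mean[1]) * direction[0]
    a1_sign = np.sign(np.median(signed[a1]))
    if a1_sign == 0:
        a1_sign = 1.0
    mask = low_mask & hull & (dv >= dv_top_a1) & (signed * a1_sign > 0)
    return AreaMask("CTR", mask)


# ----------------------------------------------------------------------
# automatic seed proposal
# ----------------------------------------------------------------------

#: Per-area anchor domains for the proposer: each is the area's most
#: isolated frequency domain, with a search box (posterior, anterior,
#: dorsal, ventral margins, um) wide enough for the area's own positional
#: variability. AAF's box is AP-asymmetric because the sampled A1-AAF gap
#: shifts all AAF domains together, mostly anteriorly.
_AREA_ANCHORS = {
    "A1": (10.0, (300.0, 300.0, 300.0, 300.0)),
    "VAF": (10.0, (300.0, 300.0, 300.0, 300.0)),
    "AAF": (10.0, (350.0, 550.0, 250.0, 250.0)),
    "A2": (3.0, (300.0, 300.0, 300.0, 300.0)),
}


def _box_max(mag: np.ndarray, ap_img: np.ndarray, dv_img: np.ndarray,
             center_mm, box_um) -> tuple[np.ndarray | None, float]:
    """Position (px) and value of the map maximum within a stereotaxic box.

    ``box_um`` gives the (posterior, anterior, dorsal, ventral) margins
    around ``center_mm``; the box is axis-aligned in (AP, DV), which is
    rotation-correct regardless of the image orientation.
    """
    post, ant, dors, vent = (b / 1000.0 for b in box_um)
    ap0, dv0 = center_mm
    inside = (
        (ap_img >= ap0 - post) & (ap_img <= ap0 + ant)
        & (dv_img >= dv0 - dors) & (dv_img <= dv0 + vent)
    )
    if not inside.any():
        return None, -np.inf
    vals = np.where(inside, mag, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(vals)), mag.shape)
    return np.array([ix, iy], dtype=float), float(mag[iy, ix])


def _box_max_excluding(mag, ap_img, dv_img, center_mm, box_um,
                       exclude_px, exclude_radius_px):
    """Box max with a disk around a competing peak removed."""
    h, w = mag.shape
    ys, xs = np.ogrid[:h, :w]
    near = ((xs - exclude_px[0]) ** 2 + (ys - exclude_px[1]) ** 2
            <= exclude_radius_px**2)
    masked = np.where(near, -np.inf, mag)
    pos, val = _box_max(masked, ap_img, dv_img, center_mm, box_um)
    return pos if np.isfinite(val) else None


def _is_local_max(mag: np.ndarray, pos_px, halfwidth: int = 2) -> bool:
    """Is ``pos_px`` the maximum of its (2h+1)^2 neighbourhood?"""
    ix, iy = int(round(pos_px[0])), int(round(pos_px[1]))
    h, w = mag.shape
    y0, y1 = max(0, iy - halfwidth), min(h, iy + halfwidth + 1)
    x0, x1 = max(0, ix - halfwidth), min(w, ix + halfwidth + 1)
    return mag[iy, ix] >= mag[y0:y1, x0:x1].max()


def _has_saddle(mag: np.ndarray, p1, p2, depth_frac: float = 0.90) -> bool:
    """Does the profile between two points dip clearly below both peaks?

    Guards against treating a shoulder on a monotone ridge as a separate
    maximum: two bumps count as resolved only when the minimum along the
    connecting segment falls below ``depth_frac`` of the weaker endpoint.
    """
    n = 25
    ts = np.linspace(0.0, 1.0, n)
    xs = np.clip(np.round(p1[0] + ts * (p2[0] - p1[0])).astype(int),
                 0, mag.shape[1] - 1)
    ys = np.clip(np.round(p1[1] + ts * (p2[1] - p1[1])).astype(int),
                 0, mag.shape[0] - 1)
    profile = mag[ys, xs]
    return profile.min() < depth_frac * min(profile[0], profile[-1])


def propose_seed_rois(
    magnitude_maps: dict,
    transform,
    template_mm: dict | None = None,
    roi_radius_um: float = 110.0,
    window_um: float = 260.0,
    peak_min_rel: float = 0.15,
    anchor_min_rel: float = 0.25,
    dedupe_um: float = 150.0,
) -> dict:
    """Propose seed ROIs from response peaks and the expected area geometry.

    Hierarchical template matching in stereotaxic mm: (1) strong local
    maxima are Hungarian-matched against the expected domain positions to
    estimate a whole-map translation; (2) each area's shift is refined
    from an isolated anchor domain (AAF gets a wider anchor window because
    the A1-AAF gap moves all AAF domains together); (3) every domain's
    peak is the window maximum around its predicted position, accepted
    above a noise floor relative to the map maximum. Same-frequency seeds
    that locked onto the same maximum are deduplicated, keeping the
    template whose prediction is closer. Accepted peaks become disk ROIs.
    """
    if template_mm is None:
        from .synthetic import CANONICAL_CENTERS_MM

        template_mm = {k: np.asarray(v, float) for k, v in CANONICAL_CENTERS_MM.items()}

    px_scale = np.sqrt(transform.scale_ap_um * transform.scale_dv_um)
    freqs = sorted(magnitude_maps)
    shape = next(iter(magnitude_maps.values())).shape
    ap_img, dv_img = transform.pixel_grid_mm(shape)

    # pass 1: global translation from strong peaks, estimated iteratively
    # (wide gate + median first, so large whole-map shifts are caught,
    # then a tight gate refines)
    all_peaks_mm = {}
    for f in freqs:
        mag = np.asarray(magnitude_maps[f], dtype=float)
        coords = peak_local_max(
            mag, min_distance=max(1, int(round(250.0 / px_scale))),
            threshold_rel=0.3,
        )
        all_peaks_mm[f] = (
            np.atleast_2d(transform.px_to_mm(coords[:, ::-1].astype(float)))
            if coords.size else np.empty((0, 2))
        )

    global_shift = np.zeros(2)
    for gate_um in (900.0, 400.0):
        residuals = []
        for f in freqs:
            pk_mm = all_peaks_mm[f]
            tkeys = [k for k in template_mm if k[1] == f]
            if not tkeys or len(pk_mm) == 0:
                continue
            tpos = np.array([template_mm[k] for k in tkeys]) + global_shift
            cost = np.linalg.norm(tpos[:, None, :] - pk_mm[None, :, :], axis=2)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] * 1000.0 <= gate_um:
                    residuals.append(pk_mm[c] - tpos[r])
        if residuals:
            global_shift = global_shift + np.median(residuals, axis=0)

    # pass 2: per-area shift from an anchor domain
    areas = sorted({k[0] for k in template_mm})
    area_shift = {}
    for area in areas:
        anchor_freq, box = _AREA_ANCHORS.get(
            area, (freqs[0], (300.0, 300.0, 300.0, 300.0))
        )
        key = (area, anchor_freq)
        shift = global_shift
        if key in template_mm and anchor_freq in magnitude_maps:
            mag = np.asarray(magnitude_maps[anchor_freq], dtype=float)
            pos, val = _box_max(
                mag, ap_img, dv_img,
                np.asarray(template_mm[key]) + global_shift, box,
            )
            if pos is not None and val >= anchor_min_rel * mag.max():
                shift = np.asarray(transform.px_to_mm(pos)) - np.asarray(
                    template_mm[key]
                )
        area_shift[area] = shift

    # pass 3: window max around every predicted domain position
    win = (window_um,) * 4
    peaks: dict[tuple, tuple[np.ndarray, float]] = {}
    half_plane: dict[tuple, np.ndarray] = {}  # seed -> neighbour peak to exclude
    for (area, f), pos_mm in template_mm.items():
        if f not in magnitude_maps:
            continue
        mag = np.asarray(magnitude_maps[f], dtype=float)
        pred_mm = np.asarray(pos_mm) + area_shift[area]
        pos, val = _box_max(mag, ap_img, dv_img, pred_mm, win)
        if pos is not None and val >= peak_min_rel * mag.max():
            pred_px = transform.mm_to_px(pred_mm)
            peaks[(area, f)] = (pos, float(np.linalg.norm(pos - pred_px)))

    # same-frequency seeds that locked onto one maximum: keep the closer
    # template's peak and fall back to the predicted position for the
    # other (a merged blob still has a known pole to seed)
    for f in freqs:
        keys = [k for k in peaks if k[1] == f]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                ka, kb = keys[i], keys[j]
                if ka not in peaks or kb not in peaks:
                    continue
                if np.linalg.norm(peaks[ka][0] - peaks[kb][0]) * px_scale < dedupe_um:
                    loser = ka if peaks[ka][1] > peaks[kb][1] else kb
                    kept = ka if loser is kb else kb
                    mag = np.asarray(magnitude_maps[f], dtype=float)
                    pred_mm = np.asarray(template_mm[loser]) + area_shift[loser[0]]
                    pred_px = np.asarray(transform.mm_to_px(pred_mm))
                    # is there a genuine separate maximum near the predicted
                    # pole, away from the winner's peak?
                    restricted = _box_max_excluding(
                        mag, ap_img, dv_img, pred_mm, (150.0,) * 4,
                        peaks[kept][0], dedupe_um / px_scale,
                    )
                    if (restricted is not None
                            and _is_local_max(mag, restricted)
                            and _has_saddle(mag, peaks[kept][0], restricted)):
                        logger.info("seed %s resolved on re-search", loser)
                        peaks[loser] = (restricted,
                                        float(np.linalg.norm(restricted - pred_px)))
                        continue
                    ix, iy = int(round(pred_px[0])), int(round(pred_px[1]))
                    inside = 0 <= iy < mag.shape[0] and 0 <= ix < mag.shape[1]
                    if inside and mag[iy, ix] >= peak_min_rel * mag.max():
                        logger.info("seed %s collided; using predicted pole", loser)
                        peaks[loser] = (pred_px, 0.0)
                        # clip both ROIs away from each other's pole
                        half_plane[loser] = peaks[kept][0]
                        half_plane[kept] = pred_px
                    else:
                        logger.info("dropping duplicate seed %s", loser)
                        del peaks[loser]

    roi_radius_px = roi_radius_um / px_scale
    rois = {}
    for key, (pos, _) in peaks.items():
        roi = disk_roi(shape, pos, roi_radius_px)
        if key in half_plane:
            # a merged blob: keep only the half of the ROI facing away
            # from the neighbouring peak, as a hand-drawn ROI would
            u = pos - half_plane[key]
            ys, xs = np.ogrid[:shape[0], :shape[1]]
            roi &= ((xs - pos[0]) * u[0] + (ys - pos[1]) * u[1]) >= 0
        rois[key] = roi
    return rois


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """All parcellation outputs for one session."""

    domains: dict = field(default_factory=dict)  # (area, freq) -> FrequencyDomain
    areas: dict = field(default_factory=dict)  # area -> AreaMask | None
    low_mask: np.ndarray | None = None
    dp: AreaMask | None = None
    ctr: AreaMask | None = None
    failures: dict = field(default_factory=dict)  # (area, freq) -> reason

    def all_area_masks(self) -> dict:
        out = {k: v for k, v in self.areas.items() if v is not None}
        if self.dp is not None:
            out["DP"] = self.dp
        if self.ctr is not None:
            out["CTR"] = self.ctr
        return out


def run_segmentation(
    magnitude_maps: dict,
    seed_rois: dict,
    params: SegmentationParams | None = None,
    transform=None,
    detect_marginal: bool = True,
) -> SegmentationResult:
    """Run the full parcellation for one session.

    ``magnitude_maps`` maps frequency (kHz) to the processed response
    magnitude image; ``seed_rois`` maps (area, frequency) to boolean seed
    ROI masks. DP and CTR are computed only when a stereotaxic
    ``transform`` is supplied (their definitions need the AP/DV axes).
    """
    params = params or SegmentationParams()
    result = SegmentationResult()

    for (area, freq), roi in sorted(seed_rois.items()):
        mag = magnitude_maps[freq]
        try:
            centroid, peak = compute_domain_centroid(mag, roi)
            mask = extract_domain_mask(
                mag, centroid, peak, params.threshold_frac, params.connectivity
            )
            result.domains[(area, freq)] = FrequencyDomain(
                area, freq, centroid, peak, mask, roi
            )
        except ValueError as exc:
            result.failures[(area, freq)] = str(exc)

    # same-frequency overlap splitting (A1/VAF exempt at 3 kHz)
    for freq in sorted(magnitude_maps):
        present = [k for k in result.domains if k[1] == freq]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                ka, kb = present[i], present[j]
                pair = frozenset({ka[0], kb[0]})
                if pair in ALLOWED_OVERLAP and freq == 3.0:
                    continue
                da, db = result.domains[ka], result.domains[kb]
                da, db = split_overlapping_domains(da, db)
                result.domains[ka], result.domains[kb] = da, db

    for area in TONOTOPIC_AREAS:
        members = [d for (a, _), d in result.domains.items() if a == area]
        result.areas[area] = merge_domains_to_area(members, params)

    present_masks = [m for m in result.areas.values() if m is not None]
    resolved = resolve_area_overlaps(present_masks)
    for m in resolved:
        result.areas[m.area] = m

    if detect_marginal:
        result.low_mask = detect_tone_low_responsive(
            magnitude_maps, list(result.domains.values()), resolved, params
        )
        if transform is not None and result.areas.get("A1") is not None:
            result.dp = identify_dp(
                result.low_mask, result.areas["A1"].mask, transform
            )
            aaf_pts = np.array([
                d.centroid_px for (a, _), d in sorted(result.domains.items())
                if a == "AAF"
            ])
            if len(aaf_pts) >= 2:
                try:
                    result.ctr = identify_ctr(
                        result.low_mask & ~result.dp.mask,
                        result.areas, aaf_pts, transform,
                    )
                except ValueError:
                    result.ctr = None
    return result
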