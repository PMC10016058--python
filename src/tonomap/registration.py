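"""Skull-mark based stereotaxic registration.

Three ink marks are placed on the skull at nominal bregma-relative
coordinates (P, V) = (-2.5, 1.5), (-3.5, 1.5), (-3.5, 2.0) mm, each scaled
by BLdist / 4.2 to compensate for skull size. Marks 1->2 span the AP axis
(1 mm x BLdist/4.2) and marks 2->3 the DV axis (0.5 mm x BLdist/4.2).
From the pixel positions of the three marks this module recovers the
rotation of the imaged plane, independent AP/DV pixel scales, and the
bregma offset, i.e. a full :class:`~tonomap.coords.StereotaxicTransform`.

When slight skull curvature makes the two mark segments non-perpendicular,
mark 2 is replaced by the foot of the perpendicular dropped from mark 1
onto the mark 2-3 line ("adjusted mark 2"), which restores an exactly
orthogonal frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import STANDARD_BLDIST_MM, StereotaxicTransform, axis_vectors

#: Nominal (P, V) mm coordinates of the three skull reference marks.
NOMINAL_MARKS_MM = np.array([[-2.5, 1.5], [-3.5, 1.5], [-3.5, 2.0]])

#: Acceptable range (degrees) for the raw angle between the two mark segments.
_ANGLE_RANGE_DEG = (80.0, 100.0)


@dataclass(frozen=True)
class ReferenceMarks:
    """Pixel positions of the three skull marks plus the animal's BLdist."""

    pixels: np.ndarray  # (3, 2) float, (x, y)
    bldist_mm: float
    nominal_mm: np.ndarray = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.shape != (3, 2):
            raise ValueError("expected exactly 3 (x, y) mark positions")
        if self.bldist_mm <= 0:
            raise ValueError("BLdist must be positive")
        object.__setattr__(self, "pixels", px)
        nom = self.nominal_mm if self.nominal_mm is not None else NOMINAL_MARKS_MM
        object.__setattr__(self, "nominal_mm", np.asarray(nom, dtype=float))


def scaled_reference_coordinates(
    bldist_mm: float, nominal_mm: np.ndarray | None = None
) -> np.ndarray:
    """Nominal mark coordinates scaled by ``BLdist / 4.2`` (mm)."""
    if bldist_mm <= 0:
        raise ValueError("BLdist must be positive")
    nom = NOMINAL_MARKS_MM if nominal_mm is None else np.asarray(nominal_mm, float)
    return nom * (bldist_mm / STANDARD_BLDIST_MM)


def adjust_mark2(marks_px) -> np.ndarray:
    """Foot of the perpendicular from mark 1 onto the mark 2-3 line.

    If the raw segments are already perpendicular this equals raw mark 2.
    Raises if mark 1 lies on the 2-3 line (collinear marks, no unique
    orthogonal frame).
    """
    m1, m2, m3 = (np.asarray(m, dtype=float) for m in marks_px)
    d = m3 - m2
    norm2 = float(d @ d)
    if norm2 == 0.0:
        raise ValueError("marks 2 and 3 coincide")
    t = float((m1 - m2) @ d) / norm2
    foot = m2 + t * d
    if np.allclose(foot, m1):
        raise ValueError("collinear marks: mark 1 lies on the mark 2-3 line")
    return foot


def fit_transform(marks: ReferenceMarks) -> StereotaxicTransform:
    """Build the pixel -> stereotaxic transform from the three marks.

    AP axis = adjusted-mark-2 -> mark-1 direction (anterior); DV axis =
    adjusted-mark-2 -> mark-3 direction (ventral). AP/DV pixel scales come
    from the known scaled mark spacings (1 and 0.5 mm x BLdist/4.2); the
    bregma offset anchors mark 1 at its scaled nominal coordinates.
    """
    m1, m2, m3 = marks.pixels
    raw_ab = m1 - m2
    raw_bc = m3 - m2
    la, lb = np.linalg.norm(raw_ab), np.linalg.norm(raw_bc)
    if la < 1.0 or lb < 1.0:
        raise ValueError("degenerate mark spacing (< 1 px)")
    cosang = float(raw_ab @ raw_bc) / (la * lb)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if not (_ANGLE_RANGE_DEG[0] < ang < _ANGLE_RANGE_DEG[1]):
        raise ValueError(
            f"angle between mark segments is {ang:.1f} deg, outside "
            f"{_ANGLE_RANGE_DEG}; marks are unreliable"
        )

    adj2 = adjust_mark2(marks.pixels)
    ap_vec = m1 - adj2
    dv_vec = m3 - adj2
    len_ap = np.linalg.norm(ap_vec)
    len_dv = np.linalg.norm(dv_vec)
    if len_ap < 1.0 or len_dv < 1.0:
        raise ValueError("degenerate adjusted mark spacing (< 1 px)")
    e_a = ap_vec / len_ap
    e_v = dv_vec / len_dv
    # handedness: ventral must be +90 deg from anterior in (x right, y down)
    if float(e_v @ np.array([-e_a[1], e_a[0]])) <= 0:
        raise ValueError("mark frame has flipped handedness")

    factor = marks.bldist_mm / STANDARD_BLDIST_MM
    nominal = marks.nominal_mm
    span_ap_mm = abs(nominal[0, 0] - nominal[1, 0]) * factor
    span_dv_mm = abs(nominal[2, 1] - nominal[1, 1]) * factor
    scale_ap = span_ap_mm * 1000.0 / len_ap
    scale_dv = span_dv_mm * 1000.0 / len_dv
    theta = float(np.arctan2(-e_a[1], e_a[0]))

    # anchor: mark 1 sits at its scaled nominal stereotaxic coordinates
    p1 = nominal[0] * factor
    e_a_t, e_v_t = axis_vectors(theta)
    bregma_px = (
        m1
        - e_a_t * (p1[0] * 1000.0 / scale_ap)
        - e_v_t * (p1[1] * 1000.0 / scale_dv)
    )
    return StereotaxicTransform(
        theta_rad=theta,
        scale_ap_um=scale_ap,
        scale_dv_um=scale_dv,
        bregma_px=bregma_px,
        bldist_mm=marks.bldist_mm,
    )


# ----------------------------------------------------------------------
# histology-based coordinate estimation (dye deposits)
# ----------------------------------------------------------------------

def histology_ventral_coordinate(
    v_top: float, v_bottom: float, a: float, b: float
) -> float:
    """Rescale a deposit depth within a histology section onto atlas DV.

    ``a`` is the histology section height, ``b`` the distance from the
    section top to the deposit centre; the deposit's ventral coordinate is
    the linear interpolation ``v_top + (v_bottom - v_top) * b / a``.
    """
    if a <= 0:
        raise ValueError("section height must be positive")
    if not (0 <= b <= a):
        raise ValueError("deposit distance b must lie within [0, a]")
    if v_bottom <= v_top:
        raise ValueError("v_bottom must be ventral of (greater than) v_top")
    return v_top + (v_bottom - v_top) * b / a


def reconstruct_border_at_deposit(
    border_px,
    craniotomy_px,
    deposit_mm,
    orientation_rad: float = 0.370,
    scale_ap_um: float = 3.13,
    scale_dv_um: float = 3.10,
) -> np.ndarray:
    """Place an imaged area border into stereotaxic mm around a dye deposit.

    Sessions without skull marks cannot be registered directly; instead the
    border polygon (image pixels) is rotated/scaled with population-mean
    orientation and pixel scales and translated so the craniotomy point maps
    onto the histologically determined deposit coordinates.
    """
    border = np.atleast_2d(np.asarray(border_px, dtype=float))
    cran = np.asarray(craniotomy_px, dtype=float)
    dep = np.asarray(deposit_mm, dtype=float)
    e_a, e_v = axis_vectors(orientation_rad)
    d = border - cran
    ap = d @ e_a * scale_ap_um / 1000.0 + dep[0]
    dv = d @ e_v * scale_dv_um / 1000.0 + dep[1]
    return np.column_stack([ap, dv])
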