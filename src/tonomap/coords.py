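"""Stereotaxic coordinate conventions and the pixel <-> millimetre transform.

Conventions used throughout the package (stated once, enforced here):

* Stereotaxic coordinates are ``(AP, DV)`` in millimetres. AP is negative
  posterior to bregma (a point 2.5 mm behind bregma has AP = -2.5); DV is
  positive ventral (deeper / more lateral-ventral on the skull surface).
* Image pixel coordinates are ``(x, y)`` with x increasing rightward
  (column index) and y increasing downward (row index).
* The in-image anterior unit vector is ``e_A = (cos theta, -sin theta)``
  and the ventral unit vector is ``e_V = (sin theta, cos theta)``, where
  ``theta`` is the map orientation in radians. With theta > 0 the posterior
  end of the AP axis points below the image horizontal ("posterior side
  down"); theta = 0 means anterior is exactly rightward and ventral exactly
  downward.

Three coordinate systems describe the same physical plane:

* ``bregma_absolute`` — raw millimetres from bregma.
* ``lambda_absolute`` — AP shifted by +BLdist so lambda sits at 0.
* ``bl_normalized``   — AP multiplied by 4.2 / BLdist so lambda sits at
  -4.2 mm regardless of skull size; DV is never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Standard bregma-lambda distance (mm) of the reference adult skull.
STANDARD_BLDIST_MM = 4.2

COORDINATE_SYSTEMS = ("bregma_absolute", "lambda_absolute", "bl_normalized")


def axis_vectors(theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Return the anterior and ventral unit vectors in pixel space."""
    e_a = np.array([np.cos(theta), -np.sin(theta)])
    e_v = np.array([np.sin(theta), np.cos(theta)])
    return e_a, e_v


@dataclass(frozen=True)
class StereotaxicTransform:
    """Affine map between image pixels and stereotaxic (AP, DV) millimetres.

    Parameters
    ----------
    theta_rad:
        Orientation of the AP axis in the image (see module docstring).
    scale_ap_um, scale_dv_um:
        Micrometres per pixel along the AP and DV axes (both > 0).
    bregma_px:
        Pixel coordinates (x, y) of bregma; may lie outside the image.
    bldist_mm:
        Bregma-lambda distance of this animal, used by the coordinate-system
        conversions.
    system:
        Tag of the coordinate system that :meth:`px_to_mm` emits.
    """

    theta_rad: float
    scale_ap_um: float
    scale_dv_um: float
    bregma_px: np.ndarray
    bldist_mm: float = STANDARD_BLDIST_MM
    system: str = "bregma_absolute"

    def __post_init__(self):
        if self.scale_ap_um <= 0 or self.scale_dv_um <= 0:
            raise ValueError("pixel scales must be positive")
        if self.bldist_mm <= 0:
            raise ValueError("BLdist must be positive")
        if self.system not in COORDINATE_SYSTEMS:
            raise ValueError(f"unknown coordinate system {self.system!r}")
        object.__setattr__(self, "bregma_px", np.asarray(self.bregma_px, dtype=float))

    # ------------------------------------------------------------------
    def px_to_mm(self, points_px) -> np.ndarray:
        """Map pixel (x, y) points to (AP, DV) mm in ``self.system``."""
        p = np.atleast_2d(np.asarray(points_px, dtype=float))
        e_a, e_v = axis_vectors(self.theta_rad)
        d = p - self.bregma_px
        ap = d @ e_a * self.scale_ap_um / 1000.0
        dv = d @ e_v * self.scale_dv_um / 1000.0
        out = to_coordinate_system(
            np.column_stack([ap, dv]), self.system, self.bldist_mm
        )
        return out if np.asarray(points_px).ndim > 1 else out[0]

    def mm_to_px(self, points_mm) -> np.ndarray:
        """Inverse of :meth:`px_to_mm`."""
        q = np.atleast_2d(np.asarray(points_mm, dtype=float))
        q = from_coordinate_system(q, self.system, self.bldist_mm)
        e_a, e_v = axis_vectors(self.theta_rad)
        px = (
            self.bregma_px
            + np.outer(q[:, 0] * 1000.0 / self.scale_ap_um, e_a)
            + np.outer(q[:, 1] * 1000.0 / self.scale_dv_um, e_v)
        )
        return px if np.asarray(points_mm).ndim > 1 else px[0]

    def with_system(self, system: str) -> "StereotaxicTransform":
        if system not in COORDINATE_SYSTEMS:
            raise ValueError(f"unknown coordinate system {system!r}")
        return replace(self, system=system)

    # ------------------------------------------------------------------
    def pixel_grid_mm(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel AP and DV images (mm) for an image of the given shape."""
        h, w = shape
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        e_a, e_v = axis_vectors(self.theta_rad)
        dx = xs - self.bregma_px[0]
        dy = ys - self.bregma_px[1]
        ap = (dx * e_a[0] + dy * e_a[1]) * self.scale_ap_um / 1000.0
        dv = (dx * e_v[0] + dy * e_v[1]) * self.scale_dv_um / 1000.0
        pts = to_coordinate_system(
            np.column_stack([ap.ravel(), dv.ravel()]), self.system, self.bldist_mm
        )
        return pts[:, 0].reshape(h, w), pts[:, 1].reshape(h, w)


def to_coordinate_system(points_mm, system: str, bldist_mm: float) -> np.ndarray:
    """Convert bregma-absolute (AP, DV) points into the requested system.

    ``lambda_absolute`` shifts AP by +BLdist (lambda becomes the origin);
    ``bl_normalized`` multiplies AP by 4.2 / BLdist so lambda maps to
    -4.2 mm. DV coordinates are never rescaled.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)).copy()
    if system == "bregma_absolute":
        pass
    elif system == "lambda_absolute":
        pts[:, 0] = pts[:, 0] + bldist_mm
    elif system == "bl_normalized":
        pts[:, 0] = pts[:, 0] * (STANDARD_BLDIST_MM / bldist_mm)
    else:
        raise ValueError(f"unknown coordinate system {system!r}")
    return pts


def from_coordinate_system(points_mm, system: str, bldist_mm: float) -> np.ndarray:
    """Convert points in ``system`` back to bregma-absolute coordinates."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)).copy()
    if system == "bregma_absolute":
        pass
    elif system == "lambda_absolute":
        pts[:, 0] = pts[:, 0] - bldist_mm
    elif system == "bl_normalized":
        pts[:, 0] = pts[:, 0] * (bldist_mm / STANDARD_BLDIST_MM)
    else:
        raise ValueError(f"unknown coordinate system {system!r}")
    return pts
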