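"""3D cardiopulmonary morphometry from a label map.

All 16 reported features are measured on transversal (axial) slices:
per-structure cross-sectional areas, diameters on the maximal-area slice
(equivalent-circle diameter for vessels, maximum Feret diameter for
chambers), and the four diameter ratios MPAd/AAd, RPAd/LPAd, RVd/LVd,
RAd/LAd.  An absent structure propagates as a missing value, never as an
exception.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import label as cc_label

from .volio import CHAMBERS, LabelMap, STRUCTURE_CODES, VESSELS

#: Ratio features and their (numerator, denominator) components.
RATIOS = {
    "MPAd/AAd": ("MPAd", "AAd"),
    "RPAd/LPAd": ("RPAd", "LPAd"),
    "RVd/LVd": ("RVd", "LVd"),
    "RAd/LAd": ("RAd", "LAd"),
}


def _largest_component(plane: np.ndarray) -> np.ndarray:
    """Largest 4-connected in-plane component of a binary 2D mask."""
    lab, n = cc_label(plane, connectivity=1, return_num=True)
    if n == 0:
        return np.zeros_like(plane, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def axial_areas(labels: LabelMap, structure: str) -> np.ndarray:
    """Per-slice cross-sectional area (mm²) of one structure.

    Each slice contributes the pixel count of its largest 4-connected
    component times the in-plane pixel area; empty slices contribute 0.
    """
    mask = labels.mask(structure)
    pix_area = labels.spacing[0] * labels.spacing[1]
    areas = np.zeros(mask.shape[2])
    for k in range(mask.shape[2]):
        plane = mask[:, :, k]
        if plane.any():
            areas[k] = _largest_component(plane).sum() * pix_area
    return areas


def structure_area(labels: LabelMap, structure: str) -> float | None:
    """Maximal axial cross-sectional area (mm²); None if absent."""
    if not labels.mask(structure).any():
        return None
    return float(axial_areas(labels, structure).max())


def feret_diameter(plane: np.ndarray, spacing2d: tuple[float, float]) -> float:
    """Maximum Feret (caliper) diameter of a 2D binary region, in mm.

    Measured over pixel *corners*, i.e. the caliper diameter of the union
    of pixel squares — exact for axis-aligned rectangles (an s-mm square
    measures s·√2).  The convex hull of pixel centers prunes candidates
    first; this is exact because the corner set is the Minkowski sum of the
    centers with one pixel's corners, so extreme corners belong to
    center-hull pixels.
    """
    idx = np.argwhere(plane)
    if len(idx) == 0:
        raise ValueError("empty cross-section")
    sp = np.asarray(spacing2d)
    pts = idx * sp
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    half = sp / 2.0
    offs = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]]) * half
    corners = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    d2 = ((corners[:, None, :] - corners[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def structure_diameter(labels: LabelMap, structure: str) -> float | None:
    """Diameter (mm) of one structure on its maximal-area axial slice.

    Vessels (MPA, RPA, LPA, AA) use the equivalent-circle diameter
    2·sqrt(area/π); chambers (LV, RV, LA, RA) use the maximum Feret
    diameter of the cross-section.  None if the structure is absent.
    """
    mask = labels.mask(structure)
    if not mask.any():
        return None
    areas = axial_areas(labels, structure)
    k = int(areas.argmax())
    if structure in VESSELS:
        return 2.0 * math.sqrt(areas[k] / math.pi)
    if structure in CHAMBERS:
        plane = _largest_component(mask[:, :, k])
        return feret_diameter(plane, labels.spacing[:2])
    raise KeyError(f"unknown structure {structure!r}")


def morpho_record(labels: LabelMap) -> dict:
    """All 16 morphological features, with None for missing values.

    Keys: the eight diameters (mm), the four chamber areas (mm²), and the
    four ratios; a ratio is missing whenever either component is missing.
    """
    rec: dict[str, float | None] = {}
    for s in VESSELS + CHAMBERS:
        rec[f"{s}d"] = structure_diameter(labels, s)
    for s in CHAMBERS:
        rec[f"{s}a"] = structure_area(labels, s)
    for name, (num, den) in RATIOS.items():
        a, b = rec.get(num), rec.get(den)
        rec[name] = None if (a is None or b is None or b == 0) else a / b
    return rec
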