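"""Per-nucleus ellipse morphometry and orientation statistics.

Each segmented nucleus is summarized by its moment-equivalent ellipse (the
ellipse with the region's area, centroid and second central moments — what
ImageJ's *Fit Ellipse* computes).  The orientation angle φ of the major
axis is measured counterclockwise from the +x axis, the direction of
uniaxial stretch, and folded into (−90°, 90°]; the orientation parameter
cos(2φ) maps parallel alignment to +1 and perpendicular alignment to −1
and is invariant to the 180° axis ambiguity.

Orientation classes follow the published ranges: cos(2φ) in [−1, −0.5] is
perpendicular, [0.5, 1] parallel, anything between oblique.  Near-circular
nuclei (eccentricity below a configurable threshold, default 0.2) have no
meaningful axis: their class is ``undefined`` and they are excluded from
orientation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

__all__ = [
    "NucleusRecord",
    "CellRecord",
    "fit_ellipse",
    "measure_labels",
    "records_to_frame",
    "orientation_parameter",
    "classify_orientation",
    "nc_ratio",
    "MIN_NUCLEUS_PX",
    "CIRCULARITY_ECC_THRESHOLD",
]

MIN_NUCLEUS_PX = 25               # below this the fit is segmentation debris
CIRCULARITY_ECC_THRESHOLD = 0.2   # below this eccentricity, φ is undefined

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class NucleusRecord:
    label: int
    centroid: tuple[float, float]       # (x, y) pixels
    semi_major: float                   # a, pixels
    semi_minor: float                   # b, pixels
    phi: float                          # degrees in (−90, 90]
    cos2phi: float
    area_um2: float
    eccentricity: float
    orientation_class: str              # perpendicular | parallel | oblique | undefined
    n_pixels: int = 0
    valid: bool = True                  # False for sub-threshold regions


@dataclass
class CellRecord:
    cell_area_um2: float
    nuclear_area_um2: float
    nc_ratio: float


def _fold(phi: float) -> float:
    phi = (phi + 90.0) % 180.0 - 90.0
    return 90.0 if phi == -90.0 else phi


def orientation_parameter(phi: float) -> float:
    """cos(2φ) for φ in degrees: +1 parallel to stretch, −1 perpendicular."""
    if not np.isfinite(phi):
        raise ValueError(f"phi must be finite, got {phi}")
    return float(np.cos(2.0 * np.deg2rad(phi)))


def classify_orientation(cos2phi: float, eccentricity: float = 1.0,
                         circularity_threshold: float = CIRCULARITY_ECC_THRESHOLD) -> str:
    """Orientation class from cos(2φ), with a circularity guard.

    Published ranges: −1 ≤ cos(2φ) ≤ −0.5 → perpendicular;
    0.5 ≤ cos(2φ) ≤ 1 → parallel; otherwise oblique.  Objects rounder than
    the eccentricity threshold are ``undefined`` regardless of cos(2φ).
    """
    if not (-1.0 - 1e-12 <= cos2phi <= 1.0 + 1e-12):
        raise ValueError(f"cos2phi out of [-1, 1]: {cos2phi}")
    if eccentricity < circularity_threshold:
        return "undefined"
    if cos2phi <= -0.5:
        return "perpendicular"
    if cos2phi >= 0.5:
        return "parallel"
    return "oblique"


def fit_ellipse(region: np.ndarray, pixel_size: float,
                min_size: int = MIN_NUCLEUS_PX,
                circularity_threshold: float = CIRCULARITY_ECC_THRESHOLD,
                label: int = 1) -> NucleusRecord:
    """Moment-equivalent ellipse of a single binary region.

    The region must be one 8-connected component.  Area is the pixel count
    times pixel_size²; φ is the major-axis angle versus the +x (stretch)
    axis folded into (−90°, 90°].  Regions below ``min_size`` pixels return
    a record flagged ``valid=False`` (excluded from summaries downstream).
    """
    mask = np.asarray(region, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty region")
    _, n_comp = ndi.label(mask, structure=_EIGHT)
    if n_comp != 1:
        raise ValueError(f"region must be a single 8-connected component, got {n_comp}")

    rp = regionprops(mask.astype(np.uint8))[0]
    cy, cx = rp.centroid
    a = rp.axis_major_length / 2.0
    b = rp.axis_minor_length / 2.0
    # regionprops orientation: angle of major axis vs the row axis (CCW,
    # (−π/2, π/2]); versus +x with y up this is orientation − 90°, folded
    phi = _fold(np.rad2deg(rp.orientation) - 90.0)
    c2p = orientation_parameter(phi)
    ecc = float(rp.eccentricity)
    return NucleusRecord(
        label=label, centroid=(float(cx), float(cy)),
        semi_major=float(a), semi_minor=float(b), phi=float(phi),
        cos2phi=c2p, area_um2=n_px * pixel_size ** 2, eccentricity=ecc,
        orientation_class=classify_orientation(c2p, ecc, circularity_threshold),
        n_pixels=n_px, valid=n_px >= min_size)


def measure_labels(labels: np.ndarray, pixel_size: float,
                   min_size: int = MIN_NUCLEUS_PX,
                   circularity_threshold: float = CIRCULARITY_ECC_THRESHOLD) -> list[NucleusRecord]:
    """Fit every labeled object in a label mask; one record per label."""
    labels = np.asarray(labels)
    out = []
    for rp in regionprops(labels):
        n_px = int(rp.area)
        cy, cx = rp.centroid
        a = rp.axis_major_length / 2.0
        b = rp.axis_minor_length / 2.0
        phi = _fold(np.rad2deg(rp.orientation) - 90.0)
        c2p = orientation_parameter(phi)
        ecc = float(rp.eccentricity)
        out.append(NucleusRecord(
            label=int(rp.label), centroid=(float(cx), float(cy)),
            semi_major=float(a), semi_minor=float(b), phi=float(phi),
            cos2phi=c2p, area_um2=n_px * pixel_size ** 2, eccentricity=ecc,
            orientation_class=classify_orientation(c2p, ecc, circularity_threshold),
            n_pixels=n_px, valid=n_px >= min_size))
    return out


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """NucleusRecords as a tidy DataFrame (fixed column order)."""
    return pd.DataFrame([{
        "label": r.label, "centroid_x": r.centroid[0], "centroid_y": r.centroid[1],
        "semi_major_px": r.semi_major, "semi_minor_px": r.semi_minor,
        "phi_deg": r.phi, "cos2phi": r.cos2phi, "area_um2": r.area_um2,
        "eccentricity": r.eccentricity, "orientation_class": r.orientation_class,
        "n_pixels": r.n_pixels, "valid": r.valid,
    } for r in records])


def nc_ratio(nuclear_mask: np.ndarray, cell_mask: np.ndarray,
             pixel_size: float = 1.0) -> CellRecord:
    """Nuclear-to-cytoplasmic area ratio: nuclear area / total cell area.

    The nuclear mask must be contained in the cell mask.  A nucleus filling
    the whole cell gives ratio 1.0 with a containment warning.
    """
    nuc = np.asarray(nuclear_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not nuc.any() or not cell.any():
        raise ValueError("empty mask")
    if (nuc & ~cell).any():
        raise ValueError("nuclear mask is not contained in the cell mask")
    n_area = nuc.sum() * pixel_size ** 2
    c_area = cell.sum() * pixel_size ** 2
    ratio = float(n_area / c_area)
    if ratio >= 1.0:
        import warnings
        warnings.warn("nucleus fills the entire cell mask (N/C = 1)", stacklevel=2)
    return CellRecord(cell_area_um2=float(c_area), nuclear_area_um2=float(n_area),
                      nc_ratio=ratio)
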