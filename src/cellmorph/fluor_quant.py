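"""Corrected total cell fluorescence (CTCF) of nuclear Src signal.

CTCF removes the uniform background contribution from an integrated
fluorescence measurement:

    integrated density = nuclear mean intensity × nuclear area
    CTCF = integrated density − background mean intensity × nuclear area

Background is estimated per cell from an annular ring just outside the
cell mask (dilation by gap+width minus dilation by gap, with any
neighboring cells excluded), or optionally from the whole image outside
all cells.  No smoothing or outlier rejection is applied — the two
formulas above hold exactly, so CTCF is invariant to a global intensity
offset and exactly linear in a global intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grids import ImageGrid

__all__ = [
    "CTCFRecord",
    "background_ring",
    "ctcf",
    "condition_fold_change",
    "DEFAULT_RING_GAP",
    "DEFAULT_RING_WIDTH",
]

DEFAULT_RING_GAP = 2     # px between cell edge and ring
DEFAULT_RING_WIDTH = 5   # px radial thickness of the ring


@dataclass
class CTCFRecord:
    object_id: int
    nuclear_area: float             # pixels (or µm² when calibrated)
    nuclear_mean_intensity: float
    integrated_density: float       # mean × area, exact
    background_mean: float
    ctcf: float                     # integrated density − background mean × area


def background_ring(cell_mask: np.ndarray, gap: int = DEFAULT_RING_GAP,
                    width: int = DEFAULT_RING_WIDTH,
                    other_cells: np.ndarray | None = None,
                    object_id: int = 0) -> np.ndarray:
    """Annular background region around a cell.

    Pixels whose Euclidean distance to the cell satisfies
    gap < d ≤ gap + width, excluding pixels of any other cell mask.
    Raises if the ring is fully clipped by the image border or neighbors.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if width < 1:
        raise ValueError("width must be >= 1")
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ValueError("empty cell mask")
    d = ndi.distance_transform_edt(~cell)
    ring = (d > gap) & (d <= gap + width)
    if other_cells is not None:
        ring &= ~np.asarray(other_cells, dtype=bool)
    if not ring.any():
        raise ValueError(
            f"background ring for object {object_id} is empty (clipped by "
            f"image border or neighboring cells)")
    return ring


def ctcf(src: ImageGrid | np.ndarray, nuclear_mask: np.ndarray,
         background_mask: np.ndarray, object_id: int = 0,
         pixel_size: float | None = None) -> CTCFRecord:
    """Corrected total cell fluorescence of one nucleus.

    Areas are in pixels unless ``pixel_size`` is given, in which case both
    the integrated density and the background term use µm² consistently
    (CTCF scales by the same global factor either way).
    """
    data = src.data if isinstance(src, ImageGrid) else np.asarray(src, dtype=float)
    nuc = np.asarray(nuclear_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if not nuc.any():
        raise ValueError("empty nuclear mask")
    if not bg.any():
        raise ValueError("empty background mask")
    if nuc.shape != data.shape or bg.shape != data.shape:
        raise ValueError("mask shape does not match image shape")
    area = float(nuc.sum())
    if pixel_size is not None:
        area *= pixel_size ** 2
    mean_int = float(data[nuc].mean())
    integ = mean_int * area
    bg_mean = float(data[bg].mean())
    return CTCFRecord(object_id=object_id, nuclear_area=area,
                      nuclear_mean_intensity=mean_int, integrated_density=integ,
                      background_mean=bg_mean, ctcf=integ - bg_mean * area)


def condition_fold_change(ctcf_a, ctcf_b) -> dict:
    """Fold change of mean CTCF between two conditions: mean(A) / mean(B).

    CTCF values can legitimately be negative per object; the fold change is
    only meaningful for positive group means, so non-positive means raise.
    Returns the fold together with group sizes, means and SEMs.
    """
    a = np.asarray(list(ctcf_a), dtype=float)
    b = np.asarray(list(ctcf_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ma, mb = float(a.mean()), float(b.mean())
    if ma <= 0 or mb <= 0:
        raise ValueError(f"non-positive group mean (A={ma:g}, B={mb:g}); "
                         "screen CTCF values before computing a fold change")
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return {"fold": ma / mb, "n_a": int(a.size), "n_b": int(b.size),
            "mean_a": ma, "mean_b": mb, "sem_a": sem(a), "sem_b": sem(b)}
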