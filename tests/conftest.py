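"""Shared fixtures: analytic rasters with known dimensions and shapes."""

import math

import numpy as np
import pytest
from skimage.draw import line as sk_line


def render_ellipse(shape, cy, cx, a, b, phi_deg):
    """Filled ellipse raster; phi measured CCW from +x with y up."""
    from cellmorph.syngen import ellipse_mask

    return ellipse_mask(shape, cy, cx, a, b, phi_deg)


@pytest.fixture(scope="session")
def koch_raster():
    """Triadic Koch curve, 4 iterations, 729-px base, rasterized 1-px lines.

    Analytic box-counting dimension log 4 / log 3 ≈ 1.2619.
    """
    seq = "F"
    for _ in range(4):
        seq = seq.replace("F", "FLFRRFLF")
    step = 729.0 / 3 ** 4
    x = y = ang = 0.0
    pts = [(x, y)]
    for ch in seq:
        if ch == "F":
            x += step * math.cos(ang)
            y += step * math.sin(ang)
            pts.append((x, y))
        elif ch == "L":
            ang += math.pi / 3
        elif ch == "R":
            ang -= math.pi / 3
    pts = np.array(pts)
    H = int(np.ptp(pts[:, 1])) + 20
    W = int(np.ptp(pts[:, 0])) + 20
    # canvas tall enough that the dyadic ladder reaches ε = 128
    canvas = np.zeros((max(H, 740), W), dtype=bool)
    ox, oy = 10 - pts[:, 0].min(), 10 - pts[:, 1].min()
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = sk_line(int(round(y0 + oy)), int(round(x0 + ox)),
                         int(round(y1 + oy)), int(round(x1 + ox)))
        canvas[rr, cc] = True
    return canvas


@pytest.fixture(scope="session")
def straight_line_512():
    """A 512-px horizontal segment spanning a 512-wide canvas (dimension 1)."""
    img = np.zeros((520, 512), dtype=bool)
    img[260, :] = True
    return img


def brute_force_box_count(mask, eps):
    """Independent double-loop box tally (origin-anchored grid)."""
    H, W = mask.shape
    count = 0
    for r0 in range(0, H, eps):
        for c0 in range(0, W, eps):
            if mask[r0:r0 + eps, c0:c0 + eps].any():
                count += 1
    return count
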