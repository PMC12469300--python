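"""Synthetic microscopy image generation with known ground truth.

Four generators emulate the measurement contexts of the analysis pipeline:

* :func:`make_nucleus_field` — a field of non-overlapping elliptical nuclei
  (Hoechst-like), with controllable area distribution and orientation law
  (uniform, or biased perpendicular to the stretch axis);
* :func:`make_fractal_contour` — a closed, non-self-intersecting cell
  contour with a prescribed box-counting fractal dimension, built by radial
  spectral synthesis r(θ) = R₀(1 + Σₖ aₖ k^(−β/2) cos(kθ + ψₖ)); the β→FD
  mapping is calibrated once against the package's own box-counting
  estimator and shipped as a monotone lookup table;
* :func:`make_height_map` — a pseudo-AFM height map: flat plateau inside a
  contour with Gaussian texture confined to a peripheral band;
* :func:`make_fluor_cell` — a two-channel (DNA + Src) fluorescence cell
  with a specified nuclear/cytoplasmic intensity partition over a uniform
  noisy background, so corrected total cell fluorescence has a closed-form
  expectation.

Every generator takes one explicit integer seed and holds no global state:
identical (preset, seed) pairs yield bit-identical rasters and tables.
Presets named after the experimental conditions they are calibrated to ship
with the package (`load_preset`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .grids import ImageGrid
from .edge_fractal import EdgeMask

__all__ = [
    "GeneratorPreset",
    "load_preset",
    "list_presets",
    "ellipse_mask",
    "make_nucleus_field",
    "NucleusField",
    "make_fractal_contour",
    "FractalContour",
    "make_height_map",
    "make_fluor_cell",
    "FluorCell",
    "fd_to_beta",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails: the requested
    object count exceeds what the field can hold at the preset's size
    distribution (density limit)."""


@dataclass
class GeneratorPreset:
    """Parameter bundle for the synthetic generators.

    Calibration parameters (``nuclear_area_mean``, ``nc_ratio_mean``,
    ``target_fd`` …) are the condition means the preset emulates; the
    remaining knobs (noise, background, aspect ratio) shape realism.
    """

    name: str = "custom"
    nuclear_area_mean: float = 550.0      # µm²
    nuclear_area_sd: float = 110.0        # µm²
    aspect_ratio_mean: float = 1.6        # major/minor, >= 1
    orientation_model: str = "uniform"    # or "perpendicular_biased"
    orientation_kappa: float = 3.0        # von-Mises concentration on 2φ
    target_fd: float = 1.10               # box-counting FD of the cell edge
    nc_ratio_mean: float = 0.30           # nuclear / total cell area
    nc_ratio_sd: float = 0.05
    nuclear_src_fold: float = 1.0         # nuclear / cytoplasmic Src signal
    cytoplasm_level: float = 60.0         # Src increment inside cell
    dna_level: float = 400.0              # DNA increment inside nucleus
    background_level: float = 100.0       # intensity units
    noise_sd: float = 5.0                 # additive Gaussian, intensity units
    pixel_size: float = 0.25              # µm / pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nuclear_area_mean > 0:
            raise ValueError("nuclear_area_mean must be > 0")
        if not (1.0 <= self.target_fd < 1.5):
            raise ValueError(f"target_fd must be in [1.0, 1.5), got {self.target_fd}")
        if not (0 < self.nc_ratio_mean < 1):
            raise ValueError(f"nc_ratio_mean must be in (0, 1), got {self.nc_ratio_mean}")
        if self.aspect_ratio_mean < 1:
            raise ValueError("aspect_ratio_mean must be >= 1")
        if self.orientation_model not in ("uniform", "perpendicular_biased"):
            raise ValueError(f"unknown orientation_model {self.orientation_model!r}")
        if not self.nuclear_src_fold > 0:
            raise ValueError("nuclear_src_fold must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    def with_(self, **kw) -> "GeneratorPreset":
        return replace(self, **kw)


def _preset_library() -> dict:
    text = resources.files("cellmorph.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def list_presets() -> list[str]:
    """Names of the condition presets shipped with the package."""
    return sorted(_preset_library())


def load_preset(name: str, **overrides) -> GeneratorPreset:
    """Load a named condition preset, optionally overriding fields."""
    lib = _preset_library()
    if name not in lib:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(lib)}")
    kw = dict(lib[name])
    kw["name"] = name
    kw.update(overrides)
    return GeneratorPreset(**kw)


# ---------------------------------------------------------------------------
# ellipse rasterization (shared by the nucleus-field and fluor-cell builders)

def ellipse_mask(shape: tuple[int, int], cy: float, cx: float, a: float,
                 b: float, phi_deg: float) -> np.ndarray:
    """Boolean raster of a filled ellipse.

    ``phi_deg`` is the angle of the semi-major axis ``a`` measured
    counterclockwise from the +x (column) axis with the mathematical y-axis
    pointing up — i.e. against the row direction.  This is the stretch-axis
    convention used throughout the package.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dx = xx - cx
    dy = -(yy - cy)
    ph = np.deg2rad(phi_deg)
    u = dx * np.cos(ph) + dy * np.sin(ph)
    v = -dx * np.sin(ph) + dy * np.cos(ph)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_patch(a: float, b: float, phi_deg: float):
    """Filled-ellipse raster in a tight local window; returns (mask, half)."""
    half = int(np.ceil(max(a, b))) + 2
    size = 2 * half + 1
    return ellipse_mask((size, size), half, half, a, b, phi_deg), half


def _fold_angle(phi: float) -> float:
    """Fold an angle in degrees into (−90, 90]."""
    phi = (phi + 90.0) % 180.0 - 90.0
    return 90.0 if phi == -90.0 else phi


def _draw_phi(rng: np.random.Generator, model: str, kappa: float, n: int) -> np.ndarray:
    """Draw orientation angles φ (degrees in (−90, 90]).

    ``uniform`` draws φ flat on (−90, 90].  ``perpendicular_biased`` draws
    2φ from a von Mises density centered at 180° with concentration κ, so
    cos(2φ) piles up near −1 (nuclei across the stretch axis).
    """
    if model == "uniform":
        return rng.uniform(-90.0, 90.0, size=n)
    two_phi = rng.vonmises(np.pi, kappa, size=n)   # radians in (−π, π]
    return np.degrees(two_phi) / 2.0


@dataclass
class NucleusField:
    """A rendered nucleus field: intensity image, labels, and ground truth."""

    image: ImageGrid
    labels: np.ndarray
    truth: pd.DataFrame


def make_nucleus_field(preset: GeneratorPreset, n: int, seed: int | None = None,
                       field_shape: tuple[int, int] | None = None,
                       max_retries: int = 1000) -> NucleusField:
    """Render ``n`` non-overlapping elliptical nuclei with known ground truth.

    Areas are drawn from a normal distribution with the preset's mean and SD
    (redrawn while non-positive or below the minimum analyzable size);
    aspect ratios from a shifted gamma with the preset's mean; orientations
    from the preset's orientation law.  Placement is
    rejection-resampled with at most ``max_retries`` attempts per nucleus —
    beyond that a :class:`PlacementError` names the density limit.

    The field auto-sizes to keep total nuclear coverage near 25% unless
    ``field_shape`` is given.  Returns the rendered intensity image
    (background + DNA level + Gaussian noise), the int label mask, and a
    ground-truth table with one row per nucleus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = preset.seed
    rng = np.random.default_rng(seed)
    pa = preset.pixel_size ** 2
    mean_area_px = preset.nuclear_area_mean / pa
    if field_shape is None:
        side = int(np.ceil(np.sqrt(n * mean_area_px / 0.25)))
        side = max(side, int(6 * np.sqrt(mean_area_px)))
        field_shape = (side, side)
    labels = np.zeros(field_shape, dtype=np.int32)

    min_area_um2 = 30 * pa  # floor well below any realistic nucleus
    rows = []
    for lab in range(1, n + 1):
        area = rng.normal(preset.nuclear_area_mean, preset.nuclear_area_sd)
        while area <= min_area_um2:
            area = rng.normal(preset.nuclear_area_mean, preset.nuclear_area_sd)
        if preset.aspect_ratio_mean == 1.0:
            q = 1.0
        else:
            q = 1.0 + rng.gamma(4.0, (preset.aspect_ratio_mean - 1.0) / 4.0)
        phi = float(_draw_phi(rng, preset.orientation_model,
                              preset.orientation_kappa, 1)[0])
        area_px = area / pa
        a = np.sqrt(area_px * q / np.pi)
        b = a / q
        patch, half = _ellipse_patch(a, b, phi)
        guard, ghalf = _ellipse_patch(a + 2, b + 2, phi)  # 2-px separation
        placed = False
        for _ in range(max_retries):
            cy = rng.integers(ghalf, field_shape[0] - ghalf)
            cx = rng.integers(ghalf, field_shape[1] - ghalf)
            win = labels[cy - ghalf:cy + ghalf + 1, cx - ghalf:cx + ghalf + 1]
            if not (win[guard]).any():
                tgt = labels[cy - half:cy + half + 1, cx - half:cx + half + 1]
                tgt[patch] = lab
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {lab}/{n} after {max_retries} retries: "
                f"field {field_shape} too dense for area_mean="
                f"{preset.nuclear_area_mean} µm² at {preset.pixel_size} µm/px")
        rows.append({
            "label": lab, "cy": int(cy), "cx": int(cx),
            "area_um2": float(area), "area_px": float(area_px),
            "a_px": float(a), "b_px": float(b), "aspect_ratio": float(q),
            "phi_deg": _fold_angle(phi),
            "cos2phi": float(np.cos(2 * np.deg2rad(phi))),
            "orientation_defined": bool(q > 1.0),
        })

    img = np.full(field_shape, preset.background_level, dtype=float)
    img[labels > 0] += preset.dna_level
    if preset.noise_sd > 0:
        img += rng.normal(0.0, preset.noise_sd, size=field_shape)
    grid = ImageGrid(img, preset.pixel_size, "um",
                     source=f"syngen:nucleus_field:{preset.name}:seed={seed}")
    return NucleusField(grid, labels, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fractal contours

_FD_LUT_CACHE: dict | None = None


def _fd_lookup() -> dict:
    global _FD_LUT_CACHE
    if _FD_LUT_CACHE is None:
        text = resources.files("cellmorph.data").joinpath("fd_calibration.json").read_text()
        _FD_LUT_CACHE = json.loads(text)
    return _FD_LUT_CACHE


def fd_to_beta(target_fd: float) -> float:
    """Invert the calibrated β→FD lookup (monotone interpolation).

    The lookup was built by measuring the box-counting FD of generated
    contours over a grid of spectral decay exponents β; measured FD
    decreases monotonically with β.  Targets at the smooth end (FD → 1.0)
    clamp to the largest calibrated β.
    """
    lut = _fd_lookup()
    if not (1.0 <= target_fd < 1.5):
        raise ValueError(f"target_fd {target_fd} outside calibrated range [1.0, 1.5)")
    fd = np.asarray(lut["fd"], dtype=float)      # ascending
    beta = np.asarray(lut["beta"], dtype=float)  # descending along fd
    if target_fd > fd.max():
        raise ValueError(
            f"target_fd {target_fd} above calibrated maximum {fd.max():.3f}")
    return float(np.interp(target_fd, fd, beta))


@dataclass
class FractalContour:
    """A synthesized closed cell contour and its rasterizations."""

    polygon: np.ndarray          # (n_theta, 2) of (x, y) vertices, closed implicitly
    edge: EdgeMask               # one-pixel-wide boundary raster
    filled: np.ndarray           # filled interior mask
    truth: pd.DataFrame          # one-row table of generation parameters


def _radial_profile(rng: np.random.Generator, beta: float, n_theta: int,
                    k_min: int, k_max: int, sigma: float) -> np.ndarray:
    """Random radial perturbation with power-law spectrum k^(−β), fixed RMS."""
    k = np.arange(k_min, k_max + 1)
    amp = k ** (-beta / 2.0)
    spec = np.zeros(n_theta // 2 + 1, dtype=complex)
    spec[k_min:k_max + 1] = (rng.standard_normal(k.size)
                             + 1j * rng.standard_normal(k.size)) * amp
    s = np.fft.irfft(spec, n=n_theta)
    s *= sigma / s.std()
    return np.clip(s, -0.85, None)   # keep r > 0: star-shaped, no self-crossing


def make_fractal_contour(preset: GeneratorPreset, grid_size: int = 1024,
                         seed: int | None = None, n_theta: int = 4096,
                         sigma: float = 0.12, k_min: int = 2,
                         k_max: int = 512) -> FractalContour:
    """Closed contour whose box-counting FD matches ``preset.target_fd``.

    Radial spectral synthesis: r(θ) = R₀(1 + s(θ)) where s has a power-law
    amplitude spectrum k^(−β/2) with random phases and fixed RMS ``sigma``.
    β comes from the calibrated FD lookup.  The contour is star-shaped about
    the grid center (strictly positive radius), hence closed and
    non-self-intersecting; the interior is filled exactly by the polar
    inequality ρ ≤ r(θ) and the edge mask is the filled mask minus its
    8-connected erosion.
    """
    if seed is None:
        seed = preset.seed
    beta = fd_to_beta(preset.target_fd)
    rng = np.random.default_rng(seed)
    s = _radial_profile(rng, beta, n_theta, k_min, k_max, sigma)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r = 0.36 * grid_size * (1.0 + s)
    r *= (0.47 * grid_size) / r.max()   # keep inside the grid with margin
    c = grid_size / 2.0
    poly = np.column_stack([c + r * np.cos(theta), c + r * np.sin(theta)])

    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    rho = np.hypot(xx - c, yy - c)
    th = np.arctan2(yy - c, xx - c) % (2 * np.pi)
    r_b = np.interp(th.ravel(), theta, r, period=2 * np.pi).reshape(grid_size, grid_size)
    filled = rho <= r_b

    # sub-pixel radial oscillations can alias into detached islands at
    # coarse grids: keep the main body and fill pinched-off holes, the same
    # cleanup the measurement path applies
    from scipy import ndimage as ndi
    lab, n = ndi.label(filled, structure=np.ones((3, 3), bool))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        filled = lab == (int(np.argmax(sizes)) + 1)
    filled = ndi.binary_fill_holes(filled)
    edge = filled & ~ndi.binary_erosion(filled, structure=np.ones((3, 3), bool),
                                        border_value=0)
    truth = pd.DataFrame([{
        "target_fd": preset.target_fd, "beta": beta, "sigma": sigma,
        "k_min": k_min, "k_max": k_max, "grid_size": grid_size,
        "n_theta": n_theta, "seed": seed,
    }])
    em = EdgeMask(edge, source=f"syngen:contour:{preset.name}:seed={seed}",
                  threshold=0.5)
    return FractalContour(poly, em, filled, truth)


# ---------------------------------------------------------------------------
# pseudo-AFM height maps

def make_height_map(contour, interior_height: float,
                    peripheral_texture_sd: float = 0.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    band_width: int = 10,
                    pixel_size: float = 0.010,
                    shape: tuple[int, int] | None = None) -> ImageGrid:
    """Pseudo-AFM height map: plateau inside the contour, textured rim.

    ``contour`` may be a :class:`FractalContour`, a boolean mask, or an
    (N, 2) polygon of (x, y) vertices.  Height is 0 outside, a constant
    plateau inside, with zero-mean Gaussian texture of SD
    ``peripheral_texture_sd`` confined to the peripheral band (mask pixels
    within ``band_width`` of the boundary) and optional global Gaussian
    noise everywhere.  Deterministic per seed.  ``pixel_size`` defaults to
    10 nm/px expressed in µm, the usual contact-mode AFM sampling.
    """
    if not interior_height > 0:
        raise ValueError("interior_height must be > 0")
    from scipy import ndimage as ndi
    if isinstance(contour, FractalContour):
        mask = contour.filled
    elif isinstance(contour, np.ndarray) and contour.ndim == 2 and contour.shape[1] == 2:
        from skimage.draw import polygon as sk_polygon
        if shape is None:
            shape = (int(contour[:, 1].max()) + 8, int(contour[:, 0].max()) + 8)
        mask = np.zeros(shape, dtype=bool)
        rr, cc = sk_polygon(contour[:, 1], contour[:, 0], shape=shape)
        mask[rr, cc] = True
    else:
        mask = np.asarray(contour, dtype=bool)
    rng = np.random.default_rng(seed)
    height = np.where(mask, float(interior_height), 0.0)
    if peripheral_texture_sd > 0:
        dist = ndi.distance_transform_edt(mask)
        band = mask & (dist <= band_width)
        height[band] += rng.normal(0.0, peripheral_texture_sd, size=int(band.sum()))
    if noise_sd > 0:
        height += rng.normal(0.0, noise_sd, size=mask.shape)
    return ImageGrid(height, pixel_size, "um", source=f"syngen:heightmap:seed={seed}")


# ---------------------------------------------------------------------------
# two-channel fluorescence cells

@dataclass
class FluorCell:
    """A rendered two-channel cell: DNA + Src images, masks, ground truth."""

    dna: ImageGrid
    src: ImageGrid
    cell_mask: np.ndarray
    nuclear_mask: np.ndarray
    truth: pd.DataFrame


def make_fluor_cell(preset: GeneratorPreset, seed: int | None = None,
                    cell_aspect: float = 1.3) -> FluorCell:
    """One cell with a specified nuclear/cytoplasmic Src partition.

    The cell is an ellipse; the nucleus a concentric co-oriented ellipse
    whose area is the drawn N/C ratio times the cell area, so the nuclear
    mask is strictly inside the cell mask by construction (verified).  The
    Src channel is background + cytoplasmic increment inside the cell + a
    nuclear increment of (fold − 1) × cytoplasmic level inside the nucleus,
    plus Gaussian noise; ground truth records the exact per-compartment
    means, giving corrected total cell fluorescence the closed-form
    expectation fold × cytoplasmic level × nuclear area.
    """
    if seed is None:
        seed = preset.seed
    rng = np.random.default_rng(seed)
    pa = preset.pixel_size ** 2

    area_n = rng.normal(preset.nuclear_area_mean, preset.nuclear_area_sd)
    while area_n <= 30 * pa:
        area_n = rng.normal(preset.nuclear_area_mean, preset.nuclear_area_sd)
    nc = float(np.clip(rng.normal(preset.nc_ratio_mean, preset.nc_ratio_sd),
                       0.05, 0.90))
    area_c = area_n / nc
    phi = float(rng.uniform(-90.0, 90.0))

    a_c = np.sqrt((area_c / pa) * cell_aspect / np.pi)
    b_c = a_c / cell_aspect
    scale = np.sqrt(area_n / area_c)
    a_n, b_n = a_c * scale, b_c * scale

    margin = 16
    half = int(np.ceil(a_c)) + margin
    size = 2 * half + 1
    shape = (size, size)
    cell = ellipse_mask(shape, half, half, a_c, b_c, phi)
    nuc = ellipse_mask(shape, half, half, a_n, b_n, phi)
    if not (nuc & ~cell).sum() == 0:
        raise ValueError("nuclear mask not strictly inside cell mask")

    cyt_level = preset.cytoplasm_level
    nuc_incr = cyt_level * (preset.nuclear_src_fold - 1.0)
    src = np.full(shape, preset.background_level, dtype=float)
    src[cell] += cyt_level
    src[nuc] += nuc_incr
    dna = np.full(shape, preset.background_level, dtype=float)
    dna[nuc] += preset.dna_level
    if preset.noise_sd > 0:
        src += rng.normal(0.0, preset.noise_sd, size=shape)
        dna += rng.normal(0.0, preset.noise_sd, size=shape)

    n_px = int(nuc.sum())
    truth = pd.DataFrame([{
        "seed": seed, "nuclear_area_um2": float(area_n),
        "cell_area_um2": float(area_c), "nc_ratio": nc, "phi_deg": _fold_angle(phi),
        "nuclear_area_px": n_px, "cell_area_px": int(cell.sum()),
        "background_level": preset.background_level,
        "cytoplasm_level": cyt_level, "nuclear_increment": nuc_incr,
        "nuclear_src_fold": preset.nuclear_src_fold,
        "noise_sd": preset.noise_sd,
        # nuclear mean above background is cyt + (fold-1)*cyt = fold*cyt
        "expected_ctcf": preset.nuclear_src_fold * cyt_level * n_px,
    }])
    tag = f"syngen:fluorcell:{preset.name}:seed={seed}"
    return FluorCell(ImageGrid(dna, preset.pixel_size, "um", tag + ":dna"),
                     ImageGrid(src, preset.pixel_size, "um", tag + ":src"),
                     cell, nuc, truth)
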