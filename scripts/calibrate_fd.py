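"""Build the β→FD calibration lookup for the fractal-contour generator.

Generates radial-spectral contours over a grid of spectral decay exponents
β, measures each with the package's own box-counting estimator (default
scales, 1024-px grid), averages over seeds, enforces monotonicity (pool
adjacent violators), and freezes the table as package data.  Rerun only
when the contour synthesis or the box-counting defaults change:

    python scripts/calibrate_fd.py
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cellmorph.edge_fractal import box_count, extract_edge_mask  # noqa: E402
from cellmorph.syngen import _radial_profile  # noqa: E402
from scipy import ndimage as ndi  # noqa: E402

GRID = 1024
N_THETA = 4096
SIGMA = 0.12
K_MIN, K_MAX = 2, 512
BETAS = [0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8,
         3.0, 3.2, 3.4, 3.6, 3.8, 4.0, 4.5, 5.0, 6.0]
SEEDS_PER_BETA = 16
CAL_SEED_BASE = 900_000   # disjoint from any runtime seed stream


def contour_fd(beta: float, seed: int) -> float:
    rng = np.random.default_rng(seed)
    s = _radial_profile(rng, beta, N_THETA, K_MIN, K_MAX, SIGMA)
    theta = np.linspace(0.0, 2 * np.pi, N_THETA, endpoint=False)
    r = 0.36 * GRID * (1.0 + s)
    r *= (0.47 * GRID) / r.max()
    c = GRID / 2.0
    yy, xx = np.mgrid[0:GRID, 0:GRID]
    rho = np.hypot(xx - c, yy - c)
    th = np.arctan2(yy - c, xx - c) % (2 * np.pi)
    rb = np.interp(th.ravel(), theta, r, period=2 * np.pi).reshape(GRID, GRID)
    filled = rho <= rb
    # measure through the same path the pipeline uses (largest component,
    # holes filled, one-pixel rim, default dyadic scales)
    em = extract_edge_mask(filled.astype(float), method="fixed", threshold=0.5)
    return box_count(em).fd


def pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-increasing sequence."""
    y = list(map(float, y))
    blocks = [[v, 1] for v in y]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] < blocks[i + 1][0]:   # violation of non-increasing
            v = (blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1])
            w = blocks[i][1] + blocks[i + 1][1]
            blocks[i] = [v / w, w]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for v, w in blocks:
        out.extend([v] * w)
    return np.array(out)


def main() -> None:
    means, sds = [], []
    for bi, beta in enumerate(BETAS):
        fds = [contour_fd(beta, CAL_SEED_BASE + bi * SEEDS_PER_BETA + s)
               for s in range(SEEDS_PER_BETA)]
        means.append(float(np.mean(fds)))
        sds.append(float(np.std(fds, ddof=1)))
        print(f"beta={beta:4.1f}  fd={means[-1]:.4f} +- {sds[-1]:.4f}")
    fd_mono = pava_decreasing(np.array(means))
    # store ascending in fd for np.interp
    order = np.argsort(fd_mono, kind="stable")
    table = {
        "grid_size": GRID, "n_theta": N_THETA, "sigma": SIGMA,
        "k_min": K_MIN, "k_max": K_MAX, "seeds_per_beta": SEEDS_PER_BETA,
        "beta": [BETAS[i] for i in order],
        "fd": [float(fd_mono[i]) for i in order],
        "fd_sd": [sds[i] for i in order],
    }
    out = Path(__file__).resolve().parents[1] / "src/cellmorph/data/fd_calibration.json"
    out.write_text(json.dumps(table, indent=1))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
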