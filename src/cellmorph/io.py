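"""Readers, writers and run configuration.

Formats: grayscale TIFF (8/16-bit) for images, PNG for binary masks,
whitespace-delimited ASCII matrices (``#`` comment lines) for exported AFM
height maps, CSV/JSON for tabular results, YAML or JSON for configuration.
Pixel sizes always come from configuration, never from TIFF tags (tag
conventions vary across instruments); the defaults mirror typical confocal
(0.025 µm/px) and contact-mode AFM (10 nm/px) sampling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import ImageGrid

__all__ = [
    "RunConfig",
    "read_image",
    "read_ascii_matrix",
    "write_records",
    "read_records",
    "write_manifest",
    "AsciiFormatError",
]

CONFOCAL_PIXEL_SIZE_UM = 0.025
AFM_PIXEL_SIZE_UM = 0.010


class AsciiFormatError(ValueError):
    """Malformed ASCII matrix (ragged rows, no data, unparseable token)."""


@dataclass
class RunConfig:
    """Serializable parameter set for a reproducible pipeline run."""

    pixel_size: float = CONFOCAL_PIXEL_SIZE_UM   # µm per pixel
    afm_pixel_size: float = AFM_PIXEL_SIZE_UM
    seed: int = 0
    threshold: str = "otsu"          # or a float as string for fixed
    band_width: int = 10             # peripheral roughness band, px
    ring_gap: int = 2                # CTCF background ring, px
    ring_width: int = 5
    fit_min: int = 4                 # smallest box size in the FD fit
    offsets: int = 1                 # box-grid offsets (1 or 4)
    min_nucleus_px: int = 25
    circularity_threshold: float = 0.2
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
            else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Stable content hash of the scientific parameters.

        Execution-location metadata (output directory, log level) is
        excluded so reruns of the same analysis hash identically wherever
        they write.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_ascii_matrix(path: str | Path) -> np.ndarray:
    """Whitespace-delimited numeric matrix; lines starting with '#' skipped.

    Raises :class:`AsciiFormatError` naming the offending line for ragged
    rows or unparseable values, and for files with no data rows.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            vals = [float(tok) for tok in stripped.split()]
        except ValueError as e:
            raise AsciiFormatError(f"{path}: line {lineno}: {e}") from None
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise AsciiFormatError(
                f"{path}: line {lineno}: ragged row ({len(vals)} values, "
                f"expected {width})")
        rows.append(vals)
    if not rows:
        raise AsciiFormatError(f"{path}: no data rows")
    return np.array(rows, dtype=float)


def read_image(path: str | Path, kind: str = "tiff",
               pixel_size: float = 1.0, units: str = "um"):
    """Read an image or mask.

    ``kind``: ``tiff`` (grayscale ImageGrid), ``ascii_matrix`` (height-map
    ImageGrid), ``png_mask`` / ``tiff_mask`` (boolean array, binarized at
    > 0).  Pixel size comes from the caller/config.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if kind == "tiff":
        data = tifffile.imread(path)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel 2-D image, "
                             f"got shape {data.shape}")
        return ImageGrid(data.astype(float), pixel_size, units, source=str(path))
    if kind == "ascii_matrix":
        return ImageGrid(read_ascii_matrix(path), pixel_size, units, source=str(path))
    if kind in ("png_mask", "tiff_mask"):
        import imageio.v3 as iio
        data = iio.imread(path)
        if data.ndim == 3:
            data = data[..., 0]
        return np.asarray(data) > 0
    raise ValueError(f"unknown image kind {kind!r}")


def _jsonable(rec):
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return dataclasses.asdict(rec)
    if isinstance(rec, dict):
        return rec
    raise TypeError(f"cannot serialize record of type {type(rec)}")


def write_records(records, path: str | Path, format: str | None = None) -> None:
    """Write dataclass records or dicts to CSV or JSON (by extension).

    Round-trip stable: numeric values survive read-back at full float
    precision (CSV uses repr-precision floats).  An empty record list gives
    a header-only CSV / empty JSON list.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    rows = [_jsonable(r) for r in records]
    if format == "csv":
        if isinstance(records, pd.DataFrame):
            records.to_csv(path, index=False, float_format="%.17g")
            return
        df = pd.DataFrame(rows)
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        if isinstance(records, pd.DataFrame):
            rows = records.to_dict(orient="records")
        path.write_text(json.dumps(rows, indent=1, default=str))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_records`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_manifest(out_dir: str | Path, config: RunConfig, inputs: list[str],
                   outputs: list[str]) -> Path:
    """Write a reproducibility manifest beside the outputs."""
    import cellmorph

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "cellmorph",
        "version": cellmorph.__version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
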