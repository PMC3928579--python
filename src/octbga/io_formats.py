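"""Open-format readers and writers.

The vendor tomograph stores volumes in a proprietary ``*.oct`` container
together with an ``info.ini`` calibration file. This module replaces that
container with open equivalents: multi-page TIFF (or a directory of
numbered grayscale images) for the B-scan stack, an INI file with a
``[scan]`` section for calibration, CSV for layer surfaces, reference
thickness profiles and feature tables, and PNG for en-face masks.

Indexing convention: all arrays and files produced here are 0-based
(files carry a header comment saying so). A volume has shape (M, N, I)
with m the axial row, n the A-scan column and i the B-scan index.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .layer_segmentation import LayerSurface
    from .preprocess import OctVolume

log = logging.getLogger(__name__)

#: Sentinel used in CSV files for undefined surface entries: an empty cell.
_CSV_HEADER = "# octbga surface file; indices are 0-based; empty row cell = undefined\n"


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Calibration:
    """Scan geometry: micrometres per pixel along each axis and scan counts."""

    axial_um_per_px: float
    lateral_um_per_px: float
    bscan_spacing_um: float
    n_ascans: int
    n_bscans: int

    def __post_init__(self) -> None:
        for name in ("axial_um_per_px", "lateral_um_per_px", "bscan_spacing_um",
                     "n_ascans", "n_bscans"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Calibration.{name} must be strictly positive")

    _KEYS = ("axial_um_per_px", "lateral_um_per_px", "bscan_spacing_um",
             "n_ascans", "n_bscans")

    @classmethod
    def from_ini(cls, path: str | Path) -> "Calibration":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"calibration file not found: {path}")
        cp = configparser.ConfigParser()
        cp.read(path)
        if "scan" not in cp:
            raise ConfigError(f"calibration file {path} has no [scan] section")
        section = cp["scan"]
        kwargs = {}
        for key, raw in section.items():
            if key in cls._KEYS:
                kwargs[key] = int(raw) if key.startswith("n_") else float(raw)
            else:
                log.warning("calibration: ignoring unknown key %r in %s", key, path)
        missing = [k for k in cls._KEYS if k not in kwargs]
        if missing:
            raise ConfigError(f"calibration file {path} missing keys: {missing}")
        return cls(**kwargs)

    def to_ini(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["scan"] = {k: str(getattr(self, k)) for k in self._KEYS}
        with open(path, "w") as fh:
            cp.write(fh)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(name: str) -> tuple:
    """Sort key ordering b2.png before b10.png."""
    parts = _NUM_RE.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_gray_u8(page: np.ndarray, source: str) -> np.ndarray:
    if page.ndim == 3:
        if page.shape[2] in (3, 4) and np.all(page[..., 0] == page[..., 1]) \
                and np.all(page[..., 1] == page[..., 2]):
            page = page[..., 0]
        else:
            raise FormatError(f"{source}: non-grayscale image with no safe conversion")
    if page.ndim != 2:
        raise FormatError(f"{source}: expected a 2-D page, got shape {page.shape}")
    if page.dtype != np.uint8:
        if np.issubdtype(page.dtype, np.integer) and page.max(initial=0) <= 255:
            page = page.astype(np.uint8)
        else:
            raise FormatError(f"{source}: expected 8-bit data, got dtype {page.dtype}")
    return page


def read_volume(path: str | Path, calibration: Calibration | None = None) -> "OctVolume":
    """Read a B-scan stack into an :class:`~octbga.preprocess.OctVolume`.

    ``path`` is either a multi-page TIFF (pages = B-scans, ascending i) or a
    directory of equally sized numbered grayscale images (numeric sort = i).
    """
    from .preprocess import OctVolume

    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir()
             if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")),
            key=lambda p: _numeric_key(p.name),
        )
        if not files:
            raise FormatError(f"no image files found in {path}")
        pages = [_to_gray_u8(np.asarray(iio.imread(f)), str(f)) for f in files]
    else:
        if not path.exists():
            raise FormatError(f"volume file not found: {path}")
        pages = [_to_gray_u8(np.asarray(p), str(path)) for p in tifffile.imread(path, key=None)]
        if not pages:
            raise FormatError(f"empty image stack: {path}")
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise FormatError(f"{path}: mixed page sizes {sorted(shapes)}")
    data = np.stack(pages, axis=-1)  # (M, N, I)
    return OctVolume(data=data, calibration=calibration)


def write_volume(volume: "OctVolume", path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, one page per B-scan."""
    pages = np.moveaxis(volume.data, -1, 0)  # (I, M, N)
    # pin the interpretation: one grayscale page per B-scan, never RGB planes
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


# ---------------------------------------------------------------------------
# reference RNFL thickness profile
# ---------------------------------------------------------------------------

class ReferenceProfile:
    """Periodic piecewise-linear RNFL thickness profile over the angle theta.

    Emulates the normative TSNIT curve against which measured peripapillary
    thickness is compared. Thickness must be strictly positive everywhere
    because the deviation score divides by it.
    """

    def __init__(self, theta_deg: Iterable[float], thickness_um: Iterable[float]):
        theta = np.asarray(list(theta_deg), dtype=float) % 360.0
        thick = np.asarray(list(thickness_um), dtype=float)
        if theta.size == 0:
            raise ValidationError("reference profile needs at least one sample")
        if np.any(thick <= 0):
            raise ValidationError("reference thickness must be strictly positive")
        order = np.argsort(theta)
        theta, thick = theta[order], thick[order]
        if np.any(np.diff(theta) == 0):
            raise ValidationError("duplicate theta values in reference profile")
        # wrap one knot on each side for periodic interpolation
        self._theta = np.concatenate([[theta[-1] - 360.0], theta, [theta[0] + 360.0]])
        self._thick = np.concatenate([[thick[-1]], thick, [thick[0]]])

    @classmethod
    def constant(cls, thickness_um: float) -> "ReferenceProfile":
        return cls([0.0], [thickness_um])

    def __call__(self, theta_deg) -> np.ndarray:
        theta = np.asarray(theta_deg, dtype=float) % 360.0
        return np.interp(theta, self._theta, self._thick)


def read_reference_profile(path: str | Path) -> ReferenceProfile:
    """Read a CSV with columns ``theta_deg``, ``thickness_um``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"reference profile not found: {path}")
    df = pd.read_csv(path, comment="#")
    for col in ("theta_deg", "thickness_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        return ReferenceProfile(df["theta_deg"], df["thickness_um"])
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_reference_profile(profile: ReferenceProfile, path: str | Path,
                            n_samples: int = 360) -> None:
    theta = np.arange(n_samples) * 360.0 / n_samples
    pd.DataFrame({"theta_deg": theta, "thickness_um": profile(theta)}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# surfaces, masks, results
# ---------------------------------------------------------------------------

def write_surface(surface: "LayerSurface", path: str | Path) -> None:
    """Write a layer surface as CSV rows (n, i, row); undefined = empty cell."""
    n_cols, n_scans = surface.rows.shape
    nn, ii = np.meshgrid(np.arange(n_cols), np.arange(n_scans), indexing="ij")
    rows = surface.rows.ravel()
    df = pd.DataFrame({"n": nn.ravel(), "i": ii.ravel(), "row": rows})
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False, float_format="%.3f")


def read_surface(path: str | Path, label: str = "") -> "LayerSurface":
    from .layer_segmentation import LayerSurface

    path = Path(path)
    if not path.exists():
        raise FormatError(f"surface file not found: {path}")
    df = pd.read_csv(path, comment="#")
    n_cols = int(df["n"].max()) + 1
    n_scans = int(df["i"].max()) + 1
    rows = np.full((n_cols, n_scans), np.nan)
    rows[df["n"].to_numpy(), df["i"].to_numpy()] = df["row"].to_numpy()
    return LayerSurface(rows=rows, label=label)


def write_mask(bits: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(bits, bool).astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_results(surfaces: dict, masks: dict, features: dict,
                  out_dir: str | Path) -> list[Path]:
    """Write pipeline outputs under ``out_dir``; returns the files written.

    ``features`` is a flat mapping of named scalars (the ``w`` symbols plus
    ``w_g(1..3)``, ``w_BGA`` and the predicted MD) written as a one-row CSV.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out_dir}: {exc}") from exc
    written = []
    for name, surface in surfaces.items():
        p = out_dir / f"surface_{name}.csv"
        write_surface(surface, p)
        written.append(p)
    for name, mask in masks.items():
        p = out_dir / f"mask_{name}.png"
        bits = mask.bits if hasattr(mask, "bits") else mask
        write_mask(bits, p)
        written.append(p)
    if features:
        p = out_dir / "features.csv"
        pd.DataFrame([features]).to_csv(p, index=False)
        written.append(p)
    return written


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a patients-by-features CSV (columns named w1..w30 or w(1)..w(30))."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"feature table not found: {path}")
    df = pd.read_csv(path, comment="#")
    # normalize w(7) -> w7 so downstream code sees one vocabulary
    df.columns = [re.sub(r"^w\((\d+)\)$", r"w\1", str(c).strip()) for c in df.columns]
    return df
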