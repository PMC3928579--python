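"""Retinal layer segmentation: RPE, ILM and the RNFL lower boundary.

The chain mirrors how these layers present in an ONH-centred OCT stack:

* the RPE is the brightest band, so each A-scan's brightness maximum
  locates it (ties are broken by continuity with already-solved
  neighbours);
* the ILM is the first bright pixel above the RPE after Otsu
  binarization of the supra-RPE region;
* the RNFL lower boundary is the first light-to-dark gradient edge
  strictly between ILM and RPE (Prewitt magnitude, masked to that band);
* an active-edge correction re-places each contour point at the offset
  maximizing the mean-brightness contrast between a window just above
  and a window just below the candidate position, which bridges gaps
  left by vessel shadows and low contrast.

Surfaces are (N, I) row-index arrays with NaN as the undefined sentinel.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .errors import AlgorithmError, ConfigError, DegenerateInputError, ValidationError
from .preprocess import OctVolume, _BORDER_MODES

log = logging.getLogger(__name__)

UNDEFINED = np.nan


@dataclasses.dataclass
class LayerSurface:
    """Per-(column, B-scan) axial row of one retinal boundary."""

    rows: np.ndarray  # (N, I) float; NaN = undefined
    label: str = ""

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise ValidationError(f"surface must be 2-D (N, I), got {self.rows.shape}")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.rows)

    @property
    def defined_fraction(self) -> float:
        return float(np.mean(self.defined))


@dataclasses.dataclass
class GradientVolume:
    """Prewitt gradient magnitude restricted to the open (ILM, RPE) band."""

    magnitudes: np.ndarray  # (M, N, I), zero outside the band


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray) -> int:
    """Threshold over the 256-bin histogram maximizing between-class variance.

    Foreground is ``value > threshold``. Among equally good cuts the lowest
    is returned. A constant sample has no two classes to separate and raises
    :class:`DegenerateInputError`.
    """
    values = np.asarray(values)
    values = values[np.isfinite(values)] if values.dtype.kind == "f" else values
    if values.size == 0:
        raise DegenerateInputError("empty sample")
    hist = np.bincount(values.astype(np.intp).ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("constant sample: no threshold separates two classes")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)                      # weight of class {0..t}
    m0 = np.cumsum(hist * levels)             # unnormalized first moment
    total, grand = w0[-1], m0[-1]
    w1 = total - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (grand - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    sigma_b = sigma_b[:-1]  # t = 255 leaves no foreground
    # a run of cuts through an empty histogram span ties exactly; take its middle
    ties = np.nonzero(sigma_b == sigma_b.max())[0]
    return int(ties[len(ties) // 2])


# ---------------------------------------------------------------------------
# RPE
# ---------------------------------------------------------------------------

def detect_rpe(volume: OctVolume) -> LayerSurface:
    """Locate the RPE as the per-A-scan brightness maximum.

    Columns with several tied global maxima take the candidate row closest
    to the median RPE of the 5x5 en-face neighbourhood of columns already
    solved uniquely (falling back to the smallest tied row). All-zero
    columns are undefined.
    """
    data = volume.data
    max_val = data.max(axis=0)
    rows = np.argmax(data, axis=0).astype(float)
    defined = max_val > 0
    tie_count = (data == max_val[None, :, :]).sum(axis=0)
    tied = (tie_count > 1) & defined

    rows[~defined] = UNDEFINED
    if np.any(tied):
        unique_rows = rows.copy()
        unique_rows[tied] = UNDEFINED
        for n, i in zip(*np.nonzero(tied)):
            candidates = np.nonzero(data[:, n, i] == max_val[n, i])[0]
            window = unique_rows[max(n - 2, 0):n + 3, max(i - 2, 0):i + 3]
            ref = np.nanmedian(window) if np.isfinite(window).any() else np.nan
            if np.isfinite(ref):
                rows[n, i] = candidates[np.argmin(np.abs(candidates - ref))]
            else:
                rows[n, i] = candidates[0]
    return LayerSurface(rows=rows, label="RPE")


# ---------------------------------------------------------------------------
# ILM
# ---------------------------------------------------------------------------

def detect_ilm(volume: OctVolume, rpe: LayerSurface, scope: str = "bscan") -> LayerSurface:
    """Locate the ILM as the first supra-threshold pixel above the RPE.

    The region from the top of each A-scan down to (and excluding) the RPE
    row is binarized at an Otsu threshold computed per B-scan (or once per
    volume with ``scope="volume"``); the ILM is the smallest foreground row
    per column. Excluding the RPE row itself keeps ILM < RPE strictly.
    """
    if scope not in ("bscan", "volume"):
        raise ConfigError(f"otsu scope must be 'bscan' or 'volume', got {scope!r}")
    if not np.any(rpe.defined):
        raise AlgorithmError("RPE surface fully undefined; cannot locate the ILM")
    if rpe.defined_fraction < 0.5:
        raise AlgorithmError(
            f"RPE defined on only {rpe.defined_fraction:.0%} of columns (need a majority)")

    data = volume.data
    n_rows = data.shape[0]
    m_grid = np.arange(n_rows)[:, None, None]
    rpe_rows = np.where(rpe.defined, rpe.rows, -1.0)[None, :, :]
    above = m_grid < rpe_rows  # strictly above the RPE row

    ilm = np.full(rpe.rows.shape, UNDEFINED)
    if scope == "volume":
        threshold = otsu_threshold(data[above])
        thresholds = [threshold] * data.shape[2]
    else:
        thresholds = []
        for i in range(data.shape[2]):
            sample = data[:, :, i][above[:, :, i]]
            thresholds.append(otsu_threshold(sample))

    for i, p_r in enumerate(thresholds):
        fg = (data[:, :, i] > p_r) & above[:, :, i]
        has_fg = fg.any(axis=0)
        first = np.argmax(fg, axis=0).astype(float)
        first[~has_fg] = UNDEFINED
        ilm[:, i] = first
    ilm[~rpe.defined] = UNDEFINED
    return LayerSurface(rows=ilm, label="ILM")


# ---------------------------------------------------------------------------
# RNFL lower boundary
# ---------------------------------------------------------------------------

def gradient_volume(volume: OctVolume, ilm: LayerSurface, rpe: LayerSurface,
                    border: str = "replicate") -> GradientVolume:
    """Prewitt gradient magnitude inside the open band (ILM, RPE).

    Each B-scan is convolved with the two orthogonal 3x3 Prewitt masks
    (axial derivative smoothed laterally, and vice versa); the magnitude is
    forced to zero wherever m <= ILM or m >= RPE so the retina/vitreous and
    RPE edges themselves cannot fire.
    """
    mode = _BORDER_MODES.get(border)
    if mode is None:
        raise ConfigError(f"border must be one of {sorted(_BORDER_MODES)}, got {border!r}")
    data = volume.data.astype(np.float32)
    deriv = np.array([1.0, 0.0, -1.0], dtype=np.float32)
    smooth = np.array([1.0, 1.0, 1.0], dtype=np.float32)
    # slice-wise 2-D Prewitt, vectorized over B-scans via separable 1-D passes
    g_v = ndimage.convolve1d(data, deriv, axis=0, mode=mode)
    g_v = ndimage.convolve1d(g_v, smooth, axis=1, mode=mode)
    g_h = ndimage.convolve1d(data, deriv, axis=1, mode=mode)
    g_h = ndimage.convolve1d(g_h, smooth, axis=0, mode=mode)
    mag = np.hypot(g_h, g_v)

    m_grid = np.arange(data.shape[0])[:, None, None]
    ilm_rows = np.where(ilm.defined, ilm.rows, np.inf)[None, :, :]
    rpe_rows = np.where(rpe.defined, rpe.rows, -np.inf)[None, :, :]
    mag[(m_grid <= ilm_rows) | (m_grid >= rpe_rows)] = 0.0
    # columns with either bound undefined carry no usable band
    bad = ~(ilm.defined & rpe.defined)
    mag[:, bad] = 0.0
    return GradientVolume(magnitudes=mag)


def detect_rnfl(volume: OctVolume, ilm: LayerSurface, rpe: LayerSurface,
                gradient_floor: float = 2.0, border: str = "replicate") -> LayerSurface:
    """Trace the RNFL lower boundary as the first gradient edge below the ILM.

    Per column, the smallest row with gradient magnitude above
    ``gradient_floor`` strictly between ILM and RPE. The floor (default 2
    gray levels) guards against noise; 0 restores the literal
    first-positive-gradient rule. Columns with no edge, or with an empty
    band, are undefined.
    """
    if gradient_floor < 0:
        raise ConfigError("gradient_floor must be >= 0")
    grad = gradient_volume(volume, ilm, rpe, border=border).magnitudes
    fires = grad > gradient_floor
    has_edge = fires.any(axis=0)
    first = np.argmax(fires, axis=0).astype(float)
    first[~has_edge] = UNDEFINED
    return LayerSurface(rows=first, label="RNFL")


# ---------------------------------------------------------------------------
# active-edge correction
# ---------------------------------------------------------------------------

def _bridge_gaps(rows: np.ndarray) -> np.ndarray:
    """Linearly interpolate undefined entries along n, per B-scan."""
    out = rows.copy()
    n_cols = rows.shape[0]
    x = np.arange(n_cols)
    for i in range(rows.shape[1]):
        col = out[:, i]
        good = np.isfinite(col)
        if not good.any():
            continue
        if not good.all():
            out[:, i] = np.interp(x, x[good], col[good])
    return out


def _windowed_means(img: np.ndarray, h_up: int, h_down: int) -> np.ndarray:
    """Contrast objective D(r) = mean(rows [r-h_up, r-1]) - mean(rows [r, r+h_down-1]).

    Row r is read as the first row *below* the edge. Windows that spill over
    the image border are clipped to the rows available.
    """
    n_rows = img.shape[0]
    cs = np.concatenate([np.zeros((1,) + img.shape[1:], img.dtype),
                         np.cumsum(img, axis=0)])
    r = np.arange(n_rows)
    up_lo, up_hi = np.maximum(r - h_up, 0), r
    dn_lo, dn_hi = r, np.minimum(r + h_down, n_rows)
    up_cnt = np.maximum(up_hi - up_lo, 1)
    dn_cnt = np.maximum(dn_hi - dn_lo, 1)
    shape = (n_rows,) + (1,) * (img.ndim - 1)
    above = (cs[up_hi] - cs[up_lo]) / up_cnt.reshape(shape)
    below = (cs[dn_hi] - cs[dn_lo]) / dn_cnt.reshape(shape)
    above[r == 0] = 0.0  # no rows above the top edge
    return above - below


def refine_contour(volume: OctVolume, contour: LayerSurface, ilm: LayerSurface,
                   rpe: LayerSurface, window: tuple[int, int] = (5, 5)) -> LayerSurface:
    """Active-edge correction of a contour (normally the RNFL lower boundary).

    Gaps in the input contour are first bridged by linear interpolation
    along n. Each contour point is then moved, within +/- the per-B-scan
    median ILM-RPE distance, to the row maximizing the difference between
    the mean brightness in a window just above and a window just below the
    candidate row -- i.e. onto the strongest light-to-dark transition.
    Candidates are kept inside (ILM, RPE] so the layer ordering survives.
    """
    h_up, h_down = window
    if h_up < 1 or h_down < 1:
        raise ConfigError(f"window heights must be positive, got {window}")
    data = volume.data.astype(np.float32)
    n_rows, n_cols, n_scans = data.shape
    if max(h_up, h_down) > n_rows:
        log.warning("refine window %s exceeds volume height %d; clipping", window, n_rows)

    bridged = _bridge_gaps(contour.rows)
    out = np.full_like(bridged, UNDEFINED)
    m = np.arange(n_rows)[:, None]

    for i in range(n_scans):
        centre = bridged[:, i]
        good = np.isfinite(centre)
        if not good.any():
            continue
        band = np.abs(ilm.rows[:, i] - rpe.rows[:, i])
        half = np.nanmedian(band)
        if not np.isfinite(half):
            half = n_rows  # no band info: scan everything
        objective = _windowed_means(data[:, :, i], h_up, h_down)

        lo = np.where(np.isfinite(ilm.rows[:, i]), ilm.rows[:, i] + 1, 0.0)
        hi = np.where(np.isfinite(rpe.rows[:, i]), rpe.rows[:, i], n_rows - 1.0)
        lo = np.maximum(lo, np.floor(centre - half))
        hi = np.minimum(hi, np.ceil(centre + half))
        allowed = (m >= lo[None, :]) & (m <= hi[None, :]) & good[None, :]
        # tiny proximity penalty: among equal-contrast rows stay near the input
        score = np.where(allowed, objective - 1e-6 * np.abs(m - centre[None, :]), -np.inf)
        best = np.argmax(score, axis=0).astype(float)
        feasible = np.isfinite(score[best.astype(int), np.arange(n_cols)])
        best[~feasible] = UNDEFINED
        out[:, i] = best
    return LayerSurface(rows=out, label=f"{contour.label or 'contour'}*")
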