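"""En-face optic-disk and cup geometry and the polar RNFL profile.

The optic disk is found where the detected RPE row departs far enough
posteriorly from its mean (the RPE terminates at the neural canal and
the brightest deep structure there lies well below the peripapillary RPE
level). The cup is the part of the disk where the ILM lies deeper than a
reference chord between the disk-edge RPE points raised 150 um
anteriorly -- the standard offset-plane cup definition. From the cleaned
masks come centroids, the equivalent radius r = sqrt(area/pi), and the
minimum cup-to-disk boundary distance. The peripapillary RNFL thickness
is finally resampled on a polar grid over the annulus [2r, 3r] around
the disk centroid, 1-degree bins, with TSNIT quadrant labels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .errors import AlgorithmError, ConfigError, NoDiskError, ValidationError
from .io_formats import Calibration, ReferenceProfile
from .layer_segmentation import UNDEFINED, LayerSurface


@dataclasses.dataclass
class EnFaceMask:
    """Binary N x I map in the en-face plane."""

    bits: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValidationError(f"mask must be 2-D (N, I), got {self.bits.shape}")

    @property
    def area(self) -> int:
        return int(self.bits.sum())


@dataclasses.dataclass
class DiskGeometry:
    n_d0: float
    i_d0: float
    r_disk: float
    n_c0: float | None = None
    i_c0: float | None = None
    r_cup: float | None = None
    r_min: float | None = None


@dataclasses.dataclass
class PolarRoi:
    """RNFL thickness per 1-degree bin, averaged over the annulus [2r, 3r]."""

    theta_deg: np.ndarray          # bin centres
    thickness_um: np.ndarray       # NaN where the bin is invalid
    valid: np.ndarray              # bool per bin
    quadrant: np.ndarray           # 'TE' / 'SU' / 'NA' / 'IN' per bin
    reference: ReferenceProfile | None = None


# ---------------------------------------------------------------------------
# disk mask
# ---------------------------------------------------------------------------

def _cleanup(bits: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill its holes."""
    labels = measure.label(bits, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(bits, dtype=bool)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def disk_mask(rpe: LayerSurface, p_m: float = 2.0 / 3.0,
              mode: str = "reciprocal") -> EnFaceMask:
    """Flag disk columns by RPE depth excursion, then clean up morphologically.

    In ``"reciprocal"`` mode (default) a column belongs to the disk when its
    RPE row exceeds mean(RPE)/p_m, i.e. sits at least 50% deeper than the
    mean for p_m = 2/3 -- the reading under which the threshold captures
    the excavated neural canal. ``"literal"`` mode applies the verbatim rule
    RPE > p_m * mean(RPE). Cleanup keeps the largest connected component
    and fills holes; an empty result raises :class:`NoDiskError`.
    """
    if not 0 < p_m < 1:
        raise ConfigError(f"p_m must lie in (0, 1), got {p_m}")
    if mode not in ("reciprocal", "literal"):
        raise ConfigError(f"unknown disk threshold mode {mode!r}")
    defined = rpe.defined
    if not defined.any() or rpe.defined_fraction < 0.5:
        raise AlgorithmError("RPE undefined on a majority of columns; no disk search possible")
    mean_row = float(np.mean(rpe.rows[defined]))
    threshold = mean_row / p_m if mode == "reciprocal" else mean_row * p_m
    bits = np.where(defined, rpe.rows > threshold, False)
    cleaned = _cleanup(bits)
    if not cleaned.any():
        raise NoDiskError(
            f"no disk region: no RPE depth excursion beyond {threshold:.1f} rows")
    return EnFaceMask(bits=cleaned, label="disk")


def mask_centroid_radius(mask: EnFaceMask) -> tuple[tuple[float, float], float]:
    """First-moment centroid (n0, i0) and equivalent radius sqrt(area/pi)."""
    bits = mask.bits
    area = bits.sum()
    if area == 0:
        raise AlgorithmError(f"empty {mask.label or 'mask'}: no centroid")
    nn, ii = np.nonzero(bits)
    return (float(nn.mean()), float(ii.mean())), float(np.sqrt(area / np.pi))


# ---------------------------------------------------------------------------
# cup mask
# ---------------------------------------------------------------------------

def detect_cup(ilm: LayerSurface, rpe: LayerSurface, disk: EnFaceMask,
               cal: Calibration, offset_um: float = 150.0) -> EnFaceMask:
    """Cup = disk columns where the ILM lies deeper than the offset chord.

    Per B-scan, a chord joins the RPE at the two disk-edge crossings
    (sampled just outside the disk); displaced ``offset_um`` anteriorly it
    forms the reference surface. A flat ILM never crosses it, so a
    cup-less disk yields an empty mask rather than an error.
    """
    if cal is None:
        raise ConfigError("calibration with axial scale required for cup detection")
    if offset_um <= 0:
        raise ConfigError("offset_um must be positive")
    if not disk.bits.any():
        raise AlgorithmError("empty disk mask: no cup search region")
    offset_px = offset_um / cal.axial_um_per_px

    disk_ilm = ilm.rows[disk.bits]
    if not np.any(np.isfinite(disk_ilm)):
        raise AlgorithmError("ILM undefined across the whole disk; cannot detect the cup")

    n_cols, n_scans = disk.bits.shape
    bits = np.zeros_like(disk.bits)
    for i in range(n_scans):
        cols = np.nonzero(disk.bits[:, i])[0]
        if cols.size == 0:
            continue
        n1, n2 = int(cols[0]), int(cols[-1])

        def _edge_rpe(inside: int, outside: int) -> float:
            if 0 <= outside < n_cols and np.isfinite(rpe.rows[outside, i]):
                return float(rpe.rows[outside, i])
            if np.isfinite(rpe.rows[inside, i]):
                return float(rpe.rows[inside, i])
            out_rows = rpe.rows[~disk.bits[:, i], i]
            out_rows = out_rows[np.isfinite(out_rows)]
            return float(np.median(out_rows)) if out_rows.size else np.nan

        r1, r2 = _edge_rpe(n1, n1 - 1), _edge_rpe(n2, n2 + 1)
        if not (np.isfinite(r1) and np.isfinite(r2)):
            continue
        span = np.arange(n1, n2 + 1)
        chord = r1 + (r2 - r1) * (span - n1) / max(n2 - n1, 1)
        ilm_rows = ilm.rows[span, i]
        deeper = np.isfinite(ilm_rows) & (ilm_rows > chord - offset_px)
        bits[span, i] = deeper & disk.bits[span, i]

    cleaned = _cleanup(bits) & disk.bits
    return EnFaceMask(bits=cleaned, label="cup")


# ---------------------------------------------------------------------------
# boundary distance
# ---------------------------------------------------------------------------

def _boundary_points(bits: np.ndarray) -> np.ndarray:
    """Mask pixels 8-adjacent to background (the whole mask if it is thin)."""
    eroded = ndimage.binary_erosion(bits, structure=np.ones((3, 3)), border_value=0)
    boundary = bits & ~eroded
    if not boundary.any():
        boundary = bits
    return np.column_stack(np.nonzero(boundary)).astype(float)


def min_boundary_distance(cup: EnFaceMask, disk: EnFaceMask) -> float:
    """Minimum Euclidean distance between cup and disk boundaries (en-face px)."""
    if not cup.bits.any() or not disk.bits.any():
        raise AlgorithmError("both masks must be nonempty for a boundary distance")
    if np.any(cup.bits & ~disk.bits):
        raise ValidationError("cup mask is not contained in the disk mask")
    disk_pts = _boundary_points(disk.bits)
    cup_pts = _boundary_points(cup.bits)
    dists, _ = cKDTree(disk_pts).query(cup_pts)
    return float(dists.min())


def measure_geometry(disk: EnFaceMask, cup: EnFaceMask | None) -> DiskGeometry:
    """Bundle centroids, equivalent radii and r_min into one record."""
    (n_d0, i_d0), r_disk = mask_centroid_radius(disk)
    geom = DiskGeometry(n_d0=n_d0, i_d0=i_d0, r_disk=r_disk)
    if cup is not None and cup.bits.any():
        (n_c0, i_c0), r_cup = mask_centroid_radius(cup)
        geom.n_c0, geom.i_c0, geom.r_cup = n_c0, i_c0, r_cup
        geom.r_min = min_boundary_distance(cup, disk)
    return geom


# ---------------------------------------------------------------------------
# polar RNFL profile
# ---------------------------------------------------------------------------

def _quadrants(theta_deg: np.ndarray, eye: str) -> np.ndarray:
    """TSNIT quadrant labels; TE centred at theta = 0 for a right eye."""
    theta = theta_deg % 360.0 if eye == "right" else (360.0 - theta_deg) % 360.0
    labels = np.empty(theta.shape, dtype="U2")
    labels[(theta < 45) | (theta >= 315)] = "TE"
    labels[(theta >= 45) & (theta < 135)] = "SU"
    labels[(theta >= 135) & (theta < 225)] = "NA"
    labels[(theta >= 225) & (theta < 315)] = "IN"
    return labels


def polar_thickness_profile(ilm: LayerSurface, rnfl_star: LayerSurface,
                            geom: DiskGeometry, cal: Calibration,
                            n_theta: int = 360,
                            reference: ReferenceProfile | None = None,
                            eye: str = "right",
                            min_valid_fraction: float = 0.5) -> PolarRoi:
    """Resample RNFL thickness over the annulus rho in [2 r_disk, 3 r_disk].

    Thickness = (RNFL* - ILM) * axial scale, interpolated bilinearly on a
    polar grid around the disk centroid: ``n_theta`` angular bins and
    ~1 px radial steps, averaged over rho per bin. The angle convention is
    theta = atan2(n - n_d0, i - i_d0), so displacement purely along +n is
    theta = 90 deg. With anisotropic en-face sampling (lateral scale !=
    B-scan spacing) rho is measured in um and the annulus is elliptical in
    pixel space; r_disk (a pixel-count radius) is converted through the
    geometric mean of the two lateral scales. Bins with under
    ``min_valid_fraction`` usable samples are flagged invalid.
    """
    if cal is None:
        raise ConfigError("calibration required for the polar profile")
    thickness = (rnfl_star.rows - ilm.rows) * cal.axial_um_per_px  # (N, I) um
    n_cols, n_scans = thickness.shape

    r_disk_um = geom.r_disk * np.sqrt(cal.lateral_um_per_px * cal.bscan_spacing_um)
    rho_step_um = min(cal.lateral_um_per_px, cal.bscan_spacing_um)
    rho = np.arange(2.0 * r_disk_um, 3.0 * r_disk_um + rho_step_um / 2, rho_step_um)
    theta_centres = (np.arange(n_theta) + 0.5) * 360.0 / n_theta
    theta_rad = np.deg2rad(theta_centres)

    # sample coordinates, (n_theta, n_rho)
    nn = geom.n_d0 + np.outer(np.sin(theta_rad), rho) / cal.lateral_um_per_px
    ii = geom.i_d0 + np.outer(np.cos(theta_rad), rho) / cal.bscan_spacing_um
    inside = (nn >= 0) & (nn <= n_cols - 1) & (ii >= 0) & (ii <= n_scans - 1)
    samples = ndimage.map_coordinates(thickness, [nn.ravel(), ii.ravel()],
                                      order=1, mode="constant", cval=np.nan)
    samples = samples.reshape(nn.shape)
    samples[~inside] = np.nan

    usable = np.isfinite(samples)
    frac = usable.mean(axis=1)
    valid = frac >= min_valid_fraction
    if not valid.any():
        raise AlgorithmError("polar annulus lies fully outside the defined image area")
    sums = np.where(usable, samples, 0.0).sum(axis=1)
    counts = usable.sum(axis=1)
    profile = sums / np.maximum(counts, 1)
    profile[~valid] = UNDEFINED
    return PolarRoi(theta_deg=theta_centres, thickness_um=profile, valid=valid,
                    quadrant=_quadrants(theta_centres, eye), reference=reference)
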