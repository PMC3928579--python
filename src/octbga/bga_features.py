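"""The BGA score and classic derived ONH features.

Biomorphological glaucoma advancement (BGA) averages three normalized
morphometric scores:

* ``w_g(1)`` -- eccentricity of the cup: Euclidean distance between cup
  and disk centroids, divided by the disk radius;
* ``w_g(2)`` -- boundary proximity: 1 - r_min / r_disk, where r_min is
  the minimum distance between cup and disk boundaries (1 when the cup
  touches the disk edge, 0 for a vanishing central cup);
* ``w_g(3)`` -- mean absolute relative deviation of the peripapillary
  RNFL thickness profile from a normative reference over the angular
  bins.

w_BGA = (w_g(1) + w_g(2) + w_g(3)) / 3 rises from 0 (healthy geometry)
towards 1 with advancing glaucomatous damage, and converts linearly to
an expected perimetric mean defect: MD = 24 * w_BGA - 9.34 dB.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .disk_cup_geometry import DiskGeometry, PolarRoi
from .errors import ValidationError


@dataclasses.dataclass
class BgaResult:
    wg1: float
    wg2: float
    wg3: float
    w_bga: float
    predicted_md: float

    @classmethod
    def from_scores(cls, wg1: float, wg2: float, wg3: float,
                    md_slope: float = 24.0, md_intercept: float = -9.34) -> "BgaResult":
        w_bga = bga(wg1, wg2, wg3)
        return cls(wg1=wg1, wg2=wg2, wg3=wg3, w_bga=w_bga,
                   predicted_md=predict_md(w_bga, md_slope, md_intercept))


def wg1(disk_centroid: tuple[float, float], cup_centroid: tuple[float, float],
        r_disk: float) -> float:
    """Relative centroid offset: |cup centroid - disk centroid| / r_disk."""
    if r_disk <= 0:
        raise ValidationError(f"r_disk must be positive, got {r_disk}")
    return math.dist(disk_centroid, cup_centroid) / r_disk


def wg2(r_min: float, r_disk: float) -> float:
    """Boundary-proximity score 1 - r_min / r_disk."""
    if r_disk <= 0:
        raise ValidationError(f"r_disk must be positive, got {r_disk}")
    if not 0 <= r_min <= r_disk:
        raise ValidationError(f"r_min must lie in [0, r_disk], got {r_min} vs {r_disk}")
    return 1.0 - r_min / r_disk


def wg3(roi: PolarRoi) -> float:
    """Mean absolute relative RNFL deviation from the reference profile.

    Averaged over the valid angular bins (the normalizer is the valid-bin
    count, so partial annulus coverage still yields a mean, not a
    coverage-weighted sum). Not clamped: thickness beyond twice the
    reference pushes the score above 1.
    """
    if roi.reference is None:
        raise ValidationError("polar ROI carries no reference profile")
    valid = roi.valid & np.isfinite(roi.thickness_um)
    if not valid.any():
        raise ValidationError("no valid angular bins to compare against the reference")
    ref = roi.reference(roi.theta_deg[valid])
    if np.any(ref <= 0):
        raise ValidationError("reference thickness must be strictly positive")
    return float(np.mean(np.abs(roi.thickness_um[valid] - ref) / ref))


def bga(wg1_score: float, wg2_score: float, wg3_score: float) -> float:
    """Arithmetic mean of the three component scores."""
    for name, score in (("wg1", wg1_score), ("wg2", wg2_score), ("wg3", wg3_score)):
        if score < 0:
            raise ValidationError(f"{name} must be non-negative, got {score}")
    return (wg1_score + wg2_score + wg3_score) / 3.0


def predict_md(w_bga: float, slope: float = 24.0, intercept: float = -9.34) -> float:
    """Expected perimetric mean defect (dB) under the linear conversion."""
    if not math.isfinite(w_bga):
        raise ValidationError(f"w_bga must be finite, got {w_bga}")
    return slope * w_bga + intercept


def bga_from_geometry(geom: DiskGeometry, roi: PolarRoi,
                      md_slope: float = 24.0, md_intercept: float = -9.34) -> BgaResult:
    """Assemble the full BGA result from measured geometry and polar profile."""
    if geom.n_c0 is None or geom.r_min is None:
        raise ValidationError("geometry lacks cup measurements; cannot score")
    return BgaResult.from_scores(
        wg1((geom.n_d0, geom.i_d0), (geom.n_c0, geom.i_c0), geom.r_disk),
        wg2(geom.r_min, geom.r_disk),
        wg3(roi),
        md_slope=md_slope, md_intercept=md_intercept,
    )


# ---------------------------------------------------------------------------
# classic derived features
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClassicFeatures:
    """Tabulated ONH indices derivable from areas and diameters.

    Field names follow the conventional feature numbering of clinical OCT
    reports: w5 cup/disk area ratio, w12 mean disk diameter, w15 mean cup
    diameter, w16/w17 horizontal/vertical C/D diameter ratios, w18 disk
    and w19 cup vertical-to-horizontal ratios. A zero denominator leaves
    the single affected feature NaN rather than failing the record.
    """

    w5: float
    w12: float
    w15: float
    w16: float
    w17: float
    w18: float
    w19: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def classic_derived_features(disk_area: float, cup_area: float,
                             d_h: float, d_v: float,
                             c_h: float, c_v: float) -> ClassicFeatures:
    """Derive the ratio/mean features from disk and cup areas and diameters.

    Areas in mm^2 and diameters in mm, as clinical software reports them.
    """
    if disk_area <= 0 or d_h <= 0 or d_v <= 0:
        raise ValidationError("disk area and diameters must be positive")
    return ClassicFeatures(
        w5=_ratio(cup_area, disk_area),
        w12=(d_h + d_v) / 2.0,
        w15=(c_h + c_v) / 2.0,
        w16=_ratio(c_h, d_h),
        w17=_ratio(c_v, d_v),
        w18=_ratio(d_v, d_h),
        w19=_ratio(c_v, c_h),
    )
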