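"""End-to-end segmentation pipeline.

Stage order: 3-D median filter -> RPE -> disk mask -> ILM -> RNFL lower
boundary -> active-edge correction -> cup mask -> polar RNFL profile ->
BGA scores -> predicted MD. Each stage logs its wall time and, for
surfaces, the percentage of undefined columns, keyed by stage name so
runs can be scraped from the log.
"""

from __future__ import annotations

import dataclasses
import logging
import time

from . import bga_features, disk_cup_geometry, layer_segmentation, preprocess
from .config import PipelineConfig
from .disk_cup_geometry import DiskGeometry, EnFaceMask, PolarRoi
from .errors import AlgorithmError
from .io_formats import ReferenceProfile
from .layer_segmentation import LayerSurface
from .preprocess import OctVolume

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SegmentationResult:
    surfaces: dict[str, LayerSurface]
    masks: dict[str, EnFaceMask]
    geometry: DiskGeometry
    roi: PolarRoi
    bga: bga_features.BgaResult

    def feature_row(self) -> dict[str, float]:
        """Flat mapping written to the results CSV."""
        geom = self.geometry
        return {
            "n_d0": geom.n_d0, "i_d0": geom.i_d0, "r_disk": geom.r_disk,
            "n_c0": geom.n_c0, "i_c0": geom.i_c0, "r_cup": geom.r_cup,
            "r_min": geom.r_min,
            "w_g(1)": self.bga.wg1, "w_g(2)": self.bga.wg2, "w_g(3)": self.bga.wg3,
            "w_BGA": self.bga.w_bga, "predicted_MD_dB": self.bga.predicted_md,
        }


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        log.info("stage=%s elapsed=%.2fs", self.name, time.perf_counter() - self.t0)


def _log_surface(name: str, surface: LayerSurface) -> None:
    log.info("stage=%s undefined_columns=%.2f%%", name,
             100.0 * (1.0 - surface.defined_fraction))


def run_segment(volume: OctVolume, reference: ReferenceProfile,
                config: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full analysis on one volume; raises on unmet stage preconditions."""
    cfg = config or PipelineConfig()
    if volume.calibration is None:
        raise AlgorithmError("volume carries no calibration; cup/polar stages need it")

    with _StageTimer("median_filter"):
        filtered = preprocess.median_filter_3d(volume, cfg.median_mask, cfg.border)
    with _StageTimer("rpe"):
        rpe = layer_segmentation.detect_rpe(filtered)
        _log_surface("rpe", rpe)
    with _StageTimer("disk"):
        disk = disk_cup_geometry.disk_mask(rpe, cfg.p_m, cfg.disk_threshold_mode)
    with _StageTimer("ilm"):
        ilm = layer_segmentation.detect_ilm(filtered, rpe, scope=cfg.otsu_scope)
        _log_surface("ilm", ilm)
    with _StageTimer("rnfl"):
        rnfl = layer_segmentation.detect_rnfl(filtered, ilm, rpe,
                                              gradient_floor=cfg.gradient_floor,
                                              border=cfg.border)
        _log_surface("rnfl", rnfl)
    with _StageTimer("refine"):
        rnfl_star = layer_segmentation.refine_contour(filtered, rnfl, ilm, rpe,
                                                      window=cfg.refine_window)
        _log_surface("refine", rnfl_star)
    with _StageTimer("cup"):
        cup = disk_cup_geometry.detect_cup(ilm, rpe, disk, volume.calibration,
                                           offset_um=cfg.cup_offset_um)
    with _StageTimer("geometry"):
        geometry = disk_cup_geometry.measure_geometry(disk, cup)
        if geometry.r_min is None:
            raise AlgorithmError("no cup detected; BGA scores need a cup")
    with _StageTimer("polar"):
        roi = disk_cup_geometry.polar_thickness_profile(
            ilm, rnfl_star, geometry, volume.calibration,
            n_theta=cfg.polar_bins, reference=reference, eye=cfg.eye)
    with _StageTimer("bga"):
        result = bga_features.bga_from_geometry(geometry, roi,
                                                md_slope=cfg.md_slope,
                                                md_intercept=cfg.md_intercept)
    return SegmentationResult(
        surfaces={"rpe": rpe, "ilm": ilm, "rnfl": rnfl, "rnfl_star": rnfl_star},
        masks={"disk": disk, "cup": cup},
        geometry=geometry,
        roi=roi,
        bga=result,
    )
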