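"""Synthetic ONH OCT phantoms with analytic ground truth.

A phantom emulates the structures the pipeline segments: a bright RNFL
slab starting at the ILM, a dark inter-layer gap, the RPE as the
brightest band, an optic disk where the peripapillary RPE terminates and
the brightest deep structure is the excavated disk floor, a cup as an
ILM depression with steep walls, vessel shadows as multiplicative
attenuation columns, and additive Gaussian noise. Geometry (circular
disk and cup, angular thickness profile) is analytic, so every
downstream measurement has a closed-form expected value.

Rendering choices: the RPE and disk floor are Gaussian-profile bands
(sigma 2 px) giving a stable per-column argmax; the RNFL slab has sharp
axial edges so the first-gradient-edge rule has a well-defined target
row. Surfaces are rounded to integer rows before rendering and the
ground truth stores the rounded surfaces, so surface-recovery errors
measure the segmentation, not the rasterization. The RNFL lower-boundary
truth is the first dark row below the slab. Speckle, eye motion and
tilted anatomies are not modelled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .bga_features import BgaResult
from .disk_cup_geometry import EnFaceMask
from .errors import ValidationError
from .io_formats import Calibration, ReferenceProfile
from .layer_segmentation import LayerSurface
from .preprocess import OctVolume

_BAND_SIGMA = 2.0      # axial st.dev. of the RPE / floor bright bands, px
_CUP_WALL_PX = 1.0     # half-width of the cup wall ramp, px

DEFAULT_BRIGHTNESS: Mapping[str, int] = {
    "background": 20,
    "rnfl": 180,
    "rpe": 230,
    "floor": 230,
    "below_rpe": 35,
}


@dataclasses.dataclass(frozen=True)
class VesselShadow:
    """A vessel casting a shadow: all rows below the inner retina in the
    affected A-scan columns are attenuated multiplicatively."""

    n_px: float
    width_px: float
    attenuation: float  # 0 = no shadow, 1 = total extinction

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValidationError(f"VesselShadow.attenuation must lie in [0, 1], "
                                  f"got {self.attenuation}")
        if self.width_px <= 0:
            raise ValidationError("VesselShadow.width_px must be positive")


@dataclasses.dataclass
class PhantomSpec:
    """Full description of one phantom; every field has an analytic meaning."""

    volume_dims: tuple[int, int, int] = (256, 256, 64)  # (M, N, I)
    axial_um_per_px: float = 4.0
    lateral_um_per_px: float = 12.0
    bscan_spacing_um: float = 12.0
    ilm_base_row: int = 60
    rnfl_thickness_um: float | Callable[[np.ndarray], np.ndarray] = 100.0
    rpe_depth_row: int = 120
    disk_center: tuple[float, float] = (128.0, 32.0)  # (n, i) en-face px
    disk_radius_px: float = 28.0
    cup_center: tuple[float, float] = (128.0, 32.0)
    cup_radius_px: float = 14.0
    cup_depth_um: float = 160.0
    disk_floor_row: int | None = None  # default: 5/3 of the RPE depth
    vessel_shadows: tuple[VesselShadow, ...] = ()
    noise_sd: float = 5.0
    layer_brightness: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BRIGHTNESS))
    reference_thickness: ReferenceProfile | float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        M, N, I = self.volume_dims
        if min(M, N, I) < 8:
            raise ValidationError(f"volume_dims too small: {self.volume_dims}")
        for name in ("axial_um_per_px", "lateral_um_per_px", "bscan_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.disk_radius_px < 0 or self.cup_radius_px < 0:
            raise ValidationError("radii must be non-negative")
        if self.cup_radius_px > self.disk_radius_px:
            raise ValidationError("cup_radius_px exceeds disk_radius_px")
        d = float(np.hypot(self.cup_center[0] - self.disk_center[0],
                           self.cup_center[1] - self.disk_center[1]))
        if d + self.cup_radius_px > self.disk_radius_px + 1e-9:
            raise ValidationError(
                "cup_center/cup_radius_px: cup boundary protrudes outside the disk")
        if self.cup_depth_um < 0 or self.noise_sd < 0:
            raise ValidationError("cup_depth_um and noise_sd must be non-negative")
        bright = dict(self.layer_brightness)
        if bright["rpe"] < max(bright.values()):
            raise ValidationError("layer_brightness: the RPE must be the brightest layer")
        if not 0 <= self.ilm_base_row < M or not 0 <= self.rpe_depth_row < M:
            raise ValidationError("ilm_base_row/rpe_depth_row outside [0, M-1]")
        if self.disk_radius_px > 0 and self.floor_row >= M - int(3 * _BAND_SIGMA):
            raise ValidationError("disk_floor_row too deep for the volume height")
        if self.ilm_base_row >= self.rpe_depth_row:
            raise ValidationError("ilm_base_row must lie above rpe_depth_row")

    # ------------------------------------------------------------------
    @property
    def floor_row(self) -> int:
        if self.disk_floor_row is not None:
            return self.disk_floor_row
        return int(round(self.rpe_depth_row * 5.0 / 3.0))

    def thickness_um_at(self, theta_deg: np.ndarray) -> np.ndarray:
        if callable(self.rnfl_thickness_um):
            return np.asarray(self.rnfl_thickness_um(np.asarray(theta_deg, float)), float)
        return np.full(np.shape(theta_deg), float(self.rnfl_thickness_um))

    def reference_um_at(self, theta_deg: np.ndarray) -> np.ndarray:
        if isinstance(self.reference_thickness, ReferenceProfile):
            return self.reference_thickness(theta_deg)
        return np.full(np.shape(theta_deg), float(self.reference_thickness))

    def reference_profile(self) -> ReferenceProfile:
        if isinstance(self.reference_thickness, ReferenceProfile):
            return self.reference_thickness
        return ReferenceProfile.constant(float(self.reference_thickness))

    def calibration(self) -> Calibration:
        M, N, I = self.volume_dims
        return Calibration(axial_um_per_px=self.axial_um_per_px,
                           lateral_um_per_px=self.lateral_um_per_px,
                           bscan_spacing_um=self.bscan_spacing_um,
                           n_ascans=N, n_bscans=I)

    # ------------------------------------------------------------------ io
    def to_ini(self, path: str | Path) -> None:
        import configparser

        if callable(self.rnfl_thickness_um) or isinstance(self.reference_thickness,
                                                          ReferenceProfile):
            raise ValidationError("only constant thickness profiles round-trip to INI")
        cp = configparser.ConfigParser()
        cp["phantom"] = {
            "volume_dims": ",".join(map(str, self.volume_dims)),
            "axial_um_per_px": str(self.axial_um_per_px),
            "lateral_um_per_px": str(self.lateral_um_per_px),
            "bscan_spacing_um": str(self.bscan_spacing_um),
            "ilm_base_row": str(self.ilm_base_row),
            "rnfl_thickness_um": str(self.rnfl_thickness_um),
            "rpe_depth_row": str(self.rpe_depth_row),
            "disk_center": ",".join(map(str, self.disk_center)),
            "disk_radius_px": str(self.disk_radius_px),
            "cup_center": ",".join(map(str, self.cup_center)),
            "cup_radius_px": str(self.cup_radius_px),
            "cup_depth_um": str(self.cup_depth_um),
            "disk_floor_row": str(self.floor_row),
            "vessel_shadows": ";".join(
                f"{v.n_px}:{v.width_px}:{v.attenuation}" for v in self.vessel_shadows),
            "noise_sd": str(self.noise_sd),
            "reference_thickness": str(self.reference_thickness),
            "seed": str(self.seed),
        }
        cp["brightness"] = {k: str(v) for k, v in self.layer_brightness.items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: str | Path) -> "PhantomSpec":
        import configparser

        cp = configparser.ConfigParser()
        cp.read(path)
        s = cp["phantom"]
        vessels = tuple(
            VesselShadow(*(float(x) for x in chunk.split(":")))
            for chunk in s.get("vessel_shadows", "").split(";") if chunk
        )
        return cls(
            volume_dims=tuple(int(v) for v in s["volume_dims"].split(",")),  # type: ignore[arg-type]
            axial_um_per_px=float(s["axial_um_per_px"]),
            lateral_um_per_px=float(s["lateral_um_per_px"]),
            bscan_spacing_um=float(s["bscan_spacing_um"]),
            ilm_base_row=int(s["ilm_base_row"]),
            rnfl_thickness_um=float(s["rnfl_thickness_um"]),
            rpe_depth_row=int(s["rpe_depth_row"]),
            disk_center=tuple(float(v) for v in s["disk_center"].split(",")),  # type: ignore[arg-type]
            disk_radius_px=float(s["disk_radius_px"]),
            cup_center=tuple(float(v) for v in s["cup_center"].split(",")),  # type: ignore[arg-type]
            cup_radius_px=float(s["cup_radius_px"]),
            cup_depth_um=float(s["cup_depth_um"]),
            disk_floor_row=int(s["disk_floor_row"]),
            vessel_shadows=vessels,
            noise_sd=float(s["noise_sd"]),
            layer_brightness={k: int(v) for k, v in cp["brightness"].items()}
            if "brightness" in cp else dict(DEFAULT_BRIGHTNESS),
            reference_thickness=float(s["reference_thickness"]),
            seed=int(s["seed"]),
        )


@dataclasses.dataclass
class GroundTruth:
    ilm: LayerSurface
    rnfl: LayerSurface
    rpe: LayerSurface
    disk_mask: EnFaceMask
    cup_mask: EnFaceMask
    true_features: BgaResult | None  # None for disk-less phantoms


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------

def analytic_truth(spec: PhantomSpec, n_theta: int = 360,
                   md_slope: float = 24.0, md_intercept: float = -9.34) -> BgaResult:
    """Closed-form BGA scores for the circular phantom geometry.

    With centroid distance d: w_g(1) = d / r_disk, and for an interior cup
    the closest boundary approach is r_min = r_disk - (d + r_cup), so
    w_g(2) = (d + r_cup) / r_disk. w_g(3) averages the absolute relative
    deviation of the angular thickness profile from the reference over
    ``n_theta`` bin centres.
    """
    if spec.disk_radius_px <= 0:
        raise ValidationError("disk_radius_px must be positive for analytic truth")
    d = float(np.hypot(spec.cup_center[0] - spec.disk_center[0],
                       spec.cup_center[1] - spec.disk_center[1]))
    r_min = spec.disk_radius_px - (d + spec.cup_radius_px)
    if r_min < -1e-9:
        raise ValidationError("cup protrudes outside the disk; no analytic truth")
    theta = (np.arange(n_theta) + 0.5) * 360.0 / n_theta
    thickness = spec.thickness_um_at(theta)
    reference = spec.reference_um_at(theta)
    if np.any(reference <= 0):
        raise ValidationError("reference thickness must be strictly positive")
    wg3 = float(np.mean(np.abs(thickness - reference) / reference))
    return BgaResult.from_scores(
        wg1=d / spec.disk_radius_px,
        wg2=1.0 - max(r_min, 0.0) / spec.disk_radius_px,
        wg3=wg3,
        md_slope=md_slope, md_intercept=md_intercept,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _surfaces(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                                          np.ndarray]:
    """Integer ILM / RNFL-lower / RPE row maps and the two en-face masks."""
    M, N, I = spec.volume_dims
    nn, ii = np.meshgrid(np.arange(N, dtype=float), np.arange(I, dtype=float),
                         indexing="ij")
    theta = np.degrees(np.arctan2(nn - spec.disk_center[0],
                                  ii - spec.disk_center[1])) % 360.0
    thickness_px = spec.thickness_um_at(theta) / spec.axial_um_per_px

    rho_disk = np.hypot(nn - spec.disk_center[0], ii - spec.disk_center[1])
    disk = rho_disk <= spec.disk_radius_px

    rho_cup = np.hypot(nn - spec.cup_center[0], ii - spec.cup_center[1])
    if spec.cup_radius_px > 0 and spec.cup_depth_um > 0:
        # cosine ramp from full depth inside the cup to zero past the wall
        t = np.clip((rho_cup - (spec.cup_radius_px - _CUP_WALL_PX))
                    / (2.0 * _CUP_WALL_PX), 0.0, 1.0)
        dip_px = (spec.cup_depth_um / spec.axial_um_per_px) * 0.5 * (1 + np.cos(np.pi * t))
        cup = rho_cup <= spec.cup_radius_px
    else:
        dip_px = np.zeros_like(rho_cup)
        cup = np.zeros_like(disk)

    ilm = np.round(spec.ilm_base_row + dip_px)
    rnfl = np.round(spec.ilm_base_row + dip_px + thickness_px)
    rpe = np.where(disk, float(spec.floor_row), float(spec.rpe_depth_row))

    if np.any(ilm < 2):
        raise ValidationError("ilm_base_row: ILM reaches the top of the volume")
    gap = rpe - rnfl
    if np.any(gap < 3 * _BAND_SIGMA):
        raise ValidationError(
            "cup_depth_um/rnfl_thickness_um: RNFL lower boundary collides with the "
            "RPE/floor band (layer ordering ILM < RNFL < RPE violated)")
    return ilm, rnfl, rpe, disk, cup


def generate_phantom(spec: PhantomSpec) -> tuple[OctVolume, GroundTruth]:
    """Render the phantom volume and return it with its ground truth.

    Deterministic for a fixed ``spec.seed``; with ``noise_sd = 0`` the seed
    is irrelevant and two renders are identical.
    """
    M, N, I = spec.volume_dims
    ilm, rnfl, rpe, disk, cup = _surfaces(spec)
    bright = dict(spec.layer_brightness)

    m = np.arange(M, dtype=np.float32)[:, None, None]
    vol = np.full((M, N, I), float(bright["background"]), dtype=np.float32)
    slab = (m >= ilm[None]) & (m < rnfl[None])
    vol[slab] = bright["rnfl"]

    band_bright = np.where(disk, float(bright["floor"]), float(bright["rpe"]))
    band = band_bright[None] * np.exp(-((m - rpe[None]) ** 2) / (2 * _BAND_SIGMA ** 2))
    np.maximum(vol, band.astype(np.float32), out=vol)
    below = m > (rpe[None] + 3 * _BAND_SIGMA)
    np.maximum(vol, np.where(below, float(bright["below_rpe"]), 0.0).astype(np.float32),
               out=vol)

    for vessel in spec.vessel_shadows:
        cols = np.abs(np.arange(N) - vessel.n_px) <= vessel.width_px / 2.0
        if not cols.any():
            continue
        # the vessel sits in the inner retina: the whole column from the ILM
        # down is dimmed, so the shadow has no artificial bright cap
        shadow_top = ilm[cols, :][None] - 0.5
        factor = np.where(m > shadow_top, 1.0 - vessel.attenuation, 1.0)
        vol[:, cols, :] *= factor.astype(np.float32)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)
    data = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        ilm=LayerSurface(rows=ilm, label="ILM"),
        rnfl=LayerSurface(rows=rnfl, label="RNFL"),
        rpe=LayerSurface(rows=rpe, label="RPE"),
        disk_mask=EnFaceMask(bits=disk, label="disk"),
        cup_mask=EnFaceMask(bits=cup, label="cup"),
        true_features=analytic_truth(spec) if spec.disk_radius_px > 0 else None,
    )
    return OctVolume(data=data, calibration=spec.calibration()), truth


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------

def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth as JSON: surfaces as row arrays (null = undefined),
    masks as 0/1 arrays, analytic features as a flat mapping."""
    def _surface(s: LayerSurface) -> list:
        return np.where(np.isfinite(s.rows), s.rows, None).tolist()

    payload = {
        "surfaces": {name: _surface(getattr(truth, name))
                     for name in ("ilm", "rnfl", "rpe")},
        "masks": {name: getattr(truth, f"{name}_mask").bits.astype(int).tolist()
                  for name in ("disk", "cup")},
        "true_features": (dataclasses.asdict(truth.true_features)
                          if truth.true_features is not None else None),
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def _surface(rows: list, label: str) -> LayerSurface:
        arr = np.array([[np.nan if v is None else float(v) for v in col]
                        for col in rows])
        return LayerSurface(rows=arr, label=label)

    return GroundTruth(
        ilm=_surface(payload["surfaces"]["ilm"], "ILM"),
        rnfl=_surface(payload["surfaces"]["rnfl"], "RNFL"),
        rpe=_surface(payload["surfaces"]["rpe"], "RPE"),
        disk_mask=EnFaceMask(bits=np.array(payload["masks"]["disk"], bool), label="disk"),
        cup_mask=EnFaceMask(bits=np.array(payload["masks"]["cup"], bool), label="cup"),
        true_features=(BgaResult(**payload["true_features"])
                       if payload["true_features"] is not None else None),
    )
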