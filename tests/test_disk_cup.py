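"""En-face geometry: disk/cup masks, moments, boundary distance, polar profile."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from octbga import preprocess
from octbga.disk_cup_geometry import (EnFaceMask, _boundary_points, detect_cup,
                                      disk_mask, mask_centroid_radius,
                                      measure_geometry, min_boundary_distance,
                                      polar_thickness_profile)
from octbga.errors import AlgorithmError, NoDiskError, ValidationError
from octbga.io_formats import Calibration, ReferenceProfile
from octbga.layer_segmentation import LayerSurface, detect_ilm, detect_rpe
from octbga.phantom import PhantomSpec, generate_phantom


def _circle(shape, centre, radius):
    nn, ii = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return np.hypot(nn - centre[0], ii - centre[1]) <= radius


# -------------------------------------------------------------------- moments

def test_centroid_radius_closed_forms():
    bits = np.zeros((16, 16), bool)
    bits[7, 9] = True
    (n0, i0), r = mask_centroid_radius(EnFaceMask(bits=bits))
    assert (n0, i0) == (7.0, 9.0)
    assert r == pytest.approx(1 / np.sqrt(np.pi))

    square = np.zeros((20, 20), bool)
    square[5:15, 5:15] = True
    (_, _), r = mask_centroid_radius(EnFaceMask(bits=square))
    assert r == pytest.approx(np.sqrt(100 / np.pi))


def test_centroid_radius_recovers_rasterized_circle():
    bits = _circle((64, 64), (31.3, 30.7), 20.0)
    (n0, i0), r = mask_centroid_radius(EnFaceMask(bits=bits))
    # pixel-count oracle: area of the same rasterization
    assert r == pytest.approx(np.sqrt(bits.sum() / np.pi))
    assert abs(r - 20.0) <= 0.2  # within 1% of the analytic radius
    assert abs(n0 - 31.3) < 1 and abs(i0 - 30.7) < 1


def test_empty_mask_rejected():
    with pytest.raises(AlgorithmError):
        mask_centroid_radius(EnFaceMask(bits=np.zeros((4, 4), bool)))


# ------------------------------------------------------------------ disk mask

def test_flat_rpe_has_no_disk():
    rpe = LayerSurface(rows=np.full((32, 32), 80.0), label="RPE")
    with pytest.raises(NoDiskError):
        disk_mask(rpe)


def test_disk_mask_recovers_phantom_excavation():
    spec = PhantomSpec(noise_sd=0.0, disk_radius_px=20.0, cup_radius_px=10.0)
    volume, truth = generate_phantom(spec)
    filtered = preprocess.median_filter_3d(volume)
    mask = disk_mask(detect_rpe(filtered))
    assert abs(mask.area - np.pi * 20.0**2) / (np.pi * 20.0**2) <= 0.10
    (n0, i0), _ = mask_centroid_radius(mask)
    assert abs(n0 - spec.disk_center[0]) <= 1 and abs(i0 - spec.disk_center[1]) <= 1


def test_largest_excavation_survives_cleanup():
    rows = np.full((64, 64), 80.0)
    rows[_circle((64, 64), (20, 32), 8)] = 140.0   # large excavation
    rows[_circle((64, 64), (50, 32), 2)] = 140.0   # small spurious one
    mask = disk_mask(LayerSurface(rows=rows, label="RPE"))
    assert mask.bits[20, 32] and not mask.bits[50, 32]


# ------------------------------------------------------------------------ cup

@pytest.fixture(scope="module")
def segmented_layers():
    spec = PhantomSpec(noise_sd=0.0)
    volume, truth = generate_phantom(spec)
    filtered = preprocess.median_filter_3d(volume)
    rpe = detect_rpe(filtered)
    ilm = detect_ilm(filtered, rpe)
    return spec, volume, rpe, ilm, disk_mask(rpe)


def test_flat_ilm_gives_empty_cup():
    spec = PhantomSpec(noise_sd=0.0, cup_depth_um=0.0)
    volume, _ = generate_phantom(spec)
    filtered = preprocess.median_filter_3d(volume)
    rpe = detect_rpe(filtered)
    ilm = detect_ilm(filtered, rpe)
    cup = detect_cup(ilm, rpe, disk_mask(rpe), volume.calibration)
    assert cup.area == 0


def test_deep_cup_radius_recovered(segmented_layers):
    spec, volume, rpe, ilm, disk = segmented_layers
    cup = detect_cup(ilm, rpe, disk, volume.calibration)
    _, r_cup = mask_centroid_radius(cup)
    assert abs(r_cup - spec.cup_radius_px) <= 2


def test_cup_area_monotone_in_offset(segmented_layers):
    # raising the reference plane farther above the RPE can only enlarge the
    # sub-plane level set of the ILM, so the cup area is non-decreasing
    spec, volume, rpe, ilm, disk = segmented_layers
    small = detect_cup(ilm, rpe, disk, volume.calibration, offset_um=150.0)
    large = detect_cup(ilm, rpe, disk, volume.calibration, offset_um=300.0)
    assert large.area >= small.area


def test_cup_requires_calibration(segmented_layers):
    _, _, rpe, ilm, disk = segmented_layers
    with pytest.raises(Exception):
        detect_cup(ilm, rpe, disk, None)


# ---------------------------------------------------------- boundary distance

def test_concentric_circle_boundary_distance():
    disk = EnFaceMask(bits=_circle((40, 40), (20, 20), 10))
    cup = EnFaceMask(bits=_circle((40, 40), (20, 20), 5))
    assert min_boundary_distance(cup, disk) == pytest.approx(5.0, abs=1.0)


def test_touching_masks_distance_zero():
    disk = EnFaceMask(bits=_circle((40, 40), (20, 20), 10))
    cup_bits = _circle((40, 40), (25, 20), 5)
    cup = EnFaceMask(bits=cup_bits & disk.bits)  # shares boundary pixels
    assert min_boundary_distance(cup, disk) == 0.0


def test_cup_not_inside_disk_rejected():
    disk = EnFaceMask(bits=_circle((40, 40), (15, 15), 8))
    cup = EnFaceMask(bits=_circle((40, 40), (28, 28), 6))
    with pytest.raises(ValidationError):
        min_boundary_distance(cup, disk)


def test_distance_matches_all_pairs_oracle(rng):
    for _ in range(20):
        disk_bits = np.zeros((32, 32), bool)
        c = rng.integers(10, 22, 2)
        disk_bits |= _circle((32, 32), c, rng.integers(6, 10))
        r_cup = rng.integers(1, 4)
        cup_bits = _circle((32, 32), c + rng.integers(-2, 3, 2), r_cup) & disk_bits
        if not cup_bits.any():
            continue
        disk = EnFaceMask(bits=disk_bits)
        cup = EnFaceMask(bits=cup_bits)
        expected = cdist(_boundary_points(cup.bits), _boundary_points(disk.bits)).min()
        assert min_boundary_distance(cup, disk) == pytest.approx(expected)


def test_r_min_decreases_as_cup_grows():
    previous = np.inf
    for r_cup in (4, 8, 12, 16):
        disk = EnFaceMask(bits=_circle((64, 64), (32, 32), 20))
        cup = EnFaceMask(bits=_circle((64, 64), (32, 32), r_cup))
        current = min_boundary_distance(cup, disk)
        assert current < previous
        previous = current


# ------------------------------------------------------------- polar profile

def _constant_thickness_setup(lateral=12.0, bspacing=12.0):
    cal = Calibration(4.0, lateral, bspacing, 256, 256)
    ilm = LayerSurface(rows=np.full((256, 256), 60.0), label="ILM")
    star = LayerSurface(rows=np.full((256, 256), 85.0), label="RNFL")  # 25 px = 100 um
    geom = measure_geometry(EnFaceMask(bits=_circle((256, 256), (128, 128), 28)), None)
    return ilm, star, geom, cal


def test_constant_thickness_profile_flat_everywhere():
    ilm, star, geom, cal = _constant_thickness_setup()
    roi = polar_thickness_profile(ilm, star, geom, cal)
    assert roi.valid.all()
    assert np.all(np.abs(roi.thickness_um[roi.valid] - 100.0) <= 2.0)
    # rotational symmetry: spread below 2% of the mean
    assert np.ptp(roi.thickness_um) <= 0.02 * 100.0


def test_anisotropic_calibration_still_recovers_constant_thickness():
    ilm, star, geom, cal = _constant_thickness_setup(lateral=6.0, bspacing=24.0)
    roi = polar_thickness_profile(ilm, star, geom, cal)
    assert np.all(np.abs(roi.thickness_um[roi.valid] - 100.0) <= 2.0)


def test_theta_convention_displacement_along_n_is_90_degrees():
    ilm, star, geom, cal = _constant_thickness_setup()
    # mark a sector by thickening the RNFL only where n > centre (theta near 90)
    rows = star.rows.copy()
    rows[170:, :] = 95.0  # 35 px = 140 um, reached only along +n
    roi = polar_thickness_profile(ilm, LayerSurface(rows=rows, label="RNFL"),
                                  geom, cal)
    bump = roi.theta_deg[roi.thickness_um > 120.0]
    assert bump.size > 0
    assert np.all((bump > 35.0) & (bump < 145.0))
    assert np.any(np.abs(bump - 90.0) < 10.0)


def test_quadrant_labels_cover_tsnit():
    ilm, star, geom, cal = _constant_thickness_setup()
    roi = polar_thickness_profile(ilm, star, geom, cal)
    assert roi.quadrant[0] == "TE"          # theta ~ 0.5 deg
    assert roi.quadrant[90] == "SU"
    assert roi.quadrant[180] == "NA"
    assert roi.quadrant[270] == "IN"


def test_annulus_outside_image_rejected():
    cal = Calibration(4.0, 12.0, 12.0, 32, 32)
    ilm = LayerSurface(rows=np.full((32, 32), np.nan), label="ILM")
    star = LayerSurface(rows=np.full((32, 32), np.nan), label="RNFL")
    geom = measure_geometry(EnFaceMask(bits=_circle((32, 32), (16, 16), 10)), None)
    with pytest.raises(AlgorithmError):
        polar_thickness_profile(ilm, star, geom, cal)
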