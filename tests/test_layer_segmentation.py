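"""Layer segmentation against brute-force oracles and phantom ground truth."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.filters import threshold_otsu

from octbga import layer_segmentation as ls, preprocess
from octbga.errors import AlgorithmError, DegenerateInputError
from octbga.layer_segmentation import (LayerSurface, detect_ilm, detect_rnfl,
                                       detect_rpe, gradient_volume, otsu_threshold,
                                       refine_contour)
from octbga.phantom import PhantomSpec, VesselShadow, generate_phantom
from octbga.preprocess import OctVolume

from conftest import random_volume


def otsu_brute_force(values: np.ndarray) -> int:
    """Exhaustive sweep of all 255 cuts maximizing between-class variance.

    Cuts through an empty histogram span tie exactly; the middle of the
    tied run is returned.
    """
    values = np.asarray(values, dtype=float).ravel()
    scores = np.full(255, -1.0)
    for t in range(255):
        lo, hi = values[values <= t], values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        scores[t] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    ties = np.nonzero(scores >= scores.max() * (1 - 1e-12))[0]
    return int(ties[len(ties) // 2])


# ------------------------------------------------------------------------ Otsu

def test_otsu_bimodal_threshold_between_modes():
    sample = np.array([0] * 50 + [200] * 50, dtype=np.uint8)
    assert 0 < otsu_threshold(sample) < 200


@given(seed=st.integers(0, 2**16))
def test_otsu_equals_exhaustive_sweep(seed):
    rng = np.random.default_rng(seed)
    sample = np.concatenate([
        rng.integers(0, 100, rng.integers(5, 60)),
        rng.integers(90, 256, rng.integers(5, 60)),
    ]).astype(np.uint8)
    if np.ptp(sample) == 0:
        return
    assert otsu_threshold(sample) == otsu_brute_force(sample)


def test_otsu_agrees_with_skimage(rng):
    # overlapping modes: no empty span between classes, so the maximum is unique
    sample = np.concatenate([rng.integers(0, 120, 300),
                             rng.integers(80, 256, 200)]).astype(np.uint8)
    ours = otsu_threshold(sample)
    theirs = threshold_otsu(hist=np.bincount(sample, minlength=256))
    assert abs(int(ours) - int(theirs)) <= 1  # bin-edge convention differs at most


def test_otsu_constant_sample_is_degenerate():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.array([5, 5, 5], dtype=np.uint8))


# ------------------------------------------------------------------------- RPE

def test_rpe_equals_argmax_oracle_on_unique_columns(rng):
    volume = random_volume(rng, shape=(16, 12, 10))
    surface = detect_rpe(volume)
    for n in range(12):
        for i in range(10):
            col = volume.data[:, n, i]
            if (col == col.max()).sum() == 1:  # oracle well-defined
                assert surface.rows[n, i] == np.argmax(col)


def test_rpe_single_band_phantom():
    data = np.zeros((40, 8, 6), dtype=np.uint8)
    data[20] = 200
    assert np.all(detect_rpe(OctVolume(data=data)).rows == 20)


def test_rpe_tie_resolved_towards_neighbourhood():
    data = np.zeros((100, 7, 7), dtype=np.uint8)
    data[41] = 200  # unique maxima around row 41 everywhere ...
    data[41, 3, 3] = 0
    data[40, 3, 3] = 200  # ... except one column tied between rows 40 and 90
    data[90, 3, 3] = 200
    assert detect_rpe(OctVolume(data=data)).rows[3, 3] == 40


def test_rpe_all_zero_column_undefined():
    data = np.zeros((20, 4, 4), dtype=np.uint8)
    data[10] = 150
    data[:, 2, 2] = 0
    data[10, 2, 2] = 0
    surface = detect_rpe(OctVolume(data=data))
    assert np.isnan(surface.rows[2, 2])
    assert np.all(surface.rows[surface.defined] == 10)


# ------------------------------------------------------------------------- ILM

def test_ilm_recovers_phantom_within_one_pixel(noise_free_phantom):
    volume, truth = noise_free_phantom
    filtered = preprocess.median_filter_3d(volume)
    rpe = detect_rpe(filtered)
    ilm = detect_ilm(filtered, rpe)
    err = np.abs(ilm.rows - truth.ilm.rows)
    assert np.mean(err[np.isfinite(err)] <= 1) >= 0.99


def test_ilm_strictly_above_rpe(noise_free_phantom):
    volume, _ = noise_free_phantom
    filtered = preprocess.median_filter_3d(volume)
    rpe = detect_rpe(filtered)
    ilm = detect_ilm(filtered, rpe)
    both = ilm.defined & rpe.defined
    assert np.all(ilm.rows[both] < rpe.rows[both])


def test_ilm_background_column_undefined():
    data = np.zeros((60, 6, 6), dtype=np.uint8)
    data[10:30, :, :] = 180
    data[45] = 250
    data[10:30, 2, 3] = 0  # one column with nothing above the RPE
    rpe = detect_rpe(OctVolume(data=data))
    ilm = detect_ilm(OctVolume(data=data), rpe)
    assert np.isnan(ilm.rows[2, 3])
    assert np.all(ilm.rows[ilm.defined] == 10)


def test_ilm_requires_rpe_majority():
    data = np.zeros((20, 4, 4), dtype=np.uint8)
    rpe = LayerSurface(rows=np.full((4, 4), np.nan), label="RPE")
    with pytest.raises(AlgorithmError):
        detect_ilm(OctVolume(data=data), rpe)


# ------------------------------------------------------------------------ RNFL

def _two_band_volume():
    """Bright slab rows 10..29, dark gap, RPE band at row 45."""
    data = np.zeros((60, 16, 8), dtype=np.uint8)
    data[10:30] = 180
    data[45] = 250
    return OctVolume(data=data)


def test_rnfl_found_at_light_to_dark_transition():
    volume = _two_band_volume()
    rpe = detect_rpe(volume)
    ilm = detect_ilm(volume, rpe)
    rnfl = detect_rnfl(volume, ilm, rpe)
    assert np.all(np.abs(rnfl.rows[rnfl.defined] - 30) <= 2)


def test_gradient_zero_outside_band():
    volume = _two_band_volume()
    rpe = detect_rpe(volume)
    ilm = detect_ilm(volume, rpe)
    grad = gradient_volume(volume, ilm, rpe).magnitudes
    m = np.arange(60)[:, None, None]
    outside = (m <= ilm.rows[None]) | (m >= rpe.rows[None])
    assert np.all(grad[outside] == 0)


def test_rnfl_undefined_when_band_uniform():
    # constant brightness between the given bounds: no edge clears the floor
    data = np.full((60, 6, 6), 100, dtype=np.uint8)
    ilm = LayerSurface(rows=np.full((6, 6), 10.0), label="ILM")
    rpe = LayerSurface(rows=np.full((6, 6), 45.0), label="RPE")
    rnfl = detect_rnfl(OctVolume(data=data), ilm, rpe)
    assert not rnfl.defined.any()


# ---------------------------------------------------------------- refinement

def test_refine_keeps_contour_on_perfect_step_edge():
    volume = _two_band_volume()
    rpe = detect_rpe(volume)
    ilm = detect_ilm(volume, rpe)
    contour = LayerSurface(rows=np.full((16, 8), 30.0), label="RNFL")
    refined = refine_contour(volume, contour, ilm, rpe)
    assert np.all(refined.rows == 30)


def test_refine_recovers_displaced_contour():
    volume = _two_band_volume()
    rpe = detect_rpe(volume)
    ilm = detect_ilm(volume, rpe)
    displaced = LayerSurface(rows=np.full((16, 8), 34.0), label="RNFL")
    refined = refine_contour(volume, displaced, ilm, rpe)
    assert np.all(refined.rows == 30)


def test_refine_bridges_vessel_shadow_gap():
    spec = PhantomSpec(noise_sd=0.0,
                       vessel_shadows=(VesselShadow(70.0, 6.0, 0.4),))
    volume, truth = generate_phantom(spec)
    filtered = preprocess.median_filter_3d(volume)
    rpe = detect_rpe(filtered)
    ilm = detect_ilm(filtered, rpe)
    rnfl = detect_rnfl(filtered, ilm, rpe)
    star = refine_contour(filtered, rnfl, ilm, rpe)
    shadow = np.abs(np.arange(256) - 70.0) <= 3.0
    err = np.abs(star.rows - truth.rnfl.rows)[shadow, :]
    assert np.isfinite(err).all()  # contour is continuous under the shadow
    assert np.nanmax(err) <= 2


def test_ordering_invariant_after_refinement(segmented):
    ilm = segmented.surfaces["ilm"]
    star = segmented.surfaces["rnfl_star"]
    rpe = segmented.surfaces["rpe"]
    ok = ilm.defined & star.defined & rpe.defined
    assert np.all(ilm.rows[ok] <= star.rows[ok])
    assert np.all(star.rows[ok] <= rpe.rows[ok])


def test_noise_degrades_median_error_by_at_most_one_pixel():
    """Zero-mean noise of sd 5 must not move the median surface error > 1 px."""
    results = {}
    for sd in (0.0, 5.0):
        spec = PhantomSpec(noise_sd=sd, seed=11)
        volume, truth = generate_phantom(spec)
        filtered = preprocess.median_filter_3d(volume)
        rpe = detect_rpe(filtered)
        ilm = detect_ilm(filtered, rpe)
        rnfl = detect_rnfl(filtered, ilm, rpe)
        star = refine_contour(filtered, rnfl, ilm, rpe)
        results[sd] = {
            "rpe": np.nanmedian(np.abs(rpe.rows - truth.rpe.rows)),
            "ilm": np.nanmedian(np.abs(ilm.rows - truth.ilm.rows)),
            "rnfl_star": np.nanmedian(np.abs(star.rows - truth.rnfl.rows)),
        }
    for layer in ("rpe", "ilm", "rnfl_star"):
        assert results[5.0][layer] <= results[0.0][layer] + 1, layer
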