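"""Radiomics extractor: normalization, quantization, GLCM/Haralick, vector."""

from __future__ import annotations

import numpy as np
import pytest

from evrad import SimulationConfig, extract_feature_vector, feature_names, simulate_lesion_image
from evrad.errors import (
    AggregationError,
    EmptyGLCMError,
    ValidationError,
    ZeroVarianceError,
)
from evrad.radiomics import (
    DIRECTIONS_3D,
    GLCM,
    aggregate_directions,
    compute_glcm,
    haralick_features,
    histogram_features,
    mask_volume,
    normalize_to_muscle,
    quantize_voi,
)
from evrad.simulate import ImagingStudy

from .oracles import glcm_bruteforce, haralick_bruteforce


def _study_from(volume, lesion, muscle, spacing=(1.0, 1.0, 1.0)):
    return ImagingStudy(
        patient_id="T",
        volume=np.asarray(volume, dtype=float),
        lesion_masks=[np.asarray(lesion, dtype=bool)],
        muscle_mask=np.asarray(muscle, dtype=bool),
        voxel_spacing_mm=spacing,
    )


# --------------------------------------------------------------------------
# muscle normalization
# --------------------------------------------------------------------------

def test_muscle_voxels_become_standard_normal(phantom):
    norm = normalize_to_muscle(phantom)
    vals = norm[phantom.muscle_mask]
    assert vals.mean() == pytest.approx(0.0, abs=1e-12)
    assert vals.std() == pytest.approx(1.0, rel=1e-12)


def test_affine_intensity_invariance(phantom):
    import copy

    shifted = copy.deepcopy(phantom)
    shifted.volume = 3.7 * phantom.volume - 120.0
    np.testing.assert_allclose(
        normalize_to_muscle(shifted), normalize_to_muscle(phantom), atol=1e-9
    )


def test_constant_muscle_raises():
    vol = np.zeros((6, 6, 6))
    lesion = np.zeros((6, 6, 6), bool)
    lesion[4:6, 4:6, 4:6] = True
    vol[lesion] = np.arange(8)
    muscle = np.zeros((6, 6, 6), bool)
    muscle[0:2, 0:2, 0:2] = True
    vol[muscle] = 5.0
    with pytest.raises(ZeroVarianceError):
        normalize_to_muscle(_study_from(vol, lesion, muscle))


# --------------------------------------------------------------------------
# quantization
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values, n_levels, expected",
    [
        ([0.0, 1.0], 2, [1, 2]),
        ([5.0, 5.0, 5.0], 4, [1, 1, 1]),  # constant VOI -> level 1
        ([0.0, 0.49, 0.51, 1.0], 2, [1, 1, 2, 2]),  # bin edge at 0.5
    ],
)
def test_quantization_examples(values, n_levels, expected):
    vol = np.zeros((1, 1, len(values)))
    vol[0, 0, :] = values
    mask = np.ones_like(vol, bool)
    quant = quantize_voi(vol, mask, n_levels)
    assert quant[0, 0, :].tolist() == expected


def test_quantize_empty_mask_raises():
    with pytest.raises(ValidationError):
        quantize_voi(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), 8)


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def test_glcm_line_example():
    """1x1x4 VOI [1,1,2,2]: pairs (1,1),(1,2),(2,2) symmetrize to the known P."""
    quant = np.array([[[1, 1, 2, 2]]])
    mask = np.ones_like(quant, bool)
    glcm = compute_glcm(quant, mask, (0, 0, 1), n_levels=2)
    np.testing.assert_allclose(
        glcm.matrix, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]], atol=1e-15
    )


def test_glcm_constant_voi_single_entry():
    quant = np.ones((3, 3, 3), dtype=int)
    glcm = compute_glcm(quant, np.ones((3, 3, 3), bool), (0, 0, 1), n_levels=4)
    expected = np.zeros((4, 4))
    expected[0, 0] = 1.0
    np.testing.assert_allclose(glcm.matrix, expected)


def test_glcm_no_pairs_raises():
    quant = np.ones((1, 1, 2), dtype=int)
    mask = np.array([[[True, False]]])
    with pytest.raises(EmptyGLCMError):
        compute_glcm(quant, mask, (0, 0, 1), n_levels=2)


def test_glcm_symmetric_unit_sum_random(rng):
    for _ in range(20):
        shape = tuple(rng.integers(3, 7, 3))
        mask = rng.random(shape) > 0.3
        if mask.sum() < 8:
            continue
        vol = rng.normal(size=shape)
        quant = quantize_voi(vol, mask, 6)
        direction = DIRECTIONS_3D[rng.integers(0, 13)]
        try:
            glcm = compute_glcm(quant, mask, direction, 6)
        except EmptyGLCMError:
            continue
        assert glcm.matrix.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(glcm.matrix, glcm.matrix.T, atol=1e-15)
        assert (glcm.matrix >= 0).all()


def test_glcm_matches_bruteforce(rng):
    for _ in range(10):
        shape = tuple(rng.integers(3, 7, 3))
        mask = rng.random(shape) > 0.25
        vol = rng.normal(size=shape)
        quant = quantize_voi(vol, np.ones(shape, bool), 5) * mask
        for direction in ((0, 0, 1), (1, -1, 0), (1, 1, 1)):
            try:
                ours = compute_glcm(quant, mask, direction, 5).matrix
            except EmptyGLCMError:
                continue
            ref = glcm_bruteforce(quant, mask, direction, 5)
            np.testing.assert_allclose(ours, ref, atol=1e-12)


# --------------------------------------------------------------------------
# Haralick features
# --------------------------------------------------------------------------

def test_haralick_constant_voi():
    p = np.zeros((4, 4))
    p[0, 0] = 1.0
    feats = haralick_features(GLCM(p, (0, 0, 1), 1))
    assert feats["energy"] == pytest.approx(1.0)
    assert feats["entropy"] == pytest.approx(0.0)
    assert feats["contrast"] == pytest.approx(0.0)
    assert feats["correlation"] == 0.0  # zero marginal variance convention


def test_haralick_two_level_example():
    p = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
    feats = haralick_features(GLCM(p, (0, 0, 1), 1))
    assert feats["energy"] == pytest.approx(10 / 36, abs=1e-15)
    assert feats["contrast"] == pytest.approx(1 / 3, abs=1e-15)


def test_haralick_matches_bruteforce_on_random_glcms(rng):
    for _ in range(50):
        g = int(rng.integers(2, 9))
        raw = rng.random((g, g)) + 1e-6
        raw = raw + raw.T
        p = raw / raw.sum()
        ours = haralick_features(GLCM(p, (0, 0, 1), 1))
        ref = haralick_bruteforce(p)
        for name in ours:
            assert ours[name] == pytest.approx(ref[name], abs=1e-10), name


# --------------------------------------------------------------------------
# aggregation and histogram features
# --------------------------------------------------------------------------

def test_aggregate_identical_directions_zero_spread():
    feats = {name: 0.7 for name in haralick_bruteforce(np.eye(2) / 2)}
    agg = aggregate_directions([feats, dict(feats), dict(feats)])
    assert len(agg) == 39
    for name, value in agg.items():
        if name.endswith(("_range", "_avar")):
            assert value == 0.0


def test_aggregate_two_point_example():
    a = {name: 1 / 3 for name in haralick_bruteforce(np.eye(2) / 2)}
    b = {name: 2 / 3 for name in a}
    agg = aggregate_directions([a, b])
    assert agg["contrast_avg"] == pytest.approx(0.5)
    assert agg["contrast_range"] == pytest.approx(1 / 3)
    assert agg["contrast_avar"] == pytest.approx(1 / 36)


def test_aggregate_single_direction_raises():
    feats = {name: 0.0 for name in haralick_bruteforce(np.eye(2) / 2)}
    with pytest.raises(AggregationError):
        aggregate_directions([feats])


def test_histogram_constant_and_arithmetic():
    vol = np.full((1, 1, 4), 2.0)
    mask = np.ones_like(vol, bool)
    feats = histogram_features(vol, mask)
    assert feats["sd"] == 0.0
    assert feats["range"] == 0.0
    assert feats["entropy"] == 0.0
    assert feats["energy"] == 1.0

    vol[0, 0, :] = [1, 2, 3, 4]
    feats = histogram_features(vol, mask)
    assert feats["mean"] == pytest.approx(2.5)
    assert feats["median"] == pytest.approx(2.5)
    assert feats["range"] == pytest.approx(3.0)


def test_histogram_moments_match_oracle(rng):
    for _ in range(10):
        vals = rng.normal(size=rng.integers(10, 200)) * rng.uniform(0.5, 3)
        vol = vals.reshape(1, 1, -1)
        feats = histogram_features(vol, np.ones_like(vol, bool))
        m = vals.mean()
        m2 = ((vals - m) ** 2).mean()
        m3 = ((vals - m) ** 3).mean()
        m4 = ((vals - m) ** 4).mean()
        assert feats["skewness"] == pytest.approx(m3 / m2**1.5, rel=1e-10)
        assert feats["kurtosis"] == pytest.approx(m4 / m2**2 - 3, rel=1e-10)


@pytest.mark.parametrize(
    "n_vox, spacing, expected",
    [(10, (1, 1, 1), 10.0), (10, (0.5, 0.5, 2), 5.0), (10, (2, 1, 1), 20.0)],
)
def test_mask_volume(n_vox, spacing, expected):
    mask = np.zeros((5, 5, 5), bool)
    mask.flat[:n_vox] = True
    assert mask_volume(mask, spacing) == pytest.approx(expected)


# --------------------------------------------------------------------------
# the 400-feature vector
# --------------------------------------------------------------------------

def test_feature_vector_structure(phantom):
    vec = extract_feature_vector(phantom)
    names = feature_names()
    assert list(vec.values) == names
    assert len(names) == 400
    assert sum(n.startswith("hist_") for n in names) == 10
    assert sum(n.endswith("_voln") for n in names) == 195
    base = [n for n in names if n.startswith("glcm_") and not n.endswith("_voln")]
    assert len(base) == 195
    for name in base:
        assert vec.values[f"{name}_voln"] == pytest.approx(
            vec.values[name] / vec.volume_mm3, rel=1e-12
        )


def test_feature_vector_deterministic(phantom):
    a = extract_feature_vector(phantom)
    b = extract_feature_vector(phantom)
    assert a.values == b.values


def test_rotation_invariance_of_feature_vector(phantom):
    """90-degree rotation permutes the direction set, leaving all 400 invariant."""
    base = extract_feature_vector(phantom)
    for axes in ((0, 1), (1, 2), (0, 2)):
        rotated = ImagingStudy(
            patient_id=phantom.patient_id,
            volume=np.rot90(phantom.volume, axes=axes),
            lesion_masks=[np.rot90(phantom.lesion_masks[0], axes=axes)],
            muscle_mask=np.rot90(phantom.muscle_mask, axes=axes),
            voxel_spacing_mm=phantom.voxel_spacing_mm,
        )
        vec = extract_feature_vector(rotated)
        # voxel volume is spacing-product so volume_mm3 is rotation-safe too
        for name in feature_names():
            assert vec.values[name] == pytest.approx(
                base.values[name], rel=1e-9, abs=1e-9
            ), name
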