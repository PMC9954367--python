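"""Texture matrices and features vs independent brute-force enumeration."""

from __future__ import annotations

import numpy as np
import pytest

from heteromap.features import texture as tx

from _oracles import (
    gldm_features_oracle,
    glcm_features_oracle,
    glrlm_features_oracle,
    glszm_features_oracle,
    ngtdm_oracle,
)
from conftest import random_level_images

BATTERY = random_level_images(24, seed=7)
TOL = 1e-10

_GLRLM_GENERIC = {v: k for k, v in tx._GLRLM_NAMES.items()}
_GLSZM_GENERIC = {v: k for k, v in tx._GLSZM_NAMES.items()}
_GLDM_GENERIC = {
    "SmallDependenceEmphasis": "ShortEmphasis",
    "LargeDependenceEmphasis": "LongEmphasis",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "DependenceVariance": "SizeVariance",
    "DependenceEntropy": "Entropy",
    "SmallDependenceLowGrayLevelEmphasis": "ShortLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "ShortHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis": "LongLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LongHighGrayLevelEmphasis",
}


def _assert_close(impl: dict, oracle: dict, prefix: str, generic_map=None, case=""):
    for name, value in impl.items():
        short = name.removeprefix(prefix)
        key = (generic_map or {}).get(short, short)
        assert key in oracle, f"{name} missing from oracle"
        assert value == pytest.approx(oracle[key], abs=TOL), f"{case}: {name}"


@pytest.mark.parametrize("idx", range(len(BATTERY)))
def test_glcm_matches_pair_enumeration(idx):
    lev, mask, ng = BATTERY[idx]
    mats = tx.glcm_matrix(lev, mask, ng)
    if not np.any(mats.sum(axis=(1, 2)) > 0):
        # no co-occurring pairs anywhere: the empty-matrix contract applies
        with pytest.raises(ValueError):
            tx.compute_glcm_features(mats)
        return
    impl = tx.compute_glcm_features(mats)
    oracle = glcm_features_oracle(lev, mask, ng)
    _assert_close(impl, oracle, "glcm_", case=f"image {idx}")


@pytest.mark.parametrize("idx", range(len(BATTERY)))
def test_glrlm_matches_run_enumeration(idx):
    lev, mask, ng = BATTERY[idx]
    impl = tx.compute_glrlm_features(tx.glrlm_matrix(lev, mask, ng), int(mask.sum()))
    oracle = glrlm_features_oracle(lev, mask, ng)
    _assert_close(impl, oracle, "glrlm_", _GLRLM_GENERIC, case=f"image {idx}")


@pytest.mark.parametrize("idx", range(len(BATTERY)))
def test_glszm_matches_zone_enumeration(idx):
    lev, mask, ng = BATTERY[idx]
    impl = tx.compute_glszm_features(tx.glszm_matrix(lev, mask, ng), int(mask.sum()))
    oracle = glszm_features_oracle(lev, mask, ng)
    _assert_close(impl, oracle, "glszm_", _GLSZM_GENERIC, case=f"image {idx}")


@pytest.mark.parametrize("idx", range(len(BATTERY)))
def test_gldm_matches_neighbour_enumeration(idx):
    lev, mask, ng = BATTERY[idx]
    impl = tx.compute_gldm_features(tx.gldm_matrix(lev, mask, ng))
    oracle = gldm_features_oracle(lev, mask, ng)
    _assert_close(impl, oracle, "gldm_", _GLDM_GENERIC, case=f"image {idx}")


@pytest.mark.parametrize("idx", range(len(BATTERY)))
def test_ngtdm_matches_neighbourhood_enumeration(idx):
    lev, mask, ng = BATTERY[idx]
    p, s, nv = tx.ngtdm_matrix(lev, mask, ng)
    oracle, nv_oracle = ngtdm_oracle(lev, mask, ng)
    assert nv == nv_oracle
    if nv == 0:
        return
    impl = tx.compute_ngtdm_features(p, s, nv)
    _assert_close(impl, oracle, "ngtdm_", case=f"image {idx}")


# ------------------------------------------------------------------
# worked examples with hand-derived values

def test_glcm_autocorrelation_two_column_image():
    """[[1,2],[1,2]] horizontally: p(1,2)=p(2,1)=0.5 so Σ p·i·j = 2."""
    lev = np.array([[1, 2], [1, 2]])
    mats = tx.glcm_matrix(lev, np.ones((2, 2), bool), 2, angles=((0, 1),))
    feats = tx.compute_glcm_features(mats)
    assert feats["glcm_Autocorrelation"] == pytest.approx(2.0)


def test_glcm_degenerate_single_level():
    lev = np.ones((3, 3), dtype=int)
    mats = tx.glcm_matrix(lev, np.ones((3, 3), bool), 1)
    feats = tx.compute_glcm_features(mats)
    assert feats["glcm_Autocorrelation"] == pytest.approx(1.0)
    assert feats["glcm_Contrast"] == pytest.approx(0.0)
    assert feats["glcm_MaximumProbability"] == pytest.approx(1.0)


def test_glrlm_run_percentage_examples():
    row = np.array([[1, 1, 2, 2, 2]])
    mask = np.ones((1, 5), bool)
    feats = tx.compute_glrlm_features(
        tx.glrlm_matrix(row, mask, 2, directions=((0, 1),)), 5
    )
    assert feats["glrlm_RunPercentage"] == pytest.approx(0.4)

    alt = np.array([[1, 2, 1, 2]])
    feats = tx.compute_glrlm_features(
        tx.glrlm_matrix(alt, np.ones((1, 4), bool), 2, directions=((0, 1),)), 4
    )
    assert feats["glrlm_RunPercentage"] == pytest.approx(1.0)

    const = np.ones((1, 7), dtype=int)
    feats = tx.compute_glrlm_features(
        tx.glrlm_matrix(const, np.ones((1, 7), bool), 1, directions=((0, 1),)), 7
    )
    assert feats["glrlm_RunPercentage"] == pytest.approx(1 / 7)


def test_glszm_large_area_emphasis_examples():
    # two 8-connected zones of sizes 2 and 3 -> LAE = (4·1+9·1)/2
    lev = np.array([[1, 1, 2], [2, 2, 0]])
    mask = lev > 0
    feats = tx.compute_glszm_features(tx.glszm_matrix(lev, mask, 2), int(mask.sum()))
    assert feats["glszm_LargeAreaEmphasis"] == pytest.approx(6.5)

    const = np.ones((3, 2), dtype=int)
    feats = tx.compute_glszm_features(tx.glszm_matrix(const, np.ones((3, 2), bool), 1), 6)
    assert feats["glszm_LargeAreaEmphasis"] == pytest.approx(36.0)

    # isolated single pixels (4-diagonal checkerboard levels differ)
    iso = np.array([[1, 2], [2, 1]])
    # all same-level neighbours are diagonal -> 8-connectivity merges them
    feats = tx.compute_glszm_features(tx.glszm_matrix(iso, np.ones((2, 2), bool), 2), 4)
    assert feats["glszm_LargeAreaEmphasis"] == pytest.approx(4.0)  # two zones of 2


def test_gldm_dependence_nonuniformity_examples():
    const = np.ones((3, 3), dtype=int)
    feats = tx.compute_gldm_features(tx.gldm_matrix(const, np.ones((3, 3), bool), 1))
    # dependence-count histogram {4 corners, 4 edges, 1 centre} -> (16+16+1)/9
    assert feats["gldm_DependenceNonUniformity"] == pytest.approx(33 / 9)

    single = np.zeros((3, 3), dtype=bool)
    single[1, 1] = True
    feats = tx.compute_gldm_features(tx.gldm_matrix(np.full((3, 3), 2), single, 2))
    assert feats["gldm_DependenceNonUniformity"] == pytest.approx(1.0)


def test_gldm_shift_invariance():
    rng = np.random.default_rng(0)
    lev = rng.integers(1, 4, size=(6, 6))
    mask = np.ones((6, 6), bool)
    dn1 = tx.compute_gldm_features(tx.gldm_matrix(lev, mask, 6))["gldm_DependenceNonUniformity"]
    dn2 = tx.compute_gldm_features(tx.gldm_matrix(lev + 2, mask, 8))["gldm_DependenceNonUniformity"]
    assert dn1 == pytest.approx(dn2)


def test_ngtdm_coarseness_examples():
    const = np.ones((4, 4), dtype=int)
    p, s, nv = tx.ngtdm_matrix(const, np.ones((4, 4), bool), 1)
    feats = tx.compute_ngtdm_features(p, s, nv)
    assert feats["ngtdm_Coarseness"] == pytest.approx(1e6)

    centre = np.ones((3, 3), dtype=int)
    centre[1, 1] = 2
    p, s, nv = tx.ngtdm_matrix(centre, np.ones((3, 3), bool), 2)
    # hand enumeration: centre s = |2 - 1| = 1; each border pixel's
    # neighbour average includes the centre once
    oracle, _ = ngtdm_oracle(centre, np.ones((3, 3), bool), 2)
    feats = tx.compute_ngtdm_features(p, s, nv)
    assert feats["ngtdm_Coarseness"] == pytest.approx(oracle["Coarseness"])
    assert feats["ngtdm_Coarseness"] < 1e6  # nonzero differences reduce coarseness


def test_glcm_normalization_and_nonnegativity():
    for lev, mask, ng in BATTERY[:10]:
        mats = tx.glcm_matrix(lev, mask, ng)
        for m in mats:
            assert np.all(m >= 0)
            if m.sum() > 0:
                assert m.sum() == pytest.approx(1.0, abs=1e-12)


def test_discretize_conventions():
    vals = np.arange(11.0).reshape(1, 11)
    mask = np.ones((1, 11), bool)
    lev = tx.discretize(vals, mask, 2)
    assert np.array_equal(lev[0], np.where(vals[0] < 5, 1, 2))

    const = np.full((2, 2), 3.3)
    assert np.all(tx.discretize(const, np.ones((2, 2), bool), 8) == 1)

    rng = np.random.default_rng(5)
    for _ in range(20):
        img = rng.normal(size=(6, 6))
        n_bins = int(rng.integers(2, 9))
        lev = tx.discretize(img, np.ones((6, 6), bool), n_bins)
        assert lev[np.unravel_index(img.argmin(), img.shape)] == 1
        assert lev[np.unravel_index(img.argmax(), img.shape)] == n_bins
        assert lev.min() >= 1 and lev.max() <= n_bins
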