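"""Radiomic feature extractor: catalogue shape, discretization, first-order
and texture families against independent brute-force oracles, and shape
features against analytic phantoms."""

import numpy as np
import pytest

import oracles
from conftest import make_ellipsoid_volume, random_levels
from radioshrink.features import (CATALOGUE, FAMILIES, FAMILY_SIZES,
                                  TOTAL_FEATURES, DiscretizationSpec,
                                  compute_first_order_features,
                                  compute_ngtdm_busyness, compute_shape_features,
                                  discretize, extract_all, glcm_matrix,
                                  gldm_matrix, glrlm_matrix, glszm_matrix,
                                  texture_features, vectors_to_frame)
from radioshrink.features.texture import (glcm_features, gldm_features,
                                          glrlm_features, glszm_features)
from radioshrink.imaging import (PreprocessConfig, RegionMasks, VolumeImage,
                                 build_triplet, extract_parenchymal_ring)


class TestCatalogue:
    def test_family_cardinalities(self):
        assert FAMILY_SIZES == {"shape": 14, "firstorder": 18, "glcm": 24,
                                "glrlm": 16, "glszm": 16, "gldm": 14}
        assert TOTAL_FEATURES == 102

    def test_names_unique(self):
        assert len(set(CATALOGUE)) == len(CATALOGUE)


class TestDiscretize:
    def test_four_values_four_bins(self):
        vol = np.array([0.0, 1.0, 2.0, 3.0]).reshape(1, 1, 4)
        mask = np.ones_like(vol, dtype=bool)
        lev = discretize(vol, mask, DiscretizationSpec("fixed_bin_count", 4))
        assert sorted(lev[mask]) == [1, 2, 3, 4]

    def test_constant_region_single_level(self):
        vol = np.full((2, 2, 2), 7.0)
        lev = discretize(vol, np.ones_like(vol, dtype=bool),
                         DiscretizationSpec("fixed_bin_count", 32))
        assert set(lev.ravel()) == {1}

    def test_bin_width_level_count(self):
        vol = np.arange(256.0).reshape(4, 8, 8)
        lev = discretize(vol, np.ones_like(vol, dtype=bool),
                         DiscretizationSpec("fixed_bin_width", 32))
        assert lev.max() == 8 and lev.min() == 1

    def test_gray_level_shift_invariance(self, rng):
        """fixed_bin_count discretization is invariant to intensity shifts."""
        vol = rng.random((4, 4, 4)) * 100
        mask = np.ones_like(vol, dtype=bool)
        spec = DiscretizationSpec("fixed_bin_count", 16)
        assert np.array_equal(discretize(vol, mask, spec),
                              discretize(vol + 500.0, mask, spec))


class TestShape:
    def test_ball_sphericity_and_flatness(self):
        _, mask = make_ellipsoid_volume((20, 20, 20), pad=2)
        feats = compute_shape_features(mask, (1, 1, 1))
        assert feats["Sphericity"] >= 0.97
        assert abs(feats["Flatness"] - 1.0) <= 0.02

    def test_ellipsoid_axis_ratios(self):
        _, mask = make_ellipsoid_volume((20, 10, 5), pad=2)
        feats = compute_shape_features(mask, (1, 1, 1))
        major, minor, least = (feats["MajorAxisLength"],
                               feats["MinorAxisLength"],
                               feats["LeastAxisLength"])
        assert abs(major / minor - 2.0) < 0.1
        assert abs(major / least - 4.0) < 0.2
        assert abs(feats["Flatness"] - 0.25) < 0.0125

    def test_principal_axes_match_pca_oracle(self):
        """Axis lengths agree with a PCA of the dense voxel point cloud."""
        _, mask = make_ellipsoid_volume((12, 8, 5), pad=2)
        coords = np.argwhere(mask).astype(float)
        cov = np.cov(coords.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        feats = compute_shape_features(mask, (1, 1, 1))
        assert np.allclose(
            [feats["MajorAxisLength"], feats["MinorAxisLength"],
             feats["LeastAxisLength"]],
            4.0 * np.sqrt(eig), rtol=1e-6)

    def test_mesh_volume_close_to_voxel_volume(self):
        _, mask = make_ellipsoid_volume((10, 10, 10), pad=2)
        feats = compute_shape_features(mask, (1, 1, 1))
        assert abs(feats["MeshVolume"] - feats["VoxelVolume"]) / feats["VoxelVolume"] < 0.05

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_shape_features(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))


class TestFirstOrder:
    def test_constant_region(self):
        vals = np.full(10, 4.0)
        levels = np.ones(10, dtype=int)
        f = compute_first_order_features(vals, levels)
        assert f["Variance"] == 0 and f["Entropy"] == 0 and f["Uniformity"] == 1

    def test_simple_arithmetic(self):
        f = compute_first_order_features(np.array([1.0, 2, 3, 4]),
                                         np.array([1, 2, 3, 4]))
        assert f["Mean"] == 2.5 and f["Range"] == 3.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            vals = rng.random(rng.integers(5, 60)) * 50
            levels = np.minimum(np.floor(vals / 10).astype(int) + 1, 6)
            ours = compute_first_order_features(vals, levels, voxel_volume_mm3=0.5)
            ref = oracles.first_order_oracle(vals, levels, voxvol=0.5)
            for name, expected in ref.items():
                assert ours[name] == pytest.approx(expected, abs=1e-10), name


class TestTextureMatrices:
    def test_glcm_tiny_array_pair_counts(self):
        levels = np.array([[1, 2], [1, 2]]).reshape(2, 2, 1).astype(np.int32)
        assert np.allclose(glcm_matrix(levels), oracles.glcm_oracle(levels))

    def test_constant_cube_single_runs(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mat = glrlm_matrix(levels)
        ref = oracles.glrlm_oracle(levels)
        assert np.allclose(mat, ref)
        assert mat.shape[1] == 3  # axial lines are single runs of length 3

    def test_isolated_levels_give_zones_of_size_one(self):
        # 8-level 3D pattern in which equal levels are never 26-adjacent
        x, y, z = np.indices((4, 4, 4))
        levels = (x % 2 + 2 * (y % 2) + 4 * (z % 2) + 1).astype(np.int32)
        mat = glszm_matrix(levels)
        assert mat.shape[1] == 1
        assert mat.sum() == 64

    @pytest.mark.parametrize("family,matrix_fn,oracle_fn", [
        ("glcm", glcm_matrix, oracles.glcm_oracle),
        ("glrlm", glrlm_matrix, oracles.glrlm_oracle),
        ("glszm", glszm_matrix, oracles.glszm_oracle),
        ("gldm", gldm_matrix, oracles.gldm_oracle),
    ])
    def test_matrices_match_enumeration(self, rng, family, matrix_fn, oracle_fn):
        for _ in range(8):
            shape = tuple(rng.integers(2, 6, size=3))
            levels = random_levels(rng, shape, rng.integers(2, 5))
            assert np.allclose(matrix_fn(levels), oracle_fn(levels),
                               atol=1e-12), family


class TestTextureFeatures:
    def test_single_cell_matrix_zero_entropy(self):
        mat = np.array([[5.0]])
        assert gldm_features(mat)["DependenceEntropy"] == 0.0

    def test_uniform_distribution_entropy(self):
        mat = np.ones((2, 2))
        assert glszm_features(mat, 100)["ZoneEntropy"] == pytest.approx(2.0)

    def test_worked_array_against_direct_sum_oracles(self, rng):
        levels = random_levels(rng, (4, 4, 1), 4)
        nvox = int((levels > 0).sum())
        P = glcm_matrix(levels)
        for name, v in oracles.glcm_features_oracle(P).items():
            assert glcm_features(P)[name] == pytest.approx(v, abs=1e-10), name
        R = glrlm_matrix(levels)
        for name, v in oracles.glrlm_features_oracle(R, nvox).items():
            assert glrlm_features(R, nvox)[name] == pytest.approx(v, abs=1e-10), name
        Z = glszm_matrix(levels)
        for name, v in oracles.glszm_features_oracle(Z, nvox).items():
            assert glszm_features(Z, nvox)[name] == pytest.approx(v, abs=1e-10), name
        D = gldm_matrix(levels)
        for name, v in oracles.gldm_features_oracle(D).items():
            assert gldm_features(D)[name] == pytest.approx(v, abs=1e-10), name


class TestBusyness:
    def test_constant_region_undefined(self):
        assert compute_ngtdm_busyness(np.ones((3, 3, 3), dtype=np.int32)) is None

    def test_random_field_busier_than_gradient(self, rng):
        rand = rng.integers(1, 3, size=(6, 6, 6)).astype(np.int32)
        grad = np.repeat(np.arange(1, 7, dtype=np.int32), 36).reshape(6, 6, 6)
        assert compute_ngtdm_busyness(rand) > compute_ngtdm_busyness(grad)

    def test_matches_enumeration(self, rng):
        for _ in range(5):
            levels = random_levels(rng, (4, 4, 3), 4)
            ref = oracles.busyness_oracle(levels)
            ours = compute_ngtdm_busyness(levels)
            if ref is None:
                assert ours is None
            else:
                assert ours == pytest.approx(ref, abs=1e-12)


def _tiny_patient(rng, spacing=(1.0, 1.0, 1.0)):
    vol, mask = make_ellipsoid_volume((5, 4, 3), pad=4, noise=3.0, rng=rng)
    s0 = VolumeImage(np.full(vol.shape, 100.0) + rng.normal(0, 2, vol.shape), spacing)
    sm = VolumeImage(s0.values + vol, spacing)
    trip = build_triplet(s0, sm)
    ring = extract_parenchymal_ring(mask, spacing, 4.0)
    return trip, RegionMasks(tumor=mask, parenchyma_ring=ring)


class TestExtractAll:
    def test_emits_exactly_102_per_sequence_and_region(self, rng):
        trip, masks = _tiny_patient(rng)
        vecs = extract_all(trip, masks, "P0", "pre")
        assert len(vecs) == 6  # 3 sequences x 2 regions
        for fv in vecs:
            catalogue_names = [n for n in fv.values if not n.startswith("extras_")]
            assert len(catalogue_names) == 102
            per_family = {}
            for n in catalogue_names:
                fam = n.split("_")[0]
                per_family[fam] = per_family.get(fam, 0) + 1
            assert per_family == {"shape": 14, "firstorder": 18, "glcm": 24,
                                  "glrlm": 16, "glszm": 16, "gldm": 14}

    def test_axis_permutation_invariance(self, rng):
        """First-order and direction-averaged texture features are invariant
        to permuting the volume axes (isotropic voxels)."""
        trip, masks = _tiny_patient(rng)
        vecs = {(v.sequence, v.region): v for v in extract_all(trip, masks, "P", "pre")}
        perm = (2, 0, 1)
        trip_p = build_triplet(
            VolumeImage(np.transpose(trip.s0.values, perm), trip.s0.spacing_mm),
            VolumeImage(np.transpose(trip.sm.values, perm), trip.sm.spacing_mm))
        masks_p = RegionMasks(tumor=np.transpose(masks.tumor, perm),
                              parenchyma_ring=np.transpose(masks.parenchyma_ring, perm))
        vecs_p = {(v.sequence, v.region): v
                  for v in extract_all(trip_p, masks_p, "P", "pre")}
        invariant_families = ("firstorder", "glcm", "glrlm", "glszm", "gldm")
        for key, fv in vecs.items():
            for name, val in fv.values.items():
                if name.split("_")[0] in invariant_families:
                    assert vecs_p[key].values[name] == pytest.approx(val, rel=1e-9), (key, name)

    def test_timepoints_tagged_for_longitudinal_model(self, rng):
        trip, masks = _tiny_patient(rng)
        pre = extract_all(trip, masks, "P0", "pre")
        early = extract_all(trip, masks, "P0", "earlyNAC")
        frame = vectors_to_frame(pre + early)
        assert set(frame["timepoint"]) == {"pre", "earlyNAC"}

    def test_undefined_features_flagged_not_silent(self, rng):
        trip, masks = _tiny_patient(rng)
        empty_ring = RegionMasks(tumor=masks.tumor,
                                 parenchyma_ring=np.zeros_like(masks.tumor))
        vecs = extract_all(trip, empty_ring, "P0", "pre")
        ring_vecs = [v for v in vecs if v.region == "parenchyma"]
        for fv in ring_vecs:
            assert fv.undefined  # everything flagged, not silently NaN
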