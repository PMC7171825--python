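"""Feature extraction: parcellation, confound removal, dynamic features."""

import numpy as np
import pandas as pd
import pytest

from longimci.features import (
    BLOCK_SETS,
    FeatureMatrix,
    assemble_cognitive,
    build_feature_matrix,
    combine_feature_sets,
    dynamic_features,
    parcellate,
    residualize_confounds,
)
from longimci.normalize import normalize_images
from longimci.syndata import CohortConfig, generate_cohort, make_atlas
from longimci.types import AtlasLabelMap, RegionVector, VoxelImage


def _img(values, mask=None, **kw):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VoxelImage(values, mask, **kw)


class TestParcellate:
    def test_constant_image_gives_constant_region_means(self):
        atlas = make_atlas((4, 4, 3), 6, seed=0)
        vec = parcellate(_img(np.full((4, 4, 3), 7.5)), atlas)
        assert np.allclose(vec.values, 7.5)
        assert np.array_equal(vec.region_ids, atlas.region_ids)

    def test_single_region_equals_global_mean(self, rng):
        raw = rng.uniform(0, 10, (4, 4, 3))
        atlas = AtlasLabelMap(np.ones((4, 4, 3), dtype=np.int32))
        vec = parcellate(_img(raw), atlas)
        assert vec.values[0] == pytest.approx(raw.mean())

    def test_means_match_hand_summed_averages(self, rng):
        # oracle: explicit per-label summation on a 6-voxel image
        labels = np.array([1, 1, 2, 2, 2, 1], dtype=np.int32).reshape(6, 1, 1)
        raw = rng.uniform(0, 5, (6, 1, 1))
        vec = parcellate(_img(raw), AtlasLabelMap(labels))
        flat = raw.ravel()
        m1 = (flat[0] + flat[1] + flat[5]) / 3
        m2 = (flat[2] + flat[3] + flat[4]) / 3
        assert vec.values == pytest.approx([m1, m2])

    def test_region_empty_under_mask_names_region(self):
        labels = np.array([1, 2], dtype=np.int32).reshape(2, 1, 1)
        mask = np.array([True, False]).reshape(2, 1, 1)
        with pytest.raises(ValueError, match="region 2"):
            parcellate(_img([[ [1.0]], [[1.0]]], mask), AtlasLabelMap(labels))


class TestResidualize:
    @pytest.fixture
    def covars(self, rng):
        return pd.DataFrame({
            "age": rng.uniform(55, 85, 40),
            "gender": rng.integers(0, 2, 40),
        })

    def test_exact_linear_in_age_residuals_vanish(self, covars):
        y = 3.0 * covars["age"].to_numpy() - 7.0
        res = residualize_confounds(y, covars)
        assert np.allclose(res, 0.0, atol=1e-9)

    def test_independent_variable_residual_is_centered(self, covars, rng):
        y = np.full(40, 5.0)
        res = residualize_confounds(y, covars)
        assert np.allclose(res, 0.0, atol=1e-9)  # centered constant
        res_keep = residualize_confounds(y, covars, keep_mean=True)
        assert np.allclose(res_keep, 5.0, atol=1e-9)

    def test_residuals_orthogonal_to_covariates(self, covars, rng):
        data = rng.normal(size=(40, 7))
        res = residualize_confounds(data, covars)
        for col in ("age", "gender"):
            dots = res.T @ covars[col].to_numpy()
            assert np.all(np.abs(dots) < 1e-8)
        # oracle: normal-equations solve
        X = np.column_stack([np.ones(40), covars["age"], covars["gender"]])
        beta = np.linalg.solve(X.T @ X, X.T @ data)
        assert np.allclose(res, data - X @ beta, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        cov = pd.DataFrame({"age": rng.uniform(55, 85, 10),
                            "gender": np.zeros(10)})
        with pytest.raises(ValueError, match="rank"):
            residualize_confounds(rng.normal(size=(10, 2)), cov)

    def test_residualize_commutes_with_parcellation(self, rng):
        # least-squares residuals are linear in the response with a shared
        # design, so voxel-level and region-level paths agree
        atlas = make_atlas((5, 5, 4), 8, seed=2)
        n = 15
        cov = pd.DataFrame({"age": rng.uniform(55, 85, n),
                            "gender": rng.integers(0, 2, n)})
        voxels = rng.normal(1.0, 0.1, size=(n, 5, 5, 4))
        # path A: residualize voxels, then parcellate
        flat = voxels.reshape(n, -1)
        res_vox = residualize_confounds(flat, cov, keep_mean=True).reshape(voxels.shape)
        a = np.vstack([
            parcellate(_img(res_vox[i]), atlas).values for i in range(n)
        ])
        # path B: parcellate, then residualize region means
        statics = np.vstack([
            parcellate(_img(voxels[i]), atlas).values for i in range(n)
        ])
        b = residualize_confounds(statics, cov, keep_mean=True)
        assert np.allclose(a, b, atol=1e-10)


class TestDynamicFeatures:
    def _vecs(self, arrays):
        ids = np.arange(1, len(next(iter(arrays.values()))) + 1)
        return {tp: RegionVector(np.asarray(v, float), ids) for tp, v in arrays.items()}

    def test_equal_timepoints_give_zero_d_and_r(self):
        v = [1.0, 2.0, 3.0]
        d, r = dynamic_features(self._vecs({"bl": v, "m6": v, "m12": v, "m18": v}))
        for i in (1, 2, 3):
            assert np.allclose(d[f"Dynamic_{i}"], 0)
            assert np.allclose(r[f"R{i}"], 0)

    def test_direct_substitution(self):
        d, r = dynamic_features(self._vecs({"bl": [2.0], "m6": [1.5]}))
        assert d["Dynamic_1"][0] == pytest.approx(0.5)
        assert r["R1"][0] == pytest.approx(0.25)

    def test_ratio_identity_on_random_vectors(self, rng):
        # oracle: scalar loop evaluation
        base = rng.uniform(0.5, 2.0, 30)
        arrays = {"bl": base}
        for tp in ("m6", "m12", "m18"):
            arrays[tp] = base * rng.uniform(0.8, 1.1, 30)
        d, r = dynamic_features(self._vecs(arrays))
        for i, tp in enumerate(("m6", "m12", "m18"), start=1):
            manual = np.array([
                (arrays["bl"][j] - arrays[tp][j]) / arrays["bl"][j]
                for j in range(30)
            ])
            assert np.allclose(r[f"R{i}"], manual, rtol=1e-14)
            assert np.allclose(r[f"R{i}"] * arrays["bl"], d[f"Dynamic_{i}"], rtol=1e-14)

    def test_region_permutation_equivariance(self, rng):
        base = rng.uniform(0.5, 2.0, 12)
        follow = base * rng.uniform(0.8, 1.0, 12)
        ids = np.arange(1, 13)
        d, r = dynamic_features({"bl": RegionVector(base, ids),
                                 "m6": RegionVector(follow, ids)})
        perm = rng.permutation(12)
        dp, rp = dynamic_features({"bl": RegionVector(base[perm], ids),
                                   "m6": RegionVector(follow[perm], ids)})
        assert np.allclose(dp["Dynamic_1"], d["Dynamic_1"][perm])
        assert np.allclose(rp["R1"], r["R1"][perm])

    def test_tiny_baseline_rejected(self):
        with pytest.raises(ValueError, match="eps"):
            dynamic_features(self._vecs({"bl": [1.0, 0.0], "m6": [1.0, 1.0]}))

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            dynamic_features(self._vecs({"m6": [1.0]}))

    def test_change_rate_matches_compound_decline(self):
        # noise-free multiplicative decline d per timepoint: R_i = 1 - (1-d)^i
        d_rate = 0.06
        base = np.full(5, 1.0)
        arrays = {"bl": base}
        for i, tp in enumerate(("m6", "m12", "m18"), start=1):
            arrays[tp] = base * (1 - d_rate) ** i
        _, r = dynamic_features(self._vecs(arrays))
        for i in (1, 2, 3):
            assert np.allclose(r[f"R{i}"], 1 - (1 - d_rate) ** i, rtol=1e-12)


class TestAssembleAndCombine:
    def _table(self, n):
        rng = np.random.default_rng(0)
        rows = {"subject_id": [f"S{i}" for i in range(n)],
                "group": ["sMCI"] * n}
        for tp in ("bl", "m6", "m12", "m18"):
            rows[f"mmse_{tp}"] = rng.uniform(24, 30, n)
            rows[f"adas_{tp}"] = rng.uniform(5, 25, n)
        return pd.DataFrame(rows)

    def test_cognitive_block_shape_for_study_cohort(self):
        block = assemble_cognitive(self._table(79))
        assert block.shape == (79, 8)

    def test_cognitive_passthrough_order(self):
        t = self._table(1)
        for tp in ("bl", "m6", "m12", "m18"):
            t[f"mmse_{tp}"] = 30.0
            t[f"adas_{tp}"] = 0.0
        vec = assemble_cognitive(t).iloc[0].to_numpy()
        assert np.allclose(vec, [30, 30, 30, 30, 0, 0, 0, 0])

    def test_missing_score_names_subject(self):
        t = self._table(3)
        t.loc[1, "adas_m12"] = np.nan
        with pytest.raises(ValueError, match="S1"):
            assemble_cognitive(t)

    def _fm(self, name, n_cols, index, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"{name}_c{i}" for i in range(n_cols)]
        df = pd.DataFrame(rng.normal(size=(len(index), n_cols)),
                          index=index, columns=cols)
        return FeatureMatrix(df, {name: cols})

    def test_static_all_has_984_columns(self):
        idx = pd.Index([f"S{i}" for i in range(5)], name="subject_id")
        parts = [self._fm(f"Static_{tp}", 246, idx, seed=i)
                 for i, tp in enumerate(("mbl", "m6", "m12", "m18"))]
        combined = combine_feature_sets(parts)
        assert combined.n_features == 984
        assert len(combined.blocks) == 4

    def test_dynamic_all_block_ranges(self):
        idx = pd.Index([f"S{i}" for i in range(4)], name="subject_id")
        parts = [self._fm(f"Dynamic_{i}", 246, idx, seed=i) for i in (1, 2, 3)]
        combined = combine_feature_sets(parts)
        assert combined.n_features == 738
        assert list(combined.blocks) == ["Dynamic_1", "Dynamic_2", "Dynamic_3"]

    def test_duplicate_block_rejected(self):
        idx = pd.Index(["S0", "S1"], name="subject_id")
        fm = self._fm("B", 3, idx)
        with pytest.raises(ValueError, match="duplicate"):
            combine_feature_sets([fm, fm])

    def test_subject_mismatch_rejected(self):
        a = self._fm("A", 2, pd.Index(["S0", "S1"], name="subject_id"))
        b = self._fm("B", 2, pd.Index(["S1", "S0"], name="subject_id"))
        with pytest.raises(ValueError, match="ordering"):
            combine_feature_sets([a, b])


class TestBuildFeatureMatrix:
    def test_blocks_and_shapes(self, small_cohort, small_config):
        mci_ids = set(small_cohort.mci_subjects()["subject_id"])
        pats = {k: im for k, im in small_cohort.images.items() if k[0] in mci_ids}
        normalized, _ = normalize_images(
            pats, small_cohort.hc_baseline_images(), small_config.timepoints)
        fm = build_feature_matrix(normalized, small_cohort.atlas,
                                  small_cohort.subjects)
        n_r = small_config.n_regions
        assert fm.n_subjects == small_config.n_smci + small_config.n_pmci
        assert fm.n_features == 4 * n_r + 6 * n_r + 8
        for name, cols in fm.blocks.items():
            expected = 8 if name == "Cognitive" else n_r
            assert len(cols) == expected
        assert set(fm.labels.unique()) == {"sMCI", "pMCI"}
        # every named benchmark configuration resolves
        for name in BLOCK_SETS:
            assert fm.feature_set(name).n_features > 0

    def test_full_pipeline_scale_invariance(self, small_cohort, small_config):
        # multiplying a subject's raw images by c > 0 changes no feature
        mci_ids = set(small_cohort.mci_subjects()["subject_id"])
        pats = {k: im for k, im in small_cohort.images.items() if k[0] in mci_ids}
        target = next(iter(mci_ids))
        scaled = {
            k: (VoxelImage(im.values * 2.9, im.mask.copy(), *k)
                if k[0] == target else im)
            for k, im in pats.items()
        }
        hc = small_cohort.hc_baseline_images()
        fm_a = build_feature_matrix(
            normalize_images(pats, hc, small_config.timepoints)[0],
            small_cohort.atlas, small_cohort.subjects)
        fm_b = build_feature_matrix(
            normalize_images(scaled, hc, small_config.timepoints)[0],
            small_cohort.atlas, small_cohort.subjects)
        assert np.allclose(fm_a.data.to_numpy(), fm_b.data.to_numpy(), atol=1e-10)

    def test_tsv_round_trip(self, tmp_path, small_cohort, small_config):
        mci_ids = set(small_cohort.mci_subjects()["subject_id"])
        pats = {k: im for k, im in small_cohort.images.items() if k[0] in mci_ids}
        normalized, _ = normalize_images(
            pats, small_cohort.hc_baseline_images(), small_config.timepoints)
        fm = build_feature_matrix(normalized, small_cohort.atlas,
                                  small_cohort.subjects)
        fm.to_tsv(tmp_path / "features.tsv")
        back = FeatureMatrix.from_tsv(tmp_path / "features.tsv")
        assert back.blocks == fm.blocks
        assert np.allclose(back.data.to_numpy(), fm.data.to_numpy())
        assert (back.labels == fm.labels).all()
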