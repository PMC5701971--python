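"""Group ANOVA, cluster-extent correction, ROIs, post-hocs, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainpe.groupstats import (
    CohortDesign,
    RoiSpec,
    cluster_threshold,
    pearson_corr,
    posthoc_pairwise,
    report_tables,
    roi_mean,
    sphere_roi_mask,
    voxelwise_group_f,
)
from brainpe.maps import VolumeMap
from conftest import constant_map, make_design


def maps_from_matrix(values, shape, affine=None, mask=None):
    """One VolumeMap per row of a (subjects, voxels) matrix."""
    affine = np.eye(4) if affine is None else affine
    mask = np.ones(shape, bool) if mask is None else mask
    out = []
    for row in values:
        data = np.full(shape, np.nan)
        data[mask] = row
        out.append(VolumeMap(data, affine, mask))
    return out


class TestVoxelwiseGroupF:
    def test_identical_maps_give_zero_f(self, small_design):
        maps = [constant_map(0.5, (3, 3, 3)) for _ in range(small_design.n_subjects)]
        f_map, p_map = voxelwise_group_f(maps, small_design)
        assert np.allclose(f_map.values, 0.0)
        assert np.allclose(p_map.values, 1.0)

    def test_two_groups_no_covariates_equals_t_squared(self, rng):
        design = CohortDesign(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(12)],
                    "group": ["NC"] * 6 + ["AD"] * 6,
                    "age": rng.normal(73, 6, 12),
                    "sex": [i % 2 for i in range(12)],
                }
            )
        )
        y = rng.standard_normal((12, 8))
        maps = maps_from_matrix(y, (2, 2, 2))
        f_map, _ = voxelwise_group_f(maps, design, covariates=())
        for v in range(8):
            t, _ = stats.ttest_ind(y[:6, v], y[6:, v])  # pooled-variance t oracle
            assert f_map.values[v] == pytest.approx(t**2, abs=1e-10)

    def test_hand_computed_three_group_anova(self):
        # groups (1,2,3), (4,5,6), (7,8,9): SSB = 54, SSW = 6 -> F = 27
        design = CohortDesign(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(9)],
                    "group": ["NC"] * 3 + ["EMCI"] * 3 + ["LMCI"] * 3,
                    "age": [70.0] * 9,
                    "sex": [0] * 9,
                }
            )
        )
        maps = maps_from_matrix(np.arange(1.0, 10.0)[:, None], (1, 1, 1))
        f_map, _ = voxelwise_group_f(maps, design, covariates=())
        assert f_map.values[0] == pytest.approx(27.0, abs=1e-10)
        assert f_map.meta["df"] == [2, 6]

    def test_covariate_adjustment_absorbs_covariate_effect(self, rng):
        """A map driven purely by age should produce no group signal."""
        design = make_design(seed=3)
        age = design.table["age"].to_numpy()
        y = np.tile(age[:, None], (1, 10)) + rng.standard_normal((24, 10)) * 0.01
        maps = maps_from_matrix(y, (10, 1, 1))
        f_adj, p_adj = voxelwise_group_f(maps, design, covariates=("age",))
        assert (p_adj.values > 0.001).all()

    def test_null_pvalues_uniform(self, rng):
        """Type-I calibration: with pure-noise maps and noise covariates the
        parametric p-values are uniform (KS test at alpha = 0.01)."""
        design = make_design(sizes=(30, 33, 32, 29), seed=1)
        y = rng.standard_normal((design.n_subjects, 2000))
        maps = maps_from_matrix(y, (20, 10, 10))
        _, p_map = voxelwise_group_f(maps, design)
        ks = stats.kstest(p_map.values, "uniform")
        assert ks.pvalue > 0.01

    def test_mismatched_grids_rejected(self, small_design):
        maps = [constant_map(1.0, (3, 3, 3)) for _ in range(small_design.n_subjects)]
        maps[0] = constant_map(1.0, (4, 4, 4))
        with pytest.raises(ValueError, match="share grid"):
            voxelwise_group_f(maps, small_design)


class TestClusterThreshold:
    def test_flat_maps_give_no_clusters(self, small_design, rng):
        y = rng.standard_normal((small_design.n_subjects, 27)) * 1e-3
        maps = maps_from_matrix(y, (3, 3, 3))
        clusters, _ = cluster_threshold(
            maps, small_design, n_perm=100, p_voxel=0.005, seed=0
        )
        assert clusters == []

    def test_implanted_blob_recovered_exactly(self, rng):
        """A 50-voxel blob with a strong group effect in a 20^3 noise field is
        recovered as exactly one cluster of 50 voxels."""
        design = make_design(sizes=(8, 8, 8, 8), seed=2)
        shape = (20, 20, 20)
        blob = np.zeros(shape, bool)
        blob[5:10, 5:10, 5:7] = True  # 5*5*2 = 50 voxels
        assert blob.sum() == 50
        effect = {"NC": 0.0, "EMCI": 2.0, "LMCI": 4.0, "AD": 6.0}
        y = rng.standard_normal((design.n_subjects, int(np.prod(shape)))) * 0.2
        for i, g in enumerate(design.groups):
            y[i, blob.reshape(-1)] += effect[g]
        maps = maps_from_matrix(y, shape)
        clusters, info = cluster_threshold(
            maps, design, n_perm=200, p_voxel=0.005, extent_alpha=0.05, seed=5
        )
        assert len(clusters) == 1
        assert clusters[0].size == 50
        assert clusters[0].p_cluster < 0.05
        got = {tuple(v) for v in clusters[0].voxels}
        assert got == {tuple(v) for v in np.argwhere(blob)}

    def test_corner_touching_blobs_are_two_clusters(self, rng):
        """Face connectivity (6) does not join components touching at a corner."""
        design = make_design(sizes=(6, 6, 6, 6), seed=4)
        shape = (10, 10, 10)
        blob_a = np.zeros(shape, bool)
        blob_b = np.zeros(shape, bool)
        blob_a[2:4, 2:4, 2:4] = True
        blob_b[4:6, 4:6, 4:6] = True  # shares only the corner at (4,4,4)
        y = rng.standard_normal((design.n_subjects, 1000)) * 0.2
        strong = (blob_a | blob_b).reshape(-1)
        for i, g in enumerate(design.groups):
            y[i, strong] += {"NC": 0, "EMCI": 3, "LMCI": 6, "AD": 9}[g]
        maps = maps_from_matrix(y, shape)
        clusters6, _ = cluster_threshold(
            maps, design, n_perm=100, p_voxel=0.005, connectivity=6, seed=1
        )
        assert len(clusters6) == 2
        clusters26, _ = cluster_threshold(
            maps, design, n_perm=100, p_voxel=0.005, connectivity=26, seed=1
        )
        assert len(clusters26) == 1

    def test_low_permutation_count_refused(self, small_design):
        maps = [constant_map(0.1, (3, 3, 3)) for _ in range(small_design.n_subjects)]
        with pytest.raises(ValueError, match="n_perm"):
            cluster_threshold(maps, small_design, n_perm=50)


class TestSphereRoi:
    def test_zero_radius_hits_single_voxel(self, affine3mm):
        roi = RoiSpec("pt", (0.0, 0.0, 0.0), 0.0)
        mask = sphere_roi_mask((12, 12, 12), affine3mm, roi)
        assert mask.sum() == 1
        # center of the 12^3 grid at 3 mm with centered origin is between
        # voxels; the one whose center is exactly at distance 0 must exist
        from nibabel.affines import apply_affine

        ijk = np.argwhere(mask)[0]
        assert np.allclose(apply_affine(affine3mm, ijk), (0, 0, 0), atol=1.5)

    def test_radius_8_matches_exhaustive_enumeration(self, affine3mm):
        from nibabel.affines import apply_affine

        roi = RoiSpec("sph", (3.0, -4.5, 6.0), 8.0)
        mask = sphere_roi_mask((12, 12, 12), affine3mm, roi)
        count = 0
        for ijk in np.ndindex(12, 12, 12):  # exhaustive distance oracle
            w = apply_affine(affine3mm, ijk)
            if np.sum((w - np.array(roi.center)) ** 2) <= 64.0 + 1e-9:
                count += 1
                assert mask[ijk]
        assert mask.sum() == count > 1

    def test_published_style_mni_center(self):
        # an ROI at world (51, 63, 15) on a grid that covers it
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (30.0, 40.0, 0.0)
        roi = RoiSpec("ITG", (51.0, 63.0, 15.0), 8.0)
        mask = sphere_roi_mask((20, 20, 20), affine, roi)
        from nibabel.affines import apply_affine

        centers = apply_affine(affine, np.argwhere(mask))
        assert (np.linalg.norm(centers - np.array(roi.center), axis=1) <= 8.0 + 1e-6).all()
        assert mask.any()

    def test_sphere_outside_grid_rejected(self, affine3mm):
        with pytest.raises(ValueError, match="outside"):
            sphere_roi_mask((12, 12, 12), affine3mm, RoiSpec("far", (500.0, 0.0, 0.0), 8.0))


class TestRoiMean:
    def test_constant_map(self, affine3mm):
        vmap = constant_map(0.9, (12, 12, 12), affine3mm)
        roi = sphere_roi_mask((12, 12, 12), affine3mm, RoiSpec("c", (0, 0, 0), 8.0))
        assert roi_mean(vmap, roi) == pytest.approx(0.9)

    def test_three_voxel_roi(self):
        data = np.full((3, 1, 1), np.nan)
        data[:, 0, 0] = [0.1, 0.2, 0.3]
        vmap = VolumeMap(data, np.eye(4), np.ones((3, 1, 1), bool))
        assert roi_mean(vmap, np.ones((3, 1, 1), bool)) == pytest.approx(0.2)

    def test_roi_outside_mask_rejected(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        vmap = VolumeMap(np.ones((4, 4, 4)), np.eye(4), mask)
        roi = np.zeros((4, 4, 4), bool)
        roi[3] = True
        with pytest.raises(ValueError):
            roi_mean(vmap, roi)


class TestPosthocPairwise:
    def test_identical_group_samples_give_p_one(self):
        design = make_design(sizes=(3, 3, 3, 3))
        values = np.tile([0.1, 0.2, 0.3], 4)  # same sample in every group
        table = posthoc_pairwise(values, design)
        assert len(table) == 6
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p_bonf"], 1.0)

    def test_overwhelming_separation(self, rng):
        design = make_design(sizes=(30, 30, 2, 2), seed=9)
        values = rng.standard_normal(design.n_subjects) * 0.1
        values[design.groups == "EMCI"] += 10.0  # ~10 pooled SDs
        table = posthoc_pairwise(values, design)
        row = table[(table.group_a == "NC") & (table.group_b == "EMCI")].iloc[0]
        assert row.p_bonf < 0.001 and row.significant

    def test_t_matches_hand_formula(self, rng):
        design = make_design(sizes=(10, 12, 2, 2), seed=5)
        values = rng.standard_normal(design.n_subjects)
        xa = values[design.groups == "NC"]
        xb = values[design.groups == "EMCI"]
        sp2 = ((len(xa) - 1) * xa.var(ddof=1) + (len(xb) - 1) * xb.var(ddof=1)) / (
            len(xa) + len(xb) - 2
        )
        t_hand = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / len(xa) + 1 / len(xb)))
        table = posthoc_pairwise(values, design)
        row = table[(table.group_a == "NC") & (table.group_b == "EMCI")].iloc[0]
        assert row.t == pytest.approx(t_hand, abs=1e-10)

    def test_bonferroni_factor_is_pair_count(self, rng):
        design = make_design(sizes=(5, 5, 5, 5), seed=6)
        values = rng.standard_normal(20)
        table = posthoc_pairwise(values, design)
        assert np.allclose(table["p_bonf"], np.minimum(1.0, table["p_raw"] * 6))

    def test_tiny_group_skipped_with_note(self):
        design = make_design(sizes=(2, 2, 2, 2))
        d2 = CohortDesign(design.table.drop(index=[3]))  # leaves EMCI with 1 subject
        values = np.arange(float(d2.n_subjects))
        table = posthoc_pairwise(values, d2)
        skipped = table[table.note != ""]
        assert (skipped[["group_a", "group_b"]] == "EMCI").any(axis=1).all()
        assert skipped.shape[0] == 3


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        n = 5
        # raw-sums formula computed independently of scipy
        r_hand = (n * np.sum(x * y) - x.sum() * y.sum()) / np.sqrt(
            (n * np.sum(x**2) - x.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
        )
        t_hand = r_hand * np.sqrt((n - 2) / (1 - r_hand**2))
        p_hand = 2 * stats.t.sf(abs(t_hand), n - 2)
        r, p = pearson_corr(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            pearson_corr(np.arange(2.0), np.arange(2.0))


class TestReportTables:
    def test_empty_cluster_list_writes_header_only(self, tmp_path):
        paths = report_tables(tmp_path, clusters=[])
        df = pd.read_csv(paths["clusters"])
        assert len(df) == 0
        assert list(df.columns)[:2] == ["region", "cluster_voxels"]

    def test_tables_round_trip(self, tmp_path, rng):
        corr = pd.DataFrame(
            {"roi": ["a"] * 3, "variable": ["mmse", "faq", "cdr"], "r": rng.uniform(-1, 1, 3),
             "p": rng.uniform(0, 1, 3)}
        )
        paths = report_tables(tmp_path, clusters=[], correlations=corr, manifest={"seed": 1})
        back = pd.read_csv(paths["correlations"])
        assert len(back) == 3  # ROIs x scores
        assert paths["manifest"].exists()
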