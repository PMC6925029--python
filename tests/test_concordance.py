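"""Preprocessing, clustering cuts, metaclusters, concordance, ICC, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcmorph import (
    CohortSpec,
    CohortTable,
    assign_patient_clusters,
    cluster_cells,
    concordance_r,
    cut_branch_level,
    feature_correlation,
    feature_tests,
    generate_cohort_features,
    icc_oneway,
    metacluster,
    pca_embed,
    preprocess_per_patient,
)
from ctcmorph.catalog import ANNOTATION_COLUMNS


def make_cohort(features: np.ndarray, patients, compartments, truth=None) -> CohortTable:
    n, p = features.shape
    df = pd.DataFrame(features, columns=[f"f{i:03d}" for i in range(p)])
    df.insert(0, "category_truth", "cell")
    df.insert(0, "cell_id", [f"c{i}" for i in range(n)])
    df.insert(0, "compartment", compartments)
    df.insert(0, "patient_id", patients)
    return CohortTable(df, truth=truth)


class TestPreprocess:
    def test_constant_feature_dropped_and_recorded(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        x[:, 2] = 7.0
        cohort = make_cohort(x, ["P1"] * 30, ["liquid"] * 30)
        table = preprocess_per_patient(cohort)
        assert "f002" not in table.feature_names
        assert table.dropped == {"P1": ["f002"]}

    def test_blocks_centered_and_scaled(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(5, 2, (40, 3)), rng.normal(-1, 0.5, (25, 3))])
        cohort = make_cohort(x, ["P1"] * 40 + ["P2"] * 25, ["liquid"] * 65)
        table = preprocess_per_patient(cohort)
        for patient in ("P1", "P2"):
            block = table.patient_matrix(patient)
            assert np.abs(block.mean(axis=0)).max() < 1e-10
            assert np.allclose(block.std(axis=0, ddof=1), 1.0)

    def test_boxcox_lambda_recovers_log_for_lognormal(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.standard_normal((2000, 1)))
        cohort = make_cohort(x, ["P1"] * 2000, ["liquid"] * 2000)
        table = preprocess_per_patient(cohort)
        lam = table.transforms.loc[0, "lambda"]
        assert -0.1 < lam < 0.1

    def test_single_cell_patient_rejected(self):
        cohort = make_cohort(np.ones((3, 2)) + np.eye(3, 2), ["P1", "P1", "P2"], ["liquid"] * 3)
        with pytest.raises(ValueError, match="P2"):
            preprocess_per_patient(cohort)


class TestPca:
    def test_orthonormal_loadings_and_variance_partition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        cohort = make_cohort(x, ["P1"] * 200, ["liquid"] * 200)
        table = preprocess_per_patient(cohort)
        _, evr, pca = pca_embed(table, n_components=5)
        comps = pca.components_
        assert np.allclose(comps @ comps.T, np.eye(5), atol=1e-8)
        assert evr.sum() == pytest.approx(1.0, abs=1e-8)

    def test_separated_populations_split_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (80, 10))
        b = rng.normal(6, 1, (80, 10))
        scores, _, _ = pca_embed(pd.DataFrame(np.vstack([a, b])), n_components=2)
        labels = np.array([0] * 80 + [1] * 80)
        assert silhouette_score(scores[:, :1], labels) > 0.5

    def test_exclusion_set_removes_channel_features(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=["a", "b", "cdx2_x", "cdx2_y"])
        _, _, pca = pca_embed(df, exclude_features={"cdx2_x", "cdx2_y"})
        assert pca.n_features_in_ == 2


class TestDendrogramCuts:
    def test_two_cells_single_merge_at_distance(self):
        z = cluster_cells(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(5.0)

    def test_complete_linkage_heights_monotone(self):
        rng = np.random.default_rng(6)
        z = cluster_cells(rng.normal(size=(40, 3)))
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_level_zero_single_cluster(self):
        rng = np.random.default_rng(7)
        z = cluster_cells(rng.normal(size=(10, 2)))
        assert len(np.unique(cut_branch_level(z, 0))) == 1

    def test_full_binary_dendrogram_levels(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(10 * k, 0.05, (4, 3)) for k in range(8)])
        z = cluster_cells(x)
        assert len(np.unique(cut_branch_level(z, 2))) == 4
        assert len(np.unique(cut_branch_level(z, 3))) == 8

    def test_two_leaf_dendrogram_capped_at_leaves(self):
        z = cluster_cells(np.array([[0.0], [1.0]]))
        assert len(np.unique(cut_branch_level(z, 3))) == 2

    def test_negative_level_rejected(self):
        z = cluster_cells(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            cut_branch_level(z, -1)

    @given(n=st.integers(2, 40), level=st.integers(0, 6), seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_cluster_count_never_exceeds_bounds(self, n, level, seed):
        rng = np.random.default_rng(seed)
        z = cluster_cells(rng.normal(size=(n, 3)))
        labels = cut_branch_level(z, level)
        k = len(np.unique(labels))
        assert k <= min(2**level, n)
        assert labels.min() == 0 and labels.max() == k - 1

    def test_planted_two_clusters_recovered_at_level_one(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(5, 0.3, (25, 4))])
        z = cluster_cells(x)
        labels = cut_branch_level(z, 1)
        truth = [0] * 20 + [1] * 25
        assert adjusted_rand_score(truth, labels) == 1.0


class TestMetacluster:
    def test_shared_single_archetype_one_metacluster(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(120, 6))
        cohort = make_cohort(
            x, ["P1"] * 60 + ["P2"] * 60, (["liquid"] * 30 + ["metastasis"] * 30) * 2
        )
        table = preprocess_per_patient(cohort)
        assign = assign_patient_clusters(table, level=2)
        report = metacluster(assign, table, main_level=0)
        assert len(report.composition) == 1
        assert report.composition["percent_of_cells"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self):
        from conftest import archetype_cohort

        cohort = archetype_cohort(within_sd=0.5, seed=2, n_patients=4, cells=20)
        table = preprocess_per_patient(cohort)
        assign = assign_patient_clusters(table, level=3)
        report = metacluster(assign, table, main_level=2)
        assert report.composition["percent_of_cells"].sum() == pytest.approx(100.0, abs=0.1)
        patients = cohort.patients
        assert set(patients) <= set(report.composition.columns)

    def test_four_archetypes_recovered_across_patients(self):
        from sklearn.metrics import adjusted_rand_score

        from conftest import archetype_cohort

        cohort = archetype_cohort(within_sd=0.5, seed=3, n_patients=4, cells=30)
        table = preprocess_per_patient(cohort)
        assign = assign_patient_clusters(table, level=3)
        report = metacluster(assign, table, main_level=2)
        ari = adjusted_rand_score(
            cohort.truth["archetype"], report.cell_labels.to_numpy().astype(int)
        )
        assert report.main_labels.nunique() == 4
        assert ari == 1.0
        # every archetype present in every patient
        assert report.composition[cohort.patients].to_numpy().all()


class TestConcordanceR:
    def test_three_compartments_symmetric_unit_diagonal(self):
        spec = CohortSpec(
            n_patients=1,
            compartments=("liquid", "metastasis", "primary"),
            cells_per_compartment=30,
            n_features=60,
            seed=11,
        )
        cohort = generate_cohort_features(spec)
        r = concordance_r(cohort, "P001")
        assert r.shape == (3, 3)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert (r.to_numpy() >= -1 - 1e-12).all() and (r.to_numpy() <= 1 + 1e-12).all()

    def test_constant_profile_flagged_missing_with_reason(self):
        # every liquid cell at 0, every solid cell at 1, in all 4 features:
        # both scaled compartment profiles are constant over features
        x = np.zeros((8, 4))
        x[1::2] = 1.0
        cohort = make_cohort(x, ["P1"] * 8, ["liquid", "metastasis"] * 4)
        r = concordance_r(cohort, "P1")
        assert np.isnan(r.loc["liquid", "metastasis"])
        assert any("constant" in m for m in r.attrs["missing"])

    def test_fewer_than_two_compartments_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 5))
        cohort = make_cohort(x, ["P1"] * 10, ["liquid"] * 10)
        with pytest.raises(ValueError):
            concordance_r(cohort, "P1")

    def test_planted_rho_half_recovered(self):
        rs = []
        for seed in range(8):
            cohort = generate_cohort_features(
                CohortSpec(
                    n_patients=1,
                    cells_per_compartment=50,
                    n_features=500,
                    target_profile_correlation=0.5,
                    seed=200 + seed,
                )
            )
            rs.append(float(concordance_r(cohort, "P001").loc["liquid", "metastasis"]))
        assert np.mean(rs) == pytest.approx(0.5, abs=0.1)


class TestIcc:
    def test_zero_within_variance_gives_one(self):
        vals = [1.0, 1.0, 5.0, 5.0, 9.0, 9.0]
        grp = [0, 0, 1, 1, 2, 2]
        assert icc_oneway(vals, grp) == pytest.approx(1.0)

    def test_matches_brute_force_anova_on_random_unbalanced(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = rng.integers(2, 8)
            counts = rng.integers(2, 9, a)
            vals = np.concatenate([rng.normal(rng.normal(0, 1), 1, c) for c in counts])
            grp = np.concatenate([[i] * c for i, c in enumerate(counts)])
            # independent oracle: explicit ANOVA sums of squares
            gm = vals.mean()
            ssb = sum(c * (vals[grp == i].mean() - gm) ** 2 for i, c in enumerate(counts))
            ssw = sum(((vals[grp == i] - vals[grp == i].mean()) ** 2).sum() for i in range(a))
            msb, msw = ssb / (a - 1), ssw / (len(vals) - a)
            kbar = (len(vals) - (counts**2).sum() / len(vals)) / (a - 1)
            oracle = (msb - msw) / (msb + (kbar - 1) * msw)
            assert icc_oneway(vals, grp) == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_on_balanced_design(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        k, n = 6, 10
        vals = np.concatenate([rng.normal(rng.normal(0, 1), 1, n) for _ in range(k)])
        grp = np.repeat(np.arange(k), n)
        df = pd.DataFrame(
            {"targets": grp, "raters": np.tile(np.arange(n), k), "ratings": vals}
        )
        table = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        )
        expected = float(table.loc[table["Type"].str.startswith("ICC1") | table["Type"].eq("ICC(1,1)"), "ICC"].iloc[0])
        assert icc_oneway(vals, grp) == pytest.approx(expected, abs=1e-9)

    def test_null_groups_near_zero(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=2000)
        grp = np.repeat(np.arange(100), 20)
        assert abs(icc_oneway(vals, grp)) < 0.05

    def test_degenerate_input_missing(self):
        assert np.isnan(icc_oneway([2.0] * 6, [0, 0, 1, 1, 2, 2]))


class TestFeatureTests:
    def _cohort(self, shift, n=50, p=5, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, p))
        b = rng.normal(shift, 1, (n, p))
        return make_cohort(
            np.vstack([a, b]), ["P1"] * (2 * n), ["liquid"] * n + ["metastasis"] * n
        )

    def test_identical_samples_large_p(self):
        x = np.tile(np.random.default_rng(1).normal(size=(50, 1)), (2, 3))
        cohort = make_cohort(x, ["P1"] * 100, ["liquid"] * 50 + ["metastasis"] * 50)
        out = feature_tests(cohort, "P1")
        assert (out["p"] > 0.99).all()

    def test_planted_two_sigma_shift_detected(self):
        out = feature_tests(self._cohort(2.0), "P1")
        assert (out["p"] < 0.01).all()

    def test_bh_adjustment_reported_alongside_raw(self):
        out = feature_tests(self._cohort(0.5), "P1")
        assert {"p", "p_bh"} <= set(out.columns)
        assert (out["p_bh"] >= out["p"] - 1e-12).all()

    def test_zero_variance_equal_means_convention(self):
        x = np.ones((8, 3))
        x[:, 1] = np.arange(8)  # keep one varying feature
        cohort = make_cohort(x, ["P1"] * 8, ["liquid"] * 4 + ["metastasis"] * 4)
        out = feature_tests(cohort, "P1")
        assert out.loc["f000", "p"] == 1.0


class TestFeatureCorrelation:
    def test_diagonal_and_monotone_transform(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=300)
        x = np.column_stack([base, np.exp(base), rng.normal(size=300)])
        cohort = make_cohort(x, ["P1"] * 300, ["liquid"] * 300)
        rho = feature_correlation(cohort)
        assert np.allclose(np.diag(rho), 1.0)
        assert rho.loc["f000", "f001"] == pytest.approx(1.0)

    def test_independent_features_near_zero_offdiagonal(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(1000, 6))
        cohort = make_cohort(x, ["P1"] * 1000, ["liquid"] * 1000)
        rho = feature_correlation(cohort).to_numpy()
        off = rho[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_ordering_groups_correlated_features(self):
        rng = np.random.default_rng(16)
        base = rng.normal(size=400)
        x = np.column_stack(
            [base + rng.normal(0, 0.1, 400), rng.normal(size=400), base]
        )
        cohort = make_cohort(x, ["P1"] * 400, ["liquid"] * 400)
        rho = feature_correlation(cohort)
        order = list(rho.columns)
        assert abs(order.index("f000") - order.index("f002")) == 1


def test_annotation_columns_preserved_through_preprocess(small_cohort):
    table = preprocess_per_patient(small_cohort)
    assert list(table.data.columns[:4]) == list(ANNOTATION_COLUMNS)
    assert len(table.data) == len(small_cohort.data)
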