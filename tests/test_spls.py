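"""Sparse PLS: oracle equivalence, sparsity, stability, permutation, clusters."""

import numpy as np
import pandas as pd
import pytest

from endopls import (GeneratorConfig, SPLSConfig, fit_component,
                     permutation_test, report_clusters, simulate_cohort,
                     stability_select, cv_association)
from endopls import cohort_prep as prep
from endopls.spls import _l1_project, l1_bound


def _align_sign(v, ref):
    return v if v @ ref >= 0 else -v


class TestFitComponent:
    def test_unpenalized_fit_matches_svd_oracle(self, rng):
        """l1_frac = 1: weights equal the leading singular pair of X'Y."""
        for _ in range(3):
            X = rng.normal(size=(30, 4))
            Y = rng.normal(size=(30, 50))
            cfg = SPLSConfig(l1_frac=1.0, tol=1e-13, max_iter=5000)
            fit = fit_component(X, Y, cfg)
            M = X.T @ Y / 30
            U, s, Vt = np.linalg.svd(M)
            np.testing.assert_allclose(_align_sign(fit.x_weights, U[:, 0]), U[:, 0],
                                       atol=1e-8)
            np.testing.assert_allclose(_align_sign(fit.brain_weights, Vt[0]), Vt[0],
                                       atol=1e-8)
            assert np.isclose(fit.objective, s[0], atol=1e-8)

    def test_planted_duplicated_column_recovered_under_sparsity(self, rng):
        n = 200
        X = rng.normal(size=(n, 4))
        signal = X[:, 0]
        Y = np.column_stack([np.tile(signal, (10, 1)).T + 0.01 * rng.normal(size=(n, 10)),
                             rng.normal(size=(n, 60))])
        fit = fit_component(X, Y, SPLSConfig(l1_frac=0.15))
        support = np.flatnonzero(fit.brain_weights)
        assert set(support) <= set(range(10))
        assert len(support) >= 4

    def test_objective_nondecreasing(self, rng):
        X = rng.normal(size=(60, 4))
        Y = rng.normal(size=(60, 80))
        fit = fit_component(X, Y, SPLSConfig(l1_frac=0.3))
        diffs = np.diff(fit.objective_trace)
        assert diffs.min() > -1e-9

    def test_sign_convention_bmi_nonnegative(self, rng):
        X = rng.normal(size=(50, 4))
        Y = rng.normal(size=(50, 30))
        fit = fit_component(X, Y, SPLSConfig(l1_frac=0.5))
        assert fit.x_weights[3] >= 0

    def test_sparsity_monotone_in_l1_frac(self, rng):
        X = rng.normal(size=(60, 4))
        Y = rng.normal(size=(60, 120))
        counts = []
        for frac in (1.0, 0.6, 0.35, 0.2, 0.08):
            fit = fit_component(X, Y, SPLSConfig(l1_frac=frac))
            counts.append(int(np.sum(fit.brain_weights != 0)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_row_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fit_component(rng.normal(size=(10, 4)), rng.normal(size=(11, 5)),
                          SPLSConfig())


class TestL1Project:
    def test_constraint_binds_and_unit_norm(self, rng):
        w = rng.normal(size=200)
        for frac in (0.05, 0.3, 0.7):
            c = l1_bound(frac, 200)
            v = _l1_project(w, c)
            assert np.isclose(np.linalg.norm(v), 1.0, atol=1e-8)
            assert np.abs(v).sum() <= c + 1e-6

    def test_no_constraint_returns_normalized_input(self, rng):
        w = rng.normal(size=50)
        v = _l1_project(w, np.sqrt(50))
        np.testing.assert_allclose(v, w / np.linalg.norm(w), atol=1e-12)


class TestStability:
    def test_same_seed_reproduces_selection_freq(self, rng):
        X = rng.normal(size=(80, 4))
        Y = rng.normal(size=(80, 60))
        cfg = SPLSConfig(l1_frac=0.3, n_resamples=20, seed=42)
        f1 = stability_select(X, Y, cfg)
        f2 = stability_select(X, Y, cfg)
        np.testing.assert_array_equal(f1.selection_freq, f2.selection_freq)

    def test_zero_threshold_keeps_all_features(self, rng):
        X = rng.normal(size=(80, 4))
        Y = rng.normal(size=(80, 40))
        cfg = SPLSConfig(l1_frac=0.3, n_resamples=15, freq_threshold=0.0, seed=1)
        fit = stability_select(X, Y, cfg)
        assert np.all(fit.brain_weights != 0)
        # refit on the full support equals the dense rank-one solution
        dense = fit_component(X, Y, SPLSConfig(l1_frac=1.0, tol=1e-12, max_iter=5000))
        got = _align_sign(fit.brain_weights, dense.brain_weights)
        np.testing.assert_allclose(got, dense.brain_weights, atol=1e-6)

    def test_too_few_resamples_raise(self, rng):
        cfg = SPLSConfig(n_resamples=5)
        with pytest.raises(ValueError, match="resamples"):
            stability_select(rng.normal(size=(30, 4)), rng.normal(size=(30, 10)), cfg)


class TestPermutation:
    def test_extreme_observation_gives_add_one_p(self):
        x = np.arange(100.0)
        _, p = permutation_test(x, x, n_permutations=999, seed=0)
        assert p == 1.0 / 1000

    def test_sign_symmetry_with_identical_permutations(self, rng):
        x = rng.normal(size=80)
        s = rng.normal(size=80) + 0.2 * x
        _, p_pos = permutation_test(x, s, n_permutations=999, seed=5)
        _, p_neg = permutation_test(-x, s, n_permutations=999, seed=5)
        # same permutation set, continuous statistic: p+ + p- = 1 + 1/(B+1)
        assert np.isclose(p_pos + p_neg, 1 + 1 / 1000, atol=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            permutation_test(np.ones(50), np.arange(50.0), 999)


class TestCVAssociation:
    def test_association_table_contract(self, rng):
        X = rng.normal(size=(120, 4))
        v = rng.normal(size=30)
        Y = np.outer(X @ [0.5, 0.5, 0.3, 0.3], v) + rng.normal(size=(120, 30))
        cfg = SPLSConfig(l1_frac=0.5, n_resamples=12, n_permutations=199,
                         cv_folds=4, seed=3)
        assoc, pooled = cv_association(X, Y, cfg)
        assert list(assoc["variable"]) == list(("prs_adhd", "prs_bmi",
                                                "impulsivity", "bmi"))
        assert len(pooled) == 120 and np.all(np.isfinite(pooled))
        assert (assoc["p_fwe"] >= assoc["p_perm"] - 1e-12).all()
        assert (assoc["p_perm"] >= 1 / 200).all()

    def test_small_fold_raises(self, rng):
        cfg = SPLSConfig(cv_folds=5, n_resamples=12)
        with pytest.raises(ValueError, match="fold"):
            cv_association(rng.normal(size=(20, 4)), rng.normal(size=(20, 10)), cfg)


class TestClusters:
    coords3 = np.array([[0, 0, 0], [1, 0, 0], [5, 5, 5]])

    def test_single_voxel_single_cluster(self):
        w = np.array([0.5, 0.0, 0.0])
        out = report_clusters(w, self.coords3, np.array(["VBM"] * 3))
        assert len(out) == 1 and out.loc[0, "n_voxels"] == 1

    def test_face_adjacent_merge_gap_splits(self):
        w = np.array([0.5, 0.4, 0.3])
        out = report_clusters(w, self.coords3, np.array(["VBM"] * 3))
        assert len(out) == 2
        assert sorted(out["n_voxels"]) == [1, 2]

    def test_corner_adjacency_counts(self):
        coords = np.array([[0, 0, 0], [1, 1, 1]])
        out = report_clusters(np.array([0.2, 0.3]), coords, np.array(["MID"] * 2))
        assert len(out) == 1   # 26-connectivity joins corner neighbours

    def test_mixed_signs_split_before_labelling(self):
        coords = np.array([[0, 0, 0], [1, 0, 0]])
        out = report_clusters(np.array([0.5, -0.5]), coords, np.array(["VBM"] * 2))
        assert len(out) == 2 and set(out["sign"]) == {1, -1}

    def test_planted_clusters_recovered_with_centroids(self):
        """Stability-selected weights reproduce the planted cluster count and
        centers to within one voxel."""
        cfg = GeneratorConfig(n_subjects=600, n_snps=300, seed=21,
                              n_causal_shared=20, n_causal_specific=20)
        cohort, vbm, mid, truth = simulate_cohort(cfg)
        design = prep.build_design(cohort)
        X = np.column_stack([
            prep.standardize(prep.residualize(cohort.df[c].to_numpy(float), design))[0]
            for c in ("prs_adhd", "prs_bmi", "impulsivity", "bmi")])
        parts, mods, coords = [], [], []
        for v in (vbm, mid):
            z, _ = prep.standardize(prep.residualize(v.features, design))
            parts.append(z / np.sqrt(z.shape[1]))
            mods.append(np.repeat(v.modality, z.shape[1]))
            coords.append(v.coords)
        Y = np.hstack(parts)
        fit = stability_select(X, Y, SPLSConfig(n_resamples=50, seed=21))
        table = report_clusters(fit.brain_weights, np.vstack(coords),
                                np.concatenate(mods))
        for name in ("VBM", "MID"):
            got = table[table["modality"] == name]
            want = truth.cluster_centers[name]
            # dominant clusters (ignore stray single voxels if any)
            got = got[got["n_voxels"] >= 5]
            assert len(got) == len(want)
            cent = got[["centroid_i", "centroid_j", "centroid_k"]].to_numpy()
            for c in want:
                assert np.min(np.linalg.norm(cent - c, axis=1)) <= 1.0
            sign = -1 if name == "VBM" else 1
            assert (got["sign"] == sign).all()
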