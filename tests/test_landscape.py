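"""Median centering, comparison matrix and structural landscape PCA."""

import numpy as np
import pytest

from chromoscape.exceptions import DegenerateLandscapeWarning, ValidationError
from chromoscape.landscape import (
    StructuralLandscape, comparison_matrix, group_average_maps, joint_landscape,
    median_center, partition_by_pc, pc_regime_proportions, pca_landscape,
)
from chromoscape.traces import DistanceEnsemble
from .conftest import random_distance_ensemble


def _dens_from_entry(values):
    """Ensembles whose (0,1) entry runs through `values`, rest zero."""
    n = len(values)
    mats = np.zeros((n, 3, 3))
    for a, v in enumerate(values):
        mats[a, 0, 1] = mats[a, 1, 0] = v
    return DistanceEnsemble(mats, np.arange(3) * 30000, 30000)


class TestMedianCenter:
    def test_even_n_midpoint(self):
        cens = median_center(_dens_from_entry([4.0, 6.0]))
        assert cens.median_matrix[0, 1] == 5.0
        assert cens.centered[0, 0, 1] == -1.0
        assert cens.centered[1, 0, 1] == 1.0

    def test_odd_n_order_statistic(self):
        cens = median_center(_dens_from_entry([1.0, 2.0, 9.0]))
        assert cens.median_matrix[0, 1] == 2.0
        np.testing.assert_allclose(cens.centered[:, 0, 1], [-1.0, 0.0, 7.0])

    def test_identical_matrices_center_to_zero(self, distance_ensemble):
        mats = np.repeat(distance_ensemble.matrices[:1], 5, axis=0)
        dens = DistanceEnsemble(mats, distance_ensemble.bin_starts,
                                distance_ensemble.resolution)
        cens = median_center(dens)
        np.testing.assert_allclose(cens.centered, 0.0)

    def test_centered_median_is_zero(self, distance_ensemble):
        cens = median_center(distance_ensemble)
        np.testing.assert_allclose(np.median(cens.centered, axis=0), 0.0, atol=1e-9)

    def test_single_structure_rejected(self, distance_ensemble):
        solo = DistanceEnsemble(distance_ensemble.matrices[:1],
                                distance_ensemble.bin_starts,
                                distance_ensemble.resolution)
        with pytest.raises(ValidationError):
            median_center(solo)


class TestComparisonMatrix:
    def test_single_pair_counts_both_triangles(self):
        cens = median_center(_dens_from_entry([4.0, 6.0]))
        cm = comparison_matrix(cens)
        # h01 = -1/+1 in both triangles: s_aa = 2, s_ab = -2
        np.testing.assert_allclose(cm.s, [[2.0, -2.0], [-2.0, 2.0]])

    def test_matches_flattened_inner_product_oracle(self, rng):
        dens = random_distance_ensemble(rng, n=6, m=5)
        cm = comparison_matrix(median_center(dens))
        h = median_center(dens).centered
        oracle = np.empty((6, 6))
        for a in range(6):
            for b in range(6):
                oracle[a, b] = float((h[a] * h[b]).sum())
        np.testing.assert_allclose(cm.s, oracle, rtol=1e-12)

    def test_positive_semidefinite(self, rng):
        for _ in range(10):
            dens = random_distance_ensemble(rng, n=7, m=6)
            cm = comparison_matrix(median_center(dens))
            w = np.linalg.eigvalsh(cm.s)
            assert w.min() >= -1e-8 * np.trace(cm.s)

    def test_scaling_quadruples_s(self, distance_ensemble):
        cm1 = comparison_matrix(median_center(distance_ensemble))
        doubled = DistanceEnsemble(distance_ensemble.matrices * 2,
                                   distance_ensemble.bin_starts,
                                   distance_ensemble.resolution)
        cm2 = comparison_matrix(median_center(doubled))
        np.testing.assert_allclose(cm2.s, 4 * cm1.s, rtol=1e-10)


class TestPCALandscape:
    def test_identical_structures_degenerate(self, distance_ensemble):
        mats = np.repeat(distance_ensemble.matrices[:1], 6, axis=0)
        dens = DistanceEnsemble(mats, distance_ensemble.bin_starts,
                                distance_ensemble.resolution)
        with pytest.warns(DegenerateLandscapeWarning):
            res = StructuralLandscape(dens).fit()
        np.testing.assert_allclose(res.pc_scores, 0.0, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        dens = random_distance_ensemble(rng, n=4, m=5)
        res = StructuralLandscape(dens, n_components=3).fit()
        s = res.comparison.s
        centered = s - s.mean(axis=0)
        cov = centered.T @ centered / (4 - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(3):
            oracle = centered @ v[:, order[k]]
            got = res.pc_scores[:, k]
            assert (np.allclose(got, oracle, atol=1e-8)
                    or np.allclose(got, -oracle, atol=1e-8))

    def test_permutation_equivariance(self, rng):
        dens = random_distance_ensemble(rng, n=9, m=6)
        res = StructuralLandscape(dens, n_components=2).fit()
        perm = rng.permutation(9)
        dens_p = DistanceEnsemble(dens.matrices[perm], dens.bin_starts, dens.resolution)
        res_p = StructuralLandscape(dens_p, n_components=2).fit()
        for k in range(2):
            a, b = res.pc_scores[perm, k], res_p.pc_scores[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_rigid_motion_leaves_landscape_unchanged(self, rng):
        from scipy.spatial.transform import Rotation
        from chromoscape.traces import compute_distance_matrices
        from .conftest import random_trace_ensemble

        ens = random_trace_ensemble(rng, n=7, m=8)
        res1 = StructuralLandscape(compute_distance_matrices(ens)).fit()
        coords = ens.coords.copy()
        for a in range(7):  # independent rigid motion per structure
            rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            coords[a] = coords[a] @ rot.T + rng.normal(size=3) * 50
        ens2 = random_trace_ensemble(rng, n=7, m=8)
        ens2.coords[:] = coords
        res2 = StructuralLandscape(compute_distance_matrices(ens2)).fit()
        np.testing.assert_allclose(res1.pc_scores, res2.pc_scores, atol=1e-6)

    def test_doubling_distances_preserves_score_ratios(self, rng):
        dens = random_distance_ensemble(rng, n=8, m=6)
        res1 = StructuralLandscape(dens, n_components=2).fit()
        doubled = DistanceEnsemble(dens.matrices * 2, dens.bin_starts, dens.resolution)
        res2 = StructuralLandscape(doubled, n_components=2).fit()
        np.testing.assert_allclose(res2.pc_scores, 4 * res1.pc_scores, rtol=1e-8)

    def test_summary_mentions_variance(self, distance_ensemble):
        res = StructuralLandscape(distance_ensemble).fit()
        assert "explained variance" in res.summary()


class TestJointLandscape:
    def test_duplicated_condition_clouds_coincide(self, distance_ensemble):
        e1 = DistanceEnsemble(distance_ensemble.matrices, distance_ensemble.bin_starts,
                              distance_ensemble.resolution, condition_label="A")
        e2 = DistanceEnsemble(distance_ensemble.matrices, distance_ensemble.bin_starts,
                              distance_ensemble.resolution, condition_label="B")
        res = joint_landscape([e1, e2])
        n = distance_ensemble.n_structures
        np.testing.assert_allclose(res.pc_scores[:n], res.pc_scores[n:], atol=1e-8)

    def test_single_ensemble_identical_to_plain_landscape(self, distance_ensemble):
        a = joint_landscape([distance_ensemble])
        b = StructuralLandscape(distance_ensemble).fit()
        np.testing.assert_allclose(a.pc_scores, b.pc_scores)

    def test_disjoint_rg_ranges_separate_along_pc1(self, rng):
        from chromoscape.synthetic import generate_scaled_ensemble
        from chromoscape.traces import compute_distance_matrices

        e1, _ = generate_scaled_ensemble(n_structures=60, m_bins=30,
                                         scale_range=(0.5, 0.8), seed=5,
                                         condition="small")
        e2, _ = generate_scaled_ensemble(n_structures=60, m_bins=30,
                                         scale_range=(1.2, 1.5), seed=5,
                                         condition="large")
        res = joint_landscape([compute_distance_matrices(e1),
                               compute_distance_matrices(e2)])
        # rank-biserial correlation from the Mann-Whitney U statistic
        from scipy.stats import mannwhitneyu
        large = res.pc_scores[res.conditions == "large", 0]
        small = res.pc_scores[res.conditions == "small", 0]
        u = mannwhitneyu(large, small).statistic
        rb = 2.0 * u / (len(large) * len(small)) - 1.0
        assert abs(rb) > 0.9

    def test_mismatched_grids_rejected(self, rng):
        d1 = random_distance_ensemble(rng, n=4, m=6)
        d2 = random_distance_ensemble(rng, n=4, m=7)
        with pytest.raises(ValidationError):
            StructuralLandscape([d1, d2])


class TestPartitionByPC:
    @pytest.mark.parametrize("n,n_groups,expected_sizes", [
        (10, 5, [2, 2, 2, 2, 2]),
        (11, 5, [3, 2, 2, 2, 2]),
        (7, 1, [7]),
    ])
    def test_group_sizes(self, rng, n, n_groups, expected_sizes):
        dens = random_distance_ensemble(rng, n=n, m=5)
        res = StructuralLandscape(dens).fit()
        assignment = partition_by_pc(res, pc=1, n_groups=n_groups)
        sizes = [int((assignment == g).sum()) for g in range(n_groups)]
        assert sizes == expected_sizes

    def test_groups_are_contiguous_in_pc_order(self, rng):
        dens = random_distance_ensemble(rng, n=20, m=5)
        res = StructuralLandscape(dens).fit()
        assignment = partition_by_pc(res, pc=1, n_groups=4)
        order = np.argsort(res.pc_scores[:, 0])
        assert (np.diff(assignment[order]) >= 0).all()


class TestGroupAverageMaps:
    def test_identity_and_mean(self):
        dens = _dens_from_entry([2.0, 4.0, 7.0])
        maps = group_average_maps(dens, np.array([0, 0, 1]))
        assert maps[0][0, 1] == pytest.approx(3.0)
        assert maps[1][0, 1] == pytest.approx(7.0)

    def test_permutation_within_group_invariant(self, rng):
        dens = random_distance_ensemble(rng, n=6, m=5)
        a1 = group_average_maps(dens, np.array([0, 0, 0, 1, 1, 1]))
        perm = DistanceEnsemble(dens.matrices[[2, 1, 0, 5, 4, 3]],
                                dens.bin_starts, dens.resolution)
        a2 = group_average_maps(perm, np.array([0, 0, 0, 1, 1, 1]))
        np.testing.assert_allclose(a1[0], a2[0])

    def test_empty_group_warns_and_omits(self, rng):
        dens = random_distance_ensemble(rng, n=3, m=5)
        with pytest.warns(UserWarning, match="empty"):
            maps = group_average_maps(dens, np.array([0, 0, 2]))
        assert 1 not in maps


class TestRegimeProportions:
    def _result_with_scores(self, scores, labels):
        from chromoscape.landscape import LandscapeResult, ComparisonMatrix
        scores = np.asarray(scores, dtype=float)
        return LandscapeResult(
            pc_scores=np.column_stack([scores, np.zeros_like(scores)]),
            explained_variance_fraction=np.array([1.0, 0.0]),
            conditions=np.asarray(labels, dtype=object),
            rg=np.ones_like(scores),
            comparison=ComparisonMatrix(s=np.eye(len(scores))),
            dens=None,
        )

    def test_hand_placed_two_regimes(self):
        res = self._result_with_scores([0.0, 1.0, 9.0, 10.0], ["A", "A", "B", "B"])
        tab = pc_regime_proportions(res, n_bins=2)
        assert tab.loc[0, "A"] == 1.0
        assert tab.loc[1, "B"] == 1.0

    def test_single_condition_everywhere_one(self, rng):
        dens = random_distance_ensemble(rng, n=10, m=5)
        res = StructuralLandscape(dens).fit()
        tab = pc_regime_proportions(res, n_bins=4)
        label = str(res.conditions[0])
        occupied = tab[tab["n"] > 0]
        assert (occupied[label] == 1.0).all()

    def test_duplicated_scores_split_half(self):
        res = self._result_with_scores([0, 0, 5, 5, 10, 10],
                                       ["A", "B", "A", "B", "A", "B"])
        tab = pc_regime_proportions(res, n_bins=2)
        occupied = tab[tab["n"] > 0]
        assert (occupied["A"] == 0.5).all()
        assert (occupied["B"] == 0.5).all()

    def test_occupied_regimes_sum_to_one(self, rng):
        from chromoscape.synthetic import generate_scaled_ensemble
        from chromoscape.traces import compute_distance_matrices

        e1, _ = generate_scaled_ensemble(n_structures=40, m_bins=20, seed=1,
                                         condition="x")
        e2, _ = generate_scaled_ensemble(n_structures=40, m_bins=20, seed=2,
                                         condition="y")
        res = joint_landscape([compute_distance_matrices(e1),
                               compute_distance_matrices(e2)])
        tab = pc_regime_proportions(res, n_bins=10)
        occ = tab[tab["n"] > 0]
        np.testing.assert_allclose(occ[["x", "y"]].sum(axis=1), 1.0)


def test_pca_landscape_functional_matches_model(rng):
    dens = random_distance_ensemble(rng, n=8, m=6)
    cm = comparison_matrix(median_center(dens))
    res_f = pca_landscape(cm, n_components=2, rg=dens.radii_of_gyration())
    res_m = StructuralLandscape(dens, n_components=2).fit()
    np.testing.assert_allclose(res_f.pc_scores, res_m.pc_scores, atol=1e-9)
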