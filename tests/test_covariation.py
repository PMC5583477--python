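"""Correlation networks, ROC evaluation, TOM and module detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from covariome.containers import AnnotationCatalog
from covariome.covariation import (
    adjacency_and_tom,
    complex_cohesion,
    detect_modules,
    export_network,
    interaction_roc,
    masked_pearson,
    module_eigengene,
    module_enrichment,
    module_module_correlation,
    pair_class_distributions,
    pairwise_correlation,
    roc_auc_from_scores,
    soft_threshold_select,
)

from conftest import make_matrix


def brute_force_auc(pos, neg):
    """Exhaustive concordant-pair count with tie-halving (the ROC oracle)."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestPairwiseCorrelation:
    def test_identical_and_negated_rows(self, rng):
        base = rng.standard_normal(20)
        m = make_matrix(np.vstack([base, base, -base]), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        assert net.pair_r("F0", "F1") == pytest.approx(1.0, abs=1e-9)
        assert net.pair_r("F0", "F2") == pytest.approx(-1.0, abs=0.02)  # +1 offset in log2

    def test_hand_pair_matches_direct_formula(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 2.5, 1.0, 4.0, 5.0])
        m = make_matrix(np.vstack([x, y]), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        lx, ly = np.log2(2.0**x * 100 + 1), np.log2(2.0**y * 100 + 1)
        expected = np.corrcoef(lx, ly)[0, 1]
        assert net.pair_r("F0", "F1") == pytest.approx(expected, abs=1e-12)

    def test_masked_pearson_matches_pandas_pairwise_complete(self, rng):
        values = rng.standard_normal((15, 30))
        values[rng.random((15, 30)) < 0.2] = np.nan
        r, n = masked_pearson(values, min_shared=3)
        expected = pd.DataFrame(values).T.corr(min_periods=3).to_numpy()
        assert np.allclose(r, expected, atol=1e-10, equal_nan=True)

    def test_quantified_fraction_filter(self, rng):
        values = rng.standard_normal((3, 10))
        values[0, :5] = np.nan  # quantified in 50% only
        m = make_matrix(values, like_intensities=True)
        net = pairwise_correlation(m, min_shared=3, min_fraction_quantified=0.8)
        assert "F0" not in net.features

    def test_low_overlap_pairs_skipped(self, rng):
        values = rng.standard_normal((2, 10))
        values[0, :5] = np.nan
        values[1, 5:] = np.nan
        m = make_matrix(values, like_intensities=True)
        net = pairwise_correlation(m, min_shared=3, min_fraction_quantified=0.4)
        assert np.isnan(net.pair_r("F0", "F1"))
        assert net.n_skipped_pairs == 1


class TestPairClassDistributions:
    def test_catalog_covering_all_pairs_gives_equal_means(self, rng):
        m = make_matrix(rng.standard_normal((4, 20)), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        catalog = AnnotationCatalog(sets={"ALL": list(net.features)})
        report = pair_class_distributions(net, catalog)
        assert report.mean_annotated == pytest.approx(report.mean_all)

    def test_planted_complexes_shift_annotated_mean(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        report = pair_class_distributions(net, small_cohort.annotations)
        assert report.mean_annotated > report.mean_all + 0.2
        assert report.ranksum_p < 1e-10

    def test_no_overlap_is_an_error(self, rng):
        m = make_matrix(rng.standard_normal((3, 20)), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        catalog = AnnotationCatalog(sets={"X": ["nope1", "nope2"]})
        with pytest.raises(ValueError, match="no annotated pair"):
            pair_class_distributions(net, catalog)


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc_from_scores(np.array([0.9, 0.8]), np.array([0.1]))
        assert roc.auc == 1.0

    def test_all_equal_scores_give_half(self):
        roc = roc_auc_from_scores(np.ones(5), np.ones(7))
        assert roc.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_from_scores(np.array([1.0]), np.array([]))

    def test_twelve_pair_instance_matches_oracle(self, rng):
        pos = rng.choice(np.linspace(-1, 1, 9), size=5)
        neg = rng.choice(np.linspace(-1, 1, 9), size=7)
        roc = roc_auc_from_scores(pos, neg)
        assert roc.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rank_auc_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 11))
        n_neg = int(rng.integers(1, 21 - n_pos))
        grid = np.linspace(-1, 1, 7)  # coarse grid forces ties
        pos = rng.choice(grid, size=n_pos)
        neg = rng.choice(grid, size=n_neg)
        roc = roc_auc_from_scores(pos, neg)
        assert roc.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_interaction_roc_on_planted_cohort(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        roc = interaction_roc(net, small_cohort.annotations.all_set_pairs())
        assert roc.auc > 0.9
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)


class TestComplexCohesion:
    def test_identical_members(self, rng):
        base = rng.standard_normal(20)
        m = make_matrix(np.vstack([base] * 4), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        report = complex_cohesion(net, list(net.features))
        assert report.median_pairwise_r == pytest.approx(1.0, abs=1e-6)
        assert report.outliers == []

    def test_three_member_hand_example(self, rng):
        values = rng.standard_normal((3, 30))
        m = make_matrix(values, like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        report = complex_cohesion(net, ["F0", "F1", "F2"])
        r01, r02, r12 = (net.pair_r("F0", "F1"), net.pair_r("F0", "F2"),
                         net.pair_r("F1", "F2"))
        assert report.median_pairwise_r == pytest.approx(float(np.median([r01, r02, r12])))
        assert report.member_mean_r["F0"] == pytest.approx((r01 + r02) / 2)

    def test_planted_outlier_subunit_flagged(self, default_cohort):
        net = pairwise_correlation(default_cohort.protein)
        flagged, total = 0, 0
        for cpx, outlier in default_cohort.truth.outlier_subunits.items():
            members = default_cohort.truth.complexes[cpx]
            if outlier not in net or sum(m in net for m in members) < 4:
                continue  # outlier or too many members lost to missingness
            report = complex_cohesion(net, members)
            total += 1
            flagged += outlier in report.outliers
        assert total > 0 and flagged >= total / 2

    def test_too_few_members_rejected(self, rng):
        m = make_matrix(rng.standard_normal((2, 20)), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        with pytest.raises(ValueError):
            complex_cohesion(net, ["F0", "F1"])


class TestSoftThresholdAndTom:
    def test_modular_signal_selects_low_power(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        result = soft_threshold_select(net.r)
        assert 1 <= result.power <= 12

    def test_connectivity_decreases_with_power(self, rng):
        r = np.clip(rng.uniform(-1, 1, size=(30, 30)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        ks = []
        for power in (1, 3, 6, 9):
            a, _ = adjacency_and_tom(r, power)
            np.fill_diagonal(a, 0.0)
            ks.append(a.sum())
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_three_node_hand_tom(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.9], [0.9, 0.9, 1.0]])
        _, tom = adjacency_and_tom(r, 1)
        # a_ij = 0.9 everywhere; k_i = 1.8; TOM_01 = (0.81 + 0.9)/(1.8 + 1 - 0.9)
        assert tom[0, 1] == pytest.approx(1.71 / 1.9)
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_identity_adjacency_gives_identity_tom(self):
        r = np.eye(5)
        _, tom = adjacency_and_tom(r, 2)
        assert np.allclose(tom, np.eye(5))

    def test_tom_bounds(self, rng):
        r = np.corrcoef(rng.standard_normal((20, 40)))
        _, tom = adjacency_and_tom(r, 6)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency_and_tom(np.eye(3), 0)


def _two_block_matrix(rng, block=10, r_within=0.9):
    lat1, lat2 = rng.standard_normal(50), rng.standard_normal(50)
    rows = [np.sqrt(r_within) * lat1 + np.sqrt(1 - r_within) * rng.standard_normal(50)
            for _ in range(block)]
    rows += [np.sqrt(r_within) * lat2 + np.sqrt(1 - r_within) * rng.standard_normal(50)
             for _ in range(block)]
    return make_matrix(np.array(rows), like_intensities=True)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        m = _two_block_matrix(rng)
        net = pairwise_correlation(m, min_shared=10)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features)
        assert part.n_modules == 2
        assert sorted(part.modules[1]) == [f"F{i}" for i in range(10)]
        assert sorted(part.modules[2]) == [f"F{i}" for i in range(10, 20)]

    def test_noise_leaves_features_unassigned(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.standard_normal((200, 50)), like_intensities=True)
        net = pairwise_correlation(m, min_shared=10)
        power = soft_threshold_select(net.r).power
        _, tom = adjacency_and_tom(net.r, power)
        part = detect_modules(tom, net.features)
        assert (part.labels > 0).mean() < 0.05

    def test_min_module_size_honored(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features, min_module_size=3)
        assert part.sizes.min() >= 3

    def test_deterministic_given_inputs(self, rng):
        m = _two_block_matrix(rng)
        net = pairwise_correlation(m, min_shared=10)
        _, tom = adjacency_and_tom(net.r, 6)
        a = detect_modules(tom, net.features)
        b = detect_modules(tom, net.features)
        assert a.labels.equals(b.labels)


class TestEigengene:
    def test_identical_rows_module(self, rng):
        base = rng.standard_normal(20)
        m = make_matrix(np.vstack([base] * 5), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features)
        module_eigengene(m, part)
        eig = part.eigengenes.iloc[0].to_numpy()
        z = (base - base.mean()) / base.std(ddof=1)
        # eigengene equals the standardized shared profile up to tiny log2(+1) warp
        assert abs(np.corrcoef(eig, z)[0, 1]) > 0.999
        assert np.corrcoef(eig, np.log2(2.0**base * 100 + 1))[0, 1] > 0

    def test_variance_explained_matches_brute_force(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features)
        module_eigengene(small_cohort.protein.subset(features=net.features), part)
        checked = 0
        for label, members in part.modules.items():
            if len(members) > 10:
                continue
            sub = np.log2(small_cohort.protein.data.loc[members].to_numpy() + 1.0)
            mu = np.nanmean(sub, axis=1, keepdims=True)
            sd = np.nanstd(sub, axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            z = np.nan_to_num((sub - mu) / sd)
            eigvals = np.linalg.eigvalsh(z @ z.T)
            expected = eigvals[-1] / eigvals.sum()
            assert part.variance_explained[label] == pytest.approx(expected, abs=1e-8)
            checked += 1
        assert checked > 0

    def test_sign_anchor_and_unit_variance(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features)
        module_eigengene(small_cohort.protein.subset(features=net.features), part)
        log2 = np.log2(small_cohort.protein.data + 1.0)
        for label, members in part.modules.items():
            eig = part.eigengenes.loc[label]
            corr = [eig.corr(log2.loc[m]) for m in members]
            assert np.nanmean(corr) > 0
        assert np.allclose(part.eigengenes.std(axis=1, ddof=1), 1.0)


class TestEnrichment:
    def test_module_equals_set_matches_exact_tail_sum(self, rng):
        m = make_matrix(rng.standard_normal((12, 30)), like_intensities=True)
        net = pairwise_correlation(m, min_shared=5)
        from covariome.covariation import ModulePartition

        members = [f"F{i}" for i in range(4)]
        universe = [f"F{i}" for i in range(12)]
        part = ModulePartition(
            pd.Series([1] * 4 + [0] * 8, index=universe), modules={1: members}
        )
        table = module_enrichment(part, {"SET": members}, universe=universe)
        # exact hypergeometric tail by enumeration: P(X >= 4), M=12, K=4, n=4
        M, K, n = 12, 4, 4
        expected = sum(
            math.comb(K, k) * math.comb(M - K, n - k) / math.comb(M, n)
            for k in range(4, 5)
        )
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_disjoint_set_is_insignificant(self, rng):
        from covariome.covariation import ModulePartition

        universe = [f"F{i}" for i in range(20)]
        part = ModulePartition(
            pd.Series([1] * 5 + [0] * 15, index=universe),
            modules={1: universe[:5]},
        )
        table = module_enrichment(part, {"SET": universe[15:]}, universe=universe)
        assert table["p"].iloc[0] > 0.2

    def test_planted_complexes_enriched(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features)
        table = module_enrichment(part, small_cohort.annotations.sets)
        recovered = set(table.loc[table["significant"], "set"])
        assert len(recovered) >= 0.8 * len(small_cohort.annotations.sets)


class TestModuleModuleAndExport:
    def test_duplicate_module_correlation_is_one(self, rng):
        eig = pd.DataFrame(
            [rng.standard_normal(10)] * 2, index=[1, 2],
            columns=[f"S{j}" for j in range(10)],
        )
        r = module_module_correlation(eig)
        assert r.loc[1, 2] == pytest.approx(1.0)

    def test_three_module_hand_case(self, rng):
        eig = pd.DataFrame(
            rng.standard_normal((3, 15)), index=[1, 2, 3],
            columns=[f"S{j}" for j in range(15)],
        )
        r = module_module_correlation(eig)
        expected = np.corrcoef(eig.to_numpy())
        assert np.allclose(r.to_numpy(), expected)
        assert np.allclose(np.diag(r), 1.0)

    def test_independent_planted_modules_weakly_correlated(self, small_cohort):
        net = pairwise_correlation(small_cohort.protein)
        _, tom = adjacency_and_tom(net.r, 6)
        part = detect_modules(tom, net.features)
        module_eigengene(small_cohort.protein.subset(features=net.features), part)
        r = module_module_correlation(part.eigengenes).to_numpy()
        iu = np.triu_indices(r.shape[0], k=1)
        assert np.median(np.abs(r[iu])) < 0.3

    @pytest.mark.parametrize("threshold, expect", [(1.0, 0), (0.0, 6)])
    def test_export_threshold_extremes(self, rng, threshold, expect):
        r = np.corrcoef(rng.standard_normal((4, 20)))
        _, tom = adjacency_and_tom(r, 2)
        edges = export_network(tom, list("ABCD"), r, weight_threshold=threshold)
        assert len(edges) == expect

    def test_export_count_matches_brute_force(self, rng):
        r = np.corrcoef(rng.standard_normal((15, 25)))
        _, tom = adjacency_and_tom(r, 3)
        edges = export_network(tom, [f"F{i}" for i in range(15)], r, weight_threshold=0.02)
        iu = np.triu_indices(15, k=1)
        assert len(edges) == int((tom[iu] > 0.02).sum())


def test_protein_network_beats_mrna_network_on_planted_complexes(small_cohort):
    """Protein co-variation predicts planted complexes better than mRNA."""
    pos = small_cohort.annotations.all_set_pairs()
    auc_p = interaction_roc(pairwise_correlation(small_cohort.protein), pos).auc
    auc_m = interaction_roc(pairwise_correlation(small_cohort.mrna), pos).auc
    assert auc_p > auc_m
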