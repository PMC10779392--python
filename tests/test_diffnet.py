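import numpy as np
import pytest

from mbmri import connectome as cm
from mbmri import diffnet
from mbmri.errors import DegenerateDataError, ValidationError
from mbmri.synthetic_cohort import SyntheticCohortSpec, simulate_bold_cohort


def toy_connectome(edges, subject, group, n=4):
    m = np.eye(n)
    iu = np.triu_indices(n, 1)
    m[iu] = edges
    m += np.triu(m, 1).T
    return cm.Connectome(matrix=m, region_ids=np.arange(1, n + 1),
                         subject=subject, group=group)


def random_cohort(rng, n_control, n_cko, n=6):
    conns = []
    for i in range(n_control + n_cko):
        data = rng.normal(size=(40, n))
        group = "control" if i < n_control else "cko"
        c = cm.compute_connectome(
            cm.RegionTimeSeriesSet(data=data, region_ids=np.arange(1, n + 1),
                                   subject=f"s{i}", group=group, tr=1.8)
        )
        conns.append(c)
    return conns


class TestDifferenceMatrices:
    def test_study_cohort_pair_counts(self, rng):
        conns = random_cohort(rng, 5, 7)
        diffs = diffnet.difference_matrices(conns)
        assert diffs["control-control"].n_pairs == 10
        assert diffs["cko-cko"].n_pairs == 21
        assert diffs["control-cko"].n_pairs == 35

    def test_identical_connectomes_give_zero_differences(self):
        e = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        conns = [toy_connectome(e, f"s{i}", g)
                 for i, g in enumerate(["control", "control", "cko", "cko"])]
        diffs = diffnet.difference_matrices(conns)
        for ds in diffs.values():
            np.testing.assert_array_equal(ds.diffs, 0.0)

    def test_two_subjects_match_hand_subtraction(self):
        e1 = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        e2 = [0.0, 0.4, 0.1, 0.2, 0.8, 0.3]
        conns = [
            toy_connectome(e1, "c1", "control"),
            toy_connectome(e2, "c2", "control"),
            toy_connectome(e1, "k1", "cko"),
            toy_connectome(e2, "k2", "cko"),
        ]
        diffs = diffnet.difference_matrices(conns)
        np.testing.assert_allclose(
            diffs["control-control"].diffs[0],
            np.array(e1) - np.array(e2),
        )
        # between-class orientation is control - cko
        assert diffs["control-cko"].pair_ids[0] == ("c1", "k1")
        np.testing.assert_allclose(diffs["control-cko"].diffs[1],
                                   np.array(e1) - np.array(e2))

    def test_single_subject_group_rejected(self, rng):
        conns = random_cohort(rng, 1, 3)
        with pytest.raises(ValidationError, match="control"):
            diffnet.difference_matrices(conns)


class TestPairwisePatternR2:
    def test_identical_single_pair_gives_r2_one(self):
        ds = diffnet.DifferenceMatrixSet(
            comparison="control-control", pair_ids=[("a", "b")],
            diffs=np.array([[0.1, -0.2, 0.3, 0.0, 0.4, -0.1]]),
            region_ids=np.arange(1, 5),
        )
        other = diffnet.DifferenceMatrixSet(
            comparison="cko-cko", pair_ids=[("c", "d")],
            diffs=ds.diffs.copy(), region_ids=np.arange(1, 5),
        )
        r2, _ = diffnet.pairwise_pattern_r2(ds, other, n_permutations=50)
        assert r2 == pytest.approx(1.0)

    def test_orientation_invariance(self, rng):
        conns = random_cohort(rng, 3, 3)
        diffs = diffnet.difference_matrices(conns)
        a, b = diffs["control-control"], diffs["cko-cko"]
        r2_orig, _ = diffnet.pairwise_pattern_r2(a, b, n_permutations=10,
                                                 seed=1)
        flipped = diffnet.DifferenceMatrixSet(
            comparison=b.comparison, pair_ids=b.pair_ids,
            diffs=b.diffs * np.where(np.arange(b.n_pairs)[:, None] % 2, -1, 1),
            region_ids=b.region_ids,
        )
        r2_flip, _ = diffnet.pairwise_pattern_r2(a, flipped, n_permutations=10,
                                                 seed=1)
        assert r2_flip == pytest.approx(r2_orig, abs=1e-12)

    def test_planted_subject_pattern_beats_permutation_null(self):
        spec = SyntheticCohortSpec(group_effect=0.0, subject_effect_sd=0.25,
                                   seed=2)
        cohort, _ = simulate_bold_cohort(spec)
        conns = [cm.compute_connectome(r) for r in cohort]
        diffs = diffnet.difference_matrices(conns)
        within = diffs["control-control"]
        _, p = diffnet.pairwise_pattern_r2(within, within,
                                           n_permutations=200, seed=0)
        assert p < 0.05

    def test_all_zero_pair_rejected(self):
        ds = diffnet.DifferenceMatrixSet(
            comparison="control-control", pair_ids=[("a", "b")],
            diffs=np.zeros((1, 6)), region_ids=np.arange(1, 5),
        )
        with pytest.raises(DegenerateDataError, match="degenerate pair"):
            diffnet.pairwise_pattern_r2(ds, ds, n_permutations=10)


class TestClassPatterns:
    def test_rms_pattern_is_orientation_proof(self, rng):
        conns = random_cohort(rng, 3, 2)
        ds = diffnet.difference_matrices(conns)["control-control"]
        p1 = diffnet.class_pattern(ds)
        flipped = diffnet.DifferenceMatrixSet(
            comparison=ds.comparison, pair_ids=ds.pair_ids, diffs=-ds.diffs,
            region_ids=ds.region_ids,
        )
        np.testing.assert_allclose(diffnet.class_pattern(flipped).values,
                                   p1.values)

    def test_identical_patterns_correlate_perfectly(self, rng):
        conns = random_cohort(rng, 3, 2)
        p = diffnet.class_pattern(
            diffnet.difference_matrices(conns)["control-control"]
        )
        r, r2, _ = diffnet.class_pattern_correlation(p, p)
        assert r == pytest.approx(1.0)

    def test_shared_subject_edges_correlate_across_groups(self):
        spec = SyntheticCohortSpec(group_effect=0.0, subject_effect_sd=0.3,
                                   seed=3)
        cohort, _ = simulate_bold_cohort(spec)
        conns = [cm.compute_connectome(r) for r in cohort]
        diffs = diffnet.difference_matrices(conns)
        r, _, p = diffnet.class_pattern_correlation(
            diffnet.class_pattern(diffs["control-control"]),
            diffnet.class_pattern(diffs["cko-cko"]),
        )
        assert r > 0
        assert p < 0.05

    def test_shuffled_pattern_loses_correlation(self, rng):
        spec = SyntheticCohortSpec(group_effect=0.0, subject_effect_sd=0.3,
                                   seed=3)
        cohort, _ = simulate_bold_cohort(spec)
        conns = [cm.compute_connectome(r) for r in cohort]
        diffs = diffnet.difference_matrices(conns)
        pa = diffnet.class_pattern(diffs["control-control"])
        pb = diffnet.class_pattern(diffs["cko-cko"])
        r_true, _, _ = diffnet.class_pattern_correlation(pa, pb)
        null_rs = []
        for s in range(200):
            shuffled = diffnet.ClassPattern(
                comparison=pb.comparison,
                values=np.random.default_rng(s).permutation(pb.values),
            )
            null_rs.append(diffnet.class_pattern_correlation(pa, shuffled)[0])
        assert r_true > np.quantile(null_rs, 0.95)

    def test_constant_pattern_rejected(self):
        p = diffnet.ClassPattern(comparison="control-control",
                                 values=np.full(6, 0.2))
        q = diffnet.ClassPattern(comparison="cko-cko",
                                 values=np.arange(6.0))
        with pytest.raises(DegenerateDataError):
            diffnet.class_pattern_correlation(p, q)


class TestDiscriminativeNetwork:
    def test_identical_subjects_give_empty_network(self):
        e = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        conns = [toy_connectome(e, f"s{i}", g)
                 for i, g in enumerate(["control", "control", "cko", "cko"])]
        net = diffnet.group_discriminative_edges(conns, threshold=0.2)
        assert net.n_edges == 0
        assert len(net.implicated_regions) == 0

    def test_zero_variance_edge_warned_not_fatal(self, caplog, rng):
        conns = random_cohort(rng, 2, 2)
        for c in conns:
            c.matrix[0, 1] = c.matrix[1, 0] = 0.5
        import logging

        with caplog.at_level(logging.WARNING, logger="mbmri"):
            net = diffnet.group_discriminative_edges(conns)
        assert "zero variance" in caplog.text
        assert net.all_r2[0] == 0.0

    def test_planted_group_edges_recovered(self):
        spec = SyntheticCohortSpec(n_control=20, n_cko=20, n_frames=1000,
                                   group_effect=0.3, seed=0)
        cohort, truth = simulate_bold_cohort(spec)
        conns = [cm.compute_connectome(r) for r in cohort]
        net = diffnet.group_discriminative_edges(conns, threshold=0.2)
        planted = set(truth.group_edge_set.tolist())
        found = set(net.edge_index.tolist())
        tp = len(planted & found)
        assert tp / max(len(found), 1) >= 0.9
        assert tp / len(planted) >= 0.9
        # planted offset is positive: higher synchrony in the knockouts
        recovered_signs = [
            s for k, s in zip(net.edge_index, net.signs) if k in planted
        ]
        assert all(s == 1 for s in recovered_signs)

    def test_threshold_monotonicity(self, rng):
        conns = random_cohort(rng, 4, 4)
        sizes = [
            diffnet.group_discriminative_edges(conns, threshold=t).n_edges
            for t in (0.1, 0.2, 0.4, 0.6)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestRegionMapping:
    def test_empty_network_all_zero_counts(self, coarse_table):
        net = diffnet.DiscriminativeNetwork(
            threshold=0.2, edge_index=np.array([], dtype=int),
            r2=np.array([]), signs=np.array([], dtype=int),
            pairs=np.empty((0, 2), dtype=int),
            region_ids=coarse_table["label"].to_numpy(),
        )
        summary = diffnet.map_edges_to_regions(net, coarse_table)
        assert (summary["n_edges"] == 0).all()

    def test_single_inter_hemisphere_edge_tally(self, coarse_table):
        # edge between region 1 (left olfactory bulb) and 15 (right counterpart)
        pairs = cm.edge_pairs(28)
        k = int(np.flatnonzero((pairs[:, 0] == 0) & (pairs[:, 1] == 14))[0])
        net = diffnet.DiscriminativeNetwork(
            threshold=0.2, edge_index=np.array([k]), r2=np.array([0.5]),
            signs=np.array([-1]), pairs=pairs[[k]],
            region_ids=coarse_table["label"].to_numpy(),
        )
        summary = diffnet.map_edges_to_regions(net, coarse_table)
        fb = summary.set_index("macro_region").loc["forebrain"]
        assert fb["n_edges"] == 1
        assert fb["inter-hemisphere"] == 1
        assert fb["n_decrease"] == 1
        assert set(net.implicated_regions) == {1, 15}

    def test_three_edge_toy_tally(self, coarse_table):
        pairs = cm.edge_pairs(28)
        wanted = [(0, 1), (0, 14), (10, 24)]  # two forebrain + medulla pair
        ks = [
            int(np.flatnonzero((pairs[:, 0] == i) & (pairs[:, 1] == j))[0])
            for i, j in wanted
        ]
        net = diffnet.DiscriminativeNetwork(
            threshold=0.2, edge_index=np.array(ks),
            r2=np.array([0.3, 0.4, 0.5]), signs=np.array([1, 1, -1]),
            pairs=pairs[ks], region_ids=coarse_table["label"].to_numpy(),
        )
        summary = diffnet.map_edges_to_regions(net, coarse_table).set_index(
            "macro_region"
        )
        assert summary.loc["forebrain", "n_edges"] == 2
        assert summary.loc["brainstem", "n_edges"] == 1
        assert summary.loc["brainstem", "n_decrease"] == 1


class TestSeparationProperty:
    def test_subject_and_group_patterns_dissociate(self):
        """Shared subject edges in both groups plus a disjoint group offset:
        within-class patterns correlate across groups while the
        discriminative network concentrates on the group edges."""
        spec = SyntheticCohortSpec(seed=0)
        cohort, truth = simulate_bold_cohort(spec)
        conns = [cm.compute_connectome(r) for r in cohort]

        diffs = diffnet.difference_matrices(conns)
        r, _, _ = diffnet.class_pattern_correlation(
            diffnet.class_pattern(diffs["control-control"]),
            diffnet.class_pattern(diffs["cko-cko"]),
        )
        assert r > 0

        net = diffnet.group_discriminative_edges(conns, threshold=0.2)
        found = set(net.edge_index.tolist())
        grp = set(truth.group_edge_set.tolist())
        subj = set(truth.subject_edge_set.tolist())
        grp_rate = len(found & grp) / len(grp)
        subj_rate = len(found & subj) / len(subj)
        assert grp_rate > subj_rate
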