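"""ASV-table filtering, diversity, ordination and permutation tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cesdyn.community import (
    ASVTable, beta_dispersion, bray_curtis, filter_asv_table,
    genus_from_taxonomy, genus_top_abundance, pcoa, permanova, shannon,
)
from cesdyn.errors import AnalysisError
from cesdyn.synthetic import default_community_scenario, gen_asv_tables


def make_table(counts: dict, taxonomy: dict | None = None) -> ASVTable:
    frame = pd.DataFrame(counts).T  # rows = ASVs
    frame.columns = [f"S{i + 1}" for i in range(frame.shape[1])]
    tax = pd.Series(taxonomy or {a: f"d;p;c;o;f;g__{a}" for a in frame.index})
    return ASVTable(counts=frame, taxonomy=tax)


class TestFiltering:
    def test_dataset_wide_singleton_rule(self):
        table = make_table({"a": [1, 0], "b": [1, 1], "c": [2, 0],
                            "d": [3, 2], "e": [4, 5]})
        kept = filter_asv_table(table, min_total_reads=2)
        assert kept.asv_ids == ["b", "c", "d", "e"]

    def test_totals_boundary_cases(self):
        table = make_table({"one": [1, 0], "two": [2, 0]})
        kept = filter_asv_table(table)
        assert kept.asv_ids == ["two"]

    def test_threshold_zero_is_identity(self):
        table = make_table({"a": [1, 0], "b": [0, 0]})
        kept = filter_asv_table(table, min_total_reads=0)
        assert kept.asv_ids == ["a", "b"]

    def test_removing_everything_is_an_error(self):
        table = make_table({"a": [1, 0]})
        with pytest.raises(AnalysisError):
            filter_asv_table(table, min_total_reads=10)

    def test_counting_example_three_survive(self):
        table = make_table({f"a{i}": [v] for i, v in enumerate((1, 1, 2, 5, 9))})
        assert len(filter_asv_table(table).asv_ids) == 3


class TestGenus:
    @pytest.mark.parametrize("lineage, genus", [
        ("d__B;p__P;c__G;o__O;f__F;g__Pseudomonas", "Pseudomonas"),
        ("a;b;c;d;e;Brevundimonas;s__x", "Brevundimonas"),
        ("a;b;c;d;e", "unclassified_genus"),
        ("a;b;c;d;e;;s", "unclassified_genus"),
        (float("nan"), "unclassified_genus"),
    ])
    def test_genus_parsing(self, lineage, genus):
        assert genus_from_taxonomy(lineage) == genus

    def test_single_genus_has_unit_abundance(self):
        table = make_table({"a": [10, 20], "b": [5, 5]},
                           taxonomy={"a": "x;x;x;x;x;g__G1",
                                     "b": "x;x;x;x;x;g__G1"})
        rel = genus_top_abundance(table)
        assert np.allclose(rel.loc["G1"], 1.0)

    def test_two_genus_proportions(self):
        table = make_table({"a": [30], "b": [70]},
                           taxonomy={"a": "x;x;x;x;x;g__G1",
                                     "b": "x;x;x;x;x;g__G2"})
        rel = genus_top_abundance(table)
        assert rel.loc["G1", "S1"] == pytest.approx(0.3)
        assert rel.loc["G2", "S1"] == pytest.approx(0.7)

    def test_top_n_pools_remainder_as_other(self):
        table = make_table({f"a{i}": [10 - i] for i in range(6)},
                           taxonomy={f"a{i}": f"x;x;x;x;x;g__G{i}"
                                     for i in range(6)})
        rel = genus_top_abundance(table, n=3)
        assert list(rel.index[:3]) == ["G0", "G1", "G2"]
        assert "other" in rel.index
        assert rel.sum(axis=0).iloc[0] == pytest.approx(1.0)

    def test_succession_scenario_recovers_dominant_genus(self):
        table, truth = gen_asv_tables(default_community_scenario(seed=4))
        rel = genus_top_abundance(table)
        for label, traj in truth.trajectories.items():
            expected = max(traj, key=traj.get)
            for sample in table.sample_metadata.index[
                    table.sample_metadata["time_point"] == label]:
                assert rel[sample].idxmax() == expected


class TestShannon:
    def test_uniform_single_and_hand_cases(self):
        assert shannon(np.ones(5)) == pytest.approx(math.log(5))
        assert shannon([3]) == 0.0
        assert shannon([1, 1, 2]) == pytest.approx(1.0397207708399179)


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        table = make_table({"a": [1, 0, 1], "b": [1, 1, 1], "c": [0, 1, 0]})
        dm = bray_curtis(table)
        assert dm["S1", "S3"] == pytest.approx(0.0)  # identical columns
        table2 = make_table({"a": [5, 0], "b": [0, 3]})
        assert bray_curtis(table2)["S1", "S2"] == pytest.approx(1.0)
        table3 = make_table({"a": [1, 0], "b": [1, 1], "c": [0, 1]})
        assert bray_curtis(table3)["S1", "S2"] == pytest.approx(0.5)

    def test_zero_total_sample_is_an_error(self):
        with pytest.raises(AnalysisError):
            bray_curtis(make_table({"a": [1, 0], "b": [2, 0]}))

    def test_bounds_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = {f"a{i}": rng.integers(0, 50, 5) + (i == 0)
                  for i in range(12)}
        table = make_table(counts)
        dm = np.asarray(bray_curtis(table).data)
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)
        assert dm.min() >= 0 and dm.max() <= 1
        shuffled = make_table({k: counts[k] for k in reversed(list(counts))})
        np.testing.assert_allclose(np.asarray(bray_curtis(shuffled).data), dm)


class TestPcoa:
    def test_euclidean_distances_are_reconstructed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        D = squareform(pdist(X))
        res = pcoa(D)
        emb = res.coordinates.to_numpy()
        np.testing.assert_allclose(squareform(pdist(emb)), D, atol=1e-9)

    def test_collinear_points_have_one_informative_axis(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(D)
        assert res.eigenvalues[0] > 1e-6
        assert abs(res.eigenvalues[1]) < 1e-9
        axis1 = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        np.testing.assert_allclose(np.diff(axis1), [1.0, 1.0], atol=1e-9)

    def test_identical_samples_embed_at_origin(self):
        res = pcoa(np.zeros((4, 4)))
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        table, _ = gen_asv_tables(default_community_scenario(seed=2))
        dm = bray_curtis(table)
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm)
        # skbio clamps small negative eigenvalues to zero; we report them,
        # so only the positive part of the spectrum is comparable
        mine = np.sort(ours.eigenvalues[ours.eigenvalues > 1e-12])[::-1]
        other = np.sort(theirs.eigvals.to_numpy())[::-1][:len(mine)]
        np.testing.assert_allclose(mine, other, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(AnalysisError):
            pcoa(np.zeros((2, 2)))


def _two_cluster_dm(rng, n_per=3, spread=1.0, gap=0.0):
    X = np.vstack([rng.normal(0, spread, (n_per, 2)),
                   rng.normal(gap, spread, (n_per, 2))])
    return squareform(pdist(X))


class TestPermanova:
    def test_fully_separated_groups_reach_minimum_p(self):
        rng = np.random.default_rng(0)
        D = _two_cluster_dm(rng, n_per=4, spread=0.01, gap=50.0)
        res = permanova(D, ["a"] * 4 + ["b"] * 4, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.r_squared > 0.99

    def test_single_group_is_an_error(self):
        with pytest.raises(AnalysisError):
            permanova(np.zeros((4, 4)), ["a"] * 4)

    def test_observed_stats_match_independent_double_loop(self):
        rng = np.random.default_rng(2)
        D = _two_cluster_dm(rng, n_per=3, spread=1.0, gap=1.0)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(D, groups, n_permutations=99, seed=0)
        # independent evaluation straight from the definition
        n, k = 6, 2
        ss_total = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in ("a", "b"):
            idx = [i for i, x in enumerate(groups) if x == g]
            ss_within += sum(D[i, j] ** 2 for i in idx for j in idx if i < j) \
                / len(idx)
        f_expected = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
        assert res.pseudo_f == pytest.approx(f_expected, rel=1e-12)
        assert res.r_squared == pytest.approx(
            (ss_total - ss_within) / ss_total, rel=1e-12)

    def test_statistic_matches_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(3)
        D = _two_cluster_dm(rng, n_per=4, spread=1.0, gap=2.0)
        groups = ["a"] * 4 + ["b"] * 4
        ours = permanova(D, groups, n_permutations=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(D), groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"],
                                              rel=1e-9)

    def test_exhaustive_p_matches_explicit_enumeration(self):
        rng = np.random.default_rng(4)
        D = _two_cluster_dm(rng, n_per=3, spread=1.0, gap=2.0)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(D, groups, exhaustive=True)

        def stat(perm):
            ss_total = sum(D[i, j] ** 2 for i in range(6)
                           for j in range(i + 1, 6)) / 6
            ss_within = 0.0
            for g in ("a", "b"):
                idx = [perm[i] for i, x in enumerate(groups) if x == g]
                ss_within += sum(D[i, j] ** 2 for i in idx for j in idx
                                 if i < j) / 3
            return ((ss_total - ss_within) / 1) / (ss_within / 4)

        obs = stat(tuple(range(6)))
        count = sum(stat(p) >= obs - 1e-12
                    for p in itertools.permutations(range(6)))
        assert res.p_value == pytest.approx(count / math.factorial(6))

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        D = _two_cluster_dm(rng)
        groups = ["a"] * 3 + ["b"] * 3
        r1 = permanova(D, groups, n_permutations=199, seed=11)
        r2 = permanova(D, groups, n_permutations=199, seed=11)
        assert r1.p_value == r2.p_value


class TestBetaDispersion:
    def test_mirrored_groups_show_no_dispersion_difference(self):
        X = np.array([[0, 0], [1, 0], [0, 1],
                      [10, 10], [11, 10], [10, 11]], dtype=float)
        D = squareform(pdist(X))
        res = beta_dispersion(D, ["a"] * 3 + ["b"] * 3, n_permutations=199,
                              seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_scale_difference_detected(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(0, 10.0, (6, 2))])
        D = squareform(pdist(X))
        res = beta_dispersion(D, ["tight"] * 6 + ["loose"] * 6,
                              n_permutations=999, seed=0)
        assert res.p_value < 0.05
        assert res.group_means["loose"] > res.group_means["tight"]

    def test_identical_samples_have_zero_dispersion(self):
        res = beta_dispersion(np.zeros((6, 6)), ["a"] * 3 + ["b"] * 3,
                              n_permutations=99, seed=0)
        assert all(v == pytest.approx(0.0) for v in res.group_means.values())

    def test_singleton_group_flagged(self):
        rng = np.random.default_rng(2)
        D = squareform(pdist(rng.normal(size=(5, 2))))
        res = beta_dispersion(D, ["a", "a", "a", "a", "b"],
                              n_permutations=99, seed=0)
        assert any("single sample" in w for w in res.warnings)


class TestTableValidation:
    def test_duplicate_ids_rejected(self):
        frame = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"],
                             columns=["S1", "S2"])
        with pytest.raises(ValueError, match="duplicate ASV"):
            ASVTable(counts=frame, taxonomy=pd.Series({"a": "x"}))

    def test_negative_counts_rejected(self):
        frame = pd.DataFrame([[1, -2]], index=["a"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="non-negative"):
            ASVTable(counts=frame, taxonomy=pd.Series({"a": "x"}))
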