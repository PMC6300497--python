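"""MLG assignment, valley-threshold detection, clone clustering and
genotypic-diversity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apoclone import bruvo, clonal
from apoclone.genotype_io import DistanceMatrix, GenotypeSet, LocusDef

from conftest import make_genotype


def dm_from(ids, pairs):
    n = len(ids)
    vals = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(ids)}
    for (a, b), d in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = d
    return DistanceMatrix(ids, vals)


class TestAssignMlgs:
    def test_zero_distance_pairs_share_mlg(self):
        dm = dm_from(["s1", "s2", "s3"], {("s1", "s2"): 0.0, ("s1", "s3"): 0.4,
                                          ("s2", "s3"): 0.4})
        part = clonal.assign_mlgs(dm)
        assert part.n_groups == 2
        assert part.group_of["s1"] == part.group_of["s2"]

    def test_all_distinct_gives_n_mlgs(self):
        ids = [f"s{i}" for i in range(13)]
        vals = np.full((13, 13), 0.3)
        np.fill_diagonal(vals, 0)
        part = clonal.assign_mlgs(DistanceMatrix(ids, vals))
        assert part.n_groups == 13

    def test_representative_is_smallest_id(self):
        dm = dm_from(["b", "a", "c"], {("b", "a"): 0.0, ("b", "c"): 0.5,
                                       ("a", "c"): 0.5})
        part = clonal.assign_mlgs(dm)
        assert "a" in part.representatives
        assert "b" not in part.representatives


class TestClonalLineages:
    def test_threshold_clustering_hand_case(self):
        dm = dm_from(["A", "B", "C"], {("A", "B"): 0.02, ("A", "C"): 0.5,
                                       ("B", "C"): 0.5})
        part = clonal.assign_clonal_lineages(dm, 0.09)
        assert part.n_groups == 2
        assert part.group_of["A"] == part.group_of["B"]

    def test_zero_threshold_reduces_to_mlgs(self, polyploid_dm):
        a = clonal.assign_clonal_lineages(polyploid_dm, 0.0)
        b = clonal.assign_mlgs(polyploid_dm)
        assert a.group_of == b.group_of

    def test_negative_threshold_rejected(self, polyploid_dm):
        with pytest.raises(ValueError):
            clonal.assign_clonal_lineages(polyploid_dm, -0.1)

    def test_partition_coarsens_with_threshold(self, polyploid_dm):
        prev = None
        for t in (0.0, 0.02, 0.05, 0.1, 0.3, 1.0):
            part = clonal.assign_clonal_lineages(polyploid_dm, t)
            if prev is not None:
                assert part.n_groups <= prev.n_groups
                # coarsening: same group before implies same group after
                for s1 in list(part.group_of)[::7]:
                    for s2 in list(part.group_of)[::11]:
                        if prev.group_of[s1] == prev.group_of[s2]:
                            assert part.group_of[s1] == part.group_of[s2]
            prev = part


class TestHistogramThreshold:
    def test_valley_between_two_modes(self):
        d = np.array([0, 0, 0.01, 0.01, 0.2, 0.22, 0.25])
        hist = clonal.histogram_and_threshold(d, bin_width=0.05)
        assert hist.detected_threshold is not None
        assert 0.05 < hist.detected_threshold < 0.2

    def test_all_zero_distances_no_valley(self):
        with pytest.warns(UserWarning, match="unimodal"):
            hist = clonal.histogram_and_threshold(np.zeros(50), bin_width=0.01)
        assert hist.detected_threshold is None

    def test_counts_include_self_comparisons(self, polyploid_dm):
        hist = clonal.histogram_and_threshold(polyploid_dm)
        n = len(polyploid_dm)
        assert hist.n_comparisons == n * n
        assert hist.counts.sum() == n * n

    def test_counts_without_self(self, polyploid_dm):
        hist = clonal.histogram_and_threshold(polyploid_dm, include_self=False)
        n = len(polyploid_dm)
        assert hist.n_comparisons == n * (n - 1) // 2


class TestSimpson:
    @pytest.mark.parametrize(
        "sizes,expected",
        [([19], 0.0), ([1] * 13, 1.0), ([31, 1], 0.0625), ([2, 2], 2 / 3)],
    )
    def test_unbiased_values(self, sizes, expected):
        assert clonal.simpson_complement(sizes) == pytest.approx(expected)

    def test_biased_variant(self):
        # plug-in lambda = sum (n_i/N)^2
        assert clonal.simpson_complement([2, 2], unbiased=False) == pytest.approx(0.5)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            clonal.simpson_complement([1])

    @given(
        sizes=st.lists(st.integers(1, 20), min_size=1, max_size=8).filter(
            lambda s: sum(s) >= 2
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_count(self, sizes):
        # probability two distinct individuals (without replacement) differ in group
        labels = [i for i, n in enumerate(sizes) for _ in range(n)]
        n = len(labels)
        diff = sum(
            labels[i] != labels[j] for i in range(n) for j in range(i + 1, n)
        )
        expected = diff / (n * (n - 1) / 2)
        assert clonal.simpson_complement(sizes) == pytest.approx(expected)


class TestRichness:
    @pytest.fixture()
    def gset(self):
        panel = [LocusDef("L1"), LocusDef("L2")]
        gts = [
            make_genotype("s1", {"L1": {10, 12}, "L2": {5}}, taxon="tx"),
            make_genotype("s2", {"L1": {10, 14}, "L2": {5, 6}}, taxon="tx"),
            make_genotype("s3", {"L1": {10}, "L2": {9}}, taxon="ty"),
        ]
        return GenotypeSet(panel, gts)

    def test_total_distinct_alleles(self, gset):
        assert clonal.allele_richness(gset, "tx") == 3 + 2
        assert clonal.allele_richness(gset, "ty") == 2

    def test_rarefied_equals_a_at_full_n(self, gset):
        a = clonal.allele_richness(gset, "tx")
        for seed in (0, 1, 99):
            assert clonal.rarefied_richness(gset, "tx", 2, reps=10, seed=seed) == a

    def test_rarefied_at_most_a_and_increases_with_n(self, study):
        _, gs, _, _ = study
        taxon = "torminalis_like"
        a = clonal.allele_richness(gs, taxon)
        means = [
            clonal.rarefied_richness(gs, taxon, n, reps=200, seed=3)
            for n in (5, 13, 25, 33)
        ]
        assert all(m <= a + 1e-9 for m in means)
        assert all(x < y + 1e-9 for x, y in zip(means, means[1:]))
        assert means[-1] == pytest.approx(a)

    def test_oversized_subsample_rejected(self, gset):
        with pytest.raises(ValueError):
            clonal.rarefied_richness(gset, "ty", 5, reps=1, seed=0)


class TestDiversityTable:
    def test_planted_degenerate_rows(self, tiny_panel):
        base = {"L1": {10, 12}, "L2": {15}, "GA": {20}}
        clones = [make_genotype(f"c{i}", base, taxon="clone") for i in range(5)]
        sexual = [
            make_genotype(f"s{i}", {"L1": {10 + i, 20 + i}, "L2": {15 + i}, "GA": {9 + i}},
                          taxon="sex")
            for i in range(4)
        ]
        gs = GenotypeSet(tiny_panel, clones + sexual)
        dm = bruvo.distance_matrix(gs)
        mlg = clonal.assign_mlgs(dm)
        lin = clonal.assign_clonal_lineages(dm, 0.09)
        div = clonal.diversity_table(gs, mlg, lin).set_index("taxon")
        assert div.loc["clone", "Ng"] == 1
        assert div.loc["clone", "simpson_complement"] == 0.0
        assert div.loc["clone", "Nc"] == 1
        assert div.loc["sex", "Ng"] == 4
        assert div.loc["sex", "simpson_complement"] == 1.0

    def test_two_lineage_taxon_counts_nc_2(self, study, polyploid_dm):
        _, gs, _, truth = study
        lin = clonal.assign_clonal_lineages(polyploid_dm, 0.05)
        poly_ids = list(polyploid_dm.ids)
        sub = gs.subset_samples(poly_ids)
        div = clonal.diversity_table(sub, clonal.assign_mlgs(polyploid_dm), lin)
        div = div.set_index("taxon")
        assert div.loc["vexans_like", "Nc"] == 2
        single = [t for t in div.index if t != "vexans_like"]
        assert (div.loc[single, "Nc"] == 1).all()
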