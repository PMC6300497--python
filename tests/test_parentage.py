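"""Parentage scoring: pool construction, per-allele mismatch counting,
pair ranking, and genome-specific contribution ratios."""

import warnings

import pytest

from apoclone import parentage
from apoclone.genotype_io import GenotypeSet, LocusDef
from apoclone.parentage import AllelePool

from conftest import make_genotype


def pool(taxon, alleles):
    return AllelePool(taxon, {k: frozenset(v) for k, v in alleles.items()})


class TestMajorityGenotype:
    @pytest.fixture()
    def gset(self):
        panel = [LocusDef("L1"), LocusDef("L2")]
        major = {"L1": {10, 12}, "L2": {20}}
        minor = {"L1": {10, 13}, "L2": {20}}
        gts = [make_genotype(f"m{i}", major, taxon="apo") for i in range(9)]
        gts.append(make_genotype("v1", minor, taxon="apo"))
        return GenotypeSet(panel, gts)

    def test_modal_mlg_dominant(self, gset):
        g = parentage.majority_genotype(gset, "apo")
        assert g.alleles["L1"] == frozenset({10, 12})

    def test_tie_warns_and_is_deterministic(self):
        panel = [LocusDef("L1")]
        gts = [
            make_genotype("b", {"L1": {10}}, taxon="t"),
            make_genotype("a", {"L1": {11}}, taxon="t"),
        ]
        gs = GenotypeSet(panel, gts)
        with pytest.warns(UserWarning, match="tied"):
            g = parentage.majority_genotype(gs, "t")
        assert g.sample_id == "a"

    def test_low_dominance_warns(self, gset):
        sub = gset.subset_samples(["m0", "v1"])
        with pytest.warns(UserWarning):
            parentage.majority_genotype(sub, "apo")

    def test_empty_taxon_errors(self, gset):
        with pytest.raises(ValueError):
            parentage.majority_genotype(gset, "nope")

    def test_variable_locus_pools_all_variants(self, gset):
        p = parentage.build_pool(gset, "apo", "majority_mlg", variable_loci=("L1",))
        assert p.at("L1") == frozenset({10, 12, 13})
        p2 = parentage.build_pool(gset, "apo", "majority_mlg")
        assert p2.at("L1") == frozenset({10, 12})


class TestMismatchScore:
    def test_covered_target_scores_zero(self):
        t = make_genotype("t", {"L1": {150, 154}})
        assert parentage.pair_mismatch_score(
            t, pool("A", {"L1": {150}}), pool("B", {"L1": {154}}), ["L1"]
        ) == 0

    def test_uncovered_allele_counts_one(self):
        t = make_genotype("t", {"L1": {150, 154, 160}})
        assert parentage.pair_mismatch_score(
            t, pool("A", {"L1": {150}}), pool("B", {"L1": {154}}), ["L1"]
        ) == 1

    def test_per_allele_not_per_locus(self):
        t = make_genotype("t", {"L1": {1, 2, 3, 4}})
        assert parentage.pair_mismatch_score(
            t, pool("A", {"L1": {1}}), pool("B", {"L1": set()}), ["L1"]
        ) == 3

    def test_locus_absent_from_both_pools_counts_all(self):
        t = make_genotype("t", {"L1": {5, 6}})
        with pytest.warns(UserWarning, match="absent from pools"):
            s = parentage.pair_mismatch_score(
                t, pool("A", {}), pool("B", {}), ["L1"]
            )
        assert s == 2

    def test_symmetric_and_monotone_in_pool(self):
        t = make_genotype("t", {"L1": {1, 2}, "L2": {8, 9}})
        pa = pool("A", {"L1": {1}, "L2": {8}})
        pb = pool("B", {"L1": {3}, "L2": {7}})
        s1 = parentage.pair_mismatch_score(t, pa, pb, ["L1", "L2"])
        assert s1 == parentage.pair_mismatch_score(t, pb, pa, ["L1", "L2"])
        bigger = pool("B", {"L1": {2, 3}, "L2": {7, 9}})
        assert parentage.pair_mismatch_score(t, pa, bigger, ["L1", "L2"]) <= s1


class TestRankParentPairs:
    def test_true_pair_ranks_first_on_planted_trio(self):
        # child = union of one allele from each parent per locus
        pa = pool("A", {"L1": {10, 11}, "L2": {20, 21}})
        pb = pool("B", {"L1": {15, 16}, "L2": {25, 26}})
        px = pool("X", {"L1": {40}, "L2": {41}})
        child = make_genotype("c", {"L1": {10, 15}, "L2": {21, 26}})
        tab = parentage.rank_parent_pairs(child, {"A": pa, "B": pb, "X": px},
                                          ["L1", "L2"])
        top = tab.iloc[0]
        assert {top.parent_a, top.parent_b} == {"A", "B"}
        assert top.mismatches == 0
        assert top["rank"] == 1

    def test_ties_share_rank_one(self):
        pa = pool("A", {"L1": {10}})
        pb = pool("B", {"L1": {10}})
        pc = pool("C", {"L1": {99}})
        child = make_genotype("c", {"L1": {10}})
        tab = parentage.rank_parent_pairs(child, {"A": pa, "B": pb, "C": pc}, ["L1"])
        zero = tab[tab.mismatches == 0]
        assert len(zero) == 3  # AB, AC, BC all cover {10}
        assert (zero["rank"] == 1).all()

    def test_self_pairs_opt_in(self):
        pa = pool("A", {"L1": {10, 11}})
        pb = pool("B", {"L1": {99}})
        child = make_genotype("c", {"L1": {10, 11}})
        tab = parentage.rank_parent_pairs(child, {"A": pa, "B": pb}, ["L1"],
                                          allow_self_pairs=True)
        selfed = tab[(tab.parent_a == "A") & (tab.parent_b == "A")]
        assert len(selfed) == 1 and selfed.mismatches.iloc[0] == 0
        tab2 = parentage.rank_parent_pairs(child, {"A": pa, "B": pb}, ["L1"])
        assert not ((tab2.parent_a == tab2.parent_b)).any()


class TestGenomeContribution:
    PANEL = [
        LocusDef("GA", genome_tag="genomeA"),
        LocusDef("GB", genome_tag="genomeB"),
        LocusDef("L1"),
    ]

    def test_triploid_two_one_ratio(self):
        g = make_genotype("t", {"GA": {10, 12}, "GB": {30}, "L1": {5}})
        gc = parentage.genome_specific_contribution(g, self.PANEL)
        assert gc.counts == {"genomeA": 2, "genomeB": 1}
        assert gc.ratio == "2:1"

    def test_tetraploid_even_contribution(self):
        g = make_genotype("t", {"GA": {10, 12}, "GB": {30, 31}})
        gc = parentage.genome_specific_contribution(g, self.PANEL)
        assert gc.ratio == "2:2"

    def test_pure_subgenus_four_zero(self):
        g = make_genotype("t", {"GA": {10, 12, 14, 16}, "GB": set()})
        gc = parentage.genome_specific_contribution(g, self.PANEL)
        assert gc.counts == {"genomeA": 4, "genomeB": 0}
        assert gc.missing == ["GB"]

    def test_untagged_panel_errors(self):
        g = make_genotype("t", {"L1": {5}})
        with pytest.raises(ValueError):
            parentage.genome_specific_contribution(g, [LocusDef("L1")])


class TestEndToEndPools(object):
    def test_synthetic_hybrids_generating_pair_attains_minimum(self, study):
        cfg, gs, _, truth = study
        from apoclone import synth

        core = synth.core_loci(cfg)
        poly = [t for t in gs.taxa()
                if any(g.ploidy > 2 for g in gs.subset_taxa([t]).genotypes)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pools = {
                t: parentage.build_pool(
                    gs, t, "all_samples" if t not in poly else "majority_mlg"
                )
                for t in gs.taxa()
            }
            for taxon, (pa, pb) in truth.parent_pair_of.items():
                if taxon not in poly:  # secondary lineages handled separately
                    continue
                target = parentage.majority_genotype(gs, taxon)
                cand = {k: v for k, v in pools.items() if k != taxon}
                tab = parentage.rank_parent_pairs(target, cand, core)
                hit = tab[
                    ((tab.parent_a == pa) & (tab.parent_b == pb))
                    | ((tab.parent_a == pb) & (tab.parent_b == pa))
                ]
                assert hit.mismatches.iloc[0] == 0
                assert hit["rank"].iloc[0] == 1
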