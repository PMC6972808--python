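"""Ploidy inference, consensus genotypes, clustering, triploid assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daceclone import (
    Biotype,
    ClusteringParams,
    MultilocusGenotype,
    assign_triploids,
    call_survey,
    cluster_lineages,
    consensus_genotype,
    infer_ploidy,
)
from daceclone.lineage_calling import AMBIGUOUS, NEW

LOCI = ("Seat412", "Ca-12", "Rhca-20", "Pho-60", "Pho-1", "Pho-2")


def hyb(ind, site="S1", **overrides):
    alleles = {
        "Seat412": (100, 200),
        "Ca-12": (110, 210),
        "Rhca-20": (120, 220),
        "Pho-60": (130,),
        "Pho-1": (140,),
        "Pho-2": (150,),
    }
    alleles.update(overrides)
    return MultilocusGenotype(ind, site, Biotype.HYB, alleles=alleles)


class TestInferPloidy:
    def test_diploid_pattern(self):
        assert infer_ploidy(hyb("a")) == "2n"

    def test_three_alleles_at_shared_locus(self):
        assert infer_ploidy(hyb("a", **{"Seat412": (100, 104, 200)})) == "3n"

    def test_two_alleles_at_eos_specific_locus(self):
        # eos-specific loci carry a single eos haplome in diploids, so a
        # second size can only be an incorporated (eos) sperm allele
        assert infer_ploidy(hyb("a", **{"Pho-1": (140, 146)})) == "3n"

    def test_all_missing_is_unknown(self):
        g = MultilocusGenotype("a", "S1", Biotype.HYB, alleles={l: None for l in LOCI})
        assert infer_ploidy(g) == "unknown"

    def test_non_hybrid_rejected(self):
        with pytest.raises(ValueError):
            infer_ploidy(MultilocusGenotype("a", "S1", Biotype.EOS, alleles={}))


class TestConsensus:
    def test_identical_members(self):
        members = [hyb("a"), hyb("b"), hyb("c")]
        cons = consensus_genotype(members)
        assert cons.alleles == members[0].alleles

    def test_modal_allele_wins(self):
        members = [hyb(f"m{i}") for i in range(5)] + [hyb("v", **{"Pho-1": (141,)})]
        cons = consensus_genotype(members)
        assert cons.alleles["Pho-1"] == (140,)

    def test_tie_breaks_to_smallest(self):
        members = [hyb("a"), hyb("b", **{"Pho-1": (141,)})]
        cons = consensus_genotype(members)
        assert cons.alleles["Pho-1"] == (140,)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            consensus_genotype([])


class TestClustering:
    def test_identical_genotypes_one_lineage(self):
        genos = [hyb(f"i{k}") for k in range(4)]
        (lineage,) = cluster_lineages(genos)
        assert len(lineage.diploid_members) == 4
        assert lineage.n_variants == 0

    def test_single_step_variant_joins(self):
        genos = [hyb("a"), hyb("b", **{"Pho-1": (141,)}), hyb("c", **{"Pho-2": (151,)})]
        (lineage,) = cluster_lineages(genos)
        assert lineage.n_variants == 2
        assert lineage.consensus.alleles["Pho-1"] == (140,)

    def test_two_steps_at_three_loci_splits(self):
        far = hyb("b", **{"Pho-60": (132,), "Pho-1": (142,), "Pho-2": (152,)})
        assert len(cluster_lineages([hyb("a"), far])) == 2

    def test_single_linkage_chains(self):
        # a-b and b-c are within tolerance; a-c is not -> still one component
        a = hyb("a")
        b = hyb("b", **{"Pho-1": (141,), "Pho-2": (151,)})
        c = hyb("c", **{"Pho-1": (142,), "Pho-2": (152,)})
        assert len(cluster_lineages([a, b, c])) == 1

    def test_unphased_pair_distance(self):
        # swapped order of a both-genomes pair is the same genotype
        a = hyb("a", **{"Seat412": (100, 200)})
        b = hyb("b", **{"Seat412": (200, 100)})
        assert len(cluster_lineages([a, b])) == 1

    def test_mixed_ploidy_rejected(self):
        trip = hyb("t", **{"Seat412": (100, 104, 200)})
        with pytest.raises(ValueError, match="triploid"):
            cluster_lineages([hyb("a"), trip])

    def test_partition_property(self):
        genos = [hyb(f"i{k}") for k in range(3)] + [
            hyb("x", **{"Pho-60": (135,), "Pho-1": (146,), "Pho-2": (157,)})
        ]
        lineages = cluster_lineages(genos)
        members = [m for L in lineages for m in L.diploid_members]
        assert sorted(members) == sorted(g.individual_id for g in genos)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.permutations(list(range(6))), st.randoms(use_true_random=False))
    def test_permutation_and_relabel_invariance(self, order, rnd):
        base = [
            hyb("a"),
            hyb("b", **{"Pho-1": (141,)}),
            hyb("c", **{"Pho-60": (133,), "Pho-1": (144,), "Pho-2": (155,)}),
            hyb("d", **{"Pho-60": (133,), "Pho-1": (144,), "Pho-2": (156,)}),
            hyb("e", site="S2"),
            hyb("f", site="S2", **{"Seat412": (101, 200)}),
        ]
        ref = cluster_lineages(base)
        shuffled = [base[i] for i in order]
        out = cluster_lineages(shuffled)
        key = lambda Ls: sorted(frozenset(L.diploid_members) for L in Ls)
        assert key(out) == key(ref)


class TestTriploidAssignment:
    def _lineage(self):
        (L,) = cluster_lineages([hyb("a"), hyb("b")])
        return L

    def test_eos_sperm_triploid_assigned(self):
        L = self._lineage()
        trip = hyb(
            "t1",
            **{
                "Seat412": (100, 106, 200),
                "Ca-12": (110, 116, 210),
                "Rhca-20": (120, 126, 220),
                "Pho-60": (130, 136),
                "Pho-1": (140, 146),
                "Pho-2": (150, 156),
            },
        )
        (a,) = assign_triploids([trip], [L])
        assert a.assigned_lineage == L.lineage_id
        assert a.sperm_origin == "eos"

    def test_neogaeus_sperm_triploid_assigned(self):
        L = self._lineage()
        # extra allele only at the both-genomes loci, eos-specific unchanged
        trip = hyb(
            "t1",
            **{
                "Seat412": (100, 200, 206),
                "Ca-12": (110, 210, 216),
                "Rhca-20": (120, 220, 226),
            },
        )
        (a,) = assign_triploids([trip], [L])
        assert a.assigned_lineage == L.lineage_id
        assert a.sperm_origin == "neogaeus"

    def test_unmatched_triploid_is_new_lineage(self):
        L = self._lineage()
        trip = hyb(
            "t1",
            **{
                "Seat412": (300, 306, 400),
                "Ca-12": (310, 316, 410),
                "Rhca-20": (320, 326, 420),
                "Pho-60": (330, 336),
                "Pho-1": (340, 346),
                "Pho-2": (350, 356),
            },
        )
        (a,) = assign_triploids([trip], [L])
        assert a.assigned_lineage.startswith(NEW)

    def test_identical_unmatched_triploids_merge(self):
        L = self._lineage()
        mk = lambda ind: hyb(
            ind,
            **{
                "Seat412": (300, 306, 400),
                "Ca-12": (310, 316, 410),
                "Rhca-20": (320, 326, 420),
                "Pho-60": (330, 336),
                "Pho-1": (340, 346),
                "Pho-2": (350, 356),
            },
        )
        a1, a2 = assign_triploids([mk("t1"), mk("t2")], [L])
        assert a1.assigned_lineage == a2.assigned_lineage  # one extra lineage, not two

    def test_equal_match_reported_ambiguous(self):
        # two lineages one step apart at one locus: consensus +- sperm
        # peeling cannot separate them for a triploid built on either
        La = cluster_lineages([hyb("a")])[0]
        Lb = cluster_lineages([hyb("b", **{"Pho-1": (141,)})])[0]
        Lb.lineage_id = "L_other"
        trip = hyb("t", **{"Pho-1": (140, 141)})
        (a,) = assign_triploids([trip], [La, Lb])
        assert a.assigned_lineage == AMBIGUOUS


def test_call_survey_end_to_end():
    genos = [hyb("a"), hyb("b"), hyb("c", **{"Pho-1": (141,)})]
    trip = hyb(
        "t",
        **{
            "Seat412": (100, 106, 200),
            "Ca-12": (110, 116, 210),
            "Rhca-20": (120, 126, 220),
            "Pho-60": (130, 136),
            "Pho-1": (140, 146),
            "Pho-2": (150, 156),
        },
    )
    lineages, assignments = call_survey(genos + [trip])
    (L,) = lineages
    assert set(L.diploid_members) == {"a", "b", "c"}
    assert L.triploid_members == ("t",)
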