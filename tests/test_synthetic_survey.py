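"""Synthetic survey generator: founders, mutation, end-to-end consistency."""

import numpy as np
import pytest

from daceclone import (
    Biotype,
    FoundingEvent,
    SyntheticConfig,
    SyntheticSite,
    call_survey,
    classify_lineages,
    cluster_lineages,
    default_allele_pools,
    generate_founder_lineages,
    generate_survey,
    mutate_genotype,
    pool_sites,
    read_genotype_table,
    write_genotype_table,
)
from daceclone.survey_io import BOTH_GENOME_LOCI, EOS_SPECIFIC_LOCI
from daceclone.synthetic_survey import ALL_LOCI


def one_site(site_id="SYN-1", network="SJ", age=100, n_founders=5, deme=500, **kw):
    return SyntheticSite(
        site_id, 46.0, -70.0, network, "130-140", deme_size=deme,
        events=(FoundingEvent(age, n_founders),), **kw
    )


class TestFounders:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.pools = default_allele_pools()

    def test_haplome_structure(self):
        (f,) = generate_founder_lineages(FoundingEvent(0, 1), self.pools, self.rng)
        # 9 allele slots: pairs at both-genomes loci, singletons at eos-specific
        slots = sum(len(f.alleles[l]) for l in ALL_LOCI)
        assert slots == 9
        for locus in EOS_SPECIFIC_LOCI:
            assert f.alleles[locus][0] in self.pools["eos"][locus]
        for locus in BOTH_GENOME_LOCI:
            lo, hi = f.alleles[locus]
            assert lo in self.pools["eos"][locus] and hi in self.pools["neogaeus"][locus]

    def test_pairwise_separation_exceeds_clustering_tolerance(self):
        founders = generate_founder_lineages(FoundingEvent(0, 6), self.pools, self.rng)
        lineages = cluster_lineages(founders)
        assert len(lineages) == 6  # every founder its own lineage

    def test_impossible_separation_errors(self):
        tiny = {
            "eos": {l: (100,) for l in ALL_LOCI},
            "neogaeus": {l: (200,) for l in BOTH_GENOME_LOCI},
        }
        with pytest.raises(ValueError, match="pools too small"):
            generate_founder_lineages(FoundingEvent(0, 2), tiny, self.rng)


class TestMutation:
    def setup_method(self):
        rng = np.random.default_rng(1)
        (self.founder,) = generate_founder_lineages(
            FoundingEvent(0, 1), default_allele_pools(), rng
        )

    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(2)
        m = mutate_genotype(self.founder, 0.0, 500, rng)
        assert m.alleles == self.founder.alleles

    def test_forced_mutation_moves_one_step(self):
        rng = np.random.default_rng(3)
        m = mutate_genotype(self.founder, 1.0, 1, rng)
        for locus in ALL_LOCI:
            before, after = self.founder.alleles[locus], m.alleles[locus]
            moved = set(after) - set(before)
            assert all(
                min(abs(a - b) for b in before) <= 1 for a in moved
            )

    def test_boundary_reflects_upward(self):
        from daceclone import MultilocusGenotype

        g = MultilocusGenotype("x", "s", Biotype.HYB, alleles={"Pho-1": (1,)})
        rng = np.random.default_rng(4)
        for _ in range(50):
            m = mutate_genotype(g, 1.0, 1, rng)
            assert m.alleles["Pho-1"][0] >= 1

    def test_expected_mutated_loci(self):
        # 6 loci x (1 - (1-mu)^g) ~ 0.57 at mu=5e-4, g=200
        rng = np.random.default_rng(5)
        diffs = [
            sum(
                1
                for l in ALL_LOCI
                if mutate_genotype(self.founder, 5e-4, 200, rng).alleles[l]
                != self.founder.alleles[l]
            )
            for _ in range(400)
        ]
        # full-genotype comparison counts each mutated locus once
        mean = np.mean([
            sum(1 for l in ALL_LOCI if m.alleles[l] != self.founder.alleles[l])
            for m in (mutate_genotype(self.founder, 5e-4, 200, rng) for _ in range(600))
        ])
        assert mean == pytest.approx(6 * (1 - (1 - 5e-4) ** 200), abs=0.12)


class TestGenerateSurvey:
    def test_exact_recovery_without_noise(self):
        cfg = SyntheticConfig(
            sites=(one_site(age=0),), mutation_rate=0.0, triploid_fraction=0.0,
            sample_n=24, seed=7,
        )
        genotypes, sites, truth = generate_survey(cfg)
        assert len(genotypes) == 24
        lineages, _ = call_survey(genotypes)
        assert len(lineages) == len({r["lineage"] for r in truth.individuals})
        # with age 0 every sampled genotype is exactly a founder genotype
        assert all(t["true_ploidy"] == "2n" for t in truth.individuals)

    def test_truth_covers_every_sample(self):
        cfg = SyntheticConfig(sites=(one_site(),), seed=8)
        genotypes, _, truth = generate_survey(cfg)
        ids = {r["individual_id"] for r in truth.individuals}
        assert ids == {g.individual_id for g in genotypes}

    def test_old_event_keeps_few_lineages(self):
        site = one_site(age=10_000, n_founders=50)
        cfg = SyntheticConfig(sites=(site,), seed=9)
        _, _, truth = generate_survey(cfg)
        assert 1 <= truth.site_lineage_counts["SYN-1"] <= 3

    def test_variants_stay_near_founder_at_low_mutation_load(self):
        # mu * generations = 0.05 per locus: mutated loci moved by one step
        cfg = SyntheticConfig(
            sites=(one_site(age=100),), mutation_rate=5e-4, triploid_fraction=0.0,
            sample_n=24, seed=10,
        )
        genotypes, _, truth = generate_survey(cfg)
        label_of = {r["individual_id"]: r["lineage"] for r in truth.individuals}
        lineages, _ = call_survey(genotypes)
        # every called lineage is dominated by one true label
        for L in lineages:
            labels = {label_of[m] for m in L.diploid_members}
            assert len(labels) == 1

    def test_triploid_truth_and_inference_agree(self):
        site = one_site(n_eos=10, n_neo=0)
        cfg = SyntheticConfig(sites=(site,), triploid_fraction=0.5, seed=11)
        genotypes, _, truth = generate_survey(cfg)
        truth_3n = {r["individual_id"] for r in truth.individuals if r["true_ploidy"] == "3n"}
        from daceclone import infer_ploidy

        called_3n = {g.individual_id for g in genotypes if infer_ploidy(g) == "3n"}
        # every detected triploid is truly triploid; eos sperm in an eos-only
        # site is nearly always visible at the eos-specific loci
        assert called_3n <= truth_3n
        assert len(called_3n) >= 0.7 * len(truth_3n)

    def test_round_trip_through_survey_io(self, tmp_path):
        cfg = SyntheticConfig(sites=(one_site(),), seed=12)
        genotypes, _, _ = generate_survey(cfg)
        path = tmp_path / "g.tsv"
        write_genotype_table(genotypes, path)
        back = read_genotype_table(path)
        assert [g.alleles for g in back] == [g.alleles for g in genotypes]

    def test_reproducible_given_seed(self):
        cfg = SyntheticConfig(sites=(one_site(),), seed=13)
        a, _, _ = generate_survey(cfg)
        b, _, _ = generate_survey(cfg)
        assert [g.alleles for g in a] == [g.alleles for g in b]

    def test_oversampling_rejected(self):
        cfg = SyntheticConfig(sites=(one_site(deme=10),), sample_n=24, seed=14)
        with pytest.raises(ValueError, match="sample_n"):
            generate_survey(cfg)


def test_shared_founder_classified_widespread():
    """A lineage seeded in two networks must classify as widespread."""
    rng = np.random.default_rng(15)
    pools = default_allele_pools()
    shared = generate_founder_lineages(FoundingEvent(50, 3), pools, rng)
    site_a = SyntheticSite(
        "SJ-90", 46.0, -70.0, "SJ", "130-140", deme_size=200,
        events=(FoundingEvent(50, 3),), founders=(tuple(shared),),
    )
    site_b = SyntheticSite(
        "OU-90", 47.1, -69.8, "OU", "130-140", deme_size=200,
        events=(FoundingEvent(50, 3),), founders=(tuple(shared),),
    )
    cfg = SyntheticConfig(
        sites=(site_a, site_b), mutation_rate=0.0, triploid_fraction=0.0,
        sample_n=20, seed=16,
    )
    genotypes, sites, truth = generate_survey(cfg)
    lineages, _ = call_survey(genotypes)
    grouping = pool_sites(sites, {L.lineage_id: set(L.sites) for L in lineages})
    ranges = classify_lineages(lineages, grouping, sites)
    spanning = [r for r in ranges if len(r.networks) == 2]
    assert spanning, "shared founders should be sampled in both networks"
    assert all(r.classification == "widespread" and r.cross_network for r in spanning)
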