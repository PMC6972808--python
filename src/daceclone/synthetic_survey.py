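"""Synthetic latitudinal surveys of clonal hybrids, with ground truth.

Each synthetic site hosts one or more founding hybridization events at
specified times before present.  Every founder is a distinct diploid hybrid
— one *C. eos* haplome (six loci) plus one *C. neogaeus* haplome (three
loci), drawn from disjoint per-species allele pools — whose descendants
drift as clonal labels in a single-deme Wright-Fisher population until
sampling.  Sampled individuals receive realized genotypes by replaying
stepwise microsatellite mutation along their lineage's survival path, and a
configurable fraction become triploid by incorporation of a sperm haplome
from the locally available parental species.

The emitted genotype/site tables round-trip through :mod:`.survey_io`, and
the ground truth (true lineage labels, events, ploidy, per-site lineage
counts at sampling time) supports end-to-end recovery tests of the lineage
caller and the private/widespread classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .survey_io import (
    BOTH_GENOME_LOCI,
    EOS_SPECIFIC_LOCI,
    PANEL_BY_NAME,
    Biotype,
    MultilocusGenotype,
    SiteRecord,
)
__all__ = [
    "SyntheticSite",
    "FoundingEvent",
    "SyntheticConfig",
    "GroundTruth",
    "default_allele_pools",
    "generate_founder_lineages",
    "mutate_genotype",
    "generate_survey",
]

ALL_LOCI = tuple(PANEL_BY_NAME)


def default_allele_pools() -> dict[str, dict[str, tuple[int, ...]]]:
    """Per-species, per-locus allele pools (fragment-size units).

    Pools are disjoint between species so the two haplomes stay
    identifiable at the both-genomes loci, and wide enough that founders
    can be made mutually distinct; real allele distributions overlap more.
    """
    eos = {locus: tuple(range(100, 140, 2)) for locus in ALL_LOCI}
    neo = {locus: tuple(range(200, 240, 2)) for locus in BOTH_GENOME_LOCI}
    return {"eos": eos, "neogaeus": neo}


@dataclass(frozen=True)
class FoundingEvent:
    """A hybridization pulse: ``n_founding_lineages`` eggs fertilised
    ``time_before_present`` generations ago."""

    time_before_present: int
    n_founding_lineages: int

    def __post_init__(self) -> None:
        if self.n_founding_lineages < 1:
            raise ValueError("a founding event needs at least one lineage")
        if self.time_before_present < 0:
            raise ValueError("event age cannot be negative")


@dataclass(frozen=True)
class SyntheticSite:
    site_id: str
    latitude: float
    longitude: float
    network: str
    lgs_category: str
    deme_size: int = 500
    n_eos: int = 10
    n_neo: int = 0
    events: tuple[FoundingEvent, ...] = ()
    # Optional pre-built founders per event (e.g. to seed one lineage in
    # several sites/networks); None -> drawn from the allele pools.
    founders: tuple[tuple[MultilocusGenotype, ...] | None, ...] | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    sites: tuple[SyntheticSite, ...]
    mutation_rate: float = 5e-4  # per locus per generation
    triploid_fraction: float = 0.2
    sample_n: int = 24
    seed: int = 0
    min_founder_separation: int = 3  # loci at which founders must differ

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation rate must be in [0, 1]")
        if not (0.0 <= self.triploid_fraction <= 1.0):
            raise ValueError("triploid fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """True labels behind a generated survey."""

    individuals: list[dict]  # individual_id, site_id, lineage, event, true_ploidy
    site_lineage_counts: dict[str, int]  # distinct lineages alive at sampling

    def label_of(self, individual_id: str) -> str:
        for rec in self.individuals:
            if rec["individual_id"] == individual_id:
                return rec["lineage"]
        raise KeyError(individual_id)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def _founder_separation(a: MultilocusGenotype, b: MultilocusGenotype) -> int:
    return sum(1 for locus in ALL_LOCI if a.alleles[locus] != b.alleles[locus])


def generate_founder_lineages(
    event: FoundingEvent,
    allele_pools: dict[str, dict[str, tuple[int, ...]]],
    rng: np.random.Generator,
    min_separation: int = 3,
    max_tries: int = 2_000,
) -> list[MultilocusGenotype]:
    """Draw pairwise-distinct founding hybrid genotypes for one event.

    Each founder carries one eos haplome (an allele at all six loci) and
    one neogaeus haplome (an allele at the three both-genomes loci); the
    eos-specific loci therefore carry only eos-pool alleles.  Rejection
    sampling enforces pairwise differences at ``min_separation`` or more
    loci so that lineage calling is well-posed at its default tolerance.
    """
    eos_pool = allele_pools["eos"]
    neo_pool = allele_pools["neogaeus"]
    founders: list[MultilocusGenotype] = []
    tries = 0
    while len(founders) < event.n_founding_lineages:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "allele pools too small to draw "
                f"{event.n_founding_lineages} founders {min_separation}+ loci apart"
            )
        alleles: dict[str, tuple[int, ...] | None] = {}
        for locus in BOTH_GENOME_LOCI:
            pair = (int(rng.choice(eos_pool[locus])), int(rng.choice(neo_pool[locus])))
            alleles[locus] = tuple(sorted(pair))
        for locus in EOS_SPECIFIC_LOCI:
            alleles[locus] = (int(rng.choice(eos_pool[locus])),)
        cand = MultilocusGenotype(
            individual_id=f"founder{len(founders)}",
            site_id="-",
            biotype=Biotype.HYB,
            ploidy="2n",
            alleles=alleles,
        )
        if all(_founder_separation(cand, f) >= min_separation for f in founders):
            founders.append(cand)
    return founders


# ---------------------------------------------------------------------------
# Stepwise mutation
# ---------------------------------------------------------------------------


def mutate_genotype(
    g: MultilocusGenotype,
    mutation_rate: float,
    generations: int,
    rng: np.random.Generator,
) -> MultilocusGenotype:
    """Replay stepwise mutation over ``generations`` along one clonal path.

    Per locus and generation, with probability ``mutation_rate`` one
    uniformly chosen allele of that locus moves one repeat unit up or down
    (strict single-step model); a step that would leave the positive allele
    domain is reflected upward instead.
    """
    if mutation_rate * generations >= 1.0:
        warnings.warn(
            "mutation_rate * generations >= 1: more than one expected mutation per locus",
            stacklevel=2,
        )
    alleles: dict[str, tuple[int, ...] | None] = {}
    for locus in ALL_LOCI:
        obs = g.alleles.get(locus)
        if obs is None:
            alleles[locus] = None
            continue
        slots = list(obs)
        n_events = int(rng.binomial(generations, mutation_rate))
        for _ in range(n_events):
            i = int(rng.integers(len(slots)))
            step = 1 if rng.random() < 0.5 else -1
            if slots[i] + step <= 0:
                step = 1
            slots[i] += step
        alleles[locus] = tuple(sorted(set(slots)))
    return MultilocusGenotype(
        individual_id=g.individual_id,
        site_id=g.site_id,
        biotype=g.biotype,
        ploidy=g.ploidy,
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------


def _sperm_haplome(
    origin: str,
    allele_pools: dict[str, dict[str, tuple[int, ...]]],
    rng: np.random.Generator,
) -> dict[str, int]:
    pool = allele_pools[origin]
    loci = ALL_LOCI if origin == "eos" else BOTH_GENOME_LOCI
    return {locus: int(rng.choice(pool[locus])) for locus in loci}


class _SimulatedDeme:
    """One founding event's deme: Wright-Fisher genealogy + founder labels.

    Each generation every individual picks its parent uniformly at random
    (the individual-level equivalent of multinomial Wright-Fisher used in
    :mod:`.drift_sim`).  Keeping the full parent matrix lets sampled
    individuals inherit mutations placed on the true genealogy, so clone-
    mates share the mutations of their common ancestry instead of
    accumulating independent full-length mutational paths.
    """

    def __init__(self, n_founders: int, deme_size: int, generations: int, rng) -> None:
        self.generations = generations
        self.deme_size = deme_size
        self.init_labels = rng.integers(0, n_founders, size=deme_size)
        self.parents = rng.integers(
            0, deme_size, size=(generations, deme_size), dtype=np.int32
        )
        labels = self.init_labels
        for g in range(generations):
            labels = labels[self.parents[g]]
        self.final_labels = labels
        self._branch_events: dict[tuple[int, int], tuple] = {}

    def alive_founders(self) -> np.ndarray:
        return np.unique(self.final_labels)

    def ancestry(self, idx: int) -> list[tuple[int, int]]:
        """Path of (generation, individual) nodes from the founder to ``idx``."""
        path = [(self.generations, idx)]
        for g in range(self.generations - 1, -1, -1):
            idx = int(self.parents[g][idx])
            path.append((g, idx))
        path.reverse()
        return path

    def mutations_along(
        self, idx: int, mutation_rate: float, rng
    ) -> list[tuple[str, int, int]]:
        """(locus, slot, direction) events on the branch path to ``idx``.

        Events are drawn once per genealogy node and cached, so individuals
        sharing ancestry share the mutations of the shared branches.
        """
        events: list[tuple[str, int, int]] = []
        for node in self.ancestry(idx)[1:]:  # root node carries no branch
            if node not in self._branch_events:
                drawn = []
                for locus in ALL_LOCI:
                    if rng.random() < mutation_rate:
                        arity = PANEL_BY_NAME[locus].n_slots_diploid
                        slot = int(rng.integers(arity))
                        direction = 1 if rng.random() < 0.5 else -1
                        drawn.append((locus, slot, direction))
                self._branch_events[node] = tuple(drawn)
            events.extend(self._branch_events[node])
        return events


def _apply_mutations(
    founder: MultilocusGenotype, events: list[tuple[str, int, int]]
) -> dict[str, tuple[int, ...] | None]:
    slots: dict[str, list[int]] = {}
    for locus in ALL_LOCI:
        obs = founder.alleles.get(locus)
        if obs is None:
            continue
        arity = PANEL_BY_NAME[locus].n_slots_diploid
        slots[locus] = list(obs) if len(obs) == arity else [obs[0]] * arity
    for locus, slot, direction in events:
        if locus not in slots:
            continue
        step = direction if slots[locus][slot] + direction > 0 else 1
        slots[locus][slot] += step
    out: dict[str, tuple[int, ...] | None] = {}
    for locus in ALL_LOCI:
        out[locus] = tuple(sorted(set(slots[locus]))) if locus in slots else None
    return out


def generate_survey(
    cfg: SyntheticConfig,
    allele_pools: dict[str, dict[str, tuple[int, ...]]] | None = None,
) -> tuple[list[MultilocusGenotype], list[SiteRecord], GroundTruth]:
    """Generate a full synthetic survey with ground truth.

    Per site and founding event, clonal drift runs as a single-deme
    Wright-Fisher population from the event's founders for its age, with
    the genealogy retained; sampled individuals get realized genotypes by
    placing stepwise mutations on the branches of that genealogy (labels
    are conserved by drift, so only sampled paths need mutations, and
    clone-mates share the mutations of their common ancestors).  A
    ``triploid_fraction`` of sampled hybrids incorporates a sperm haplome
    whose species of origin follows the local parental abundances.
    """
    allele_pools = allele_pools or default_allele_pools()
    rng = np.random.default_rng(cfg.seed)
    genotypes: list[MultilocusGenotype] = []
    sites: list[SiteRecord] = []
    truth_rows: list[dict] = []
    site_counts: dict[str, int] = {}

    for site in cfg.sites:
        if not site.events:
            raise ValueError(f"site {site.site_id} has no founding events")
        if cfg.sample_n > site.deme_size * len(site.events):
            raise ValueError(f"sample_n exceeds the population at {site.site_id}")
        demes: list[_SimulatedDeme] = []
        founders_by_event: list[list[MultilocusGenotype]] = []
        for e_idx, event in enumerate(site.events):
            preset = site.founders[e_idx] if site.founders else None
            founders = (
                list(preset)
                if preset is not None
                else generate_founder_lineages(
                    event, allele_pools, rng, cfg.min_founder_separation
                )
            )
            founders_by_event.append(founders)
            demes.append(
                _SimulatedDeme(len(founders), site.deme_size, event.time_before_present, rng)
            )
        site_counts[site.site_id] = sum(len(d.alive_founders()) for d in demes)

        total = site.deme_size * len(demes)
        n = min(cfg.sample_n, total)
        picked = rng.choice(total, size=n, replace=False)
        eos_share = (
            site.n_eos / (site.n_eos + site.n_neo) if (site.n_eos + site.n_neo) > 0 else 1.0
        )
        for k, flat_idx in enumerate(sorted(int(i) for i in picked), start=1):
            e_idx, idx = divmod(flat_idx, site.deme_size)
            deme = demes[e_idx]
            f_idx = int(deme.final_labels[idx])
            founder = founders_by_event[e_idx][f_idx]
            label = f"{site.site_id}:e{e_idx}:f{f_idx}"
            ind_id = f"{site.site_id}-h{k:03d}"
            alleles = _apply_mutations(
                founder, deme.mutations_along(idx, cfg.mutation_rate, rng)
            )
            true_ploidy = "2n"
            if rng.random() < cfg.triploid_fraction:
                true_ploidy = "3n"
                origin = "eos" if rng.random() < eos_share else "neogaeus"
                for locus, allele in _sperm_haplome(origin, allele_pools, rng).items():
                    obs = alleles.get(locus)
                    alleles[locus] = tuple(sorted(({allele} if obs is None else set(obs) | {allele})))
            genotypes.append(
                MultilocusGenotype(
                    individual_id=ind_id,
                    site_id=site.site_id,
                    biotype=Biotype.HYB,
                    ploidy="unknown",  # ploidy is an inference target
                    alleles=alleles,
                )
            )
            truth_rows.append(
                {
                    "individual_id": ind_id,
                    "site_id": site.site_id,
                    "lineage": label,
                    "event": f"{site.site_id}:e{e_idx}",
                    "true_ploidy": true_ploidy,
                }
            )
        sites.append(
            SiteRecord(
                site_id=site.site_id,
                latitude=site.latitude,
                longitude=site.longitude,
                network=site.network,
                lgs_category=site.lgs_category,
                n_eos=site.n_eos,
                n_hyb=n,
                n_neo=site.n_neo,
            )
        )
    return genotypes, sites, GroundTruth(individuals=truth_rows, site_lineage_counts=site_counts)
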