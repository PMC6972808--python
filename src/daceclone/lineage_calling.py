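"""Calling clonal lineages from hybrid multilocus genotypes.

Clonally reproducing hybrids inherit their multilocus genotype unchanged
except for occasional stepwise microsatellite mutations, so members of one
lineage (descendants of a single fertilised egg) differ at most by a
single-step mutation at one or a few loci.  Lineages are therefore called
as single-linkage connected components of the step-distance graph, each
summarised by a consensus genotype (the invariant allele where members
agree, the modal allele where they vary).

Triploids arise when a sperm genome is incorporated into a hybrid egg; they
display a lineage's consensus genotype plus one extra haplome and are
assigned back to the lineage whose consensus remains after peeling off a
sperm haplome consistent with a single genome of origin.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .survey_io import (
    BOTH_GENOME_LOCI,
    DEFAULT_PANEL,
    EOS_SPECIFIC_LOCI,
    Biotype,
    MultilocusGenotype,
    PANEL_BY_NAME,
)

__all__ = [
    "ClusteringParams",
    "Lineage",
    "TriploidAssignment",
    "infer_ploidy",
    "consensus_genotype",
    "cluster_lineages",
    "assign_triploids",
    "call_survey",
]

logger = logging.getLogger(__name__)

NEW = "NEW"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ClusteringParams:
    """Tolerance for within-lineage microsatellite variation.

    ``max_step_per_locus`` is the largest allele-size difference (in
    mutational steps) tolerated at a variable locus; ``max_variable_loci``
    the number of loci allowed to vary.  Defaults operationalise "a
    single-step mutation at one or a few loci".
    """

    max_step_per_locus: int = 1
    max_variable_loci: int = 2
    tie_break: str = "smallest-allele"

    def __post_init__(self) -> None:
        if self.max_step_per_locus < 1 or self.max_variable_loci < 1:
            raise ValueError("clustering tolerances must be >= 1")


@dataclass
class Lineage:
    lineage_id: str
    consensus: MultilocusGenotype
    diploid_members: tuple[str, ...]
    triploid_members: tuple[str, ...] = ()
    n_variants: int = 0
    sites: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TriploidAssignment:
    triploid_id: str
    assigned_lineage: str  # lineage_id, "NEW:<k>", or AMBIGUOUS
    sperm_origin: str  # "eos" | "neogaeus" | "ambiguous"
    site_id: str


# ---------------------------------------------------------------------------
# Ploidy inference
# ---------------------------------------------------------------------------


def infer_ploidy(g: MultilocusGenotype) -> str:
    """Classify a hybrid genotype as diploid-compatible or triploid.

    A hybrid is triploid when any both-genomes locus shows three distinct
    alleles or any eos-specific locus shows two: the extra size can only be
    an incorporated sperm haplome.  Otherwise "2n" (strictly
    "2n-compatible": a dosage-masked triploid whose sperm allele matches an
    existing size cannot be detected from fragment sizes alone).
    """
    if g.biotype != Biotype.HYB:
        raise ValueError(f"{g.individual_id}: ploidy inference applies to hybrids")
    observed = [obs for obs in g.alleles.values() if obs is not None]
    if not observed:
        return "unknown"
    for locus in BOTH_GENOME_LOCI:
        obs = g.alleles.get(locus)
        if obs is not None and len(obs) >= 3:
            return "3n"
    for locus in EOS_SPECIFIC_LOCI:
        obs = g.alleles.get(locus)
        if obs is not None and len(obs) >= 2:
            return "3n"
    return "2n"


# ---------------------------------------------------------------------------
# Step distances
# ---------------------------------------------------------------------------


def _as_pair(obs: tuple[int, ...]) -> tuple[int, int]:
    # A single observed size at a both-genomes locus is read as two co-
    # migrating alleles (the two haplomes are not phased).
    if len(obs) == 1:
        return (obs[0], obs[0])
    return (obs[0], obs[1])


def _locus_distance(locus: str, a: tuple[int, ...] | None, b: tuple[int, ...] | None) -> int | None:
    """Step distance at one locus between two diploid genotypes.

    Both-genomes loci carry an unordered allele pair; the distance is the
    better of the two pairings (haplomes are unphased).  ``None`` when
    either side is missing (the locus then carries no information).
    """
    if a is None or b is None:
        return None
    if PANEL_BY_NAME[locus].specificity == "eos-specific":
        return abs(a[0] - b[0])
    a1, a2 = _as_pair(a)
    b1, b2 = _as_pair(b)
    return min(
        max(abs(a1 - b1), abs(a2 - b2)),
        max(abs(a1 - b2), abs(a2 - b1)),
    )


def _within_tolerance(
    ga: MultilocusGenotype, gb: MultilocusGenotype, params: ClusteringParams
) -> bool:
    n_variable = 0
    for locus in PANEL_BY_NAME:
        d = _locus_distance(locus, ga.alleles.get(locus), gb.alleles.get(locus))
        if d is None or d == 0:
            continue
        if d > params.max_step_per_locus:
            return False
        n_variable += 1
        if n_variable > params.max_variable_loci:
            return False
    return True


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _modal(values: list[int], tie_break: str, context: str) -> int:
    counts = Counter(values)
    top = max(counts.values())
    modes = sorted(v for v, c in counts.items() if c == top)
    if len(modes) > 1:
        logger.info("consensus tie at %s among %s; taking smallest", context, modes)
        if tie_break != "smallest-allele":
            raise ValueError(f"unknown tie_break {tie_break!r}")
    return modes[0]


def consensus_genotype(
    members: list[MultilocusGenotype], params: ClusteringParams | None = None
) -> MultilocusGenotype:
    """Consensus of a set of diploid hybrid genotypes.

    Per locus (and per unphased haplome slot at both-genomes loci): the
    shared allele where members are invariant, otherwise the modal allele;
    ties break to the smallest allele, logged.
    """
    if not members:
        raise ValueError("consensus of an empty member list")
    params = params or ClusteringParams()
    alleles: dict[str, tuple[int, ...] | None] = {}
    for locus in PANEL_BY_NAME:
        observed = [m.alleles.get(locus) for m in members if m.alleles.get(locus) is not None]
        if not observed:
            alleles[locus] = None
            continue
        if PANEL_BY_NAME[locus].specificity == "eos-specific":
            alleles[locus] = (_modal([o[0] for o in observed], params.tie_break, locus),)
        else:
            pairs = [_as_pair(o) for o in observed]
            lo = _modal([p[0] for p in pairs], params.tie_break, f"{locus}[lo]")
            hi = _modal([p[1] for p in pairs], params.tie_break, f"{locus}[hi]")
            alleles[locus] = tuple(sorted({lo, hi}))
    return MultilocusGenotype(
        individual_id="consensus",
        site_id=min(m.site_id for m in members),
        biotype=Biotype.HYB,
        ploidy="2n",
        alleles=alleles,
    )


def _consensus_key(g: MultilocusGenotype) -> tuple:
    return tuple(g.alleles.get(l.name) or () for l in DEFAULT_PANEL)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_lineages(
    genotypes: list[MultilocusGenotype], params: ClusteringParams | None = None
) -> list[Lineage]:
    """Group diploid hybrid genotypes into lineages.

    Single-linkage connected components of the graph joining genotypes
    whose allele distance is at most ``max_step_per_locus`` at no more than
    ``max_variable_loci`` loci (identical elsewhere).  Output order is
    deterministic: by earliest site then consensus genotype.
    """
    params = params or ClusteringParams()
    for g in genotypes:
        if g.biotype != Biotype.HYB:
            raise ValueError(f"{g.individual_id}: lineage calling applies to hybrids")
        ploidy = g.ploidy if g.ploidy != "unknown" else infer_ploidy(g)
        if ploidy == "3n":
            raise ValueError(
                f"{g.individual_id} is triploid; cluster diploids first, then assign triploids"
            )
    graph = nx.Graph()
    graph.add_nodes_from(range(len(genotypes)))
    # Exact duplicates are connected through their first occurrence so the
    # pairwise pass is over distinct genotypes only.
    by_key: dict[tuple, list[int]] = {}
    for i, g in enumerate(genotypes):
        by_key.setdefault(_consensus_key(g), []).append(i)
    reps = [idxs[0] for idxs in by_key.values()]
    for idxs in by_key.values():
        for j in idxs[1:]:
            graph.add_edge(idxs[0], j)
    for a_pos, i in enumerate(reps):
        for j in reps[a_pos + 1 :]:
            if _within_tolerance(genotypes[i], genotypes[j], params):
                graph.add_edge(i, j)
    lineages: list[Lineage] = []
    for component in nx.connected_components(graph):
        members = [genotypes[i] for i in sorted(component)]
        cons = consensus_genotype(members, params)
        n_var = sum(
            1
            for m in members
            if any(
                (d := _locus_distance(l, m.alleles.get(l), cons.alleles.get(l))) not in (None, 0)
                for l in PANEL_BY_NAME
            )
        )
        lineages.append(
            Lineage(
                lineage_id="",
                consensus=cons,
                diploid_members=tuple(m.individual_id for m in members),
                n_variants=n_var,
                sites=frozenset(m.site_id for m in members),
            )
        )
    lineages.sort(key=lambda L: (min(L.sites), _consensus_key(L.consensus)))
    width = max(3, len(str(len(lineages))))
    for k, L in enumerate(lineages, start=1):
        L.lineage_id = f"L{k:0{width}d}"
    return lineages


# ---------------------------------------------------------------------------
# Triploid assignment
# ---------------------------------------------------------------------------


def _locus_reductions(
    locus: str, obs: tuple[int, ...], sperm_here: bool
) -> list[tuple[int, ...]]:
    """Candidate diploid allele sets after peeling one sperm allele.

    When the sperm genome amplifies at this locus, the sperm allele is
    either one of the observed sizes (removed) or dosage-masked behind an
    existing size (observation kept).  Reductions that still exceed the
    diploid arity are discarded.
    """
    arity = PANEL_BY_NAME[locus].n_slots_diploid
    candidates: set[tuple[int, ...]] = set()
    if sperm_here:
        if len(obs) <= arity:
            candidates.add(obs)  # sperm allele masked behind an existing size
        for drop in set(obs):
            reduced = tuple(a for a in obs if a != drop) + tuple(
                a for a in obs if a == drop
            )[1:]
            reduced = tuple(sorted(reduced))
            if 1 <= len(reduced) <= arity:
                candidates.add(reduced)
    else:
        if len(obs) <= arity:
            candidates.add(obs)
    return sorted(candidates)


def _matches_consensus(
    trip: MultilocusGenotype,
    consensus: MultilocusGenotype,
    origin: str,
    params: ClusteringParams,
) -> bool:
    """Does removing one ``origin``-derived allele per locus leave ``consensus``?

    An eos sperm haplome amplifies at all six loci; a neogaeus one only at
    the both-genomes loci.  The residual diploid genotype must match the
    consensus under the same step tolerance used for clustering.
    """
    n_variable = 0
    for locus in PANEL_BY_NAME:
        obs = trip.alleles.get(locus)
        cons = consensus.alleles.get(locus)
        if obs is None or cons is None:
            continue
        sperm_here = origin == "eos" or PANEL_BY_NAME[locus].specificity == "both-genomes"
        best: int | None = None
        for reduced in _locus_reductions(locus, obs, sperm_here):
            d = _locus_distance(locus, reduced, cons)
            if best is None or d < best:
                best = d
        if best is None:
            return False
        if best == 0:
            continue
        if best > params.max_step_per_locus:
            return False
        n_variable += 1
        if n_variable > params.max_variable_loci:
            return False
    return True


def _n_maskings(trip: MultilocusGenotype, origin: str) -> int:
    """Loci where ``origin``'s sperm allele would have to be dosage-masked."""
    n = 0
    for locus in PANEL_BY_NAME:
        obs = trip.alleles.get(locus)
        if obs is None:
            continue
        sperm_here = origin == "eos" or PANEL_BY_NAME[locus].specificity == "both-genomes"
        if sperm_here and len(obs) <= PANEL_BY_NAME[locus].n_slots_diploid:
            n += 1
    return n


def assign_triploids(
    triploids: list[MultilocusGenotype],
    lineages: list[Lineage],
    params: ClusteringParams | None = None,
) -> list[TriploidAssignment]:
    """Assign triploid hybrids to already-called lineages.

    A triploid matches a lineage when peeling off one sperm allele per
    locus (consistent with a single genome of origin) leaves the lineage
    consensus within the clustering tolerance.  Triploids matching no
    lineage are additional lineages ("NEW"), merged when identical to each
    other; triploids matching two or more lineages equally are reported
    AMBIGUOUS and excluded from lineage counts.
    """
    params = params or ClusteringParams()
    assignments: list[TriploidAssignment] = []
    new_ids: dict[tuple, str] = {}
    for trip in triploids:
        matched: list[tuple[str, set[str]]] = []
        for L in lineages:
            origins = {
                o for o in ("eos", "neogaeus") if _matches_consensus(trip, L.consensus, o, params)
            }
            if origins:
                matched.append((L.lineage_id, origins))
        if len(matched) == 1:
            lineage_id, origins = matched[0]
            if len(origins) == 1:
                origin = origins.pop()
            else:
                # Both origins fit; prefer the one needing fewer dosage-
                # masked sperm alleles (a sperm allele hidden behind an
                # existing size at a locus it should amplify).
                scores = {o: _n_maskings(trip, o) for o in origins}
                best = min(scores.values())
                parsimonious = [o for o, s in scores.items() if s == best]
                origin = parsimonious[0] if len(parsimonious) == 1 else "ambiguous"
            assignments.append(
                TriploidAssignment(trip.individual_id, lineage_id, origin, trip.site_id)
            )
        elif len(matched) > 1:
            logger.warning(
                "triploid %s matches %d lineages equally; excluded from counts",
                trip.individual_id,
                len(matched),
            )
            assignments.append(
                TriploidAssignment(trip.individual_id, AMBIGUOUS, "ambiguous", trip.site_id)
            )
        else:
            key = _consensus_key(trip)
            if key not in new_ids:
                new_ids[key] = f"{NEW}:{len(new_ids) + 1}"
            assignments.append(
                TriploidAssignment(trip.individual_id, new_ids[key], "ambiguous", trip.site_id)
            )
    return assignments


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def call_survey(
    genotypes: list[MultilocusGenotype], params: ClusteringParams | None = None
) -> tuple[list[Lineage], list[TriploidAssignment]]:
    """Infer ploidy, cluster diploids, and assign triploids in one pass.

    Triploid members (and NEW-triploid pseudo-lineages) are folded back into
    the returned :class:`Lineage` list; NEW pseudo-lineages carry an empty
    diploid membership and their own consensus-free genotype.
    """
    params = params or ClusteringParams()
    hybrids = [g for g in genotypes if g.biotype == Biotype.HYB]
    for g in hybrids:
        if g.ploidy == "unknown":
            g.ploidy = infer_ploidy(g)
    diploids = [g for g in hybrids if g.ploidy != "3n"]
    triploids = [g for g in hybrids if g.ploidy == "3n"]
    lineages = cluster_lineages(diploids, params)
    assignments = assign_triploids(triploids, lineages, params)
    by_id = {L.lineage_id: L for L in lineages}
    trip_members: dict[str, list[str]] = {}
    trip_sites: dict[str, set[str]] = {}
    for a in assignments:
        trip_members.setdefault(a.assigned_lineage, []).append(a.triploid_id)
        trip_sites.setdefault(a.assigned_lineage, set()).add(a.site_id)
    for lid, members in trip_members.items():
        if lid in by_id:
            L = by_id[lid]
            L.triploid_members = tuple(members)
            L.sites = L.sites | trip_sites[lid]
        elif lid.startswith(NEW):
            proto = next(g for g in triploids if g.individual_id == members[0])
            lineages.append(
                Lineage(
                    lineage_id=lid,
                    consensus=proto,
                    diploid_members=(),
                    triploid_members=tuple(members),
                    sites=frozenset(trip_sites[lid]),
                )
            )
    return lineages, assignments
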