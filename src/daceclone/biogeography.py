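"""Geographic classification of clonal lineages.

Lineages restricted to a single site — or to a pool of nearby sites in the
same hydrographic network sharing the very same hybrid assemblage — are
"private" and read as products of local hybridization.  Lineages shared
between distant sites (and especially across networks) are candidates for
Pleistocene migrants that spread through proglacial connections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .survey_io import LGS_CATEGORIES, Biotype, SiteRecord
from .lineage_calling import Lineage

__all__ = [
    "PoolingParams",
    "LineageRange",
    "haversine_km",
    "pool_sites",
    "classify_lineages",
    "occupancy_by_category",
    "diversity_by_category",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class PoolingParams:
    """Criteria for pooling adjacent, assemblage-identical sites.

    The survey design gives no distance threshold in kilometres; 10 km is
    the configurable default for "geographically close" and is echoed in
    output so the choice is always visible.
    """

    max_distance_km: float = 10.0
    require_same_network: bool = True
    require_identical_assemblage: bool = True

    def __post_init__(self) -> None:
        if self.max_distance_km <= 0:
            raise ValueError("max_distance_km must be positive")


@dataclass
class LineageRange:
    lineage_id: str
    sites: frozenset[str]
    pooled_groups: frozenset[str]
    networks: frozenset[str]
    classification: str  # "private" | "widespread"
    cross_network: bool = False


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two decimal-degree coordinates."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def pool_sites(
    sites: list[SiteRecord],
    occurrences: dict[str, frozenset[str] | set[str]],
    params: PoolingParams | None = None,
) -> dict[str, str]:
    """Group sites that plausibly sample one local hybridization event.

    Two sites join one pooled group when they lie in the same hydrographic
    network, within ``max_distance_km`` great-circle distance, and harbour
    the identical lineage assemblage; grouping is the transitive closure of
    that pairwise relation.  ``occurrences`` maps lineage_id to the set of
    occupied site_ids.  Returns a site_id -> group_id map (group id = the
    lexicographically first member site).
    """
    params = params or PoolingParams()
    for s in sites:
        if s.latitude is None or s.longitude is None:
            raise ValueError(f"site {s.site_id} is missing coordinates")
    assemblage: dict[str, frozenset[str]] = {s.site_id: frozenset() for s in sites}
    for lineage_id, occ in occurrences.items():
        for site_id in occ:
            if site_id in assemblage:
                assemblage[site_id] = assemblage[site_id] | {lineage_id}
    graph = nx.Graph()
    graph.add_nodes_from(s.site_id for s in sites)
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            if params.require_same_network and a.network != b.network:
                continue
            if haversine_km(a.latitude, a.longitude, b.latitude, b.longitude) > params.max_distance_km:
                continue
            if params.require_identical_assemblage and assemblage[a.site_id] != assemblage[b.site_id]:
                continue
            graph.add_edge(a.site_id, b.site_id)
    grouping: dict[str, str] = {}
    for component in nx.connected_components(graph):
        gid = min(component)
        for site_id in component:
            grouping[site_id] = gid
    return grouping


def classify_lineages(
    lineages: list[Lineage] | dict[str, set[str]],
    grouping: dict[str, str],
    sites: list[SiteRecord],
) -> list[LineageRange]:
    """Classify lineages as private (one pooled group) or widespread.

    Widespread lineages are Pleistocene-migrant candidates; those spanning
    two or more hydrographic networks are additionally flagged
    ``cross_network``.
    """
    network_of = {s.site_id: s.network for s in sites}
    if isinstance(lineages, dict):
        occurrence_items = list(lineages.items())
    else:
        occurrence_items = [(L.lineage_id, set(L.sites)) for L in lineages]
    out: list[LineageRange] = []
    for lineage_id, occ in occurrence_items:
        if not occ:
            raise ValueError(f"lineage {lineage_id} has no site occurrences")
        missing = occ - set(grouping)
        if missing:
            raise ValueError(f"lineage {lineage_id}: sites {sorted(missing)} not in grouping")
        groups = frozenset(grouping[s] for s in occ)
        networks = frozenset(network_of[s] for s in occ if s in network_of)
        classification = "private" if len(groups) == 1 else "widespread"
        out.append(
            LineageRange(
                lineage_id=lineage_id,
                sites=frozenset(occ),
                pooled_groups=groups,
                networks=networks,
                classification=classification,
                cross_network=len(networks) >= 2,
            )
        )
    return out


def occupancy_by_category(sites: list[SiteRecord], biotype: Biotype) -> list[tuple[int, int]]:
    """(occupied, unoccupied) site counts per LGS category, south to north."""
    table = []
    for cat in LGS_CATEGORIES:
        in_cat = [s for s in sites if s.lgs_category == cat]
        occ = sum(1 for s in in_cat if s.count(biotype) > 0)
        table.append((occ, len(in_cat) - occ))
    return table


def diversity_by_category(
    ranges: list[LineageRange], sites: list[SiteRecord]
) -> dict[str, dict[str, float]]:
    """Private-lineage counts and per-site means per LGS category.

    A private lineage is attributed to the LGS category of its (single)
    pooled group's sites.
    """
    category_of = {s.site_id: s.lgs_category for s in sites}
    counts = {c: 0 for c in LGS_CATEGORIES}
    for r in ranges:
        if r.classification != "private":
            continue
        cats = {category_of[s] for s in r.sites if s in category_of}
        for c in cats:  # a private lineage's pooled group sits in one category
            counts[c] += 1
    n_sites = {c: sum(1 for s in sites if s.lgs_category == c) for c in LGS_CATEGORIES}
    return {
        c: {
            "n_private": counts[c],
            "n_sites": n_sites[c],
            "mean_per_site": counts[c] / n_sites[c] if n_sites[c] else float("nan"),
        }
        for c in LGS_CATEGORIES
    }
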