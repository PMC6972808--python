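"""Data model and I/O for clonal-hybrid genotype surveys.

The survey design follows the *Chrosomus eos–neogaeus* system: gynogenetic
all-female hybrids carry one haploid genome ("haplome") from each parental
species.  Six microsatellite loci resolve nine haplome slots — three loci
amplify both parental genomes (two slots each) and three are specific to the
*C. eos* genome (one slot each).

This module defines the record types (locus panel, multilocus genotypes,
site records, per-site survey summaries), tab-separated readers/writers for
them, and the embedded 51-site survey summary table that anchors the
in-package statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Biotype",
    "LocusDefinition",
    "DEFAULT_PANEL",
    "BOTH_GENOME_LOCI",
    "EOS_SPECIFIC_LOCI",
    "LGS_CATEGORIES",
    "MultilocusGenotype",
    "SiteRecord",
    "SurveyRow",
    "SurveySummary",
    "parse_dms",
    "read_genotype_table",
    "write_genotype_table",
    "read_site_table",
    "write_site_table",
    "load_table1_summary",
    "write_results",
    "write_genepop",
]


class Biotype(str, Enum):
    """Sampled biotypes: the two parental species and their clonal hybrids."""

    EOS = "EOS"
    NEO = "NEO"
    HYB = "HYB"


@dataclass(frozen=True)
class LocusDefinition:
    """A microsatellite locus and which parental genome(s) it amplifies."""

    name: str
    specificity: str  # "both-genomes" | "eos-specific"

    @property
    def n_slots_diploid(self) -> int:
        return 2 if self.specificity == "both-genomes" else 1


# Default panel: 3 loci amplifying both genomes, 3 specific to the C. eos
# genome -> 9 haplome slots per diploid hybrid (6 eos + 3 neogaeus).
DEFAULT_PANEL: tuple[LocusDefinition, ...] = (
    LocusDefinition("Seat412", "both-genomes"),
    LocusDefinition("Ca-12", "both-genomes"),
    LocusDefinition("Rhca-20", "both-genomes"),
    LocusDefinition("Pho-60", "eos-specific"),
    LocusDefinition("Pho-1", "eos-specific"),
    LocusDefinition("Pho-2", "eos-specific"),
)
BOTH_GENOME_LOCI = tuple(l.name for l in DEFAULT_PANEL if l.specificity == "both-genomes")
EOS_SPECIFIC_LOCI = tuple(l.name for l in DEFAULT_PANEL if l.specificity == "eos-specific")
PANEL_BY_NAME = {l.name: l for l in DEFAULT_PANEL}

# Length-of-growing-season categories (days), ordered south -> north
# (longer growing season = warmer = southern end of the transect).
LGS_CATEGORIES: tuple[str, ...] = ("150-160", "140-150", "130-140", "120-130")

NETWORKS: tuple[str, ...] = ("RI", "YA", "SF", "CH", "SJ", "OU", "LO", "RM", "MI")


@dataclass
class MultilocusGenotype:
    """One individual's allele multisets over the locus panel.

    ``alleles`` maps locus name to a sorted tuple of distinct allele scores
    (what a fragment-size genotyper observes; dosage is not resolved), or to
    ``None`` when the locus failed to amplify.  Allele scores are plain
    positive integers; whether they denote repeat counts or fragment sizes
    is a table-header dialect flag and one unit is one mutational step.
    """

    individual_id: str
    site_id: str
    biotype: Biotype
    ploidy: str = "unknown"  # "2n" | "3n" | "unknown"
    alleles: dict[str, tuple[int, ...] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, obs in self.alleles.items():
            if locus not in PANEL_BY_NAME:
                raise ValueError(f"unknown locus {locus!r}")
            if obs is None:
                continue
            obs = tuple(sorted(obs))
            self.alleles[locus] = obs
            if any(a <= 0 for a in obs):
                raise ValueError(f"allele scores must be positive at {locus}: {obs}")
            limit = 3 if PANEL_BY_NAME[locus].specificity == "both-genomes" else 2
            if len(obs) > limit:
                raise ValueError(
                    f"{self.individual_id}: {len(obs)} distinct alleles at {locus} "
                    f"exceed the triploid bound of {limit}"
                )

    def distinct(self, locus: str) -> tuple[int, ...] | None:
        return self.alleles.get(locus)


@dataclass
class SiteRecord:
    """Per-site metadata: coordinates, network, LGS category, biotype counts."""

    site_id: str
    latitude: float
    longitude: float
    network: str
    lgs_category: str
    n_eos: int = 0
    n_hyb: int = 0
    n_neo: int = 0
    pooled_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.lgs_category not in LGS_CATEGORIES:
            raise ValueError(
                f"site {self.site_id}: LGS category {self.lgs_category!r} is not one "
                f"of {LGS_CATEGORIES}"
            )
        if self.network not in NETWORKS:
            raise ValueError(f"site {self.site_id}: unknown network {self.network!r}")

    def count(self, biotype: Biotype) -> int:
        return {Biotype.EOS: self.n_eos, Biotype.HYB: self.n_hyb, Biotype.NEO: self.n_neo}[biotype]


@dataclass(frozen=True)
class SurveyRow:
    """One row of the per-site survey summary (site + lineage tallies)."""

    site: SiteRecord
    n_private_lineages: int
    shared_lineage_letters: frozenset[str]


@dataclass
class SurveySummary:
    """The per-site survey summary mirroring the published site table."""

    rows: tuple[SurveyRow, ...]

    def sites(self) -> list[SiteRecord]:
        return [r.site for r in self.rows]

    def total_private(self) -> int:
        return sum(r.n_private_lineages for r in self.rows)

    def shared_letters(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.rows:
            out |= r.shared_lineage_letters
        return frozenset(out)

    def total_distinct_lineages(self) -> int:
        return self.total_private() + len(self.shared_letters())

    def rows_in_category(self, lgs: str) -> list[SurveyRow]:
        return [r for r in self.rows if r.site.lgs_category == lgs]

    def sites_per_category(self) -> dict[str, int]:
        return {c: len(self.rows_in_category(c)) for c in LGS_CATEGORIES}

    def private_per_category(self) -> dict[str, int]:
        return {
            c: sum(r.n_private_lineages for r in self.rows_in_category(c))
            for c in LGS_CATEGORIES
        }

    def mean_private_per_site(self) -> dict[str, float]:
        return {
            c: self.private_per_category()[c] / self.sites_per_category()[c]
            for c in LGS_CATEGORIES
        }

    def occupancy(self, biotype: Biotype) -> dict[str, tuple[int, int]]:
        """Per LGS category: (sites occupied by ``biotype``, sites not)."""
        out = {}
        for c in LGS_CATEGORIES:
            rows = self.rows_in_category(c)
            occ = sum(1 for r in rows if r.site.count(biotype) > 0)
            out[c] = (occ, len(rows) - occ)
        return out

    def total_occupied(self, biotype: Biotype) -> int:
        return sum(occ for occ, _ in self.occupancy(biotype).values())

    def sites_with_private(self) -> int:
        return sum(1 for r in self.rows if r.n_private_lineages > 0)

    def shared_letter_site_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            for letter in r.shared_lineage_letters:
                counts[letter] = counts.get(letter, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Coordinate parsing
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d+)\s*[°d]\s*(\d+)\s*[′'’]\s*(?:(\d+(?:\.\d+)?)\s*[ʺ″"”]?)?\s*([NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str | float) -> float:
    """Parse a degree-minute-second coordinate to decimal degrees.

    Accepts typographic prime/double-prime glyphs as well as ASCII quotes,
    or an already-decimal value.  A trailing S or W hemisphere letter
    negates the result.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    try:
        return float(s)
    except ValueError:
        pass
    m = _DMS_RE.match(s)
    if not m:
        raise ValueError(f"cannot parse coordinate {text!r}")
    deg, minutes, seconds, hemi = m.groups()
    value = int(deg) + int(minutes) / 60.0 + (float(seconds) if seconds else 0.0) / 3600.0
    if hemi in ("S", "W"):
        value = -value
    return value


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------
#
# TSV dialect: columns individual_id, site_id, biotype, then one column per
# panel locus with comma-joined allele scores ("178,182"); "." = missing.
# An optional leading "#units=..." comment records whether scores are repeat
# counts or fragment sizes (downstream code treats 1 unit = 1 step either way).

_BIOTYPE_ALIASES = {"E": Biotype.EOS, "N": Biotype.NEO, "H": Biotype.HYB}


def _parse_biotype(token: str) -> Biotype:
    token = token.strip().upper()
    if token in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[token]
    return Biotype(token)


def read_genotype_table(path: str | Path) -> list[MultilocusGenotype]:
    """Read a genotype TSV into :class:`MultilocusGenotype` records.

    Missing loci (".") are kept as explicit ``None`` entries, never dropped.
    Malformed rows raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    records: list[MultilocusGenotype] = []
    with path.open() as fh:
        lineno = 0
        header: list[str] | None = None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:3] != ["individual_id", "site_id", "biotype"]:
                    raise ValueError(
                        f"{path}:{lineno}: genotype header must start with "
                        "individual_id, site_id, biotype"
                    )
                for locus in header[3:]:
                    if locus not in PANEL_BY_NAME:
                        raise ValueError(f"{path}:{lineno}: unknown locus {locus!r}")
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            alleles: dict[str, tuple[int, ...] | None] = {}
            for locus, token in zip(header[3:], fields[3:]):
                token = token.strip()
                if token in (".", ""):
                    alleles[locus] = None
                    continue
                try:
                    scores = tuple(sorted(int(t) for t in token.split(",")))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad allele field {token!r}") from exc
                alleles[locus] = scores
            # Every panel locus must be present or explicitly missing.
            for locus in PANEL_BY_NAME:
                alleles.setdefault(locus, None)
            try:
                rec = MultilocusGenotype(
                    individual_id=fields[0],
                    site_id=fields[1],
                    biotype=_parse_biotype(fields[2]),
                    alleles=alleles,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if header is None:
        raise ValueError(f"{path}: empty genotype table")
    return records


def write_genotype_table(
    records: Iterable[MultilocusGenotype], path: str | Path, units: str = "size"
) -> None:
    path = Path(path)
    loci = [l.name for l in DEFAULT_PANEL]
    with path.open("w") as fh:
        fh.write(f"#units={units}\n")
        fh.write("\t".join(["individual_id", "site_id", "biotype"] + loci) + "\n")
        for rec in records:
            row = [rec.individual_id, rec.site_id, rec.biotype.value]
            for locus in loci:
                obs = rec.alleles.get(locus)
                row.append("." if obs is None else ",".join(str(a) for a in obs))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["site_id", "lat", "lon", "network", "lgs_category", "n_eos", "n_hyb", "n_neo"]


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read a site TSV; coordinates may be decimal or DMS text."""
    path = Path(path)
    records: list[SiteRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in SITE_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"{path}:{lineno}: missing columns {missing}")
                continue
            row = dict(zip(header, fields))
            site_id = row["site_id"]
            if site_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate site_id {site_id!r}")
            seen.add(site_id)
            try:
                rec = SiteRecord(
                    site_id=site_id,
                    latitude=parse_dms(row["lat"]),
                    longitude=parse_dms(row["lon"]),
                    network=row["network"],
                    lgs_category=row["lgs_category"],
                    n_eos=int(row["n_eos"]),
                    n_hyb=int(row["n_hyb"]),
                    n_neo=int(row["n_neo"]),
                    pooled_members=tuple(
                        t for t in row.get("pooled_members", "").split(",") if t
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if header is None:
        raise ValueError(f"{path}: empty site table")
    return records


def write_site_table(sites: Iterable[SiteRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SITE_COLUMNS + ["pooled_members"]) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.site_id,
                        f"{s.latitude:.6f}",
                        f"{s.longitude:.6f}",
                        s.network,
                        s.lgs_category,
                        str(s.n_eos),
                        str(s.n_hyb),
                        str(s.n_neo),
                        ",".join(s.pooled_members),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Embedded 51-site survey summary (the published per-site table)
# ---------------------------------------------------------------------------
#
# Columns: site, latitude (N), longitude (W), n_eos, n_hyb, n_neo,
# n_private_lineages, shared lineage letters ("-" = none), LGS category,
# sampling campaign (1 = earlier survey of the southern networks, 2 = the
# latitudinal extension).  Pooled rows (e.g. SF-4,5,7,8) are kept as single
# entries, as published; ranges like RI-2-4 expand to consecutive members.

_TABLE1 = """\
RI-2-4	45°03′01ʺ	72°19′03ʺ	31	40	0	3	-	150-160	1
SF-3,18	45°03′05ʺ	72°11′39ʺ	0	5	0	1	-	150-160	1
SF-11	45°04′23ʺ	71°52′37ʺ	0	2	0	1	-	150-160	1
SF-12	45°07′48ʺ	71°40′21ʺ	28	51	12	2	-	150-160	1
SF-13,14	45°11′04ʺ	71°33′13ʺ	14	114	0	3	A	150-160	1
SF-9-10	45°12′23ʺ	71°56′33ʺ	30	0	0	0	-	150-160	1
SF-6	45°13′20ʺ	71°55′01ʺ	9	0	0	0	-	150-160	1
SF-4,5,7,8	45°14′01ʺ	71°54′28ʺ	12	54	0	2	-	150-160	1
RI-1	45°15′03ʺ	72°18′20ʺ	0	4	0	1	-	150-160	1
SF-2	45°21′17ʺ	72°13′05ʺ	14	7	0	2	-	150-160	1
CH-1	45°22′48ʺ	70°50′02ʺ	0	1	3	1	-	140-150	1
YA-1	45°23′23ʺ	72°27′01ʺ	10	24	0	2	B	150-160	1
YA-2	45°24′25ʺ	72°25′18ʺ	24	0	0	0	-	150-160	1
SF-15	45°24′53ʺ	71°46′53ʺ	0	6	0	3	-	140-150	1
SF-20,21	45°25′50ʺ	71°40′19ʺ	2	24	0	6	-	140-150	1
SF-1	45°27′00ʺ	71°49′32ʺ	16	14	0	5	A	140-150	1
CH-2	45°29′03ʺ	71°04′48ʺ	80	0	0	0	-	140-150	1
SF-19,22	45°32′15ʺ	71°49′40ʺ	0	12	0	1	B	140-150	1
CH-3	45°41′10ʺ	70°55′01ʺ	1	47	0	3	C,D	140-150	2
SF-16,17	45°42′10ʺ	71°09′59ʺ	0	6	0	2	-	140-150	1
CH-4	45°46′59ʺ	70°51′13ʺ	13	24	4	13	D,E	140-150	2
CH-5	45°50′45ʺ	70°53′19ʺ	19	16	29	5	E	140-150	2
CH-6	45°56′02ʺ	70°47′37ʺ	3	4	0	1	-	140-150	2
CH-7	46°06′29ʺ	70°24′50ʺ	7	21	0	2	C	130-140	2
SJ-1	46°10′52ʺ	70°18′19ʺ	10	15	11	2	F	130-140	2
SJ-2	46°11′22ʺ	70°18′40ʺ	21	16	7	2	F	130-140	2
SJ-3	46°20′40ʺ	70°14′48ʺ	8	2	0	0	G	130-140	2
SJ-4	46°32′42ʺ	70°14′38ʺ	5	3	2	0	F,G	130-140	2
SJ-5	46°39′05ʺ	70°14′35ʺ	0	4	23	0	F	130-140	2
SJ-6	46°40′19ʺ	70°10′16ʺ	4	0	0	0	-	130-140	2
SJ-7	46°48′54ʺ	70°13′45ʺ	21	12	0	2	F,G	130-140	2
SJ-8	46°51′27ʺ	70°10′12ʺ	1	11	10	1	F,H	130-140	2
SJ-9	46°51′45ʺ	70°10′37ʺ	17	2	3	0	G	130-140	2
SJ-10	46°54′33ʺ	70°14′23ʺ	3	8	0	0	F,G,H	130-140	2
SJ-11	46°55′50ʺ	70°04′22ʺ	4	0	0	0	-	130-140	2
OU-1	47°05′23ʺ	69°51′50ʺ	17	4	3	0	F,H	130-140	2
OU-2	47°06′31ʺ	69°53′52ʺ	15	2	9	0	H	130-140	2
OU-3	47°06′32ʺ	70°00′30ʺ	9	0	7	0	-	130-140	2
OU-4	47°07′33ʺ	69°50′40ʺ	0	2	0	0	F	130-140	2
OU-5	47°09′12ʺ	69°48′26ʺ	25	22	1	2	-	130-140	2
LO-1	47°30′44ʺ	69°32′24ʺ	12	0	0	0	-	130-140	2
LO-2	47°32′15ʺ	69°35′07ʺ	8	0	4	0	-	130-140	2
SJ-12	47°42′05ʺ	68°59′36ʺ	0	6	0	1	-	130-140	2
SJ-13	47°55′03ʺ	68°57′16ʺ	0	0	1	0	-	130-140	2
SJ-14	47°55′41ʺ	68°50′53ʺ	1	0	0	0	-	130-140	2
RM-1	48°05′02ʺ	68°32′47ʺ	2	0	0	0	-	120-130	2
RM-2	48°06′43ʺ	68°31′50ʺ	2	0	0	0	-	120-130	2
RM-3	48°08′05ʺ	68°25′04ʺ	12	0	6	0	-	120-130	2
MI-2	48°18′15ʺ	68°14′32ʺ	2	0	0	0	-	120-130	2
MI-1	48°19′33ʺ	68°18′54ʺ	3	0	1	0	-	120-130	2
MI-3	48°29′38ʺ	68°14′27ʺ	16	1	0	1	-	120-130	2
"""


def _pooled_members(site_id: str) -> tuple[str, ...]:
    """Expand a pooled site label into its member site labels.

    "SF-4,5,7,8" lists members explicitly; "RI-2-4" denotes the consecutive
    range RI-2..RI-4; plain labels have no members.
    """
    m = re.match(r"^([A-Z]{2})-(.+)$", site_id)
    if not m:
        return ()
    prefix, rest = m.groups()
    if "," in rest:
        parts = [p.strip() for p in rest.split(",")]
        return tuple(f"{prefix}-{p}" for p in parts)
    m2 = re.match(r"^(\d+)-(\d+)$", rest)
    if m2:
        lo, hi = int(m2.group(1)), int(m2.group(2))
        return tuple(f"{prefix}-{i}" for i in range(lo, hi + 1))
    return ()


def load_table1_summary() -> SurveySummary:
    """Return the embedded 51-site survey summary, exactly as published."""
    rows: list[SurveyRow] = []
    for line in _TABLE1.splitlines():
        site_id, lat, lon, n_eos, n_hyb, n_neo, n_priv, shared, lgs, _campaign = line.split("\t")
        members = _pooled_members(site_id)
        site = SiteRecord(
            site_id=site_id,
            latitude=parse_dms(lat),
            longitude=-parse_dms(lon),  # published longitudes are °W
            network=site_id[:2],
            lgs_category=lgs,
            n_eos=int(n_eos),
            n_hyb=int(n_hyb),
            n_neo=int(n_neo),
            pooled_members=members if len(members) > 1 else (),
        )
        letters = frozenset() if shared == "-" else frozenset(shared.split(","))
        rows.append(SurveyRow(site=site, n_private_lineages=int(n_priv), shared_lineage_letters=letters))
    return SurveySummary(rows=tuple(rows))


# ---------------------------------------------------------------------------
# Generic result writing
# ---------------------------------------------------------------------------


def write_results(results, path: str | Path) -> None:
    """Write a stage result to a re-readable text file.

    Accepts a sequence of mappings (-> TSV with deterministic column order:
    first-row key order, extras sorted), a mapping (-> two-column TSV), or a
    pandas DataFrame.  An empty sequence produces a header-only file when a
    header can be inferred, otherwise an empty file.
    """
    path = Path(path)
    try:
        import pandas as pd

        if isinstance(results, pd.DataFrame):
            results.to_csv(path, sep="\t", index=False)
            return
    except ImportError:  # pragma: no cover
        pass
    if isinstance(results, Mapping):
        with path.open("w") as fh:
            fh.write("key\tvalue\n")
            for k in results:
                fh.write(f"{k}\t{results[k]}\n")
        return
    rows = list(results)
    with path.open("w") as fh:
        if not rows:
            fh.write("")
            return
        first = rows[0]
        if isinstance(first, Mapping):
            columns = list(first)
            extras = sorted({k for r in rows for k in r} - set(columns))
            columns += extras
            fh.write("\t".join(str(c) for c in columns) + "\n")
            for r in rows:
                fh.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")
        else:
            for r in rows:
                if isinstance(r, (tuple, list)):
                    fh.write("\t".join(str(v) for v in r) + "\n")
                else:
                    fh.write(f"{r}\n")


def write_genepop(
    genotypes: Sequence[MultilocusGenotype], path: str | Path, title: str = "diploid hybrid genotypes"
) -> None:
    """Export diploid hybrid genotypes in Genepop format (3-digit codes).

    Only the three loci amplifying both genomes are exported (Genepop is a
    diploid format; the eos-specific loci are haploid in these hybrids).
    Individuals are grouped into one POP per site.
    """
    path = Path(path)
    loci = list(BOTH_GENOME_LOCI)
    diploids = [g for g in genotypes if g.biotype == Biotype.HYB and g.ploidy != "3n"]
    by_site: dict[str, list[MultilocusGenotype]] = {}
    for g in diploids:
        by_site.setdefault(g.site_id, []).append(g)
    with path.open("w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        for site in sorted(by_site):
            fh.write("POP\n")
            for g in by_site[site]:
                codes = []
                for locus in loci:
                    obs = g.alleles.get(locus)
                    if obs is None:
                        codes.append("000000")
                    else:
                        pair = (obs[0], obs[-1])  # single observed size -> homozygous
                        codes.append(f"{pair[0] % 1000:03d}{pair[1] % 1000:03d}")
                fh.write(f"{g.individual_id},  " + " ".join(codes) + "\n")
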