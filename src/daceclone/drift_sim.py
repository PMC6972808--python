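"""Forward clonal lineage-sorting simulator and diversity calibration.

After a hybridization pulse, each fertilised egg founds a distinct clonal
lineage; with strictly clonal (gynogenetic) reproduction no process creates
new lineages, so genetic drift erodes the initial diversity generation by
generation.  The simulator is a haploid multinomial Wright-Fisher model of
a metapopulation of demes connected by island-model migration: each
generation every deme draws its offspring from a parental pool that is the
local deme with probability 1 - m and the equal mixture of all other demes
with probability m.

Two read-outs calibrate field observations against this neutral clock:

* rarefaction — how many lineages a sample of N individuals reveals from a
  population of known composition, used to bound the effective lineage
  number behind an under-sampled, high-diversity site;
* trajectory bracketing — the generation interval over which the mean
  system-wide lineage count passes through an observed diversity, read as
  the plausible time since hybridization (1 generation = 1 year by
  default, matching the ~10,000-year postglacial window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "Trajectory",
    "RarefactionConfig",
    "CalibrationResult",
    "simulate_lineage_sorting",
    "per_deme_crossing",
    "rarefy",
    "estimate_effective_lineages",
    "calibrate_time",
]


@dataclass(frozen=True)
class SimConfig:
    """Island-model clonal drift parameters.

    Defaults mirror the survey's simulated metapopulation: 20 demes of 500
    clonal individuals (10,000 total, the scale of small-brook populations),
    migration m = 0.01, 100 founding lineages assigned uniformly at random,
    10,000 generations, 100 replicates.
    """

    n_demes: int = 20
    deme_size: int = 500
    migration_rate: float = 0.01
    init_lineages: int = 100
    generations: int = 10_000
    replicates: int = 100
    seed: int = 0
    migration_scheme: str = "island"  # or "stepping-stone" (ring)
    initialization: str = "uniform"  # or "balanced"
    track_heterozygosity: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValueError("migration rate must be in [0, 1]")
        if self.init_lineages > self.n_demes * self.deme_size:
            raise ValueError("more founding lineages than individuals")
        if self.migration_scheme not in ("island", "stepping-stone"):
            raise ValueError(f"unknown migration scheme {self.migration_scheme!r}")
        if self.initialization not in ("uniform", "balanced"):
            raise ValueError(f"unknown initialization {self.initialization!r}")


@dataclass
class Trajectory:
    """Per-generation lineage-count summaries over replicates."""

    generations: np.ndarray  # 0..G
    mean_system: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    mean_per_deme: np.ndarray
    replicate_system: np.ndarray | None = None  # replicates x (G+1)
    mean_heterozygosity: np.ndarray | None = None
    config: SimConfig | None = None

    def to_table(self) -> list[dict]:
        return [
            {
                "generation": int(g),
                "mean_system": float(self.mean_system[i]),
                "lo95": float(self.lo95[i]),
                "hi95": float(self.hi95[i]),
                "mean_per_deme": float(self.mean_per_deme[i]),
            }
            for i, g in enumerate(self.generations)
        ]


def _init_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial deme x lineage count matrix."""
    K = cfg.init_lineages
    if cfg.initialization == "uniform":
        labels = rng.integers(0, K, size=(cfg.n_demes, cfg.deme_size))
        return np.stack([np.bincount(row, minlength=K) for row in labels])
    total = cfg.n_demes * cfg.deme_size
    flat = np.arange(total) % K
    rng.shuffle(flat)
    return np.stack(
        [
            np.bincount(chunk, minlength=K)
            for chunk in flat.reshape(cfg.n_demes, cfg.deme_size)
        ]
    )


def _parental_pool(freq: np.ndarray, m: float, scheme: str) -> np.ndarray:
    D = freq.shape[0]
    if D == 1 or m == 0.0:
        return freq
    if scheme == "island":
        migrant = (freq.sum(axis=0, keepdims=True) - freq) / (D - 1)
    else:  # ring stepping-stone: equal mixture of the two neighbours
        migrant = 0.5 * (np.roll(freq, 1, axis=0) + np.roll(freq, -1, axis=0))
    return (1.0 - m) * freq + m * migrant


def simulate_lineage_sorting(cfg: SimConfig) -> Trajectory:
    """Simulate clonal lineage sorting and summarise over replicates.

    Within each replicate surviving lineages are tracked as a deme-by-
    lineage count matrix; globally extinct lineages are pruned as the run
    proceeds (counts are label-conserving, so extinction is irreversible).
    The 95% band is the 2.5-97.5 percentile interval of the system-wide
    count across replicates.  Replicate r of a given (seed, config) is
    bit-reproducible: each replicate draws from its own spawned stream.
    """
    G = cfg.generations
    sys_counts = np.zeros((cfg.replicates, G + 1), dtype=np.int64)
    deme_counts = np.zeros((cfg.replicates, G + 1), dtype=float)
    het = np.zeros((cfg.replicates, G + 1), dtype=float) if cfg.track_heterozygosity else None
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    for r in range(cfg.replicates):
        rng = np.random.default_rng(streams[r])
        counts = _init_counts(cfg, rng)
        for g in range(G + 1):
            alive = counts.sum(axis=0) > 0
            sys_counts[r, g] = int(alive.sum())
            deme_counts[r, g] = float((counts > 0).sum(axis=1).mean())
            if het is not None:
                p = counts / cfg.deme_size
                het[r, g] = float(np.mean(1.0 - (p**2).sum(axis=1)))
            if g == G:
                break
            if alive.sum() < counts.shape[1]:
                counts = counts[:, alive]
            freq = counts / cfg.deme_size
            pool = _parental_pool(freq, cfg.migration_rate, cfg.migration_scheme)
            counts = rng.multinomial(cfg.deme_size, pool)
    return Trajectory(
        generations=np.arange(G + 1),
        mean_system=sys_counts.mean(axis=0),
        lo95=np.percentile(sys_counts, 2.5, axis=0),
        hi95=np.percentile(sys_counts, 97.5, axis=0),
        mean_per_deme=deme_counts.mean(axis=0),
        replicate_system=sys_counts,
        mean_heterozygosity=het.mean(axis=0) if het is not None else None,
        config=cfg,
    )


def per_deme_crossing(traj: Trajectory, threshold: int) -> int | None:
    """First generation with mean per-deme lineage count <= ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive (the last lineage never dies)")
    below = traj.mean_per_deme <= threshold
    if not below.any():
        return None
    return int(traj.generations[int(np.argmax(below))])


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(
    lineage_counts,
    n: int,
    reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mean (and sd) distinct lineages in samples of ``n`` without replacement."""
    counts = np.asarray(lineage_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative lineage counts")
    total = int(counts.sum())
    if n > total:
        raise ValueError(f"sample size {n} exceeds population size {total}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    distinct = np.empty(reps, dtype=np.int64)
    for i in range(reps):
        sample = rng.multivariate_hypergeometric(counts, n)
        distinct[i] = int((sample > 0).sum())
    return float(distinct.mean()), float(distinct.std(ddof=0))


@dataclass(frozen=True)
class RarefactionConfig:
    """Effective-lineage estimation for an under-sampled site.

    The simulated population keeps one anchor lineage at the observed modal
    frequency (0.33 of 1,000 individuals rounds to 330 copies) and spreads
    the remaining K - 1 candidate lineages uniformly at random over the
    rest, then asks how many lineages 100 samples of 24 individuals reveal.
    """

    population_size: int = 1_000
    anchor_frequency: float = 0.33
    candidate_k: tuple[int, ...] = (15, 30, 40, 50)
    samplings: int = 100
    sample_size: int = 24
    seed: int = 0
    adequacy_margin: float = 0.5
    # populations rebuilt per K; 1 is the survey's protocol, larger values
    # average out the construction noise to estimate its expectation
    n_populations: int = 1

    def __post_init__(self) -> None:
        if self.sample_size > self.population_size:
            raise ValueError("sample_size exceeds population_size")
        if not (0.0 < self.anchor_frequency < 1.0):
            raise ValueError("anchor_frequency must be in (0, 1)")


def _anchored_population(K: int, cfg: RarefactionConfig, rng: np.random.Generator) -> np.ndarray:
    n_anchor = int(round(cfg.anchor_frequency * cfg.population_size))
    rest = cfg.population_size - n_anchor
    counts = np.zeros(K, dtype=np.int64)
    counts[0] = n_anchor
    if K > 1:
        labels = rng.integers(1, K, size=rest)
        counts += np.bincount(labels, minlength=K)
    else:
        counts[0] += rest
    return counts


@dataclass
class EffectiveLineageEstimate:
    curve: dict[int, tuple[float, float]]  # K -> (mean distinct, sd)
    observed: int
    minimal_adequate_k: int | None
    at_least: bool  # adequate K is the largest candidate (true value may exceed it)

    def describe(self) -> str:
        if self.minimal_adequate_k is None:
            return f">= {max(self.curve)} lineages (no candidate reaches the observed diversity)"
        prefix = "at least " if self.at_least else ""
        return f"{prefix}{self.minimal_adequate_k} lineages"


def estimate_effective_lineages(
    observed_diversity: int, cfg: RarefactionConfig | None = None
) -> EffectiveLineageEstimate:
    """Bound the effective lineage number behind an observed sample diversity.

    For each candidate K the anchored population is rebuilt and rarefied;
    a candidate is adequate when its mean sampled diversity reaches the
    observation (mean >= observed - ``adequacy_margin``; 0.5 = agreement
    of the rounded mean) and the estimate is the smallest adequate K.
    When no candidate suffices, or only the largest does, the population
    "should include at least max(K)" lineages.
    """
    cfg = cfg or RarefactionConfig()
    if observed_diversity < 1:
        raise ValueError("observed diversity must be >= 1")
    if observed_diversity > cfg.sample_size:
        raise ValueError("observed diversity cannot exceed the sample size")
    rng = np.random.default_rng(cfg.seed)
    curve: dict[int, tuple[float, float]] = {}
    minimal: int | None = None
    for K in sorted(cfg.candidate_k):
        means, sds = [], []
        for _ in range(cfg.n_populations):
            counts = _anchored_population(K, cfg, rng)
            m, s = rarefy(counts, cfg.sample_size, cfg.samplings, rng)
            means.append(m)
            sds.append(s)
        mean, sd = float(np.mean(means)), float(np.mean(sds))
        curve[K] = (mean, sd)
        if minimal is None and mean >= observed_diversity - cfg.adequacy_margin:
            minimal = K
    return EffectiveLineageEstimate(
        curve=curve,
        observed=observed_diversity,
        minimal_adequate_k=minimal,
        at_least=minimal is not None and minimal == max(cfg.candidate_k),
    )


# ---------------------------------------------------------------------------
# Time calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    observed_count: tuple[float, float]  # lo, hi of the observed diversity
    generation_interval: tuple[int | None, int | None]
    years_bp: tuple[float | None, float | None]
    open_ended: bool


def calibrate_time(
    observed_count: float | tuple[float, float],
    traj: Trajectory,
    years_per_generation: float = 1.0,
) -> CalibrationResult:
    """Bracket the time since hybridization from an observed diversity.

    Returns the generation interval over which the mean system-wide count
    lies within the observed count (a single value or a [lo, hi] range),
    converted to years BP.  When the trajectory never decays to the
    observed range the interval is open-ended on the right.
    """
    if isinstance(observed_count, (int, float)):
        lo_obs = hi_obs = float(observed_count)
    else:
        lo_obs, hi_obs = float(observed_count[0]), float(observed_count[1])
        if lo_obs > hi_obs:
            raise ValueError("observed count range must satisfy lo <= hi")
    init = traj.mean_system[0]
    if lo_obs > init:
        raise ValueError("observed count exceeds the number of founding lineages")
    mean = traj.mean_system
    gens = traj.generations
    reached = mean <= hi_obs
    if not reached.any():
        return CalibrationResult(
            observed_count=(lo_obs, hi_obs),
            generation_interval=(int(gens[-1]), None),
            years_bp=(float(gens[-1]) * years_per_generation, None),
            open_ended=True,
        )
    first = int(gens[int(np.argmax(reached))])
    at_or_above = mean >= lo_obs
    last = int(gens[int(np.nonzero(at_or_above)[0][-1])]) if at_or_above.any() else first
    last = max(last, first)
    open_ended = bool(mean[-1] >= lo_obs)  # never drops below the observed range
    return CalibrationResult(
        observed_count=(lo_obs, hi_obs),
        generation_interval=(first, None if open_ended else last),
        years_bp=(
            first * years_per_generation,
            None if open_ended else last * years_per_generation,
        ),
        open_ended=open_ended,
    )
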