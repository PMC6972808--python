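# daceclone

Tools for inferring **where and when hybridization happened** from surveys
of clonally reproducing hybrids, built around the *Chrosomus eos–neogaeus*
(northern redbelly dace × finescale dace) system.

These all-female hybrids reproduce by gynogenesis: every fertilised egg
founds a clonal lineage whose multilocus microsatellite genotype persists
through time, modified only by occasional stepwise mutations.  A lineage
restricted to one site is evidence of **local** hybridization; a lineage
shared across distant sites and hydrographic networks is a relic of
**Pleistocene** hybridization that spread through proglacial connections.
Because drift erodes clonal diversity generation by generation, the number
of lineages a site still carries is a clock for the time since its founding
hybridization pulse.

The package covers the full analysis chain:

* **`survey_io`** — record types (locus panel, multilocus genotypes, site
  records), TSV readers/writers, Genepop export, and the embedded 51-site
  survey summary table from a 500-km latitudinal transect of southeastern
  Quebec (sites binned by length of growing season, LGS, in 10-day
  categories).
* **`lineage_calling`** — clonal lineage calling: single-linkage clustering
  of diploid hybrid genotypes under a stepwise-mutation tolerance (≤ 1 step
  at ≤ 2 loci by default), consensus genotypes, ploidy inference, and
  assignment of triploids (diploid hybrids that incorporated a sperm
  haplome) back to their source lineage.
* **`biogeography`** — pooling of adjacent assemblage-identical sites,
  private-versus-widespread classification, occupancy and diversity by LGS
  category.
* **`lgs_stats`** — the statistical battery: Freeman–Halton r×2 exact
  tests, Yates-corrected 2×2 χ², sites-proportional goodness of fit,
  Mann–Whitney U, OLS sampling-effort check, and LOESS (tricube local
  quadratic) with GCV-selected span.
* **`drift_sim`** — forward clonal Wright–Fisher simulation of lineage
  sorting in an island-model metapopulation (20 demes × 500, m = 0.01 by
  default), rarefaction, effective-lineage estimation for under-sampled
  sites, and diversity→time calibration.
* **`synthetic_survey`** — a generator of complete synthetic surveys
  (founding events, genealogy-aware stepwise mutation, triploid production,
  per-site sampling) with ground truth, for end-to-end recovery tests.

## The model in brief

A deme of $N$ clonal individuals carrying lineage labels evolves by
multinomial Wright–Fisher resampling; with island-model migration at rate
$m$, deme $d$ draws its offspring from the pool
$(1-m)\,p_d + m\,\overline{p_{-d}}$ where $\overline{p_{-d}}$ is the mean
frequency vector of the other demes.  No process creates labels, so the
system-wide lineage count decays from its founding value $K$; expected
heterozygosity obeys the classical $E[H_t] = H_0 (1 - 1/N)^t$.  Rarefaction
of a population with per-lineage counts $n_i$ follows the hypergeometric
expectation
$E[\text{distinct}] = \sum_i \left(1 - \binom{N-n_i}{n}/\binom{N}{n}\right)$.

## Worked example

Recompute the survey's headline numbers from the embedded site table:

```python
import numpy as np
from daceclone import (load_table1_summary, Biotype, chisq_yates_2x2,
                       chisq_gof_proportional, fisher_exact_rx2)

s = load_table1_summary()
print(f"sites: {len(s.rows)}   lineages: {s.total_distinct_lineages()} "
      f"({s.total_private()} private + {len(s.shared_letters())} shared)")
print("private per LGS category (south->north):",
      [s.private_per_category()[c] for c in ('150-160','140-150','130-140','120-130')])

eos, neo = s.total_occupied(Biotype.EOS), s.total_occupied(Biotype.NEO)
r = chisq_yates_2x2([[eos, 51-eos], [neo, 51-neo]])
print(f"eos vs neogaeus occupancy: chi2 = {r.chi2:.2f} (df={r.df}, p={r.p:.5f})")

table = np.array([s.occupancy(Biotype.EOS)[c]
                  for c in ('150-160','140-150','130-140','120-130')])
print(f"eos occupancy evenness (Fisher exact): p = {fisher_exact_rx2(table):.4f}")

r = chisq_gof_proportional([17, 27], [12, 10])
print(f"150-160 vs 140-150 diversity (outlier excluded): chi2 = {r.chi2:.3f} (p={r.p:.4f})")
```

prints

```
sites: 51   lineages: 78 (70 private + 8 shared)
private per LGS category (south->north): [17, 40, 12, 1]
eos vs neogaeus occupancy: chi2 = 17.63 (df=1, p=0.00003)
eos occupancy evenness (Fisher exact): p = 0.3745
150-160 vs 140-150 diversity (outlier excluded): chi2 = 4.492 (p=0.0341)
```

The transect carries 78 distinct hybrid lineages, 70 of them private to a
single site or site pool — overwhelmingly products of local hybridization
rather than postglacial migrants.  Private diversity concentrates in the
southern half (17 + 40 = 57 lineages) and peaks in the 140–150-day LGS band,
the signature of a northward-moving hybridization wave.

How many lineages does the high-diversity outlier site really hold?  Its
sample of 24 hybrids showed 15 lineages with the commonest at frequency
0.33.  Rebuilding anchored populations and rarefying (100 samples of 24;
20 rebuilt populations per candidate averaged):

```bash
$ daceclone --seed 1 rarefy --observed 15 --pops 20
K= 15  mean distinct = 10.65  (sd 1.39)
K= 30  mean distinct = 13.48  (sd 1.85)
K= 40  mean distinct = 14.27  (sd 1.98)
K= 50  mean distinct = 14.77  (sd 2.02)
estimate: at least 50 lineages
```

Only a population of at least 50 lineages reproduces the observed sample
diversity — an order of magnitude above every other site, pointing to
hybridization within recent decades.

The lineage-sorting simulator calibrates older sites: run
`daceclone --seed 1 simulate --out traj.tsv` (defaults: 20 demes × 500,
m = 0.01, 100 founding lineages, 100 replicates, 10,000 generations) and
`daceclone calibrate --traj traj.tsv --observed 5-6` to bracket the
generations at which mean system-wide diversity passes through an observed
count.

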