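# admixcape

Toolkit for characterizing admixture in diploid SNP genotype panels,
built for the analysis pattern of a recently founded, predominantly
European population carrying a few percent of African and Asian ancestry:
estimate **where** the ancestry came from, **when** it arrived, and
**what** it left in the genome.

It provides, as a library, a CLI (`admixcape`) and a one-command
pipeline:

- **QC / merging** — missingness, exact Hardy–Weinberg, strand-ambiguous
  SNP removal, flip-once dataset merging, PI-HAT relatedness pruning,
  local-ancestry masking (PED/MAP and VCF I/O).
- **f-statistics** — Weir–Cockerham FST, f3(T; A, B) and f4(A, B; C, D)
  with weighted block-jackknife standard errors, exhaustive f3 source
  screens, Fisher-exact carrier-frequency comparison.
- **Selection scans** — locus-specific branch length
  LSBL(T) = (F_ST(T,R1) + F_ST(T,R2) − F_ST(R1,R2))/2 with peak calling;
  EHH-based iHS and XP-EHH with the 200-kb gap rule.
- **Runs of homozygosity** — scanning-window caller (5 Mb windows, ≤1
  het, hit rate ≥ 0.05, segments ≥ 500 kb / ≥ 25 SNPs) with per-length-class
  summaries.
- **Shared private alleles** — exact rarefaction to g allele copies,
  P_present = 1 − C(n−k, g)/C(n, g), for population pairs against all others.
- **Admixture dating** — weighted-LD decay: per-distance-bin average of
  admixed genotype covariance weighted by reference frequency differences,
  fit to A·e^(−n·d) + c, where n is generations since the pulse; plus
  conversions to years/calendar dates and ancestor-slot equivalents
  (f·2^g of 2^g, truncated to one decimal).
- **Ancestry proportions** — supervised EM on the binomial likelihood
  with panel frequencies re-estimated jointly (SQUAREM-accelerated),
  G′-based mode matching of replicate Q matrices, and composition
  summaries (grouped means, per-individual bins, rank correlations).

Because the data that motivated this pipeline are access-restricted, the
package includes a first-class synthetic cohort generator
(`admixcape.simcohort`): Balding–Nichols source panels around a shared
ancestral spectrum plus a single-pulse admixed population whose ancestry
tracts form a Poisson/Markov mosaic (switch rate g per Morgan), emitting
phased haplotypes, genotypes, truth tracts and realized ancestry
fractions. Every estimator is tested by recovering the generator's truth;
see `docs/methods.md` for the model, defaults and their rationale, and
what a green test does and does not establish.

## Worked example

Run the full synthetic replica (simulate → QC → ancestry → f3/f4 → LSBL →
iHS/XP-EHH → RoH → private alleles → dating → report):

```
$ admixcape run --outdir out --seed 1
report written to out/report.json
dated admixture: 8.4 generations ago
```

The same run through the acceptance script prints:

```
simulated cohort: 600 samples, 20000 SNPs
non-European ancestry mean: 5.03%
dated admixture: 8.40 generations (~252 years before reference year)
```

Reading these numbers: the simulated world put 4.7% non-European ancestry
(in expectation) into 200 admixed individuals via a single pulse 9.3
generations before sampling. The supervised EM recovers a cohort mean of
5.03% (the realized truth of this seed, not the expectation, is the right
benchmark — the report's `mean_abs_error_vs_truth` is ~0.007), and the
weighted-LD decay dates the pulse at 8.40 generations, within the ~1
generation standard deviation such a 95/5 split supports. `out/` also
holds the per-stage TSVs: the Q matrix, f3 screen ranking, LSBL track and
peaks, scan tracks, RoH segments, the rarefaction curve and the binned
weighted-LD curve.

Library use, e.g. dating alone:

```python
from admixcape import simcohort as sc, weighted_ld_curve, fit_decay

specs = (sc.SourcePopSpec("R1", 0.2, 40), sc.SourcePopSpec("R2", 0.2, 40))
scen = sc.AdmixtureScenario(specs, (0.7, 0.3), 10.0, 300, n_snps=4000, seed=3)
gm = sc.simulate_cohort(scen).genotypes
fit = fit_decay(weighted_ld_curve(gm, "ADMIX", "R1", "R2"))
print(f"{fit.generations:.2f}")   # 9.35 — true value 10, SD ~0.7 at this scale
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the default end-to-end pipeline from scratch with the given seed
(artifacts under `scratch/acceptance_run/`, full report in
`scratch/acceptance_run/report.json`) and writes the results JSON to
`--out`.
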