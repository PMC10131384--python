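# sweepdriver

Two-level selection analysis for cancer driver genes: a recent-selection
genome scan on phased population haplotypes, plus the statistical decision
layers that accompany it across evolutionary timescales.

## Who this is for

Population geneticists and cancer-evolution researchers who want to ask, on
phased cohort data (or fully synthetic stand-ins), whether specific loci —
e.g. exonic SNPs of cancer driver genes — show the signature of recent
positive selection in particular populations, and whether longer-timescale
protein-level selection and present-day incidence differences line up with
those signals.

## What it computes

**Recent-selection scan** (modules `popio`, `haplostats`, `diffstats`,
`scan`, `pipeline`):

- **EHH / iHH / iHS.** Extended haplotype homozygosity around a core SNP,
  `EHH(j) = Σ_h C(k_h,2)/C(n,2)` over carrier sub-haplotype groups;
  iHH is its trapezoidal integral against physical distance per arm
  (truncated at EHH < 0.05); the integrated haplotype score is
  `iHS = ln(iHH_ancestral / iHH_derived)`, standardized within
  derived-allele-frequency bins of the genome-wide empirical distribution.
- **xpEHH.** `ln(iHH_A / iHH_B)` between two populations, pooled alleles,
  both areas integrated over the boundary set by the two populations'
  combined EHH; positive values mean longer haplotypes in population A.
- **Weir–Cockerham F_ST.** The 1984 two-population variance-component
  estimator `a/(a+b+c)` per SNP on diploid genotypes, with per-frequency-bin
  empirical top-5% outlier thresholds (F_ST co-varies with allele frequency,
  so each SNP is contrasted with its own frequency class).
- **PBS.** `(T_ts + T_to − T_so)/2` with `T = −ln(1 − F_ST)` for a
  (test, sister, outgroup) triplet, with genome-wide top-5% flags.
- **Windowed intersection rule.** SNPs with |standardized iHS| or |xpEHH| > 2
  clustered in top-1% 51-SNP windows count as haplotype-test hits; the final
  per-SNP, per-population call requires a haplotype hit **and** a high-F_ST
  flag (in every pairwise comparison involving that population, by default)
  **and** exonic location; PBS is attached as corroboration.

**Supporting layers:**

- `lrt` — branch-site likelihood-ratio decisions on externally fitted
  codon-model log-likelihood pairs: `LRT = 2(lnL_alt − lnL_null)`, p-value
  from the 50:50 chi-square(1)/point-mass mixture (`p/2`), Bonferroni
  correction per foreground branch.
- `incidence` — pooled two-proportion Z tests comparing case/person counts
  between populations, matrix output per sex.
- `synthpop` — a forward Wright–Fisher simulator (serial splits, migration,
  infinite-sites mutation, crossover recombination, optional hard sweep with
  restart-on-loss conditioning; coalescent initialization of the ancestral
  deme) that generates phased VCF + truth tables so the entire scan runs
  without any external data.

## Worked example

Simulate a three-deme cohort with a hard sweep (s = 0.05) planted in the
most recently founded deme, then run the full scan:

```python
import sweepdriver as sd

sim_cfg = sd.experiments.study_sim_config(seed=8, sweep=True)
matrices, truth = sd.synthpop.simulate(sim_cfg)
result = sd.pipeline.run_pipeline(matrices, sd.experiments.study_scan_config())

calls = result.candidates.query("final_call")
print(truth.focal_final_freqs)
print(calls[["pos", "population", "xpehh_hit", "fst_high", "pbs", "pbs_high"]])
```

Output:

```
{'pop0': 0.0, 'pop1': 0.004, 'pop2': 0.89}
      pos population  xpehh_hit  fst_high       pbs  pbs_high
8   85839       pop2       True      True  0.267424     False
14  91515       pop2       True      True  0.355339     False
17  91803       pop2       True      True  1.204078      True
```

The sweep allele rose to frequency 0.89 in the sweep deme (`pop2`) while
staying rare elsewhere, and the scan's final calls land on SNPs dragged by
the sweep within ~8–15 kb of the planted focal site (position 100,000) —
each an xpEHH hit inside a top window with top-5%-of-bin F_ST in both
pairwise comparisons involving `pop2`; the call nearest the focal site also
carries a top-5% PBS value. Not every replicate recovers the planted site:
at this reduced scale (a 200 kb region instead of a genome) the empirical
outlier thresholds compete sweep-dragged SNPs against each other, and the
acceptance script below measures the resulting operating characteristics
honestly.

The same stages are exposed as a CLI for file-based work:

```bash
sweepdriver simulate --config sim.yaml --out-prefix cohort
sweepdriver ihs --vcf cohort.vcf --panel cohort.panel.tsv --pop pop2 --out ihs.tsv
sweepdriver run-all --config scan.yaml --out-dir results/
sweepdriver lrt --table loglik.tsv --out lrt.tsv
sweepdriver incidence --table counts.tsv --out-prefix z
```

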