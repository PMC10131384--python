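# Methods

## The scan model

The package implements a two-level test for recent positive selection on
phased haplotypes. The haplotype level exploits the fact that a beneficial
allele rises in frequency faster than recombination can break up its
surrounding haplotype, leaving an unusually long, low-diversity haplotype.
EHH quantifies this: for the n haplotypes carrying a given core allele,
partitioned into identity groups of sizes k_h over the interval from the
core out to site j,

    EHH(j) = Σ_h C(k_h, 2) / C(n, 2),

i.e. the probability that two randomly drawn carriers are identical across
the interval. EHH is defined as 1 at the core (a zero-length interval) and
is non-increasing outward; the interval spans the core through j inclusive.
iHH integrates EHH against physical position separately per arm, dropping
the first extent whose EHH falls below the cutoff (no interpolation at the
boundary — simple, and identical between iHS and xpEHH). Distances are
physical bp; no genetic map is used.

- **iHS** = ln(iHH_ancestral / iHH_derived) at each core SNP with MAF ≥ 0.05
  in the focal population. Cores are skipped, with machine-readable reason
  codes, when an allele class has < 2 carriers, when an arm reaches the
  chromosome edge with EHH still above the cutoff, or when an inter-site gap
  exceeds `max_gap` (default 200 kb).
- **xpEHH** = ln(iHH_A / iHH_B), pooled alleles per population, both areas
  integrated over the common boundary where the two populations' *combined*
  EHH first drops below the cutoff. Because both areas share one boundary,
  the ratio remains comparable even when that boundary is the chromosome
  edge; edge-truncated cores are therefore scored by default (`trunc_ok`),
  while iHS — whose two allele classes decay at different rates — keeps the
  conservative edge-drop rule.

Raw scores are standardized against the genome-wide empirical distribution
within derived-allele-frequency bins (100 equal bins for iHS; a single
genome-wide bin for xpEHH; both configurable). Standardization uses
population moments (divide by n), so each bin's sample mean and variance of
the standardized scores are exactly 0 and 1; bins with fewer than
`min_per_bin` (20) defined scores are greedily merged with neighbors.

The differentiation level uses the Weir & Cockerham (1984) two-population
variance-component estimator on diploid genotypes (haplotype pairs 2i, 2i+1
recombined into dosages), F_ST = a/(a+b+c). Because F_ST and allele
frequency are strongly correlated, outlier calling is per frequency class:
defined F_ST values are binned by pooled minor allele frequency (width 0.10
over [0, 0.5] by default — wide enough that a few hundred sites support
each bin's percentile — sparse bins merged), and a SNP is flagged iff its
F_ST reaches the bin's k-th largest value, k = ceil(5% · n), ties included,
and strictly exceeds the bin minimum. Including ties matters because SNPs
in perfect LD carry identical F_ST: a tied maximal block must be flagged as
a unit, not excluded because the threshold order statistic lands on it. On
distinct data this flags exactly the top ceil(5% · n) values; an all-equal
bin flags nothing. PBS isolates allele-frequency change on the test population's
branch: T = −ln(1 − F_ST) (F_ST clamped into [0, 1−1e−12]; negative
estimates clamp to 0 for the transform only, the raw values are preserved
everywhere else), PBS = (T_test,sister + T_test,outgroup −
T_sister,outgroup)/2, flagged against a genome-wide top-5% threshold under
the same rank-with-ties rule. All
six role assignments of a four-population design are reached by relabeling;
the outgroup is a configuration label, never hard-coded.

## Windows and the decision rule

Haplotype scores cluster under sweeps, so single-SNP exceedances are
corroborated by their neighborhood: sliding (step-1) windows of 51
consecutive scored SNPs are ranked by their count of |standardized
score| > 2 members, pooled genome-wide per statistic and population (pair).
Window qualification defaults to a rank rule — the k = ceil(1% · n_windows)
largest counts qualify, ties at the k-th count included, zero counts never
qualify. On a long-tailed genome-scale count distribution this coincides
with the strict-percentile rule (also available as
`window_policy="strict-percentile"`); unlike it, the most extreme windows
still qualify when the outlier cluster itself spans more than 1% of all
windows, which is unavoidable when the scanned region is a few hundred kb
rather than a genome. A SNP is a haplotype-test hit iff it exceeds the
score cutoff *and* lies in a qualifying window.

The final call per SNP and population is the intersection

    final_call = (iHS hit OR xpEHH hit) AND fst_high AND exonic

with xpEHH hits attributed to the population on the positive side of the
score. `fst_high` requires the top-5%-of-bin flag in at least
`fst_min_pairs` pairwise comparisons involving the attributed population;
the default is *all* such pairs (both, in a three-population design).
Requiring breadth suppresses single-pair drift outliers, which at desk
scale otherwise dominate the false calls; a lenient any-one-pair mode is a
flag away. PBS is corroborative by default — candidates lacking a top-5%
PBS value are reported with `pbs_high = False` rather than vetoed — with a
`pbs_strict` mode that makes it gating. Exon membership comes from BED
intervals (0-based half-open) tested against the VCF's 1-based positions;
the conversion happens in exactly one place.

## The synthetic cohort

`synthpop` is a discrete-generation forward Wright–Fisher simulator. Each
deme holds N diploids; each child gamete picks a diploid parent (uniformly,
or proportional to fitness 1/1+s/1+2s at the focal site in the sweep deme),
recombines the parent's haplotypes with Poisson(rec_rate × L) crossovers,
and gains Poisson(mu × L) new infinite-sites mutations. Demes split
serially — deme i+1 is founded as a full copy of deme i, without a
bottleneck — and exchange migrants at a per-gamete rate thereafter. The
ancestral state of every site is the founding population's allele, so
polarization of the emitted VCF (INFO/AA) is exact by construction. Sweeps
start as a single copy; if the allele is lost the sweep phase restarts from
an onset snapshot (bounded retries), so surviving replicates carry a
detectable signal. Random streams are keyed per (attempt, deme, generation)
off the master seed: adding a deme or retrying a sweep does not perturb the
other streams, and a fixed seed reproduces output bit-for-bit.

The ancestral deme is initialized from a neutral coalescent sample
(msprime) by default — the standard recapitation-style shortcut that starts
the forward phase at mutation–drift equilibrium instead of spending ~8N
generations of burn-in; a pure-forward `founder` initialization is kept and
is the one validated against the coalescent expectation (mean pairwise
diversity 4NμL) in the test suite.

Default study conditions (N = 500 diploids per deme, L = 2×10⁵ bp, splits
600 and 300 generations before present, migration 10⁻³, sweep s = 0.05 at
onset 200 in the most recent deme, 100 sampled haplotypes per deme) give
human-like differentiation (pairwise F_ST roughly 0.10–0.25). The scaled
mutation rate 2.5×10⁻⁷/bp/generation (θ ≈ 5×10⁻⁴/bp) is human-like; the
scaled recombination rate is deliberately higher, 2×10⁻⁶/bp, so that the
sweep footprint — roughly s/(r·ln 2Ns) ≈ 6 kb per side — occupies a small
fraction of the region. Genome-wide empirical standardization and per-bin
outlier thresholds presuppose a predominantly neutral background; a whole
genome provides it for free, a 200 kb region must buy it with a faster
recombination clock. With the footprint at human-scale r (≈50 kb per side)
the sweep saturates the region and its own signal is absorbed into the
empirical null — a property of the study design at reduced scale, not of
the statistics.

What the generator does *not* emulate: variable recombination and mutation
rate along the sequence, genotyping or phasing error, overlapping or soft
sweeps, background selection, and realistic human demographic detail
(bottlenecks, growth, admixture). Passing tests therefore demonstrate that
the statistics and decision rules behave correctly under a clean
Wright–Fisher null and a clean hard sweep; they do not calibrate error
rates for real cohorts.

## Supporting layers

The branch-site LRT layer consumes log-likelihood pairs produced by
external codon-model fits (alternative model with a positively selected
foreground site class vs a null with that class's ω fixed at 1);
LRT = 2(lnL_alt − lnL_null), negative values (optimizer noise) are reported
and flagged, p = ½·P(χ²₁ > max(stat, 0)) because the null is a 50:50
mixture of χ²₁ and a point mass at zero, and Bonferroni correction is
applied per foreground branch across genes (family size configurable; the
natural reading when several lineages are tested separately). The
incidence layer computes the pooled two-proportion Z statistic on crude
case/person counts, keeping the signed value (positive when the first
population's proportion is higher) alongside the two-sided normal p; the
bundled four-region table is a synthetic reconstruction from published
age-standardized rates treated as crude, adequate for the test's input
contract but not registry microdata.

## Numerical and edge-case policy

- Empirical outlier thresholds are rank-based (k-th largest, ties
  included, degenerate distributions flag nothing); reported thresholds
  are the k-th largest value used.
- Undefined values (monomorphic F_ST, zero-area iHH, zero-variance bins)
  propagate as NaN with reason codes; they are excluded from empirical
  distributions and cannot be flagged or called.
- The EHH inner loop is a compiled (numba) group-splitting walk whose
  arithmetic the tests pin against an O(n²) all-pairs oracle exactly.
- All pipeline outputs are deterministic functions of inputs and
  configuration; output TSVs embed the resolved configuration in '#'
  header lines.

## Problem sizes used by the test suite

Unit tests run on matrices of tens of haplotypes and tens-to-hundreds of
sites. The stochastic calibrations use: 200 founder-initialized replicates
at N = 25, L = 2 kb for the diversity expectation; 100 replicates per split
time at N = 50 for the F_ST ranking; 50 replicate pairs at N = 500,
L = 2×10⁵ for the sweep-signal invariants; and 50 sweep + 50 neutral
replicates at the full study conditions for sweep recovery and false-call
control. These sizes keep the default suite within a desktop-scale run
while leaving each stochastic check adequately powered.

## Known limitations

- Per-SNP intersection with per-bin top-5% F_ST competes sweep-dragged SNPs
  against each other inside small frequency bins when the scanned region is
  short; power at desk scale is accordingly below what a genome-scale scan
  of the same statistics would achieve. Three scale effects compound on a
  200 kb region: the swept haplotype class is near-identical across much of
  the region (all ancestry is recent at N = 500), so xpEHH scores at the
  fixed-difference SNPs are diluted while the score peaks sit on the sweep
  flanks; the frequency bins hold only ~100–200 sites each, so the top-5%
  F_ST flags cover a sliver of the sweep cluster; and the final call
  requires hit and flag on the same SNP. The acceptance script measures the
  resulting operating characteristics (sweep-recovery and neutral
  false-call rates) on 50+50 replicates; recovery at these conditions runs
  well below the near-certain detection a genome-scale scan of a comparable
  sweep would give, while neutral false calls stay rare.
- xpEHH edge truncation (`trunc_ok`) slightly biases scores at cores whose
  combined EHH never reaches the cutoff; the bias is shared by both
  populations and cancels to first order in the log-ratio.
- The Weir–Cockerham estimator is the two-population form; multi-population
  F_ST and Hudson/Nei estimators are out of scope.
- The LRT layer performs no model fitting: its guarantees extend only to
  the decision arithmetic on supplied log-likelihoods.
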