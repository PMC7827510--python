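# Methods

`sweepscan` detects recent positive selection from a two-group contrast
within one population (group A vs group B, e.g. low- vs high-fecundity
animals), starting from a multi-sample VCF of biallelic SNPs. This note
documents the statistical model behind each component, the defaults and
why they were chosen, what the built-in simulator does and does not
emulate, and the numerical conventions.

## Differentiation: per-SNP FST and windowed Z(FST)

The default estimator is the Weir–Cockerham (1984) two-population
variance-components estimator

    theta = a / (a + b + c)

computed per SNP from the called diploid sample sizes, allele
frequencies and observed heterozygote frequencies of the two groups
(components: a among populations, b among individuals within
populations, c within individuals). It is the canonical estimator that
corrects for small, unequal sample sizes — which matters at n = 5 per
group. A Hudson-type estimator with the Bhatia et al. (2013)
finite-sample correction is selectable (`estimator="hudson"`).

Conventions:

- Sites with fewer than two called genotypes in either group are
  undefined (NaN), never zero.
- Sites monomorphic in both groups are defined as 0 (all three
  components vanish).
- Negative per-site estimates are **kept**: clamping at zero before
  window averaging biases window means upward.
- Per-site values are averaged in fixed windows (default 50 kb,
  non-overlapping, at least `min_snps = 10` defined SNPs per window;
  sparser windows are NaN and excluded from normalization). The window
  track is then Z-transformed genome-wide — all chromosomes pooled,
  sample standard deviation (n−1) — and windows with Z(FST) above the
  threshold (default 5) are merged into sweep regions.

A caveat worth knowing: the *mean of per-site theta ratios* is not an
unbiased genome-wide FST. Each site's theta is a ratio of noisy
components, and with 5v5 samples the mean of ratios sits a few parts per
thousand below zero even for identical populations. The unbiased
genome-wide aggregate is the ratio of summed components,
`popgen.fst_genomewide` = Σa / Σ(a+b+c), and that is what the neutrality
checks use. The windowed scan is unaffected: the Z-transform removes any
constant offset.

## Haplotype length: EHH, iHH, XP-EHH

EHH at marker x for a core allele is the probability that two randomly
drawn carrier haplotypes are identical over every marker from the core
to x; computed by partition refinement, EHH(x) = Σ_h C(k_h, 2)/C(n, 2)
over haplotype classes h. iHH is the trapezoidal integral of the EHH
curve against physical distance (bp), left plus right of the core.
Extension stops once EHH drops below a cutoff (default 0.05, the
reference convention); the first below-cutoff marker is still included
as the final trapezoid endpoint. Curves reaching a chromosome end are
integrated to the terminal marker with no edge correction — a known
boundary caveat for cores near contig ends.

XP-EHH compares groups site by site:

    raw(s) = ln iHH_A(s) − ln iHH_B(s)

where each group's per-site iHH pools both core alleles (the partition
starts split by the core allele, so EHH(0) is the core-site
homozygosity) — the standard cross-population convention, as opposed to
the allele-specific curves of iHS, which remain available through
`ehh`/`ihh`. Computing the difference of logarithms (not the log of the
ratio) keeps the group-swap antisymmetry raw_AB = −raw_BA bit-exact.
Raw scores are normalized to mean 0, sd 1 over all defined sites
genome-wide in one pass (no allele-frequency binning: XP-EHH, unlike
iHS, is conventionally normalized unbinned). Positive scores mean
longer haplotypes — a sweep — in group A.

Windowed XP-EHH (default 50 kb non-overlapping, `min_snps = 10`)
averages the already-normalized per-site scores, and the fixed
threshold |window mean| > 2 calls regions; window means are not
re-standardized. Region direction follows the sign (+ → A, − → B) and a
run of significant windows is broken where the sign flips, so each
region names the selected group. No genetic map is consumed; physical
distance is the integration measure. The inner partition loop is JIT
compiled with numba when available, with a bit-identical numpy
fallback.

## Pooled heterozygosity Hp

Per window (default 10 kb, non-overlapping), within one group:

    Hp = 2 ΣnMAJ ΣnMIN / (ΣnMAJ + ΣnMIN)^2

where ΣnMAJ and ΣnMIN sum the major- and minor-allele counts of the
window's SNPs over non-missing calls. Major/minor is resolved per site
*within the analyzed group*; an exact 50/50 tie contributes equally to
either sum, so the tie-break (ref as major) cannot change Hp. Hp lies
in [0, 0.5], reaching 0.5 iff the summed counts balance; hard sweeps
depress it in the selected group.

## Tajima's D

Standard 1989 formulation per window (default 50 kb):
D = (π − θ_W)/sqrt(e1·S + e2·S(S−1)), with π the mean pairwise
difference accumulated from per-site allele frequencies using each
site's called-copy count (the unbiased 2·c_alt·c_ref/(n(n−1)) form) and
the a1…e2 constants evaluated at the window median of called copies
over segregating sites. Recomputing constants per site would change D
only in heavily missing data; the median-n shortcut is the documented
approximation, and the simulator's default has no missingness. Windows
with S = 0 are undefined.

## LD decay

r² between phased sites from haplotype frequencies,
r² = (p_AB − p_A p_B)² / (p_A q_A p_B q_B), with |D′| reported
alongside. `ld_decay` subsamples sites passing a MAF filter (default
0.1) with a seeded RNG, scores all intra-chromosome pairs closer than
the largest bin edge, and reports mean r² per left-closed right-open
distance bin. On simulator output, note that background sites are
unlinked by construction: distance decay is only visible in
sweep-bearing configurations.

## Region → gene layer

Genes (BED or GFF3 `gene` features) overlap a region if the half-open
intervals share ≥ 1 bp; gene sets are deduplicated by id, and the two
methods' sets are combined by union and intersection. Protein-altering
SNPs (nonsynonymous, stopgain, stoploss, frameshift — read from input
annotation, never computed) inside candidate regions are ranked by
descending single-site FST with positional tie-break. Enrichment is
database-free: user-supplied term→gene maps are scored with the
one-sided hypergeometric tail and Benjamini–Hochberg adjustment
(statsmodels). Group genotype-distribution differences at a candidate
SNP use Fisher's exact test (scipy for 2×2; exact conditional
enumeration for 2×3, since no closed form is available in scipy);
chi-square is selectable. Fisher is the default because per-genotype
counts at a single SNP in small cohorts are far from the chi-square
regime.

## Trees

The distance is allele-sharing on dosages, d(i,j) = mean over co-called
sites of |dos_i − dos_j|/2 — a similarity measure appropriate for
within-population SNP data, not a substitution-model distance.
Neighbor joining is the Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion; ties break on the smallest index pair, so
results are deterministic, and negative branch-length estimates are
clamped to zero with a per-node flag. On additive inputs the
reconstruction is exact (tested to 1e-9 against path lengths and
against scikit-bio's NJ).

The *sweep-SNP tree* contrasts with the whole-genome tree: its sites
are SNPs inside called regions **selected by FST score** (single-site
FST ≥ 0.25, Wright's classical "very great differentiation" level).
Region membership alone keeps the many neutral bystander SNPs of a
50 kb window; at realistic sweep strength (carrier frequencies 0.9 vs
0.1, leaving about one admixed sample per group) those bystanders
dilute the between-group signal enough that the expected two-cluster
topology appears in only ~2/3 of simulations, while FST-selected sites
recover it in ≥ 90%.

## The simulator

A generative haplotype-copying model, not a coalescent. Per
chromosome: SNP positions from a Poisson process (mean spacing 200 bp);
a shared derived-allele frequency per site drawn from a neutral-shaped
SFS (weight k^−1 over derived copy counts k = 1…2N−1, exponent
configurable); every haplotype draws background alleles independently
from that shared frequency, so neutral FST ≈ 0 in expectation and
*all* linkage comes from planted cores. Inside each sweep interval a
fixed random core haplotype exists; each haplotype of group g copies it
with probability `carrier_freq(g)` (defaults 0.9 selected / 0.1 other,
two groups of five diploids), with each copied allele flipped at rate
0.01. Ref/alt pairs are drawn with P(transition) = 0.7, giving ts/tv
≈ 2.3, the mammalian genome-wide value. Genotypes are haplotype-pair
sums; optional uniform missingness exercises missing-data paths
(default 0).

What it does *not* emulate — and hence what passing tests do not show
about real data: neutral background LD and its decay, recombination
gradients at sweep edges, demography and population structure,
soft/partial sweeps, genotyping error, and reference bias. The
simulator's job is to provide planted, parameterized signal structure
(high FST, low Hp, long shared haplotypes) with exact ground truth, so
detection logic and sign conventions are testable end to end.

## Problem sizes and checks

The packaged verification runs use desk-scale genomes chosen to keep
every statistic well populated: single- or two-chromosome genomes of
2 Mb (≈ 10,000 SNPs each, 40 windows of 50 kb), 50 seeded replicates
for sweep recovery and Hp depression, 20 for the tree contrast, and
exhaustive or 100-case random comparisons against independently coded
oracles for the FST, Tajima, EHH/iHH, BH and Fisher kernels.
`scripts/acceptance.py` re-runs all of it from scratch and writes the
measured rates as JSON.

## Known limitations

- XP-EHH needs fully phased, complete haplotypes; phasing itself is out
  of scope (consume phased VCFs or simulator output).
- Only two groups are supported; multi-population FST is out of scope.
- Windows are physical (bp); no genetic-map support.
- The 2×3 exact test enumerates tables and is meant for small cohort
  counts, not biobank-scale tables.
- Multi-allelic records are skipped, not decomposed.
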