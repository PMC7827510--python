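# sweepscan

Selective-sweep detection for a **two-group contrast within one
population** — for example five high- vs five low-fecundity animals
resequenced from a single breed. Given a multi-sample VCF of biallelic
SNPs and a sample→group assignment, `sweepscan` computes the classical
sweep-scan statistics, calls candidate regions, intersects them with
gene annotation, and contrasts population structure inside vs outside
the candidate regions.

The toolkit is aimed at population-genetics practitioners who want the
whole published scan protocol — per-SNP **Weir–Cockerham F_ST** averaged
over 50 kb windows and Z-transformed with a Z(F_ST) > 5 cutoff, per-site
**XP-EHH** from phased haplotypes averaged over 50 kb windows with an
|XP-EHH| > 2 cutoff, **pooled heterozygosity H_p** in 10 kb windows,
**Tajima's D**, **LD r² decay**, and a **neighbor-joining tree** from
allele-sharing distances — as one reproducible, tested package with a
built-in simulator that plants hard sweeps with known ground truth.

## The statistics

- **F_ST (Weir–Cockerham 1984)**: per-SNP variance-components estimator
  θ = a/(a+b+c), the canonical small-sample correction (a Hudson/Bhatia
  estimator is selectable). Window means are Z-transformed genome-wide;
  Z(F_ST) > 5 windows merge into regions.
- **XP-EHH**: per site, ln iHH_A − ln iHH_B, where iHH integrates the
  extended-haplotype-homozygosity decay curve against distance; scores
  are normalized genome-wide. Positive ⇒ selection in group A, negative
  ⇒ group B; |windowed score| > 2 calls directional regions.
- **H_p** = 2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)² over a window's summed
  major/minor allele counts — depressed where a sweep has fixed a
  haplotype.
- **Tajima's D**, **LD r² decay**, **NJ trees** (allele-sharing
  distance, Saitou–Nei joining, Newick output) complete the protocol.

See `docs/methods.md` for definitions, conventions and caveats.

## Worked example

Simulate a study-like dataset — 5 vs 5 diploids, two 2 Mb chromosomes,
one 50 kb sweep planted in group B at chr1:975,000–1,025,000 — then run
the full scan:

```bash
sweepscan simulate --seed 11 --out sim.vcf --truth-bed truth.bed
# wrote sim.vcf (19846 SNPs, 10 samples)

printf 'A%d\tA\n' 1 2 3 4 5 >  groups.tsv
printf 'B%d\tB\n' 1 2 3 4 5 >> groups.tsv

sweepscan scan --vcf sim.vcf --groups groups.tsv --out-dir out
# {"fst": 1, "xpehh": 1, "xpehh_direction_A": 0, "xpehh_direction_B": 1}
```

The summary line says each method called exactly one region, and the
XP-EHH region's direction is group B — the group the sweep was planted
in. The region files pin it to the right place (BED, 0-based half-open;
columns: method, peak value, direction, member windows):

```
$ cat out/xpehh_regions.bed
chr1	950000	1050000	XPEHH	-2.4896375269352404	B	2
$ cat out/fst_regions.bed
chr1	950000	1000000	FST	5.364633082538269	nondirectional	1
```

Both overlap the planted truth interval (`truth.bed`:
`chr1 975000 1025000 sweep_B`). The negative peak XP-EHH window mean
(−2.49) means group B carries the unusually long haplotypes; the peak
Z(F_ST) of 5.36 is the differentiation outlier. `out/` also contains
the windowed Z(F_ST)/XP-EHH/H_p/Tajima-D tracks (TSV, 1-based
inclusive), per-site F_ST, gene lists when an annotation is supplied,
and two Newick trees: in this run `summary.json` reports
`"sweep_tree_separates_groups": true` and
`"whole_genome_tree_separates_groups": false` — sweep-region SNPs split
the groups into two clean clusters while genome-wide SNPs leave them
mixed, the expected signature of recent within-population selection.

Every step is also callable as a library function
(`sweepscan.popgen.fst_per_site`, `sweepscan.haplotype.xpehh`,
`sweepscan.phylo.neighbor_joining`, ...) or as individual CLI verbs
(`fst`, `xpehh`, `hp`, `tajima`, `ld`, `tree`, `enrich`).

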