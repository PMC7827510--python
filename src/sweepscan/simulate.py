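"""Two-group diploid sweep simulator with ground truth.

A generative haplotype-copying model, not a coalescent: background sites
are unlinked, with a shared derived-allele frequency per site drawn from
a neutral-shaped site-frequency spectrum (weight 1/k over derived copy
counts), so neutral FST is ~0 in expectation and all linkage in the data
comes from planted sweep cores. Inside a sweep interval, haplotypes of
each group copy a fixed core haplotype with the group's carrier
frequency (each copied allele flipped with a small per-site rate),
producing the hard-sweep signal triad: elevated FST, depressed pooled
heterozygosity, and extended haplotype homozygosity in the selected
group.

Defaults emulate the contrast the statistics are designed for: two
groups of five diploid samples, ~200 bp SNP spacing, one 50 kb sweep in
group B at carrier frequencies 0.9 (selected) vs 0.1 (other).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan.model import MISSING, GenotypeMatrix, HaplotypeMatrix

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
# P(transition) = 0.7 gives ts/tv ~= 2.3, the mammalian genome-wide value
_P_TRANSITION = 0.7


@dataclass
class SweepSpec:
    """One planted hard sweep."""

    chrom: str
    center: int  # bp
    half_width: int  # bp
    selected_group: str = "B"
    carrier_freq_selected: float = 0.9
    carrier_freq_other: float = 0.1
    core_mutation_rate: float = 0.01

    def __post_init__(self):
        if not (0 <= self.carrier_freq_other <= 1 and 0 <= self.carrier_freq_selected <= 1):
            raise ValueError("carrier frequencies must be in [0, 1]")
        if self.carrier_freq_selected <= self.carrier_freq_other:
            raise ValueError("carrier_freq_selected must exceed carrier_freq_other")
        if self.selected_group not in ("A", "B"):
            raise ValueError("selected_group must be A or B")

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width


@dataclass
class SimulationConfig:
    seed: int
    n_per_group: int = 5
    chrom_specs: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000), ("chr2", 2_000_000)]
    )
    snp_spacing: int = 200  # mean bp between SNPs (Poisson process)
    sfs_shape: float = 1.0  # SFS weight exponent: P(k copies) prop. to k^-shape
    sweeps: list[SweepSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    effect_class_rate: float = 0.0  # fraction of sites given a coding annotation

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name, length in self.chrom_specs:
            if length < 10 * self.snp_spacing:
                raise ValueError(f"chromosome {name} too short for snp_spacing")
        by_chrom: dict[str, list[SweepSpec]] = {}
        for sw in self.sweeps:
            by_chrom.setdefault(sw.chrom, []).append(sw)
        for chrom, sws in by_chrom.items():
            sws = sorted(sws, key=lambda s: s.start)
            for a, b in zip(sws, sws[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping sweep intervals on {chrom}")


def default_config(seed: int, n_chroms: int = 2, chrom_length: int = 2_000_000,
                   sweep_on: str = "chr1") -> SimulationConfig:
    """The default study-like configuration: 5 vs 5 diploids, 2 x 2 Mb
    chromosomes, one 50 kb sweep in group B centered on chr1."""
    return SimulationConfig(
        seed=seed,
        chrom_specs=[(f"chr{i+1}", chrom_length) for i in range(n_chroms)],
        sweeps=[
            SweepSpec(chrom=sweep_on, center=chrom_length // 2, half_width=25_000)
        ],
    )


@dataclass
class SweepTruth:
    """Planted intervals: (chrom, start, end, selected_group), 0-based
    half-open bp."""

    intervals: list[tuple[str, int, int, str]]

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, grp in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\tsweep_{grp}\n")


@dataclass
class SimResult:
    gm: GenotypeMatrix
    haplotypes: dict[str, HaplotypeMatrix]
    truth: SweepTruth
    config: SimulationConfig


_EFFECTS = ["synonymous", "nonsynonymous", "stopgain", "stoploss", "other"]
_EFFECT_W = [0.55, 0.4, 0.02, 0.01, 0.02]


def simulate(config: SimulationConfig) -> SimResult:
    """Generate genotypes, phased haplotypes and sweep ground truth.

    Fully reproducible from config.seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    samples = [f"A{i+1}" for i in range(n)] + [f"B{i+1}" for i in range(n)]
    groups = {s: s[0] for s in samples}
    n_hap = 4 * n  # total haplotypes over both groups
    group_of_hap = np.array([0] * (2 * n) + [1] * (2 * n))

    # background SFS over derived copy counts 1..n_hap-1, weight k^-shape
    k = np.arange(1, n_hap)
    sfs_w = k.astype(float) ** (-config.sfs_shape)
    sfs_w /= sfs_w.sum()

    site_frames = []
    geno_blocks = []
    hap_mats: dict[str, HaplotypeMatrix] = {}
    truth_rows = []

    for chrom, length in config.chrom_specs:
        gaps = rng.exponential(scale=config.snp_spacing, size=int(2.5 * length / config.snp_spacing))
        pos = np.unique(np.maximum(1, np.cumsum(gaps).astype(np.int64) + 1))
        pos = pos[pos <= length]
        m = len(pos)
        freq = k[rng.choice(len(k), size=m, p=sfs_w)] / n_hap
        haps = (rng.random((n_hap, m)) < freq).astype(np.uint8)

        for sw in (s for s in config.sweeps if s.chrom == chrom):
            in_sweep = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
            idx = np.flatnonzero(in_sweep)
            if len(idx) == 0:
                continue
            core = (rng.random(len(idx)) < freq[idx]).astype(np.uint8)
            sel = 0 if sw.selected_group == "A" else 1
            carrier_p = np.where(
                group_of_hap == sel, sw.carrier_freq_selected, sw.carrier_freq_other
            )
            carriers = rng.random(n_hap) < carrier_p
            flips = rng.random((int(carriers.sum()), len(idx))) < sw.core_mutation_rate
            haps[np.ix_(carriers, idx)] = core[None, :] ^ flips.astype(np.uint8)
            truth_rows.append((chrom, sw.start, sw.end, sw.selected_group))

        ref = rng.choice(list("ACGT"), size=m)
        alt = np.empty(m, dtype=object)
        ts = rng.random(m) < _P_TRANSITION
        tv_pick = rng.integers(0, 2, size=m)
        for i in range(m):
            alt[i] = _TRANSITION[ref[i]] if ts[i] else _TRANSVERSIONS[ref[i]][tv_pick[i]]

        effect = np.full(m, None, dtype=object)
        if config.effect_class_rate > 0:
            coding = rng.random(m) < config.effect_class_rate
            effect[coding] = rng.choice(_EFFECTS, size=int(coding.sum()), p=_EFFECT_W)

        geno = (haps[0::2] + haps[1::2]).astype(np.int8)
        if config.missing_rate > 0:
            miss = rng.random(geno.shape) < config.missing_rate
            geno[miss] = MISSING

        site_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "effect_class": effect}
            )
        )
        geno_blocks.append(geno)
        hap_mats[chrom] = HaplotypeMatrix(
            chrom=chrom,
            positions=pos,
            haplotypes=haps,
            sample_of=[s for s in samples for _ in range(2)],
            chrom_length=length,
        )

    gm = GenotypeMatrix(
        samples=samples,
        sites=pd.concat(site_frames, ignore_index=True),
        genotypes=np.hstack(geno_blocks),
        groups=groups,
        chrom_lengths={c: l for c, l in config.chrom_specs},
    )
    return SimResult(gm=gm, haplotypes=hap_mats, truth=SweepTruth(truth_rows), config=config)


def split_haplotypes_by_group(
    hm: HaplotypeMatrix, groups: dict[str, str]
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    a = hm.subset_samples({s for s, g in groups.items() if g == "A"})
    b = hm.subset_samples({s for s, g in groups.items() if g == "B"})
    return a, b


def _config_json(config: SimulationConfig) -> str:
    d = asdict(config)
    d["chrom_specs"] = [list(cl) for cl in d["chrom_specs"]]
    return json.dumps(d, separators=(",", ":"))


def write_simulated_vcf(sim: SimResult, path, truth_bed: str | Path | None = None) -> None:
    """Write the simulation as a phased VCF 4.2 (plus optional truth BED).

    The full config is serialized into the header for provenance; the
    file round-trips losslessly through read_vcf / read_phased (phased
    reading requires missing_rate = 0).
    """
    gm = sim.gm
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sim.config.chrom_specs:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(f"##sweepscan_config={_config_json(sim.config)}\n")
        fh.write('##INFO=<ID=ANN_CLASS,Number=1,Type=String,Description="Effect class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        offset = {}
        for chrom, hm in sim.haplotypes.items():
            offset[chrom] = {int(p): i for i, p in enumerate(hm.positions)}
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            chrom, pos = row["chrom"], int(row["pos"])
            hm = sim.haplotypes[chrom]
            i_site = offset[chrom][pos]
            ec = row["effect_class"]
            info = f"ANN_CLASS={ec}" if ec is not None and not pd.isna(ec) else "."
            gts = []
            for s_i in range(gm.n_samples):
                if gm.genotypes[s_i, j] == MISSING:
                    gts.append("./.")
                else:
                    a = hm.haplotypes[2 * s_i, i_site]
                    b = hm.haplotypes[2 * s_i + 1, i_site]
                    gts.append(f"{a}|{b}")
            fh.write(
                f"{chrom}\t{pos}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts) + "\n"
            )
    if truth_bed is not None:
        sim.truth.write_bed(truth_bed)
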