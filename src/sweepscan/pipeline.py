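"""End-to-end scan: filters -> FST/Hp/Tajima tracks -> XP-EHH ->
Z-transform and thresholds -> regions -> genes -> trees -> summary.

Every default mirrors the published scan protocol: 50 kb windows for FST
and XP-EHH, 10 kb for Hp, thresholds Z(FST) > 5 and |XP-EHH| > 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan import __version__
from sweepscan.model import GenotypeMatrix, HaplotypeMatrix
from sweepscan import vcf_io, popgen, haplotype, sweeps, phylo
from sweepscan.simulate import split_haplotypes_by_group

log = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    vcf: str | None = None
    group_file: str | None = None
    annotation: str | None = None
    term_map: str | None = None
    out_dir: str = "scan_out"
    fst_window: int = 50_000
    fst_step: int | None = None  # None -> non-overlapping
    hp_window: int = 10_000
    xpehh_window: int = 50_000
    xpehh_step: int | None = None
    tajima_window: int = 50_000
    zfst_threshold: float = 5.0
    xpehh_abs_threshold: float = 2.0
    fst_estimator: str = "wc"
    min_snps: int = 10
    min_maf: float = 0.0
    max_missing: float = 1.0
    ehh_cutoff: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.zfst_threshold <= 0 or self.xpehh_abs_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for w in (self.fst_window, self.hp_window, self.xpehh_window, self.tajima_window):
            if w < 1_000:
                raise ValueError("windows must be >= 1000 bp")


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV term<TAB>gene, one pair per line."""
    term_map: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, gene = line.split("\t")[:2]
        term_map.setdefault(term, set()).add(gene)
    return term_map


def run_scan(
    config: ScanConfig,
    gm: GenotypeMatrix | None = None,
    haplotypes: dict[str, HaplotypeMatrix] | None = None,
) -> dict:
    """Run the full two-group sweep scan; returns the summary dict.

    Inputs come either from config paths (VCF + group file) or as
    in-memory objects (e.g. straight from the simulator). All outputs
    land in config.out_dir.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if gm is None:
        if not config.vcf or not config.group_file:
            raise ValueError("need either in-memory data or vcf + group_file paths")
        groups = vcf_io.read_group_file(config.group_file)
        gm = vcf_io.read_vcf(config.vcf, groups)
        try:
            haplotypes = vcf_io.read_phased(config.vcf, groups)
        except vcf_io.VcfIOError as exc:
            log.warning("phased haplotypes unavailable (%s); skipping XP-EHH", exc)
            haplotypes = None
    if config.min_maf > 0 or config.max_missing < 1:
        gm = vcf_io.filter_sites(gm, config.min_maf, config.max_missing)

    summary: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "n_samples": gm.n_samples,
        "n_sites": gm.n_sites,
    }

    # --- FST branch -------------------------------------------------------
    fst_track = popgen.fst_per_site(gm, estimator=config.fst_estimator)
    _write_site_track(fst_track, out / "fst_per_site.tsv")
    fst_win = popgen.window_mean(
        fst_track, config.fst_window, config.fst_step, config.min_snps
    )
    zfst = popgen.z_transform(fst_win)
    vcf_io.write_track(zfst, out / "zfst_windows.tsv", "TSV")
    fst_regions = sweeps.call_regions(
        zfst, config.zfst_threshold, mode="greater", method="FST"
    )
    sweeps.write_regions(fst_regions, out / "fst_regions.bed")

    # --- Hp and Tajima's D ------------------------------------------------
    for grp in ("A", "B"):
        hp = popgen.pooled_heterozygosity(gm, grp, config.hp_window)
        vcf_io.write_track(hp, out / f"hp_{grp}.tsv", "TSV")
        td = popgen.tajimas_d(gm, grp, config.tajima_window)
        vcf_io.write_track(td, out / f"tajimas_d_{grp}.tsv", "TSV")

    # --- XP-EHH branch ----------------------------------------------------
    xpehh_regions: list[sweeps.SweepRegion] = []
    if haplotypes:
        tracks = []
        for chrom in sorted(haplotypes):
            hmA, hmB = split_haplotypes_by_group(haplotypes[chrom], gm.groups)
            tracks.append(haplotype.xpehh(hmA, hmB, config.ehh_cutoff))
        xp_win = haplotype.window_xpehh_multi(
            tracks, config.xpehh_window, config.xpehh_step, config.min_snps
        )
        vcf_io.write_track(xp_win, out / "xpehh_windows.tsv", "TSV")
        xpehh_regions = sweeps.call_regions(
            xp_win, config.xpehh_abs_threshold, mode="abs_greater", method="XPEHH"
        )
        sweeps.write_regions(xpehh_regions, out / "xpehh_regions.bed")

    # --- genes, variants, enrichment -------------------------------------
    genes_fst: set[str] = set()
    genes_xp: set[str] = set()
    if config.annotation:
        annotation = sweeps.read_annotation(config.annotation)
        genes_fst = sweeps.genes_in_regions(fst_regions, annotation)
        genes_xp = sweeps.genes_in_regions(xpehh_regions, annotation)
        union, inter = sweeps.combine_methods(genes_fst, genes_xp)
        for name, gene_set in (
            ("genes_fst", genes_fst), ("genes_xpehh", genes_xp),
            ("genes_union", union), ("genes_intersection", inter),
        ):
            (out / f"{name}.txt").write_text("".join(g + "\n" for g in sorted(gene_set)))
        summary["n_genes"] = {
            "fst": len(genes_fst), "xpehh": len(genes_xp),
            "union": len(union), "intersection": len(inter),
        }
        if config.term_map and union:
            universe = {g.gene_id for g in annotation}
            table = sweeps.enrich(union & universe, universe,
                                  read_term_map(config.term_map))
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        ranked = sweeps.rank_coding_variants(
            gm, fst_track, fst_regions + xpehh_regions
        )
        ranked.to_csv(out / "ranked_coding_variants.tsv", sep="\t", index=False)

    # --- trees ------------------------------------------------------------
    if gm.n_samples >= 3:
        dm_all = phylo.pairwise_distance(gm)
        tree_all = phylo.neighbor_joining(dm_all)
        (out / "tree_whole_genome.nwk").write_text(phylo.to_newick(tree_all) + "\n")
        all_regions = fst_regions + xpehh_regions
        if all_regions:
            mask = sweeps.sweep_tree_sites(gm, all_regions, fst_track)
            if mask.sum() >= 2:
                dm_sw = phylo.pairwise_distance(gm, mask)
                tree_sw = phylo.neighbor_joining(dm_sw)
                (out / "tree_sweep_snps.nwk").write_text(phylo.to_newick(tree_sw) + "\n")
                summary["sweep_tree_separates_groups"] = phylo.groups_are_separated(
                    tree_sw, gm.groups
                )
        summary["whole_genome_tree_separates_groups"] = phylo.groups_are_separated(
            tree_all, gm.groups
        )

    # --- summary ----------------------------------------------------------
    summary["regions"] = {
        "fst": len(fst_regions),
        "xpehh": len(xpehh_regions),
        "xpehh_direction_A": sum(r.direction == "A" for r in xpehh_regions),
        "xpehh_direction_B": sum(r.direction == "B" for r in xpehh_regions),
    }
    summary["heterozygosity_rate"] = {
        "A": heterozygosity_round(gm, "A"), "B": heterozygosity_round(gm, "B")
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def heterozygosity_round(gm, grp, digits: int = 6) -> float:
    return round(popgen.heterozygosity_rate(gm, grp), digits)


def _write_site_track(track: popgen.SiteStatTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# statistic={track.name}\n")
        fh.write("chrom\tpos\tvalue\n")
        for c, p, v in zip(track.chroms, track.positions, track.values):
            fh.write(f"{c}\t{p}\t{'NA' if np.isnan(v) else repr(float(v))}\n")


def manhattan_export(
    track: popgen.WindowStatTrack,
    chrom_lengths: dict[str, int],
    chrom_order: list[str] | None = None,
) -> pd.DataFrame:
    """Cumulative-coordinate table (chrom, cumulative_pos, value) for
    Manhattan plotting; offsets advance by each chromosome's length even
    when it contributed no windows.
    """
    order = chrom_order or list(chrom_lengths)
    offsets = {}
    cum = 0
    for chrom in order:
        offsets[chrom] = cum
        cum += int(chrom_lengths[chrom])
    df = track.df.copy()
    unknown = set(df["chrom"]) - set(offsets)
    if unknown:
        raise ValueError(f"track chromosomes missing from chrom_lengths: {sorted(unknown)}")
    mid = (df["start"] + df["end"]) // 2
    df["cumulative_pos"] = mid + df["chrom"].map(offsets)
    return df[["chrom", "cumulative_pos", "value"]]
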