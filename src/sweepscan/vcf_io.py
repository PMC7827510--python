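"""VCF input, site filtering, and track serialization.

VCF parsing goes through cyvcf2. Only biallelic SNPs are retained;
multi-allelic records and indels are skipped with a logged count.
Half-called genotypes ("./1") are treated as fully missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from sweepscan.model import MISSING, GenotypeMatrix, HaplotypeMatrix, _BASES, EFFECT_CLASSES

log = logging.getLogger(__name__)


class VcfIOError(RuntimeError):
    """Fatal I/O or contract error while reading/writing genomic files."""


def read_group_file(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample<TAB>A|B`` into a group map."""
    groups: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sample, grp = line.split("\t")[:2]
        if grp not in ("A", "B"):
            raise VcfIOError(f"group must be A or B, got {grp!r} for sample {sample}")
        groups[sample] = grp
    if not groups:
        raise VcfIOError(f"empty group file {path}")
    return groups


def _open_vcf(path: str | Path, group_map: dict[str, str]):
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad paths
        raise VcfIOError(f"cannot read VCF {path}: {exc}") from exc
    absent = sorted(set(group_map) - set(vcf.samples))
    if absent:
        raise VcfIOError(f"group_map samples absent from VCF header: {absent}")
    keep = [s for s in vcf.samples if s in group_map]
    keep_idx = [vcf.samples.index(s) for s in keep]
    return vcf, keep, keep_idx


def _contig_lengths(vcf) -> dict[str, int] | None:
    names = list(vcf.seqnames)
    try:
        lens = list(vcf.seqlens)
    except Exception:
        return None
    if not names or len(names) != len(lens):
        return None
    return {n: int(l) for n, l in zip(names, lens) if l}


def read_vcf(
    path: str | Path,
    group_map: dict[str, str],
    effect_info_key: str = "ANN_CLASS",
) -> GenotypeMatrix:
    """Read biallelic SNPs from a multi-sample VCF into a GenotypeMatrix.

    Samples absent from ``group_map`` are dropped. Multi-allelic records,
    indels and non-ACGT alleles are skipped (count logged). "./." and
    half-calls map to missing dosage. ``effect_info_key`` names the INFO
    field carrying a functional effect class, if annotated upstream.
    """
    vcf, keep, keep_idx = _open_vcf(path, group_map)
    rows = []
    dosages = []
    skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or var.REF not in _BASES or alts[0] not in _BASES:
            skipped += 1
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        dos = np.full(len(keep), MISSING, dtype=np.int8)
        for out_i, vcf_i in enumerate(keep_idx):
            a, b = gts[vcf_i][0], gts[vcf_i][1]
            if a >= 0 and b >= 0:
                dos[out_i] = a + b
        effect = var.INFO.get(effect_info_key)
        if effect is not None and effect not in EFFECT_CLASSES:
            effect = "unknown"
        rows.append((var.CHROM, var.POS, var.REF, alts[0], effect))
        dosages.append(dos)
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise VcfIOError(f"no usable biallelic SNPs in {path}")
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "effect_class"])
    gm = GenotypeMatrix(
        samples=keep,
        sites=sites,
        genotypes=np.vstack(dosages).T,
        groups={s: group_map[s] for s in keep},
        chrom_lengths=_contig_lengths(vcf),
    )
    gm.n_skipped_records = skipped
    return gm


def read_phased(
    path: str | Path, group_map: dict[str, str]
) -> dict[str, HaplotypeMatrix]:
    """Read a fully phased VCF into one HaplotypeMatrix per chromosome.

    Every genotype must be phased ("|") and non-missing; the first
    offending record is named in the error.
    """
    vcf, keep, keep_idx = _open_vcf(path, group_map)
    lengths = _contig_lengths(vcf) or {}
    by_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    n_usable = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or var.REF not in _BASES or alts[0] not in _BASES:
            continue
        gts = var.genotypes
        alleles = np.empty(2 * len(keep), dtype=np.uint8)
        for out_i, vcf_i in enumerate(keep_idx):
            a, b, phased = gts[vcf_i][0], gts[vcf_i][1], gts[vcf_i][2]
            if a < 0 or b < 0 or not phased:
                raise VcfIOError(
                    f"unphased or missing genotype for sample {keep[out_i]} "
                    f"at {var.CHROM}:{var.POS}"
                )
            alleles[2 * out_i] = a
            alleles[2 * out_i + 1] = b
        pos_list, allele_list = by_chrom.setdefault(var.CHROM, ([], []))
        pos_list.append(var.POS)
        allele_list.append(alleles)
        n_usable += 1
    if not n_usable:
        raise VcfIOError(f"no usable phased SNPs in {path}")
    sample_of = [s for s in keep for _ in range(2)]
    out = {}
    for chrom, (pos_list, allele_list) in by_chrom.items():
        out[chrom] = HaplotypeMatrix(
            chrom=chrom,
            positions=np.asarray(pos_list, dtype=np.int64),
            haplotypes=np.vstack(allele_list).T,
            sample_of=sample_of,
            chrom_length=lengths.get(chrom),
        )
    return out


def filter_sites(
    gm: GenotypeMatrix,
    min_maf: float = 0.0,
    max_missing: float = 1.0,
    chroms: set[str] | None = None,
) -> GenotypeMatrix:
    """Retain sites with MAF >= min_maf, missing fraction <= max_missing,
    and (optionally) chrom in ``chroms``. Thresholds are computed over the
    matrix's retained samples only; order is preserved.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    G = gm.genotypes
    called = G != MISSING
    n_called = called.sum(axis=0)
    alt_copies = np.where(called, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt_copies / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    miss_frac = 1.0 - n_called / gm.n_samples
    keep = (miss_frac <= max_missing) & (n_called > 0) & (maf >= min_maf)
    if chroms is not None:
        keep &= gm.sites["chrom"].isin(chroms).to_numpy()
    if not keep.any():
        raise VcfIOError("filter_sites removed every site")
    return gm.subset_sites(keep)


# ---------------------------------------------------------------------------
# track serialization


def write_track(track, path: str | Path, format: str = "TSV") -> None:
    """Write a WindowStatTrack as TSV (1-based inclusive) or BED (0-based
    half-open). TSV carries a comment header with the statistic name and
    any normalization constants, and round-trips through read_track.
    """
    df = track.df
    if df.empty:
        raise VcfIOError("refusing to write an empty track")
    path = Path(path)
    fmt = format.upper()
    try:
        with path.open("w") as fh:
            if fmt == "TSV":
                meta = f"# statistic={track.name}"
                if track.mean is not None:
                    meta += f"\tmean={track.mean!r}\tsd={track.sd!r}"
                fh.write(meta + "\n")
                fh.write("chrom\tstart\tend\tn_snps\tvalue\n")
                for row in df.itertuples(index=False):
                    val = "NA" if pd.isna(row.value) else repr(float(row.value))
                    fh.write(f"{row.chrom}\t{row.start + 1}\t{row.end}\t{row.n_snps}\t{val}\n")
            elif fmt == "BED":
                for row in df.itertuples(index=False):
                    val = "NA" if pd.isna(row.value) else repr(float(row.value))
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{track.name}\t{val}\n")
            else:
                raise ValueError(f"unknown track format {format!r}")
    except OSError as exc:
        raise VcfIOError(f"cannot write track to {path}: {exc}") from exc


def read_track(path: str | Path):
    """Read a TSV written by write_track back into a WindowStatTrack."""
    from sweepscan.popgen import WindowStatTrack

    path = Path(path)
    name, mean, sd = "statistic", None, None
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            for field_ in line.lstrip("# ").split("\t"):
                key, _, v = field_.partition("=")
                if key == "statistic":
                    name = v
                elif key == "mean":
                    mean = float(v)
                elif key == "sd":
                    sd = float(v)
            continue
        if line.startswith("chrom\t") or not line.strip():
            continue
        chrom, start, end, n_snps, value = line.split("\t")
        rows.append(
            (chrom, int(start) - 1, int(end), int(n_snps),
             np.nan if value == "NA" else float(value))
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])
    return WindowStatTrack(df=df, name=name, mean=mean, sd=sd)
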