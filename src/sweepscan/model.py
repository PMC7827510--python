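"""Core in-memory containers: variant sites, genotype and haplotype matrices.

Coordinates are 1-based inclusive on the way in and out (VCF convention);
window arithmetic elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for a missing (or half-called) genotype

_BASES = frozenset("ACGT")
EFFECT_CLASSES = frozenset(
    {"synonymous", "nonsynonymous", "stopgain", "stoploss", "frameshift", "other", "unknown"}
)
PROTEIN_ALTERING = frozenset({"nonsynonymous", "stopgain", "stoploss", "frameshift"})


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP. ``effect_class`` comes from upstream annotation."""

    chrom: str
    pos: int  # 1-based bp
    ref: str
    alt: str
    effect_class: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.effect_class is not None and self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect_class {self.effect_class!r}")


SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "effect_class"]


@dataclass
class GenotypeMatrix:
    """Diploid alternate-allele dosages for samples x biallelic SNP sites.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``genotypes``).
    sites : pandas.DataFrame
        One row per SNP with columns chrom, pos (1-based), ref, alt,
        effect_class; sorted by (chrom, pos), strictly increasing within
        each chromosome.
    genotypes : ndarray of int8, shape (n_samples, n_sites)
        Alt-allele dosage 0/1/2, or ``MISSING`` (-1).
    groups : dict
        sample -> "A" or "B"; both groups non-empty.
    chrom_lengths : dict or None
        Chromosome lengths in bp when known (VCF contig headers or
        simulator config); used to bound terminal windows.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    groups: dict[str, str]
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites missing columns {missing_cols}")
        groups_seen = {self.groups[s] for s in self.samples if s in self.groups}
        if not {"A", "B"} <= groups_seen:
            raise ValueError("both groups A and B must be non-empty")
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("site positions must be strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_indices(self, group: str) -> np.ndarray:
        """Row indices of samples in ``group`` ("A", "B", or "all")."""
        if group == "all":
            return np.arange(self.n_samples)
        idx = [i for i, s in enumerate(self.samples) if self.groups.get(s) == group]
        if not idx:
            raise ValueError(f"group {group!r} has no samples")
        return np.asarray(idx)

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        ec = row["effect_class"]
        return VariantSite(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            effect_class=None if pd.isna(ec) else ec,
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping sites where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            groups=dict(self.groups),
            chrom_lengths=self.chrom_lengths,
        )

    def chrom_length(self, chrom: str) -> int:
        """Known length of ``chrom``, else the largest observed position."""
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        on = self.sites["chrom"] == chrom
        return int(self.sites.loc[on, "pos"].max())


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes (two per sample) over one chromosome.

    No missing alleles are permitted: phased input must be complete.
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    haplotypes: np.ndarray  # uint8 (2*n_samples, n_sites), values 0/1
    sample_of: list[str]  # haplotype row -> sample id
    chrom_length: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even")
        if self.haplotypes.shape != (len(self.sample_of), len(self.positions)):
            raise ValueError("haplotypes shape inconsistent with sample_of/positions")
        if np.any(self.positions[1:] <= self.positions[:-1]):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def subset_samples(self, samples: set[str]) -> "HaplotypeMatrix":
        rows = [i for i, s in enumerate(self.sample_of) if s in samples]
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions,
            haplotypes=self.haplotypes[rows],
            sample_of=[self.sample_of[i] for i in rows],
            chrom_length=self.chrom_length,
        )

    def length(self) -> int:
        return int(self.chrom_length) if self.chrom_length else int(self.positions.max())
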