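"""Turn statistic tracks into sweep regions, candidate genes, ranked
coding variants, enrichment tables and group genotype-distribution tests.

Region calling applies the scan thresholds (Z(FST) > 5, |XP-EHH| > 2 by
default elsewhere) and merges adjacent or overlapping significant windows
into maximal "unique regions"; XP-EHH regions carry a direction from the
sign of the window mean and a run breaks when the sign flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sweepscan.model import MISSING, PROTEIN_ALTERING, GenotypeMatrix
from sweepscan.popgen import SiteStatTrack, WindowStatTrack, _counts

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepRegion:
    """A merged run of threshold-exceeding windows."""

    chrom: str
    start: int  # 0-based half-open bp
    end: int
    method: str  # "FST" or "XPEHH"
    direction: str  # "A", "B", or "nondirectional"
    peak_value: float
    member_windows: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if self.member_windows < 1:
            raise ValueError("region needs >= 1 member window")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("gene end must exceed start")


def call_regions(
    track: WindowStatTrack,
    threshold: float,
    mode: str = "greater",
    method: str = "FST",
    sign_direction_map: dict[str, str] | None = None,
) -> list[SweepRegion]:
    """Merge threshold-exceeding windows into maximal sweep regions.

    mode "greater" flags value > threshold (nondirectional, for Z(FST));
    mode "abs_greater" flags |value| > threshold with direction from the
    sign (default + -> A, - -> B). Runs merge while windows are adjacent
    or overlapping on one chromosome with one direction; undefined
    windows break runs. peak_value is the extreme member value.
    """
    if mode not in ("greater", "abs_greater"):
        raise ValueError(f"unknown mode {mode!r}")
    signs = sign_direction_map or {"+": "A", "-": "B"}
    regions: list[SweepRegion] = []
    cur = None  # [chrom, start, end, direction, peak, count]

    def flush():
        nonlocal cur
        if cur is not None:
            regions.append(SweepRegion(*cur[:3], method, *cur[3:]))
            cur = None

    for row in track.df.itertuples(index=False):
        v = row.value
        if pd.isna(v):
            flush()
            continue
        if mode == "greater":
            sig = v > threshold
            direction = "nondirectional"
        else:
            sig = abs(v) > threshold
            direction = signs["+"] if v > 0 else signs["-"]
        if not sig:
            flush()
            continue
        if (
            cur is not None
            and row.chrom == cur[0]
            and row.start <= cur[2]
            and direction == cur[3]
        ):
            cur[2] = max(cur[2], row.end)
            better = abs(v) > abs(cur[4]) if mode == "abs_greater" else v > cur[4]
            if better:
                cur[4] = float(v)
            cur[5] += 1
        else:
            flush()
            cur = [row.chrom, int(row.start), int(row.end), direction, float(v), 1]
    flush()
    return regions


def read_annotation(path: str | Path, gff_feature: str = "gene") -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based) or GFF3 (1-based) text."""
    path = Path(path)
    genes = []
    is_gff = path.suffix.lower() in (".gff", ".gff3") or _looks_gff(path)
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if is_gff:
            if f[2] != gff_feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            name = attrs.get("Name", gid)
            genes.append(
                GeneAnnotation(gid, name, f[0], int(f[3]) - 1, int(f[4]),
                               f[6] if len(f) > 6 else ".")
            )
        else:
            gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            strand = f[5] if len(f) > 5 else "."
            genes.append(GeneAnnotation(gid, gid, f[0], int(f[1]), int(f[2]), strand))
    return genes


def _looks_gff(path: Path) -> bool:
    head = path.read_text()[:512]
    return head.startswith("##gff-version") or "\tgene\t" in head


def genes_in_regions(
    regions: list[SweepRegion], annotation: list[GeneAnnotation]
) -> set[str]:
    """Gene ids whose interval overlaps any region by >= 1 bp (half-open
    test); duplicates collapsed by gene_id. Warns when region chromosomes
    are absent from the annotation.
    """
    ann_chroms = {g.chrom for g in annotation}
    missing = sorted({r.chrom for r in regions} - ann_chroms)
    if missing:
        counts = {c: sum(r.chrom == c for r in regions) for c in missing}
        log.warning("regions on chromosomes absent from annotation: %s", counts)
    hits = set()
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in regions:
        for g in by_chrom.get(r.chrom, ()):
            if g.start < r.end and r.start < g.end:
                hits.add(g.gene_id)
    return hits


def combine_methods(genes_fst: set[str], genes_xpehh: set[str]):
    """Union and intersection of the two methods' candidate gene sets."""
    return genes_fst | genes_xpehh, genes_fst & genes_xpehh


def rank_coding_variants(
    gm: GenotypeMatrix,
    fst_track: SiteStatTrack,
    intervals: list,
) -> pd.DataFrame:
    """Protein-altering SNPs inside the given regions or genes, ranked by
    descending single-site FST (ties by chrom, pos), with per-group
    alt-allele frequencies attached.

    ``intervals`` may be SweepRegion or GeneAnnotation objects (anything
    with chrom/start/end half-open).
    """
    nA, altA, _ = _counts(gm, "A")
    nB, altB, _ = _counts(gm, "B")
    with np.errstate(invalid="ignore", divide="ignore"):
        freqA = np.where(nA > 0, altA / (2.0 * nA), np.nan)
        freqB = np.where(nB > 0, altB / (2.0 * nB), np.nan)
    rows = []
    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    effects = gm.sites["effect_class"].to_numpy()
    for i in range(gm.n_sites):
        ec = effects[i]
        if pd.isna(ec) or ec not in PROTEIN_ALTERING:
            continue
        if not any(
            iv.chrom == chroms[i] and iv.start <= pos0[i] < iv.end for iv in intervals
        ):
            continue
        rows.append(
            {
                "chrom": chroms[i],
                "pos": int(pos0[i]) + 1,
                "ref": gm.sites["ref"].iloc[i],
                "alt": gm.sites["alt"].iloc[i],
                "effect_class": ec,
                "fst": float(fst_track.values[i]),
                "alt_freq_A": float(freqA[i]),
                "alt_freq_B": float(freqB[i]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "effect_class", "fst",
                 "alt_freq_A", "alt_freq_B"],
    )
    if len(df):
        df = df.sort_values(
            ["fst", "chrom", "pos"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def enrich(
    gene_set: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, with
    Benjamini-Hochberg adjusted p-values.

    p = P(X >= overlap) with X hypergeometric(|universe|, |term genes in
    universe|, |gene_set|); zero overlap gives p = 1.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    M = len(universe)
    N = len(gene_set)
    rows = []
    for term in sorted(term_map):
        term_genes = term_map[term] & universe
        K = len(term_genes)
        k = len(term_genes & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append((term, K, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "n_term_genes", "overlap", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df


def genotype_distribution_test(counts, method: str = "fisher") -> float:
    """Two-sided test for different genotype distributions between groups.

    ``counts`` is a 2 x k (k in {2, 3}) table of genotype counts by
    group. Default Fisher's exact test (scipy for 2x2, exact conditional
    enumeration for 2x3); chi-square selectable with method="chi2".
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.shape[0] != 2 or table.shape[1] not in (2, 3):
        raise ValueError("counts must be a 2x2 or 2x3 table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every margin must be positive")
    if method == "chi2":
        return float(stats.chi2_contingency(table, correction=False)[1])
    if method != "fisher":
        raise ValueError(f"unknown method {method!r}")
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return _fisher_2x3(table)


def _fisher_2x3(table: np.ndarray) -> float:
    """Exact conditional test for a 2x3 table: sum the probabilities of
    all tables with the observed margins whose probability does not
    exceed the observed table's.
    """
    r1 = int(table[0].sum())
    cols = table.sum(axis=0)
    n = int(table.sum())

    def prob(a):
        num = 1.0
        for aj, cj in zip(a, cols):
            num *= comb(int(cj), int(aj))
        return num / comb(n, r1)

    p_obs = prob(table[0])
    total = 0.0
    for a0 in range(min(r1, cols[0]) + 1):
        for a1 in range(min(r1 - a0, cols[1]) + 1):
            a2 = r1 - a0 - a1
            if 0 <= a2 <= cols[2]:
                p = prob((a0, a1, a2))
                if p <= p_obs * (1 + 1e-9):
                    total += p
    return min(total, 1.0)


def write_regions(regions: list[SweepRegion], path: str | Path) -> None:
    """Regions as BED with method, direction, peak and window count."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.method}\t{r.peak_value!r}"
                f"\t{r.direction}\t{r.member_windows}\n"
            )


def sites_in_regions(gm: GenotypeMatrix, regions: list[SweepRegion]) -> np.ndarray:
    """Boolean mask of sites falling inside any of the regions."""
    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    mask = np.zeros(gm.n_sites, dtype=bool)
    for r in regions:
        mask |= (chroms == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
    return mask


def sweep_tree_sites(
    gm: GenotypeMatrix,
    regions: list[SweepRegion],
    fst_track: SiteStatTrack,
    min_fst: float = 0.25,
) -> np.ndarray:
    """Site mask for the sweep-SNP tree: SNPs inside called regions
    selected by FST score (single-site FST >= min_fst).

    The 0.25 default is Wright's classical "very great differentiation"
    threshold; region membership alone keeps many neutral bystander SNPs
    of the 50 kb windows, which dilute the between-group signal.
    """
    vals = np.nan_to_num(fst_track.values, nan=-1.0)
    return sites_in_regions(gm, regions) & (vals >= min_fst)
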