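"""Per-site and windowed diversity and differentiation statistics.

The differentiation kernel is the Weir & Cockerham (1984) two-population
variance-components estimator theta = a/(a+b+c), the canonical
small-sample-corrected FST; a Hudson-type estimator with the Bhatia et al.
(2013) finite-sample correction is selectable. Windowed statistics use
fixed-size windows (default non-overlapping) and undefined values are NaN,
never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sweepscan.model import MISSING, GenotypeMatrix


@dataclass
class SiteStatTrack:
    """One value per SNP site; NaN marks undefined."""

    chroms: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    name: str
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self):
        if not (len(self.chroms) == len(self.positions) == len(self.values)):
            raise ValueError("chroms/positions/values must have equal length")


@dataclass
class WindowStatTrack:
    """Per-window statistic with (chrom, start, end) half-open windows.

    ``mean``/``sd`` hold the genome-wide normalization constants after a
    Z-transform (None otherwise).
    """

    df: pd.DataFrame  # columns chrom, start, end, n_snps, value
    name: str
    mean: float | None = None
    sd: float | None = None

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()

    def defined(self) -> pd.DataFrame:
        return self.df[self.df["value"].notna()]


def iter_windows(length: int, size: int, step: int):
    """Yield (start, end) half-open windows covering [0, length).

    The terminal window is truncated at the chromosome end.
    """
    if not (1 <= step <= size):
        raise ValueError("require window size >= step >= 1")
    start = 0
    while start < length:
        yield start, min(start + size, length)
        start += step


# ---------------------------------------------------------------------------
# per-site summaries


def _counts(gm: GenotypeMatrix, group: str):
    """(n_called_samples, alt_copies, het_calls) per site for a group."""
    G = gm.genotypes[gm.group_indices(group)]
    called = G != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, G, 0).sum(axis=0)
    het = (G == 1).sum(axis=0)
    return n_called, alt, het


def allele_frequencies(gm: GenotypeMatrix, group: str = "all") -> pd.DataFrame:
    """Per-site called-sample count, alt-allele frequency and MAF.

    Frequencies are computed over non-missing calls only; a site with zero
    calls gets NaN frequencies.
    """
    n_called, alt, _ = _counts(gm, group)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "n_called": n_called,
            "alt_freq": alt_freq,
            "maf": maf,
        }
    )


def maf_spectrum(gm: GenotypeMatrix, group: str = "all", n_bins: int = 10):
    """Histogram of per-site MAF over [0, 0.5]; returns (counts, edges)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    maf = allele_frequencies(gm, group)["maf"].to_numpy()
    maf = maf[~np.isnan(maf)]
    counts, edges = np.histogram(maf, bins=np.linspace(0.0, 0.5, n_bins + 1))
    return counts, edges


def heterozygosity_rate(gm: GenotypeMatrix, group: str = "all") -> float:
    """Fraction of non-missing genotype calls that are heterozygous."""
    G = gm.genotypes[gm.group_indices(group)]
    n_called = int((G != MISSING).sum())
    if n_called == 0:
        return float("nan")
    return int((G == 1).sum()) / n_called


def ts_tv_ratio(gm: GenotypeMatrix, group: str = "all") -> float:
    """Transition/transversion ratio over sites polymorphic in the group.

    Transitions are A<->G and C<->T; NaN if no transversions.
    """
    n_called, alt, _ = _counts(gm, group)
    poly = (alt > 0) & (alt < 2 * n_called)
    transitions = (frozenset("AG"), frozenset("CT"))
    pairs = gm.sites.loc[poly, ["ref", "alt"]]
    n_ts = sum(
        frozenset((r, a)) in transitions
        for r, a in zip(pairs["ref"], pairs["alt"])
    )
    n_tv = len(pairs) - n_ts
    if n_tv == 0:
        return float("nan")
    return n_ts / n_tv


# ---------------------------------------------------------------------------
# FST


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) variance components a, b, c, vectorized.

    n: called diploid sample sizes; p: alt-allele frequencies; h: observed
    heterozygote frequencies. Components are NaN where either n < 2.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    bad = ~((n1 >= 2) & (n2 >= 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _wc_theta(n1, p1, h1, n2, p2, h2):
    """Per-site theta = a/(a+b+c); 0 where the site is monomorphic in
    both groups (a = b = c = 0), NaN where either n < 2."""
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), 0.0)
    return np.where(np.isnan(a), np.nan, theta)


def _hudson_fst(n1, p1, n2, p2):
    """Hudson FST with the Bhatia et al. finite-sample correction.

    n here counts called allele copies per group.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1.0)
            - p2 * (1 - p2) / (n2 - 1.0)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    return np.where(ok, fst, np.nan)


def fst_per_site(gm: GenotypeMatrix, estimator: str = "wc") -> SiteStatTrack:
    """Per-SNP FST between the two groups.

    ``estimator`` is "wc" (Weir-Cockerham 1984 variance components,
    default) or "hudson" (Bhatia-corrected Hudson). Sites with fewer than
    two called genotypes in either group are NaN; negative estimates are
    retained as computed; sites monomorphic in both groups are 0.
    """
    nA, altA, hetA = _counts(gm, "A")
    nB, altB, hetB = _counts(gm, "B")
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.where(nA > 0, altA / (2.0 * nA), np.nan)
        pB = np.where(nB > 0, altB / (2.0 * nB), np.nan)
        hA = np.where(nA > 0, hetA / np.maximum(nA, 1), np.nan)
        hB = np.where(nB > 0, hetB / np.maximum(nB, 1), np.nan)
    if estimator == "wc":
        vals = _wc_theta(nA, pA, hA, nB, pB, hB)
    elif estimator == "hudson":
        vals = _hudson_fst(2 * nA, pA, 2 * nB, pB)
    else:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    return SiteStatTrack(
        chroms=gm.sites["chrom"].to_numpy(),
        positions=gm.sites["pos"].to_numpy(),
        values=vals,
        name=f"fst_{estimator}",
        chrom_lengths=gm.chrom_lengths,
    )


def fst_genomewide(gm: GenotypeMatrix) -> float:
    """Multi-locus Weir-Cockerham FST: ratio of summed variance
    components sum(a)/sum(a+b+c) over all sites with defined components.

    Unlike the mean of per-site theta ratios (which carries a small
    finite-sample bias), this ratio-of-sums aggregate is the standard
    genome-wide estimate and is ~0 under identical group frequencies.
    """
    nA, altA, hetA = _counts(gm, "A")
    nB, altB, hetB = _counts(gm, "B")
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.where(nA > 0, altA / (2.0 * nA), np.nan)
        pB = np.where(nB > 0, altB / (2.0 * nB), np.nan)
        hA = np.where(nA > 0, hetA / np.maximum(nA, 1), np.nan)
        hB = np.where(nB > 0, hetB / np.maximum(nB, 1), np.nan)
    a, b, c = _wc_components(nA, pA, hA, nB, pB, hB)
    ok = ~np.isnan(a)
    denom = float((a[ok] + b[ok] + c[ok]).sum())
    if denom == 0:
        return float("nan")
    return float(a[ok].sum()) / denom


# ---------------------------------------------------------------------------
# windowing and normalization


def _chrom_order(chroms: np.ndarray) -> list[str]:
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    return list(seen)


def window_mean(
    track: SiteStatTrack,
    window_size: int = 50_000,
    step: int | None = None,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowStatTrack:
    """Arithmetic mean of defined per-site values in fixed windows.

    Windows with fewer than ``min_snps`` defined sites are NaN. Default
    50 kb non-overlapping windows (step = size when step is None).
    """
    if step is None:
        step = window_size
    lengths = chrom_lengths or track.chrom_lengths or {}
    rows = []
    for chrom in _chrom_order(track.chroms):
        on = track.chroms == chrom
        pos0 = track.positions[on] - 1  # to 0-based
        vals = track.values[on]
        length = lengths.get(chrom, int(track.positions[on].max()))
        order = np.argsort(pos0, kind="stable")
        pos0, vals = pos0[order], vals[order]
        for start, end in iter_windows(length, window_size, step):
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            v = vals[lo:hi]
            v = v[~np.isnan(v)]
            value = float(v.mean()) if len(v) >= min_snps else np.nan
            rows.append((chrom, start, end, len(v), value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])
    return WindowStatTrack(df=df, name=f"mean_{track.name}")


def z_transform(track: WindowStatTrack) -> WindowStatTrack:
    """Genome-wide Z-transform: (value - mean) / sd over defined windows.

    Uses the sample standard deviation (n-1). All chromosomes present in
    the track are pooled into one mean/sd, matching a genome-wide outlier
    scan. Fatal on a degenerate (constant or near-empty) track.
    """
    vals = track.values
    defined = vals[~np.isnan(vals)]
    if len(defined) < 2:
        raise ValueError("z_transform needs at least 2 defined windows")
    mean = float(defined.mean())
    sd = float(defined.std(ddof=1))
    if sd == 0:
        raise ValueError("z_transform on a constant track (zero sd)")
    df = track.df.copy()
    df["value"] = (df["value"] - mean) / sd
    return WindowStatTrack(df=df, name=f"z_{track.name}", mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# pooled heterozygosity and Tajima's D


def pooled_heterozygosity(
    gm: GenotypeMatrix,
    group: str,
    window_size: int = 10_000,
    step: int | None = None,
) -> WindowStatTrack:
    """Pooled heterozygosity Hp per window for one group.

    Per window, sum major- and minor-allele counts over SNPs (counts over
    non-missing calls; major/minor resolved per site within the group,
    exact 50/50 ties assign ref as major) and evaluate

        Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2

    Hp lies in [0, 0.5]; a window with no called alleles is NaN. Default
    10 kb non-overlapping windows.
    """
    if step is None:
        step = window_size
    n_called, alt, _ = _counts(gm, group)
    ref_copies = 2 * n_called - alt
    minor = np.minimum(alt, ref_copies)
    major = np.maximum(alt, ref_copies)  # tie -> equal, assignment irrelevant
    lengths = gm.chrom_lengths or {}
    rows = []
    chroms = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    for chrom in _chrom_order(chroms):
        on = chroms == chrom
        p = pos0[on]
        maj, mino, nc = major[on], minor[on], n_called[on]
        length = lengths.get(chrom, int(p.max()) + 1)
        for start, end in iter_windows(length, window_size, step):
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="left")
            s_maj = int(maj[lo:hi].sum())
            s_min = int(mino[lo:hi].sum())
            n_snps = int((nc[lo:hi] > 0).sum())
            tot = s_maj + s_min
            value = 2.0 * s_maj * s_min / tot**2 if tot > 0 else np.nan
            rows.append((chrom, start, end, n_snps, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])
    return WindowStatTrack(df=df, name=f"hp_{group}")


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sequences."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    gm: GenotypeMatrix,
    group: str = "all",
    window_size: int = 50_000,
    step: int | None = None,
) -> WindowStatTrack:
    """Tajima's D per window for one group.

    D = (pi - theta_W) / sqrt(e1*S + e2*S*(S-1)) with the 1989 constants.
    pi is the mean pairwise difference from per-site allele frequencies
    using each site's called-copy count; the variance constants use the
    window median of called copies over segregating sites (a documented
    approximation for missing data). Windows with S = 0 are NaN.
    """
    if step is None:
        step = window_size
    n_called, alt, _ = _counts(gm, group)
    copies = 2 * n_called
    lengths = gm.chrom_lengths or {}
    rows = []
    chroms = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    for chrom in _chrom_order(chroms):
        on = chroms == chrom
        p = pos0[on]
        a, nc = alt[on], copies[on]
        length = lengths.get(chrom, int(p.max()) + 1)
        for start, end in iter_windows(length, window_size, step):
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="left")
            aw, nw = a[lo:hi], nc[lo:hi]
            seg = (aw > 0) & (aw < nw) & (nw >= 2)
            S = int(seg.sum())
            if S == 0:
                rows.append((chrom, start, end, S, np.nan))
                continue
            aws, nws = aw[seg].astype(float), nw[seg].astype(float)
            pi = float(np.sum(2.0 * aws * (nws - aws) / (nws * (nws - 1.0))))
            n_med = int(np.median(nws))
            if n_med < 2:
                rows.append((chrom, start, end, S, np.nan))
                continue
            k = tajima_constants(n_med)
            theta_w = S / k["a1"]
            var = k["e1"] * S + k["e2"] * S * (S - 1.0)
            value = (pi - theta_w) / np.sqrt(var) if var > 0 else np.nan
            rows.append((chrom, start, end, S, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])
    return WindowStatTrack(df=df, name=f"tajimas_d_{group}")
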