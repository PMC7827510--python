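"""Haplotype-length statistics from phased data.

EHH (extended haplotype homozygosity) is the probability that two randomly
drawn core-carrying haplotypes are identical over the segment from the
core SNP out to a marker; iHH integrates the EHH curve against physical
distance (bp); XP-EHH is the ln ratio of the two groups' per-site iHH,
normalized genome-wide, with positive scores indicating longer haplotypes
(a sweep) in group A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan.model import HaplotypeMatrix
from sweepscan.popgen import WindowStatTrack, iter_windows

EHH_CUTOFF = 0.05  # stop extending once EHH drops below this


@dataclass
class EHHCurve:
    """EHH decay in one direction from a core SNP allele.

    offsets are absolute bp distances from the core (offset 0 = core);
    ehh values are non-increasing. n_carriers < 2 leaves the curve
    undefined (empty arrays).
    """

    chrom: str
    core_pos: int
    allele: int
    offsets: np.ndarray
    ehh: np.ndarray
    n_carriers: int

    @property
    def defined(self) -> bool:
        return self.n_carriers >= 2


def _pair_homozygosity(labels: np.ndarray) -> float:
    """Sum over classes of C(k,2) / C(n,2) for a label partition."""
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _extend(haps: np.ndarray, positions: np.ndarray, core: int, rows: np.ndarray,
            direction: int, cutoff: float):
    """Walk outward from the core refining the haplotype partition.

    Returns (offsets, ehh) including the first marker whose EHH falls
    below the cutoff (it is the final trapezoid endpoint).
    """
    labels = np.zeros(len(rows), dtype=np.int64)
    offsets = [0.0]
    values = [1.0]
    idx = core
    m = haps.shape[1]
    while True:
        idx += direction
        if idx < 0 or idx >= m:
            break
        col = haps[rows, idx]
        labels = labels * 2 + col
        # re-densify labels to keep them small
        _, labels = np.unique(labels, return_inverse=True)
        e = _pair_homozygosity(labels)
        offsets.append(abs(float(positions[idx] - positions[core])))
        values.append(e)
        if e < cutoff:
            break
    return np.asarray(offsets), np.asarray(values)


def ehh(
    hm: HaplotypeMatrix,
    core_index: int,
    allele: int,
    direction: str = "right",
    cutoff: float = EHH_CUTOFF,
) -> EHHCurve:
    """Allele-specific EHH decay curve in one direction from a core SNP.

    Carriers are the haplotypes with ``allele`` at ``core_index``; EHH at
    the core is 1 by definition. Extension stops when EHH < cutoff or the
    chromosome end is reached.
    """
    if not 0 <= core_index < hm.n_sites:
        raise IndexError(f"core_index {core_index} out of range")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    rows = np.flatnonzero(hm.haplotypes[:, core_index] == allele)
    if len(rows) < 2:
        return EHHCurve(hm.chrom, int(hm.positions[core_index]), allele,
                        np.empty(0), np.empty(0), len(rows))
    sign = 1 if direction == "right" else -1
    offsets, values = _extend(hm.haplotypes, hm.positions, core_index, rows, sign, cutoff)
    return EHHCurve(hm.chrom, int(hm.positions[core_index]), allele,
                    offsets, values, len(rows))


def _integrate(offsets: np.ndarray, values: np.ndarray) -> float:
    if len(offsets) < 2:
        return 0.0
    return float(np.trapezoid(values, offsets))


def ihh(hm: HaplotypeMatrix, core_index: int, allele: int,
        cutoff: float = EHH_CUTOFF) -> float:
    """Integrated EHH (bp): trapezoid area of the left plus right curves.

    NaN when fewer than two carriers.
    """
    left = ehh(hm, core_index, allele, "left", cutoff)
    right = ehh(hm, core_index, allele, "right", cutoff)
    if not left.defined:
        return float("nan")
    return _integrate(left.offsets, left.ehh) + _integrate(right.offsets, right.ehh)


def _site_ihh_pooled(hm: HaplotypeMatrix, core_index: int, cutoff: float) -> float:
    """Per-site iHH over ALL haplotypes of one group, both core alleles
    pooled: the partition starts split by the core allele, so EHH at the
    core equals the core-site homozygosity (the unstandardized XP-EHH
    convention).
    """
    hapsT = _columns(hm)
    positions = hm.positions
    n = hm.n_haplotypes
    pairs_tot = n * (n - 1)
    total = 0.0
    m = hm.n_sites
    for sign in (1, -1):
        labels = hapsT[core_index].astype(np.int64)
        counts = np.bincount(labels, minlength=2)
        e_prev = float((counts * (counts - 1)).sum() / pairs_tot)
        area = 0.0
        prev_off = 0.0
        idx = core_index
        if e_prev >= cutoff:
            # re-densify labels so they stay < n
            labels = _densify(labels)
            while True:
                idx += sign
                if idx < 0 or idx >= m:
                    break
                labels = labels * 2 + hapsT[idx]
                counts = np.bincount(labels, minlength=1)
                e = float((counts * (counts - 1)).sum() / pairs_tot)
                off = abs(float(positions[idx] - positions[core_index]))
                area += (off - prev_off) * (e_prev + e) / 2.0
                prev_off, e_prev = off, e
                if e < cutoff:
                    break
                labels = _densify(labels)
        total += area
    return total


def _ihh_all_sites(hm: HaplotypeMatrix, cutoff: float) -> np.ndarray:
    """Pooled per-site iHH for every site of one group's matrix."""
    if hm.n_haplotypes < 2:
        return np.zeros(hm.n_sites)
    kernel = _numba_kernel()
    if kernel is not None:
        return kernel(_columns(hm), hm.positions.astype(np.float64), cutoff)
    return np.array(
        [_site_ihh_pooled(hm, i, cutoff) for i in range(hm.n_sites)]
    )


_KERNEL = None


def _numba_kernel():
    """Compile (once) the numba inner loop; None if numba is unusable."""
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL if _KERNEL is not False else None
    try:
        from numba import njit
    except Exception:  # pragma: no cover - numba is normally present
        _KERNEL = False
        return None

    @njit(cache=False)
    def kernel(hapsT, positions, cutoff):  # pragma: no cover - compiled
        m, n = hapsT.shape
        pairs = n * (n - 1)
        out = np.zeros(m)
        labels = np.empty(n, np.int64)
        cnt = np.empty(2 * n, np.int64)
        mapping = np.empty(2 * n, np.int64)
        for core in range(m):
            total = 0.0
            for sdir in range(2):
                sign = 1 if sdir == 0 else -1
                c1 = 0
                for i in range(n):
                    labels[i] = hapsT[core, i]
                    c1 += hapsT[core, i]
                c0 = n - c1
                e_prev = (c0 * (c0 - 1) + c1 * (c1 - 1)) / pairs
                if e_prev < cutoff:
                    continue
                area = 0.0
                prev_off = 0.0
                idx = core
                while True:
                    idx += sign
                    if idx < 0 or idx >= m:
                        break
                    for i in range(n):
                        labels[i] = labels[i] * 2 + hapsT[idx, i]
                    for v in range(2 * n):
                        cnt[v] = 0
                    for i in range(n):
                        cnt[labels[i]] += 1
                    s = 0
                    k = 0
                    for v in range(2 * n):
                        if cnt[v] > 0:
                            s += cnt[v] * (cnt[v] - 1)
                            mapping[v] = k
                            k += 1
                    e = s / pairs
                    off = positions[idx] - positions[core]
                    if off < 0.0:
                        off = -off
                    area += (off - prev_off) * (e_prev + e) / 2.0
                    prev_off = off
                    e_prev = e
                    if e < cutoff:
                        break
                    for i in range(n):
                        labels[i] = mapping[labels[i]]
                total += area
            out[core] = total
        return out

    _KERNEL = kernel
    return kernel


def _densify(labels: np.ndarray) -> np.ndarray:
    counts = np.bincount(labels)
    mapping = np.cumsum(counts > 0) - 1
    return mapping[labels]


def _columns(hm: HaplotypeMatrix) -> np.ndarray:
    """C-contiguous site-major copy of the haplotypes, cached on the
    matrix (column slices dominate the EHH inner loop)."""
    cached = getattr(hm, "_columns_cache", None)
    if cached is None:
        cached = np.ascontiguousarray(hm.haplotypes.T).astype(np.int64)
        hm._columns_cache = cached
    return cached


@dataclass
class XpehhTrack:
    """Per-site XP-EHH scores on one chromosome.

    raw = ln(iHH_A / iHH_B); norm = (raw - mean)/sd with constants taken
    genome-wide (recomputed jointly across chromosomes by
    normalize_xpehh). Positive scores mean longer haplotypes in group A.
    """

    chrom: str
    positions: np.ndarray
    raw: np.ndarray
    norm: np.ndarray
    mean: float
    sd: float
    chrom_length: int | None = None


def xpehh(hmA: HaplotypeMatrix, hmB: HaplotypeMatrix,
          cutoff: float = EHH_CUTOFF) -> XpehhTrack:
    """Cross-population EHH track for one chromosome.

    Both matrices must cover identical site lists. Sites where either
    group's iHH is zero or undefined are NaN. Scores are normalized over
    the defined sites of this track; use normalize_xpehh to renormalize
    several chromosomes jointly.
    """
    if not np.array_equal(hmA.positions, hmB.positions) or hmA.chrom != hmB.chrom:
        raise ValueError("xpehh requires identical site lists in both groups")
    m = hmA.n_sites
    ia = _ihh_all_sites(hmA, cutoff)
    ib = _ihh_all_sites(hmB, cutoff)
    raw = np.full(m, np.nan)
    ok = (ia > 0) & (ib > 0)
    # log(a) - log(b) rather than log(a/b): keeps group-swap
    # antisymmetry bit-exact
    raw[ok] = np.log(ia[ok]) - np.log(ib[ok])
    track = XpehhTrack(
        chrom=hmA.chrom,
        positions=hmA.positions.copy(),
        raw=raw,
        norm=np.full(m, np.nan),
        mean=0.0,
        sd=1.0,
        chrom_length=hmA.chrom_length or hmB.chrom_length,
    )
    normalize_xpehh([track])
    return track


def normalize_xpehh(tracks: list[XpehhTrack]) -> None:
    """Normalize raw scores to mean 0, sd 1 over all defined sites of all
    given tracks (genome-wide, one pass, no frequency binning); updates
    each track's norm/mean/sd in place.
    """
    allraw = np.concatenate([t.raw for t in tracks])
    defined = allraw[~np.isnan(allraw)]
    if len(defined) < 2:
        raise ValueError("normalize_xpehh needs >= 2 defined sites")
    mean = float(defined.mean())
    sd = float(defined.std(ddof=1))
    for t in tracks:
        t.mean, t.sd = mean, sd
        if sd == 0:
            # degenerate (e.g. identical groups): scores all equal the
            # mean, so the standardized score is 0 everywhere
            t.norm = t.raw - mean
        else:
            t.norm = (t.raw - mean) / sd


def window_xpehh(
    track: XpehhTrack,
    window_size: int = 50_000,
    step: int | None = None,
    min_snps: int = 10,
) -> WindowStatTrack:
    """Mean normalized XP-EHH per window (default 50 kb non-overlapping)."""
    if step is None:
        step = window_size
    length = track.chrom_length or int(track.positions.max())
    pos0 = track.positions - 1
    rows = []
    for start, end in iter_windows(length, window_size, step):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        v = track.norm[lo:hi]
        v = v[~np.isnan(v)]
        value = float(v.mean()) if len(v) >= min_snps else np.nan
        rows.append((track.chrom, start, end, len(v), value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])
    return WindowStatTrack(df=df, name="xpehh", mean=track.mean, sd=track.sd)


def window_xpehh_multi(
    tracks: list[XpehhTrack],
    window_size: int = 50_000,
    step: int | None = None,
    min_snps: int = 10,
) -> WindowStatTrack:
    """Windowed XP-EHH over several chromosomes, jointly normalized."""
    normalize_xpehh(tracks)
    dfs = [window_xpehh(t, window_size, step, min_snps).df for t in tracks]
    df = pd.concat(dfs, ignore_index=True)
    return WindowStatTrack(df=df, name="xpehh", mean=tracks[0].mean, sd=tracks[0].sd)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _ld_pair(haps: np.ndarray, i: int, j: int):
    """(r2, dprime) from phased haplotype counts; NaN if monomorphic."""
    a = haps[:, i].astype(float)
    b = haps[:, j].astype(float)
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan"), float("nan")
    pab = (a * b).mean()
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    dmax = min(pa * (1 - pb), pb * (1 - pa)) if d > 0 else min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else float("nan")
    return float(r2), float(dprime)


def ld_r2(hm: HaplotypeMatrix, site_i: int, site_j: int) -> float:
    """Squared allele-frequency correlation r^2 between two sites."""
    return _ld_pair(hm.haplotypes, site_i, site_j)[0]


def ld_decay(
    hms: HaplotypeMatrix | list[HaplotypeMatrix],
    groups: dict[str, str] | None = None,
    group: str | None = None,
    n_snps_sample: int = 10_000,
    min_maf: float = 0.1,
    distance_bins: list[int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 (and D') per physical-distance bin.

    Sites passing the MAF filter are randomly subsampled to
    ``n_snps_sample`` with ``seed``; all intra-chromosome pairs closer
    than the largest bin edge are scored. Bins are left-closed
    right-open; a bin with no pairs reports NaN.
    """
    if distance_bins is None:
        distance_bins = [0, 1_000, 2_000, 5_000, 10_000, 20_000, 50_000]
    if distance_bins[0] != 0 or any(
        lo >= hi for lo, hi in zip(distance_bins, distance_bins[1:])
    ):
        raise ValueError("distance_bins must be strictly increasing with first edge 0")
    if isinstance(hms, HaplotypeMatrix):
        hms = [hms]
    rng = np.random.default_rng(seed)
    edges = np.asarray(distance_bins)
    max_dist = edges[-1]
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    dsums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    # budget the subsample across chromosomes proportionally
    total_sites = sum(h.n_sites for h in hms)
    for hm in hms:
        haps = hm.haplotypes
        if groups is not None and group is not None:
            keep = {s for s, g in groups.items() if g == group}
            hm_g = hm.subset_samples(keep)
            haps = hm_g.haplotypes
        freq = haps.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        eligible = np.flatnonzero(maf >= min_maf)
        quota = max(2, int(round(n_snps_sample * hm.n_sites / max(total_sites, 1))))
        if len(eligible) > quota:
            eligible = np.sort(rng.choice(eligible, size=quota, replace=False))
        pos = hm.positions[eligible]
        sub = haps[:, eligible].astype(float)
        p = sub.mean(axis=0)
        q = 1 - p
        for a in range(len(eligible)):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="left")
            if hi <= a + 1:
                continue
            js = np.arange(a + 1, hi)
            dist = pos[js] - pos[a]
            pab = (sub[:, a : a + 1] * sub[:, js]).mean(axis=0)
            d = pab - p[a] * p[js]
            r2 = d**2 / (p[a] * q[a] * p[js] * q[js])
            dmax = np.where(
                d > 0,
                np.minimum(p[a] * q[js], p[js] * q[a]),
                np.minimum(p[a] * p[js], q[a] * q[js]),
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                dp = np.abs(d) / dmax
            which = np.searchsorted(edges, dist, side="right") - 1
            ok = (which >= 0) & (which < n_bins)
            np.add.at(sums, which[ok], r2[ok])
            np.add.at(dsums, which[ok], dp[ok])
            np.add.at(counts, which[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
        mean_dp = np.where(counts > 0, dsums / counts, np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "n_pairs": counts,
            "mean_r2": mean_r2,
            "mean_dprime": mean_dp,
        }
    )
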