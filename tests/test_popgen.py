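"""Per-site and windowed statistics: frequencies, FST, Hp, Tajima's D."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import popgen
from sweepscan.popgen import (
    SiteStatTrack,
    WindowStatTrack,
    allele_frequencies,
    fst_per_site,
    heterozygosity_rate,
    maf_spectrum,
    pooled_heterozygosity,
    tajimas_d,
    ts_tv_ratio,
    window_mean,
    z_transform,
    iter_windows,
)

from conftest import make_gm
from oracles import wc_fst_oracle, tajima_d_oracle


class TestAlleleFrequencies:
    def test_all_hets(self):
        gm = make_gm([[1], [1], [1], [1]])
        af = allele_frequencies(gm)
        assert af["alt_freq"].iloc[0] == 0.5
        assert af["maf"].iloc[0] == 0.5

    def test_missing_excluded_from_denominator(self):
        # dosages (0,1,2,2,missing): 5 alt copies among 8 called alleles
        gm = make_gm([[0], [1], [2], [2], [-1]], groups=list("AABBB"))
        af = allele_frequencies(gm)
        assert af["n_called"].iloc[0] == 4
        assert af["alt_freq"].iloc[0] == pytest.approx(5 / 8)
        assert af["maf"].iloc[0] == pytest.approx(3 / 8)

    def test_all_missing_flagged_undefined(self):
        gm = make_gm([[-1, 1], [-1, 1], [-1, 0], [-1, 0]])
        af = allele_frequencies(gm)
        assert np.isnan(af["alt_freq"].iloc[0])
        assert not np.isnan(af["alt_freq"].iloc[1])


class TestMafSpectrum:
    def test_all_maf_half_in_last_bin(self):
        gm = make_gm([[1, 1], [1, 1], [1, 1], [1, 1]])
        counts, edges = maf_spectrum(gm, n_bins=5)
        assert counts.tolist() == [0, 0, 0, 0, 2]
        assert edges[0] == 0 and edges[-1] == 0.5

    def test_hand_binned_toy(self):
        # MAFs: 0.0, 0.125, 0.25, 0.375, 0.5, 0.5 over 4 diploids
        gm = make_gm(
            [
                [0, 0, 0, 0, 1, 1],
                [0, 0, 0, 1, 1, 1],
                [0, 0, 1, 1, 1, 1],
                [0, 1, 1, 1, 1, 1],
            ]
        )
        counts, _ = maf_spectrum(gm, n_bins=4)
        # bins [0,.125) [.125,.25) [.25,.375) [.375,.5]
        assert counts.tolist() == [1, 1, 1, 3]
        assert counts.sum() == 6

    def test_counts_sum_to_defined_sites(self):
        gm = make_gm([[1, -1], [0, -1], [2, -1], [1, -1]])
        counts, _ = maf_spectrum(gm, n_bins=3)
        assert counts.sum() == 1  # the all-missing site is excluded


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "dosages,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[0, 2], [2, 0]], 0.0),
            ([[1, 0, 0, 2, 1], [1, 2, 1, 0, 0]], 0.4),
        ],
    )
    def test_rates(self, dosages, expected):
        gm = make_gm(dosages)
        assert heterozygosity_rate(gm) == pytest.approx(expected)


class TestTsTv:
    def test_classification(self):
        gm = make_gm(
            [[1, 1, 1, 1], [0, 0, 0, 0], [1, 1, 1, 1], [0, 0, 0, 0]],
            refs=["A", "C", "A", "G"],
            alts=["G", "T", "T", "C"],
        )
        # A->G and C->T transitions; A->T and G->C transversions
        assert ts_tv_ratio(gm) == pytest.approx(1.0)

    def test_no_transversions_undefined(self):
        gm = make_gm([[1], [0], [1], [0]], refs=["A"], alts=["G"])
        assert np.isnan(ts_tv_ratio(gm))

    def test_transversion_only_zero(self):
        gm = make_gm([[1], [0], [1], [0]], refs=["A"], alts=["T"])
        assert ts_tv_ratio(gm) == 0.0

    def test_monomorphic_sites_excluded(self):
        gm = make_gm(
            [[1, 0], [0, 0], [1, 0], [0, 0]], refs=["A", "C"], alts=["T", "T"]
        )
        # second site monomorphic -> only the A->T transversion counts
        assert ts_tv_ratio(gm) == 0.0


class TestFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[0]] * 5 + [[2]] * 5, groups=list("AAAAABBBBB"))
        assert fst_per_site(gm).values[0] == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self):
        col = [[0], [1], [2], [1], [0]]
        gm = make_gm(col + col, groups=list("AAAAABBBBB"))
        assert fst_per_site(gm).values[0] <= 0

    def test_monomorphic_in_both_defined_zero(self):
        gm = make_gm([[0]] * 10, groups=list("AAAAABBBBB"))
        assert fst_per_site(gm).values[0] == 0.0

    def test_insufficient_group_calls_undefined(self):
        gm = make_gm(
            [[1], [-1], [-1], [-1], [-1], [1], [0], [2], [1], [0]],
            groups=list("AAAAABBBBB"),
        )
        assert np.isnan(fst_per_site(gm).values[0])

    def test_matches_wc_oracle_on_random_tables(self):
        """100 random 5v5 genotype tables against the independently
        transcribed Weir-Cockerham variance-components oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            G = rng.integers(0, 3, size=(10, 1))
            if rng.random() < 0.3:  # sprinkle missingness
                G[rng.integers(0, 10), 0] = -1
            gm = make_gm(G.tolist(), groups=list("AAAAABBBBB"))
            got = fst_per_site(gm).values[0]
            dosA = [None if d < 0 else int(d) for d in G[:5, 0]]
            dosB = [None if d < 0 else int(d) for d in G[5:, 0]]
            want = wc_fst_oracle(dosA, dosB)
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_hudson_estimator_selectable(self):
        gm = make_gm([[0]] * 5 + [[2]] * 5, groups=list("AAAAABBBBB"))
        assert fst_per_site(gm, estimator="hudson").values[0] == pytest.approx(1.0)

    def test_neutral_genomewide_near_zero(self):
        """Identical group frequencies (10k simulated sites): the
        multi-locus ratio-of-sums FST is within 3 standard errors of 0,
        and the mean of per-site ratios is small in magnitude (it keeps
        the known finite-sample negative bias of a ratio estimator, so
        only a magnitude bound applies to it)."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, size=10_000)
        G = (rng.random((10, 10_000, 2)) < p[None, :, None]).sum(axis=2)
        gm = make_gm(G.astype(np.int8).tolist(), groups=list("AAAAABBBBB"),
                     positions=list(range(1, 10_001)))
        vals = fst_per_site(gm).values
        vals = vals[~np.isnan(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(popgen.fst_genomewide(gm)) < 3 * se
        assert abs(vals.mean()) < 0.01


class TestWindows:
    def test_window_arithmetic_with_truncated_terminal(self):
        wins = list(iter_windows(120_000, 50_000, 50_000))
        assert wins == [(0, 50_000), (50_000, 100_000), (100_000, 120_000)]

    def test_mean_of_sites_in_window(self):
        track = SiteStatTrack(
            chroms=np.array(["chr1", "chr1"]),
            positions=np.array([10_000, 20_000]),
            values=np.array([0.2, 0.4]),
            name="fst",
            chrom_lengths={"chr1": 50_000},
        )
        win = window_mean(track, 50_000, min_snps=1)
        assert win.df["value"].iloc[0] == pytest.approx(0.3)
        assert win.df["n_snps"].iloc[0] == 2

    def test_min_snps_flags_undefined(self):
        track = SiteStatTrack(
            chroms=np.array(["chr1"] * 3),
            positions=np.array([1_000, 2_000, 3_000]),
            values=np.array([0.1, 0.2, 0.3]),
            name="fst",
            chrom_lengths={"chr1": 50_000},
        )
        win = window_mean(track, 50_000, min_snps=10)
        assert np.isnan(win.df["value"].iloc[0])

    def test_partition_counts_every_defined_site_once(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(1, 200_001), size=500, replace=False))
        track = SiteStatTrack(
            chroms=np.array(["chr1"] * 500),
            positions=pos,
            values=rng.random(500),
            name="x",
            chrom_lengths={"chr1": 200_000},
        )
        win = window_mean(track, 50_000, min_snps=0)
        assert win.df["n_snps"].sum() == 500


class TestZTransform:
    def test_simple_values(self):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 50_000, 100_000],
             "end": [50_000, 100_000, 150_000], "n_snps": 10,
             "value": [1.0, 2.0, 3.0]}
        )
        z = z_transform(WindowStatTrack(df=df, name="t"))
        assert z.values.tolist() == [-1.0, 0.0, 1.0]
        assert z.mean == 2.0 and z.sd == 1.0

    def test_constant_track_fatal(self):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 50_000], "end": [50_000, 100_000],
             "n_snps": 10, "value": [1.0, 1.0]}
        )
        with pytest.raises(ValueError):
            z_transform(WindowStatTrack(df=df, name="t"))

    def test_mean_zero_sd_one_and_rank_preserved(self):
        rng = np.random.default_rng(5)
        vals = rng.random(200)
        vals[::17] = np.nan
        df = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(200) * 1000,
             "end": (np.arange(200) + 1) * 1000, "n_snps": 10, "value": vals}
        )
        z = z_transform(WindowStatTrack(df=df, name="t"))
        defined = z.values[~np.isnan(z.values)]
        assert abs(defined.mean()) < 1e-9
        assert abs(defined.std(ddof=1) - 1) < 1e-9
        raw_defined = vals[~np.isnan(vals)]
        assert (np.argsort(defined) == np.argsort(raw_defined)).all()


class TestPooledHeterozygosity:
    def test_balanced_counts_maximal(self):
        gm = make_gm([[1]] * 5, groups=list("AABBB"),
                     chrom_lengths={"chr1": 10_000})
        hp = pooled_heterozygosity(gm, "B")
        # B group: 3 samples all het -> 3 maj, 3 min
        assert hp.df["value"].iloc[0] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        gm = make_gm([[0, 2]] * 4, chrom_lengths={"chr1": 10_000})
        hp = pooled_heterozygosity(gm, "A")
        assert hp.df["value"].iloc[0] == 0.0

    def test_toy_window_formula(self):
        """(maj,min) = (9,1) and (7,3): Hp = 2*16*4/400 = 0.32."""
        # group A = 5 diploids: site1 has one alt copy, site2 has three
        G = np.array(
            [[0, 1], [0, 1], [0, 1], [0, 0], [1, 0],  # group A
             [0, 0], [0, 0]]  # group B (unused by the A-group statistic)
        )
        gm = make_gm(G.tolist(), groups=list("AAAAABB"),
                     chrom_lengths={"chr1": 10_000})
        hp = pooled_heterozygosity(gm, "A")
        assert hp.df["value"].iloc[0] == pytest.approx(0.32)

    def test_range_invariant(self):
        rng = np.random.default_rng(11)
        G = rng.integers(0, 3, size=(6, 300))
        pos = np.sort(rng.choice(np.arange(1, 100_000), 300, replace=False))
        gm = make_gm(G.tolist(), positions=pos.tolist(),
                     chrom_lengths={"chr1": 100_000})
        hp = pooled_heterozygosity(gm, "A")
        vals = hp.df["value"].dropna()
        assert ((vals >= 0) & (vals <= 0.5)).all()

    def test_no_calls_undefined(self):
        gm = make_gm([[-1], [-1], [0], [2]], groups=list("AABB"),
                     chrom_lengths={"chr1": 10_000})
        assert np.isnan(pooled_heterozygosity(gm, "A").df["value"].iloc[0])


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        gm = make_gm([[0, 2]] * 4, chrom_lengths={"chr1": 50_000})
        td = tajimas_d(gm, "all")
        assert np.isnan(td.df["value"].iloc[0])

    def test_matches_independent_transcription(self):
        """Random windows against a second implementation of the 1989
        constants, to 1e-10."""
        rng = np.random.default_rng(21)
        for _ in range(30):
            m = rng.integers(3, 40)
            minor = rng.integers(0, 6, size=m)  # minor copies among n=10
            # build dosage columns with exactly `minor` alt copies in 5 diploids
            cols = []
            for c in minor:
                alleles = np.zeros(10, dtype=int)
                alleles[:c] = 1
                rng.shuffle(alleles)
                cols.append(alleles[0::2] + alleles[1::2])
            G = np.array(cols).T
            gm = make_gm(
                G.tolist(), groups=list("AAABB"),
                positions=list(range(1000, 1000 + 100 * m, 100)),
                chrom_lengths={"chr1": 50_000},
            )
            got = tajimas_d(gm, "all").df["value"].iloc[0]
            want = tajima_d_oracle(minor.tolist(), 10)
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_singletons_more_negative_than_intermediates(self):
        def build(minor_count):
            cols = []
            for _ in range(20):
                alleles = np.zeros(10, dtype=int)
                alleles[:minor_count] = 1
                cols.append(alleles[0::2] + alleles[1::2])
            G = np.array(cols).T
            return make_gm(G.tolist(), groups=list("AAABB"),
                           positions=list(range(1000, 3000, 100)),
                           chrom_lengths={"chr1": 50_000})

        d_single = tajimas_d(build(1), "all").df["value"].iloc[0]
        d_mid = tajimas_d(build(5), "all").df["value"].iloc[0]
        assert d_single < d_mid
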