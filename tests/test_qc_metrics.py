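"""Cross-correlation, NSC/RSC, FRiP and peak overlap against independent
brute-force oracles."""
import numpy as np
import pytest

from sonichip import qc_metrics as qc
from sonichip import synthetic_data as sd
from sonichip.core import AlignedReadSet, IntervalSet

from conftest import uniform_reads


def brute_force_cc(reads: AlignedReadSet, max_shift: int) -> np.ndarray:
    """Hand Pearson of fwd vs d-shifted rev 5'-end count vectors (one chrom)."""
    (chrom,) = set(reads.chrom)
    size = reads.chrom_sizes[chrom]
    five = reads.five_prime()
    f = np.bincount(five[reads.strand == "+"], minlength=size).astype(float)
    r = np.bincount(five[reads.strand == "-"], minlength=size).astype(float)
    return np.array(
        [np.corrcoef(f[: size - d], r[d:])[0, 1] for d in range(max_shift + 1)]
    )


def fragment_reads(starts, frag_len, chrom_len, read_len=36):
    """Two reads per fragment: forward at the start, reverse 5' at the last
    fragment base."""
    chroms, s, l, st = [], [], [], []
    for x in starts:
        chroms += ["chrS", "chrS"]
        s += [x, x + frag_len - read_len]
        l += [read_len, read_len]
        st += ["+", "-"]
    return AlignedReadSet(chroms, s, l, st, {"chrS": chrom_len})


class TestReadAlignments:
    def test_unmapped_and_chrm_filtered(self, tmp_path):
        import pysam

        path = tmp_path / "toy.sam"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "chr1", "LN": 1000}, {"SN": "chrM", "LN": 500},
                         {"SN": "chr1_random", "LN": 400}]}
        with pysam.AlignmentFile(path, "w", header=header) as out:
            def rec(tid, pos, flag=0):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"r{tid}_{pos}"
                a.reference_id = tid
                a.reference_start = pos
                a.flag = flag
                a.cigarstring = None if flag & 4 else "36M"
                a.mapping_quality = 30
                return a
            for pos in (10, 50, 90, 130, 170):
                out.write(rec(0, pos))
            for pos in (10, 20):
                out.write(rec(-1, -1, flag=4))  # unmapped
            for pos in (5, 15, 25):
                out.write(rec(1, pos))  # chrM
            out.write(rec(2, 7))       # unplaced
        reads = qc.read_alignments(path)
        assert len(reads) == 5
        assert set(reads.chrom) == {"chr1"}
        kept_all = qc.read_alignments(path, drop_mito=False, drop_unplaced=False)
        assert len(kept_all) == 9

    def test_simulator_sam_round_trip(self, sim_experiment, tmp_path):
        reads = sim_experiment["reads"]
        reads.to_sam(tmp_path / "sim.sam")
        back = qc.read_alignments(tmp_path / "sim.sam")
        assert len(back) == len(reads)
        np.testing.assert_array_equal(np.sort(back.five_prime()),
                                      np.sort(reads.five_prime()))
        assert back.read_length == reads.read_length


class TestStrandCC:
    def test_matches_hand_pearson_at_every_shift(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.choice(np.arange(100, 1800), size=10, replace=False))
        reads = fragment_reads(starts, frag_len=100, chrom_len=2000)
        prof = qc.strand_cc_profile(reads, max_shift=150)
        brute = brute_force_cc(reads, 150)
        np.testing.assert_allclose(prof.cc, brute, rtol=1e-10, atol=1e-12)
        assert prof.shift[np.argmax(prof.cc)] == 99  # length 100, half-open 5' ends
        assert (np.abs(prof.cc) <= 1 + 1e-12).all()

    def test_shifted_copy_gives_unit_correlation_at_zero(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(200, 1800), size=20, replace=False))
        # reverse reads whose 5' ends coincide with the forward 5' ends
        reads = AlignedReadSet(
            ["chrS"] * 40,
            np.concatenate([pos, pos - 35]),
            np.full(40, 36),
            ["+"] * 20 + ["-"] * 20,
            {"chrS": 2000},
        )
        prof = qc.strand_cc_profile(reads, max_shift=50)
        assert prof.cc[0] == pytest.approx(1.0)

    def test_single_strand_rejected(self):
        reads = AlignedReadSet(["chrS"] * 3, [10, 50, 90], [36] * 3, ["+"] * 3,
                               {"chrS": 1000})
        with pytest.raises(ValueError, match="both strands"):
            qc.strand_cc_profile(reads, 100)


class TestNscRsc:
    @staticmethod
    def synthetic_profile(read_length=36, frag_shift=200, cc_min=0.01,
                          cc_frag=0.05, cc_phantom=0.03, max_shift=400):
        cc = np.full(max_shift + 1, cc_min)
        cc[frag_shift] = cc_frag
        cc[read_length] = cc_phantom
        return qc.CrossCorrelationProfile(np.arange(max_shift + 1), cc, read_length)

    def test_definition_arithmetic(self):
        res = qc.nsc_rsc(self.synthetic_profile())
        assert res.nsc == pytest.approx(5.0)
        assert res.rsc == pytest.approx(2.0)
        assert res.est_fragment_length == 200
        assert res.phantom_shift == 36

    def test_fragment_peak_inside_exclusion_zone_is_ignored(self):
        prof = self.synthetic_profile(frag_shift=40)  # inside 36 +- 10
        res = qc.nsc_rsc(prof)
        assert res.est_fragment_length != 40

    def test_undefined_rsc_reported_not_raised(self):
        prof = self.synthetic_profile(cc_phantom=0.01)  # phantom == cc_min
        res = qc.nsc_rsc(prof)
        assert np.isnan(res.rsc)
        assert any("RSC undefined" in d for d in res.diagnostics)

    def test_fragment_length_recovery_over_seeds(self, motif):
        """Simulated 200 bp fragments, 36 bp reads: estimate within +-20 bp."""
        for seed in range(5):
            g = sd.simulate_genome(300_000, 0.45, seed=100 + seed)
            sites = sd.place_sites(g, motif, 60, 40, seed=200 + seed)
            reads = sd.simulate_chip_reads(
                g, sites, sd.IPEfficiencyModel.no_occlusion(), 200, 30,
                20_000, 36, background_fraction=0.5, seed=300 + seed,
            )
            res = qc.nsc_rsc(qc.strand_cc_profile(reads, 400))
            assert abs(res.est_fragment_length - 200) <= 20

    def test_uniform_reads_have_no_fragment_peak(self):
        """i.i.d. reads: RSC stays far below the 1.5-2.5 clean-data band."""
        rscs = []
        for seed in range(5):
            reads = uniform_reads(20_000, 200_000, seed=seed)
            rscs.append(qc.nsc_rsc(qc.strand_cc_profile(reads, 400)).rsc)
        assert np.mean(rscs) < 1.5


class TestFrip:
    def test_counting_fraction(self):
        reads = AlignedReadSet(
            ["chrS"] * 100, np.arange(100) * 100, np.full(100, 36), ["+"] * 100,
            {"chrS": 20_000},
        )
        peaks = IntervalSet.from_arrays("chrS", [0], [40 * 100 - 80])
        assert qc.frip(reads, peaks) == pytest.approx(0.40)

    def test_empty_peaks_zero(self, sim_experiment):
        import pandas as pd

        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert qc.frip(sim_experiment["reads"], empty) == 0.0

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(17)
        n, m, L = 1000, 100, 50_000
        reads = uniform_reads(n, L, seed=18)
        starts = rng.integers(0, L - 500, m)
        peaks = IntervalSet.from_arrays(
            "chrS", starts, starts + rng.integers(50, 500, m)
        )
        got = qc.frip(reads, peaks)
        hit = 0
        ps, pe = peaks.df["start"].to_numpy(), peaks.df["end"].to_numpy()
        for s, e in zip(reads.start, reads.end):
            hit += bool(((s < pe) & (e > ps)).any())
        assert got == pytest.approx(hit / n)

    def test_monotone_under_peak_union(self, sim_experiment):
        reads, truth = sim_experiment["reads"], sim_experiment["truth"]
        half = truth.subset(np.arange(len(truth)) < len(truth) // 2)
        assert qc.frip(reads, half) <= qc.frip(reads, truth)

    def test_uniform_reads_match_area_fraction(self):
        reads = uniform_reads(30_000, 1_000_000, seed=19)
        peaks = IntervalSet.from_arrays(
            "chrS", np.arange(10) * 100_000, np.arange(10) * 100_000 + 1000
        )
        # overlap rule: each 1000 bp peak catches reads starting in a
        # (1000 + read_len - 1) bp window
        expect = 10 * (1000 + 35) / (1_000_000 - 36)
        sigma = (expect / 30_000) ** 0.5
        assert qc.frip(reads, peaks) == pytest.approx(expect, abs=4 * sigma)


class TestOverlapPeaks:
    def test_half_open_boundary(self):
        a = IntervalSet.from_arrays("c", [100], [200])
        kept = qc.overlap_peaks(a, IntervalSet.from_arrays("c", [199], [300]))
        assert len(kept.intervals) == 1 and kept.fraction == 1.0
        dropped = qc.overlap_peaks(a, IntervalSet.from_arrays("c", [200], [300]))
        assert len(dropped.intervals) == 0 and dropped.fraction == 0.0

    def test_self_overlap_identity(self, sim_experiment):
        truth = sim_experiment["truth"]
        res = qc.overlap_peaks(truth, truth)
        assert len(res.intervals) == len(truth)
        assert res.fraction == 1.0

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(23)
        L = 10_000
        mk = lambda seed: IntervalSet.from_arrays(
            "c",
            s := np.random.default_rng(seed).integers(0, L - 200, 60),
            s + np.random.default_rng(seed + 1).integers(10, 200, 60),
        )
        a, b = mk(1), mk(3)
        got = qc.overlap_peaks(a, b)
        bs, be = b.df["start"].to_numpy(), b.df["end"].to_numpy()
        expect = [
            bool(((s < be) & (e > bs)).any())
            for s, e in zip(a.df["start"], a.df["end"])
        ]
        assert got.intervals.df["name"].tolist() == a.df.loc[expect, "name"].tolist()


class TestFripHc:
    def test_peaks_subset_of_hc_equals_frip(self, sim_experiment):
        reads, truth = sim_experiment["reads"], sim_experiment["truth"]
        assert qc.frip_hc(reads, truth, truth) == qc.frip(reads, truth)

    def test_disjoint_hc_zero(self, sim_experiment):
        reads, truth = sim_experiment["reads"], sim_experiment["truth"]
        g = sim_experiment["genome"]
        far = IntervalSet.from_arrays(g.name, [g.length - 50], [g.length - 10])
        assert qc.frip_hc(reads, truth, far) == 0.0

    def test_decoy_peaks_reduce_frip_hc(self, sim_experiment):
        reads, truth = sim_experiment["reads"], sim_experiment["truth"]
        g = sim_experiment["genome"]
        rng = np.random.default_rng(29)
        ds = rng.integers(0, g.length - 400, 50)
        decoys = IntervalSet.from_arrays(g.name, ds, ds + 300)
        peaks = truth.union(decoys)
        assert qc.frip_hc(reads, peaks, truth) <= qc.frip(reads, peaks)


class TestCallPeaksSimple:
    def test_null_calibration(self):
        """False-call rate on uniform reads stays at or below the nominal
        threshold (Poisson discreteness makes it conservative)."""
        called = windows = 0
        for seed in range(10):
            reads = uniform_reads(20_000, 1_000_000, seed=40 + seed)
            peaks = qc.call_peaks_simple(reads, window=200,
                                         fdr_like_threshold=1e-5)
            called += len(peaks)
            windows += 1_000_000 // 200
        # expected <= windows * 1e-5 = 0.5; allow generous sampling slack
        assert called <= 5

    def test_strong_site_called_exactly(self, motif):
        g = sd.simulate_genome(200_000, 0.5, seed=50)
        sites = sd.place_sites(g, motif, 1, 0, seed=51)
        reads = sd.simulate_chip_reads(
            g, sites, sd.IPEfficiencyModel.no_occlusion(), 200, 20,
            10_000, background_fraction=0.0, seed=52,
        )
        peaks = qc.call_peaks_simple(reads, window=200, fragment_length=200)
        assert len(peaks) == 1
        s, e = peaks.df.loc[0, "start"], peaks.df.loc[0, "end"]
        assert s <= sites[0].position < e

    def test_empty_control_matches_no_control(self, sim_experiment):
        reads = sim_experiment["reads"]
        empty = AlignedReadSet([], [], [], [], dict(reads.chrom_sizes))
        a = qc.call_peaks_simple(reads, control=None, window=200)
        b = qc.call_peaks_simple(reads, control=empty, window=200)
        assert a.df[["chrom", "start", "end"]].equals(b.df[["chrom", "start", "end"]])

    def test_control_raises_local_lambda(self, motif):
        """Windows enriched in the control stop being called."""
        g = sd.simulate_genome(200_000, 0.5, seed=53)
        sites = sd.place_sites(g, motif, 1, 0, seed=54)
        treat = sd.simulate_chip_reads(
            g, sites, sd.IPEfficiencyModel.no_occlusion(), 200, 20,
            5_000, background_fraction=0.0, seed=55,
        )
        no_ctrl = qc.call_peaks_simple(treat, window=200, fragment_length=200)
        ctrl = sd.simulate_chip_reads(
            g, sites, sd.IPEfficiencyModel.no_occlusion(), 200, 20,
            5_000, background_fraction=0.0, seed=56,
        )
        with_ctrl = qc.call_peaks_simple(treat, control=ctrl, window=200,
                                         fragment_length=200)
        assert len(no_ctrl) >= 1
        assert len(with_ctrl) == 0
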