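import numpy as np
import pytest

from refnorm import (GenomicRegion, aggregate_profile, bin_genome, bin_track,
                     extract_signal, track_total_signal, write_bigwig)
from refnorm.errors import DataError
from conftest import make_track


class TestExtractSignal:
    def test_constant_track_gives_constant_rows(self, tmp_path):
        p = tmp_path / "c.bw"
        make_track(p, {"chrA": np.full(200, 5.0)})
        mat = extract_signal(p, [GenomicRegion("chrA", 4000, 4400)], n_bins=8, flank=400)
        assert np.allclose(mat.values, 5.0)

    def test_rectangular_pulse_hits_one_bin(self, tmp_path):
        # pulse of height 10 exactly covering bin [5000, 5050); extraction
        # window [4800, 5200) with 8 x 50bp bins puts it in bin index 4
        p = tmp_path / "p.bw"
        arr = np.zeros(200)
        arr[100] = 10.0
        make_track(p, {"chrA": arr})
        mat = extract_signal(p, [GenomicRegion("chrA", 4900, 5100)], n_bins=8, flank=200)
        expected = np.zeros(8)
        expected[4] = 10.0
        assert np.allclose(mat.values[0], expected)

    def test_step_function_bin_means_match_direct_summation(self, tmp_path):
        # step: 1.0 on [0, 5000), 3.0 on [5000, 10000); oracle recomputes
        # each bin mean by direct base-pair summation over the step
        p = tmp_path / "s.bw"
        arr = np.where(np.arange(200) < 100, 1.0, 3.0)
        make_track(p, {"chrA": arr})
        region = GenomicRegion("chrA", 4875, 4925)  # center 4900
        mat = extract_signal(p, [region], n_bins=4, flank=300)
        base = np.repeat(arr, 50)  # per-bp values
        oracle = [base[4600 + 150 * k: 4600 + 150 * (k + 1)].mean() for k in range(4)]
        assert np.allclose(mat.values[0], oracle)

    def test_minus_strand_row_is_reversed_forward_row(self, tmp_path):
        p = tmp_path / "r.bw"
        rng = np.random.default_rng(0)
        make_track(p, {"chrA": rng.uniform(0, 5, 400)})
        fwd = GenomicRegion("chrA", 9000, 9400, strand="+")
        rev = GenomicRegion("chrA", 9000, 9400, strand="-")
        mat = extract_signal(p, [fwd, rev], n_bins=10, flank=500)
        assert np.allclose(mat.values[1], mat.values[0][::-1])

    def test_window_clipped_at_chromosome_start_pads_zero(self, tmp_path):
        p = tmp_path / "e.bw"
        make_track(p, {"chrA": np.full(100, 2.0)})
        # center 100: window [-900, 1100), first bins fall off the chromosome
        mat = extract_signal(p, [GenomicRegion("chrA", 50, 150)], n_bins=10, flank=1000)
        assert mat.values[0][0] == 0.0
        assert mat.values[0][-1] == 2.0

    def test_missing_chromosome_is_listed(self, tmp_path):
        p = tmp_path / "m.bw"
        make_track(p, {"chrA": np.ones(100)})
        with pytest.raises(DataError, match="chrZ"):
            extract_signal(p, [GenomicRegion("chrZ", 1000, 2000)])


class TestAggregateProfile:
    def test_mean_of_rows(self, tmp_path):
        p = tmp_path / "a.bw"
        bins = make_track(p, {"chrA": np.arange(200, dtype=float)})
        mat = extract_signal(p, [GenomicRegion("chrA", 2000, 2400),
                                 GenomicRegion("chrA", 6000, 6400)], n_bins=4, flank=200)
        assert np.allclose(aggregate_profile(mat), mat.values.mean(axis=0))

    def test_single_row_is_identity(self, tmp_path):
        p = tmp_path / "a.bw"
        make_track(p, {"chrA": np.arange(200, dtype=float)})
        mat = extract_signal(p, [GenomicRegion("chrA", 2000, 2400)], n_bins=4, flank=200)
        assert np.allclose(aggregate_profile(mat), mat.values[0])

    def test_permutation_invariance(self, tmp_path):
        p = tmp_path / "a.bw"
        rng = np.random.default_rng(1)
        make_track(p, {"chrA": rng.uniform(0, 10, 400)})
        regions = [GenomicRegion("chrA", s, s + 200) for s in range(2000, 12000, 2000)]
        mat = extract_signal(p, regions, n_bins=8, flank=400)
        shuffled = mat.subset(rng.permutation(len(regions)))
        assert np.allclose(aggregate_profile(mat), aggregate_profile(shuffled))

    def test_noisy_gaussian_rows_recover_template_within_3_sem(self, tmp_path):
        rng = np.random.default_rng(2)
        n_bins, n_rows, sd = 20, 100, 0.3
        template = 1 + 8 * np.exp(-((np.arange(n_bins) - 9.5) ** 2) / 8.0)
        rows = np.clip(template + rng.normal(0, sd, (n_rows, n_bins)), 0, None)
        from refnorm import SignalMatrix
        regions = [GenomicRegion("c", 1000 * i, 1000 * i + 100) for i in range(n_rows)]
        prof = aggregate_profile(SignalMatrix(regions, rows, flank=500))
        sem = sd / np.sqrt(n_rows)
        # clipping at 0 never triggers here (template >> 3*sd), so the mean is unbiased
        assert np.all(np.abs(prof - template) < 3.5 * sem + 1e-12)


class TestBigWigRoundTrip:
    def test_write_then_read_recovers_values_within_float32(self, tmp_path):
        rng = np.random.default_rng(3)
        arrays = {f"chr{i}": rng.uniform(0, 100, rng.integers(50, 150)) for i in range(3)}
        p = tmp_path / "rt.bw"
        bins = make_track(p, arrays)
        back = bin_track(p, bins)
        for ch, v in arrays.items():
            assert np.allclose(back[ch], v, rtol=1e-6, atol=1e-5)

    def test_all_zero_track_reads_back_zero(self, tmp_path):
        p = tmp_path / "z.bw"
        bins = make_track(p, {"chrA": np.zeros(100)})
        assert np.all(bin_track(p, bins)["chrA"] == 0.0)

    def test_rejects_negative_or_nonfinite_values(self, tmp_path):
        bins = bin_genome({"chrA": 100}, 50)
        with pytest.raises(DataError):
            write_bigwig(bins, {"chrA": np.array([1.0, -2.0])}, tmp_path / "bad.bw")
        with pytest.raises(DataError):
            write_bigwig(bins, {"chrA": np.array([1.0, np.nan])}, tmp_path / "bad.bw")

    def test_total_signal_matches_sum(self, tmp_path):
        arr = np.array([1.0, 2.0, 3.0])
        p = tmp_path / "t.bw"
        make_track(p, {"chrA": arr}, bin_size=10)
        assert track_total_signal(p) == pytest.approx(arr.sum() * 10, rel=1e-6)
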