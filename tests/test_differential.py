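import numpy as np
import pytest
from scipy import stats

from refnorm import (GenomicRegion, RunConfig, fold_change_call, ma_transform,
                     poisson_test, quantify_regions, run_differential)
from refnorm.errors import ConfigError, DataError
from conftest import make_track


def poisson_two_sided_oracle(lam, k):
    """Brute-force pmf summation: p = 2*min(P[X<=k], P[X>=k]) capped at 1."""
    ks = np.arange(0, max(int(k), int(lam)) + 200)
    pmf = stats.poisson.pmf(ks, lam)
    lower = pmf[ks <= k].sum()
    upper = pmf[ks >= k].sum()
    return min(1.0, 2.0 * min(lower, upper))


class TestQuantifyRegions:
    def test_constant_tracks(self, tmp_path):
        c, t = tmp_path / "c.bw", tmp_path / "t.bw"
        make_track(c, {"chrA": np.full(100, 5.0)})
        make_track(t, {"chrA": np.full(100, 10.0)})
        regions = [GenomicRegion("chrA", 100, 600), GenomicRegion("chrA", 2000, 2100)]
        vc, vt = quantify_regions(c, t, regions)
        assert np.allclose(vc, 5.0) and np.allclose(vt, 10.0)

    def test_region_covering_one_bin_returns_that_value(self, tmp_path):
        p = tmp_path / "b.bw"
        arr = np.zeros(100)
        arr[10] = 7.0
        make_track(p, {"chrA": arr})
        vc, _ = quantify_regions(p, p, [GenomicRegion("chrA", 500, 550)])
        assert vc[0] == pytest.approx(7.0, rel=1e-6)

    def test_step_function_mean_matches_direct_summation(self, tmp_path):
        p = tmp_path / "s.bw"
        arr = np.where(np.arange(100) < 40, 2.0, 6.0)
        make_track(p, {"chrA": arr})
        region = GenomicRegion("chrA", 1900, 2300)  # straddles the step at 2000
        vc, _ = quantify_regions(p, p, [region])
        base = np.repeat(arr, 50)
        assert vc[0] == pytest.approx(base[1900:2300].mean(), rel=1e-6)

    def test_missing_chromosome(self, tmp_path):
        p = tmp_path / "m.bw"
        make_track(p, {"chrA": np.ones(10)})
        with pytest.raises(DataError, match="chrB"):
            quantify_regions(p, p, [GenomicRegion("chrB", 0, 10)])


class TestFoldChangeCall:
    def test_equal_values_unchanged(self):
        assert fold_change_call(np.array([10.0]), np.array([10.0]), 1.5)[0] == "unchanged"

    def test_boundary_ratio_is_inclusive(self):
        # (9+1)/(4+1) = 2.0 exactly -> called up at cutoff 2
        assert fold_change_call(np.array([4.0]), np.array([9.0]), 2.0, 1.0)[0] == "up"
        # just below the boundary is not called
        assert fold_change_call(np.array([4.0]), np.array([8.94]), 2.0, 1.0)[0] == "unchanged"

    def test_matches_brute_force_inequalities(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(0, 20, 500)
        tgt = rng.uniform(0, 20, 500)
        calls = fold_change_call(ctrl, tgt, 2.0, 1.0)
        for i in range(500):
            r = (tgt[i] + 1) / (ctrl[i] + 1)
            expected = "up" if r >= 2 else ("down" if 1 / r >= 2 else "unchanged")
            assert calls[i] == expected

    def test_antisymmetry_under_sample_swap(self):
        rng = np.random.default_rng(1)
        ctrl = rng.uniform(0, 20, 300)
        tgt = rng.uniform(0, 20, 300)
        fwd = fold_change_call(ctrl, tgt, 2.0)
        rev = fold_change_call(tgt, ctrl, 2.0)
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert [swap[c] for c in fwd] == list(rev)

    def test_cutoff_below_one_rejected(self):
        with pytest.raises(ConfigError):
            fold_change_call(np.ones(1), np.ones(1), 0.5)


class TestPoissonTest:
    def test_center_of_distribution_is_not_significant(self):
        assert poisson_test(5, 5, 1.0) >= 0.5

    def test_matches_pmf_summation_oracle(self):
        for lam in (0.5, 1, 3, 7.7, 20, 50):
            for k in (0, 1, 3, 10, 60, 200):
                p = poisson_test(lam, k, 1.0, pseudo_floor=0.0)
                assert p == pytest.approx(poisson_two_sided_oracle(lam, k), abs=1e-12)

    def test_double_floor_degenerate_zeros_cap_at_one(self):
        assert poisson_test(0, 0, 1.0, pseudo_floor=1.0) == 1.0

    def test_exposure_ratio_scales_rate(self):
        assert poisson_test(10, 30, 3.0) == pytest.approx(
            poisson_two_sided_oracle(30, 30), abs=1e-12)

    def test_invalid_exposure(self):
        with pytest.raises(ConfigError):
            poisson_test(1, 1, 0.0)


class TestRunDifferential:
    def test_identical_tracks_yield_no_calls(self, tmp_path):
        p = tmp_path / "x.bw"
        rng = np.random.default_rng(2)
        make_track(p, {"chrA": rng.uniform(1, 10, 200)})
        regions = [GenomicRegion("chrA", s, s + 500) for s in range(0, 9000, 1000)]
        for stat in ("fc", "poisson", "both"):
            df = run_differential(p, p, regions, config=RunConfig(stat=stat, make_plots=False))
            assert not df["significant"].any()
            assert (df["direction"] == "unchanged").all()

    def test_empty_region_list_is_vacuous_success(self, tmp_path):
        p = tmp_path / "x.bw"
        make_track(p, {"chrA": np.ones(50)})
        out = tmp_path / "out"
        df = run_differential(p, p, [], config=RunConfig(make_plots=False), outdir=out)
        assert len(df) == 0
        assert (out / "calls.tsv").exists()
        assert (out / "up.bed").read_text() == ""

    def test_m_and_a_consistent_with_ma_transform(self, tmp_path):
        c, t = tmp_path / "c.bw", tmp_path / "t.bw"
        rng = np.random.default_rng(3)
        make_track(c, {"chrA": rng.uniform(0, 10, 200)})
        make_track(t, {"chrA": rng.uniform(0, 10, 200)})
        regions = [GenomicRegion("chrA", s, s + 400) for s in range(0, 8000, 800)]
        cfg = RunConfig(make_plots=False)
        df = run_differential(c, t, regions, config=cfg)
        ma = ma_transform(df["value_control"].to_numpy(),
                          df["value_target"].to_numpy(), cfg.pseudocount)
        assert np.allclose(df["M"], ma.M) and np.allclose(df["A"], ma.A)

    def test_planted_folds_recovered_on_normalized_pair(self, normalized_pair, tmp_path):
        truth, result = normalized_pair
        out = tmp_path / "diff"
        df = run_differential(truth.control_path, str(result.output_path),
                              truth.candidates_bed,
                              config=RunConfig(make_plots=False), outdir=out)
        planted = {r.name for r, _ in truth.planted_differential}
        called = set(df.loc[df["significant"], "name"])
        missed = planted - called
        false = called - planted
        assert len(missed) / len(planted) <= 0.05
        assert len(false) / max(len(called), 1) <= 0.1
        # planted direction agrees with the dialed fold
        by_name = df.set_index("name")
        for region, fold in truth.planted_differential:
            if region.name in called:
                want = "up" if fold > 1 else "down"
                assert by_name.loc[region.name, "direction"] == want
        # BED export keeps the calls' coordinates
        from refnorm import read_bed
        up = read_bed(out / "up.bed") if (out / "up.bed").read_text() else []
        up_names = {r.name for r in up}
        assert up_names == set(df.loc[df["direction"] == "up", "name"])
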