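import numpy as np
import pytest
import scipy.stats

import riskcline as rc
from riskcline.null_resampling import correct_multiplicity, EmpiricalResult


def _matrix(freqs, prefix="rs"):
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    return rc.FrequencyMatrix(
        np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        [f"p{j}" for j in range(freqs.shape[1])],
        freqs,
        np.array(["A"] * n, dtype=object),
    )


class TestBinning:
    @pytest.mark.parametrize(
        "freq, bin_idx",
        [(0.16, 1), (1.0, 9), (0.1, 1), (0.0, 0), (0.95, 9), (0.3999, 3)],
        ids=["worked-example", "top-closed", "half-open-edge", "bottom", "upper", "interior"],
    )
    def test_bin_assignment(self, freq, bin_idx):
        m = _matrix([[freq]])
        bins = rc.bin_by_global_frequency(m)
        assert bins.bin_of[0] == bin_idx
        assert bins.bin_index(freq) == bin_idx

    def test_pools_partition_all_snps(self, small_world):
        bins = rc.bin_by_global_frequency(small_world["matrix"])
        assert sum(len(p) for p in bins.pools) == small_world["matrix"].n_snps

    def test_global_frequency_is_unweighted_population_mean(self):
        m = _matrix([[0.1, 0.5]])  # mean 0.3 -> bin 3
        assert rc.bin_by_global_frequency(m).bin_of[0] == 3

    def test_european_mode_bins_on_subset(self):
        m = _matrix([[0.05, 0.95]])
        assert rc.bin_by_global_frequency(m, populations=["p1"]).bin_of[0] == 9


class TestResampleSet:
    def test_contract_length_distinct_disjoint(self, small_world):
        m = small_world["matrix"]
        rs = rc.make_risk_sets(m, [15], seed=20)[0]
        bins = rc.bin_by_global_frequency(m)
        got = rc.resample_set(rs, bins, m, rng=21)
        assert len(got) == 15
        assert len(set(got)) == 15
        assert not set(got) & set(rs.snp_ids)

    def test_every_draw_matches_its_bin(self, small_world):
        m = small_world["matrix"]
        rs = rc.make_risk_sets(m, [20], seed=22)[0]
        bins = rc.bin_by_global_frequency(m)
        risk_bins = bins.bin_of[m.rows(rs.snp_ids)]
        for trial in range(20):
            got = rc.resample_set(rs, bins, m, rng=100 + trial)
            assert np.array_equal(bins.bin_of[m.rows(got)], risk_bins)

    def test_single_alternative_is_deterministic(self):
        # one risk SNP whose bin holds exactly one other SNP
        m = _matrix([[0.15, 0.15], [0.12, 0.12], [0.55, 0.55]])
        rs = rc.RiskSet("d", [("rs0", "A")])
        bins = rc.bin_by_global_frequency(m)
        for trial in range(5):
            assert rc.resample_set(rs, bins, m, rng=trial) == ["rs1"]

    def test_exhausted_pool_names_the_bin(self):
        m = _matrix([[0.15, 0.15], [0.55, 0.55]])
        rs = rc.RiskSet("d", [("rs0", "A")])
        bins = rc.bin_by_global_frequency(m)
        with pytest.raises(ValueError, match=r"\[0\.1, 0\.2\)"):
            rc.resample_set(rs, bins, m, rng=0)

    def test_inclusion_uniform_within_binomial_error(self):
        # 12 eligible SNPs in one bin, panel of 2; chi-square on inclusion counts
        rows = [[0.42, 0.42]] * 14
        m = _matrix(rows)
        rs = rc.RiskSet("d", [("rs0", "A"), ("rs1", "A")])
        bins = rc.bin_by_global_frequency(m)
        rng = np.random.default_rng(23)
        counts = {f"rs{i}": 0 for i in range(2, 14)}
        n_draws = 6000
        for _ in range(n_draws):
            for s in rc.resample_set(rs, bins, m, rng=rng):
                counts[s] += 1
        observed = np.array(list(counts.values()))
        _, p = scipy.stats.chisquare(observed)
        assert p > 0.001


class TestBuildNull:
    def test_identical_frequency_twin_reproduces_observed_r2(self, small_world):
        m0 = small_world["matrix"]
        # duplicate 5 SNPs under new ids so each has an exact-frequency twin
        freq = np.vstack([m0.freq, m0.freq[:5]])
        ids = np.concatenate([m0.snp_ids, [f"twin{i}" for i in range(5)]])
        m = rc.FrequencyMatrix(ids, list(m0.populations), freq,
                               np.array(["A"] * len(ids), dtype=object))
        rs = rc.RiskSet("d", [(s, "A") for s in m0.snp_ids[:5]])
        pred = small_world["predictors"]
        # force the twins to be the only alternatives by shrinking pools:
        bins = rc.bin_by_global_frequency(m)
        risk_rows = set(m.rows(rs.snp_ids).tolist())
        twin_rows = m.rows([f"twin{i}" for i in range(5)])
        bins.pools = [
            np.array(sorted(r for r in twin_rows if bins.bin_of[r] == b), dtype=np.intp)
            if set(pool.tolist()) & risk_rows else pool
            for b, pool in enumerate(bins.pools)
        ]
        nulls = rc.build_null(rs, m, pred, statistic="heterozygosity", n_sets=3, seed=1, bins=bins)
        observed = rc.observed_r_squared(rs, m, pred, "heterozygosity")
        for name, nd in nulls.items():
            assert np.allclose(nd.r_squared_samples, observed[name], atol=1e-12)

    def test_same_seed_identical_null(self, small_world):
        m, pred = small_world["matrix"], small_world["predictors"]
        rs = rc.make_risk_sets(m, [10], seed=24)[0]
        a = rc.build_null(rs, m, pred, n_sets=50, seed=7)
        b = rc.build_null(rs, m, pred, n_sets=50, seed=7)
        for k in a:
            assert np.array_equal(a[k].r_squared_samples, b[k].r_squared_samples)

    def test_matches_slow_reimplementation_statistically(self, small_world):
        """Null mean agrees with an independent one-set-at-a-time pipeline."""
        m, pred = small_world["matrix"], small_world["predictors"]
        rs = rc.make_risk_sets(m, [12], seed=25)[0]
        bins = rc.bin_by_global_frequency(m)
        fast = rc.build_null(rs, m, pred, statistic="heterozygosity",
                             n_sets=1000, seed=8, bins=bins)["distance_km"]
        base = rc.genomewide_baseline(m)
        rng = np.random.default_rng(9)
        slow = []
        for _ in range(300):
            ids = rc.resample_set(rs, bins, m, rng=rng)
            fake = rc.RiskSet("resample", [(s, "A") for s in ids])
            prof = rc.adjusted_profile(rc.risk_profile(m, fake), base)
            slow.append(rc.ols(prof.table["adj_heterozygosity"], pred["distance_km"]).r_squared)
        slow = np.array(slow)
        se = np.sqrt(fast.r_squared_samples.var() / fast.n_sets + slow.var() / len(slow))
        assert abs(fast.r_squared_samples.mean() - slow.mean()) < 4 * se
        assert fast.r_squared_samples.std() == pytest.approx(slow.std(), rel=0.3)


class TestEmpiricalP:
    def test_extremes_and_paper_scale(self):
        null = rc.NullDistribution("d", "het", "x", np.linspace(0.0, 0.5, 10_000))
        assert rc.empirical_p(0.9, null) == 0.0
        assert rc.empirical_p(-0.1, null) == 1.0
        # 300 of 10,000 samples higher -> 0.03
        samples = np.concatenate([np.full(9700, 0.2), np.full(300, 0.8)])
        assert rc.empirical_p(0.5, rc.NullDistribution("d", "het", "x", samples)) == 0.03

    def test_ties_count_as_not_higher(self):
        null = rc.NullDistribution("d", "het", "x", np.full(100, 0.4))
        assert rc.empirical_p(0.4, null) == 0.0

    def test_plus_one_estimator_never_zero(self):
        null = rc.NullDistribution("d", "het", "x", np.linspace(0, 0.5, 999))
        assert rc.empirical_p(0.9, null, plus_one=True) == pytest.approx(1 / 1000)


class TestCorrectMultiplicity:
    def _results(self, pvals):
        return [
            EmpiricalResult("d", "het", f"v{i}", 0.5, p) for i, p in enumerate(pvals)
        ]

    def test_bonferroni_threshold(self):
        res = correct_multiplicity(self._results([0.0024] + [1.0] * 19))
        assert res[0].bonferroni_significant
        res = correct_multiplicity(self._results([0.0026] + [1.0] * 19))
        assert not res[0].bonferroni_significant

    def test_all_ones_no_flags(self):
        res = correct_multiplicity(self._results([1.0] * 20))
        assert not any(r.bonferroni_significant or r.fdr_significant for r in res)

    def test_bh_walkthrough(self):
        # hand-computed BH at q=0.2 over 20 tests: sorted p vs 0.2*k/20 = 0.01*k
        # p = (0.003, 0.011, 0.02, 0.041, 1, ...): thresholds 0.01, 0.02, 0.03,
        # 0.04 -> largest k with p_(k) <= 0.01k is k=3 (0.02 <= 0.03); reject 3.
        pvals = [0.003, 0.011, 0.02, 0.041] + [1.0] * 16
        res = correct_multiplicity(self._results(pvals))
        flags = [r.fdr_significant for r in res]
        assert flags[:4] == [True, True, True, False]
        assert not any(flags[4:])

    def test_unexpected_test_count_warns(self):
        with pytest.warns(UserWarning):
            correct_multiplicity(self._results([0.5] * 7))


class TestEvaluatePanelCalibration:
    def test_neutral_panel_p_not_extreme(self, small_world):
        """A neutral random panel should sit inside the bulk of its null."""
        m, pred = small_world["matrix"], small_world["predictors"]
        hits = 0
        for i in range(30):
            rs = rc.make_risk_sets(m, [15], seed=600 + i)[0]
            res = rc.evaluate_panel(rs, m, pred, statistics=("heterozygosity",),
                                    n_sets=200, seed=700 + i)
            hits += sum(r.empirical_p < 0.025 or r.empirical_p > 0.975 for r in res)
        # 30 panels x 10 predictors, nominal ~5% outside the central 95%
        assert hits / 300 < 0.15
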