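"""Kinetic null model: rates, order probability, simulation, excess test,
steady-state square law."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from spliceorder.kinetic_model import (
    KineticParams,
    PairKinetics,
    SteadyStateModel,
    draw_splicing_rate,
    excess_test,
    p_upstream_first,
    p_upstream_first_mc,
    parameter_sweep,
    simulate_null_distribution,
    simulate_pair,
    steady_state_intermediate_ratio,
    transcription_delay,
    extrapolate_dependent_intron_count,
)
from spliceorder.order_inference import OrderDistribution, bin_distribution
from spliceorder.synthetic import generate_cohort


class TestRateDraws:
    def test_zero_sd_returns_mean(self, rng):
        params = KineticParams(rate_sd=0.0)
        assert draw_splicing_rate(params, rng) == pytest.approx(0.169)

    def test_seed_determinism(self):
        params = KineticParams()
        a = draw_splicing_rate(params, np.random.default_rng(5), size=100)
        b = draw_splicing_rate(params, np.random.default_rng(5), size=100)
        np.testing.assert_array_equal(a, b)

    def test_sample_moments(self, rng):
        """1e5 draws: mean within 1% of 0.169, sd within 5% of 0.048."""
        draws = draw_splicing_rate(KineticParams(), rng, size=100_000)
        assert draws.mean() == pytest.approx(0.169, rel=0.01)
        assert draws.std() == pytest.approx(0.048, rel=0.05)
        assert (draws > 0).all()

    def test_mostly_negative_distribution_refused(self, rng):
        # ~46% of this distribution is non-positive: rejection would distort
        # the intended law, so the draw is refused
        with pytest.raises(ValueError, match="truncat"):
            draw_splicing_rate(KineticParams(rate_mean=0.01, rate_sd=0.1), rng)


class TestOrderProbability:
    def test_symmetric_zero_delay(self):
        assert p_upstream_first(0.3, 0.3, 0.0) == pytest.approx(0.5)

    def test_competing_exponentials_zero_delay(self):
        assert p_upstream_first(0.2, 0.1, 0.0) == pytest.approx(2 / 3)

    def test_default_geometry_value(self):
        """150-nt exon + 3-kb downstream intron at 3.87 kb/min, equal
        rates: delay ~0.814 min, p ~0.5643 (frozen from the Monte-Carlo
        oracle)."""
        delay = transcription_delay(150, 3000, 3.87)
        assert delay == pytest.approx(0.81395, abs=1e-4)
        assert p_upstream_first(0.169, 0.169, delay) == pytest.approx(0.5643, abs=5e-4)

    def test_monotone_in_delay_and_rate(self):
        delays = np.linspace(0, 10, 25)
        p = p_upstream_first(0.169, 0.169, delays)
        assert (np.diff(p) >= 0).all()
        rates = np.linspace(0.01, 1.0, 25)
        p2 = p_upstream_first(rates, 0.169, 0.5)
        assert (np.diff(p2) >= 0).all()

    def test_limits(self):
        assert p_upstream_first(0.2, 0.1, 1e6) == pytest.approx(1.0)
        assert p_upstream_first(0.2, 0.3, 0.0) == pytest.approx(0.4)

    @pytest.mark.parametrize("k_up", [0.05, 0.169, 0.5])
    @pytest.mark.parametrize("k_down", [0.05, 0.169, 0.5])
    @pytest.mark.parametrize("delay", [0.0, 0.8, 5.0])
    def test_against_mc_oracle(self, k_up, k_down, delay):
        """Closed form vs brute-force two-exponential race, 1e5 draws per
        grid point, within 3 binomial standard errors."""
        rng = np.random.default_rng(hash((k_up, k_down, delay)) % 2**31)
        n = 100_000
        est = p_upstream_first_mc(k_up, k_down, delay, n, rng)
        p = p_upstream_first(k_up, k_down, delay)
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(est - p) <= 3 * se + 1e-9


class TestPairSimulation:
    def test_degenerate_p_one(self, rng):
        pk = PairKinetics(k_up=100.0, k_down=1e-9 + 0.001, delay=50.0, n_reads=20)
        assert simulate_pair(pk, rng) == 0.0

    def test_determinism(self):
        pk = PairKinetics(0.169, 0.169, 0.8, 10)
        a = simulate_pair(pk, np.random.default_rng(3))
        b = simulate_pair(pk, np.random.default_rng(3))
        assert a == b

    def test_binomial_oracle_mean(self, rng):
        """1e4 replicates at p_downstream_first = 0.3, n = 10: replicate
        mean within 0.01 of 0.3."""
        # choose rates/delay so that 1 - p_upstream_first = 0.3
        # at delay 0: k_down/(k_up+k_down) = 0.3
        pk = PairKinetics(k_up=0.7, k_down=0.3, delay=0.0, n_reads=10)
        sims = [simulate_pair(pk, rng) for _ in range(10_000)]
        assert np.mean(sims) == pytest.approx(0.3, abs=0.01)


class TestNullDistribution:
    def _table(self, n, exon=0, down=0, reads=20):
        return pd.DataFrame(
            {"exon_len": [exon] * n, "down_intron_len": [down] * n, "n_reads": [reads] * n}
        )

    def test_zero_delay_equal_rates_symmetric(self):
        tab = self._table(4000, exon=0, down=0)
        params = KineticParams(rate_sd=0.0)
        dist = simulate_null_distribution(tab, params, n_bins=20, seed=1, n_reps=20)
        left = dist.counts[:10].sum()
        right = dist.counts[10:].sum()
        # fraction 0.5 falls in the right half bin [0.5,0.55); compare
        # strictly-below vs strictly-above mass instead
        fr_mid = dist.counts[10]
        assert abs(left - (dist.total - left - fr_mid)) < 0.1 * dist.total

    def test_fast_transcription_removes_bias(self):
        tab = pd.DataFrame(
            {"exon_len": [150] * 3000, "down_intron_len": [3000] * 3000, "n_reads": [50] * 3000}
        )
        slow = simulate_null_distribution(tab, KineticParams(txn_rate=1.9), seed=2, n_reps=5)
        fast = simulate_null_distribution(tab, KineticParams(txn_rate=1000.0), seed=2, n_reps=5)

        def mean_frac(d):
            mids = (d.bin_edges[:-1] + d.bin_edges[1:]) / 2
            return float((d.counts * mids).sum() / d.total)

        assert mean_frac(slow) < mean_frac(fast)
        assert mean_frac(fast) == pytest.approx(0.5, abs=0.02)

    def test_missing_lengths_skipped(self):
        tab = pd.DataFrame(
            {
                "exon_len": [150, np.nan],
                "down_intron_len": [1000, 2000],
                "n_reads": [10, 10],
            }
        )
        dist = simulate_null_distribution(tab, KineticParams(), seed=0, n_reps=3)
        assert dist.total == pytest.approx(1.0)


class TestExcessTest:
    def _dist(self, counts):
        c = np.asarray(counts, dtype=float)
        return OrderDistribution(np.linspace(0, 1, len(c) + 1), c)

    def test_identity_gives_zero(self):
        d = self._dist([10, 20, 30, 20, 10])
        res = excess_test(d, d)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_scale_property(self):
        obs = self._dist([30, 50, 40, 60, 20])
        sim = self._dist([40, 40, 40, 40, 40])
        r1 = excess_test(obs, sim)
        r2 = excess_test(self._dist([60, 100, 80, 120, 40]), self._dist([80] * 5))
        assert r2.chi_square == pytest.approx(2 * r1.chi_square)

    def test_mismatched_edges_rejected(self):
        a = self._dist([1, 2, 3])
        b = self._dist([1, 2, 3, 4])
        with pytest.raises(ValueError):
            excess_test(a, b)

    def test_first_last_bin_excess_reported(self):
        obs = self._dist([50, 10, 10, 10, 50])
        sim = self._dist([26, 26, 26, 26, 26])
        res = excess_test(obs, sim)
        assert res.first_bin_excess == pytest.approx(50 - 26)
        assert res.last_bin_excess == pytest.approx(50 - 26)

    def test_small_bins_pooled(self):
        obs = self._dist([100, 0.5, 0.5, 0.5, 100])
        sim = self._dist([100, 0.5, 0.5, 0.5, 100])
        res = excess_test(obs, sim)
        assert res.df < 4  # pooling reduced the effective bin count

    def test_forced_always_first_cohort_detected(self, rng):
        """20% dependency-forced pairs against the kinetic null: strongly
        significant."""
        params = KineticParams()
        cohort = generate_cohort(1000, params, rng, dep_fraction=0.2)
        obs = bin_distribution(cohort["fraction_downstream_first"], 20)
        null = simulate_null_distribution(cohort, params, n_bins=20, seed=rng, n_reps=50)
        assert excess_test(obs, null).p_value < 0.001


class TestSteadyStateSquareLaw:
    @pytest.mark.parametrize("ratio,expected", [(2.0, 4.0), (0.5, 0.25), (1.0, 1.0)])
    def test_square_of_rate_ratio(self, ratio, expected):
        m = SteadyStateModel(k1=0.1 * ratio, k2=0.1)
        assert steady_state_intermediate_ratio(m) == pytest.approx(expected)

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0, 4.0])
    def test_against_forward_integration(self, ratio):
        """Integrate P -> I1 -> M, P -> I2 -> M at constant synthesis to
        steady state; [I1]/[I2] must match (k1/k2)^2 within 0.1%."""
        k1, k2 = 0.2 * ratio, 0.2
        s = 1.0

        def rhs(t, y):
            P, I1, I2, M = y
            return [
                s - (k1 + k2) * P,
                k1 * P - k2 * I1,
                k2 * P - k1 * I2,
                k2 * I1 + k1 * I2,
            ]

        t_end = 400.0 / min(k1, k2)
        sol = solve_ivp(rhs, (0, t_end), [0, 0, 0, 0], rtol=1e-10, atol=1e-12)
        I1, I2 = sol.y[1, -1], sol.y[2, -1]
        assert I1 / I2 == pytest.approx((k1 / k2) ** 2, rel=1e-3)

    def test_reciprocal_symmetry(self):
        a = steady_state_intermediate_ratio(SteadyStateModel(0.2, 0.1))
        b = steady_state_intermediate_ratio(SteadyStateModel(0.1, 0.2))
        assert a * b == pytest.approx(1.0)


class TestParameterSweep:
    def _cohort(self, rng, n=400):
        return generate_cohort(n, KineticParams(), rng)

    def test_grid_of_one_matches_direct_call(self, rng):
        cohort = self._cohort(rng)
        obs = bin_distribution(cohort["fraction_downstream_first"], 20)
        df = parameter_sweep(cohort, obs, {"txn_rate": [3.87]}, seed=9, n_reps=10)
        rng2 = np.random.default_rng(np.random.SeedSequence(9).spawn(1)[0])
        direct = simulate_null_distribution(cohort, KineticParams(), seed=rng2, n_reps=10)
        from spliceorder.kinetic_model import excess_test as et

        assert df.loc[0, "chi_square"] == pytest.approx(et(obs, direct).chi_square)

    def test_row_count_is_grid_size(self, rng):
        cohort = self._cohort(rng, 200)
        obs = bin_distribution(cohort["fraction_downstream_first"], 20)
        df = parameter_sweep(
            cohort, obs, {"txn_rate": [1.9, 3.87], "rate_sd": [0.0, 0.048]},
            seed=3, n_reps=3,
        )
        assert len(df) == 4

    def test_upstream_bias_decreases_with_txn_rate(self, rng):
        """Faster polymerase -> shorter delays -> weaker upstream-first
        bias (mean simulated downstream-first fraction rises toward 0.5)."""
        cohort = self._cohort(rng, 2000)
        obs = bin_distribution(cohort["fraction_downstream_first"], 20)
        df = parameter_sweep(
            cohort, obs, {"txn_rate": [1.9, 3.87, 7.7]}, seed=11, n_reps=10
        )
        means = df.sort_values("txn_rate")["mean_null_fraction"].to_numpy()
        assert (np.diff(means) > 0).all()


def test_extrapolation_arithmetic():
    assert extrapolate_dependent_intron_count(0.4, 18_000) == pytest.approx(7200)
    with pytest.raises(ValueError):
        extrapolate_dependent_intron_count(1.4, 100)
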