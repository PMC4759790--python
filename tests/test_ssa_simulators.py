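import numpy as np
import pytest
from scipy import stats

from burstswitch.model_core import ModelParams
from burstswitch.ssa_simulators import (
    DiscreteState,
    proteins_per_mrna_lifetime,
    sample_burst,
    simulate,
    stationary_histogram,
)
from burstswitch.summary_stats import js_distance


class TestSampleBurst:
    def test_geometric_moments(self):
        rng = np.random.default_rng(0)
        k = sample_burst("geometric", 30.0, rng, size=1_000_000)
        assert k.min() >= 0
        assert k.mean() == pytest.approx(30.0, abs=0.1)
        # E[k^2] = 2B^2 + B
        assert np.mean(k.astype(float) ** 2) == pytest.approx(1830.0, rel=0.01)

    def test_geometric_mass_at_zero(self):
        rng = np.random.default_rng(1)
        k = sample_burst("geometric", 30.0, rng, size=1_000_000)
        # P(0) = 1/(1+B) = 1/31
        assert np.mean(k == 0) == pytest.approx(1.0 / 31.0, abs=5e-4)

    def test_constant(self):
        rng = np.random.default_rng(2)
        k = sample_burst("constant", 30.0, rng, size=100)
        assert np.all(k == 30)
        assert sample_burst("constant", 30.0, rng) == 30

    def test_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            sample_burst("geometric", -1.0, rng)
        with pytest.raises(ValueError):
            sample_burst("constant", 2.5, rng)
        with pytest.raises(ValueError):
            sample_burst("lognormal", 3.0, rng)


class TestMrnaLifecycle:
    def test_mean_and_variance(self, table1):
        # translation gB = 900 vs degradation gamma = 30: geometric with
        # mean B = 30 and variance B(B+1) = 930
        k = proteins_per_mrna_lifetime(table1, 100_000, seed=7)
        se = k.std() / np.sqrt(len(k))
        assert abs(k.mean() - 30.0) < 3 * se
        assert k.var() == pytest.approx(930.0, rel=0.05)


class TestSimulate:
    def test_unknown_tag(self, table1):
        with pytest.raises(ValueError, match="unknown model tag"):
            simulate("XX", table1, t_end=1.0)

    def test_cb_requires_integer_burst(self):
        p = ModelParams(B=4.5, K=50.0)
        with pytest.raises(ValueError, match="integer"):
            simulate("CB", p, t_end=1.0)

    @pytest.mark.parametrize("tag", ["FM", "GB", "CB", "NB"])
    def test_trajectory_contract(self, mini_toggle, tag):
        init = DiscreteState(NX=40, NY=5)
        traj = simulate(tag, mini_toggle, initial=init, t_end=5.0, seed=9)
        assert traj.model == tag
        assert np.all(np.diff(traj.t) > 0)
        for col in ("NX", "NY"):
            assert np.all(traj.column(col) >= 0)
        assert traj.final_state["t"] == pytest.approx(5.0)
        if tag == "FM":
            assert "mX" in traj.columns
        else:
            assert "mX" not in traj.columns

    def test_seed_reproducibility(self, mini_toggle):
        init = DiscreteState(NX=40, NY=5)
        a = simulate("GB", mini_toggle, initial=init, t_end=5.0, seed=11)
        b = simulate("GB", mini_toggle, initial=init, t_end=5.0, seed=11)
        c = simulate("GB", mini_toggle, initial=init, t_end=5.0, seed=12)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_chunked_continuation(self, mini_toggle):
        # tiny buffer forces multiple kernel chunks; time stays monotone
        init = DiscreteState(NX=40, NY=5)
        traj = simulate("GB", mini_toggle, initial=init, t_end=5.0, seed=1,
                        max_events=200)
        assert traj.final_state["t"] == pytest.approx(5.0)
        assert np.all(np.diff(traj.t) > 0)


class TestStationaryHistogram:
    def test_absorbing_origin(self):
        p = ModelParams(r=0.0, r0=0.0)
        for tag in ("FM", "GB", "NB"):
            h = stationary_histogram(
                tag, p, t_burn=1.0, t_total=10.0, seed=3,
                initial=DiscreteState(NX=0, NY=0), nmax=10,
            )
            assert h.masses[0, 0] == pytest.approx(1.0)

    def test_burn_in_validation(self, mini_toggle):
        with pytest.raises(ValueError):
            stationary_histogram("GB", mini_toggle, t_burn=10.0, t_total=5.0)

    def test_gb_broader_than_nb(self, table1):
        hg = stationary_histogram("GB", table1, 50.0, 1050.0, seed=5)
        hn = stationary_histogram("NB", table1, 50.0, 1050.0, seed=6)
        assert hg.variance()[0] > hn.variance()[0]

    def test_negative_binomial_oracle(self, frozen_rate):
        # frozen-rate GB: stationary law is NB(shape a/gamma0,
        # success B/(1+B)); X and Y are iid so both marginals pool
        lam = frozen_rate.r0 * frozen_rate.K
        h = stationary_histogram(
            "GB", frozen_rate, 50.0, 400_050.0, seed=13,
            initial=DiscreteState(NX=20, NY=20), nmax=300,
        )
        ks = np.arange(300)
        ref = stats.nbinom.pmf(ks, lam / frozen_rate.gamma0,
                               1.0 / (1.0 + frozen_rate.B))
        ref /= ref.sum()
        pooled = 0.5 * (h.marginal_x() + h.marginal_y())
        assert js_distance(pooled, ref) < 5e-3

    def test_poisson_oracle_single_births(self):
        # NB engine with B = 1 is a linear birth-death process:
        # stationary law Poisson(a/gamma0)
        p = ModelParams(B=1.0, K=50.0, r=0.0, r0=8.0 / 50.0)
        h = stationary_histogram(
            "NB", p, 50.0, 200_050.0, seed=15,
            initial=DiscreteState(NX=8, NY=8), nmax=60,
        )
        ks = np.arange(60)
        ref = stats.poisson.pmf(ks, 8.0)
        ref /= ref.sum()
        pooled = 0.5 * (h.marginal_x() + h.marginal_y())
        assert js_distance(pooled, ref) < 5e-3

    def test_flux_balance(self, mini_toggle):
        # time-averaged production flux of X equals gamma0 * E[N_X]
        h = stationary_histogram("GB", mini_toggle, 50.0, 20_050.0, seed=17)
        flux = h.meta["prodX"] / h.meta["w_tot"]
        assert flux == pytest.approx(
            mini_toggle.gamma0 * h.meta["mean_NX"], rel=0.05
        )

    def test_fm_small_mrna_numbers(self, table1):
        # mean mRNA copy number ~ a/gamma stays below 0.5
        h = stationary_histogram("FM", table1, 50.0, 1050.0, seed=19)
        assert h.meta["mean_mX"] < 0.5
        assert h.meta["mean_mY"] < 0.5

    def test_fm_frozen_mrna_mean(self):
        # frozen regulation: mRNA marginal is Poisson(a/gamma)
        p = ModelParams(r=0.0, r0=6.0 / 200.0)  # a = 6 per cycle
        h = stationary_histogram(
            "FM", p, 20.0, 2020.0, seed=21, initial=DiscreteState(NX=180, NY=180)
        )
        assert h.meta["mean_mX"] == pytest.approx(6.0 / p.gamma, rel=0.1)

    def test_xy_symmetry_of_law(self, mini_toggle):
        # pooling mirrored initial conditions, the law is symmetric
        # under species swap: compare the histogram to its transpose
        ha = stationary_histogram(
            "GB", mini_toggle, 50.0, 30_050.0, seed=23,
            initial=DiscreteState(NX=40, NY=5), nmax=200,
        )
        hb = stationary_histogram(
            "GB", mini_toggle, 50.0, 30_050.0, seed=24,
            initial=DiscreteState(NX=5, NY=40), nmax=200,
        )
        pooled = 0.5 * (ha.masses + hb.masses)
        assert js_distance(pooled.ravel(), pooled.T.ravel()) < 0.05
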