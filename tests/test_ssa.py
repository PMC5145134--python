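import numpy as np
import pytest
from scipy import stats

from stochcell import (
    Parameter,
    Reaction,
    ReactionNetworkModel,
    Species,
    run_ensemble,
    select_reaction,
    simulate_ode,
    simulate_ssa,
)

from conftest import immigration_death


class TestSelectReaction:
    def test_below_midpoint_selects_first(self):
        assert select_reaction([1.0, 1.0], 0.25) == 0

    def test_single_channel(self):
        for u in (0.01, 0.5, 0.99):
            assert select_reaction([3.7], u) == 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_reaction([0.0, 0.0], 0.5)

    def test_zero_propensity_channels_skipped(self):
        # a zero channel can never be selected (smallest-index tie rule)
        assert select_reaction([0.0, 2.0, 0.0], 1e-12) == 1

    def test_empirical_frequencies_match_categorical(self):
        """Selection frequencies over 1e5 uniform draws match p_j = a_j/a0
        by chi-square at alpha = 0.01 (categorical oracle)."""
        rng = np.random.default_rng(123)
        a = rng.uniform(0.1, 5.0, size=6)
        draws = rng.random(100_000)
        picks = np.array([select_reaction(a, u) for u in draws])
        observed = np.bincount(picks, minlength=len(a))
        expected = len(draws) * a / a.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=len(a) - 1)


class TestSimulateSSA:
    def test_no_reactions_constant_trajectory(self):
        m = ReactionNetworkModel("still", "population", species=[Species("A", 7)])
        traj = simulate_ssa(m, 10.0, [0.0, 5.0, 10.0], seed=1)
        assert np.all(traj["A"] == 7)

    def test_rejects_concentration_model(self, grn_ode):
        with pytest.raises(ValueError, match="population"):
            simulate_ssa(grn_ode, 1.0, [0.0, 1.0], seed=1)

    def test_immigration_death_stationary_poisson(self):
        """End states after ~12 relaxation times follow Poisson(mu/gamma);
        chi-square against the analytic pmf at alpha = 0.01."""
        m = immigration_death(mu=10.0, gamma=1.0)
        ens = run_ensemble(m, "ssa-direct", 2000, 11, [0.0, 12.0])
        samples = ens.end_states("A").astype(int)
        lam = 10.0
        kmax = samples.max()
        observed = np.bincount(samples, minlength=kmax + 1)
        expected = 2000 * stats.poisson.pmf(np.arange(kmax + 1), lam)
        # merge low-expectation tails for chi-square validity
        obs, exp = _merge_tails(observed, expected, min_expected=5.0)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=len(obs) - 1)

    def test_closed_system_conservation_exact(self):
        m = ReactionNetworkModel(
            "iso",
            "population",
            species=[Species("A", 50), Species("B", 0)],
            parameters=[Parameter("kf", 1.0), Parameter("kr", 0.5)],
            reactions=[
                Reaction("f", {"A": 1}, {"B": 1}, rate_parameter="kf"),
                Reaction("r", {"B": 1}, {"A": 1}, rate_parameter="kr"),
            ],
        )
        traj = simulate_ssa(m, 5.0, np.linspace(0, 5, 21), seed=5)
        assert np.all(traj["A"] + traj["B"] == 50)

    def test_direct_and_odm_same_distribution(self, grn_wellmixed):
        """KS distance between direct and optimized-direct end-state samples
        stays below the alpha = 0.01 two-sample critical value."""
        n = 2000
        direct = run_ensemble(grn_wellmixed, "ssa-direct", n, 21, [0.0, 1500.0])
        odm = run_ensemble(grn_wellmixed, "ssa-optimized_direct", n, 22, [0.0, 1500.0])
        ks = stats.ks_2samp(direct.end_states("P"), odm.end_states("P"))
        critical = 1.628 * np.sqrt(2 * n / (n * n))  # c(0.01) * sqrt((n+m)/(nm))
        assert ks.statistic < critical

    def test_linear_network_mean_matches_ode(self):
        """For a first-order network the SSA ensemble mean equals the rate
        equations at every output time, within 3 standard errors."""
        m = immigration_death(mu=20.0, gamma=0.5)
        times = np.linspace(0, 8, 9)
        ens = run_ensemble(m, "ssa-direct", 400, 33, times)
        ode = simulate_ode(
            ReactionNetworkModel(
                "id_conc",
                "concentration",
                species=[Species("A", 0.0)],
                parameters=[Parameter("mu", 20.0), Parameter("gamma", 0.5)],
                reactions=[
                    Reaction("in", {}, {"A": 1}, rate_parameter="mu"),
                    Reaction("out", {"A": 1}, {}, rate_parameter="gamma"),
                ],
            ),
            times,
        )
        mean = ens.mean()[:, 0]
        se = np.sqrt(ens.variance()[:, 0] / ens.n_reps)
        gap = np.abs(mean - ode["A"])
        assert np.all(gap[1:] <= 3 * se[1:] + 1e-9)


class TestEnsemble:
    def test_single_replicate_statistics(self):
        m = immigration_death(5.0, 1.0)
        ens = run_ensemble(m, "ssa-direct", 1, 3, [0.0, 2.0])
        assert np.all(ens.mean() == ens.trajectories[0].values)
        assert np.all(ens.variance() == 0.0)

    def test_same_seed_bitwise_identical(self, grn_wellmixed):
        times = [0.0, 500.0, 1000.0]
        a = run_ensemble(grn_wellmixed, "ssa-direct", 5, 99, times)
        b = run_ensemble(grn_wellmixed, "ssa-direct", 5, 99, times)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.values, tb.values)

    def test_statistics_recomputable_from_replicates(self, grn_wellmixed):
        ens = run_ensemble(grn_wellmixed, "ssa-direct", 8, 4, [0.0, 800.0])
        stack = np.stack([t.values for t in ens.trajectories]).astype(float)
        assert np.allclose(ens.mean(), stack.mean(axis=0))
        assert np.allclose(ens.variance(), stack.var(axis=0))

    def test_grn_reduced_workload_statistics_finite(self, grn_wellmixed):
        """A scaled-down bulk ensemble of the gene-expression model yields
        finite, positive mean expression with no NaNs."""
        ens = run_ensemble(grn_wellmixed, "ssa", 200, 17, np.linspace(0, 3600, 7))
        mean, var = ens.mean(), ens.variance()
        assert np.all(np.isfinite(mean)) and np.all(np.isfinite(var))
        assert mean[-1, ens.species_names.index("P")] > 0

    def test_rejects_zero_replicates(self, grn_wellmixed):
        with pytest.raises(ValueError):
            run_ensemble(grn_wellmixed, "ssa", 0, 1, [0.0, 1.0])


def _merge_tails(observed, expected, min_expected=5.0):
    """Pool bins from both ends until every expected count is adequate."""
    obs, exp = list(observed.astype(float)), list(expected)
    while len(exp) > 2 and exp[0] < min_expected:
        o0, e0 = obs.pop(0), exp.pop(0)
        obs[0] += o0
        exp[0] += e0
    while len(exp) > 2 and exp[-1] < min_expected:
        o_last, e_last = obs.pop(), exp.pop()
        obs[-1] += o_last
        exp[-1] += e_last
    return np.array(obs), np.array(exp)
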