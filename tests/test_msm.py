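"""MSM core: counting, reversible MLE, ITS, CK, PCCA+, MFPT, Bayesian draws."""

import numpy as np
import pytest
import scipy.optimize

from msmbind import (
    DiscreteChainSpec,
    FeatureSeries,
    bayesian_sample,
    ck_test,
    count_transitions,
    estimate_reversible_msm,
    generate_discrete_chain,
    implied_timescales,
    kmeans_discretize,
    largest_connected_set,
    mfpt,
    mfpt_monte_carlo,
    pcca_two_state,
    reversible_mle,
    stationary_distribution,
)


def series_1d(arrays):
    return FeatureSeries(
        metric_id="SHORTEST_N_CA",
        values=[np.asarray(a, float).reshape(-1, 1) for a in arrays],
        dimension=1,
        frame_spacing=1.0,
    )


def brute_force_reversible_mle(C):
    """Direct numerical maximisation of the detailed-balance likelihood.

    Parameterises the symmetric fluxes in log space and maximises
    sum_ij C_ij log(x_ij / x_i) with scipy — independent of the fixed-point
    implementation it checks.
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    iu = np.triu_indices(n)

    def unpack(theta):
        x = np.zeros((n, n))
        x[iu] = np.exp(theta)
        x = x + x.T - np.diag(np.diag(x))
        return x

    def neg_ll(theta):
        x = unpack(theta)
        xi = x.sum(axis=1)
        return -np.sum(C * (np.log(x) - np.log(xi)[:, None]))

    x0 = C + C.T + 1.0
    theta0 = np.log(x0[iu])
    res = scipy.optimize.minimize(
        neg_ll, theta0, method="L-BFGS-B",
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 20000},
    )
    x = unpack(res.x)
    xi = x.sum(axis=1)
    return x / xi[:, None], xi / xi.sum()


class TestCounting:
    @pytest.mark.parametrize(
        "dtraj,lag,expected",
        [
            ([0, 0, 1, 1, 0], 1, [[1, 1], [1, 1]]),
            ([0, 0, 1, 1, 0], 2, [[0, 2], [1, 0]]),
        ],
    )
    def test_sliding_window_examples(self, dtraj, lag, expected):
        C = count_transitions([np.array(dtraj)], float(lag), 1.0)
        np.testing.assert_array_equal(C, expected)

    def test_no_cross_replica_pairs(self):
        C = count_transitions([np.array([0, 1]), np.array([1, 0])], 1.0, 1.0)
        np.testing.assert_array_equal(C, [[0, 1], [1, 0]])

    def test_lag_longer_than_replicas_errors(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions([np.array([0, 1, 0])], 5.0, 1.0)

    def test_non_multiple_lag_errors(self):
        with pytest.raises(ValueError, match="multiple"):
            count_transitions([np.array([0, 1, 0])], 1.5, 1.0)

    def test_matches_pair_enumeration_on_random_dtrajs(self):
        """100 random instances against a per-pair counting oracle."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_states = rng.integers(2, 6)
            dtrajs = [
                rng.integers(0, n_states, size=rng.integers(5, 40))
                for _ in range(rng.integers(1, 4))
            ]
            lag = int(rng.integers(1, 4))
            try:
                C = count_transitions(dtrajs, float(lag), 1.0, n_states=n_states)
            except ValueError:
                assert all(len(d) <= lag for d in dtrajs)
                continue
            oracle = np.zeros((n_states, n_states))
            for d in dtrajs:
                for t in range(len(d) - lag):
                    oracle[d[t], d[t + lag]] += 1
            np.testing.assert_array_equal(C, oracle)


class TestReversibleMLE:
    def test_symmetric_counts_give_symmetric_t(self):
        model = estimate_reversible_msm(np.array([[8.0, 2.0], [2.0, 8.0]]), lag=1.0)
        np.testing.assert_allclose(model.transition_matrix, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)
        np.testing.assert_allclose(model.stationary_distribution, [0.5, 0.5], atol=1e-10)

    def test_two_state_closed_form_stationary(self):
        """Counts sampled from T=[[.9,.1],[.2,.8]] recover π = (2/3, 1/3)."""
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([2 / 3, 1 / 3])
        C = 30_000 * pi[:, None] * T  # expected counts: reversibility exact
        model = estimate_reversible_msm(C, lag=1.0)
        np.testing.assert_allclose(model.transition_matrix, T, atol=1e-8)
        np.testing.assert_allclose(model.stationary_distribution, pi, atol=1e-8)

    def test_matches_brute_force_optimizer(self):
        """Random 4-state counts: MLE equals direct constrained optimisation."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            C = rng.integers(1, 2500, size=(4, 4)).astype(float)
            T, pi = reversible_mle(C)
            T_bf, pi_bf = brute_force_reversible_mle(C)
            np.testing.assert_allclose(T, T_bf, atol=1e-6)
            np.testing.assert_allclose(pi, pi_bf, atol=1e-6)

    def test_detailed_balance_and_row_stochasticity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(2, 8)
            C = rng.integers(1, 100, size=(n, n)).astype(float)
            T, pi = reversible_mle(C)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
            np.testing.assert_allclose(
                pi[:, None] * T, (pi[:, None] * T).T, atol=1e-8
            )

    def test_trimming_keeps_largest_component(self):
        # states {0,1} strongly connected; state 2 only receives
        C = np.array([[5.0, 5.0, 1.0], [5.0, 5.0, 0.0], [0.0, 0.0, 0.0]])
        model = estimate_reversible_msm(C, lag=1.0)
        np.testing.assert_array_equal(model.active_set, [0, 1])
        assert model.n_states_full == 3

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            reversible_mle(np.zeros((2, 2)))


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        """λ2 = 0.7 at τ = 200 ps gives t2 = -200/ln 0.7 = 560.7 ps."""
        pi = np.array([0.5, 0.5])
        T = np.array([[0.85, 0.15], [0.15, 0.85]])  # λ2 = 0.7
        C = 1e6 * pi[:, None] * T
        model = estimate_reversible_msm(C, lag=200.0)
        t2 = model.implied_timescales(1)[0]
        assert t2 == pytest.approx(-200.0 / np.log(0.7), rel=1e-9)
        assert t2 == pytest.approx(560.7, abs=0.05)

    def test_unit_eigenvalue_flagged_infinite(self):
        pi = np.array([0.5, 0.5])
        T = np.eye(2)
        C = 100 * pi[:, None] * T + 1e-12  # numerically reducible
        model = estimate_reversible_msm(C, lag=1.0)
        assert np.isinf(model.implied_timescales(1)[0])

    def test_markovian_data_have_flat_its(self):
        """Exact Markov chain: t2 lag-independent within the Bayesian CI."""
        T = np.array([[0.95, 0.05], [0.1, 0.9]])
        spec = DiscreteChainSpec(T, n_steps=50_000, n_replicas=4, seed=5)
        dtrajs = generate_discrete_chain(spec)
        its = implied_timescales(
            dtrajs, lags=[1.0, 2.0, 3.0, 4.0, 5.0], n_its=1,
            frame_spacing=1.0, n_samples=40, seed=2,
        )
        lo, hi = its.confidence_interval(0.95)
        ts = its.timescales[:, 0]
        # flat in lag: all point estimates agree within 5%
        assert ts.max() / ts.min() < 1.05
        # and the generating chain's exact t2 sits within ~3 posterior SD
        lam2 = np.sort(np.linalg.eigvals(T).real)[0]
        t_true = -1.0 / np.log(lam2)
        post_sd = (hi[0, 0] - lo[0, 0]) / 3.92
        assert abs(ts[0] - t_true) < 3 * post_sd


class TestPCCA:
    def _block_model(self, coupling=1e-3):
        T = np.array(
            [
                [0.89, 0.1, coupling, coupling],
                [0.1, 0.89, coupling, coupling],
                [coupling, coupling, 0.89, 0.1],
                [coupling, coupling, 0.1, 0.89],
            ]
        )
        T = T / T.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
        C = 1e6 * pi[:, None] * T
        return estimate_reversible_msm(C, lag=1.0)

    def test_block_structure_recovered(self):
        model = self._block_model()
        macro = pcca_two_state(model, microstate_distances=np.array([1.0, 1.0, 9.0, 9.0]))
        crisp = macro.crisp_assignment
        assert crisp[0] == crisp[1] != crisp[2] == crisp[3]
        # low-distance block labelled bound (=1)
        assert crisp[0] == 1

    def test_memberships_partition_of_unity(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(3, 10)
            C = rng.integers(1, 50, size=(n, n)).astype(float)
            model = estimate_reversible_msm(C, lag=1.0)
            macro = pcca_two_state(model, microstate_distances=rng.uniform(1, 10, n))
            np.testing.assert_allclose(macro.memberships.sum(axis=1), 1.0, atol=1e-10)
            assert 0 <= macro.memberships.min() and macro.memberships.max() <= 1 + 1e-12
            assert macro.pi1 + macro.pi2 == pytest.approx(1.0, abs=1e-9)

    def test_pi_sums_over_assigned_microstates(self):
        model = self._block_model()
        macro = pcca_two_state(model, microstate_distances=np.array([1.0, 1.0, 9.0, 9.0]))
        pi = model.stationary_distribution
        assert macro.pi2 == pytest.approx(pi[macro.bound_set].sum(), abs=1e-12)
        assert macro.pi1 == pytest.approx(pi[macro.unbound_set].sum(), abs=1e-12)


class TestMFPT:
    def test_two_state_geometric_waiting_time(self):
        pi = np.array([2 / 3, 1 / 3])
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        C = 1e7 * pi[:, None] * T
        model = estimate_reversible_msm(C, lag=200.0)
        assert mfpt(model, [0], [1]) == pytest.approx(2000.0, rel=1e-6)
        assert mfpt(model, [1], [0]) == pytest.approx(1000.0, rel=1e-6)

    def test_overlapping_sets_rejected(self):
        C = np.array([[5.0, 5.0], [5.0, 5.0]])
        model = estimate_reversible_msm(C, lag=1.0)
        with pytest.raises(ValueError, match="disjoint"):
            mfpt(model, [0], [0])

    def test_three_state_matches_monte_carlo(self):
        T = np.array(
            [[0.9, 0.08, 0.02], [0.1, 0.85, 0.05], [0.05, 0.1, 0.85]]
        )
        pi = stationary_distribution(T)
        # build a reversible chain from the symmetrised flux of this T
        x = 0.5 * (pi[:, None] * T + (pi[:, None] * T).T)
        T_rev = x / x.sum(axis=1)[:, None]
        C = 1e7 * pi[:, None] * T_rev
        model = estimate_reversible_msm(C, lag=1.0)
        analytic = mfpt(model, [0], [2])
        walks = mfpt_monte_carlo(T_rev, 0, [2], lag=1.0, n_walks=100_000, seed=8)
        mc = walks.mean()
        sem = walks.std(ddof=1) / np.sqrt(len(walks))
        assert abs(analytic - mc) < 3 * sem


class TestBayesian:
    def test_posterior_mean_near_mle(self):
        pi = np.array([0.6, 0.4])
        T = np.array([[0.9, 0.1], [0.15, 0.85]])
        x = 0.5 * (pi[:, None] * T + (pi[:, None] * T).T)
        T_rev = x / x.sum(axis=1)[:, None]
        C = np.round(5e4 * x / x.sum() * 2)
        T_mle, _ = reversible_mle(C)
        draws = bayesian_sample(C, lag=1.0, n_samples=400, seed=9)
        mean_T = np.mean([m.transition_matrix for m in draws.models], axis=0)
        # posterior concentrates near the MLE at this count depth
        np.testing.assert_allclose(mean_T, T_mle, atol=0.01)

    def test_every_sample_reversible_and_stochastic(self):
        rng = np.random.default_rng(10)
        C = rng.integers(1, 60, size=(4, 4)).astype(float)
        draws = bayesian_sample(C, lag=1.0, n_samples=25, seed=11)
        assert draws.n_samples == 25
        for m in draws.models:
            T, pi = m.transition_matrix, m.stationary_distribution
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
            np.testing.assert_allclose(pi[:, None] * T, (pi[:, None] * T).T, atol=1e-10)

    def test_seeded_reproducibility(self):
        C = np.array([[50.0, 5.0], [5.0, 40.0]])
        a = bayesian_sample(C, lag=1.0, n_samples=3, seed=12)
        b = bayesian_sample(C, lag=1.0, n_samples=3, seed=12)
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.transition_matrix, mb.transition_matrix)

    def test_posterior_spread_shrinks_with_data(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([2 / 3, 1 / 3])
        spreads = []
        for scale in (1e2, 1e4):
            C = np.round(scale * pi[:, None] * T) + 1
            draws = bayesian_sample(C, lag=1.0, n_samples=150, seed=13)
            spreads.append(np.std([m.transition_matrix[0, 1] for m in draws.models]))
        assert spreads[1] < spreads[0] / 3


class TestCKTest:
    def _chain_model(self, T, n_steps=40_000, lag=1.0, seed=14):
        pi = stationary_distribution(T)
        spec = DiscreteChainSpec(T, n_steps=n_steps, n_replicas=4, seed=seed)
        dtrajs = generate_discrete_chain(spec)
        C = count_transitions(dtrajs, lag, 1.0)
        model = estimate_reversible_msm(C, lag)
        macro = pcca_two_state(
            model, microstate_distances=np.arange(model.n_states, dtype=float)
        )
        return model, macro, dtrajs

    def test_factor_one_predicted_equals_estimated(self):
        T = np.array([[0.95, 0.05], [0.1, 0.9]])
        model, macro, dtrajs = self._chain_model(T)
        res = ck_test(model, macro, dtrajs, 1.0, factors=[1])
        np.testing.assert_allclose(res.predicted[0], res.estimated[0], atol=1e-10)

    def test_markovian_data_pass_ck(self):
        """Exact Markov chain: prediction inside the 95% band at all factors."""
        T = np.array(
            [[0.94, 0.05, 0.01], [0.05, 0.9, 0.05], [0.01, 0.05, 0.94]]
        )
        model, macro, dtrajs = self._chain_model(T, n_steps=50_000)
        res = ck_test(
            model, macro, dtrajs, 1.0, factors=[1, 2, 3, 4, 5], n_samples=40, seed=15
        )
        inside = (res.est_lower - 0.01 <= res.predicted) & (
            res.predicted <= res.est_upper + 0.01
        )
        # diagonal entries at every factor
        assert inside[:, 0, 0].all() and inside[:, 1, 1].all()

    def test_hidden_state_violation_detected(self):
        """Merging two hidden states into one label breaks the CK test."""
        # 3-state chain where states 1 and 2 are lumped in the observation
        T = np.array(
            [[0.98, 0.02, 0.0], [0.05, 0.9, 0.05], [0.0, 0.02, 0.98]]
        )
        pi = stationary_distribution(T)
        spec = DiscreteChainSpec(T, n_steps=80_000, n_replicas=4, seed=16)
        dtrajs = [np.minimum(d, 1) for d in generate_discrete_chain(spec)]
        C = count_transitions(dtrajs, 1.0, 1.0)
        model = estimate_reversible_msm(C, 1.0)
        macro = pcca_two_state(model, microstate_distances=np.array([9.0, 1.0]))
        res = ck_test(
            model, macro, dtrajs, 1.0, factors=[1, 8], n_samples=40, seed=17
        )
        gap = np.abs(res.predicted[1] - res.estimated[1]).max()
        band = (res.est_upper[1] - res.est_lower[1]).max()
        assert gap > band  # systematic deviation beyond the statistical band


class TestKMeans:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(18)
        a = rng.normal(2.0, 0.1, size=(500, 1))
        b = rng.normal(12.0, 0.1, size=(500, 1))
        fs = series_1d([np.concatenate([a, b])])
        disc = kmeans_discretize(fs, k=2, seed=0)
        centers = np.sort(disc.centers[:, 0])
        assert abs(centers[0] - 2.0) < 0.2 and abs(centers[1] - 12.0) < 0.2

    def test_k_equals_n_points_zero_inertia(self):
        fs = series_1d([np.arange(5.0)])
        disc = kmeans_discretize(fs, k=5, seed=0)
        assert disc.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(disc.dtrajs[0])) == 5

    def test_seeded_determinism(self):
        rng = np.random.default_rng(19)
        fs = series_1d([rng.uniform(0, 10, 300), rng.uniform(0, 10, 200)])
        a = kmeans_discretize(fs, k=10, seed=4)
        b = kmeans_discretize(fs, k=10, seed=4)
        for da, db in zip(a.dtrajs, b.dtrajs):
            np.testing.assert_array_equal(da, db)

    def test_too_few_distinct_points_errors(self):
        fs = series_1d([np.array([1.0, 1.0, 1.0, 2.0])])
        with pytest.raises(ValueError, match="distinct"):
            kmeans_discretize(fs, k=3, seed=0)


class TestConnectivity:
    def test_relabeling_invariance_of_its(self):
        """Permuting microstate labels leaves implied timescales unchanged."""
        T = np.array([[0.9, 0.07, 0.03], [0.07, 0.9, 0.03], [0.05, 0.05, 0.9]])
        spec = DiscreteChainSpec(T, n_steps=30_000, n_replicas=2, seed=20)
        dtrajs = generate_discrete_chain(spec)
        perm = np.array([2, 0, 1])
        dtrajs_perm = [perm[d] for d in dtrajs]
        its_a = implied_timescales(dtrajs, [1.0, 2.0], 2, 1.0)
        its_b = implied_timescales(dtrajs_perm, [1.0, 2.0], 2, 1.0)
        np.testing.assert_allclose(its_a.timescales, its_b.timescales, rtol=1e-8)

    def test_largest_connected_set_by_size(self):
        C = np.zeros((5, 5))
        C[0, 1] = C[1, 0] = 1  # 2-cycle
        C[2, 3] = C[3, 4] = C[4, 2] = 1  # 3-cycle
        np.testing.assert_array_equal(largest_connected_set(C), [2, 3, 4])
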