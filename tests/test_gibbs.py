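"""Engine-level tests: initialisation, warm-up, sweeps, convergence
diagnostics, and result extraction."""

import numpy as np
import pytest

from bcrclone import gibbs, model
from bcrclone.model import ModelData


def _copy_state(s):
    import copy

    return copy.deepcopy(s)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


class TestInitialize:
    def test_identical_bcrs_share_cluster(self, tiny_hyper):
        x = model.encode_sequences(["AC", "AC", "GT", "GT", "GT"])
        data = ModelData(
            alt=np.zeros((1, 5), dtype=int),
            total=np.zeros((1, 5), dtype=int),
            omega=np.array([[1, 0]], dtype=np.int8),
            x=x,
        )
        hyper = model.Hyperparams(
            kappa=(1, 19), nu0=(0.2, 99.8), nu_i=np.array([[4.5, 5.5]]),
            g=np.full((2, 4), 0.01),
        )
        state = gibbs.initialize(data, hyper, 0)
        assert state.n_clusters == 2
        assert state.t[0] == state.t[1]
        assert len(set(state.t[2:])) == 1

    def test_distinct_bcrs_get_singletons(self, tiny_data, tiny_hyper):
        state = gibbs.initialize(tiny_data, tiny_hyper, 0)
        # cells 0 and 1 share a sequence; cell 2 differs
        assert state.n_clusters == 2

    def test_same_seed_same_state(self, tiny_data, tiny_hyper):
        s1 = gibbs.initialize(tiny_data, tiny_hyper, 42)
        s2 = gibbs.initialize(tiny_data, tiny_hyper, 42)
        assert np.array_equal(s1.t, s2.t)
        assert np.array_equal(s1.c, s2.c)
        assert s1.xi == s2.xi and s1.alpha0 == s2.alpha0
        assert np.allclose(s1.log_b, s2.log_b)


class TestWarmup:
    def test_t_is_held_fixed(self, tiny_data, tiny_hyper):
        rng = np.random.default_rng(0)
        state = gibbs.initialize(tiny_data, tiny_hyper, rng)
        t_before = state.t.copy()
        gibbs.warmup(state, tiny_data, tiny_hyper, 25, rng)
        assert np.array_equal(state.t, t_before)

    def test_zero_iterations_keep_discrete_state(self, tiny_data, tiny_hyper):
        rng = np.random.default_rng(0)
        state = gibbs.initialize(tiny_data, tiny_hyper, rng)
        c_before = state.c.copy()
        gibbs.warmup(state, tiny_data, tiny_hyper, 0, rng)
        assert np.array_equal(state.c, c_before)


# ---------------------------------------------------------------------------
# alpha0 sampler
# ---------------------------------------------------------------------------


class TestAlpha0:
    def test_mixture_weight_relation(self):
        # odds (a + Q - 1) / (M (b - ln sigma)); at a=b=1, Q=1, M=1 and
        # sigma -> 1 the two mixture components are equally likely
        w = gibbs.alpha0_mixture_weight((1.0, 1.0), 1, 1, 1 - 1e-12)
        assert w == pytest.approx(0.5, abs=1e-9)
        w2 = gibbs.alpha0_mixture_weight((1.0, 1.0), 5, 10, np.exp(-1.0))
        assert w2 / (1 - w2) == pytest.approx(5 / 20)

    def test_requires_positive_counts(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            gibbs.sample_alpha0(1.0, 0, 5, (1, 1), rng)

    def test_all_singletons_raise_posterior_mean(self):
        """Q = M pulls alpha0 above its prior mean of 1."""
        rng = np.random.default_rng(1)
        al = 1.0
        draws = []
        for _ in range(4000):
            al, _sig = gibbs.sample_alpha0(al, 50, 50, (1.0, 1.0), rng)
            draws.append(al)
        assert np.mean(draws[500:]) > 1.0


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("collapsed", [True, False])
def test_sweep_preserves_state_invariants(tiny_data, tiny_hyper, collapsed):
    rng = np.random.default_rng(3)
    state = gibbs.initialize(tiny_data, tiny_hyper, rng)
    for _ in range(30):
        gibbs.full_sweep(state, tiny_data, tiny_hyper, rng, collapsed_t=collapsed)
        state.validate()
        assert len(state.i_assign) == state.n_clusters
        assert np.all(state.occupancy() > 0)


def test_single_clone_no_bcr_variation_is_constant():
    """With K=1 every cell trivially maps to the only clone."""
    data = ModelData(
        alt=np.zeros((1, 3), dtype=int),
        total=np.zeros((1, 3), dtype=int),
        omega=np.array([[1]], dtype=np.int8),
        x=np.zeros((3, 1), dtype=np.int8),
    )
    hyper = model.Hyperparams(
        kappa=(1, 19), nu0=(0.2, 99.8), nu_i=np.array([[4.5, 5.5]]),
        g=np.full((1, 4), 0.01),
    )
    rng = np.random.default_rng(0)
    state = gibbs.initialize(data, hyper, rng)
    for _ in range(10):
        gibbs.full_sweep(state, data, hyper, rng)
        assert np.all(state.i_assign == 0)


def test_deterministic_fit(tiny_data, tiny_hyper):
    r1 = gibbs.fit(tiny_data, tiny_hyper, chains=2, seed=9, n_init=20, block=30,
                   max_blocks=1)
    r2 = gibbs.fit(tiny_data, tiny_hyper, chains=2, seed=9, n_init=20, block=30,
                   max_blocks=1)
    assert np.array_equal(r1.map_assignment, r2.map_assignment)
    assert np.array_equal(r1.map_genotypes, r2.map_genotypes)
    assert np.allclose(r1.assignment_probs, r2.assignment_probs)
    assert r1.selected_chain == r2.selected_chain


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------


class TestConvergence:
    def test_identical_chains_converged(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=(200, 3))
        val = gibbs.mpsrf([samples, samples.copy()])
        assert val <= 1.0
        assert val == pytest.approx((200 - 1) / 200, abs=1e-9)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(500, 1))
        b = rng.normal(10, 1, size=(500, 1))
        val = gibbs.mpsrf([a, b])
        assert val > 10

    def test_univariate_matches_textbook_psrf(self):
        """p=1 reduces to the classic (n-1)/n + (m+1)/m * B/(n W)."""
        rng = np.random.default_rng(5)
        chains = [rng.normal(mu, 1, size=(300, 1)) for mu in (0.0, 0.3, -0.2)]
        n, m = 300, 3
        W = np.mean([np.var(c, ddof=1) for c in chains])
        means = [c.mean() for c in chains]
        Bn = np.var(means, ddof=1)
        expected = (n - 1) / n + (m + 1) / m * Bn / W
        assert gibbs.mpsrf(chains) == pytest.approx(expected, rel=1e-9)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gibbs.check_convergence([gibbs.ChainTrace()])


# ---------------------------------------------------------------------------
# result extraction
# ---------------------------------------------------------------------------


def _trace_from_samples(t_list, i_list, c_list, lps):
    tr = gibbs.ChainTrace()
    for t, i, c, lp in zip(t_list, i_list, c_list, lps):
        tr.t_snaps.append(np.asarray(t))
        tr.i_snaps.append(np.asarray(i))
        tr.c_snaps.append(np.asarray(c, dtype=np.int8))
        tr.joint_lp.append(lp)
        tr.marginal_lp.append(lp)
        tr.theta0.append(0.01)
        tr.theta_i.append(np.array([0.4]))
        tr.alpha0.append(1.0)
        tr.n_full += 1
    return tr


def test_extract_results_frequency_counting(tiny_hyper):
    data = ModelData(
        alt=np.zeros((1, 1), dtype=int),
        total=np.zeros((1, 1), dtype=int),
        omega=np.array([[1, 0]], dtype=np.int8),
        x=np.zeros((1, 1), dtype=np.int8),
    )
    # 10 samples, burn-in drops the first 5; among the kept, the cell's
    # clone is 0 in 7/10... construct 70/30 split over the kept half
    t = [[0]] * 20
    i = [[0]] * 7 + [[1]] * 3
    i = [[0]] * 10 + i  # first half burned
    c = [[[1, 0]]] * 20
    tr = _trace_from_samples(t, i, c, list(range(20)))
    res = gibbs.extract_results([tr], data)
    assert res.assignment_probs[0] == pytest.approx([0.7, 0.3])
    assert res.map_assignment[0] == 0

    # all samples identical: one-hot rows, zero entropy
    tr2 = _trace_from_samples([[0]] * 10, [[1]] * 10, c[:10], list(range(10)))
    res2 = gibbs.extract_results([tr2], data)
    assert res2.assignment_probs[0] == pytest.approx([0.0, 1.0])


def test_extract_results_genotype_tie_resolves_to_omega():
    data = ModelData(
        alt=np.zeros((1, 1), dtype=int),
        total=np.zeros((1, 1), dtype=int),
        omega=np.array([[1, 0]], dtype=np.int8),
        x=np.zeros((1, 1), dtype=np.int8),
    )
    c = [[[0, 0]], [[1, 1]], [[0, 1]], [[1, 0]]]  # kept half ties 50/50
    tr = _trace_from_samples([[0]] * 8, [[0]] * 8, c + c, list(range(8)))
    res = gibbs.extract_results([tr], data)
    assert res.map_genotypes[0, 0] == 1  # omega says 1
    assert res.map_genotypes[0, 1] == 0  # omega says 0


def test_extract_selects_highest_likelihood_chain():
    data = ModelData(
        alt=np.zeros((1, 1), dtype=int),
        total=np.zeros((1, 1), dtype=int),
        omega=np.array([[1, 0]], dtype=np.int8),
        x=np.zeros((1, 1), dtype=np.int8),
    )
    lo = _trace_from_samples([[0]] * 10, [[0]] * 10, [[[1, 0]]] * 10, [0.0] * 10)
    hi = _trace_from_samples([[0]] * 10, [[1]] * 10, [[[1, 0]]] * 10, [5.0] * 10)
    res = gibbs.extract_results([lo, hi], data)
    assert res.selected_chain == 1
    assert res.map_assignment[0] == 1


def test_fit_requires_a_chain(tiny_data, tiny_hyper):
    with pytest.raises(ValueError):
        gibbs.fit(tiny_data, tiny_hyper, chains=0)
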