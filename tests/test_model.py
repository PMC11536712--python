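"""Unit and property tests for the core conditionals.

The deep checks (every conditional vs brute-force enumeration of the joint)
live in test_acceptance; here each operation is pinned to hand-computed
values and its conjugate sufficient statistics are verified against naive
counting.
"""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcrclone import model


def test_encode_decode_roundtrip():
    seqs = ["ACGT", "TTNN", "GGGG"]
    codes = model.encode_sequences(seqs)
    assert model.decode_sequences(codes) == seqs
    assert codes[1, 2] == model.MISSING_CODE


def test_encode_rejects_bad_symbol_and_ragged():
    with pytest.raises(ValueError, match="invalid nucleotide"):
        model.encode_sequences(["ACGX"])
    with pytest.raises(ValueError, match="equal length"):
        model.encode_sequences(["ACG", "AC"])


def test_prob_c_given_omega_rule():
    assert model.prob_c_given_omega(1, 0.2) == pytest.approx(0.8)
    assert model.prob_c_given_omega(0, 0.2) == pytest.approx(0.2)
    assert model.prob_c_given_omega(1, 1e-12) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        model.prob_c_given_omega(1, 1.5)


@pytest.mark.parametrize(
    "a,d,mutated,theta0,theta_i,expected",
    [
        (0, 0, True, 0.002, 0.45, 0.0),
        (1, 2, True, 0.002, 0.5, np.log(0.5)),  # 2 * 0.5 * 0.5
        (1, 1, False, 0.002, 0.45, np.log(0.002)),
    ],
)
def test_read_loglik_values(a, d, mutated, theta0, theta_i, expected):
    assert model.read_loglik(a, d, mutated, theta0, theta_i) == pytest.approx(expected)


def test_read_loglik_rejects_a_above_d():
    with pytest.raises(ValueError):
        model.read_loglik(3, 2, True, 0.002, 0.45)


@pytest.mark.parametrize(
    "c,expected",
    [
        (np.array([[1, 0], [0, 1]]), (1, 23)),  # zero disagreements
        (np.array([[0, 0], [0, 1]]), (2, 22)),  # one of four disagrees
        (np.array([[0, 1], [1, 0]]), (5, 19)),  # all disagree
    ],
)
def test_cond_xi_counts(c, expected):
    omega = np.array([[1, 0], [0, 1]])
    assert model.cond_xi(omega, c, (1, 19)) == expected


@given(
    st.integers(1, 4), st.integers(1, 4), st.integers(0, 2**31 - 1)
)
@settings(max_examples=25, deadline=None)
def test_cond_xi_matches_naive_counting(n, k, seed):
    rng = np.random.default_rng(seed)
    omega = rng.integers(0, 2, size=(n, k))
    c = rng.integers(0, 2, size=(n, k))
    a, b = model.cond_xi(omega, c, (2.0, 3.0))
    dis = sum(
        int(omega[i, j] != c[i, j]) for i in range(n) for j in range(k)
    )
    assert a == 2.0 + dis
    assert b == 3.0 + n * k - dis


def test_cond_c_entry_single_cell_example(tiny_hyper):
    # one assigned cell with A=1, D=1: posterior odds are
    # (0.8 * 0.45) / (0.2 * 0.002)
    data = model.ModelData(
        alt=np.array([[1]]),
        total=np.array([[1]]),
        omega=np.array([[1]], dtype=np.int8),
        x=np.array([[0]], dtype=np.int8),
    )
    state = model.ModelState(
        xi=0.2,
        c=np.array([[1]], dtype=np.int8),
        t=np.array([0]),
        i_assign=np.array([0]),
        log_b=np.log(np.full((1, 1, 4), 0.25)),
        theta0=0.002,
        theta_i=np.array([0.45]),
        alpha0=1.0,
    )
    expected = 0.8 * 0.45 / (0.8 * 0.45 + 0.2 * 0.002)
    assert model.cond_c_entry(0, 0, state, data) == pytest.approx(expected, abs=1e-12)


def test_cond_c_reduces_to_prior_without_evidence():
    # theta_i == theta0 makes the likelihood cancel; so does zero depth
    data = model.ModelData(
        alt=np.array([[0]]),
        total=np.array([[3]]),
        omega=np.array([[0]], dtype=np.int8),
        x=np.array([[0]], dtype=np.int8),
    )
    state = model.ModelState(
        xi=0.3,
        c=np.array([[0]], dtype=np.int8),
        t=np.array([0]),
        i_assign=np.array([0]),
        log_b=np.log(np.full((1, 1, 4), 0.25)),
        theta0=0.1,
        theta_i=np.array([0.1]),
        alpha0=1.0,
    )
    assert model.cond_c_entry(0, 0, state, data) == pytest.approx(0.3, abs=1e-12)


def test_cond_i_two_clone_example():
    # C column 0 all ones, column 1 all zeros; A=0 of D=2 with theta_i=0.5
    # and theta0 -> 0 gives P(clone 1) = 1 / (1 + 0.25) = 0.8
    data = model.ModelData(
        alt=np.array([[0]]),
        total=np.array([[2]]),
        omega=np.array([[1, 0]], dtype=np.int8),
        x=np.array([[0]], dtype=np.int8),
    )
    state = model.ModelState(
        xi=0.2,
        c=np.array([[1, 0]], dtype=np.int8),
        t=np.array([0]),
        i_assign=np.array([0]),
        log_b=np.log(np.full((1, 1, 4), 0.25)),
        theta0=1e-12,
        theta_i=np.array([0.5]),
        alpha0=1.0,
    )
    probs = model.cond_i(0, state, data)
    assert probs[1] == pytest.approx(0.8, rel=1e-6)


def test_cond_i_uniform_without_reads(tiny_hyper):
    data = model.ModelData(
        alt=np.zeros((1, 2), dtype=int),
        total=np.zeros((1, 2), dtype=int),
        omega=np.array([[1, 0]], dtype=np.int8),
        x=np.zeros((2, 1), dtype=np.int8),
    )
    state = model.ModelState(
        xi=0.2,
        c=np.array([[1, 0]], dtype=np.int8),
        t=np.array([0, 0]),
        i_assign=np.array([0]),
        log_b=np.log(np.full((1, 1, 4), 0.25)),
        theta0=0.002,
        theta_i=np.array([0.45]),
        alpha0=1.0,
    )
    assert model.cond_i(0, state, data) == pytest.approx([0.5, 0.5])


@pytest.mark.parametrize(
    "column,expected",
    [
        ("AAA", [3.01, 0.01, 0.01, 0.01]),
        ("NNN", [0.01, 0.01, 0.01, 0.01]),  # all missing: prior only
        ("ACN", [1.01, 1.01, 0.01, 0.01]),
    ],
)
def test_cond_b_count_accumulation(column, expected):
    x = model.encode_sequences(list(column))  # three cells, one position
    g = np.full((1, 4), 0.01)
    t = np.zeros(3, dtype=int)
    assert model.cond_b(0, 0, g, x, t) == pytest.approx(expected)


def test_cond_theta_sufficient_statistics(tiny_hyper):
    # one cell whose clone carries variant 0 (A=2, D=5) and a second cell
    # whose clone does not (A=1, D=4)
    data = model.ModelData(
        alt=np.array([[2, 1]]),
        total=np.array([[5, 4]]),
        omega=np.array([[1, 0]], dtype=np.int8),
        x=np.zeros((2, 1), dtype=np.int8),
    )
    hyper = model.Hyperparams(
        kappa=(1, 19), nu0=(0.2, 99.8), nu_i=np.array([[4.5, 5.5]]),
        g=np.full((1, 4), 0.01),
    )
    state = model.ModelState(
        xi=0.2,
        c=np.array([[1, 0]], dtype=np.int8),
        t=np.array([0, 1]),
        i_assign=np.array([0, 1]),
        log_b=np.log(np.full((2, 1, 4), 0.25)),
        theta0=0.002,
        theta_i=np.array([0.45]),
        alpha0=1.0,
    )
    nu0p, nuip = model.cond_theta(state, data, hyper)
    assert nu0p == pytest.approx((0.2 + 1, 99.8 + 3))
    assert nuip[0] == pytest.approx([4.5 + 2, 5.5 + 3])


def test_cond_theta_no_reads_returns_prior(tiny_hyper, tiny_data, tiny_state):
    data = model.ModelData(
        alt=np.zeros_like(tiny_data.alt),
        total=np.zeros_like(tiny_data.total),
        omega=tiny_data.omega,
        x=tiny_data.x,
    )
    nu0p, nuip = model.cond_theta(tiny_state, data, tiny_hyper)
    assert nu0p == pytest.approx(tiny_hyper.nu0)
    assert nuip == pytest.approx(tiny_hyper.nu_i)


def test_joint_logprob_additivity(tiny_data, tiny_hyper, tiny_state):
    """Adding one read changes the joint by exactly that read's factor."""
    base = model.joint_logprob(tiny_state, tiny_data, tiny_hyper)
    alt = tiny_data.alt.copy()
    total = tiny_data.total.copy()
    total[0, 1] += 1  # one extra reference read at variant 0, cell 1
    data2 = model.ModelData(
        alt=alt, total=total, omega=tiny_data.omega, x=tiny_data.x
    )
    mutated = bool(
        tiny_state.c[0, tiny_state.i_assign[tiny_state.t[1]]]
    )
    delta = model.read_loglik(
        int(alt[0, 1]), int(total[0, 1]), mutated,
        tiny_state.theta0, tiny_state.theta_i[0],
    ) - model.read_loglik(
        int(tiny_data.alt[0, 1]), int(tiny_data.total[0, 1]), mutated,
        tiny_state.theta0, tiny_state.theta_i[0],
    )
    assert model.joint_logprob(tiny_state, data2, tiny_hyper) == pytest.approx(
        base + delta, abs=1e-9
    )


def test_joint_logprob_matches_independent_summation(tiny_data, tiny_hyper, tiny_state):
    """Term-by-term oracle built from scipy.stats distributions."""
    from scipy.stats import beta, binom, dirichlet, gamma

    st_, d, h = tiny_state, tiny_data, tiny_hyper
    lp = beta.logpdf(st_.xi, *h.kappa)
    lp += beta.logpdf(st_.theta0, *h.nu0)
    lp += sum(beta.logpdf(st_.theta_i[i], *h.nu_i[i]) for i in range(2))
    lp += gamma.logpdf(st_.alpha0, h.alpha0_prior[0], scale=1 / h.alpha0_prior[1])
    lp += model.crp_log_prob(st_.t, st_.alpha0)
    lp += -st_.n_clusters * np.log(2)
    for q in range(st_.n_clusters):
        for l in range(2):
            lp += dirichlet.logpdf(
                np.exp(st_.log_b[q, l]) / np.exp(st_.log_b[q, l]).sum(), h.g[l]
            )
    for i in range(2):
        for k in range(2):
            p1 = 1 - st_.xi if d.omega[i, k] == 1 else st_.xi
            lp += np.log(p1 if st_.c[i, k] == 1 else 1 - p1)
    clone = st_.i_assign[st_.t]
    for i in range(2):
        for j in range(3):
            p = st_.theta_i[i] if st_.c[i, clone[j]] else st_.theta0
            lp += binom.logpmf(d.alt[i, j], d.total[i, j], p)
    for j in range(3):
        for l in range(2):
            if d.x[j, l] < 4:
                lp += st_.log_b[st_.t[j], l, d.x[j, l]]
    assert model.joint_logprob(st_, d, h) == pytest.approx(lp, abs=1e-8)


def test_joint_logprob_flags_nonfinite(tiny_data, tiny_hyper, tiny_state):
    bad = copy.deepcopy(tiny_state)
    bad.alpha0 = 0.0  # log prior density diverges
    with pytest.raises(FloatingPointError, match="alpha0"):
        model.joint_logprob(bad, tiny_data, tiny_hyper)


def test_no_underflow_at_large_depth():
    ll = model.read_loglik(10**6 // 2, 10**6, True, 0.002, 0.45)
    assert np.isfinite(ll)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_sample_dirichlet_log_is_normalised(seed):
    rng = np.random.default_rng(seed)
    alpha = np.full((5, 4), 0.01)
    lb = model.sample_dirichlet_log(alpha, rng)
    assert np.exp(lb).sum(axis=-1) == pytest.approx(np.ones(5), abs=1e-9)
    assert np.all(np.isfinite(lb))
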