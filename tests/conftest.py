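"""Shared fixtures and independent oracles.

The enumeration oracle computes the exact posterior over (partition,
cell-clone labels) on tiny instances by integrating xi, theta and the BCR
profiles out analytically (Beta-binomial and Dirichlet-multinomial
marginals) and summing the corrected genotypes C exhaustively.  It shares
no code with the sampler's likelihood path beyond numpy/scipy primitives.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import betaln, gammaln, logsumexp

from bcrclone.model import Hyperparams, ModelData


def partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def partition_key(t, clone_of_cell):
    """Label-invariant key: sorted blocks plus per-cell clone labels."""
    blocks = {}
    for j, q in enumerate(t):
        blocks.setdefault(q, []).append(j)
    return (
        tuple(sorted(tuple(sorted(b)) for b in blocks.values())),
        tuple(int(c) for c in clone_of_cell),
    )


def exact_posterior(data: ModelData, hyper: Hyperparams, alpha0: float) -> dict:
    """Exact P(partition, clone per cell | data) with alpha0 held fixed.

    Marginalises xi (Beta), theta0/theta_i (Beta), B (Dirichlet-multinomial)
    analytically and C by exhaustive summation.
    """
    N, M, K = data.n_variants, data.n_cells, data.n_clones
    L = data.n_positions
    g = hyper.g
    A, D = data.alt, data.total
    logs, keys = [], []
    for blocks in partitions(list(range(M))):
        t = np.empty(M, dtype=int)
        for qi, blk in enumerate(blocks):
            for j in blk:
                t[j] = qi
        Q = len(blocks)
        lp_t = (
            Q * np.log(alpha0)
            + sum(gammaln(len(b)) for b in blocks)
            - np.log(alpha0 + np.arange(M)).sum()
        )
        lp_x = 0.0
        for blk in blocks:
            for l in range(L):
                col = data.x[blk, l]
                col = col[col < 4]
                n = np.bincount(col, minlength=4)
                lp_x += (
                    gammaln(g[l].sum())
                    - gammaln(g[l].sum() + n.sum())
                    + (gammaln(g[l] + n) - gammaln(g[l])).sum()
                )
        lp_i_prior = -Q * np.log(K)
        for I in itertools.product(range(K), repeat=Q):
            clone = np.array([I[t[j]] for j in range(M)])
            terms = []
            for cflat in itertools.product([0, 1], repeat=N * K):
                C = np.array(cflat).reshape(N, K)
                dis = int((C != data.omega).sum())
                lp_c = betaln(
                    hyper.kappa[0] + dis, hyper.kappa[1] + N * K - dis
                ) - betaln(*hyper.kappa)
                mut = C[:, clone]
                a0p = hyper.nu0[0] + ((1 - mut) * A).sum()
                b0p = hyper.nu0[1] + ((1 - mut) * (D - A)).sum()
                lp_r = betaln(a0p, b0p) - betaln(*hyper.nu0)
                for i in range(N):
                    aip = hyper.nu_i[i, 0] + (mut[i] * A[i]).sum()
                    bip = hyper.nu_i[i, 1] + (mut[i] * (D[i] - A[i])).sum()
                    lp_r += betaln(aip, bip) - betaln(*hyper.nu_i[i])
                terms.append(lp_c + lp_r)
            logs.append(lp_t + lp_x + lp_i_prior + logsumexp(terms))
            keys.append(partition_key(t, clone))
    logs = np.asarray(logs)
    probs = np.exp(logs - logsumexp(logs))
    out = {}
    for k, p in zip(keys, probs):
        out[k] = out.get(k, 0.0) + p
    return out


@pytest.fixture
def tiny_data() -> ModelData:
    """M=3 cells, N=2 variants, K=2 clones, L=2 BCR positions."""
    return ModelData(
        alt=np.array([[1, 0, 2], [0, 1, 0]]),
        total=np.array([[2, 0, 3], [1, 2, 0]]),
        omega=np.array([[1, 0], [0, 1]], dtype=np.int8),
        x=np.array([[0, 1], [0, 1], [2, 3]], dtype=np.int8),
    )


@pytest.fixture
def tiny_hyper() -> Hyperparams:
    return Hyperparams(
        kappa=(1.0, 19.0),
        nu0=(0.2, 99.8),
        nu_i=np.array([[4.5, 5.5]] * 2),
        g=np.full((2, 4), 0.5),
        alpha0_prior=(1.0, 1.0),
    )


@pytest.fixture
def tiny_state(tiny_data, tiny_hyper):
    """A valid state reached by a few sweeps from a seeded start."""
    from bcrclone import gibbs

    rng = np.random.default_rng(7)
    state = gibbs.initialize(tiny_data, tiny_hyper, rng)
    for _ in range(5):
        gibbs.full_sweep(state, tiny_data, tiny_hyper, rng)
    state.validate()
    return state
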