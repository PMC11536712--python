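"""Gibbs sampling engine: initialisation, warm-up, sweeps, convergence,
result extraction.

A fit proceeds the way the model is applied in practice:

1. ``initialize`` seats cells with *identical* BCR sequences together and
   draws the remaining variables from their priors;
2. ``warmup`` runs initial iterations over (xi, C, I, theta) only, keeping
   the hyperclustering fixed, so that major disagreements between the input
   genotypes and the scRNA reads are resolved before the clustering moves;
3. blocks of ``full_sweep`` update every variable, including the CRP
   hypercluster labels (with one auxiliary cluster per cell move, Neal's
   Algorithm 8 with m = 1) and the concentration parameter ``alpha0``
   (auxiliary-variable scheme of Escobar & West);
4. convergence is declared when the multivariate potential scale reduction
   factor over the continuous variables drops below a threshold (1.001 by
   default), and results are extracted from the chain with the highest
   marginal posterior score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Hyperparams,
    ModelData,
    ModelState,
    cell_clone_loglik,
    cond_c_matrix,
    cond_i_matrix,
    cond_theta,
    cond_xi,
    collapsed_logprob,
    loglik_matrices,
    nucleotide_counts,
    prob_c_given_omega,
    sample_dirichlet_log,
)

logger = logging.getLogger("bcrclone")

DEFAULT_N_INIT = 5000
DEFAULT_BLOCK = 500
DEFAULT_MPSRF_THRESHOLD = 1.001


# ---------------------------------------------------------------------------
# concentration parameter
# ---------------------------------------------------------------------------


def alpha0_mixture_weight(alpha0_prior, Q: int, M: int, sigma: float) -> float:
    """Mixture weight pi of the two-Gamma conditional of alpha0.

    With Gamma(a, b) prior, Q occupied clusters among M cells and auxiliary
    sigma, the conditional is pi * Gamma(a+Q, b - ln sigma) +
    (1 - pi) * Gamma(a+Q-1, b - ln sigma) with odds
    pi / (1 - pi) = (a + Q - 1) / (M * (b - ln sigma)).
    """
    a, b = alpha0_prior
    odds = (a + Q - 1.0) / (M * (b - np.log(sigma)))
    return odds / (1.0 + odds)


def sample_alpha0(
    alpha0: float, Q: int, M: int, prior, rng: np.random.Generator
) -> tuple[float, float]:
    """One auxiliary-variable update of the CRP concentration.

    sigma ~ Beta(alpha0 + 1, M) given the previous alpha0, then alpha0 from
    the two-component Gamma mixture given (Q, sigma).
    """
    if Q < 1 or M < 1:
        raise ValueError("require Q >= 1 and M >= 1")
    a, b = prior
    sigma = rng.beta(alpha0 + 1.0, M)
    rate = b - np.log(sigma)
    pi = alpha0_mixture_weight(prior, Q, M, sigma)
    shape = a + Q if rng.random() < pi else a + Q - 1.0
    new_alpha0 = rng.standard_gamma(shape) / rate
    return float(new_alpha0), float(sigma)


# ---------------------------------------------------------------------------
# initialisation and warm-up
# ---------------------------------------------------------------------------


def initialize(data: ModelData, hyper: Hyperparams, seed) -> ModelState:
    """Initial state: hyperclusters of cells with byte-identical BCR rows
    (missing symbols must match too); other variables drawn from priors,
    profiles from their conditionals given that clustering."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, t = np.unique(data.x, axis=0, return_inverse=True)
    t = t.astype(np.int64)
    Q = int(t.max()) + 1
    K = data.n_clones
    xi = float(_beta_rate(rng, *hyper.kappa))
    theta0 = float(_beta_rate(rng, *hyper.nu0))
    theta_i = _beta_rate(rng, hyper.nu_i[:, 0], hyper.nu_i[:, 1])
    c = (rng.random(data.omega.shape) < prob_c_given_omega(data.omega, xi)).astype(
        np.int8
    )
    i_assign = rng.integers(K, size=Q)
    counts = nucleotide_counts(data.x, t, Q)
    log_b = sample_dirichlet_log(counts + hyper.g[None], rng)
    a, b = hyper.alpha0_prior
    alpha0 = float(rng.standard_gamma(a) / b)
    alpha0, sigma = sample_alpha0(alpha0, Q, data.n_cells, hyper.alpha0_prior, rng)
    return ModelState(
        xi=xi,
        c=c,
        t=t,
        i_assign=i_assign,
        log_b=log_b,
        theta0=theta0,
        theta_i=theta_i,
        alpha0=alpha0,
        sigma_aux=sigma,
    )


_RATE_EPS = 1e-12


def _beta_rate(rng: np.random.Generator, a, b):
    """Beta draw clipped into (0, 1); shapes far below 1 can underflow to
    an exact 0/1, which the log-likelihoods cannot represent."""
    return np.clip(rng.beta(a, b), _RATE_EPS, 1.0 - _RATE_EPS)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one index per row of a row-stochastic matrix."""
    u = rng.random((probs.shape[0], 1))
    return (probs.cumsum(axis=1) > u).argmax(axis=1)


def warmup(
    state: ModelState,
    data: ModelData,
    hyper: Hyperparams,
    n_init: int,
    rng: np.random.Generator,
) -> ModelState:
    """Initial iterations over (xi, C, I, theta) with T held fixed; ends by
    refreshing B and alpha0 from their conditionals."""
    for _ in range(n_init):
        ll_ref, ll_mut = loglik_matrices(data, state.theta0, state.theta_i)
        ka, kb = cond_xi(data.omega, state.c, hyper.kappa)
        state.xi = float(_beta_rate(rng, ka, kb))
        p1 = cond_c_matrix(state, data, ll_ref, ll_mut)
        state.c = (rng.random(p1.shape) < p1).astype(np.int8)
        probs_i = cond_i_matrix(state, data, ll_ref, ll_mut)
        state.i_assign = _sample_rows(probs_i, rng)
        nu0p, nuip = cond_theta(state, data, hyper)
        state.theta0 = float(_beta_rate(rng, *nu0p))
        state.theta_i = _beta_rate(rng, nuip[:, 0], nuip[:, 1])
    counts = nucleotide_counts(data.x, state.t, state.n_clusters)
    state.log_b = sample_dirichlet_log(counts + hyper.g[None], rng)
    state.alpha0, state.sigma_aux = sample_alpha0(
        state.alpha0, state.n_clusters, data.n_cells, hyper.alpha0_prior, rng
    )
    return state


# ---------------------------------------------------------------------------
# full sweep
# ---------------------------------------------------------------------------


def _update_t(
    state: ModelState,
    data: ModelData,
    hyper: Hyperparams,
    rng: np.random.Generator,
    cc: np.ndarray,
):
    """One pass of hypercluster reassignments over all cells (Algorithm 8,
    one auxiliary table).  ``cc`` is the (M, K) cell-by-clone read
    log-likelihood, constant during the pass."""
    M, L = data.x.shape
    K = data.n_clones
    Q = state.n_clusters
    cap = max(2 * Q + 4, 16)
    log_b = np.empty((cap, L, 4))
    log_b[:Q] = state.log_b
    i_assign = np.empty(cap, dtype=np.int64)
    i_assign[:Q] = state.i_assign
    t = state.t.copy()
    n = np.zeros(cap, dtype=np.int64)
    n[:Q] = state.occupancy()
    oh = data.bcr_onehot  # (L*4, M)
    # every cell's BCR log-likelihood under every active profile, maintained
    # incrementally as clusters are created and deleted during the pass
    bcr_ll = np.empty((cap, M))
    bcr_ll[:Q] = log_b[:Q].reshape(Q, -1) @ oh
    log_n = np.log(np.arange(1, M + 1))  # lookup for occupancies
    log_alpha0 = np.log(state.alpha0)

    for j in range(M):
        q0 = t[j]
        n[q0] -= 1
        if n[q0] == 0:
            # singleton: its own parameters serve as the auxiliary cluster
            aux_i = int(i_assign[q0])
            aux_lb = log_b[q0].copy()
            aux_ll = bcr_ll[q0].copy()
            last = Q - 1
            if q0 != last:
                i_assign[q0] = i_assign[last]
                log_b[q0] = log_b[last]
                bcr_ll[q0] = bcr_ll[last]
                n[q0] = n[last]
                t[t == last] = q0
            n[last] = 0
            Q -= 1
        else:
            aux_i = int(rng.integers(K))
            aux_lb = sample_dirichlet_log(hyper.g, rng)
            aux_ll = None
        logw = np.empty(Q + 1)
        logw[:Q] = log_n[n[:Q] - 1] + cc[j, i_assign[:Q]] + bcr_ll[:Q, j]
        aux_ll_j = (
            aux_ll[j] if aux_ll is not None else float(aux_lb.ravel() @ oh[:, j])
        )
        logw[Q] = log_alpha0 + cc[j, aux_i] + aux_ll_j
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        choice = int((w.cumsum() > rng.random()).argmax())
        if choice == Q:
            if Q + 1 >= cap:
                cap *= 2
                log_b = np.concatenate([log_b, np.empty_like(log_b)])
                i_assign = np.concatenate([i_assign, np.empty_like(i_assign)])
                n = np.concatenate([n, np.zeros_like(n)])
                bcr_ll = np.concatenate([bcr_ll, np.empty_like(bcr_ll)])
            log_b[Q] = aux_lb
            bcr_ll[Q] = aux_ll if aux_ll is not None else aux_lb.ravel() @ oh
            i_assign[Q] = aux_i
            n[Q] = 1
            t[j] = Q
            Q += 1
        else:
            t[j] = choice
            n[choice] += 1

    state.t = t
    state.i_assign = i_assign[:Q].copy()
    state.log_b = log_b[:Q].copy()


def _update_t_collapsed(
    state: ModelState,
    data: ModelData,
    hyper: Hyperparams,
    rng: np.random.Generator,
    cc: np.ndarray,
) -> np.ndarray:
    """One pass of hypercluster reassignments with the profiles B
    integrated out (Dirichlet-categorical conjugacy).

    Existing clusters weigh ``n_{q,-j}`` times the posterior-predictive
    probability of the cell's BCR given the cluster's current nucleotide
    counts; the new-cluster option weighs ``alpha0`` times the prior
    predictive, with the clone drawn from its prior as the auxiliary (a
    singleton's own clone assignment is retained as that auxiliary).  This
    partially collapsed pass targets the same posterior as the
    instantiated-profile conditional but mixes across near-deterministic
    profiles; B is redrawn from its full conditional right afterwards.
    Returns the final (Q, L, 4) nucleotide counts.
    """
    M, L = data.x.shape
    K = data.n_clones
    Q = state.n_clusters
    g = hyper.g  # (L, 4)
    g_tot = g.sum(axis=1)  # (L,)
    cap = max(2 * Q + 4, 16)
    i_assign = np.empty(cap, dtype=np.int64)
    i_assign[:Q] = state.i_assign
    t = state.t.copy()
    n = np.zeros(cap, dtype=np.int64)
    n[:Q] = state.occupancy()
    counts = np.zeros((cap, L, 4))
    counts[:Q] = nucleotide_counts(data.x, t, Q)
    tot = counts.sum(axis=2)  # (cap, L) observed members per position
    # val[q, l, nuc] = log posterior-predictive of nuc at l in cluster q
    val = np.empty((cap, L * 4))

    def _refresh(q):
        val[q] = (np.log(g + counts[q]) - np.log(g_tot + tot[q])[:, None]).ravel()

    for q in range(Q):
        _refresh(q)
    # per-cell flat indices of the observed (position, nucleotide) pairs
    flat_idx = [
        np.flatnonzero(data.bcr_onehot[:, j]) for j in range(M)
    ]
    prior_val = (np.log(g) - np.log(g_tot)[:, None]).ravel()
    log_n = np.log(np.arange(1, M + 1))
    log_alpha0 = np.log(state.alpha0)

    for j in range(M):
        fi = flat_idx[j]
        obs_l = fi // 4
        obs_nuc = fi % 4
        q0 = t[j]
        n[q0] -= 1
        if n[q0] == 0:
            aux_i = int(i_assign[q0])
            last = Q - 1
            if q0 != last:
                i_assign[q0] = i_assign[last]
                counts[q0] = counts[last]
                tot[q0] = tot[last]
                val[q0] = val[last]
                n[q0] = n[last]
                t[t == last] = q0
            n[last] = 0
            Q -= 1
        else:
            counts[q0, obs_l, obs_nuc] -= 1.0
            tot[q0, obs_l] -= 1.0
            _refresh(q0)
            aux_i = int(rng.integers(K))
        logw = np.empty(Q + 1)
        logw[:Q] = log_n[n[:Q] - 1] + cc[j, i_assign[:Q]] + val[:Q, fi].sum(axis=1)
        logw[Q] = log_alpha0 + cc[j, aux_i] + prior_val[fi].sum()
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        choice = int((w.cumsum() > rng.random()).argmax())
        if choice == Q:
            if Q + 1 >= cap:
                cap *= 2
                i_assign = np.concatenate([i_assign, np.empty_like(i_assign)])
                n = np.concatenate([n, np.zeros_like(n)])
                counts = np.concatenate([counts, np.zeros_like(counts)])
                tot = np.concatenate([tot, np.zeros_like(tot)])
                val = np.concatenate([val, np.empty_like(val)])
            counts[Q] = 0.0
            tot[Q] = 0.0
            i_assign[Q] = aux_i
            n[Q] = 1
            t[j] = Q
            Q += 1
        else:
            t[j] = choice
            n[choice] += 1
        q_new = t[j]
        counts[q_new, obs_l, obs_nuc] += 1.0
        tot[q_new, obs_l] += 1.0
        _refresh(q_new)

    state.t = t
    state.i_assign = i_assign[:Q].copy()
    return counts[:Q]


def full_sweep(
    state: ModelState,
    data: ModelData,
    hyper: Hyperparams,
    rng: np.random.Generator,
    update_alpha0: bool = True,
    collapsed_t: bool = True,
) -> ModelState:
    """One full Gibbs sweep: xi, C, I, T, B, theta, alpha0 (in that order).

    ``collapsed_t`` chooses the profile-marginalised cell-move pass
    (default); ``False`` runs the instantiated-profile auxiliary-cluster
    scheme instead.  Both target the same posterior.
    """
    ll_ref, ll_mut = loglik_matrices(data, state.theta0, state.theta_i)
    ka, kb = cond_xi(data.omega, state.c, hyper.kappa)
    state.xi = float(_beta_rate(rng, ka, kb))
    p1 = cond_c_matrix(state, data, ll_ref, ll_mut)
    state.c = (rng.random(p1.shape) < p1).astype(np.int8)
    probs_i = cond_i_matrix(state, data, ll_ref, ll_mut)
    state.i_assign = _sample_rows(probs_i, rng)
    cc = cell_clone_loglik(data, state.c, ll_ref, ll_mut)
    if collapsed_t:
        counts = _update_t_collapsed(state, data, hyper, rng, cc)
    else:
        _update_t(state, data, hyper, rng, cc)
        counts = nucleotide_counts(data.x, state.t, state.n_clusters)
    state.log_b = sample_dirichlet_log(counts + hyper.g[None], rng)
    state._bcr_counts = counts
    nu0p, nuip = cond_theta(state, data, hyper)
    state.theta0 = float(_beta_rate(rng, *nu0p))
    state.theta_i = _beta_rate(rng, nuip[:, 0], nuip[:, 1])
    if update_alpha0:
        state.alpha0, state.sigma_aux = sample_alpha0(
            state.alpha0, state.n_clusters, data.n_cells, hyper.alpha0_prior, rng
        )
    return state


# ---------------------------------------------------------------------------
# traces, chains
# ---------------------------------------------------------------------------


@dataclass
class ChainTrace:
    """Per-sweep records of a single chain's full sampling iterations."""

    theta0: list = field(default_factory=list)
    theta_i: list = field(default_factory=list)
    alpha0: list = field(default_factory=list)
    joint_lp: list = field(default_factory=list)
    marginal_lp: list = field(default_factory=list)
    t_snaps: list = field(default_factory=list)
    i_snaps: list = field(default_factory=list)
    c_snaps: list = field(default_factory=list)
    n_init: int = 0
    n_full: int = 0


@dataclass
class Chain:
    state: ModelState
    rng: np.random.Generator
    trace: ChainTrace
    seed: int = 0


def start_chain(
    data: ModelData, hyper: Hyperparams, seed: int, n_init: int = DEFAULT_N_INIT
) -> Chain:
    rng = np.random.default_rng(seed)
    state = initialize(data, hyper, rng)
    state = warmup(state, data, hyper, n_init, rng)
    trace = ChainTrace(n_init=n_init)
    return Chain(state=state, rng=rng, trace=trace, seed=seed)


def advance_chain(
    chain: Chain,
    data: ModelData,
    hyper: Hyperparams,
    n_sweeps: int,
    thin: int = 1,
    update_alpha0: bool = True,
    collapsed_t: bool = True,
):
    """Run ``n_sweeps`` full sweeps, recording the trace after each (discrete
    snapshots every ``thin`` sweeps)."""
    for _ in range(n_sweeps):
        full_sweep(
            chain.state, data, hyper, chain.rng,
            update_alpha0=update_alpha0, collapsed_t=collapsed_t,
        )
        tr = chain.trace
        tr.n_full += 1
        tr.theta0.append(chain.state.theta0)
        tr.theta_i.append(chain.state.theta_i.copy())
        tr.alpha0.append(chain.state.alpha0)
        tr.marginal_lp.append(
            collapsed_logprob(
                chain.state, data, hyper,
                counts=getattr(chain.state, "_bcr_counts", None),
            )
        )
        if tr.n_full % thin == 0:
            tr.t_snaps.append(chain.state.t.copy())
            tr.i_snaps.append(chain.state.i_assign.copy())
            tr.c_snaps.append(chain.state.c.copy())


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------


def _default_cov(samples: np.ndarray) -> np.ndarray:
    return np.atleast_2d(np.cov(samples.T, ddof=1))


def trace_param_matrix(trace: ChainTrace, full_theta_i: bool = False) -> np.ndarray:
    """Continuous-variable samples of one chain as an (n, p) matrix.

    Default columns: theta0, the across-variant mean of theta_i, alpha0;
    with ``full_theta_i`` every theta_i becomes its own column.
    """
    theta0 = np.asarray(trace.theta0)
    alpha0 = np.asarray(trace.alpha0)
    ti = np.asarray(trace.theta_i)
    if full_theta_i:
        return np.column_stack([theta0, ti, alpha0])
    return np.column_stack([theta0, ti.mean(axis=1), alpha0])


def mpsrf(chain_samples: list[np.ndarray], cov_estimator=_default_cov) -> float:
    """Multivariate potential scale reduction factor (Brooks & Gelman).

    MPSRF = (n-1)/n + (m+1)/m * lambda_max(W^+ B/n) over m chains of n
    samples each; the covariance estimator is pluggable.
    """
    m = len(chain_samples)
    if m < 2:
        raise ValueError("MPSRF requires at least two chains")
    n = min(s.shape[0] for s in chain_samples)
    if n < 2:
        raise ValueError("need at least two samples per chain")
    chains = [np.atleast_2d(np.asarray(s)[-n:].astype(float)) for s in chain_samples]
    chains = [s if s.ndim == 2 else s[:, None] for s in chains]
    W = np.mean([cov_estimator(s) for s in chains], axis=0)
    means = np.array([s.mean(axis=0) for s in chains])
    Bn = np.atleast_2d(np.cov(means.T, ddof=1))
    # pinv(W) @ Bn need not be symmetric; take the largest real eigenvalue
    lam = np.linalg.eigvals(np.linalg.pinv(W) @ Bn)
    lam_max = float(np.max(lam.real)) if lam.size else 0.0
    lam_max = max(lam_max, 0.0)
    return (n - 1) / n + (m + 1) / m * lam_max


def check_convergence(
    traces: list[ChainTrace],
    threshold: float = DEFAULT_MPSRF_THRESHOLD,
    discard_frac: float = 0.5,
    full_theta_i: bool = False,
    cov_estimator=_default_cov,
) -> tuple[float, bool]:
    """MPSRF over (theta0, mean theta_i, alpha0) on post-burn-in samples."""
    if len(traces) < 2:
        raise ValueError("convergence assessment requires at least two chains")
    mats = []
    for tr in traces:
        m = trace_param_matrix(tr, full_theta_i=full_theta_i)
        mats.append(m[int(discard_frac * m.shape[0]):])
    val = mpsrf(mats, cov_estimator=cov_estimator)
    return val, bool(val < threshold)


# ---------------------------------------------------------------------------
# result extraction
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    assignment_probs: np.ndarray  # (M, K), rows sum to 1
    map_assignment: np.ndarray  # (M,)
    map_genotypes: np.ndarray  # (N, K)
    ml_hyperclustering: np.ndarray  # (M,)
    chain_summaries: list
    selected_chain: int
    mpsrf: float | None = None
    converged: bool | None = None


def extract_results(
    traces: list[ChainTrace],
    data: ModelData,
    burnin_frac: float = 0.5,
) -> FitResult:
    """Summarise chains into the fitted output.

    The chain with the highest mean post-burn-in marginal log posterior
    (conjugate variables integrated out) is selected; cell-to-clone
    posterior frequencies, modal (MAP) assignments and genotypes come from
    its retained snapshots, and the output hyperclustering is the sampled T
    with the highest marginal log posterior across that chain's iterations.
    Genotype ties are resolved toward the input genotype call.
    """
    M, K, N = data.n_cells, data.n_clones, data.n_variants
    summaries = []
    scores = []
    for ci, tr in enumerate(traces):
        lp = np.asarray(tr.marginal_lp if tr.marginal_lp else tr.joint_lp)
        burn = int(burnin_frac * len(lp))
        score = float(lp[burn:].mean()) if len(lp) > burn else -np.inf
        scores.append(score)
        summaries.append(
            {
                "chain": ci,
                "n_init": tr.n_init,
                "n_full": tr.n_full,
                "mean_marginal_lp": score,
                "mean_theta0": float(np.mean(tr.theta0[burn:])) if tr.theta0 else None,
                "mean_alpha0": float(np.mean(tr.alpha0[burn:])) if tr.alpha0 else None,
            }
        )
    best = int(np.argmax(scores))
    tr = traces[best]
    n_snap = len(tr.t_snaps)
    burn_snap = int(burnin_frac * n_snap)
    kept = range(burn_snap, n_snap)
    counts = np.zeros((M, K))
    c_sum = np.zeros((N, K))
    for s in kept:
        clone = tr.i_snaps[s][tr.t_snaps[s]]
        counts[np.arange(M), clone] += 1.0
        c_sum += tr.c_snaps[s]
    n_kept = max(len(kept), 1)
    assignment_probs = counts / counts.sum(axis=1, keepdims=True)
    map_assignment = assignment_probs.argmax(axis=1)
    c_mean = c_sum / n_kept
    map_genotypes = (c_mean > 0.5).astype(np.int8)
    ties = np.isclose(c_mean, 0.5)
    if ties.any():
        logger.info("genotype MAP ties at %d entries resolved toward omega", ties.sum())
        map_genotypes[ties] = data.omega[ties]
    sel_lp = tr.marginal_lp if tr.marginal_lp else tr.joint_lp
    ml_idx = int(np.argmax(sel_lp)) if sel_lp else 0
    # snapshots may be thinned; map the sweep index to the nearest snapshot
    snap_idx = min(ml_idx * n_snap // max(len(sel_lp), 1), n_snap - 1)
    ml_hyperclustering = tr.t_snaps[snap_idx].copy()
    return FitResult(
        assignment_probs=assignment_probs,
        map_assignment=map_assignment,
        map_genotypes=map_genotypes,
        ml_hyperclustering=ml_hyperclustering,
        chain_summaries=summaries,
        selected_chain=best,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def fit(
    data: ModelData,
    hyper: Hyperparams,
    chains: int = 4,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
    block: int = DEFAULT_BLOCK,
    max_blocks: int = 10,
    mpsrf_threshold: float = DEFAULT_MPSRF_THRESHOLD,
    thin: int = 1,
    update_alpha0: bool = True,
    collapsed_t: bool = True,
) -> FitResult:
    """Initialise, warm up and run blocks of full sweeps until converged.

    Chain c is seeded with ``seed + c``.  With a single chain no
    between-chain diagnostic is possible and ``converged`` stays ``None``.
    """
    if chains < 1:
        raise ValueError("need at least one chain")
    if max_blocks < 1:
        raise ValueError("need at least one block of full sweeps")
    chain_objs = []
    for c in range(chains):
        logger.info("chain %d: warm-up (%d iterations)", c, n_init)
        chain_objs.append(start_chain(data, hyper, seed + c, n_init=n_init))
    mpsrf_val, converged = None, None
    for b in range(max_blocks):
        for ch in chain_objs:
            advance_chain(
                ch, data, hyper, block, thin=thin,
                update_alpha0=update_alpha0, collapsed_t=collapsed_t,
            )
        if chains >= 2:
            mpsrf_val, converged = check_convergence(
                [ch.trace for ch in chain_objs], threshold=mpsrf_threshold
            )
            logger.info(
                "block %d: MPSRF=%.6f (threshold %.4f)", b, mpsrf_val, mpsrf_threshold
            )
            if converged:
                break
        else:
            logger.info(
                "block %d: joint lp %.2f",
                b,
                chain_objs[0].trace.joint_lp[-1],
            )
            break
    if chains >= 2 and not converged:
        logger.warning("chains did not converge within %d blocks", max_blocks)
    result = extract_results([ch.trace for ch in chain_objs], data)
    result.mpsrf = mpsrf_val
    result.converged = converged
    return result
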