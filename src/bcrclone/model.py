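"""Core probabilistic model: state container and Gibbs conditionals.

The model couples three layers of evidence about a tumour sample:

* an error-prone binary clone-genotype matrix ``omega`` (N variants x K
  clones) whose latent corrected counterpart is ``C``, with a Beta-prior
  error rate ``xi``;
* per-cell alternate/total UMI counts ``A``/``D`` at the N variant
  positions, modelled as binomial draws with success probability
  ``theta_i`` (cell's clone carries variant i) or ``theta0`` (it does not);
* per-cell BCR nucleotide sequences ``X`` (M cells x L variable positions),
  clustered nonparametrically: cells join *hyperclusters* under a Chinese
  Restaurant Process with concentration ``alpha0``, each hypercluster q
  carrying a per-position nucleotide frequency profile ``B[q, l, :]`` with a
  Dirichlet(g) prior, and a clone assignment ``I[q]`` with a uniform prior.

All conditionals below are exact (conjugate where conjugacy applies) and are
what the Gibbs sweep in :mod:`bcrclone.gibbs` samples from.  Likelihood
accumulation is done in log space throughout; hypercluster profiles are kept
as log-probabilities so that the sparse ``g = 0.01`` prior never underflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit, gammaln, logsumexp

NUCLEOTIDES = "ACGT"
#: integer code for a missing / unobserved BCR nucleotide
MISSING_CODE = 4

_NUC_TO_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}


def encode_sequences(seqs, missing: str = "N") -> np.ndarray:
    """Encode equal-length nucleotide strings as an (M, L) int8 matrix.

    A/C/G/T map to 0..3; the ``missing`` symbol maps to :data:`MISSING_CODE`.
    Any other character raises ``ValueError``.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences given")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be pre-aligned to equal length")
    out = np.empty((len(seqs), L), dtype=np.int8)
    for j, s in enumerate(seqs):
        for l, ch in enumerate(s.upper()):
            if ch in _NUC_TO_CODE:
                out[j, l] = _NUC_TO_CODE[ch]
            elif ch == missing.upper():
                out[j, l] = MISSING_CODE
            else:
                raise ValueError(
                    f"invalid nucleotide {ch!r} in sequence {j} position {l}"
                )
    return out


def decode_sequences(codes: np.ndarray, missing: str = "N") -> list[str]:
    alphabet = NUCLEOTIDES + missing
    return ["".join(alphabet[c] for c in row) for row in np.asarray(codes)]


# ---------------------------------------------------------------------------
# hyperparameters and data
# ---------------------------------------------------------------------------


@dataclass
class Hyperparams:
    """Prior parameters of the model.

    kappa
        Beta parameters of the genotype error rate ``xi``; ``kappa[0]`` is
        the error (disagreement) pseudo-count, ``kappa[1]`` the agreement
        pseudo-count.
    nu0
        Beta parameters of ``theta0`` (alt-read probability in non-carrier
        clones).
    nu_i
        (N, 2) Beta parameters of each ``theta_i``.
    g
        (L, 4) Dirichlet parameters of the hypercluster BCR profiles.
    alpha0_prior
        Gamma(a, b) prior (shape, rate) of the CRP concentration.
    """

    kappa: tuple[float, float]
    nu0: tuple[float, float]
    nu_i: np.ndarray
    g: np.ndarray
    alpha0_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.nu_i = np.atleast_2d(np.asarray(self.nu_i, dtype=float))
        self.g = np.atleast_2d(np.asarray(self.g, dtype=float))
        for name, val in [
            ("kappa", self.kappa),
            ("nu0", self.nu0),
            ("alpha0_prior", self.alpha0_prior),
            ("nu_i", self.nu_i),
            ("g", self.g),
        ]:
            if np.any(np.asarray(val) <= 0):
                raise ValueError(f"hyperparameter {name} must be strictly positive")


@dataclass
class ModelData:
    """Validated in-memory inputs: counts, input genotypes, encoded BCRs."""

    alt: np.ndarray  # (N, M) int
    total: np.ndarray  # (N, M) int
    omega: np.ndarray  # (N, K) int8 in {0,1}
    x: np.ndarray  # (M, L) int8 codes, MISSING_CODE = unobserved
    variant_ids: list[str] = field(default_factory=list)
    cell_barcodes: list[str] = field(default_factory=list)
    clone_ids: list[str] = field(default_factory=list)
    position_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.alt = np.asarray(self.alt)
        self.total = np.asarray(self.total)
        self.omega = np.asarray(self.omega, dtype=np.int8)
        self.x = np.asarray(self.x, dtype=np.int8)
        if self.alt.shape != self.total.shape:
            raise ValueError("alt and total count matrices differ in shape")
        if np.any(self.alt < 0) or np.any(self.total < 0):
            raise ValueError("negative read counts")
        if np.any(self.alt > self.total):
            i, j = np.argwhere(self.alt > self.total)[0]
            raise ValueError(f"alt > total at variant {i}, cell {j}")
        if self.omega.shape[0] != self.alt.shape[0]:
            raise ValueError("omega rows must match the number of variants")
        if self.x.shape[0] != self.alt.shape[1]:
            raise ValueError("BCR rows must match the number of cells")
        if not np.all(np.isin(self.omega, [0, 1])):
            raise ValueError("omega entries must be 0/1")
        # cached pieces reused every sweep
        self._log_coef = (
            gammaln(self.total + 1)
            - gammaln(self.alt + 1)
            - gammaln(self.total - self.alt + 1)
        )
        self._observed = self.x < MISSING_CODE
        self._bcr_onehot = None

    @property
    def bcr_onehot(self) -> np.ndarray:
        """(L*4, M) one-hot encoding of observed nucleotides.

        A flattened profile ``log_b[q].ravel()`` matmul'ed against this gives
        every cell's BCR log-likelihood under cluster q in one BLAS call;
        missing positions contribute all-zero rows and are thereby skipped.
        """
        if self._bcr_onehot is None:
            M, L = self.x.shape
            oh = np.zeros((L * 4, M))
            obs_j, obs_l = np.nonzero(self._observed)
            oh[obs_l * 4 + self.x[obs_j, obs_l], obs_j] = 1.0
            self._bcr_onehot = oh
        return self._bcr_onehot

    @property
    def n_variants(self) -> int:
        return self.alt.shape[0]

    @property
    def n_cells(self) -> int:
        return self.alt.shape[1]

    @property
    def n_clones(self) -> int:
        return self.omega.shape[1]

    @property
    def n_positions(self) -> int:
        return self.x.shape[1]


@dataclass
class ModelState:
    """One Gibbs configuration.

    ``t`` holds compact hypercluster labels in 0..Q-1 (every label
    non-empty); ``log_b`` stores the profiles as log-probabilities, rows
    normalised so ``exp(log_b[q, l]).sum() == 1``.
    """

    xi: float
    c: np.ndarray  # (N, K) int8
    t: np.ndarray  # (M,) int
    i_assign: np.ndarray  # (Q,) int
    log_b: np.ndarray  # (Q, L, 4)
    theta0: float
    theta_i: np.ndarray  # (N,)
    alpha0: float
    sigma_aux: float = 0.5

    @property
    def n_clusters(self) -> int:
        return len(self.i_assign)

    @property
    def b(self) -> np.ndarray:
        return np.exp(self.log_b)

    def occupancy(self) -> np.ndarray:
        return np.bincount(self.t, minlength=self.n_clusters)

    def validate(self):
        Q = self.n_clusters
        if not 0 < self.xi < 1:
            raise ValueError("xi outside (0,1)")
        if self.t.min() < 0 or self.t.max() >= Q:
            raise ValueError("t labels not compact")
        if np.any(self.occupancy() == 0):
            raise ValueError("empty hypercluster present")
        if self.log_b.shape[0] != Q:
            raise ValueError("log_b rows do not match cluster count")
        sums = np.exp(self.log_b).sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("B rows do not sum to 1")

    def clone_of_cells(self) -> np.ndarray:
        """Composed assignment cell -> clone via its hypercluster."""
        return self.i_assign[self.t]


# ---------------------------------------------------------------------------
# elementary probabilities
# ---------------------------------------------------------------------------


def prob_c_given_omega(omega_entry, xi: float):
    """P(C = 1 | Omega, xi): 1 - xi where Omega = 1, xi where Omega = 0."""
    if not 0 < xi < 1:
        raise ValueError("xi must lie in (0, 1)")
    return np.where(np.asarray(omega_entry) == 1, 1.0 - xi, xi)


def read_loglik(a: int, d: int, mutated: bool, theta0: float, theta_i: float) -> float:
    """Log binomial likelihood of a alt reads out of d under the carrier
    (``theta_i``) or non-carrier (``theta0``) rate; zero-depth gives 0."""
    if a < 0 or a > d:
        raise ValueError("require 0 <= a <= d")
    if d == 0:
        return 0.0
    p = theta_i if mutated else theta0
    return float(
        gammaln(d + 1)
        - gammaln(a + 1)
        - gammaln(d - a + 1)
        + a * np.log(p)
        + (d - a) * np.log1p(-p)
    )


def loglik_matrices(data: ModelData, theta0: float, theta_i: np.ndarray):
    """(N, M) log-likelihood matrices under the non-carrier / carrier rates."""
    alt, ref = data.alt, data.total - data.alt
    ll_ref = data._log_coef + alt * np.log(theta0) + ref * np.log1p(-theta0)
    lt = np.log(theta_i)[:, None]
    l1t = np.log1p(-theta_i)[:, None]
    ll_mut = data._log_coef + alt * lt + ref * l1t
    return ll_ref, ll_mut


def cell_clone_loglik(data: ModelData, c: np.ndarray, ll_ref, ll_mut) -> np.ndarray:
    """(M, K) read log-likelihood of each cell under each clone genotype."""
    cf = c.astype(float)
    return ll_mut.T @ cf + ll_ref.T @ (1.0 - cf)


def crp_log_prob(t: np.ndarray, alpha0: float) -> float:
    """Log probability of a partition under the CRP (sequential seating)."""
    m = len(t)
    n_q = np.bincount(t)
    n_q = n_q[n_q > 0]
    return float(
        len(n_q) * np.log(alpha0)
        + gammaln(n_q).sum()
        - np.log(alpha0 + np.arange(m)).sum()
    )


# ---------------------------------------------------------------------------
# Gibbs conditionals
# ---------------------------------------------------------------------------


def cond_xi(omega: np.ndarray, c: np.ndarray, kappa) -> tuple[float, float]:
    """Beta posterior parameters of xi; a *success* is a disagreement
    between the input and corrected genotype (xi is an error rate)."""
    if omega.shape != c.shape:
        raise ValueError("omega and c differ in shape")
    dis = int(np.sum(omega != c))
    agr = omega.size - dis
    return (kappa[0] + dis, kappa[1] + agr)


def cond_c_log_odds(
    state: ModelState, data: ModelData, ll_ref=None, ll_mut=None
) -> np.ndarray:
    """(N, K) log-odds of C[i,k] = 1 given everything else.

    Entries are conditionally independent given (T, I, theta): each read
    (i, j) touches only C[i, clone(j)].
    """
    if ll_ref is None:
        ll_ref, ll_mut = loglik_matrices(data, state.theta0, state.theta_i)
    K = data.n_clones
    clone = state.clone_of_cells()
    z = np.zeros((data.n_cells, K))
    z[np.arange(data.n_cells), clone] = 1.0
    delta = (ll_mut - ll_ref) @ z  # (N, K) log-likelihood-ratio sums
    p1 = prob_c_given_omega(data.omega, state.xi)
    return np.log(p1) - np.log1p(-p1) + delta


def cond_c_matrix(
    state: ModelState, data: ModelData, ll_ref=None, ll_mut=None
) -> np.ndarray:
    """(N, K) matrix of P(C[i,k] = 1 | rest), sampled in one vectorised
    Bernoulli draw during a sweep."""
    return expit(cond_c_log_odds(state, data, ll_ref, ll_mut))


def cond_c_entry(i: int, k: int, state: ModelState, data: ModelData) -> float:
    return float(cond_c_matrix(state, data)[i, k])


def cond_i_matrix(
    state: ModelState, data: ModelData, ll_ref=None, ll_mut=None
) -> np.ndarray:
    """(Q, K) posterior probabilities of each hypercluster's clone.

    Uniform prior over clones; rows are conditionally independent given
    (C, T, theta).
    """
    if ll_ref is None:
        ll_ref, ll_mut = loglik_matrices(data, state.theta0, state.theta_i)
    cc = cell_clone_loglik(data, state.c, ll_ref, ll_mut)  # (M, K)
    Q = state.n_clusters
    z = np.zeros((data.n_cells, Q))
    z[np.arange(data.n_cells), state.t] = 1.0
    logw = z.T @ cc  # (Q, K)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def cond_i(q: int, state: ModelState, data: ModelData) -> np.ndarray:
    return cond_i_matrix(state, data)[q]


def bcr_loglik_cells_vs_profiles(
    x: np.ndarray, observed: np.ndarray, log_b: np.ndarray
) -> np.ndarray:
    """(M, Q) BCR categorical log-likelihood; missing positions skipped."""
    M = x.shape[0]
    Q = log_b.shape[0]
    out = np.zeros((M, Q))
    for j in range(M):
        obs = observed[j]
        out[j] = log_b[:, obs, x[j, obs]].sum(axis=1)
    return out


def _bcr_loglik_cell(x_row, obs_row, log_b) -> np.ndarray:
    """(Q,) BCR log-likelihood of one cell against active profiles."""
    return log_b[:, obs_row, x_row[obs_row]].sum(axis=1)


def cond_t(
    j: int,
    state: ModelState,
    data: ModelData,
    aux_i: int,
    aux_log_b: np.ndarray,
    cell_clone_ll: np.ndarray | None = None,
):
    """Conditional over the hypercluster of cell j, auxiliary included.

    Returns ``(probs, i_options, singleton_removed)``: ``probs`` has one
    entry per surviving existing cluster plus a final new-cluster entry
    whose parameters are ``(aux_i, aux_log_b)``.  Existing clusters weigh
    ``n_{q,-j}``, the auxiliary weighs ``alpha0`` (the common normaliser
    ``M - 1 + alpha0`` cancels).  If cell j is currently a singleton its
    cluster is removed from the existing set first; by Neal's Algorithm-8
    singleton rule the caller should pass that cluster's own parameters as
    the auxiliary in that case.
    """
    n = state.occupancy().astype(float)
    n[state.t[j]] -= 1.0
    keep = n > 0
    singleton_removed = not keep[state.t[j]]
    if cell_clone_ll is None:
        ll_ref, ll_mut = loglik_matrices(data, state.theta0, state.theta_i)
        cell_clone_ll = cell_clone_loglik(data, state.c, ll_ref, ll_mut)[j]
    obs = data._observed[j]
    xj = data.x[j]
    bcr = _bcr_loglik_cell(xj, obs, state.log_b)
    read = cell_clone_ll[state.i_assign]
    logw_exist = np.log(n[keep]) + read[keep] + bcr[keep]
    bcr_new = aux_log_b[obs, xj[obs]].sum()
    logw_new = np.log(state.alpha0) + cell_clone_ll[aux_i] + bcr_new
    logw = np.append(logw_exist, logw_new)
    probs = np.exp(logw - logsumexp(logw))
    probs /= probs.sum()
    i_options = np.append(state.i_assign[keep], aux_i)
    return probs, i_options, singleton_removed


def nucleotide_counts(x: np.ndarray, t: np.ndarray, Q: int) -> np.ndarray:
    """(Q, L, 4) counts of observed nucleotides per hypercluster/position."""
    M, L = x.shape
    z = np.zeros((M, Q))
    z[np.arange(M), t] = 1.0
    counts = np.empty((Q, L, 4))
    for nuc in range(4):
        counts[:, :, nuc] = z.T @ (x == nuc)
    return counts


def cond_b(l: int, q: int, g: np.ndarray, x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Dirichlet posterior parameters of the profile at position l of
    hypercluster q (Dirichlet-multinomial conjugacy; missing skipped)."""
    members = np.flatnonzero(t == q)
    if members.size == 0:
        raise ValueError(f"hypercluster {q} is empty")
    col = x[members, l]
    counts = np.bincount(col[col < MISSING_CODE], minlength=4).astype(float)
    return np.asarray(g[l], dtype=float) + counts


def cond_theta(state: ModelState, data: ModelData, hyper: Hyperparams):
    """Beta posterior parameters for theta0 and every theta_i.

    theta0 pools alt/ref reads across all (variant, cell) pairs whose
    cell's clone does not carry the variant; each theta_i pools across
    cells whose clone does.
    """
    mut = state.c[:, state.clone_of_cells()]  # (N, M) carrier flag per read
    alt, ref = data.alt, data.total - data.alt
    non = 1 - mut
    a0p = hyper.nu0[0] + float((non * alt).sum())
    b0p = hyper.nu0[1] + float((non * ref).sum())
    aip = hyper.nu_i[:, 0] + (mut * alt).sum(axis=1)
    bip = hyper.nu_i[:, 1] + (mut * ref).sum(axis=1)
    return (a0p, b0p), np.column_stack([aip, bip])


# ---------------------------------------------------------------------------
# joint log-probability
# ---------------------------------------------------------------------------


def _beta_logpdf(x, a, b):
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def joint_logprob(state: ModelState, data: ModelData, hyper: Hyperparams) -> float:
    """Complete-data log joint probability of one configuration.

    Sum of the prior log-densities of xi, theta, alpha0 and B, the CRP log
    probability of T (uniform prior of I), the genotype-error term
    P(C | Omega, xi), the read log-likelihood, and the BCR categorical
    log-likelihood.  Raises if any component is non-finite.
    """
    parts = {}
    a, b = hyper.alpha0_prior
    parts["xi_prior"] = float(_beta_logpdf(state.xi, *hyper.kappa))
    parts["theta0_prior"] = float(_beta_logpdf(state.theta0, *hyper.nu0))
    parts["theta_i_prior"] = float(
        _beta_logpdf(state.theta_i, hyper.nu_i[:, 0], hyper.nu_i[:, 1]).sum()
    )
    parts["alpha0_prior"] = float(
        a * np.log(b) - gammaln(a) + (a - 1) * np.log(state.alpha0) - b * state.alpha0
    )
    parts["crp"] = crp_log_prob(state.t, state.alpha0)
    parts["i_prior"] = -state.n_clusters * np.log(data.n_clones)
    g = hyper.g  # (L, 4)
    dir_norm = gammaln(g.sum(axis=1)) - gammaln(g).sum(axis=1)  # (L,)
    parts["b_prior"] = float(
        state.n_clusters * dir_norm.sum() + ((g - 1.0)[None] * state.log_b).sum()
    )
    agree = data.omega == state.c
    parts["c_given_omega"] = float(
        agree.sum() * np.log1p(-state.xi) + (~agree).sum() * np.log(state.xi)
    )
    ll_ref, ll_mut = loglik_matrices(data, state.theta0, state.theta_i)
    mut = state.c[:, state.clone_of_cells()]
    parts["reads"] = float(np.where(mut == 1, ll_mut, ll_ref).sum())
    xc = np.minimum(data.x, 3)
    L = data.n_positions
    vals = state.log_b[state.t[:, None], np.arange(L)[None, :], xc]
    parts["bcr"] = float(vals[data._observed].sum())
    total = 0.0
    for name, val in parts.items():
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite joint log-probability term: {name}")
        total += val
    return total


def collapsed_logprob(
    state: ModelState, data: ModelData, hyper: Hyperparams, counts=None
) -> float:
    """Marginal log posterior (up to a constant) of (T, I, C, alpha0).

    Integrates the conjugate variables out analytically: xi and the thetas
    via Beta-binomial marginals, the profiles B via Dirichlet-multinomial
    marginals.  Unlike the complete-data joint density, this quantity is
    comparable across states with different hypercluster counts (a Dirichlet
    *density* at a near-vertex profile is huge, so joint-density comparisons
    reward fragmented clusterings); it is the score used to select chains
    and the output hyperclustering.
    """
    Q = state.n_clusters
    a, b = hyper.alpha0_prior
    lp = float(
        a * np.log(b) - gammaln(a) + (a - 1) * np.log(state.alpha0) - b * state.alpha0
    )
    lp += crp_log_prob(state.t, state.alpha0)
    lp += -Q * np.log(data.n_clones)
    # xi marginal given the C/Omega agreement pattern
    dis = int((data.omega != state.c).sum())
    agr = data.omega.size - dis
    k0, k1 = hyper.kappa
    lp += float(betaln(k0 + dis, k1 + agr) - betaln(k0, k1))
    # read marginals: theta0 pooled, theta_i per variant
    mut = state.c[:, state.clone_of_cells()]
    alt, ref = data.alt, data.total - data.alt
    non = 1 - mut
    lp += float(
        betaln(
            hyper.nu0[0] + (non * alt).sum(), hyper.nu0[1] + (non * ref).sum()
        )
        - betaln(*hyper.nu0)
    )
    aip = hyper.nu_i[:, 0] + (mut * alt).sum(axis=1)
    bip = hyper.nu_i[:, 1] + (mut * ref).sum(axis=1)
    lp += float(
        (betaln(aip, bip) - betaln(hyper.nu_i[:, 0], hyper.nu_i[:, 1])).sum()
    )
    lp += float(data._log_coef.sum())
    # BCR Dirichlet-multinomial marginals per cluster/position
    if counts is None:
        counts = nucleotide_counts(data.x, state.t, Q)  # (Q, L, 4)
    g = hyper.g[None]  # (1, L, 4)
    g_tot = hyper.g.sum(axis=1)[None]  # (1, L)
    lp += float(
        (
            gammaln(g_tot)
            - gammaln(g_tot + counts.sum(axis=2))
            + (gammaln(g + counts) - gammaln(g)).sum(axis=2)
        ).sum()
    )
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite collapsed log-probability")
    return lp


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def sample_dirichlet_log(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw returned as log-probabilities, stable for tiny shapes.

    Uses the boost identity G(a) = G(a+1) * U^{1/a} evaluated in log space,
    so shapes like 0.01 never underflow to exact zero.
    """
    alpha = np.asarray(alpha, dtype=float)
    g1 = rng.standard_gamma(alpha + 1.0)
    logx = np.log(np.maximum(g1, np.finfo(float).tiny)) + np.log(
        rng.random(alpha.shape)
    ) / alpha
    m = logx.max(axis=-1, keepdims=True)
    return logx - (m + np.log(np.exp(logx - m).sum(axis=-1, keepdims=True)))
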