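"""Performance metrics and downstream helper computations.

Three headline metrics score a fit against simulation truth: the fraction
of cells assigned to their true clone, the fraction of genotype entries
agreeing with the hidden clonal profiles, and the adjusted Rand index
between inferred and generating hyperclusterings.  Clone identity is pinned
to the columns of the input genotype matrix, so accuracies need no
partition matching; the ARI is permutation-invariant by construction.

Helpers used downstream: per-cell assignment entropy, modal-sequence
Hamming distances between hypercluster sets, the reliable-genotype-call
rule, and single-linkage Manhattan dendrograms of clone genotypes.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .model import MISSING_CODE


@dataclass
class EvalReport:
    assignment_accuracy: float
    genotype_accuracy: float
    hypercluster_ari: float
    mean_assignment_entropy: float
    per_cell_entropy: np.ndarray

    def to_json(self) -> str:
        d = asdict(self)
        d["per_cell_entropy"] = np.asarray(self.per_cell_entropy).tolist()
        return json.dumps(d, indent=2)


def assignment_accuracy(map_assignment, t_true, i_true) -> float:
    """Fraction of cells whose MLE clone equals their generating clone."""
    pred = np.asarray(map_assignment)
    t_true = np.asarray(t_true)
    i_true = np.asarray(i_true)
    if pred.shape != t_true.shape:
        raise ValueError("assignment vectors differ in length")
    truth = i_true[t_true]
    K = max(int(truth.max()), int(pred.max())) + 1
    if not (np.isin(pred, np.arange(K)).any() and np.isin(truth, np.arange(K)).any()):
        raise ValueError("clone label sets are disjoint from the clone range")
    return float(np.mean(pred == truth))


def genotype_accuracy(map_genotypes, c_true) -> float:
    """Elementwise agreement with the hidden clonal profiles."""
    g = np.asarray(map_genotypes)
    c = np.asarray(c_true)
    if g.shape != c.shape:
        raise ValueError(f"genotype shapes differ: {g.shape} vs {c.shape}")
    return float(np.mean(g == c))


def hypercluster_ari(t_pred, t_true) -> float:
    """Adjusted Rand index between two cell partitions."""
    t_pred, t_true = np.asarray(t_pred), np.asarray(t_true)
    if t_pred.shape != t_true.shape:
        raise ValueError("partitions differ in length")
    return float(adjusted_rand_score(t_true, t_pred))


def assignment_entropy(assignment_probs) -> tuple[np.ndarray, float]:
    """Shannon entropy (natural log) of each cell's clone posterior row."""
    p = np.asarray(assignment_probs, dtype=float)
    if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be probability vectors summing to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    per_cell = terms.sum(axis=1)
    return per_cell, float(per_cell.mean())


def cluster_modal_sequences(
    nucleotides: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster modal nucleotide at each position, ignoring missing.

    Returns (cluster_ids, modal codes (Q, L), defined mask (Q, L)); a
    position with no observed nucleotide in a cluster is undefined there.
    Ties break in fixed A<C<G<T order.
    """
    labels = np.asarray(labels)
    x = np.asarray(nucleotides)
    ids = np.unique(labels)
    Q, L = len(ids), x.shape[1]
    modal = np.zeros((Q, L), dtype=np.int8)
    defined = np.zeros((Q, L), dtype=bool)
    for qi, q in enumerate(ids):
        sub = x[labels == q]
        for l in range(L):
            col = sub[:, l]
            col = col[col < MISSING_CODE]
            if col.size:
                modal[qi, l] = np.bincount(col, minlength=4).argmax()
                defined[qi, l] = True
    return ids, modal, defined


def hypercluster_hamming(
    bcr_a, labels_a, bcr_b, labels_b, mode: str = "modal"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise BCR distances between two hypercluster sets.

    Both alignments must share position ids; distances are counted over the
    shared positions only.  ``mode='modal'`` (default) is the number of
    mismatching positions between cluster modal sequences; ``mode='mean'``
    averages per-cell pairwise mismatch counts across the two clusters.
    Returns (ids_a, ids_b, distance matrix).
    """
    shared = [p for p in bcr_a.position_ids if p in set(bcr_b.position_ids)]
    if not shared:
        raise ValueError("no shared BCR positions between the two alignments")
    idx_a = [bcr_a.position_ids.index(p) for p in shared]
    idx_b = [bcr_b.position_ids.index(p) for p in shared]
    xa = bcr_a.nucleotides[:, idx_a]
    xb = bcr_b.nucleotides[:, idx_b]
    la, lb = np.asarray(labels_a), np.asarray(labels_b)
    if mode == "modal":
        ids_a, mod_a, def_a = cluster_modal_sequences(xa, la)
        ids_b, mod_b, def_b = cluster_modal_sequences(xb, lb)
        dist = np.zeros((len(ids_a), len(ids_b)))
        for i in range(len(ids_a)):
            both = def_a[i][None, :] & def_b  # (Qb, L)
            dist[i] = ((mod_a[i][None, :] != mod_b) & both).sum(axis=1)
        return ids_a, ids_b, dist
    if mode == "mean":
        ids_a, ids_b = np.unique(la), np.unique(lb)
        dist = np.zeros((len(ids_a), len(ids_b)))
        for i, qa in enumerate(ids_a):
            sa = xa[la == qa]
            for j, qb in enumerate(ids_b):
                sb = xb[lb == qb]
                d = 0.0
                for row in sa:
                    both = (row[None, :] < MISSING_CODE) & (sb < MISSING_CODE)
                    d += ((row[None, :] != sb) & both).sum()
                dist[i, j] = d / (len(sa) * len(sb))
        return ids_a, ids_b, dist
    raise ValueError(f"unknown mode {mode!r}")


def reliable_call_mask(reads, map_assignment, clone: int) -> np.ndarray:
    """Per-variant flag: a genotype call for this clone counts as reliable
    when its cells carry at least one alternate read or at least three
    reference reads at the position."""
    cells = np.asarray(map_assignment) == clone
    alt = reads.alt_counts[:, cells].sum(axis=1)
    ref = (reads.total_counts - reads.alt_counts)[:, cells].sum(axis=1)
    return (alt >= 1) | (ref >= 3)


def genotype_dendrogram(
    map_genotypes: np.ndarray, clone_ids: list[str] | None = None
) -> tuple[np.ndarray, str]:
    """Single-linkage tree on Manhattan distances between clone genotype
    columns; returns the linkage matrix and a Newick string."""
    g = np.asarray(map_genotypes, dtype=float).T  # clones as observations
    if g.shape[0] < 2:
        raise ValueError("need at least two clones")
    if clone_ids is None:
        clone_ids = [f"clone{k + 1}" for k in range(g.shape[0])]
    z = linkage(pdist(g, metric="cityblock"), method="single")
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, id_list=list(clone_ids))
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return z, buf.getvalue().strip()


def evaluate_fit(fit, truth) -> EvalReport:
    """Score a :class:`~bcrclone.gibbs.FitResult` against simulation truth."""
    per_cell, mean_ent = assignment_entropy(fit.assignment_probs)
    return EvalReport(
        assignment_accuracy=assignment_accuracy(
            fit.map_assignment, truth.t_true, truth.i_true
        ),
        genotype_accuracy=genotype_accuracy(fit.map_genotypes, truth.c_true),
        hypercluster_ari=hypercluster_ari(fit.ml_hyperclustering, truth.t_true),
        mean_assignment_entropy=mean_ent,
        per_cell_entropy=per_cell,
    )
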