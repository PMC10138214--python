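"""Optimal-transport alignment of partitions to a reference.

Cluster labels produced by independent clustering runs are arbitrary; before
any cross-run comparison the clusters must be put into correspondence.  The
coupling between two partitions is found by solving the discrete
transportation problem

    D(P1, P2) = min_W  sum_ij w_ij d(C_i, C_j)
    s.t.  W 1 = q^(1),  W^T 1 = q^(2),  W >= 0,

with Jaccard ground costs between cluster member sets and the cluster
proportions as marginals, so the total influence of a cluster equals its
share of the data.  The LP is solved exactly (HiGHS); the optimum is a
vertex of the transportation polytope, so when the two partitions are
label-permuted copies of one another the coupling is exactly the scaled
permutation matrix and the transport cost is 0.

Row-normalizing W gives the cluster mapping matrix Gamma (the soft
assignment of source clusters to reference clusters); column-normalizing
gives Gamma-tilde.  Aligned labels are obtained by the maximum-a-posteriori
rule on Gamma, and mutual-dominance of Gamma / Gamma-tilde defines the
"match" relation used by the stability machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .partitions import Partition, pairwise_jaccard

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentResult",
    "AlignedEnsemble",
    "solve_transport",
    "solve_ot_alignment",
    "map_relabel",
    "classify_relations",
    "align_ensemble",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal coupling of one partition (source) to a reference.

    Attributes
    ----------
    W : array (k1, kr)
        Optimal coupling; row sums q^(1), column sums q^(r).
    gamma : array (k1, kr)
        Row-normalized W: soft mapping of source clusters onto reference clusters.
    gamma_tilde : array (k1, kr)
        Column-normalized W.
    cost : float
        Achieved transport objective (the Wasserstein distance between the
        partitions under Jaccard ground costs); lies in [0, 1].
    """

    W: np.ndarray
    gamma: np.ndarray
    gamma_tilde: np.ndarray
    cost: float


def solve_transport(cost: np.ndarray, r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the transportation LP exactly. Returns (coupling, objective).

    Solved with HiGHS, which returns an optimal *basic* solution, i.e. a
    vertex of the transportation polytope (at most k1 + k2 - 1 nonzeros).
    """
    cost = np.asarray(cost, dtype=float)
    k1, k2 = cost.shape
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    if abs(r.sum() - c.sum()) > 1e-9:
        raise AssertionError("infeasible marginals: masses differ")
    # equality constraints: k1 row sums + k2 column sums (one redundant row kept;
    # HiGHS handles the rank deficiency)
    rows = []
    for i in range(k1):
        a = np.zeros((k1, k2))
        a[i, :] = 1.0
        rows.append(a.ravel())
    for j in range(k2):
        a = np.zeros((k1, k2))
        a[:, j] = 1.0
        rows.append(a.ravel())
    A_eq = np.array(rows)
    b_eq = np.concatenate([r, c])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - guarded by the marginal check above
        raise AssertionError(f"transport LP failed: {res.message}")
    W = res.x.reshape(k1, k2)
    W[W < 1e-12] = 0.0
    return W, float(res.fun)


def solve_ot_alignment(p1: Partition, ref: Partition) -> AlignmentResult:
    """Align the clusters of ``p1`` with those of ``ref`` by exact OT (Jaccard costs).

    Empty source clusters (possible when ``p1`` lives in a fixed label space)
    carry no mass; their W and Gamma rows are zero.  The reference must have
    no empty clusters.
    """
    if p1.n != ref.n:
        raise ValueError(f"partitions of different sizes: {p1.n} vs {ref.n}")
    q1, qr = p1.q, ref.q
    if np.any(qr == 0):
        raise ValueError("reference partition has empty clusters; compact it first")
    nonempty = np.flatnonzero(q1 > 0)
    D = pairwise_jaccard(p1, ref)[nonempty, :]
    W_sub, cost = solve_transport(D, q1[nonempty], qr)
    W = np.zeros((p1.K, ref.K))
    W[nonempty, :] = W_sub
    gamma = np.zeros_like(W)
    gamma[nonempty, :] = W_sub / q1[nonempty, None]
    gamma_tilde = W / qr[None, :]
    return AlignmentResult(W=W, gamma=gamma, gamma_tilde=gamma_tilde, cost=cost)


def map_relabel(p1: Partition, align: AlignmentResult) -> Partition:
    """Relabel ``p1`` into the reference label space by the MAP rule.

    For a hard partition the cluster-posterior matrix is one-hot, so the
    aligned posterior of an item with source label ``a`` is row ``a`` of
    Gamma; the item takes ``argmax_j gamma[a, j]``.  Ties break to the
    smallest reference label (np.argmax convention), deterministically.

    The result lives in the reference label space (``fixed_K``): labels keep
    their reference meaning even if some reference clusters receive no items.
    """
    targets = np.argmax(align.gamma, axis=1) + 1  # 1-based reference labels
    return Partition(targets[p1.labels - 1], fixed_K=align.gamma.shape[1])


def classify_relations(align: AlignmentResult, zeta: float = 0.7) -> dict:
    """Classify cluster-pair relations: match / split / merge / lack-of-correspondence.

    ``C_i`` (source) and ``C_j`` (reference) *match* when ``gamma_ij >= zeta``
    and ``gamma_tilde_ij >= zeta``; zeta in (0.5, 1] makes the match partner
    of any reference cluster unique.  The split/merge taxonomy beyond "match"
    is diagnostic only: a source cluster with no match that spreads mass
    ``gamma_tilde >= 1 - zeta`` over two or more reference clusters is a
    split, and symmetrically (Gamma roles swapped) for merge; a reference
    cluster with no match at all lacks correspondence in this partition.

    Returns a dict with:
      ``match``: {reference cluster j (1-based) -> source cluster i (1-based)}
      ``relations``: list of (source i, reference j, relation-name)
      ``zeta``: threshold used.
    """
    if not 0.5 < zeta <= 1.0:
        raise ValueError(f"zeta must lie in (0.5, 1], got {zeta}")
    g, gt = align.gamma, align.gamma_tilde
    k1, kr = g.shape
    match: dict[int, int] = {}
    relations: list[tuple[int, int, str]] = []
    matched_sources = set()
    for j in range(kr):
        hits = np.flatnonzero((g[:, j] >= zeta) & (gt[:, j] >= zeta))
        if hits.size:
            i = int(hits[0])
            match[j + 1] = i + 1
            matched_sources.add(i)
            relations.append((i + 1, j + 1, "match"))
    for i in range(k1):
        if i in matched_sources:
            continue
        targets = np.flatnonzero(gt[i, :] >= 1 - zeta)
        if targets.size >= 2:
            for j in targets:
                relations.append((i + 1, int(j) + 1, "split"))
    for j in range(kr):
        if j + 1 in match:
            continue
        sources = np.flatnonzero(g[:, j] >= 1 - zeta)
        if sources.size >= 2:
            for i in sources:
                relations.append((int(i) + 1, j + 1, "merge"))
        # every unmatched reference cluster lacks correspondence in this
        # partition — the only relation downstream tightness consumes
        relations.append((0, j + 1, "lack-of-correspondence"))
    return {"match": match, "relations": relations, "zeta": zeta}


@dataclass
class AlignedEnsemble:
    """A reference partition plus m perturbed partitions relabeled to its label set.

    ``raw`` keeps the pre-alignment partitions: the view-contribution measures
    need them, since they are re-aligned later against the *final* partition.
    """

    reference: Partition
    aligned: list[Partition]
    raw: list[Partition]
    alignments: list[AlignmentResult]
    name: str = "view"
    extras: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.aligned)


def align_ensemble(raw_partitions: list[Partition], reference: Partition, name: str = "view") -> AlignedEnsemble:
    """OT-align and MAP-relabel each raw partition to the reference."""
    aligned, results = [], []
    for p, part in enumerate(raw_partitions):
        try:
            res = solve_ot_alignment(part, reference)
            aligned.append(map_relabel(part, res))
            results.append(res)
        except Exception as exc:
            raise RuntimeError(f"alignment failed for partition {p} of {name}: {exc}") from exc
    return AlignedEnsemble(reference=reference, aligned=aligned, raw=list(raw_partitions),
                           alignments=results, name=name)
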