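"""Covering point sets, cluster tightness, and CAP separability.

The stability of a reference cluster is judged against its *matched*
replicates in an ensemble of perturbed partitions.  The covering point set
(CPS) ``S_alpha`` of a cluster is the smallest point set containing at
least ``100(1 - alpha)%`` of the matched replicates as subsets — the
set-valued counterpart of a confidence interval.  Tightness

    R_t(k) = p_k * (sum_i |S_i| / |S_alpha|) / m_k

combines the match frequency ``p_k = m_k / m`` with the mean relative size
of the replicates inside the CPS; 1 means perfectly reproducible, 0 means
the cluster never re-appears.  CAP separability between two reference
clusters is the Jaccard distance between their CPSs: low values flag
clusters whose uncertainty regions overlap, i.e. merge candidates.

The minimal covering set is found by the greedy Least-Impact-First
Targeted-removal (LIFT) heuristic: starting from all replicates, repeatedly
discard the replicate whose removal shrinks the running union least, until
the required number survive; the CPS is the union of the survivors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .alignment import AlignedEnsemble, classify_relations, solve_ot_alignment
from .partitions import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "CoveringPointSet",
    "TightnessReport",
    "matched_sets",
    "covering_point_set",
    "tightness",
    "cap_separability",
    "ensemble_tightness",
]


@dataclass(frozen=True)
class CoveringPointSet:
    """CPS of one reference cluster: union of the kept replicate sets."""

    members: frozenset
    alpha: float
    covered_count: int
    n_sets: int

    def __len__(self) -> int:
        return len(self.members)


def covering_point_set(sets: list, alpha: float, m_basis: int | None = None) -> CoveringPointSet:
    """Greedy LIFT covering point set of a collection of item-index sets.

    Parameters
    ----------
    sets : list of item-index collections
        The matched replicate sets S_i.
    alpha : float in [0, 1)
        Coverage level; at least ``ceil(m_basis * (1 - alpha))`` of the sets
        must be subsets of the result.
    m_basis : int, optional
        Denominator of the coverage constraint; defaults to ``len(sets)``.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    sets = [frozenset(map(int, s)) for s in sets]
    if m_basis is None:
        m_basis = len(sets)
    required = math.ceil(m_basis * (1 - alpha))
    if required <= 0:
        logger.warning("covering_point_set: zero sets required at alpha=%.3g; empty CPS", alpha)
        return CoveringPointSet(frozenset(), alpha, 0, len(sets))
    if required > len(sets):
        logger.warning(
            "covering_point_set: required coverage %d exceeds %d available sets; covering all",
            required, len(sets))
        required = len(sets)
    m = len(sets)
    universe = sorted(frozenset().union(*sets))
    bit_of = {x: 1 << i for i, x in enumerate(universe)}
    masks = [sum(bit_of[x] for x in s) for s in sets]
    n_drop = m - required
    if math.comb(m, n_drop) <= 20_000:
        # exact: the number of removal choices is small in every practical
        # setting (alpha * m_k sets are dropped), so enumerate them
        best_keep, best_size = None, None
        for dropped in itertools.combinations(range(m), n_drop):
            drop_set = set(dropped)
            union = 0
            for i in range(m):
                if i not in drop_set:
                    union |= masks[i]
            size = union.bit_count()
            if best_size is None or size < best_size:
                best_keep, best_size = [i for i in range(m) if i not in drop_set], size
        kept = best_keep
    else:
        # greedy targeted removal: repeatedly discard the set whose exclusion
        # leaves the smallest union of the remainder (largest exclusive
        # contribution goes first)
        kept = list(range(m))
        while len(kept) > required:
            best_i, best_size = None, None
            for pos, i in enumerate(kept):
                union = 0
                for j in kept:
                    if j != i:
                        union |= masks[j]
                size = union.bit_count()
                if best_size is None or size < best_size:
                    best_i, best_size = pos, size
            kept.pop(best_i)
    union = frozenset().union(*(sets[j] for j in kept))
    return CoveringPointSet(union, alpha, len(kept), len(sets))


def matched_sets(k: int, ensemble: AlignedEnsemble, zeta: float = 0.7) -> tuple[list[frozenset], float]:
    """Member sets of the clusters matched with reference cluster ``k`` across the ensemble.

    Returns the list of matched member sets (one per partition that contains
    a match for ``k``) and the match frequency ``p_k = m_k / m``.
    """
    out = []
    for part, align in zip(ensemble.raw, ensemble.alignments):
        rel = classify_relations(align, zeta)
        src = rel["match"].get(k)
        if src is not None:
            out.append(frozenset(map(int, part.members(src))))
    p_k = len(out) / ensemble.m if ensemble.m else 0.0
    return out, p_k


def tightness(k: int, ensemble: AlignedEnsemble, alpha: float = 0.1, zeta: float = 0.7) -> float:
    """Tightness R_t of reference cluster ``k`` in an aligned ensemble."""
    sets, p_k = matched_sets(k, ensemble, zeta)
    return _tightness_from_sets(sets, p_k, alpha)


def _tightness_from_sets(sets: list[frozenset], p_k: float, alpha: float) -> float:
    m_k = len(sets)
    if m_k == 0:
        return 0.0
    cps = covering_point_set(sets, alpha, m_basis=m_k)
    if len(cps) == 0:
        logger.warning("tightness: empty CPS with %d matched sets; R_t = 0", m_k)
        return 0.0
    return p_k * sum(len(s) for s in sets) / len(cps) / m_k


def cap_separability(cps_j, cps_jp) -> float:
    """CAP separability: Jaccard distance between two clusters' covering point sets."""
    a = cps_j.members if isinstance(cps_j, CoveringPointSet) else frozenset(map(int, cps_j))
    b = cps_jp.members if isinstance(cps_jp, CoveringPointSet) else frozenset(map(int, cps_jp))
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


@dataclass
class TightnessReport:
    """Per-cluster stability summary of a reference partition against an ensemble.

    Attributes (arrays indexed by reference cluster, 0-based position = label - 1):
    ``R_t`` tightness, ``p`` match frequency, ``m_matched`` match counts,
    ``cps`` covering point sets (degenerate clusters fall back to their own
    member set so separability stays defined), ``overall`` mean tightness.
    """

    R_t: np.ndarray
    p: np.ndarray
    m_matched: np.ndarray
    cps: list[CoveringPointSet]

    @property
    def overall(self) -> float:
        return float(np.mean(self.R_t))

    def separability_matrix(self) -> np.ndarray:
        K = len(self.cps)
        delta = np.zeros((K, K))
        for i in range(K):
            for j in range(i + 1, K):
                delta[i, j] = delta[j, i] = cap_separability(self.cps[i], self.cps[j])
        return delta

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "cluster": np.arange(1, len(self.R_t) + 1),
            "p_k": self.p,
            "m_k": self.m_matched,
            "cps_size": [len(c) for c in self.cps],
            "R_t": self.R_t,
        })


def ensemble_tightness(reference: Partition, partitions: list[Partition],
                       alpha: float = 0.1, zeta: float = 0.7) -> TightnessReport:
    """Full CPS analysis of a reference partition against perturbed partitions.

    Solves OT between every partition and the reference, extracts matched
    replicate sets per reference cluster, and computes CPS and tightness.
    Clusters never matched keep their own member set as a degenerate CPS
    (tightness 0) so that pairwise separability remains defined.
    """
    m = len(partitions)
    K = reference.K
    sets_per_cluster: list[list[frozenset]] = [[] for _ in range(K)]
    for part in partitions:
        align = solve_ot_alignment(part, reference)
        rel = classify_relations(align, zeta)
        for k, src in rel["match"].items():
            sets_per_cluster[k - 1].append(frozenset(map(int, part.members(src))))
    R_t = np.zeros(K)
    p = np.zeros(K)
    m_matched = np.zeros(K, dtype=int)
    cps_list: list[CoveringPointSet] = []
    for k in range(K):
        sets = sets_per_cluster[k]
        m_k = len(sets)
        m_matched[k] = m_k
        p[k] = m_k / m if m else 0.0
        if m_k == 0:
            own = frozenset(map(int, reference.members(k + 1)))
            cps_list.append(CoveringPointSet(own, alpha, 0, 0))
            continue
        cps = covering_point_set(sets, alpha, m_basis=m_k)
        cps_list.append(cps)
        if len(cps) == 0:
            logger.warning("cluster %d: empty CPS; R_t = 0", k + 1)
            continue
        R_t[k] = p[k] * sum(len(s) for s in sets) / len(cps) / m_k
    return TightnessReport(R_t=R_t, p=p, m_matched=m_matched, cps=cps_list)
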