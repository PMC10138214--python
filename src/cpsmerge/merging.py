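"""Two-stage merging of Cartesian-product clusters to maximize tightness.

The number of product clusters can be far larger than the number of real
clusters, and many product cells exist only through noise.  The final
partition is obtained by greedily merging unstable clusters so as to
maximize the summed per-cluster tightness (an intrinsically combinatorial
objective, approached dendrogram-style, two clusters at a time).

*First stage* (optional, triggered when the product label count is large):
the per-pair OT couplings between the two views' partitions are averaged
into a matching weight matrix W-bar; its entries weight a bipartite graph
between view-A and view-B clusters, and Leiden communities of that graph
form *super-clusters*.  Product labels whose two view clusters fall in
different communities (unmatched-product blocks) are collapsed wholesale;
labels within one community (matched-product blocks) keep product
granularity.  This shrinks the problem handed to the second stage while
preserving the interaction structure where cross-view correspondence is
sharp.

*Second stage*: repeatedly take the cluster with the lowest tightness and
merge it with the cluster closest to it in CAP separability, recomputing
tightness and separability from scratch after every merge, until the
requested number of clusters is reached or every cluster's tightness
clears the goal (default 0.8).  The accelerated variant processes an ascending
ladder of tightness thresholds and performs all merges below the current
threshold in one round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedEnsemble, map_relabel, solve_ot_alignment, solve_transport
from .cps import TightnessReport, ensemble_tightness
from .partitions import Partition, pairwise_jaccard
from .product import ProductEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "SuperClustering",
    "MergeEvent",
    "MergeTree",
    "matching_weight_matrix",
    "bipartite_super_clusters",
    "first_stage_merge",
    "cps_merge",
    "accelerated_cps_merge",
]

DEFAULT_THRESHOLDS = (0.35, 0.5, 0.65, 0.8)


def _coupling(pa: Partition, pb: Partition) -> np.ndarray:
    """Exact OT coupling between two partitions' clusters (Jaccard costs).

    Unlike :func:`solve_ot_alignment` neither side is privileged; empty
    clusters on either side get zero rows/columns.
    """
    qa, qb = pa.q, pb.q
    ra, rb = np.flatnonzero(qa > 0), np.flatnonzero(qb > 0)
    D = pairwise_jaccard(pa, pb)[np.ix_(ra, rb)]
    W_sub, _ = solve_transport(D, qa[ra], qb[rb])
    W = np.zeros((pa.K, pb.K))
    W[np.ix_(ra, rb)] = W_sub
    return W


def matching_weight_matrix(ea: AlignedEnsemble, eb: AlignedEnsemble) -> np.ndarray:
    """Average OT coupling W-bar between the paired aligned partitions of two views."""
    if ea.m != eb.m:
        raise ValueError(f"ensemble sizes differ: {ea.m} vs {eb.m}")
    kA, kB = ea.reference.K, eb.reference.K
    Wbar = np.zeros((kA, kB))
    for a, b in zip(ea.aligned, eb.aligned):
        Wbar += _coupling(a, b)
    return Wbar / ea.m


@dataclass
class SuperClustering:
    """Leiden communities of the bipartite cluster-matching graph.

    ``community_A[i]`` / ``community_B[j]`` give the community id (0-based)
    of view-A cluster i+1 / view-B cluster j+1.
    """

    community_A: np.ndarray
    community_B: np.ndarray

    def build_g0(self, codebook: dict[int, tuple[int, int]]) -> np.ndarray:
        """Mapping g0 from dense product labels to first-stage labels 1..kappa_0.

        Product labels in an unmatched-product block (the two view clusters
        belong to different communities) share one id per (community pair);
        labels in a matched-product block keep distinct ids.
        """
        group_of: dict = {}
        g0 = np.zeros(len(codebook) + 1, dtype=np.int64)
        next_id = 1
        for code in sorted(codebook):
            a, b = codebook[code]
            ca, cb = int(self.community_A[a - 1]), int(self.community_B[b - 1])
            key = ("MP", code) if ca == cb else ("UP", ca, cb)
            if key not in group_of:
                group_of[key] = next_id
                next_id += 1
            g0[code] = group_of[key]
        return g0


def bipartite_super_clusters(Wbar: np.ndarray, resolution: float = 1.0,
                             seed: int = 0) -> SuperClustering:
    """Super-clusters from Leiden community detection on the bipartite matching graph.

    Nodes are the view-A and view-B reference clusters; an edge of weight
    ``wbar_ij`` connects A-cluster i to B-cluster j.  If W-bar is all zero
    every cluster becomes its own super-cluster (logged).
    """
    import igraph
    import leidenalg

    if np.any(Wbar < 0):
        raise ValueError("matching weight matrix must be nonnegative")
    kA, kB = Wbar.shape
    ii, jj = np.nonzero(Wbar)
    if ii.size == 0:
        logger.warning("all-zero matching weight matrix: every cluster is its own super-cluster")
        return SuperClustering(np.arange(kA), np.arange(kA, kA + kB))
    edges = [(int(i), int(kA + j)) for i, j in zip(ii, jj)]
    weights = [float(Wbar[i, j]) for i, j in zip(ii, jj)]
    g = igraph.Graph(n=kA + kB, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights=weights,
        resolution_parameter=resolution, seed=int(seed))
    membership = np.asarray(part.membership)
    return SuperClustering(membership[:kA], membership[kA:])


def first_stage_merge(pe: ProductEnsemble, sc: SuperClustering | None) -> tuple[Partition, list[Partition], np.ndarray]:
    """Collapse product labels through g0 and align the ensemble to the combined reference.

    Returns ``(C, parts, g0_to_C)`` where ``C`` is the combined reference
    partition (labels 1..kappa_0, compacted over the labels the reference
    occupies), ``parts`` are the m g0-collapsed product partitions
    OT-aligned and MAP-relabeled into C's label space, and ``g0_to_C`` maps
    each dense product label to its C label (0 for labels absent from the
    reference; such mass is folded in via the per-partition alignment).

    With ``sc=None`` the first stage is skipped and g0 is the identity.
    """
    K = pe.n_product_labels
    g0 = np.concatenate([[0], np.arange(1, K + 1)]) if sc is None else sc.build_g0(pe.codebook)
    collapsed_ref = Partition(g0[pe.reference.labels])  # compacted
    # record product label -> C label (0 if the reference never occupies its g0 group)
    ref_g0 = g0[pe.reference.labels]
    present = {}
    for g, c in zip(ref_g0, collapsed_ref.labels):
        present[int(g)] = int(c)
    g0_to_C = np.array([present.get(int(g0[code]), 0) for code in range(K + 1)], dtype=np.int64)
    parts = []
    for p, part in enumerate(pe.partitions):
        collapsed = Partition(g0[part.labels])
        try:
            align = solve_ot_alignment(collapsed, collapsed_ref)
            parts.append(map_relabel(collapsed, align))
        except Exception as exc:
            raise RuntimeError(f"combined-partition alignment failed for pair {p}: {exc}") from exc
    return collapsed_ref, parts, g0_to_C


@dataclass(frozen=True)
class MergeEvent:
    """One merge step: clusters ``children`` (pre-merge ids) fuse into ``parent``."""

    children: tuple[int, ...]
    parent: int
    tightness_before: float
    separability: float
    n_clusters_after: int


@dataclass
class MergeTree:
    """Recorded merge trajectory with the resulting label mapping g1."""

    events: list[MergeEvent]
    g1: np.ndarray  # maps 1..kappa_0 -> 1..kappa_1 (index 0 unused)
    final_reference: Partition
    final_partitions: list[Partition]
    final_report: TightnessReport
    kappa_0: int

    @property
    def kappa_1(self) -> int:
        return self.final_reference.K

    def replay(self) -> np.ndarray:
        """Re-derive g1 from the event list (used to verify the tree is faithful)."""
        mapping = np.arange(self.kappa_0 + 1, dtype=np.int64)
        for ev in self.events:
            cur = sorted(set(mapping[1:]))
            children = set(ev.children)
            parent = min(children)
            relabel = {}
            nxt = 1
            for c in cur:
                if c in children and c != parent:
                    continue
                relabel[c] = nxt
                nxt += 1
            for c in children:
                relabel[c] = relabel[parent]
            mapping = np.array([0] + [relabel[int(mapping[k])] for k in range(1, self.kappa_0 + 1)])
        return mapping

    def to_json(self) -> str:
        return json.dumps({
            "kappa_0": self.kappa_0,
            "kappa_1": self.kappa_1,
            "events": [{
                "children": list(ev.children), "parent": ev.parent,
                "tightness_before": ev.tightness_before,
                "separability": ev.separability,
                "n_clusters_after": ev.n_clusters_after,
            } for ev in self.events],
            "g1": self.g1[1:].tolist(),
        }, indent=2)

    def to_newick(self) -> str:
        """Newick string over the initial cluster ids, branch lengths = merge order."""
        node = {k: str(k) for k in range(1, self.kappa_0 + 1)}
        live = {k: k for k in range(1, self.kappa_0 + 1)}  # current id -> tree key
        for step, ev in enumerate(self.events, start=1):
            keys = [live[c] for c in ev.children]
            sub = ",".join(f"{node[k]}:{step}" for k in keys)
            parent_key = min(keys)
            node[parent_key] = f"({sub})"
            # relabel live ids exactly as the merge does
            children = set(ev.children)
            parent = min(children)
            new_live = {}
            nxt = 1
            for c in sorted(live):
                if c in children and c != parent:
                    continue
                new_live[nxt] = parent_key if c == parent else live[c]
                nxt += 1
            live = new_live
        return "(" + ",".join(node[k] for k in sorted(set(live.values()))) + ");"


def _apply_merge(labels_k: int, children: set[int]) -> np.ndarray:
    """LUT (1-based) merging ``children`` into min(children) and compacting."""
    parent = min(children)
    lut = np.zeros(labels_k + 1, dtype=np.int64)
    nxt = 1
    for c in range(1, labels_k + 1):
        if c in children and c != parent:
            continue
        lut[c] = nxt
        nxt += 1
    for c in children:
        lut[c] = lut[parent]
    return lut


def _choose_partner(i: int, delta: np.ndarray, sizes: np.ndarray) -> int:
    """Closest cluster to i (0-based): min separability, ties -> larger size, then smaller id."""
    K = delta.shape[0]
    cand = [j for j in range(K) if j != i]
    return min(cand, key=lambda j: (delta[i, j], -sizes[j], j))


def _stop(report: TightnessReport, K: int, n_clusters: int | None, tightness_goal: float) -> bool:
    # the tightness goal is per cluster: merging continues while any cluster
    # stays below it (mirrors the accelerated ladder, whose final threshold
    # keeps merging until every cluster clears it)
    if n_clusters is not None:
        return K <= n_clusters
    return bool(np.min(report.R_t) >= tightness_goal)


def cps_merge(C: Partition, parts: list[Partition], n_clusters: int | None = None,
              tightness_goal: float = 0.8, alpha: float = 0.1, zeta: float = 0.7) -> MergeTree:
    """Greedy one-at-a-time CPS merging.

    At every step the cluster with minimal tightness is merged with its
    minimal-separability partner; tightness and separability are recomputed
    from scratch on the merged label space.  Stops when ``n_clusters`` is
    reached (if given, it takes precedence) or every cluster's tightness
    reaches ``tightness_goal``.
    """
    kappa_0 = C.K
    if n_clusters is not None and n_clusters > kappa_0:
        raise ValueError(f"n_clusters={n_clusters} exceeds initial cluster count {kappa_0}")
    ref, cur_parts = C, list(parts)
    g1 = np.arange(kappa_0 + 1, dtype=np.int64)
    events: list[MergeEvent] = []
    while True:
        report = ensemble_tightness(ref, cur_parts, alpha, zeta)
        K = ref.K
        if _stop(report, K, n_clusters, tightness_goal):
            break
        if K == 1:
            logger.warning("cps_merge: reached a single cluster before the stop condition")
            break
        i = int(np.lexsort((np.arange(K), report.R_t))[0])  # min R_t, ties -> smallest id
        delta = report.separability_matrix()
        j = _choose_partner(i, delta, ref.sizes())
        logger.info("merge: cluster %d (R_t=%.3f) + cluster %d (delta=%.3f), %d -> %d clusters",
                    i + 1, report.R_t[i], j + 1, delta[i, j], K, K - 1)
        lut = _apply_merge(K, {i + 1, j + 1})
        events.append(MergeEvent(children=(i + 1, j + 1), parent=int(lut[min(i, j) + 1]),
                                 tightness_before=report.overall,
                                 separability=float(delta[i, j]), n_clusters_after=K - 1))
        ref = Partition(lut[ref.labels], fixed_K=K - 1)
        cur_parts = [Partition(lut[p.labels], fixed_K=K - 1) for p in cur_parts]
        g1 = lut[g1]
    final_report = ensemble_tightness(ref, cur_parts, alpha, zeta)
    return MergeTree(events=events, g1=g1, final_reference=ref,
                     final_partitions=cur_parts, final_report=final_report, kappa_0=kappa_0)


def accelerated_cps_merge(C: Partition, parts: list[Partition],
                          thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                          n_clusters: int | None = None, tightness_goal: float = 0.8,
                          alpha: float = 0.1, zeta: float = 0.7) -> MergeTree:
    """Accelerated CPS merging: batch merges under an ascending tightness ladder.

    At each threshold, every cluster with tightness below it is merged with
    its closest cluster in one round (merges resolved in ascending cluster
    id with union-find chaining), then tightness/separability are
    recomputed; rounds repeat until no cluster falls below the threshold.
    """
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly increasing")
    if not all(0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    kappa_0 = C.K
    if n_clusters is not None and n_clusters > kappa_0:
        raise ValueError(f"n_clusters={n_clusters} exceeds initial cluster count {kappa_0}")
    ref, cur_parts = C, list(parts)
    g1 = np.arange(kappa_0 + 1, dtype=np.int64)
    events: list[MergeEvent] = []
    done = False
    for t in thresholds:
        if done:
            break
        while True:
            report = ensemble_tightness(ref, cur_parts, alpha, zeta)
            K = ref.K
            if _stop(report, K, n_clusters, tightness_goal) or K == 1:
                done = True
                break
            below = [k for k in range(K) if report.R_t[k] < t]
            if not below:
                break
            delta = report.separability_matrix()
            sizes = ref.sizes()
            # union-find over 1..K; chain merges within the round
            parent = list(range(K + 1))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            groups = K
            budget = None if n_clusters is None else K - n_clusters
            for k in below:
                if budget is not None and (K - groups) >= budget:
                    break
                j = _choose_partner(k, delta, sizes)
                ra, rb = find(k + 1), find(j + 1)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
                    groups -= 1
            # collapse each multi-member root group; one recorded event per group,
            # applied sequentially with a cumulative LUT so events replay exactly
            root_members: dict[int, list[int]] = {}
            for c in range(1, K + 1):
                root_members.setdefault(find(c), []).append(c)
            group_list = [sorted(ms) for _, ms in sorted(root_members.items()) if len(ms) >= 2]
            if not group_list:
                break
            cum = np.arange(K + 1, dtype=np.int64)  # pre-round label -> current label
            for members in group_list:
                cur_members = sorted({int(cum[m]) for m in members})
                Kcur = ref.K
                lut = _apply_merge(Kcur, set(cur_members))
                events.append(MergeEvent(
                    children=tuple(cur_members), parent=int(lut[min(cur_members)]),
                    tightness_before=report.overall,
                    separability=float(min(delta[a - 1, b - 1]
                                           for a in members for b in members if a < b)),
                    n_clusters_after=Kcur - len(cur_members) + 1))
                ref = Partition(lut[ref.labels], fixed_K=Kcur - len(cur_members) + 1)
                cur_parts = [Partition(lut[p.labels], fixed_K=ref.K) for p in cur_parts]
                g1 = lut[g1]
                cum = lut[cum]
    final_report = ensemble_tightness(ref, cur_parts, alpha, zeta)
    return MergeTree(events=events, g1=g1, final_reference=ref,
                     final_partitions=cur_parts, final_report=final_report, kappa_0=kappa_0)
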