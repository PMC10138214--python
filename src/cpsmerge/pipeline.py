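"""End-to-end multi-view clustering: perturbation ensembles through merging.

``run_pipeline`` wires the stages together: per-view perturbation
ensembles -> OT alignment to each view's reference -> Cartesian-product
partitions -> rare-label cleaning -> optional bipartite first-stage
merging -> tightness-maximizing CPS merging -> per-view contribution
scores.  Views can be raw feature matrices (clustered internally) or
precomputed label ensembles (late integration: only cluster labels are
needed, so any external clustering pipeline can feed in).

With more than two views the product is folded progressively, two views
at a time: the merged result of the first pair is treated as one view and
paired with the next.  Only the two-view path carries validated behavior.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedEnsemble, align_ensemble
from .contribution import ContributionReport, evaluate_contributions
from .cps import TightnessReport
from .merging import (DEFAULT_THRESHOLDS, MergeTree, SuperClustering, accelerated_cps_merge,
                      bipartite_super_clusters, cps_merge, first_stage_merge,
                      matching_weight_matrix)
from .partitions import Partition
from .perturb import ClustererSpec, ViewData, build_ensemble, make_clusterer
from .product import ProductEnsemble, clean_rare_labels, pair_ensembles

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produces, final partition first."""

    final: Partition
    tightness: TightnessReport
    merge_tree: MergeTree
    contributions: ContributionReport
    product: ProductEnsemble
    super_clustering: SuperClustering | None
    view_ensembles: list[AlignedEnsemble]
    f_map: dict[tuple[int, int], int]
    manifest: dict = field(default_factory=dict)

    @property
    def labels_(self) -> np.ndarray:
        return self.final.labels


def _as_clusterer(spec, params) -> ClustererSpec:
    if isinstance(spec, ClustererSpec):
        return spec
    if callable(spec):
        return ClustererSpec(fn=spec, name=getattr(spec, "__name__", "custom"))
    return make_clusterer(spec, **(params or {}))


def _merge_two(ea: AlignedEnsemble, eb: AlignedEnsemble, *, alpha: float, zeta: float,
               n_clusters: int | None, tightness_goal: float, merge_mode: str,
               thresholds, first_stage_threshold: int, leiden_resolution: float,
               seed: int):
    pe = clean_rare_labels(pair_ensembles(ea, eb))
    sc = None
    if pe.n_product_labels > first_stage_threshold:
        Wbar = matching_weight_matrix(ea, eb)
        sc = bipartite_super_clusters(Wbar, resolution=leiden_resolution, seed=seed)
    C, parts, g0_to_C = first_stage_merge(pe, sc)
    if merge_mode == "full":
        tree = cps_merge(C, parts, n_clusters=n_clusters, tightness_goal=tightness_goal,
                         alpha=alpha, zeta=zeta)
    elif merge_mode == "accelerated":
        tree = accelerated_cps_merge(C, parts, thresholds=tuple(thresholds),
                                     n_clusters=n_clusters, tightness_goal=tightness_goal,
                                     alpha=alpha, zeta=zeta)
    else:
        raise ValueError(f"unknown merge_mode {merge_mode!r}; choose full/accelerated")
    f_map = {pe.codebook[code]: int(tree.g1[g0_to_C[code]])
             for code in pe.codebook if g0_to_C[code] > 0}
    return pe, sc, tree, f_map


def run_pipeline(views: list | None = None, *, ensembles: list | None = None,
                 clusterer="kmeans", clusterer_params=None, m: int = 20,
                 noise_fraction: float = 0.1, alpha: float = 0.1, zeta: float = 0.7,
                 n_clusters: int | None = None, tightness_goal: float = 0.8,
                 merge_mode: str = "full", thresholds=DEFAULT_THRESHOLDS,
                 first_stage_threshold: int = 100, leiden_resolution: float = 1.0,
                 perturb_views=None, contribution_rule: str = "allzero",
                 seed: int = 0, view_names=None) -> PipelineResult:
    """Run the full multi-view clustering pipeline on two or more views.

    Parameters
    ----------
    views : list of (n, d) arrays or ViewData, optional
        Raw per-view feature matrices; clustered internally with
        ``clusterer`` under noise perturbation.
    ensembles : list of (reference, raw_partitions) pairs, optional
        Labels-only input: per view, a reference :class:`Partition` (or
        label vector) and the list of m perturbed partitions.  Mutually
        exclusive with ``views``; perturbation is the caller's
        responsibility in this mode.
    clusterer : str, callable, ClustererSpec, or list of these
        Per-view clustering algorithm(s).
    perturb_views : list of bool, optional
        Per-view flags; False re-runs the clusterer on unperturbed data
        (for a dominant view whose clustering is trusted as-is).
    seed : int
        Master seed; every stage's randomness derives from it.
    """
    t0 = time.time()
    if (views is None) == (ensembles is None):
        raise ValueError("provide exactly one of views= or ensembles=")
    aligned_ensembles: list[AlignedEnsemble] = []
    if views is not None:
        views = [v if isinstance(v, ViewData) else ViewData(np.asarray(v), f"view_{i + 1}")
                 for i, v in enumerate(views)]
        L = len(views)
        if view_names:
            for v, nm in zip(views, view_names):
                v.name = nm
        ns = {v.n for v in views}
        if len(ns) != 1:
            raise ValueError(f"views have inconsistent item counts: {sorted(ns)}")
        specs = clusterer if isinstance(clusterer, (list, tuple)) else [clusterer] * L
        params = clusterer_params if isinstance(clusterer_params, (list, tuple)) else [clusterer_params] * L
        flags = perturb_views if perturb_views is not None else [True] * L
        for l, view in enumerate(views):
            spec = _as_clusterer(specs[l], params[l])
            ref, raw = build_ensemble(view, spec, m=m, noise_fraction=noise_fraction,
                                      seed=seed + 10_000 * l, perturb_this_view=flags[l])
            aligned_ensembles.append(align_ensemble(raw, ref, name=view.name))
    else:
        L = len(ensembles)
        names = view_names or [f"view_{l + 1}" for l in range(L)]
        for l, (ref, raw) in enumerate(ensembles):
            ref = ref if isinstance(ref, Partition) else Partition(np.asarray(ref))
            raw = [p if isinstance(p, Partition) else Partition(np.asarray(p)) for p in raw]
            aligned_ensembles.append(align_ensemble(raw, ref, name=names[l]))
    if L < 2:
        raise ValueError("at least two views are required")
    ms = {e.m for e in aligned_ensembles}
    if len(ms) != 1:
        raise ValueError(f"views have inconsistent ensemble sizes: {sorted(ms)}")

    merge_kwargs = dict(alpha=alpha, zeta=zeta, n_clusters=n_clusters,
                        tightness_goal=tightness_goal, merge_mode=merge_mode,
                        thresholds=thresholds, first_stage_threshold=first_stage_threshold,
                        leiden_resolution=leiden_resolution, seed=seed)
    ea = aligned_ensembles[0]
    pe = sc = tree = f_map = None
    for l in range(1, L):
        pe, sc, tree, f_map = _merge_two(ea, aligned_ensembles[l], **merge_kwargs)
        if l < L - 1:  # progressive folding: merged result becomes one view
            ea = AlignedEnsemble(reference=tree.final_reference.compacted(),
                                 aligned=tree.final_partitions,
                                 raw=tree.final_partitions, alignments=[],
                                 name=f"combined_1..{l + 1}")
    F = tree.final_reference.compacted()
    contributions = evaluate_contributions(
        F, [e.raw for e in aligned_ensembles], alpha=alpha, zeta=zeta,
        rule=contribution_rule, view_names=[e.name for e in aligned_ensembles])
    manifest = {
        "seed": seed, "m": m, "noise_fraction": noise_fraction, "alpha": alpha,
        "zeta": zeta, "n_clusters": n_clusters, "tightness_goal": tightness_goal,
        "merge_mode": merge_mode, "thresholds": list(thresholds),
        "first_stage_threshold": first_stage_threshold,
        "leiden_resolution": leiden_resolution,
        "views": [e.name for e in aligned_ensembles],
        "kappa_per_view": [e.reference.K for e in aligned_ensembles],
        "n_product_labels": pe.n_product_labels,
        "first_stage_used": sc is not None,
        "kappa_0": tree.kappa_0, "kappa_1": tree.kappa_1,
        "overall_tightness": tree.final_report.overall,
        "selected_contribution": contributions.selected,
        "runtime_s": round(time.time() - t0, 3),
    }
    return PipelineResult(final=F, tightness=tree.final_report, merge_tree=tree,
                          contributions=contributions, product=pe, super_clustering=sc,
                          view_ensembles=aligned_ensembles, f_map=f_map, manifest=manifest)
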