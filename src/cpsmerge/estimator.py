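"""Scikit-learn style estimator wrapping the multi-view pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .merging import DEFAULT_THRESHOLDS
from .pipeline import run_pipeline

__all__ = ["CPSMerge"]


class CPSMerge(ClusterMixin, BaseEstimator):
    """Multi-view clustering by product-cluster merging under stability.

    Clusters each view separately (under Gaussian noise perturbation, to
    expose assignment uncertainty), aligns the per-view ensembles by
    optimal transport, forms Cartesian-product clusters, and greedily
    merges unstable product clusters to maximize their tightness.  Both
    consensus structure (shared across views) and complementary structure
    (visible only in the joint label space) survive integration, and each
    final cluster gets per-view contribution scores.

    Parameters
    ----------
    m : int, default=20
        Number of perturbed partitions per view.
    noise_fraction : float, default=0.1
        Perturbation variance as a fraction of the average within-cluster
        variance of the view's reference clustering.
    alpha : float, default=0.1
        CPS coverage level: the covering point set must contain at least
        100(1 - alpha)% of a cluster's matched replicates.
    zeta : float, default=0.7
        Match-relation threshold in (0.5, 1]: clusters match when both
        mapping-matrix entries reach it.
    n_clusters : int or None, default=None
        Target number of final clusters.  If set it is a hard stop;
        otherwise merging stops once every cluster's tightness reaches
        ``tightness_goal``.
    tightness_goal : float, default=0.8
        Per-cluster tightness stopping level when ``n_clusters`` is None.
    merge_mode : {"full", "accelerated"}, default="full"
        One merge at a time with full recomputation, or batched rounds
        under the ``thresholds`` ladder.
    thresholds : tuple of float, default=(0.35, 0.5, 0.65, 0.8)
        Ascending tightness ladder for the accelerated mode.
    first_stage_threshold : int, default=100
        Product-label count above which bipartite (Leiden) super-cluster
        merging runs before CPS merging.
    leiden_resolution : float, default=1.0
        Resolution of the bipartite Leiden community detection.
    clusterer : str, callable, or list, default="kmeans"
        Per-view base clustering: "kmeans", "gmm", "leiden", a
        ``(X, seed) -> labels`` callable, or one per view.
    clusterer_params : dict or list of dict, optional
        Parameters for the named clusterer(s), e.g. ``{"n_clusters": 3}``.
    perturb_views : list of bool, optional
        Set False for a dominant view whose clustering should not be
        perturbed (it is re-run on clean data instead).
    contribution_rule : {"allzero", "any", "all", "pooled"}, default="allzero"
        How the 40% zero-tightness rule aggregates across views when
        choosing between the tightness- and matching-weight-based
        contribution measures; "allzero" counts clusters with zero
        tightness in every view.
    random_state : int, default=0
        Master seed; fixes every source of randomness.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Final cluster assignment (0-based).
    n_clusters_ : int
        Number of final clusters.
    tightness_ : ndarray of shape (n_clusters_,)
        Per-cluster tightness of the final partition.
    overall_tightness_ : float
        Mean final tightness.
    contributions_ : ndarray of shape (n_clusters_, n_views)
        Selected per-view contribution of each final cluster (rows sum to 1).
    contribution_report_ : ContributionReport
        Both contribution measures and the selection.
    merge_tree_ : MergeTree
        The recorded merge trajectory (JSON / Newick exportable).
    result_ : PipelineResult
        Every intermediate artifact.

    Examples
    --------
    >>> from cpsmerge import CPSMerge
    >>> from cpsmerge.simulate import SyntheticScenario, generate
    >>> va, vb, truth = generate(SyntheticScenario(regime="complementary", seed=1))
    >>> est = CPSMerge(clusterer="kmeans",
    ...                clusterer_params={"n_clusters": 2}, random_state=1)
    >>> labels = est.fit_predict([va.X, vb.X])
    >>> est.n_clusters_
    4
    """

    def __init__(self, m=20, noise_fraction=0.1, alpha=0.1, zeta=0.7,
                 n_clusters=None, tightness_goal=0.8, merge_mode="full",
                 thresholds=DEFAULT_THRESHOLDS, first_stage_threshold=100,
                 leiden_resolution=1.0, clusterer="kmeans", clusterer_params=None,
                 perturb_views=None, contribution_rule="allzero", random_state=0):
        self.m = m
        self.noise_fraction = noise_fraction
        self.alpha = alpha
        self.zeta = zeta
        self.n_clusters = n_clusters
        self.tightness_goal = tightness_goal
        self.merge_mode = merge_mode
        self.thresholds = thresholds
        self.first_stage_threshold = first_stage_threshold
        self.leiden_resolution = leiden_resolution
        self.clusterer = clusterer
        self.clusterer_params = clusterer_params
        self.perturb_views = perturb_views
        self.contribution_rule = contribution_rule
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a list of per-view feature matrices (same rows, any columns).

        Parameters
        ----------
        X : list of array-like of shape (n_samples, n_features_view)
            One matrix per view.
        y : ignored
        """
        if not isinstance(X, (list, tuple)) or len(X) < 2:
            raise ValueError("X must be a list of at least two per-view matrices")
        views = [check_array(v, dtype=float) for v in X]
        result = run_pipeline(
            views, clusterer=self.clusterer, clusterer_params=self.clusterer_params,
            m=self.m, noise_fraction=self.noise_fraction, alpha=self.alpha,
            zeta=self.zeta, n_clusters=self.n_clusters,
            tightness_goal=self.tightness_goal, merge_mode=self.merge_mode,
            thresholds=self.thresholds, first_stage_threshold=self.first_stage_threshold,
            leiden_resolution=self.leiden_resolution, perturb_views=self.perturb_views,
            contribution_rule=self.contribution_rule, seed=int(self.random_state or 0))
        self.result_ = result
        self.labels_ = result.final.labels - 1
        self.n_clusters_ = result.final.K
        self.tightness_ = result.tightness.R_t
        self.overall_tightness_ = result.tightness.overall
        self.contributions_ = result.contributions.contributions
        self.contribution_report_ = result.contributions
        self.merge_tree_ = result.merge_tree
        self.n_features_in_ = sum(v.shape[1] for v in views)
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the final cluster labels (0-based)."""
        return self.fit(X).labels_

    def _more_tags(self):
        return {"X_types": ["2darray"], "non_deterministic": False}

    def __sklearn_is_fitted__(self):
        return hasattr(self, "labels_")
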