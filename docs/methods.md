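# Methods

This note documents the model, the numerical choices, and the places
where the design was genuinely open, in the order the pipeline runs.

## Perturbation ensembles

Clustering stability is probed by re-clustering noise-perturbed copies of
each view.  Noise is isotropic, homoscedastic Gaussian, added
independently to every point and coordinate, with variance
`noise_fraction × v̄` where `v̄` is the *average within-cluster variance*
of the view's reference clustering.  We define `v̄` as the unweighted
mean over clusters of the mean across coordinates of the per-coordinate
sample variance (denominator `n_k − 1`; singleton clusters contribute 0).
This convention is scale-free in both the number of clusters and the
dimension; users comparing against other stability tools should check
which convention those use, since "average within-cluster variance" is
not standardized.  The default `noise_fraction = 0.1` perturbs points by
about a third of a within-cluster standard deviation — enough to flip
genuinely ambiguous assignments, not enough to destroy real structure.

Per-partition seeds are `master_seed + p`, so one integer reproduces the
entire run bit-for-bit (integer labels and set operations are exact; only
floating summaries carry rounding).

A view can be flagged unperturbed (`perturb_views=[False, True]`) when
prior knowledge says its clustering should be taken at face value — e.g.
a high-coverage modality paired with a noisy ancillary one.  Its m
ensemble members are then clusterer re-runs under distinct seeds.

## Exact transport alignment

Partitions are aligned by the transportation problem with Jaccard ground
costs between cluster member sets and cluster proportions as marginals.
We solve the LP exactly with HiGHS (`scipy.optimize.linprog`); the
returned optimal *basic* solution is a vertex of the transportation
polytope, which is what makes the permutation-recovery guarantee exact
(an entropic solver would smear the coupling).  Cluster counts are tiny
(tens), so exactness costs nothing.  MAP relabeling breaks posterior ties
toward the smallest reference label; all tie-breaks in the package are
deterministic and documented at their definition sites.

Two clusters *match* when both mapping-matrix entries (row- and
column-normalized coupling) reach the threshold `zeta`; `zeta` must
exceed 0.5, which makes the match partner of any reference cluster
unique.  Default `zeta = 0.7`, the midpoint of the admissible (0.5, 1]
range: values near 0.5 admit sloppy matches that inflate tightness,
values near 1 starve small clusters of matches.  The split/merge/
lack-of-correspondence taxonomy beyond "match" is reported in diagnostics
only; nothing downstream consumes it, so its exact thresholds are
cosmetic.

## Covering point sets and tightness

The covering point set of a cluster must contain at least
`⌈m_k(1−alpha)⌉` of its `m_k` matched replicates as subsets, and be
smallest among such sets; tightness then reads
`R_t(k) = p_k · (Σ|Sᵢ|/|S_α|)/m_k`.  Default `alpha = 0.1`.

Two open points were settled as follows:

- **Coverage denominator.** The coverage constraint is taken over the
  `m_k` matched replicates rather than all m partitions (only matched
  replicates exist as sets); the match frequency `p_k = m_k/m` already
  penalizes clusters that match rarely, so using m twice would
  double-count instability.  `m_basis` is exposed for the alternative.
- **Solving the cover.** Choosing which `⌊alpha·m_k⌋` replicates to drop
  is a joint combinatorial choice; a one-at-a-time greedy is provably
  suboptimal (we found 9-vs-7 counterexamples on random instances).
  Since the number of dropped sets is small in every practical setting
  (2 at the defaults), we enumerate drop choices exactly whenever
  `C(m_k, drops) ≤ 20000` — bitmask unions make this microseconds — and
  fall back to a greedy that discards the largest-exclusive-contribution
  set first at larger scale.

Clusters with no matched replicate have tightness 0 and fall back to
their own member set as a degenerate covering set, so CAP separability
(Jaccard distance between covering sets) stays defined for every pair —
such clusters still need a merge partner.

## Merging

The merge objective — maximize summed tightness over final clusters — is
combinatorial; the implementation is the greedy dendrogram: fuse the
least-tight cluster with its minimal-separability partner, recompute
everything from scratch (per-partition member sets are memoized; each
round is O(κ²) set operations plus m small LPs).  Ties: lowest `R_t`,
then smallest cluster id; lowest separability, then largest partner,
then smallest id.

**Stopping.**  With a requested cluster count `κ₁`, that is a hard stop
and takes precedence.  Otherwise merging continues while *any* cluster
sits below the tightness goal (default 0.8).  The per-cluster reading —
rather than stopping on the ensemble average — is what the accelerated
ladder does by construction (it keeps merging while any cluster is below
the current threshold), and it is what removes tiny spurious cells:
a handful of consistently mislabeled boundary points can form a stable
enough cell to keep the *average* above 0.8 while its own tightness is
~0.3.

**Accelerated mode** processes thresholds 0.35 / 0.5 / 0.65 / 0.8 in
order, merging every below-threshold cluster into its nearest cluster in
one round (ascending id, chained through union–find so A→B and B→C
collapse together), recomputing between rounds.  On the benchmark
regimes it reproduces the one-at-a-time result exactly or nearly so.

**First stage.**  With more than `first_stage_threshold = 100` occupied
product labels, the averaged per-pair coupling matrix weights a bipartite
graph between the two views' clusters; Leiden communities
(RBConfiguration, resolution 1.0, seeded from the master seed) form
super-clusters.  Product labels straddling two communities (unmatched
product blocks) are collapsed wholesale; within-community labels keep
product granularity.  Second-stage alignment of the ensemble to the
combined reference happens once; merges thereafter collapse labels
through the merge map rather than re-aligning.

**Rare-label cleaning** precedes all merging: a product label occupied
fewer than m times in total across the m paired partitions (occupancy
exactly m is kept) is voted away — every point holding it anywhere takes
its most frequent *non-rare* label, in all partitions and the reference.
Restricting the vote to non-rare labels prevents cleaning from
re-introducing rarity; ties break to the globally larger label, then the
smaller code.

## View contributions

Both measures treat the final partition F as reference and each view's
*raw pre-alignment* ensemble as its perturbed replicates.

- ζ (tightness-based): `R_t(k, l)` of final cluster k against view l's
  ensemble, normalized across views (0.5 fallback when all views give 0).
- η (matching-weight-based): the column sums of the *row-normalized*
  coupling Γ between each raw partition and F, divided by that
  partition's cluster count and averaged, then normalized across views.
  The row-normalized form matters: the raw coupling's column sums are
  pinned to F's cluster proportions by the marginal constraints and would
  be identical in every view; mapping shares are not so constrained and
  concentrate on final clusters that correspond sharply to a view
  cluster.

η replaces ζ when more than 40% of final clusters "have tightness 0",
which we read as `R_t(k, l) = 0` in *every* view — exactly the clusters
where ζ degenerates to its 0.5 fallback.  Per-view and pooled variants
of the rule are available (`contribution_rule`).  The 40% bound is
strict: exactly 40% keeps ζ.

## Synthetic benchmarks

The generator draws unit-variance Gaussian blobs with means on a 1-D
lattice in each view's first coordinate, `separation` standard deviations
apart, in four regimes: *consensus* (one shared label drives both
views), *complementary* (view A's means depend only on the view-A label,
view B's only on the view-B label — the truth is the product structure),
*mixed* (by default 4 clusters: two separable only in view A, two only
in view B), and *ancillary* (view B is a single blob).  Membership is
i.i.d. uniform over clusters.  Study-scale settings used throughout the
tests and the acceptance script: n = 1000, separation 6, m = 20
perturbed partitions, defaults elsewhere.

What the benchmarks emulate — and what they do not: Gaussian blobs in
two or a few dimensions stand in for dimension-reduced embeddings (PCA /
SVD components), not raw counts; there is no over-dispersion, dropout,
batch structure, or cluster-size imbalance.  Passing these tests shows
the integration machinery is correct (alignment exactness, product
formation, stability-driven merging, contribution direction); it does
not certify performance on real single-cell matrices, where the quality
of the single-view clusterings dominates.

At separation 6, adjacent clusters overlap at ≈ 0.13% per boundary, so
a handful of points per run are mislabeled within a view.  Points
misassigned in one view only are usually rescued by the other view
through merging; points deep on the wrong side of a boundary in one view
form product cells whose separability to either neighbour ties at ≈ 1,
and their merge direction is effectively arbitrary — recovery ARI
therefore fluctuates in roughly the 0.98–1.0 range across seeds rather
than hitting 1 exactly.

## Known limitations

- More than two views are handled by progressive two-at-a-time folding;
  only the two-view path is validated.
- The merge loop re-solves m small LPs per step; for very large κ₀ the
  first stage is required to keep the second stage tractable.
- Stable but *wrong* single-view clusterings cannot be detected from
  labels alone; stability-driven merging inherits them.
- The final partition should be trusted only when the reported tightness
  is high; low overall tightness flags an unstable integration.
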