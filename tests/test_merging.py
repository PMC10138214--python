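import itertools
import json

import numpy as np
import pytest

from conftest import make_aligned_ensemble, make_partition
from cpsmerge.cps import ensemble_tightness
from cpsmerge.merging import (SuperClustering, accelerated_cps_merge,
                              bipartite_super_clusters, cps_merge, first_stage_merge,
                              matching_weight_matrix)
from cpsmerge.partitions import Partition
from cpsmerge.perturb import ViewData, build_ensemble, make_clusterer
from cpsmerge.product import pair_ensembles
from cpsmerge.simulate import ari


def test_matching_weight_identical_pairs():
    ref_a, ref_b = [1, 1, 2, 2], [1, 1, 2, 2]
    ea = make_aligned_ensemble(ref_a, [ref_a] * 3)
    eb = make_aligned_ensemble(ref_b, [ref_b] * 3)
    Wbar = matching_weight_matrix(ea, eb)
    np.testing.assert_allclose(Wbar, np.diag([0.5, 0.5]), atol=1e-9)
    assert Wbar.sum() == pytest.approx(1.0)


def test_matching_weight_hand_mean():
    """Mean of two analytically known couplings, verified entrywise."""
    # pair 1: identical partitions -> diag(0.5, 0.5)
    # pair 2: A=[1,1,1,2] vs B=[1,1,2,2] -> unique optimum [[0.5,0.25],[0,0.25]]
    ea = make_aligned_ensemble([1, 1, 2, 2], [[1, 1, 2, 2], [1, 1, 1, 2]])
    eb = make_aligned_ensemble([1, 1, 2, 2], [[1, 1, 2, 2], [1, 1, 2, 2]])
    Wbar = matching_weight_matrix(ea, eb)
    expected = (np.diag([0.5, 0.5]) + np.array([[0.5, 0.25], [0.0, 0.25]])) / 2
    np.testing.assert_allclose(Wbar, expected, atol=1e-9)


def test_bipartite_block_diagonal():
    Wbar = np.array([[0.3, 0.2, 0.0, 0.0],
                     [0.1, 0.1, 0.0, 0.0],
                     [0.0, 0.0, 0.2, 0.1]])
    sc = bipartite_super_clusters(Wbar, seed=0)
    assert sc.community_A[0] == sc.community_A[1] == sc.community_B[0] == sc.community_B[1]
    assert sc.community_A[2] == sc.community_B[2] == sc.community_B[3]
    assert sc.community_A[0] != sc.community_A[2]


def test_bipartite_stable_under_tiny_noise():
    Wbar = np.array([[0.4, 0.0], [0.0, 0.6]])
    noisy = Wbar + 1e-3 * np.array([[0.0, 1.0], [1.0, 0.0]])
    a = bipartite_super_clusters(Wbar, seed=3)
    b = bipartite_super_clusters(noisy, seed=3)
    assert np.array_equal(a.community_A, b.community_A)
    assert np.array_equal(a.community_B, b.community_B)


def test_bipartite_all_zero_weights():
    sc = bipartite_super_clusters(np.zeros((2, 3)), seed=0)
    assert len(set(sc.community_A) | set(sc.community_B)) == 5


def test_up_blocks_collapse_mp_blocks_keep_granularity():
    # communities: A-clusters {1,2} with B-clusters {1,2} (S1); A3 with B3 (S2)
    sc = SuperClustering(community_A=np.array([0, 0, 1]), community_B=np.array([0, 0, 1]))
    codebook = {i + 1: ab for i, ab in enumerate(
        (a, b) for a in (1, 2, 3) for b in (1, 2, 3))}
    g0 = sc.build_g0(codebook)
    # MP labels (both clusters in the same community) stay distinct
    mp_codes = [c for c, (a, b) in codebook.items()
                if sc.community_A[a - 1] == sc.community_B[b - 1]]
    assert len({g0[c] for c in mp_codes}) == len(mp_codes)
    # UP labels with the same community pair share one id
    up_12 = [c for c, (a, b) in codebook.items()
             if sc.community_A[a - 1] == 0 and sc.community_B[b - 1] == 1]
    assert len({g0[c] for c in up_12}) == 1


def test_first_stage_skip_is_identity():
    ea = make_aligned_ensemble([1, 1, 2, 2], [[1, 1, 2, 2]] * 2)
    eb = make_aligned_ensemble([1, 2, 1, 2], [[1, 2, 1, 2]] * 2)
    pe = pair_ensembles(ea, eb)
    C, parts, g0_to_C = first_stage_merge(pe, None)
    assert C.K == pe.n_product_labels
    for part in parts:
        assert np.array_equal(part.labels, C.labels)


def test_perfect_ensemble_zero_merges():
    """All clusters at tightness 1: merging stops immediately."""
    ref = [1, 1, 1, 2, 2, 2, 3, 3, 3]
    ens = make_aligned_ensemble(ref, [ref] * 4)
    tree = cps_merge(make_partition(ref), ens.aligned, tightness_goal=0.8)
    assert tree.events == []
    assert tree.kappa_1 == 3
    np.testing.assert_array_equal(tree.g1[1:], [1, 2, 3])


def test_n_clusters_stop_takes_precedence():
    ref = [1, 1, 1, 2, 2, 2, 3, 3, 3]
    ens = make_aligned_ensemble(ref, [ref] * 4)
    tree = cps_merge(make_partition(ref), ens.aligned, n_clusters=2, tightness_goal=0.8)
    assert tree.kappa_1 == 2
    assert len(tree.events) == 1


def test_n_clusters_exceeding_kappa0_rejected():
    ref = [1, 1, 2, 2]
    ens = make_aligned_ensemble(ref, [ref])
    with pytest.raises(ValueError, match="n_clusters"):
        cps_merge(make_partition(ref), ens.aligned, n_clusters=5)


def _split_blob_setup(seed=0):
    """Two well-separated blobs; k-means with k=3 splits one of them."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, size=(60, 2)), rng.normal((30, 0), 1, size=(60, 2))])
    view = ViewData(X)
    km = make_clusterer("kmeans", n_clusters=3)
    ref, raw = build_ensemble(view, km, m=10, noise_fraction=0.1, seed=seed)
    truth = np.repeat([1, 2], 60)
    return ref, raw, truth


def test_first_merge_reunites_split_blob():
    ref, raw, truth = _split_blob_setup()
    from cpsmerge.alignment import align_ensemble

    ens = align_ensemble(raw, ref)
    tree = cps_merge(ref, ens.aligned, n_clusters=2)
    assert len(tree.events) == 1
    merged = set(tree.events[0].children)
    blob_of = [set(np.unique(truth[ref.members(k)])) for k in range(1, 4)]
    a, b = sorted(merged)
    assert blob_of[a - 1] == blob_of[b - 1]
    assert ari(truth, tree.final_reference.labels) == 1.0


def test_greedy_merge_matches_one_step_lookahead():
    """Where a uniquely best merge exists, greedy picks the pair that
    maximizes the summed tightness after one merge."""
    ref, raw, truth = _split_blob_setup(seed=3)
    from cpsmerge.alignment import align_ensemble

    ens = align_ensemble(raw, ref)
    K = ref.K
    best_pair, best_score = None, -np.inf
    for i, j in itertools.combinations(range(1, K + 1), 2):
        lut = np.arange(K + 1)
        lut[j] = i
        merged_ref = Partition(lut[ref.labels])
        merged_parts = [Partition(lut[p.labels]) for p in ens.aligned]
        rep = ensemble_tightness(merged_ref, merged_parts)
        score = rep.R_t.sum()
        if score > best_score:
            best_pair, best_score = {i, j}, score
    tree = cps_merge(ref, ens.aligned, n_clusters=K - 1)
    assert set(tree.events[0].children) == best_pair


def test_merge_tree_replay_and_json():
    ref, raw, _ = _split_blob_setup(seed=1)
    from cpsmerge.alignment import align_ensemble

    ens = align_ensemble(raw, ref)
    tree = cps_merge(ref, ens.aligned, n_clusters=1)
    np.testing.assert_array_equal(tree.replay()[1:], tree.g1[1:])
    payload = json.loads(tree.to_json())
    assert payload["kappa_1"] == 1
    assert len(payload["events"]) == tree.kappa_0 - 1
    for ev in tree.events:
        assert ev.n_clusters_after >= 1


def test_merge_tree_newick_leaves():
    ref, raw, _ = _split_blob_setup(seed=1)
    from cpsmerge.alignment import align_ensemble

    ens = align_ensemble(raw, ref)
    tree = cps_merge(ref, ens.aligned, n_clusters=1)
    nwk = tree.to_newick()
    assert nwk.endswith(");")
    # every initial cluster id appears exactly once as a leaf
    import re

    leaves = re.findall(r"(?<![\d])\d+(?=:)", nwk)
    assert sorted(map(int, leaves)) == list(range(1, tree.kappa_0 + 1))


def test_accelerated_no_merges_when_all_tight():
    ref = [1, 1, 1, 2, 2, 2]
    ens = make_aligned_ensemble(ref, [ref] * 4)
    tree = accelerated_cps_merge(make_partition(ref), ens.aligned)
    assert tree.events == []


def test_accelerated_thresholds_must_increase():
    ref = [1, 1, 2, 2]
    ens = make_aligned_ensemble(ref, [ref])
    with pytest.raises(ValueError, match="increasing"):
        accelerated_cps_merge(make_partition(ref), ens.aligned, thresholds=(0.5, 0.35))


def test_accelerated_respects_n_clusters():
    ref, raw, truth = _split_blob_setup(seed=2)
    from cpsmerge.alignment import align_ensemble

    ens = align_ensemble(raw, ref)
    tree = accelerated_cps_merge(ref, ens.aligned, n_clusters=2)
    assert tree.kappa_1 == 2
    assert ari(truth, tree.final_reference.labels) == 1.0


def test_pipeline_with_forced_first_stage():
    """Bipartite super-clustering path: forcing the first stage on small
    product spaces must not change what the pipeline recovers."""
    from cpsmerge import run_pipeline
    from cpsmerge.simulate import SyntheticScenario, generate

    va, vb, truth = generate(SyntheticScenario(regime="complementary", n=300, seed=4))
    r = run_pipeline([va.X, vb.X], clusterer="kmeans",
                     clusterer_params={"n_clusters": 2}, m=6, seed=4,
                     first_stage_threshold=1)
    assert r.manifest["first_stage_used"]
    assert r.final.K == 4
    assert ari(truth["labels"], r.final.labels) >= 0.95

    va, vb, truth = generate(SyntheticScenario(regime="consensus", n=300, kappa_A=3, seed=4))
    r = run_pipeline([va.X, vb.X], clusterer="kmeans",
                     clusterer_params={"n_clusters": 3}, m=6, seed=4,
                     first_stage_threshold=1)
    assert r.manifest["first_stage_used"]
    assert r.final.K == 3
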