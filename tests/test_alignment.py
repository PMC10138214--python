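import numpy as np
import pytest

from conftest import make_partition, random_coupling_ipf
from cpsmerge.alignment import (AlignmentResult, align_ensemble, classify_relations,
                                map_relabel, solve_ot_alignment)
from cpsmerge.partitions import Partition, pairwise_jaccard


def test_identity_alignment():
    p = make_partition([1, 1, 2, 2])
    res = solve_ot_alignment(p, p)
    np.testing.assert_allclose(res.W, np.diag([0.5, 0.5]), atol=1e-9)
    assert res.cost == pytest.approx(0.0, abs=1e-12)


def test_permutation_recovery():
    """Label-permuted copies are realigned exactly: W is the scaled permutation, cost 0."""
    ref = make_partition([1, 1, 1, 2, 2, 3])
    perm = {1: 3, 2: 1, 3: 2}
    p1 = make_partition([perm[v] for v in ref.labels])
    res = solve_ot_alignment(p1, ref)
    assert res.cost == pytest.approx(0.0, abs=1e-12)
    # W has exactly one positive entry per row/column, at the inverse permutation
    expected = np.zeros((3, 3))
    for old, new in perm.items():
        expected[new - 1, old - 1] = (ref.labels == old).mean()
    np.testing.assert_allclose(res.W, expected, atol=1e-9)
    realigned = map_relabel(p1, res)
    assert np.array_equal(realigned.labels, ref.labels)


def test_three_by_two_against_grid_oracle():
    """LP optimum matches a dense grid search over the polytope's 2 degrees of freedom."""
    p1 = make_partition([1] * 6 + [2] * 4 + [3] * 2)
    ref = make_partition([1] * 5 + [2] * 7)
    D = pairwise_jaccard(p1, ref)
    r, c = p1.q, ref.q
    best = np.inf
    for w11 in np.linspace(0, min(r[0], c[0]), 301):
        for w21 in np.linspace(0, min(r[1], c[0]), 301):
            w31 = c[0] - w11 - w21
            if w31 < -1e-12 or w31 > r[2] + 1e-12:
                continue
            W = np.array([[w11, r[0] - w11], [w21, r[1] - w21],
                          [max(w31, 0), r[2] - max(w31, 0)]])
            best = min(best, float((W * D).sum()))
    res = solve_ot_alignment(p1, ref)
    assert res.cost <= best + 1e-9
    assert res.cost == pytest.approx(best, abs=2e-3)


def test_objective_beats_random_feasible_couplings(rng):
    l1 = rng.integers(1, 5, size=60)
    l2 = rng.integers(1, 4, size=60)
    p1, ref = Partition(l1), Partition(l2)
    res = solve_ot_alignment(p1, ref)
    D = pairwise_jaccard(p1, ref)
    for _ in range(50):
        W = random_coupling_ipf(rng, p1.q, ref.q)
        assert res.cost <= (W * D).sum() + 1e-8


def test_marginals_and_stochasticity(rng):
    l1 = rng.integers(1, 6, size=80)
    l2 = rng.integers(1, 4, size=80)
    p1, ref = Partition(l1), Partition(l2)
    res = solve_ot_alignment(p1, ref)
    np.testing.assert_allclose(res.W.sum(axis=1), p1.q, atol=1e-8)
    np.testing.assert_allclose(res.W.sum(axis=0), ref.q, atol=1e-8)
    np.testing.assert_allclose(res.gamma.sum(axis=1), 1.0, atol=1e-8)
    np.testing.assert_allclose(res.gamma_tilde.sum(axis=0), 1.0, atol=1e-8)
    np.testing.assert_allclose(res.gamma, res.W / p1.q[:, None])
    np.testing.assert_allclose(res.gamma_tilde, res.W / ref.q[None, :])
    assert 0.0 <= res.cost <= 1.0


def test_cost_symmetric_and_zero_on_self(rng):
    l1 = rng.integers(1, 4, size=40)
    l2 = rng.integers(1, 5, size=40)
    p1, p2 = Partition(l1), Partition(l2)
    assert solve_ot_alignment(p1, p1).cost == pytest.approx(0.0, abs=1e-12)
    assert solve_ot_alignment(p1, p2).cost == pytest.approx(
        solve_ot_alignment(p2, p1).cost, abs=1e-9)


def test_map_relabel_majority_split():
    """A source cluster split 70/30 over two reference clusters follows the 70% side."""
    ref = make_partition([1] * 7 + [2] * 3 + [2] * 10)
    p1 = make_partition([1] * 10 + [2] * 10)  # cluster 1 overlaps ref1 (7) and ref2 (3)
    res = solve_ot_alignment(p1, ref)
    out = map_relabel(p1, res)
    assert np.all(out.labels[:10] == out.labels[0])
    assert out.labels[0] == 1


def test_map_relabel_permutation_equivariance(rng):
    labels = rng.integers(1, 5, size=50)
    ref = Partition(labels)
    perm = rng.permutation(4) + 1
    p1 = Partition(perm[labels - 1])
    out = map_relabel(p1, solve_ot_alignment(p1, ref))
    assert np.array_equal(out.labels, ref.labels)


def _fake_alignment(gamma, gamma_tilde):
    g = np.asarray(gamma, dtype=float)
    gt = np.asarray(gamma_tilde, dtype=float)
    return AlignmentResult(W=g, gamma=g, gamma_tilde=gt, cost=0.0)


def test_match_requires_both_thresholds():
    align = _fake_alignment([[0.9, 0.1], [0.1, 0.9]], [[0.6, 0.1], [0.4, 0.9]])
    rel = classify_relations(align, zeta=0.7)
    assert 1 not in rel["match"]  # gamma_tilde 0.6 < 0.7 fails
    assert rel["match"][2] == 2


def test_identity_alignment_all_match():
    p = make_partition([1, 1, 2, 2, 3, 3])
    rel = classify_relations(solve_ot_alignment(p, p), zeta=0.8)
    assert rel["match"] == {1: 1, 2: 2, 3: 3}


def test_equal_absorption_is_lack_of_correspondence():
    """A reference cluster pulled 50/50 by two source clusters matches neither."""
    align = _fake_alignment([[0.5, 0.5], [0.5, 0.5]], [[0.5, 0.5], [0.5, 0.5]])
    rel = classify_relations(align, zeta=0.8)
    assert rel["match"] == {}
    assert any(r == "lack-of-correspondence" for _, _, r in rel["relations"])


def test_zeta_out_of_range_rejected():
    p = make_partition([1, 1, 2, 2])
    with pytest.raises(ValueError, match="zeta"):
        classify_relations(solve_ot_alignment(p, p), zeta=0.5)


def test_align_ensemble_permuted_copies():
    ref = make_partition([1, 1, 2, 2, 3, 3])
    perms = [[2, 2, 3, 3, 1, 1], [3, 3, 1, 1, 2, 2], [1, 1, 2, 2, 3, 3]]
    ens = align_ensemble([make_partition(p) for p in perms], ref)
    for aligned in ens.aligned:
        assert np.array_equal(aligned.labels, ref.labels)
    assert all(a.cost == pytest.approx(0.0, abs=1e-12) for a in ens.alignments)


def test_alignment_with_empty_source_cluster():
    """Fixed-label-space partitions may have empty clusters; they carry no mass."""
    p1 = Partition(np.array([1, 1, 3, 3]), fixed_K=3)
    ref = make_partition([1, 1, 2, 2])
    res = solve_ot_alignment(p1, ref)
    np.testing.assert_allclose(res.W[1, :], 0.0)
    np.testing.assert_allclose(res.W.sum(axis=0), ref.q, atol=1e-8)
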