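import itertools
import math

import numpy as np
import pytest

from conftest import make_aligned_ensemble, make_partition
from cpsmerge.cps import (CoveringPointSet, cap_separability, covering_point_set,
                          ensemble_tightness, matched_sets, tightness)


def exhaustive_min_cover(sets, alpha, m_basis=None):
    """Brute-force minimal covering set size over all drop choices."""
    m_basis = len(sets) if m_basis is None else m_basis
    required = max(0, min(math.ceil(m_basis * (1 - alpha)), len(sets)))
    if required == 0:
        return 0
    best = None
    for keep in itertools.combinations(range(len(sets)), required):
        size = len(set().union(*(sets[i] for i in keep)))
        best = size if best is None else min(best, size)
    return best


def test_cps_identical_sets():
    sets = [{1, 2, 3}] * 5
    for alpha in (0.0, 0.2, 0.4):
        cps = covering_point_set(sets, alpha)
        assert cps.members == frozenset({1, 2, 3})


def test_cps_zero_required_is_empty():
    cps = covering_point_set([{1, 2}], alpha=0.5, m_basis=0)
    assert len(cps) == 0


def test_cps_required_exceeding_available_covers_all():
    cps = covering_point_set([{1}, {2}], alpha=0.0, m_basis=5)
    assert cps.members == frozenset({1, 2})
    assert cps.covered_count == 2


def test_cps_coverage_constraint(rng):
    """At least ceil(m(1-alpha)) of the input sets are subsets of the CPS."""
    for _ in range(30):
        m = rng.integers(2, 8)
        sets = [set(rng.choice(12, size=rng.integers(1, 8), replace=False)) for _ in range(m)]
        alpha = float(rng.choice([0.0, 0.2, 0.4]))
        cps = covering_point_set(sets, alpha)
        required = math.ceil(m * (1 - alpha))
        covered = sum(frozenset(s) <= cps.members for s in sets)
        assert covered >= required


def test_lift_matches_exhaustive_minimum(rng):
    """Greedy LIFT attains the exhaustive-minimum CPS cardinality on small fixtures."""
    for _ in range(40):
        m = int(rng.integers(2, 8))
        universe = int(rng.integers(5, 15))
        sets = [set(rng.choice(universe, size=rng.integers(1, universe), replace=False))
                for _ in range(m)]
        alpha = float(rng.choice([0.0, 0.2, 0.4]))
        got = len(covering_point_set(sets, alpha))
        assert got == exhaustive_min_cover(sets, alpha)


def test_alpha_out_of_range():
    with pytest.raises(ValueError, match="alpha"):
        covering_point_set([{1}], alpha=1.0)


def test_tightness_perfect_ensemble():
    ref = [1, 1, 1, 2, 2, 2]
    ens = make_aligned_ensemble(ref, [ref, ref, ref])
    rep = ensemble_tightness(ens.reference, ens.raw, alpha=0.0)
    np.testing.assert_allclose(rep.R_t, 1.0)
    np.testing.assert_allclose(rep.p, 1.0)
    assert rep.overall == pytest.approx(1.0)


def test_tightness_unmatched_cluster_is_zero():
    # reference cluster 3 ({4,5}) is split 50/50 in every partition: no match
    ref = [1, 1, 2, 2, 3, 3]
    part = [1, 1, 2, 2, 1, 2]
    ens = make_aligned_ensemble(ref, [part, part])
    rep = ensemble_tightness(ens.reference, ens.raw, alpha=0.1)
    assert rep.R_t[2] == 0.0
    assert rep.m_matched[2] == 0
    # degenerate CPS falls back to the cluster's own members
    assert rep.cps[2].members == frozenset({4, 5})


def test_tightness_hand_fixture():
    """Matched sets {0,1,2} and {0,1,2,3} at alpha=0: R_t = (3/4 + 4/4)/2 = 0.875."""
    ref = [1, 1, 1, 2, 2, 2]
    part_exact = [1, 1, 1, 2, 2, 2]           # matched set {0,1,2}
    part_bigger = [1, 1, 1, 1, 2, 2]          # matched set {0,1,2,3}
    ens = make_aligned_ensemble(ref, [part_exact, part_bigger])
    rep = ensemble_tightness(ens.reference, ens.raw, alpha=0.0)
    assert rep.R_t[0] == pytest.approx(0.875)


def test_matched_sets_counts():
    ref = [1, 1, 2, 2, 3, 3]
    matching = [1, 1, 2, 2, 3, 3]
    non_matching = [1, 1, 2, 2, 1, 2]  # cluster 3 lost
    ens = make_aligned_ensemble(ref, [matching, matching, non_matching, matching])
    sets, p3 = matched_sets(3, ens)
    assert len(sets) == 3
    assert p3 == pytest.approx(0.75)
    assert tightness(3, ens, alpha=0.0) == pytest.approx(0.75)


@pytest.mark.parametrize("a, b, expected", [
    (range(1, 7), range(4, 10), 2 / 3),
    ({1, 2}, {1, 2}, 0.0),
    ({1, 2}, {5, 6}, 1.0),
])
def test_cap_separability_values(a, b, expected):
    assert cap_separability(set(a), set(b)) == pytest.approx(expected)
    assert cap_separability(set(b), set(a)) == pytest.approx(expected)


def test_separability_matrix_is_pseudometric(rng):
    ref = rng.integers(1, 5, size=60)
    parts = [np.where(rng.random(60) < 0.1, rng.integers(1, 5, size=60), ref)
             for _ in range(5)]
    ens = make_aligned_ensemble(ref, parts)
    rep = ensemble_tightness(ens.reference, ens.raw)
    delta = rep.separability_matrix()
    assert np.allclose(delta, delta.T)
    assert np.allclose(np.diag(delta), 0.0)
    K = delta.shape[0]
    for i, j, k in itertools.permutations(range(K), 3):
        assert delta[i, k] <= delta[i, j] + delta[j, k] + 1e-9
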