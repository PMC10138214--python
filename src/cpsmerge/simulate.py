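"""Synthetic two-view Gaussian-mixture benchmarks and agreement metrics.

The generator emulates the canonical regimes of two-view cluster structure:

- ``consensus``: one shared label drives the cluster means in both views —
  the views are noisy copies of a single clustering.
- ``complementary``: view A's means depend only on the view-A label and
  view B's only on the view-B label; the true clusters are the
  ``kappa_A x kappa_B`` product cells, invisible in either view alone.
- ``mixed``: some true clusters are separable only in view A, some only in
  view B, the rest in both.
- ``ancillary``: view A carries the structure; view B is a single blob.

Cluster means sit on a 1-D lattice in each view's first coordinate,
``separation`` within-cluster standard deviations apart (unit noise), so
``separation`` directly states how hard the single-view clustering task is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .perturb import ViewData

__all__ = ["SyntheticScenario", "generate", "ari", "nmi", "f_measure"]

REGIMES = ("consensus", "complementary", "mixed", "ancillary")


@dataclass
class SyntheticScenario:
    """Parameters of a two-view Gaussian-blob benchmark.

    ``separation`` is the distance between adjacent cluster means in units
    of the within-cluster standard deviation (which is 1).
    """

    regime: str = "complementary"
    n: int = 1000
    kappa_A: int = 2
    kappa_B: int = 2
    separation: float = 6.0
    dims: tuple[int, int] = (2, 2)
    seed: int = 0
    # mixed regime: how many of the kappa_A true clusters are separable only in A,
    # and how many of the kappa_B only in B (defaults set in generate)
    mixed_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0, got {self.separation}")
        if min(self.n, self.kappa_A, self.kappa_B, *self.dims) < 1:
            raise ValueError("n, cluster counts, and dims must be >= 1")


def _lattice_means(k: int, d: int, sep: float) -> np.ndarray:
    """k means on a 1-D lattice along coordinate 0 of a d-dim space."""
    mu = np.zeros((k, d))
    mu[:, 0] = sep * np.arange(k)
    return mu


def generate(scenario: SyntheticScenario) -> tuple[ViewData, ViewData, dict]:
    """Draw the two views and return (view_A, view_B, truth).

    ``truth`` holds ``labels`` (overall true clusters, 1-based),
    ``labels_A`` / ``labels_B`` (the per-view mean indices), and the
    scenario itself.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    dA, dB = sc.dims
    if sc.regime == "consensus":
        kappa = sc.kappa_A
        truth = rng.integers(1, kappa + 1, size=sc.n)
        lab_A = lab_B = truth
        mu_A = _lattice_means(kappa, dA, sc.separation)
        mu_B = _lattice_means(kappa, dB, sc.separation)
    elif sc.regime == "complementary":
        lab_A = rng.integers(1, sc.kappa_A + 1, size=sc.n)
        lab_B = rng.integers(1, sc.kappa_B + 1, size=sc.n)
        truth = (lab_A - 1) * sc.kappa_B + lab_B
        mu_A = _lattice_means(sc.kappa_A, dA, sc.separation)
        mu_B = _lattice_means(sc.kappa_B, dB, sc.separation)
    elif sc.regime == "ancillary":
        kappa = sc.kappa_A
        truth = rng.integers(1, kappa + 1, size=sc.n)
        lab_A = truth
        lab_B = np.ones(sc.n, dtype=np.int64)
        mu_A = _lattice_means(kappa, dA, sc.separation)
        mu_B = np.zeros((1, dB))
    else:  # mixed
        n_a_only = sc.mixed_spec.get("a_only", 2)
        n_b_only = sc.mixed_spec.get("b_only", 2)
        n_both = sc.mixed_spec.get("both", 0)
        kappa = n_a_only + n_b_only + n_both
        truth = rng.integers(1, kappa + 1, size=sc.n)
        # A-only clusters: distinct A mean, one shared B mean; B-only: mirrored;
        # "both" clusters: distinct means in both views
        lab_A = np.zeros(sc.n, dtype=np.int64)
        lab_B = np.zeros(sc.n, dtype=np.int64)
        a_idx, b_idx = 1, 1
        a_shared = None
        b_shared = None
        assign: dict[int, tuple[int, int]] = {}
        for c in range(1, n_a_only + 1):
            if b_shared is None:
                b_shared = b_idx
                b_idx += 1
            assign[c] = (a_idx, b_shared)
            a_idx += 1
        for c in range(n_a_only + 1, n_a_only + n_b_only + 1):
            if a_shared is None:
                a_shared = a_idx
                a_idx += 1
            assign[c] = (a_shared, b_idx)
            b_idx += 1
        for c in range(n_a_only + n_b_only + 1, kappa + 1):
            assign[c] = (a_idx, b_idx)
            a_idx += 1
            b_idx += 1
        for c, (ia, ib) in assign.items():
            mask = truth == c
            lab_A[mask] = ia
            lab_B[mask] = ib
        mu_A = _lattice_means(a_idx - 1, dA, sc.separation)
        mu_B = _lattice_means(b_idx - 1, dB, sc.separation)
    XA = mu_A[lab_A - 1] + rng.standard_normal((sc.n, dA))
    XB = mu_B[lab_B - 1] + rng.standard_normal((sc.n, dB))
    truth_info = {"labels": np.asarray(truth, dtype=np.int64),
                  "labels_A": np.asarray(lab_A, dtype=np.int64),
                  "labels_B": np.asarray(lab_B, dtype=np.int64),
                  "scenario": sc}
    return ViewData(XA, "view_A"), ViewData(XB, "view_B"), truth_info


# ---------------------------------------------------------------------------
# external agreement metrics


def ari(labels1, labels2) -> float:
    """Adjusted Rand index between two labelings (1 = identical up to permutation).

    Both labelings constant is a degenerate identity (returns 1).
    """
    from sklearn.metrics import adjusted_rand_score

    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(l1, l2))


def nmi(labels1, labels2, average_method: str = "arithmetic") -> float:
    """Normalized mutual information; the normalizer is configurable
    (``arithmetic``, ``min``, ``max``, ``geometric``)."""
    from sklearn.metrics import normalized_mutual_info_score

    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("label vectors differ in length")
    return float(normalized_mutual_info_score(l1, l2, average_method=average_method))


def f_measure(truth, pred, variant: str = "pairwise") -> float:
    """F-measure between a ground truth and a predicted labeling.

    ``pairwise`` (default): harmonic mean of pair-counting precision and
    recall — a pair of items co-clustered in the prediction counts as a
    true positive when also co-clustered in the truth.  ``bestmatch``:
    size-weighted average over truth clusters of the best per-cluster F
    against any predicted cluster.
    """
    t, p = np.asarray(truth), np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    from .partitions import Partition, contingency

    cont = contingency(Partition(t), Partition(p)).astype(float)

    def comb2(x):
        return x * (x - 1) / 2.0

    if variant == "pairwise":
        tp = comb2(cont).sum()
        pairs_pred = comb2(cont.sum(axis=0)).sum()
        pairs_truth = comb2(cont.sum(axis=1)).sum()
        if pairs_pred == 0 or pairs_truth == 0 or tp == 0:
            return 1.0 if pairs_pred == pairs_truth == tp else 0.0
        precision = tp / pairs_pred
        recall = tp / pairs_truth
        return float(2 * precision * recall / (precision + recall))
    if variant == "bestmatch":
        row = cont.sum(axis=1, keepdims=True)
        col = cont.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = 2 * cont / (row + col)
        f = np.nan_to_num(f)
        best = f.max(axis=1)
        return float((best * cont.sum(axis=1)).sum() / cont.sum())
    raise ValueError(f"unknown variant {variant!r}; choose pairwise/bestmatch")
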