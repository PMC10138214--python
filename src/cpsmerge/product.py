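"""Cartesian-product partitions across two views and rare-label cleaning.

Once both views' ensembles are aligned to their respective references, the
pair of labels ``(a_h, b_h)`` of an item defines its *product cluster*.
Product clusters carry the cross-view interaction structure: a cluster
may only exist in the joint label space even when invisible in each view
alone.  The ensemble of product partitions pairs partition p of view A
with partition p of view B — since the ensembles are generated
independently, index pairing realizes a random pairing — keeping m pairs
rather than all m^2 combinations.

A product label occupied fewer than m times in total across the m paired
partitions (less than once per result on average) is *rare*: an artifact
of perturbation noise rather than a reproducible cell.  Every point
holding a rare label anywhere is re-labeled, in all m results and in the
reference, by its most frequent non-rare label across the m results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignedEnsemble
from .partitions import Partition

logger = logging.getLogger(__name__)

__all__ = ["ProductEnsemble", "cartesian_product", "pair_ensembles", "clean_rare_labels"]


@dataclass
class ProductEnsemble:
    """Reference product partition plus m paired product partitions.

    ``codebook`` maps each dense product label (1-based) to its originating
    view-label pair (xi_A, xi_B); all partitions share this codebook's label
    space (``fixed_K = len(codebook)``).
    """

    reference: Partition
    partitions: list[Partition]
    codebook: dict[int, tuple[int, int]]
    kappa_A: int
    kappa_B: int
    rare_labels: frozenset = field(default_factory=frozenset)

    @property
    def m(self) -> int:
        return len(self.partitions)

    @property
    def n_product_labels(self) -> int:
        return len(self.codebook)

    def codebook_frame(self) -> pd.DataFrame:
        occ = np.zeros(len(self.codebook), dtype=int)
        for part in self.partitions:
            occ += np.bincount(part.labels, minlength=len(self.codebook) + 1)[1:]
        return pd.DataFrame({
            "code": list(self.codebook),
            "xi_A": [ab[0] for ab in self.codebook.values()],
            "xi_B": [ab[1] for ab in self.codebook.values()],
            "occupancy": occ,
            "rare": [c in self.rare_labels for c in self.codebook],
        })


def _pair_codes(pa: Partition, pb: Partition, kappa_B: int) -> np.ndarray:
    """Raw product code (0-based) of each item: (a-1) * kappa_B + (b-1)."""
    if pa.n != pb.n:
        raise ValueError(f"partitions of different sizes: {pa.n} vs {pb.n}")
    return (pa.labels - 1) * kappa_B + (pb.labels - 1)


def cartesian_product(pa: Partition, pb: Partition) -> Partition:
    """Product partition of two partitions: label = dense code of (a_h, b_h)."""
    return Partition(_pair_codes(pa, pb, pb.K) + 1)


def pair_ensembles(ea: AlignedEnsemble, eb: AlignedEnsemble) -> ProductEnsemble:
    """Pair the two views' aligned ensembles into a product ensemble.

    The codebook covers every product label occupied in the reference or in
    any paired partition, so all product partitions share one label space.
    """
    if ea.m != eb.m:
        raise ValueError(f"ensemble sizes differ: {ea.m} vs {eb.m}")
    if ea.reference.n != eb.reference.n:
        raise ValueError("views have different item counts")
    kA, kB = ea.reference.K, eb.reference.K
    raw_ref = _pair_codes(ea.reference, eb.reference, kB)
    raw_parts = [_pair_codes(a, b, kB) for a, b in zip(ea.aligned, eb.aligned)]
    occupied = np.unique(np.concatenate([raw_ref] + raw_parts))
    code_of = {int(c): i + 1 for i, c in enumerate(occupied)}
    codebook = {i + 1: (int(c) // kB + 1, int(c) % kB + 1) for i, c in enumerate(occupied)}
    lut = np.full(kA * kB, -1, dtype=np.int64)
    for c, dense in code_of.items():
        lut[c] = dense
    K = len(codebook)
    reference = Partition(lut[raw_ref], fixed_K=K)
    partitions = [Partition(lut[rp], fixed_K=K) for rp in raw_parts]
    return ProductEnsemble(reference=reference, partitions=partitions, codebook=codebook,
                           kappa_A=kA, kappa_B=kB)


def clean_rare_labels(pe: ProductEnsemble) -> ProductEnsemble:
    """Re-label points holding rare product labels by majority vote.

    A product label with total occupancy below m across the m paired
    partitions is rare (occupancy exactly m is kept).  Each point holding a
    rare label in any partition is reassigned its most frequent *non-rare*
    label across its own m labels — restricting the vote to non-rare labels
    prevents cleaning from re-introducing rarity — in all m partitions and
    in the reference.  Vote ties break to the label with the larger global
    occupancy, then the smaller code.  If every label a point holds is
    rare, its most frequent label wins regardless of rarity (logged).
    """
    m, K = pe.m, pe.n_product_labels
    label_mat = np.stack([part.labels for part in pe.partitions])  # (m, n)
    occupancy = np.bincount(label_mat.ravel(), minlength=K + 1)[1:]
    rare = np.flatnonzero(occupancy < m) + 1
    rare_set = frozenset(int(r) for r in rare)
    if not rare_set:
        return ProductEnsemble(reference=pe.reference, partitions=list(pe.partitions),
                               codebook=dict(pe.codebook), kappa_A=pe.kappa_A,
                               kappa_B=pe.kappa_B, rare_labels=rare_set)
    is_rare = np.zeros(K + 1, dtype=bool)
    is_rare[list(rare_set)] = True
    affected = np.flatnonzero(is_rare[label_mat].any(axis=0))
    new_mat = label_mat.copy()
    new_ref = pe.reference.labels.copy()
    for h in affected:
        votes = np.bincount(label_mat[:, h], minlength=K + 1)
        candidates = np.flatnonzero((votes > 0) & ~is_rare)
        if candidates.size == 0:
            candidates = np.flatnonzero(votes > 0)
            logger.warning("point %d holds only rare labels; voting among them", h)
        # max count, then max global occupancy, then smallest code
        order = sorted(candidates, key=lambda c: (-votes[c], -occupancy[c - 1], c))
        winner = int(order[0])
        new_mat[:, h] = winner
        new_ref[h] = winner
        logger.debug("point %d re-labeled to %d (rare labels held: %s)",
                     h, winner, sorted(set(map(int, label_mat[:, h])) & rare_set))
    # drop now-empty labels: compact a shared label space over all partitions
    used = np.unique(np.concatenate([new_ref[None, :], new_mat]).ravel())
    lut = np.zeros(K + 1, dtype=np.int64)
    lut[used] = np.arange(1, used.size + 1)
    codebook = {int(lut[c]): pe.codebook[int(c)] for c in used}
    Knew = used.size
    reference = Partition(lut[new_ref], fixed_K=Knew)
    partitions = [Partition(lut[row], fixed_K=Knew) for row in new_mat]
    return ProductEnsemble(reference=reference, partitions=partitions, codebook=codebook,
                           kappa_A=pe.kappa_A, kappa_B=pe.kappa_B,
                           rare_labels=frozenset(int(lut[c]) for c in rare_set if lut[c] > 0))
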