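"""Hard partitions of a finite item set, and the distances between clusters.

A :class:`Partition` stores a hard cluster assignment of ``n`` items as a
1-based integer label vector (items are indexed 0-based internally; cluster
labels are 1-based, matching the usual statistical notation).  Cluster
proportions ``q_k = |C_k| / n`` act as the significance weights carried into
the optimal-transport alignment.  The distance between two clusters is the
Jaccard distance on their member sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "cluster_proportions",
    "jaccard_distance",
    "contingency",
    "pairwise_jaccard",
    "read_label_table",
    "write_label_table",
]


def _compact_labels(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Map the distinct values of ``labels`` onto 1..K preserving order of value.

    Returns the compacted vector and the mapping {original -> compact}.
    """
    uniq = np.unique(labels)
    mapping = {int(u): i + 1 for i, u in enumerate(uniq)}
    lut = np.searchsorted(uniq, labels) + 1
    return lut.astype(np.int64), mapping


@dataclass(frozen=True)
class Partition:
    """A hard partition of ``n`` items into ``K`` clusters labeled 1..K.

    Parameters
    ----------
    labels : array of int, shape (n,)
        Cluster label of each item.  Arbitrary integers are accepted and
        compacted to 1..K; the original values are kept in ``label_map``.
    fixed_K : int, optional
        Pin the label space to 1..fixed_K without compaction (labels must
        already lie in that range).  Used for partitions relabeled into a
        reference label space, where some reference labels may be unused
        but must keep their meaning; such partitions may have empty
        clusters (q_k = 0).
    """

    labels: np.ndarray
    fixed_K: int | None = None
    label_map: dict[int, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("empty input: a partition needs at least one item")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == labels.astype(np.int64)):
                raise ValueError("labels must be integers")
            labels = labels.astype(np.int64)
        if self.fixed_K is not None:
            if labels.min() < 1 or labels.max() > self.fixed_K:
                raise ValueError("labels outside 1..fixed_K")
            object.__setattr__(self, "labels", labels.astype(np.int64))
            if not self.label_map:
                object.__setattr__(self, "label_map", {k: k for k in range(1, self.fixed_K + 1)})
            return
        compact, mapping = _compact_labels(labels)
        object.__setattr__(self, "labels", compact)
        if not self.label_map:
            object.__setattr__(self, "label_map", mapping)

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def K(self) -> int:
        if self.fixed_K is not None:
            return self.fixed_K
        return int(self.labels.max())

    def compacted(self) -> "Partition":
        """Drop empty clusters (possible only with ``fixed_K``) and renumber 1..K."""
        return Partition(self.labels)

    @property
    def q(self) -> np.ndarray:
        """Cluster proportion vector, q_k = |C_k| / n."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:] / self.n

    def members(self, k: int) -> np.ndarray:
        """0-based item indices of cluster ``k`` (1-based label)."""
        return np.flatnonzero(self.labels == k)

    def membership_matrix(self) -> np.ndarray:
        """Boolean matrix of shape (K, n); row k-1 flags the members of cluster k."""
        return self.labels == np.arange(1, self.K + 1)[:, None]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    def relabel(self, mapping: dict[int, int] | np.ndarray) -> "Partition":
        """Apply a (many-to-one) label mapping and compact the result."""
        if isinstance(mapping, dict):
            lut = np.empty(self.K + 1, dtype=np.int64)
            for k in range(1, self.K + 1):
                lut[k] = mapping[k]
        else:
            lut = np.concatenate([[0], np.asarray(mapping, dtype=np.int64)])
        return Partition(lut[self.labels])


def cluster_proportions(partition: Partition) -> np.ndarray:
    """Proportion of items in each cluster; sums to 1."""
    return partition.q


def jaccard_distance(a, b) -> float:
    """Jaccard distance ``1 - |A ∩ B| / |A ∪ B|`` between two item-index sets.

    Both-empty input is a degenerate case arising only when two clusters
    vanish together under relabeling; it is defined as distance 0 and logged.
    """
    sa, sb = set(map(int, a)), set(map(int, b))
    union = len(sa | sb)
    if union == 0:
        logger.warning("jaccard_distance of two empty sets: defined as 0")
        return 0.0
    return 1.0 - len(sa & sb) / union


def contingency(p1: Partition, p2: Partition) -> np.ndarray:
    """K1 x K2 matrix of intersection counts |C_i ∩ C_j| between two partitions."""
    if p1.n != p2.n:
        raise ValueError(f"partitions of different sizes: {p1.n} vs {p2.n}")
    idx = (p1.labels - 1) * p2.K + (p2.labels - 1)
    return np.bincount(idx, minlength=p1.K * p2.K).reshape(p1.K, p2.K)


def pairwise_jaccard(p1: Partition, p2: Partition) -> np.ndarray:
    """K1 x K2 matrix of Jaccard distances between clusters of two partitions.

    Computed from the contingency table: |A ∪ B| = |A| + |B| - |A ∩ B|.
    """
    inter = contingency(p1, p2).astype(float)
    union = p1.sizes()[:, None] + p2.sizes()[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # two empty clusters: treated as identical
    return d


def read_label_table(path, reference_first: bool = True) -> list[Partition]:
    """Read an n-row label table (CSV/TSV, one column per partition, header row).

    Missing values are forbidden.  Returns one :class:`Partition` per column;
    by convention column 0 is the reference partition.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        raise ValueError(f"missing values in label table {path}")
    return [Partition(df[c].to_numpy()) for c in df.columns]


def write_label_table(path, partitions: list[Partition], names: list[str] | None = None) -> None:
    if names is None:
        names = [f"partition_{i}" for i in range(len(partitions))]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame({nm: p.labels for nm, p in zip(names, partitions)}).to_csv(path, sep=sep, index=False)
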