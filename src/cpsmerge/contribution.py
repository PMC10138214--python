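"""Cluster-wise contribution of each view to the final partition.

After merging, each final cluster may owe its existence to one view, to
both, or to their interaction.  Two complementary scores quantify this,
both computed by treating the final partition F as the reference and the
*raw* (pre-alignment) per-view ensembles as its perturbed replicates:

- *tightness-based* zeta_{k,l}: the tightness of final cluster k measured
  against view l's raw ensemble, normalized across views.  High when the
  cluster is reproducibly found in that view alone.
- *matching-weight-based* eta_{k,l}: the average mapping share received
  by cluster k from view l's raw partitions (column sums of the
  row-normalized OT coupling, scaled by the partition's cluster count),
  normalized across views.  Meaningful even when no single-view cluster
  corresponds sharply to k.

Both sum to 1 across views per cluster, with a 0.5 fallback when the
denominator vanishes.  When many final clusters have zero tightness
(interaction-driven structure), zeta is uninformative: if more than 40%
of the clusters have tightness 0, eta is selected instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cps import ensemble_tightness
from .partitions import Partition
from .alignment import solve_ot_alignment

logger = logging.getLogger(__name__)

__all__ = [
    "ContributionReport",
    "tightness_contribution",
    "matching_weight_contribution",
    "select_contribution",
    "evaluate_contributions",
]


def tightness_contribution(F: Partition, raw_ensembles: list[list[Partition]],
                           alpha: float = 0.1, zeta: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Tightness-based contribution zeta_{k,l} of each view to each final cluster.

    Returns ``(zeta_mat, R_t_mat)``, both of shape (kappa_1, n_views);
    ``zeta_mat`` rows sum to 1 (0.5 fallback when all views give R_t = 0).
    """
    L = len(raw_ensembles)
    Rt = np.zeros((F.K, L))
    for l, raws in enumerate(raw_ensembles):
        Rt[:, l] = ensemble_tightness(F, raws, alpha, zeta).R_t
    return _normalize(Rt), Rt


def matching_weight_contribution(F: Partition, raw_ensembles: list[list[Partition]]
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Matching-weight-based contribution eta_{k,l} of each view to each final cluster.

    For each raw partition p of view l, the exact OT coupling against F is
    solved and row-normalized into the cluster mapping matrix Gamma
    (kappa_{p,l} x kappa_1), whose entry gamma_ij is the proportion of view
    cluster i mapped onto final cluster F_j.  The cluster aligning vector
    is Gamma's column-sum vector divided by kappa_{p,l} — the average
    mapping share received by each final cluster — and v_{k,l} averages it
    over the m partitions.  The *raw coupling's* column sums would be
    uninformative here (the marginal constraints pin them to F's cluster
    proportions in every view); the row-normalized shares are not so
    constrained and concentrate on final clusters that correspond sharply
    to a view cluster.

    Returns ``(eta_mat, v_mat)``; ``eta_mat`` rows sum to 1 (0.5 fallback
    when all views give v = 0).
    """
    L = len(raw_ensembles)
    v = np.zeros((F.K, L))
    for l, raws in enumerate(raw_ensembles):
        for part in raws:
            align = solve_ot_alignment(part, F)
            kpl = int(np.sum(part.q > 0))
            v[:, l] += align.gamma.sum(axis=0) / kpl
        v[:, l] /= len(raws)
    return _normalize(v), v


def _normalize(mat: np.ndarray) -> np.ndarray:
    totals = mat.sum(axis=1, keepdims=True)
    out = np.full_like(mat, 1.0 / mat.shape[1])
    np.divide(mat, totals, out=out, where=totals > 0)
    return out


def select_contribution(Rt_mat: np.ndarray, rule: str = "allzero") -> str:
    """Choose between the two measures by the zero-tightness fraction.

    If more than 40% of the final clusters "have tightness 0", the
    matching-weight measure (eta) is selected, else the tightness measure
    (zeta).  Under the default ``allzero`` rule a cluster counts as
    zero-tightness when R_t(k, l) = 0 in *every* view — exactly the
    clusters for which zeta degenerates to its 0.5 fallback, i.e. no
    single view reproduces them.  Alternative aggregations: ``any`` (a
    view with > 40% zeros triggers eta), ``all`` (every view must),
    ``pooled`` (fraction over all (cluster, view) cells).  The 40% bound
    is strict: exactly 40% keeps zeta.
    """
    zero_frac = (Rt_mat == 0).mean(axis=0)
    if rule == "allzero":
        trigger = bool((Rt_mat == 0).all(axis=1).mean() > 0.4)
    elif rule == "any":
        trigger = bool(np.any(zero_frac > 0.4))
    elif rule == "all":
        trigger = bool(np.all(zero_frac > 0.4))
    elif rule == "pooled":
        trigger = bool((Rt_mat == 0).mean() > 0.4)
    else:
        raise ValueError(f"unknown rule {rule!r}; choose allzero/any/all/pooled")
    return "eta" if trigger else "zeta"


@dataclass
class ContributionReport:
    """Both contribution measures for every (final cluster, view) pair."""

    zeta: np.ndarray
    eta: np.ndarray
    R_t: np.ndarray
    v: np.ndarray
    selected: str
    view_names: list[str]

    @property
    def contributions(self) -> np.ndarray:
        """The selected measure's matrix (kappa_1 x n_views)."""
        return self.zeta if self.selected == "zeta" else self.eta

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.zeta.shape[0]):
            for l, name in enumerate(self.view_names):
                rows.append({
                    "cluster": k + 1, "view": name,
                    "R_t": self.R_t[k, l], "v": self.v[k, l],
                    "zeta": self.zeta[k, l], "eta": self.eta[k, l],
                    "selected": self.selected,
                })
        return pd.DataFrame(rows)


def evaluate_contributions(F: Partition, raw_ensembles: list[list[Partition]],
                           alpha: float = 0.1, zeta: float = 0.7, rule: str = "allzero",
                           view_names: list[str] | None = None) -> ContributionReport:
    """Compute zeta and eta contributions and apply the 40% selection rule."""
    if view_names is None:
        view_names = [f"view_{l + 1}" for l in range(len(raw_ensembles))]
    zeta_mat, Rt_mat = tightness_contribution(F, raw_ensembles, alpha, zeta)
    eta_mat, v_mat = matching_weight_contribution(F, raw_ensembles)
    selected = select_contribution(Rt_mat, rule)
    return ContributionReport(zeta=zeta_mat, eta=eta_mat, R_t=Rt_mat, v=v_mat,
                              selected=selected, view_names=view_names)
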