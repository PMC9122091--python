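"""Significance thresholding, mesh clusters, and evaluation metrics.

A *cluster* is a maximal connected set of Bonferroni-significant vertices
within one structure's mesh graph (clusters never span measurement types,
hemispheres or structures).  A cluster is a true positive (TP) when it
contains at least one truly causal vertex that itself reached significance;
otherwise it is a false positive (FP).  From replicated simulations this
module computes the standard calibration and discovery metrics:

* inflation factor ``lambda`` -- empirical over expected median chi-square
  on null vertices (expected median of chi-square(1) ~ 0.4549);
* nominal FPR -- share of null vertices with p < 0.05;
* TPR -- share of causal vertices reaching significance;
* vertex / cluster FWER -- share of replicates with >= 1 FP vertex /
  cluster;
* cluster FDR -- FP clusters over all significant clusters (pooled across
  replicates, with the per-replicate mean as a secondary statistic);
* mapping precision -- median (and max) TP-cluster size;
* calibrated power -- TPR at the largest threshold whose cluster FWER does
  not exceed a target (0.2 by default), found by bisection on log10(alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2 as chi2_dist

from .association import AssocResult
from .data import MEAS_TYPES, VertexAtlas

__all__ = [
    "Cluster",
    "ClusterSet",
    "MetricsReport",
    "CHI2_1_MEDIAN",
    "bonferroni_alpha",
    "threshold_and_cluster",
    "inflation_factor",
    "replicate_metrics",
    "calibrate_power",
]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(chi2_dist.ppf(0.5, df=1))  # 0.45493642311957174


def bonferroni_alpha(n_tests: int, base: float = 0.05, n_phenotypes: int = 1) -> float:
    """Brain-wide Bonferroni threshold ``base / (n_tests * n_phenotypes)``.

    With the full-resolution vertex census (652,283 tests) this gives the
    conventional 7.7e-8 threshold, and 1.5e-8 when further correcting for
    five phenotypes.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    return base / (n_tests * n_phenotypes)


@dataclass
class Cluster:
    """One maximal connected set of significant vertices."""

    members: np.ndarray
    meas_type: str
    hemisphere: str
    structure_id: int
    top_vertex: int
    size: int
    is_tp: bool


@dataclass
class ClusterSet:
    """All clusters of one thresholded association scan."""

    clusters: list[Cluster]
    alpha_used: float

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_tp(self) -> int:
        return sum(c.is_tp for c in self.clusters)

    @property
    def n_fp(self) -> int:
        return sum(not c.is_tp for c in self.clusters)

    def tp_sizes(self) -> list[int]:
        return [c.size for c in self.clusters if c.is_tp]


def threshold_and_cluster(
    res: AssocResult,
    atlas: VertexAtlas,
    alpha: float,
    truth: Iterable[int] | None = None,
) -> ClusterSet:
    """Form mesh clusters from the vertices with ``p < alpha``.

    Clusters are connected components of the significant set within each
    structure's graph (singletons allowed).  A cluster is labelled TP iff
    it contains a causal vertex from ``truth`` -- such a vertex is a member
    and hence significant by construction.
    """
    if len(res) != atlas.n_vertices:
        raise ValueError("result length does not match atlas")
    truth_set = np.zeros(atlas.n_vertices, dtype=bool)
    if truth is not None:
        truth_set[np.asarray(list(truth), dtype=np.int64)] = True

    sig = np.flatnonzero(res.pval < alpha)
    if sig.size == 0:
        return ClusterSet([], alpha)

    sub = atlas.adjacency()[sig][:, sig]
    n_comp, labels = connected_components(sub, directed=False)
    table = atlas.table
    clusters: list[Cluster] = []
    for c in range(n_comp):
        members = sig[labels == c]
        pv = res.pval[members]
        # top vertex: smallest p, ties broken toward the lowest id
        top = int(members[np.lexsort((members, pv))[0]])
        row = table.iloc[members[0]]
        clusters.append(
            Cluster(
                members=members,
                meas_type=str(row["meas_type"]),
                hemisphere=str(row["hemisphere"]),
                structure_id=int(row["structure_id"]),
                top_vertex=top,
                size=int(members.size),
                is_tp=bool(truth_set[members].any()),
            )
        )
    return ClusterSet(clusters, alpha)


def inflation_factor(chi2: np.ndarray) -> float:
    """Inflation factor: median observed chi-square over the chi2(1) median."""
    chi2 = np.asarray(chi2, dtype=np.float64)
    if chi2.size == 0:
        raise ValueError("empty chi-square vector")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


@dataclass
class MetricsReport:
    """Aggregated evaluation metrics over replicates.

    Rates are in [0, 1]; ``fdr_cluster`` pools clusters across replicates
    and is ``nan`` when no cluster reached significance anywhere.
    ``lambda_`` averages the per-replicate inflation factors (computed on
    null vertices).
    """

    lambda_: float
    fpr_nominal: float
    tpr: float
    fwer_vertex: float
    fwer_cluster: float
    fdr_cluster: float
    fdr_cluster_mean: float
    precision_median: float
    precision_max: float
    n_replicates: int
    alpha_used: float
    per_type_fwer: dict[str, float] = field(default_factory=dict)
    power_at_cfwer: float | None = None
    calibrated_alpha: float | None = None


def replicate_metrics(
    replicates: Sequence[tuple[AssocResult, ClusterSet, Iterable[int]]],
    alpha: float,
    atlas: VertexAtlas | None = None,
) -> MetricsReport:
    """Aggregate metrics over ``(result, clusters, causal_ids)`` replicates.

    ``lambda`` and nominal FPR are computed over the *null* (non-causal)
    vertices of each replicate; vertex/cluster FWER count replicates with
    at least one false positive; cluster FDR pools clusters.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    lam, fpr, tpr = [], [], []
    fwer_v = fwer_c = 0
    n_fp_pool = n_all_pool = 0
    fdr_per_rep = []
    tp_sizes: list[int] = []
    type_hits = {t: 0 for t in MEAS_TYPES}

    for res, cs, truth in replicates:
        truth_idx = np.asarray(list(truth), dtype=np.int64)
        is_null = np.ones(len(res), dtype=bool)
        is_null[truth_idx] = False
        if is_null.any():
            lam.append(inflation_factor(res.chi2[is_null]))
            fpr.append(float(np.mean(res.pval[is_null] < 0.05)))
        if truth_idx.size:
            tpr.append(float(np.mean(res.pval[truth_idx] < alpha)))
        fp_vertices = np.flatnonzero(is_null & (res.pval < alpha))
        if fp_vertices.size:
            fwer_v += 1
        if atlas is not None and fp_vertices.size:
            for t in MEAS_TYPES:
                if np.any(atlas.meas_type[fp_vertices] == t):
                    type_hits[t] += 1
        if cs.n_fp:
            fwer_c += 1
        n_fp_pool += cs.n_fp
        n_all_pool += len(cs)
        if len(cs):
            fdr_per_rep.append(cs.n_fp / len(cs))
        tp_sizes.extend(cs.tp_sizes())

    r = len(replicates)
    return MetricsReport(
        lambda_=float(np.mean(lam)) if lam else float("nan"),
        fpr_nominal=float(np.mean(fpr)) if fpr else float("nan"),
        tpr=float(np.mean(tpr)) if tpr else float("nan"),
        fwer_vertex=fwer_v / r,
        fwer_cluster=fwer_c / r,
        fdr_cluster=(n_fp_pool / n_all_pool) if n_all_pool else float("nan"),
        fdr_cluster_mean=float(np.mean(fdr_per_rep)) if fdr_per_rep else float("nan"),
        precision_median=float(np.median(tp_sizes)) if tp_sizes else float("nan"),
        precision_max=float(np.max(tp_sizes)) if tp_sizes else float("nan"),
        n_replicates=r,
        alpha_used=alpha,
        per_type_fwer={t: type_hits[t] / r for t in MEAS_TYPES}
        if atlas is not None
        else {},
    )


def calibrate_power(
    replicates: Sequence[tuple[AssocResult, Iterable[int]]],
    atlas: VertexAtlas,
    target_cfwer: float = 0.2,
    base_alpha: float | None = None,
    log10_tol: float = 0.1,
) -> tuple[float, float]:
    """Largest threshold with cluster FWER <= target, and the power there.

    Starting from the Bonferroni threshold, the significance level is
    lowered by bisection on log10(alpha) until the cluster FWER constraint
    is met, bracketing ``alpha*`` to ``log10_tol`` decades.  Returns
    ``(alpha_star, power)`` where power is the mean TPR at ``alpha_star``;
    if even the smallest representable threshold fails the constraint,
    ``(0.0, 0.0)`` is returned.
    """

    def cfwer(alpha: float) -> float:
        bad = 0
        for res, truth in replicates:
            cs = threshold_and_cluster(res, atlas, alpha, truth)
            if cs.n_fp:
                bad += 1
        return bad / len(replicates)

    def power(alpha: float) -> float:
        vals = []
        for res, truth in replicates:
            truth_idx = np.asarray(list(truth), dtype=np.int64)
            if truth_idx.size:
                vals.append(float(np.mean(res.pval[truth_idx] < alpha)))
        return float(np.mean(vals)) if vals else float("nan")

    if not replicates:
        raise ValueError("need at least one replicate")
    a0 = base_alpha if base_alpha is not None else bonferroni_alpha(len(replicates[0][0]))
    if cfwer(a0) <= target_cfwer:
        return a0, power(a0)

    hi = np.log10(a0)  # known to violate the constraint
    lo = hi - 1.0
    while cfwer(10.0**lo) > target_cfwer:
        hi = lo
        lo -= 1.0
        if lo < -300.0:
            return 0.0, 0.0
    while hi - lo > log10_tol:
        mid = 0.5 * (hi + lo)
        if cfwer(10.0**mid) <= target_cfwer:
            lo = mid
        else:
            hi = mid
    alpha_star = 10.0**lo
    return alpha_star, power(alpha_star)
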