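"""Linear phenotype predictors built from significant vertices.

A predictor is a weighted sum of selected vertex values, using the marginal
association weights from a mass-univariate scan.  Either the single most
significant vertex per cluster is kept (``top_per_cluster``; redundant
within-cluster signal would otherwise overweight large clusters) or every
significant vertex (``all_significant``).  Training-cohort standardization
statistics are frozen into the predictor and replayed on test cohorts --
test-sample statistics are never used, so scoring a held-out cohort leaks
nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .association import AssocResult
from .clusters import ClusterSet
from .data import CohortMatrix

__all__ = [
    "Predictor",
    "build_predictor",
    "score_cohort",
    "evaluate_prediction",
    "SignificantVertexPredictor",
]


@dataclass
class Predictor:
    """Frozen linear predictor: vertex ids, weights and training scale."""

    vertex_ids: np.ndarray
    weights: np.ndarray
    train_means: np.ndarray
    train_sds: np.ndarray
    mode: str
    source_model: str = ""

    def __post_init__(self) -> None:
        if len(set(self.vertex_ids.tolist())) != len(self.vertex_ids):
            raise ValueError("vertex ids must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_json(self, path) -> None:
        payload = {
            "vertex_ids": self.vertex_ids.tolist(),
            "weights": self.weights.tolist(),
            "train_means": self.train_means.tolist(),
            "train_sds": self.train_sds.tolist(),
            "mode": self.mode,
            "source_model": self.source_model,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "Predictor":
        with open(path) as f:
            d = json.load(f)
        return cls(
            vertex_ids=np.asarray(d["vertex_ids"], dtype=np.int64),
            weights=np.asarray(d["weights"], dtype=np.float64),
            train_means=np.asarray(d["train_means"], dtype=np.float64),
            train_sds=np.asarray(d["train_sds"], dtype=np.float64),
            mode=d["mode"],
            source_model=d.get("source_model", ""),
        )


def build_predictor(
    res: AssocResult,
    clusters: ClusterSet,
    data: CohortMatrix,
    mode: str = "top_per_cluster",
) -> Predictor:
    """Select vertices from significant clusters and freeze their weights.

    ``top_per_cluster`` keeps each cluster's most significant vertex (ties
    toward the lowest id, deterministically); ``all_significant`` keeps
    every member.  Weights are the marginal effects ``b`` on the training
    standardized scale; the training column means/sds are recorded for
    out-of-sample scoring.  Raises when no cluster is available.
    """
    if mode not in ("top_per_cluster", "all_significant"):
        raise ValueError(f"unknown predictor mode {mode!r}")
    if len(clusters) == 0:
        raise ValueError("no predictor available: no significant clusters")
    if data.col_means is None or data.col_sds is None:
        raise ValueError("training cohort must carry standardization statistics")
    if mode == "top_per_cluster":
        ids = np.array(sorted(c.top_vertex for c in clusters.clusters), dtype=np.int64)
    else:
        ids = np.sort(np.concatenate([c.members for c in clusters.clusters]))
    return Predictor(
        vertex_ids=ids,
        weights=res.b[ids],
        train_means=np.asarray(data.col_means)[ids],
        train_sds=np.asarray(data.col_sds)[ids],
        mode=mode,
        source_model=res.model_name,
    )


def score_cohort(pred: Predictor, data: CohortMatrix) -> np.ndarray:
    """Linear scores on a (raw or standardized) cohort.

    Test values are put on the *training* standardized scale using the
    frozen means/sds: ``score_j = sum_i w_i (x_ji - m_i) / s_i``.
    """
    if pred.vertex_ids.size and pred.vertex_ids.max() >= data.n_vertices:
        raise ValueError("predictor references vertices absent from the cohort")
    raw = data.raw_values()[:, pred.vertex_ids]
    return ((raw - pred.train_means) / pred.train_sds) @ pred.weights


def evaluate_prediction(scores, y, covariates=None) -> dict[str, float]:
    """Prediction accuracy: Pearson r with a Fisher-z 95% CI, plus partial r.

    The partial correlation residualizes both scores and phenotype on the
    covariates (OLS with intercept) before correlating.  Zero-variance
    scores give ``nan``.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if scores.shape != y.shape:
        raise ValueError("length mismatch between scores and phenotype")
    n = scores.size
    if n < 10:
        raise ValueError("need at least 10 subjects to evaluate prediction")

    def _corr(a, b):
        if a.std() <= 0 or b.std() <= 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r = _corr(scores, y)
    if np.isfinite(r) and n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        ci_low = ci_high = float("nan")

    r_partial = float("nan")
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.hstack([np.ones((n, 1)), C])
        q, _ = np.linalg.qr(Z)
        rs = scores - q @ (q.T @ scores)
        ry = y - q @ (q.T @ y)
        r_partial = _corr(rs, ry)

    return {"r": r, "ci_low": ci_low, "ci_high": ci_high, "r_partial": r_partial}


class SignificantVertexPredictor:
    """End-to-end predictor estimator (scikit-learn style).

    ``fit`` runs one association model on the training cohort, thresholds
    and clusters, selects vertices and freezes their weights; ``predict``
    scores a new cohort on the frozen training scale.
    """

    def __init__(
        self,
        atlas,
        model: str = "glm_no_covariates",
        alpha: float | None = None,
        mode: str = "top_per_cluster",
    ):
        self.atlas = atlas
        self.model = model
        self.alpha = alpha
        self.mode = mode

    def get_params(self, deep=True):
        return {
            "atlas": self.atlas,
            "model": self.model,
            "alpha": self.alpha,
            "mode": self.mode,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, data: CohortMatrix, y, truth=None):
        from .association import ModelSuite
        from .clusters import bonferroni_alpha, threshold_and_cluster

        suite = ModelSuite(data, self.atlas, models=[self.model])
        res = suite.run_one(np.asarray(y, dtype=np.float64), self.model)
        alpha = self.alpha if self.alpha is not None else bonferroni_alpha(len(res))
        clusters = threshold_and_cluster(res, self.atlas, alpha, truth)
        self.predictor_ = build_predictor(res, clusters, data, mode=self.mode)
        self.result_ = res
        self.clusters_ = clusters
        return self

    def predict(self, data: CohortMatrix) -> np.ndarray:
        return score_cohort(self.predictor_, data)

    def score(self, data: CohortMatrix, y) -> float:
        """Pearson correlation between scores and the phenotype."""
        return evaluate_prediction(self.predict(data), y)["r"]
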