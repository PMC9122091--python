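"""Core containers and linear-algebra primitives for vertexwise cohorts.

The package works on subjects x vertices matrices of gray-matter-like
measurements.  Vertices are partitioned into four measurement types
(cortical thickness ``ct``, cortical surface area ``ca``, subcortical
thickness ``st``, subcortical surface area ``sa``), each living on a mesh
whose adjacency is an explicit edge list.  This module provides:

* :class:`VertexAtlas` -- vertex annotations plus mesh adjacency;
* :class:`CohortMatrix` -- the measurement matrix with its covariate table
  and standardization state;
* :class:`BRM` -- the brain-relatedness matrix ``B = X X' / p`` over
  standardized vertex columns;
* :class:`PCSet` -- principal components of gray-matter variation;
* column standardization, BRM construction, PCs and graph smoothing, both
  as scikit-learn style transformers and as plain functions.

Conventions: 0-based vertex ids everywhere; column variances use the
population denominator ``N`` so that ``mean(diag(B)) == 1`` holds exactly
for standardized data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

MEAS_TYPES = ("ct", "ca", "st", "sa")
CORTICAL_TYPES = ("ct", "ca")
SUBCORTICAL_TYPES = ("st", "sa")
HEMISPHERES = ("L", "R")

__all__ = [
    "MEAS_TYPES",
    "CORTICAL_TYPES",
    "SUBCORTICAL_TYPES",
    "HEMISPHERES",
    "VertexAtlas",
    "CohortMatrix",
    "BRM",
    "PCSet",
    "VertexStandardizer",
    "GraphSmoother",
    "standardize_columns",
    "compute_brm",
    "compute_pcs",
    "smooth_graph",
]


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


@dataclass
class VertexAtlas:
    """Vertex annotation table plus mesh adjacency.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per vertex with columns ``vertex_id`` (0..p-1),
        ``meas_type`` (one of :data:`MEAS_TYPES`), ``hemisphere``
        (``L``/``R``) and ``structure_id`` (integer mesh-sheet label).
    edges : numpy.ndarray of shape (E, 2)
        Unordered mesh edges, stored with the smaller id first.  Edges must
        connect vertices of the same measurement type, hemisphere and
        structure.
    """

    table: pd.DataFrame
    edges: np.ndarray
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)
    _smoother: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        edges = np.asarray(self.edges, dtype=np.int64)
        if edges.size == 0:
            edges = edges.reshape(0, 2)
        edges = np.sort(edges, axis=1)
        self.edges = np.unique(edges, axis=0)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.table)

    @property
    def meas_type(self) -> np.ndarray:
        return self.table["meas_type"].to_numpy()

    @property
    def hemisphere(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def structure_id(self) -> np.ndarray:
        return self.table["structure_id"].to_numpy()

    def vertex_ids_of_type(self, meas_type: str) -> np.ndarray:
        """0-based ids of all vertices of one measurement type."""
        if meas_type not in MEAS_TYPES:
            raise ValueError(f"unknown measurement type {meas_type!r}")
        return np.flatnonzero(self.meas_type == meas_type)

    # -- graph machinery ----------------------------------------------------

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix of the mesh graph."""
        if self._adjacency is None:
            p = self.n_vertices
            if len(self.edges):
                i, j = self.edges[:, 0], self.edges[:, 1]
                data = np.ones(len(self.edges))
                a = sp.coo_matrix((data, (i, j)), shape=(p, p))
                a = a + a.T
            else:
                a = sp.coo_matrix((p, p))
            self._adjacency = a.tocsr()
        return self._adjacency

    def smoothing_operator(self) -> sp.csr_matrix:
        """Row-stochastic one-round smoothing kernel.

        Each vertex keeps weight 1/2 and spreads 1/2 equally over its mesh
        neighbors; isolated vertices keep weight 1.  Smoothing therefore
        never mixes values across structures, hemispheres or measurement
        types, and preserves spatially constant fields.
        """
        if self._smoother is None:
            a = self.adjacency()
            deg = np.asarray(a.sum(axis=1)).ravel()
            inv = np.where(deg > 0, 0.5 / np.maximum(deg, 1), 0.0)
            self_w = np.where(deg > 0, 0.5, 1.0)
            s = sp.diags(inv) @ a + sp.diags(self_w)
            self._smoother = s.tocsr()
        return self._smoother

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        tab = self.table
        expected = {"vertex_id", "meas_type", "hemisphere", "structure_id"}
        if not expected.issubset(tab.columns):
            raise ValueError(f"atlas table must have columns {sorted(expected)}")
        if not np.array_equal(tab["vertex_id"].to_numpy(), np.arange(len(tab))):
            raise ValueError("vertex_id must be the contiguous 0-based index")
        unknown = set(tab["meas_type"]) - set(MEAS_TYPES)
        if unknown:
            raise ValueError(f"unknown measurement types {sorted(unknown)}")
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= len(tab):
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop in edge list")
            for col in ("meas_type", "hemisphere", "structure_id"):
                vals = tab[col].to_numpy()
                if np.any(vals[self.edges[:, 0]] != vals[self.edges[:, 1]]):
                    raise ValueError(f"edge connects vertices with different {col}")


# ---------------------------------------------------------------------------
# cohort matrix
# ---------------------------------------------------------------------------


@dataclass
class CohortMatrix:
    """Subjects x vertices measurement matrix with covariates.

    ``values`` is an ``(N, p)`` float array with no missing entries.  When
    ``standardized`` is true every column has mean 0 and population
    (denominator ``N``) variance 1, and ``col_means``/``col_sds`` record the
    raw-scale statistics for later out-of-sample reuse.
    """

    subject_id: list[str]
    values: np.ndarray
    covariates: pd.DataFrame
    standardized: bool = False
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (subjects x vertices)")
        if len(self.subject_id) != self.values.shape[0]:
            raise ValueError("subject_id length does not match values")
        if len(self.covariates) != self.values.shape[0]:
            raise ValueError("covariate table length does not match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def raw_values(self) -> np.ndarray:
        """Values on the raw (pre-standardization) scale."""
        if not self.standardized:
            return self.values
        return self.values * self.col_sds + self.col_means


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


class VertexStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise standardizer with population (1/N) variance.

    Unlike the usual sample convention, variances use denominator ``N`` so
    that a BRM built from the transformed columns has ``mean(diag) == 1``
    exactly.  Constant columns are an error (they carry no information and
    would divide by zero); the error names the offending vertex ids.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # ddof=0
        bad = np.flatnonzero(self.scale_ <= 0)
        if bad.size:
            shown = ", ".join(map(str, bad[:10]))
            raise ValueError(f"constant vertex column(s) cannot be standardized: {shown}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=np.float64) * self.scale_ + self.mean_


def standardize_columns(data: CohortMatrix) -> CohortMatrix:
    """Return a standardized copy of ``data`` (mean 0, variance 1, 1/N).

    Records the raw column means and standard deviations on the result so
    that the exact training-scale transform can be replayed on held-out
    cohorts.  Raises if ``data`` is already standardized or any column is
    constant.
    """
    if data.standardized:
        raise ValueError("cohort is already standardized")
    st = VertexStandardizer().fit(data.values)
    return replace(
        data,
        values=st.transform(data.values),
        standardized=True,
        col_means=st.mean_,
        col_sds=st.scale_,
    )


# ---------------------------------------------------------------------------
# brain relatedness matrix
# ---------------------------------------------------------------------------


@dataclass
class BRM:
    """Brain relatedness matrix ``B = X X' / p`` over standardized columns.

    ``B[i, j]`` is the gray-matter similarity of subjects ``i`` and ``j``;
    with denominator-``N`` standardization ``mean(diag(B)) == 1`` exactly,
    which makes the attached variance component directly interpretable as a
    share of phenotypic variance (morphometricity).
    """

    matrix: np.ndarray
    p_used: int
    component_label: str = "global"
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    _rot_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached ``(eigenvalues, eigenvectors)`` of the BRM (ascending)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            self._eig = (vals, vecs)
        return self._eig

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """``U' M`` in the BRM eigenbasis, cached per source array.

        Rotating the full vertex matrix is the dominant cost of repeated
        mixed-model scans on one cohort, so results are memoized (keyed by
        array identity, holding a reference so ids stay valid).
        """
        key = id(M)
        hit = self._rot_cache.get(key)
        if hit is not None and hit[0] is M:
            return hit[1]
        _, vecs = self.eigendecomposition()
        out = vecs.T @ M
        if len(self._rot_cache) > 4:
            self._rot_cache.clear()
        self._rot_cache[key] = (M, out)
        return out


def _resolve_subset(
    subset, atlas: VertexAtlas | None, p: int
) -> tuple[np.ndarray, str]:
    if subset is None:
        return np.arange(p), "global"
    if isinstance(subset, str):
        if atlas is None:
            raise ValueError("an atlas is required to resolve a type-label subset")
        ids = atlas.vertex_ids_of_type(subset)
        return ids, subset
    ids = np.asarray(sorted(set(int(v) for v in subset)), dtype=np.int64)
    return ids, "subset"


def compute_brm(
    data: CohortMatrix,
    subset=None,
    atlas: VertexAtlas | None = None,
    component_label: str | None = None,
) -> BRM:
    """Build ``B = X_S X_S' / |S|`` from standardized columns ``S``.

    ``subset`` may be ``None`` (all vertices), a measurement-type label
    (requires ``atlas``), or an iterable of vertex ids.  The global BRM is
    the p-weighted average of the four per-type BRMs.
    """
    if not data.standardized:
        raise ValueError("compute_brm requires standardized data")
    ids, label = _resolve_subset(subset, atlas, data.n_vertices)
    if ids.size == 0:
        raise ValueError("empty vertex subset")
    X = data.values[:, ids]
    B = X @ X.T / ids.size
    B = (B + B.T) / 2.0
    return BRM(matrix=B, p_used=int(ids.size), component_label=component_label or label)


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


@dataclass
class PCSet:
    """Principal components of gray-matter variation.

    ``scores`` are subject-level component scores (``U * s``, i.e. the
    projections of the standardized matrix on its top left singular
    vectors); ``loadings`` are the corresponding vertex weights.  For
    ``scope='per_type'`` the blocks of ``k`` components per measurement type
    are concatenated in :data:`MEAS_TYPES` order (scores are orthogonal
    within each type block).  ``variance_explained`` is the fraction of the
    (sub)matrix total variance per component.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    scope: str = "global"


def _pcs_of_block(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = X.shape[0]
    gram = X @ X.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:k]
    lam = np.maximum(vals[order], 0.0)
    u = vecs[:, order]
    s = np.sqrt(lam)
    scores = u * s
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = np.where(s > 0, (X.T @ u) / s, 0.0)
    ve = lam / max(vals.sum(), np.finfo(float).tiny)
    return scores, loadings, ve


def compute_pcs(
    data: CohortMatrix,
    k: int,
    scope: str = "global",
    atlas: VertexAtlas | None = None,
) -> PCSet:
    """Top-``k`` principal components of the standardized matrix.

    ``scope='global'`` decomposes the full matrix; ``scope='per_type'``
    computes ``k`` components within each measurement type (requires
    ``atlas``) and concatenates them, as used for the "modality specific
    PCs" covariate set.
    """
    if not data.standardized:
        raise ValueError("compute_pcs requires standardized data")
    if k <= 0:
        raise ValueError("k must be positive")
    n, p = data.values.shape
    if scope == "global":
        if k > min(n - 1, p):
            raise ValueError(f"k={k} exceeds min(N-1, p)={min(n - 1, p)}")
        scores, loadings, ve = _pcs_of_block(data.values, k)
        return PCSet(scores, loadings, ve, scope="global")
    if scope == "per_type":
        if atlas is None:
            raise ValueError("per_type PCs require an atlas")
        all_scores, all_ve = [], []
        loadings = np.zeros((p, 0))
        for t in MEAS_TYPES:
            ids = atlas.vertex_ids_of_type(t)
            if ids.size == 0:
                continue
            if k > min(n - 1, ids.size):
                raise ValueError(f"k={k} exceeds min(N-1, p_type) for type {t!r}")
            s, ld, ve = _pcs_of_block(data.values[:, ids], k)
            all_scores.append(s)
            all_ve.append(ve)
            block = np.zeros((p, k))
            block[ids] = ld
            loadings = np.hstack([loadings, block])
        return PCSet(
            np.hstack(all_scores), loadings, np.concatenate(all_ve), scope="per_type"
        )
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# graph smoothing
# ---------------------------------------------------------------------------


class GraphSmoother(TransformerMixin, BaseEstimator):
    """Iterated neighbor-averaging smoother on the atlas mesh graph.

    One round replaces each vertex value by half its own value plus half the
    mean of its mesh neighbors.  ``rounds`` iterations emulate the effect of
    a surface smoothing kernel of increasing width while never mixing values
    across structures.  ``rounds=0`` is the identity.
    """

    def __init__(self, atlas: VertexAtlas, rounds: int = 1):
        self.atlas = atlas
        self.rounds = rounds

    def fit(self, X=None, y=None):
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        self.operator_ = self.atlas.smoothing_operator()
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if self.rounds == 0:
            return X
        st = self.operator_.T
        for _ in range(self.rounds):
            X = X @ st
        return np.ascontiguousarray(X)


def smooth_graph(data: CohortMatrix, atlas: VertexAtlas, rounds: int) -> CohortMatrix:
    """Smooth raw vertex values over the mesh graph.

    Smoothing is applied to raw (not standardized) values; standardize
    afterwards.  Returns a new cohort; ``rounds=0`` returns an identical
    copy.
    """
    if data.standardized:
        raise ValueError("smooth raw values, then standardize")
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if atlas.n_vertices != data.n_vertices:
        raise ValueError("atlas size does not match cohort")
    sm = GraphSmoother(atlas, rounds).fit()
    return replace(data, values=sm.transform(data.values))
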