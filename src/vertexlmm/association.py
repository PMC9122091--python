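"""Per-vertex association engines: mass-univariate GLMs and BRM mixed models.

Eight model configurations are supported, mirroring common practice in
vertexwise brain mapping:

========================  =======================================================
name                      model
========================  =======================================================
``glm_no_covariates``     OLS of y on [1, x_i]
``glm_age_sex_icv``       OLS with age / sex / ICV covariates
``glm_pc5``               OLS with 5 global gray-matter PCs
``glm_pc10``              OLS with 10 global PCs
``glm_pc10_per_type``     OLS with 10 PCs per measurement type (40 covariates)
``lmm_global``            LMM: all vertices as a random effect via the global BRM
``lmm_covariates``        LMM with age / sex / ICV fixed effects
``lmm_multi_brm``         LMM with 4 random effects (one BRM per measurement type)
========================  =======================================================

The LMMs follow the one-pass omic-association (MOA) strategy: variance
components are estimated once under the null model (candidate vertex
excluded from the fixed part but *not* from the BRM), then every vertex is
tested by generalized least squares against the resulting covariance
``V = sum_k v_k B_k + v_e I``:

    b_i = x_i' P y / (x_i' P x_i),   SE^2 = 1 / (x_i' P x_i),

with ``P = V^-1 - V^-1 Z (Z' V^-1 Z)^-1 Z' V^-1``.  Both engines report
``chi2 = (b / SE)^2`` with an upper-tail chi-square(1) p-value.  Because the
candidate sits in the BRM as well ("double fitting"), LMM statistics are
slightly deflated relative to an exact per-vertex refit; the one-pass cost
is O(p N^2 + N^3 + p N) instead of O(p N^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .data import MEAS_TYPES, BRM, CohortMatrix, PCSet, VertexAtlas, compute_brm, compute_pcs
from .reml import REMLOptions, VarianceComponents, fit_reml

__all__ = [
    "ModelSpec",
    "AssocResult",
    "MODEL_SPECS",
    "DEFAULT_MODEL_NAMES",
    "MassUnivariateGLM",
    "MassUnivariateLMM",
    "ModelSuite",
    "run_glm",
    "run_lmm",
    "run_model_suite",
]

_AGE_SEX_ICV = ("age", "sex", "icv")
_PVAL_FLOOR = np.finfo(np.float64).tiny
#: partial variance below this fraction of N flags a vertex as collinear
_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """One of the eight association-model configurations.

    ``family`` is ``'glm'`` or ``'lmm'``; ``covariate_set`` one of
    ``none / age_sex_icv / pc5_global / pc10_global / pc10_per_type`` for
    GLMs and ``none / age_sex_icv`` for LMMs; ``brm_structure``
    (``global`` or ``per_type_4``) applies to LMMs only.
    """

    family: str
    covariate_set: str = "none"
    brm_structure: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("glm", "lmm"):
            raise ValueError("family must be 'glm' or 'lmm'")
        glm_sets = ("none", "age_sex_icv", "pc5_global", "pc10_global", "pc10_per_type")
        lmm_sets = ("none", "age_sex_icv")
        if self.family == "glm":
            if self.covariate_set not in glm_sets:
                raise ValueError(f"invalid GLM covariate set {self.covariate_set!r}")
            if self.brm_structure is not None:
                raise ValueError("brm_structure applies to LMMs only")
        else:
            if self.covariate_set not in lmm_sets:
                raise ValueError(f"invalid LMM covariate set {self.covariate_set!r}")
            if self.brm_structure not in ("global", "per_type_4"):
                raise ValueError("LMM needs brm_structure 'global' or 'per_type_4'")


MODEL_SPECS: dict[str, ModelSpec] = {
    "glm_no_covariates": ModelSpec("glm", "none"),
    "glm_age_sex_icv": ModelSpec("glm", "age_sex_icv"),
    "glm_pc5": ModelSpec("glm", "pc5_global"),
    "glm_pc10": ModelSpec("glm", "pc10_global"),
    "glm_pc10_per_type": ModelSpec("glm", "pc10_per_type"),
    "lmm_global": ModelSpec("lmm", "none", "global"),
    "lmm_covariates": ModelSpec("lmm", "age_sex_icv", "global"),
    "lmm_multi_brm": ModelSpec("lmm", "none", "per_type_4"),
}

DEFAULT_MODEL_NAMES = list(MODEL_SPECS)


@dataclass
class AssocResult:
    """Per-vertex association statistics for one model.

    ``b`` is the effect on the standardized scale, ``chi2 = (b/se)^2`` and
    ``pval`` its upper-tail chi-square(1) probability (floored at the
    smallest positive double).  ``flagged`` marks vertices collinear with
    the covariates, which are reported as null results (chi2 0, p 1)
    rather than raising mid-scan.
    """

    b: np.ndarray
    se: np.ndarray
    chi2: np.ndarray
    pval: np.ndarray
    model: ModelSpec
    n_subjects: int
    model_name: str = ""
    flagged: np.ndarray | None = None
    vc: VarianceComponents | None = None

    def __len__(self) -> int:
        return len(self.b)

    def to_frame(self, atlas: VertexAtlas | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "vertex_id": np.arange(len(self.b)),
                "b": self.b,
                "se": self.se,
                "chi2": self.chi2,
                "p": self.pval,
            }
        )
        if atlas is not None:
            df.insert(1, "meas_type", atlas.meas_type)
        return df


def _chi2_pvals(chi2: np.ndarray) -> np.ndarray:
    return np.clip(chi2_dist.sf(chi2, df=1), _PVAL_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# covariate assembly
# ---------------------------------------------------------------------------


def assemble_covariates(
    data: CohortMatrix,
    covariate_set: str,
    pcs_global: PCSet | None = None,
    pcs_per_type: PCSet | None = None,
) -> np.ndarray | None:
    """Covariate matrix (without intercept) for one covariate set."""
    if covariate_set == "none":
        return None
    if covariate_set == "age_sex_icv":
        missing = [c for c in _AGE_SEX_ICV if c not in data.covariates.columns]
        if missing:
            raise ValueError(f"covariate table lacks columns {missing}")
        return data.covariates.loc[:, list(_AGE_SEX_ICV)].to_numpy(dtype=np.float64)
    if covariate_set in ("pc5_global", "pc10_global"):
        k = 5 if covariate_set == "pc5_global" else 10
        if pcs_global is None or pcs_global.scores.shape[1] < k:
            raise ValueError(f"{covariate_set} requires >= {k} global PCs")
        return pcs_global.scores[:, :k]
    if covariate_set == "pc10_per_type":
        if pcs_per_type is None:
            raise ValueError("pc10_per_type requires per-type PCs")
        return pcs_per_type.scores
    raise ValueError(f"unknown covariate set {covariate_set!r}")


def _design_q(covariates: np.ndarray | None, n: int) -> np.ndarray:
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.hstack([Z, C])
    return Z


# ---------------------------------------------------------------------------
# scan cores
# ---------------------------------------------------------------------------


def _residualize(Z: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """QR-based residualization of M's columns on the design Z."""
    Q, _ = np.linalg.qr(Z)
    return M - Q @ (Q.T @ M), Q


def _ols_scan(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    precomp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
):
    """Vectorized per-vertex OLS of y on [1, covariates, x_i].

    ``precomp`` optionally carries ``(Q, X_resid, xtx)`` so repeated scans
    on the same cohort skip the O(N p q) residualization.
    """
    n, p = X.shape
    if precomp is None:
        Z = _design_q(covariates, n)
        Xr, Q = _residualize(Z, X)
        xtx = np.einsum("ij,ij->j", Xr, Xr)
    else:
        Q, Xr, xtx = precomp
    q_tot = Q.shape[1] + 1  # intercept+covariates plus the vertex
    df = n - q_tot
    if df <= 0:
        raise ValueError("not enough subjects for the covariate set")

    yr = y - Q @ (Q.T @ y)
    xty = Xr.T @ yr
    flagged = xtx < _COLLINEAR_TOL * n
    safe = np.where(flagged, 1.0, xtx)
    b = np.where(flagged, 0.0, xty / safe)
    rss = np.maximum(yr @ yr - b * xty, 0.0)
    sigma2 = rss / df
    sigma2 = np.where(sigma2 <= 0, np.finfo(np.float64).tiny, sigma2)
    se = np.sqrt(sigma2 / safe)
    with np.errstate(over="ignore"):
        chi2 = np.where(flagged, 0.0, b**2 * safe / sigma2)
    pval = _chi2_pvals(chi2)
    pval[flagged] = 1.0
    se = np.where(flagged, np.inf, se)
    return b, se, chi2, pval, flagged


def _gls_core(X, vix, y_piece, Z, viz, Wc):
    """Shared GLS scan algebra given V^{-1}X (or its rotated analog)."""
    xpx = np.einsum("ij,ij->j", X, vix)
    t = Z.T @ vix
    xpx -= np.einsum("ij,ij->j", t, cho_solve(Wc, t))
    xpy = X.T @ y_piece
    return xpx, xpy


def _finalize_gls(xpx, xpy, n):
    flagged = xpx < _COLLINEAR_TOL * n
    safe = np.where(flagged, 1.0, xpx)
    b = np.where(flagged, 0.0, xpy / safe)
    se = np.where(flagged, np.inf, np.sqrt(1.0 / safe))
    chi2 = np.where(flagged, 0.0, xpy**2 / safe)
    pval = _chi2_pvals(chi2)
    pval[flagged] = 1.0
    return b, se, chi2, pval, flagged


def _gls_scan_rotated(Xr, yr, Zr, w, n):
    """GLS scan with V diagonal (single-BRM model in the BRM eigenbasis)."""
    iw = 1.0 / w
    viz = Zr * iw[:, None]
    Wc = cho_factor(Zr.T @ viz)
    yiw = yr * iw
    py = yiw - viz @ cho_solve(Wc, Zr.T @ yiw)
    vix = Xr * iw[:, None]
    xpx, xpy = _gls_core(Xr, vix, py, Zr, viz, Wc)
    return _finalize_gls(xpx, xpy, n)


def _gls_scan_dense(X, y, Z, V, n):
    """GLS scan with a dense V (multi-BRM model)."""
    Vc = cho_factor(V, lower=True)
    viz = cho_solve(Vc, Z)
    Wc = cho_factor(Z.T @ viz)
    viy = cho_solve(Vc, y)
    py = viy - viz @ cho_solve(Wc, Z.T @ viy)
    vix = cho_solve(Vc, X)
    xpx, xpy = _gls_core(X, vix, py, Z, viz, Wc)
    return _finalize_gls(xpx, xpy, n)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class MassUnivariateGLM(BaseEstimator):
    """Per-vertex ordinary least squares scan (scikit-learn style).

    Each vertex is tested in its own linear model
    ``y = Z c + x_i b_i + e`` with ``Z`` the intercept plus the supplied
    covariates; fitted attributes ``b_``, ``se_``, ``chi2_``, ``pvalues_``
    and ``flagged_`` have one entry per vertex.
    """

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        b, se, chi2, pval, flagged = _ols_scan(X, y, covariates)
        self.b_, self.se_, self.chi2_, self.pvalues_, self.flagged_ = (
            b,
            se,
            chi2,
            pval,
            flagged,
        )
        self.n_subjects_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        return self


class MassUnivariateLMM(BaseEstimator):
    """One-pass mixed-model scan against fitted BRM variance components.

    When all BRM components are zero (null-model REML hit the boundary)
    GLS with ``V = v_e I`` reduces to OLS; the scan then dispatches to the
    OLS engine so the degenerate limit agrees exactly with
    :class:`MassUnivariateGLM`.
    """

    def fit(self, X, y, covariates=None, vc: VarianceComponents = None, brms=None):
        if vc is None or brms is None:
            raise ValueError("MassUnivariateLMM requires fitted vc and the BRMs")
        brm_list = [brms] if isinstance(brms, BRM) else list(brms)
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n = X.shape[0]
        if np.all(vc.v_components == 0.0):
            b, se, chi2, pval, flagged = _ols_scan(X, y, covariates)
        else:
            Z = _design_q(covariates, n)
            if len(brm_list) == 1:
                d, U = brm_list[0].eigendecomposition()
                w = vc.v_components[0] * np.clip(d, 0.0, None) + vc.v_e
                Xr = brm_list[0].rotate(X)
                b, se, chi2, pval, flagged = _gls_scan_rotated(
                    Xr, U.T @ y, U.T @ Z, w, n
                )
            else:
                V = np.zeros((n, n))
                for t, brm in zip(vc.v_components, brm_list):
                    if t != 0.0:
                        V += t * brm.matrix
                V[np.diag_indices_from(V)] += vc.v_e
                b, se, chi2, pval, flagged = _gls_scan_dense(X, y, Z, V, n)
        self.b_, self.se_, self.chi2_, self.pvalues_, self.flagged_ = (
            b,
            se,
            chi2,
            pval,
            flagged,
        )
        self.n_subjects_ = n
        self.n_features_in_ = X.shape[1]
        return self


# ---------------------------------------------------------------------------
# functional interface
# ---------------------------------------------------------------------------


def run_glm(
    y,
    data: CohortMatrix,
    spec: ModelSpec,
    pcs: PCSet | None = None,
    pcs_per_type: PCSet | None = None,
    model_name: str = "",
) -> AssocResult:
    """Run one GLM configuration over every vertex."""
    if spec.family != "glm":
        raise ValueError("run_glm expects a GLM ModelSpec")
    if not data.standardized:
        raise ValueError("association scans require standardized data")
    C = assemble_covariates(data, spec.covariate_set, pcs, pcs_per_type)
    est = MassUnivariateGLM().fit(data.values, y, covariates=C)
    return AssocResult(
        est.b_,
        est.se_,
        est.chi2_,
        est.pvalues_,
        spec,
        est.n_subjects_,
        model_name or f"glm_{spec.covariate_set}",
        est.flagged_,
    )


def run_lmm(
    y,
    data: CohortMatrix,
    spec: ModelSpec,
    vc: VarianceComponents,
    brms: BRM | list[BRM],
    model_name: str = "",
) -> AssocResult:
    """Run one LMM configuration given null-model variance components.

    ``vc`` must have been fitted on the same ``y``, covariates and BRM
    structure.  A non-converged ``vc`` is used anyway (matching the usual
    boundary behavior) -- callers may inspect ``vc.converged``.
    """
    if spec.family != "lmm":
        raise ValueError("run_lmm expects an LMM ModelSpec")
    if not data.standardized:
        raise ValueError("association scans require standardized data")
    C = assemble_covariates(data, spec.covariate_set)
    est = MassUnivariateLMM().fit(data.values, y, covariates=C, vc=vc, brms=brms)
    return AssocResult(
        est.b_,
        est.se_,
        est.chi2_,
        est.pvalues_,
        spec,
        est.n_subjects_,
        model_name or f"lmm_{spec.covariate_set}",
        est.flagged_,
        vc=vc,
    )


class ModelSuite:
    """Shared precomputation for running many traits through many models.

    Builds (lazily, at most once) the global and per-type BRMs, the global
    BRM eigendecomposition, the PC covariate sets, and the per-covariate-set
    residualized vertex matrices -- everything that depends on the cohort
    but not on the phenotype.  ``run(y)`` then scans one trait through all
    requested models.
    """

    def __init__(
        self,
        data: CohortMatrix,
        atlas: VertexAtlas,
        models: list[str] | None = None,
        reml_options: REMLOptions | None = None,
    ):
        if not data.standardized:
            raise ValueError("ModelSuite requires standardized data")
        if atlas.n_vertices != data.n_vertices:
            raise ValueError("atlas does not match cohort")
        self.data = data
        self.atlas = atlas
        self.model_names = list(models) if models is not None else list(DEFAULT_MODEL_NAMES)
        unknown = [m for m in self.model_names if m not in MODEL_SPECS]
        if unknown:
            raise ValueError(f"unknown model names {unknown}")
        self.reml_options = reml_options or REMLOptions()
        self._pcs_global: PCSet | None = None
        self._pcs_per_type: PCSet | None = None
        self._brm_global: BRM | None = None
        self._brms_per_type: list[BRM] | None = None
        self._glm_precomp: dict[str, tuple] = {}

    # -- lazy shared structures --------------------------------------------

    @property
    def pcs_global(self) -> PCSet:
        if self._pcs_global is None:
            self._pcs_global = compute_pcs(self.data, 10, scope="global")
        return self._pcs_global

    @property
    def pcs_per_type(self) -> PCSet:
        if self._pcs_per_type is None:
            self._pcs_per_type = compute_pcs(
                self.data, 10, scope="per_type", atlas=self.atlas
            )
        return self._pcs_per_type

    @property
    def brm_global(self) -> BRM:
        if self._brm_global is None:
            self._brm_global = compute_brm(self.data)
        return self._brm_global

    @property
    def brms_per_type(self) -> list[BRM]:
        if self._brms_per_type is None:
            self._brms_per_type = [
                compute_brm(self.data, subset=t, atlas=self.atlas) for t in MEAS_TYPES
            ]
        return self._brms_per_type

    def _covariates_for(self, spec: ModelSpec) -> np.ndarray | None:
        pcs = pcs_pt = None
        if spec.covariate_set in ("pc5_global", "pc10_global"):
            pcs = self.pcs_global
        if spec.covariate_set == "pc10_per_type":
            pcs_pt = self.pcs_per_type
        return assemble_covariates(self.data, spec.covariate_set, pcs, pcs_pt)

    def _glm_cached(self, spec: ModelSpec):
        key = spec.covariate_set
        if key not in self._glm_precomp:
            C = self._covariates_for(spec)
            Z = _design_q(C, self.data.n_subjects)
            Xr, Q = _residualize(Z, self.data.values)
            xtx = np.einsum("ij,ij->j", Xr, Xr)
            self._glm_precomp[key] = (Q, Xr, xtx)
        return self._glm_precomp[key]

    # -- running traits -----------------------------------------------------

    def fit_null_model(self, y, spec: ModelSpec) -> VarianceComponents:
        """REML variance components for one LMM configuration."""
        C = self._covariates_for(spec)
        brms = (
            [self.brm_global] if spec.brm_structure == "global" else self.brms_per_type
        )
        return fit_reml(y, C, brms, self.reml_options)

    def run_one(self, y, name: str) -> AssocResult:
        spec = MODEL_SPECS[name]
        y = np.asarray(y, dtype=np.float64).ravel()
        n = self.data.n_subjects
        if spec.family == "glm":
            precomp = self._glm_cached(spec)
            b, se, chi2, pval, flagged = _ols_scan(
                self.data.values, y, None, precomp=precomp
            )
            return AssocResult(b, se, chi2, pval, spec, n, name, flagged)
        vc = self.fit_null_model(y, spec)
        brms = (
            [self.brm_global] if spec.brm_structure == "global" else self.brms_per_type
        )
        if np.all(vc.v_components == 0.0):
            precomp = self._glm_cached(ModelSpec("glm", spec.covariate_set))
            b, se, chi2, pval, flagged = _ols_scan(
                self.data.values, y, None, precomp=precomp
            )
            return AssocResult(b, se, chi2, pval, spec, n, name, flagged, vc=vc)
        res = run_lmm(y, self.data, spec, vc, brms, model_name=name)
        return res

    def run(self, y) -> dict[str, AssocResult]:
        """Scan one trait through every configured model (same subjects)."""
        return {name: self.run_one(y, name) for name in self.model_names}


def run_model_suite(
    y,
    data: CohortMatrix,
    atlas: VertexAtlas,
    models: list[str] | None = None,
) -> dict[str, AssocResult]:
    """Run the full model census on one trait (thin one-shot wrapper)."""
    return ModelSuite(data, atlas, models=models).run(y)
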