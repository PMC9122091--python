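"""Restricted maximum likelihood (REML) for BRM variance components.

The model is ``y = Z c + u_1 + ... + u_K + e`` with ``u_k ~ N(0, v_k B_k)``
and ``e ~ N(0, v_e I)``, where each ``B_k`` is a brain-relatedness matrix
with mean diagonal 1.  The component ``v_k`` is therefore directly the
share of phenotypic variance attached to that BRM (``p_k sigma_beta_k^2``
in the marker-effect parameterization), and

    morphometricity = sum_k v_k / (sum_k v_k + v_e).

Estimation uses average-information (AI) REML with an EM fallback whenever
an AI step proposes a negative component; a component whose update is
negative twice in a row is pinned to zero (boundary estimate).  With a
single BRM the problem is rotated into the BRM eigenbasis once, which makes
each iteration O(N q^2) instead of O(N^3); repeated fits on the same cohort
(e.g. 100 simulated traits) then cost almost nothing beyond the initial
eigendecomposition.

Standard errors come from the inverse AI matrix at convergence, with a
delta-method SE for the morphometricity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.linalg.lapack import dpotri
from sklearn.base import BaseEstimator

from .data import MEAS_TYPES, BRM, CohortMatrix, VertexAtlas, compute_brm

__all__ = [
    "REMLOptions",
    "VarianceComponents",
    "fit_reml",
    "reml_loglik",
    "MorphometricityREML",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REMLOptions:
    """Convergence and constraint options for AI-REML.

    ``tol`` is the absolute restricted log-likelihood change declaring
    convergence; ``constraint='truncate_to_zero'`` pins persistently
    negative components to the zero boundary (``'error'`` raises instead);
    ``em_fallback`` replaces negative AI proposals by EM steps (otherwise
    they are floored).
    """

    tol: float = 1e-8
    max_iter: int = 100
    constraint: str = "truncate_to_zero"
    em_fallback: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.constraint not in ("truncate_to_zero", "error"):
            raise ValueError("constraint must be 'truncate_to_zero' or 'error'")


@dataclass
class VarianceComponents:
    """Fitted variance components of a BRM mixed model.

    ``v_components[k]`` is the variance attached to the k-th BRM (on the
    phenotypic scale, i.e. ``p_k sigma_beta_k^2``), ``v_e`` the residual
    variance.  ``se_components`` aligns with ``v_components + [v_e]``;
    boundary (pinned) components have ``nan`` SEs.
    """

    v_components: np.ndarray
    v_e: float
    morphometricity: float
    se_morph: float
    loglik: float
    converged: bool
    n_iter: int
    component_labels: list[str] = field(default_factory=list)
    se_components: np.ndarray | None = None

    @property
    def theta(self) -> np.ndarray:
        return np.append(self.v_components, self.v_e)


# ---------------------------------------------------------------------------
# kernels: how to apply V^{-1} and the covariance structures G_k
# ---------------------------------------------------------------------------


class _DenseKernel:
    """Cholesky-based solves with explicit BRM matrices."""

    def __init__(self, mats: list[np.ndarray]):
        self.mats = mats
        self.n = mats[0].shape[0] if mats else 0

    def set_theta(self, theta: np.ndarray) -> None:
        n = self.n
        V = np.zeros((n, n))
        for t, G in zip(theta[:-1], self.mats):
            if t != 0.0:
                V += t * G
        V[np.diag_indices_from(V)] += theta[-1]
        try:
            self._cho = cho_factor(V, lower=True)
        except LinAlgError:
            # one shot of diagonal jitter before giving up
            V[np.diag_indices_from(V)] += 1e-10 * np.trace(V) / n
            try:
                self._cho = cho_factor(V, lower=True)
            except LinAlgError as err:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"V is not positive definite at components {theta}"
                ) from err
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self._cho[0]))))
        self._vinv = None

    def solve(self, M: np.ndarray) -> np.ndarray:
        return cho_solve(self._cho, M)

    def gmul(self, k: int, M: np.ndarray) -> np.ndarray:
        if k == len(self.mats):
            return M
        return self.mats[k] @ M

    def vinv(self) -> np.ndarray:
        if self._vinv is None:
            tri, info = dpotri(self._cho[0], lower=1)
            if info != 0:  # pragma: no cover - defensive
                raise RuntimeError("dpotri failed")
            # dpotri fills only the lower triangle (upper keeps factor junk)
            low = np.tril(tri)
            self._vinv = low + np.tril(tri, -1).T
        return self._vinv

    def trace_vinv_g(self, k: int) -> float:
        vinv = self.vinv()
        if k == len(self.mats):
            return float(np.trace(vinv))
        return float(np.sum(vinv * self.mats[k]))


class _DiagKernel:
    """Single-BRM model rotated into the BRM eigenbasis (V diagonal)."""

    def __init__(self, d: np.ndarray):
        self.d = np.clip(d, 0.0, None)

    def set_theta(self, theta: np.ndarray) -> None:
        w = theta[0] * self.d + theta[1]
        if np.any(w <= 0):
            raise RuntimeError(f"V is singular at components {theta}")
        self.w = w
        self.logdet = float(np.sum(np.log(w)))

    def solve(self, M: np.ndarray) -> np.ndarray:
        if M.ndim == 1:
            return M / self.w
        return M / self.w[:, None]

    def gmul(self, k: int, M: np.ndarray) -> np.ndarray:
        if k == 1:
            return M
        if M.ndim == 1:
            return self.d * M
        return self.d[:, None] * M

    def trace_vinv_g(self, k: int) -> float:
        if k == 1:
            return float(np.sum(1.0 / self.w))
        return float(np.sum(self.d / self.w))


# ---------------------------------------------------------------------------
# the AI-REML loop
# ---------------------------------------------------------------------------


def _reml_quantities(y, Z, kernel, n_g):
    """Per-iteration quantities at the kernel's current components."""
    n, q = Z.shape
    viy = kernel.solve(y)
    viz = kernel.solve(Z)
    W = Z.T @ viz
    Wc = cho_factor(W)
    logdet_w = 2.0 * float(np.sum(np.log(np.diag(Wc[0]))))
    py = viy - viz @ cho_solve(Wc, Z.T @ viy)
    ypy = float(y @ py)
    ll = -0.5 * (kernel.logdet + logdet_w + ypy + (n - q) * _LOG2PI)

    T = np.column_stack([kernel.gmul(k, py) for k in range(n_g + 1)])
    ypgpy = T.T @ py
    vit = kernel.solve(T)
    pt = vit - viz @ cho_solve(Wc, Z.T @ vit)
    ai = 0.5 * (T.T @ pt)
    tr_pg = np.empty(n_g + 1)
    for k in range(n_g + 1):
        gviz = kernel.gmul(k, viz)
        tr_pg[k] = kernel.trace_vinv_g(k) - float(
            np.trace(cho_solve(Wc, viz.T @ gviz))
        )
    score = -0.5 * (tr_pg - ypgpy)
    return ll, score, ai, ypgpy, tr_pg


def _ai_reml(y, Z, kernel, n_g, opts: REMLOptions):
    n, q = Z.shape
    vy = float(y.var())
    if vy <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vy

    theta = np.full(n_g + 1, vy / (n_g + 1))
    free = np.ones(n_g + 1, dtype=bool)
    negcount = np.zeros(n_g + 1, dtype=int)
    ll_prev = None
    converged = False
    n_iter = 0
    ll = score = ai = ypgpy = tr_pg = None

    for n_iter in range(1, opts.max_iter + 1):
        kernel.set_theta(theta)
        ll, score, ai, ypgpy, tr_pg = _reml_quantities(y, Z, kernel, n_g)
        if ll_prev is not None and abs(ll - ll_prev) < opts.tol:
            converged = True
            break
        ll_prev = ll

        idx = np.flatnonzero(free)
        prop = None
        try:
            delta = np.linalg.solve(ai[np.ix_(idx, idx)], score[idx])
            prop = theta.copy()
            prop[idx] += delta
        except np.linalg.LinAlgError:
            prop = None

        for k in idx:
            cand = prop[k] if prop is not None else -1.0
            if cand >= floor:
                theta[k] = cand
                negcount[k] = 0
                continue
            # negative (or failed) AI proposal for this component
            negcount[k] += 1
            if k < n_g and negcount[k] >= 2:
                if opts.constraint == "error":
                    raise RuntimeError(
                        f"variance component {k} driven negative twice"
                    )
                theta[k] = 0.0
                free[k] = False
                continue
            if opts.em_fallback:
                em = theta[k] + theta[k] ** 2 * (ypgpy[k] - tr_pg[k]) / n
                theta[k] = em if em >= floor else max(theta[k] / 2.0, floor)
            else:
                theta[k] = floor

    # SEs from the inverse AI matrix over free components
    idx = np.flatnonzero(free)
    se = np.full(n_g + 1, np.nan)
    cov_free = None
    if ai is not None and idx.size:
        try:
            cov_free = np.linalg.inv(ai[np.ix_(idx, idx)])
            se[idx] = np.sqrt(np.maximum(np.diag(cov_free), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            cov_free = None

    s = float(theta[:n_g].sum())
    total = s + float(theta[n_g])
    morph = s / total if total > 0 else 0.0

    se_morph = np.nan
    if cov_free is not None:
        grad = np.empty(n_g + 1)
        grad[:n_g] = theta[n_g] / total**2
        grad[n_g] = -s / total**2
        g = grad[idx]
        se_morph = float(np.sqrt(max(g @ cov_free @ g, 0.0)))

    return theta, morph, se_morph, se, float(ll), converged, n_iter


def _design(y, covariates, n):
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match BRM size")
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.hstack([Z, C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate design (with intercept) is rank deficient")
    return y, Z


def fit_reml(
    y,
    covariates,
    brms: BRM | list[BRM],
    options: REMLOptions | None = None,
) -> VarianceComponents:
    """Fit BRM variance components by AI-REML.

    Parameters
    ----------
    y : length-N phenotype (standardized).
    covariates : optional N x q fixed-effect matrix; an intercept is always
        added internally.
    brms : one :class:`~vertexlmm.data.BRM` or a list (e.g. the four
        per-measurement-type BRMs).
    options : :class:`REMLOptions`.

    Returns
    -------
    :class:`VarianceComponents` -- components, morphometricity with its
    delta-method SE, the restricted log-likelihood and convergence state.
    """
    opts = options or REMLOptions()
    brm_list = [brms] if isinstance(brms, BRM) else list(brms)
    if not brm_list:
        raise ValueError("at least one BRM is required")
    n = brm_list[0].n_subjects
    if any(b.n_subjects != n for b in brm_list):
        raise ValueError("all BRMs must share the same subjects")
    y, Z = _design(y, covariates, n)

    if len(brm_list) == 1:
        d, U = brm_list[0].eigendecomposition()
        kernel = _DiagKernel(d)
        theta, morph, se_m, se, ll, conv, it = _ai_reml(
            U.T @ y, U.T @ Z, kernel, 1, opts
        )
    else:
        kernel = _DenseKernel([b.matrix for b in brm_list])
        theta, morph, se_m, se, ll, conv, it = _ai_reml(
            y, Z, kernel, len(brm_list), opts
        )

    return VarianceComponents(
        v_components=theta[:-1],
        v_e=float(theta[-1]),
        morphometricity=float(morph),
        se_morph=se_m,
        loglik=ll,
        converged=conv,
        n_iter=it,
        component_labels=[b.component_label for b in brm_list],
        se_components=se,
    )


def reml_loglik(y, covariates, brms: BRM | list[BRM], components) -> float:
    """Restricted log-likelihood at fixed variance components.

    ``components`` lists the BRM variances followed by the residual
    variance (length ``K + 1``).  Used by grid-search oracles and for
    convergence diagnostics; raises on a singular V.
    """
    brm_list = [brms] if isinstance(brms, BRM) else list(brms)
    theta = np.asarray(components, dtype=np.float64).ravel()
    if theta.shape[0] != len(brm_list) + 1:
        raise ValueError("components must list one variance per BRM plus residual")
    if np.any(theta < 0):
        raise ValueError("components must be non-negative")
    n = brm_list[0].n_subjects
    y, Z = _design(y, covariates, n)
    kernel = _DenseKernel([b.matrix for b in brm_list])
    try:
        kernel.set_theta(theta)
    except RuntimeError as err:
        raise ValueError("V is singular at the supplied components") from err
    n_, q = Z.shape
    viy = kernel.solve(y)
    viz = kernel.solve(Z)
    W = Z.T @ viz
    Wc = cho_factor(W)
    logdet_w = 2.0 * float(np.sum(np.log(np.diag(Wc[0]))))
    py = viy - viz @ cho_solve(Wc, Z.T @ viy)
    return float(
        -0.5 * (kernel.logdet + logdet_w + y @ py + (n_ - q) * _LOG2PI)
    )


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------


class MorphometricityREML(BaseEstimator):
    """Morphometricity estimator (scikit-learn style).

    Fits the BRM mixed model on a standardized vertex matrix and exposes
    the variance components and morphometricity as fitted attributes.

    Parameters
    ----------
    brm_structure : ``'global'`` (one BRM over all vertices) or
        ``'per_type_4'`` (one BRM per measurement type; requires an atlas
        at fit time unless prebuilt BRMs are supplied).
    tol, max_iter, constraint, em_fallback : see :class:`REMLOptions`.
    """

    def __init__(
        self,
        brm_structure: str = "global",
        tol: float = 1e-8,
        max_iter: int = 100,
        constraint: str = "truncate_to_zero",
        em_fallback: bool = True,
    ):
        self.brm_structure = brm_structure
        self.tol = tol
        self.max_iter = max_iter
        self.constraint = constraint
        self.em_fallback = em_fallback

    def _options(self) -> REMLOptions:
        return REMLOptions(
            tol=self.tol,
            max_iter=self.max_iter,
            constraint=self.constraint,
            em_fallback=self.em_fallback,
        )

    def fit(
        self,
        X,
        y,
        covariates=None,
        atlas: VertexAtlas | None = None,
        brms: list[BRM] | None = None,
    ):
        """Fit on ``X`` (standardized CohortMatrix or array) and trait ``y``."""
        if brms is None:
            data = (
                X
                if isinstance(X, CohortMatrix)
                else CohortMatrix(
                    subject_id=[str(i) for i in range(len(y))],
                    values=np.asarray(X, dtype=np.float64),
                    covariates=pd.DataFrame(index=range(len(y))),
                    standardized=True,
                )
            )
            if self.brm_structure == "global":
                brms = [compute_brm(data)]
            elif self.brm_structure == "per_type_4":
                if atlas is None:
                    raise ValueError("per_type_4 requires an atlas or prebuilt BRMs")
                brms = [compute_brm(data, subset=t, atlas=atlas) for t in MEAS_TYPES]
            else:
                raise ValueError(f"unknown brm_structure {self.brm_structure!r}")
        vc = fit_reml(y, covariates, brms, self._options())
        self.result_ = vc
        self.v_components_ = vc.v_components
        self.v_e_ = vc.v_e
        self.morphometricity_ = vc.morphometricity
        self.se_morphometricity_ = vc.se_morph
        self.loglik_ = vc.loglik
        self.converged_ = vc.converged
        self.n_iter_ = vc.n_iter
        return self
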