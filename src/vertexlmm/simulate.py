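"""Synthetic vertexwise cohorts with realistic correlation structure.

The generator emulates the two features of real gray-matter data that drive
false positives in mass-univariate analyses:

* **local spatial correlation** -- each measurement type / hemisphere block
  is a 2-D lattice mesh and the noise field is smoothed over it;
* **long-range and cross-type correlation** -- a small set of latent
  subject-level factors (head-size, demographic and scanner analogs) load
  smoothly but globally on every measurement type.  Some factors are
  exported as observed covariates (age / sex / ICV analogs), the rest stay
  hidden, so covariate-adjusted models remove only part of the confounding.

Each vertex value is ``sqrt(share) * factors . loadings + sqrt(1-share) *
smoothed noise`` with unit-variance pieces, so ``confounder_share`` is the
fraction of per-vertex variance attributable to the latent factors, and the
expected correlation between two vertices loading on the same single factor
equals ``share``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import HEMISPHERES, MEAS_TYPES, CohortMatrix, VertexAtlas

__all__ = [
    "GeneratorConfig",
    "LatentRecord",
    "lattice_edges",
    "build_atlas",
    "generate_cohort",
    "generate_replication",
]

#: default per-hemisphere lattice sizes (rows, cols); two hemispheres per
#: type gives p = 20,000 with a 9:1 cortical:subcortical vertex ratio.
DEFAULT_GRID_DIMS: dict[str, tuple[int, int]] = {
    "ct": (60, 75),
    "ca": (60, 75),
    "st": (20, 25),
    "sa": (20, 25),
}

#: desk-scale presets keeping the 9:1 cortical:subcortical ratio.
_DESK_GRIDS: dict[int, dict[str, tuple[int, int]]] = {
    5000: {"ct": (45, 25), "ca": (45, 25), "st": (5, 25), "sa": (5, 25)},
    10000: {"ct": (45, 50), "ca": (45, 50), "st": (5, 50), "sa": (5, 50)},
    20000: DEFAULT_GRID_DIMS,
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator.

    Parameters
    ----------
    N : number of subjects.
    grid_dims : per-type lattice size (rows, cols); each type gets one such
        lattice per hemisphere.
    K_confounders : number of latent subject factors (default 6).
    confounder_share : fraction of per-vertex variance carried by the latent
        factors (default 0.3); must lie in [0, 1).
    n_observed : how many factors are exported as covariates (default 3,
        labelled age / sex / ICV analogs; the rest stay hidden).
    smooth_rounds : lattice-smoothing rounds applied to the noise field.
    loading_smooth_rounds : smoothing rounds applied to each factor's
        loading map (confounders act regionally, not per-vertex).
    n_noise_covariates : pure-noise covariates added to the covariate table.
    seed : base seed for the single random generator.
    """

    N: int = 1000
    grid_dims: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GRID_DIMS)
    )
    K_confounders: int = 6
    confounder_share: float = 0.3
    n_observed: int = 3
    smooth_rounds: int = 2
    loading_smooth_rounds: int = 4
    n_noise_covariates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confounder_share < 1.0:
            raise ValueError("confounder_share must be in [0, 1)")
        for t, (r, c) in self.grid_dims.items():
            if r < 2 or c < 2:
                raise ValueError(f"grid for {t!r} must be at least 2x2")
        if self.n_observed > self.K_confounders:
            raise ValueError("n_observed cannot exceed K_confounders")

    @property
    def n_vertices(self) -> int:
        return 2 * sum(r * c for r, c in self.grid_dims.values())

    @classmethod
    def desk(cls, N: int = 1000, p: int = 5000, **kwargs) -> "GeneratorConfig":
        """Desk-scale preset (p in {5000, 10000, 20000}, ratio 9:1)."""
        if p not in _DESK_GRIDS:
            raise ValueError(f"no desk preset for p={p}")
        return cls(N=N, grid_dims=dict(_DESK_GRIDS[p]), **kwargs)


@dataclass
class LatentRecord:
    """Ground truth of the latent confounder structure.

    ``factor_values`` (N x K) are subject scores, ``loadings`` (p x K) the
    spatially smooth vertex weights (rows unit norm), ``observed_mask``
    marks factors exported as covariates.  Replication cohorts reuse the
    loadings with fresh factor values and noise.
    """

    factor_values: np.ndarray
    loadings: np.ndarray
    observed_mask: np.ndarray


def lattice_edges(n_rows: int, n_cols: int, offset: int = 0) -> np.ndarray:
    """4-neighbor edges of an ``n_rows x n_cols`` lattice, ids offset."""
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    return np.vstack([horiz, vert]) + offset


def build_atlas(config: GeneratorConfig) -> VertexAtlas:
    """Deterministic lattice atlas: one grid per (type, hemisphere)."""
    rows = []
    edges = []
    structure = 0
    offset = 0
    for t in MEAS_TYPES:
        r, c = config.grid_dims[t]
        for hemi in HEMISPHERES:
            n = r * c
            rows.append(
                pd.DataFrame(
                    {
                        "vertex_id": np.arange(offset, offset + n),
                        "meas_type": t,
                        "hemisphere": hemi,
                        "structure_id": structure,
                    }
                )
            )
            edges.append(lattice_edges(r, c, offset=offset))
            structure += 1
            offset += n
    atlas = VertexAtlas(table=pd.concat(rows, ignore_index=True), edges=np.vstack(edges))
    atlas.validate()
    return atlas


def _smooth_columns(M: np.ndarray, smoother, rounds: int) -> np.ndarray:
    for _ in range(rounds):
        M = smoother @ M
    return M


_OBSERVED_NAMES = ("age", "sex", "icv")


def generate_cohort(
    config: GeneratorConfig,
    latent: LatentRecord | None = None,
    seed: int | None = None,
    subject_prefix: str = "S",
    factor_mean_shift: float = 0.0,
) -> tuple[CohortMatrix, LatentRecord]:
    """Generate a raw (unstandardized) cohort and its latent record.

    When ``latent`` is supplied its loadings and observed mask are reused
    (replication design); otherwise fresh smooth loading maps are drawn.
    The covariate table holds the observed factors (the second one
    dichotomized at its median as the sex analog) plus pure-noise columns.
    """
    atlas = build_atlas(config)
    p = atlas.n_vertices
    n = config.N
    k = config.K_confounders
    share = config.confounder_share
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s_op = atlas.smoothing_operator()

    if latent is None:
        raw_load = rng.standard_normal((p, k))
        load = _smooth_columns(raw_load, s_op, config.loading_smooth_rounds)
        norms = np.linalg.norm(load, axis=1, keepdims=True)
        load = load / np.maximum(norms, np.finfo(float).tiny)
        observed_mask = np.arange(k) < config.n_observed
    else:
        load = latent.loadings
        observed_mask = latent.observed_mask
        if load.shape != (p, k):
            raise ValueError("latent loadings do not match the configured atlas")

    factors = rng.standard_normal((n, k))
    if factor_mean_shift:
        factors[:, observed_mask] += factor_mean_shift

    noise = rng.standard_normal((n, p))
    st = s_op.T.tocsr()
    for _ in range(config.smooth_rounds):
        noise = noise @ st
    sd = noise.std(axis=0)
    noise = noise / np.maximum(sd, np.finfo(float).tiny)

    values = np.sqrt(share) * (factors @ load.T) + np.sqrt(1.0 - share) * noise

    cov = {}
    obs_idx = np.flatnonzero(observed_mask)
    for j, fi in enumerate(obs_idx):
        name = _OBSERVED_NAMES[j] if j < len(_OBSERVED_NAMES) else f"factor{fi}"
        col = factors[:, fi].copy()
        if name == "sex":
            col = (col > np.median(col)).astype(np.float64)
        cov[name] = col
    noise_cov = rng.standard_normal((n, config.n_noise_covariates))
    for j in range(config.n_noise_covariates):
        cov[f"noise{j + 1}"] = noise_cov[:, j]

    data = CohortMatrix(
        subject_id=[f"{subject_prefix}{i:06d}" for i in range(n)],
        values=values,
        covariates=pd.DataFrame(cov),
    )
    return data, LatentRecord(factors, load, observed_mask)


def generate_replication(
    config: GeneratorConfig,
    latent: LatentRecord,
    seed: int,
    N: int | None = None,
    factor_mean_shift: float = 0.0,
) -> CohortMatrix:
    """New subjects with the same latent loading structure.

    ``factor_mean_shift`` offsets the observed-factor means, emulating a
    transfer cohort drawn from a shifted population.  Standardization
    statistics are never shared with the training cohort -- the returned
    cohort is raw.
    """
    cfg = replace(config, N=config.N if N is None else N)
    data, _ = generate_cohort(
        cfg,
        latent=latent,
        seed=seed,
        subject_prefix="R",
        factor_mean_shift=factor_mean_shift,
    )
    return data
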