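"""Phenotype simulation from vertexwise data under H0 and H1.

Traits are linear combinations of a randomly drawn causal vertex set plus
Gaussian noise, scaled so the vertexwise measurements account for a target
share of phenotypic variance (the trait's *morphometricity*).  The three
standard alternative-hypothesis scenarios are

* (i)   10 causal vertices, morphometricity R^2 = 0.20,
* (ii)  100 causal vertices, R^2 = 0.50,
* (iii) 1000 causal vertices, R^2 = 0.40,

each usually replicated 100 times, plus 100 null traits (pure noise) and
variants restricting the causal set to a single measurement type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MEAS_TYPES, CohortMatrix, VertexAtlas

__all__ = [
    "TraitSpec",
    "SimulatedTrait",
    "SCENARIOS",
    "simulate_trait",
    "simulate_null",
    "scenario_grid",
]

#: (m_causal, target_r2) of the three H1 scenarios.
SCENARIOS: dict[str, tuple[int, float]] = {
    "i": (10, 0.20),
    "ii": (100, 0.50),
    "iii": (1000, 0.40),
}


@dataclass(frozen=True)
class TraitSpec:
    """Specification of one simulated trait.

    ``m_causal`` vertices are drawn uniformly without replacement from the
    eligible set (all vertices, or one measurement type when
    ``type_restriction`` is set); their effects are standard normal.  With
    ``exact_rescale`` (default) the noise is orthogonalized and scaled so
    the realized sample-level variance share equals ``target_r2`` exactly;
    otherwise the noise variance is drawn at its theoretical value
    ``var(g) (1 - R^2) / R^2``.
    """

    m_causal: int
    target_r2: float
    type_restriction: str | None = None
    seed: int = 0
    exact_rescale: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_r2 <= 1.0:
            raise ValueError("target_r2 must be in [0, 1]")
        if self.m_causal < 0:
            raise ValueError("m_causal must be non-negative")
        if self.type_restriction is not None and self.type_restriction not in MEAS_TYPES:
            raise ValueError(f"unknown measurement type {self.type_restriction!r}")


@dataclass
class SimulatedTrait:
    """A simulated phenotype with its ground truth.

    ``y`` is standardized (mean 0, variance 1, denominator N);
    ``causal_ids`` and ``effects`` define the generating linear signal;
    ``realized_r2`` is the sample-level variance share of that signal.
    """

    y: np.ndarray
    causal_ids: np.ndarray
    effects: np.ndarray
    realized_r2: float


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd <= 0:
        raise ValueError("cannot standardize a constant vector")
    return v / sd


def simulate_trait(
    data: CohortMatrix,
    spec: TraitSpec,
    atlas: VertexAtlas | None = None,
) -> SimulatedTrait:
    """Simulate one H1 trait from standardized vertex data.

    The genetic-style signal is ``g = X[:, causal] @ effects``; noise is
    added so that the variance share of ``g`` in ``y`` equals
    ``spec.target_r2`` (exactly under ``exact_rescale``, in expectation
    otherwise), and ``y`` is standardized.
    """
    if not data.standardized:
        raise ValueError("simulate_trait requires standardized data")
    if spec.m_causal == 0 or spec.target_r2 == 0.0:
        raise ValueError(
            "a trait with no causal signal is a null trait; use simulate_null"
        )
    if spec.type_restriction is not None:
        if atlas is None:
            raise ValueError("type_restriction requires an atlas")
        eligible = atlas.vertex_ids_of_type(spec.type_restriction)
    else:
        eligible = np.arange(data.n_vertices)
    if spec.m_causal > eligible.size:
        raise ValueError(
            f"m_causal={spec.m_causal} exceeds {eligible.size} eligible vertices"
        )

    rng = np.random.default_rng(spec.seed)
    causal = np.sort(rng.choice(eligible, size=spec.m_causal, replace=False))
    effects = rng.standard_normal(spec.m_causal)
    g = data.values[:, causal] @ effects
    g_std = _standardize(g)

    r2 = spec.target_r2
    if r2 == 1.0:
        return SimulatedTrait(g_std, causal, effects, 1.0)

    e = rng.standard_normal(data.n_subjects)
    if spec.exact_rescale:
        # orthogonalize the noise against the signal so the sample-level
        # variance split is exact
        e = e - e.mean()
        e = e - (e @ g_std) / (g_std @ g_std) * g_std
        e_std = _standardize(e)
        y = np.sqrt(r2) * g_std + np.sqrt(1.0 - r2) * e_std
        realized = r2
    else:
        noise_sd = np.sqrt(g.var() * (1.0 - r2) / r2)
        y_raw = g + noise_sd * e
        realized = float(np.corrcoef(y_raw, g)[0, 1] ** 2)
        y = _standardize(y_raw)
    return SimulatedTrait(y, causal, effects, float(realized))


def simulate_null(N: int, seed: int = 0) -> SimulatedTrait:
    """A null trait: standard normal, standardized, no causal vertices."""
    if N < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    y = _standardize(rng.standard_normal(N))
    return SimulatedTrait(
        y, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64), 0.0
    )


def scenario_grid(
    n_replicates: int = 100,
    base_seed: int = 0,
    include_per_type: bool = True,
) -> list[tuple[str, TraitSpec | None]]:
    """The full simulation grid as (label, spec) pairs.

    Labels are ``"i"``, ``"ii"``, ``"iii"`` for the three H1 scenarios,
    ``"<scenario>:<type>"`` for the per-type restricted variants, and
    ``"null"`` with spec ``None`` for the null traits (simulate those with
    :func:`simulate_null`).  Replicate ``r`` of grid row ``s`` uses seed
    ``base_seed + 1000 * s + r``.
    """
    grid: list[tuple[str, TraitSpec | None]] = []
    row = 0

    def seeds():
        nonlocal row
        out = [base_seed + 1000 * row + r for r in range(n_replicates)]
        row += 1
        return out

    for label, (m, r2) in SCENARIOS.items():
        for s in seeds():
            grid.append((label, TraitSpec(m, r2, seed=s)))
    for s in seeds():
        grid.append(("null", None))
    if include_per_type:
        for label, (m, r2) in SCENARIOS.items():
            for t in MEAS_TYPES:
                for s in seeds():
                    grid.append(
                        (f"{label}:{t}", TraitSpec(m, r2, type_restriction=t, seed=s))
                    )
    return grid
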