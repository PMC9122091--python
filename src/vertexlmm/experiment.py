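"""Orchestration of the simulation studies.

``run_experiment`` executes a scenario grid x model census x replicates
design with deterministic seeding, per-replicate caching (resumable runs)
and a tabular summary (one row per scenario x model with every evaluation
metric).  The module also exposes three self-contained desk-scale studies
used for calibration and benchmarking:

* :func:`h0_calibration_study` -- null traits through the full model
  census: inflation factor, nominal FPR, vertex FWER;
* :func:`morphometricity_recovery_study` -- REML recovery of the simulated
  morphometricity under scenarios (i) and (ii);
* :func:`glm_lmm_contrast_study` -- the headline GLM-vs-LMM contrast on
  confounded data under scenario (ii): null-vertex FPR and pooled cluster
  FDR per model.

Desk-scale defaults (N=1000, p=5000 or N=2000, p=10000) keep each study in
the minutes range on one CPU; the full-cohort setting (N~10^4, p~6.5x10^5)
is cluster-scale and deliberately not a default.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import DEFAULT_MODEL_NAMES, ModelSuite
from .clusters import (
    MetricsReport,
    bonferroni_alpha,
    replicate_metrics,
    threshold_and_cluster,
)
from .data import compute_brm, standardize_columns
from .predict import build_predictor, evaluate_prediction, score_cohort
from .reml import fit_reml
from .simulate import GeneratorConfig, build_atlas, generate_cohort, generate_replication
from .traits import SCENARIOS, TraitSpec, simulate_null, simulate_trait

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "h0_suite",
    "h0_calibration_study",
    "morphometricity_recovery_study",
    "glm_lmm_contrast_study",
]

log = logging.getLogger("vertexlmm")


@dataclass
class ExperimentConfig:
    """Declarative configuration of one simulation experiment.

    ``scenarios`` maps a label to ``(m_causal, target_r2)`` (or to ``None``
    for null traits); replicate ``r`` of a scenario uses trait seed
    ``base_seed + 1000 * scenario_index + r``.  ``alpha=None`` means the
    Bonferroni threshold for the cohort's vertex count.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scenarios: dict = field(default_factory=lambda: {"i": SCENARIOS["i"]})
    replicates: int = 10
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODEL_NAMES))
    alpha: float | None = None
    target_cfwer: float = 0.2
    output_dir: str | None = None
    base_seed: int = 0
    with_replication: bool = False
    replication_N: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.models:
            raise ValueError("need at least one model")


def _prepare_cohort(cfg: ExperimentConfig):
    raw, latent = generate_cohort(cfg.generator, seed=cfg.generator.seed)
    atlas = build_atlas(cfg.generator)
    data = standardize_columns(raw)
    return data, atlas, latent


def _trait_for(cfg: ExperimentConfig, data, atlas, label, s_idx, r):
    seed = cfg.base_seed + 1000 * s_idx + r
    scen = cfg.scenarios[label]
    if scen is None:
        return simulate_null(data.n_subjects, seed=seed)
    m, r2 = scen
    return simulate_trait(data, TraitSpec(m, r2, seed=seed), atlas)


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full design and return the summary table.

    One summary row per (scenario, model) with the aggregated
    :class:`~vertexlmm.clusters.MetricsReport` fields, plus out-of-sample
    prediction accuracy on a matched replication cohort when
    ``with_replication`` is set.  Per-replicate records are cached as JSON
    under ``output_dir`` and reused on reruns (resumability); reruns with
    an identical config yield byte-identical summaries.
    """
    data, atlas, latent = _prepare_cohort(cfg)
    suite = ModelSuite(data, atlas, models=cfg.models)
    alpha = cfg.alpha if cfg.alpha is not None else bonferroni_alpha(data.n_vertices)

    repl = None
    if cfg.with_replication:
        raw_repl = generate_replication(
            cfg.generator,
            latent,
            seed=cfg.generator.seed + 777_000,
            N=cfg.replication_N,
        )
        repl = raw_repl  # scored on the frozen training scale; kept raw

    cache_dir = None
    if cfg.output_dir:
        cache_dir = os.path.join(cfg.output_dir, "replicates")
        os.makedirs(cache_dir, exist_ok=True)

    records: dict[tuple[str, str], list] = {
        (lab, m): [] for lab in cfg.scenarios for m in cfg.models
    }
    pred_acc: dict[tuple[str, str], list] = {k: [] for k in records}

    for s_idx, label in enumerate(cfg.scenarios):
        for r in range(cfg.replicates):
            cache_path = (
                os.path.join(cache_dir, f"{label}_{r}.json") if cache_dir else None
            )
            if cache_path and os.path.exists(cache_path):
                with open(cache_path) as f:
                    stored = json.load(f)
                log.info("scenario %s replicate %d: cache hit", label, r)
            else:
                stored = _run_replicate(
                    cfg, suite, data, atlas, repl, label, s_idx, r, alpha
                )
                if cache_path:
                    with open(cache_path, "w") as f:
                        json.dump(stored, f)
            for m in cfg.models:
                rec = stored["models"][m]
                records[(label, m)].append(rec)
                if rec.get("pred_r") is not None:
                    pred_acc[(label, m)].append(rec["pred_r"])

    rows = []
    for (label, m), recs in records.items():
        row = _aggregate(recs, alpha)
        row.update(scenario=label, model=m)
        accs = pred_acc[(label, m)]
        row["pred_r_mean"] = float(np.mean(accs)) if accs else float("nan")
        rows.append(row)
    summary = pd.DataFrame(rows)
    lead = ["scenario", "model"]
    summary = summary[lead + [c for c in summary.columns if c not in lead]]
    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        summary.to_csv(
            os.path.join(cfg.output_dir, "summary.tsv"),
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    return summary


def _run_replicate(cfg, suite, data, atlas, repl, label, s_idx, r, alpha) -> dict:
    trait = _trait_for(cfg, data, atlas, label, s_idx, r)
    results = suite.run(trait.y)
    out = {"models": {}}
    for m, res in results.items():
        truth = trait.causal_ids
        is_null = np.ones(len(res), dtype=bool)
        is_null[truth] = False
        cs = threshold_and_cluster(res, atlas, alpha, truth)
        sig = np.flatnonzero(res.pval < alpha)
        rec = {
            "truth": truth.tolist(),
            "median_null_chi2": float(np.median(res.chi2[is_null])),
            "fpr": float(np.mean(res.pval[is_null] < 0.05)),
            "tpr": float(np.mean(res.pval[truth] < alpha)) if truth.size else None,
            "sig_vertices": sig.tolist(),
            "sig_pvals": res.pval[sig].tolist(),
            "n_fp_clusters": cs.n_fp,
            "n_clusters": len(cs),
            "tp_sizes": cs.tp_sizes(),
            "fp_vertex": bool(np.any(is_null & (res.pval < alpha))),
            "pred_r": None,
        }
        if repl is not None and len(cs):
            pred = build_predictor(res, cs, data, mode="top_per_cluster")
            scores = score_cohort(pred, repl)
            # the replication trait: same causal effects on the new subjects
            if truth.size:
                repl_std = (repl.values - data.col_means) / data.col_sds
                g = repl_std[:, truth] @ trait.effects
                if g.std() > 0 and scores.std() > 0:
                    rec["pred_r"] = evaluate_prediction(scores, g)["r"]
        out["models"][m] = rec
    return out


def _aggregate(recs: list[dict], alpha: float) -> dict:
    n = len(recs)
    n_fp = sum(r["n_fp_clusters"] for r in recs)
    n_all = sum(r["n_clusters"] for r in recs)
    tp_sizes = [s for r in recs for s in r["tp_sizes"]]
    tprs = [r["tpr"] for r in recs if r["tpr"] is not None]
    return {
        "lambda": float(np.mean([r["median_null_chi2"] for r in recs]))
        / 0.45493642311957174,
        "fpr_nominal": float(np.mean([r["fpr"] for r in recs])),
        "tpr": float(np.mean(tprs)) if tprs else float("nan"),
        "fwer_vertex": sum(r["fp_vertex"] for r in recs) / n,
        "fwer_cluster": sum(r["n_fp_clusters"] > 0 for r in recs) / n,
        "fdr_cluster": (n_fp / n_all) if n_all else float("nan"),
        "precision_median": float(np.median(tp_sizes)) if tp_sizes else float("nan"),
        "precision_max": float(np.max(tp_sizes)) if tp_sizes else float("nan"),
        "alpha": alpha,
        "n_replicates": n,
    }


def h0_suite(cfg: ExperimentConfig) -> dict[str, MetricsReport]:
    """Null-trait calibration: one MetricsReport per model."""
    data, atlas, _ = _prepare_cohort(cfg)
    suite = ModelSuite(data, atlas, models=cfg.models)
    alpha = cfg.alpha if cfg.alpha is not None else bonferroni_alpha(data.n_vertices)
    per_model: dict[str, list] = {m: [] for m in cfg.models}
    for r in range(cfg.replicates):
        trait = simulate_null(data.n_subjects, seed=cfg.base_seed + r)
        for m, res in suite.run(trait.y).items():
            cs = threshold_and_cluster(res, atlas, alpha, trait.causal_ids)
            per_model[m].append((res, cs, trait.causal_ids))
    return {
        m: replicate_metrics(reps, alpha, atlas) for m, reps in per_model.items()
    }


# ---------------------------------------------------------------------------
# named desk-scale studies
# ---------------------------------------------------------------------------


def h0_calibration_study(
    seed: int = 1,
    n_traits: int = 100,
    N: int = 1000,
    p: int = 5000,
    confounder_share: float = 0.3,
    models: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Null-hypothesis calibration of every model on a confounded cohort.

    Generates one cohort, simulates ``n_traits`` null traits, scans each
    through the model census, and returns a per-model table with columns
    ``fwer`` (vertex FWER at the Bonferroni threshold), ``fpr`` (mean share
    of vertices with p < 0.05) and ``lambda`` (mean inflation factor).
    """
    cfg = GeneratorConfig.desk(N=N, p=p, confounder_share=confounder_share, seed=seed)
    raw, _ = generate_cohort(cfg)
    atlas = build_atlas(cfg)
    data = standardize_columns(raw)
    suite = ModelSuite(data, atlas, models=list(models) if models else None)
    alpha = bonferroni_alpha(data.n_vertices)

    names = suite.model_names
    hits = {m: 0 for m in names}
    fpr = {m: [] for m in names}
    lam = {m: [] for m in names}
    for r in range(1, n_traits + 1):
        y = simulate_null(N, seed=100_000 * seed + r).y
        for m, res in suite.run(y).items():
            if np.any(res.pval < alpha):
                hits[m] += 1
            fpr[m].append(float(np.mean(res.pval < 0.05)))
            lam[m].append(float(np.median(res.chi2)) / 0.45493642311957174)
        log.info("h0 calibration: trait %d/%d done", r, n_traits)
    return pd.DataFrame(
        {
            "fwer": [hits[m] / n_traits for m in names],
            "fpr": [float(np.mean(fpr[m])) for m in names],
            "lambda": [float(np.mean(lam[m])) for m in names],
        },
        index=pd.Index(names, name="model"),
    )


def morphometricity_recovery_study(
    seed: int = 2,
    n_traits: int = 20,
    N: int = 2000,
    p: int = 10000,
    confounder_share: float = 0.3,
    scenarios: Sequence[str] = ("i", "ii"),
) -> pd.DataFrame:
    """REML recovery of the simulated morphometricity.

    For each scenario, simulates ``n_traits`` exact-rescale traits and fits
    the single-global-BRM REML; returns per-scenario mean and SD of the
    morphometricity estimates next to the simulated target.
    """
    cfg = GeneratorConfig.desk(N=N, p=p, confounder_share=confounder_share, seed=seed)
    raw, _ = generate_cohort(cfg)
    atlas = build_atlas(cfg)
    data = standardize_columns(raw)
    brm = compute_brm(data)
    brm.eigendecomposition()

    rows = []
    for s_idx, label in enumerate(scenarios):
        m, r2 = SCENARIOS[label]
        ests = []
        for r in range(1, n_traits + 1):
            spec = TraitSpec(m, r2, seed=100_000 * seed + 1000 * s_idx + r)
            trait = simulate_trait(data, spec, atlas)
            vc = fit_reml(trait.y, None, [brm])
            ests.append(vc.morphometricity)
        rows.append(
            {
                "scenario": label,
                "m_causal": m,
                "target_r2": r2,
                "mean_estimate": float(np.mean(ests)),
                "sd_estimate": float(np.std(ests, ddof=1)),
                "n_traits": n_traits,
            }
        )
        log.info("recovery: scenario %s done", label)
    return pd.DataFrame(rows).set_index("scenario")


def glm_lmm_contrast_study(
    seed: int = 3,
    n_replicates: int = 50,
    N: int = 1000,
    p: int = 5000,
    confounder_share: float = 0.3,
    scenario: str = "ii",
    models: Sequence[str] = ("glm_no_covariates", "glm_age_sex_icv", "lmm_global"),
) -> pd.DataFrame:
    """The headline contrast: GLM inflation vs LMM parsimony under H1.

    Simulates ``n_replicates`` scenario traits on a confounded cohort and
    reports, per model: mean null-vertex FPR, mean TPR, vertex/cluster
    FWER, pooled cluster FDR and mapping precision at the Bonferroni
    threshold.
    """
    cfg = GeneratorConfig.desk(N=N, p=p, confounder_share=confounder_share, seed=seed)
    raw, _ = generate_cohort(cfg)
    atlas = build_atlas(cfg)
    data = standardize_columns(raw)
    suite = ModelSuite(data, atlas, models=list(models))
    alpha = bonferroni_alpha(data.n_vertices)
    m_causal, r2 = SCENARIOS[scenario]

    per_model: dict[str, list] = {m: [] for m in suite.model_names}
    for r in range(1, n_replicates + 1):
        spec = TraitSpec(m_causal, r2, seed=100_000 * seed + r)
        trait = simulate_trait(data, spec, atlas)
        for m, res in suite.run(trait.y).items():
            cs = threshold_and_cluster(res, atlas, alpha, trait.causal_ids)
            per_model[m].append((res, cs, trait.causal_ids))
        log.info("contrast: replicate %d/%d done", r, n_replicates)

    rows = []
    for m, reps in per_model.items():
        rep = replicate_metrics(reps, alpha, atlas)
        rows.append(
            {
                "model": m,
                "fpr_null": rep.fpr_nominal,
                "lambda": rep.lambda_,
                "tpr": rep.tpr,
                "fwer_vertex": rep.fwer_vertex,
                "fwer_cluster": rep.fwer_cluster,
                "fdr_cluster": rep.fdr_cluster,
                "precision_median": rep.precision_median,
                "n_replicates": rep.n_replicates,
            }
        )
    return pd.DataFrame(rows).set_index("model")
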