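"""End-to-end orchestration of the D-P analysis on in-memory data.

This module wires the stages together (atlas -> developmental matrix,
annotations -> NMF phenotypic space, similarity profiles, classification,
pleiotropy, mediators) and, for synthetic datasets, scores how well the
planted ground truth is recovered.  The CLI, the test suite, and the
reproduction script all call through here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

from . import atlas_space, mediator_analysis, phenotype_space, pleiotropy_analysis, similarity_rule
from .synthetic_data import GeneratorConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticRunResult",
    "run_synthetic_analysis",
    "module_component_map",
    "balanced_accuracy",
]


@dataclass
class SyntheticRunResult:
    """All artifacts of one synthetic end-to-end run plus recovery metrics."""

    dataset: SyntheticDataset
    active: sp.csr_matrix
    dev: atlas_space.DevelopmentalMatrix
    stage_prof: pd.DataFrame
    model: phenotype_space.NMFModel
    profiles: pd.DataFrame
    pleiotropy: phenotype_space.PleiotropyResult
    mediator: mediator_analysis.MediatorResult | None
    module_to_component: dict
    metrics: dict = field(default_factory=dict)


def module_component_map(model: phenotype_space.NMFModel, module_map: Mapping) -> dict:
    """One-to-one matching of planted phenotype modules to NMF components.

    Components are matched to modules by maximizing the total H mass each
    component places on the module's terms (Hungarian assignment), since NMF
    component indices are arbitrary.
    """
    comp_labels = list(model.H.index)
    modules = sorted(module_map)
    score = np.zeros((len(modules), len(comp_labels)))
    H = model.H
    row_mass = H.values.sum(axis=1)
    row_mass[row_mass == 0] = 1.0
    for i, m in enumerate(modules):
        cols = [t for t in module_map[m] if t in H.columns]
        if cols:
            score[i] = H[cols].values.sum(axis=1) / row_mass
    rows, cols = linear_sum_assignment(-score)
    return {modules[i]: comp_labels[j] for i, j in zip(rows, cols)}


def balanced_accuracy(
    truth: pd.Series, predicted: Sequence, classes: Sequence[str] = ("D-P", "D-p", "d-P")
) -> float:
    """Mean per-class recall of the planted rule classes."""
    predicted = pd.Series(predicted, index=truth.index)
    recalls = []
    for cls in classes:
        mask = truth == cls
        if mask.sum() == 0:
            continue
        recalls.append(float((predicted[mask] == cls).mean()))
    return float(np.mean(recalls)) if recalls else float("nan")


def run_synthetic_analysis(
    config: GeneratorConfig | None = None,
    *,
    min_count: int = 1,
    min_cells: int = 1,
    nmf_restarts: int = 5,
    span: float = 0.3,
    simD_hi_pct: float = 70.0,
    simD_lo_pct: float = 30.0,
    resid_pct: float = 20.0,
    upper_pct: float = 95.0,
    lower_pct: float = 5.0,
    mediator_min_cells: int = 50,
    alpha: float = 1e-4,
    run_mediator: bool = True,
) -> SyntheticRunResult:
    """Generate a synthetic dataset, run the full analysis, score recovery.

    The NMF rank equals the number of planted phenotype modules so components
    are identifiable; all randomness descends from ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    ds = generate_dataset(cfg)

    active = atlas_space.binarize_activity(ds.atlas, min_count)
    coords = atlas_space.assign_coordinates(ds.atlas, cfg.stage_edges)
    dev = atlas_space.build_developmental_matrix(
        active, coords, min_cells=min_cells, gene_ids=ds.atlas.gene_ids
    )
    stage_prof = atlas_space.stage_profile(dev)

    closed = phenotype_space.ancestor_closure(ds.ontology, ds.annotations)
    model = phenotype_space.factorize(
        closed, k=cfg.n_phenotype_modules, seed=cfg.seed, n_restarts=nmf_restarts
    )
    profiles = similarity_rule.compute_profiles(
        dev.to_frame(), model.W,
        span=span, simD_hi_pct=simD_hi_pct, simD_lo_pct=simD_lo_pct, resid_pct=resid_pct,
    )
    pleio = phenotype_space.pleiotropy_scores(model, upper_pct=upper_pct, lower_pct=lower_pct)
    mod2comp = module_component_map(model, ds.module_map)

    mediator = None
    if run_mediator:
        # align gene columns of the activity matrix with the NMF gene rows
        gene_pos = pd.Index(ds.atlas.gene_ids).get_indexer(model.gene_ids)
        mediator = mediator_analysis.mediator_scan(
            active[:, gene_pos], model, ds.atlas.cell_type,
            min_cells=mediator_min_cells, alpha=alpha,
        )

    metrics = _score_recovery(ds, profiles, pleio, mediator, mod2comp, alpha)
    return SyntheticRunResult(
        dataset=ds,
        active=active,
        dev=dev,
        stage_prof=stage_prof,
        model=model,
        profiles=profiles,
        pleiotropy=pleio,
        mediator=mediator,
        module_to_component=mod2comp,
        metrics=metrics,
    )


def _score_recovery(
    ds: SyntheticDataset,
    profiles: pd.DataFrame,
    pleio: phenotype_space.PleiotropyResult,
    mediator: mediator_analysis.MediatorResult | None,
    mod2comp: dict,
    alpha: float,
) -> dict:
    truth = ds.truth.classes().loc[profiles.index]
    pred = profiles["rule_class"]

    rho = float(
        spearmanr(profiles["median_simD"], profiles["median_simP"], nan_policy="omit").statistic
    )
    metrics: dict = {
        "n_genes": int(len(profiles)),
        "spearman_simD_simP": rho,
        "balanced_accuracy": balanced_accuracy(truth, pred),
        "recall": {
            cls: float((pred[truth == cls] == cls).mean()) if (truth == cls).any() else float("nan")
            for cls in ("D-P", "D-p", "d-P")
        },
    }

    # pleiotropy ordering across predicted rule classes
    scores = pleio.scores
    medians = {}
    for cls in ("D-P", "D-p", "d-P"):
        genes = pred.index[pred == cls].intersection(scores.index)
        medians[cls] = float(scores.loc[genes].median()) if len(genes) else float("nan")
    metrics["median_pleiotropy_by_class"] = medians
    metrics["pleiotropy_DP_gt_Dp"] = bool(medians["D-P"] > medians["D-p"])

    if mediator is not None:
        hits = []
        for cell_type, module in ds.truth.mediator_pairs:
            comp = mod2comp[module]
            col_ks = mediator.ks_matrix[comp]
            col_p = mediator.p_matrix[comp]
            top_type = col_ks.idxmax()
            hits.append(bool(top_type == cell_type and col_p.loc[cell_type] < alpha))
        metrics["mediator_top_hits"] = hits
        metrics["mediators_recovered"] = bool(all(hits)) if hits else True
    return metrics
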