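"""Pleiotropy in developmental context: breadth, stage usage, coordinate z-scores.

Pleiotropic genes (top percentile of the NMF row-sum score) are profiled
against resampling nulls: the fraction of all sampled cells expressing them
(expression breadth) against means of randomly drawn same-size gene sets, the
earliest stage and range of stages they are expressed in, and per-coordinate
enrichment z-scores against resampled gene sets.  All nulls are plain
resampling without replacement, reproducible from a seed, with the +1
correction on empirical p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde

from .atlas_space import DevelopmentalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "expression_breadth",
    "BreadthResult",
    "breadth_null",
    "stage_usage",
    "CoordinateEnrichment",
    "coordinate_enrichment",
    "pleiotropy_by_class",
]


def expression_breadth(active: sp.spmatrix, gene_ids: Sequence | None = None) -> pd.Series:
    """Fraction of retained cells in which each gene is active.

    Cell type and stage are ignored here: breadth is a single number per gene
    over all cells of the activity matrix.
    """
    active = sp.csr_matrix(active)
    if active.shape[0] < 1:
        raise ValueError("need at least one retained cell")
    # integer count then divide, so a gene active in every cell gets exactly 1.0
    frac = np.asarray((active != 0).sum(axis=0)).ravel() / active.shape[0]
    if gene_ids is None:
        gene_ids = list(range(active.shape[1]))
    return pd.Series(frac, index=list(gene_ids), name="expression_breadth")


@dataclass
class BreadthResult:
    """Observed set means against a resampled expression-breadth null."""

    breadth: pd.Series
    set_means: dict  # set name -> observed mean breadth
    null_means: dict  # set name -> array of B resampled means
    p_upper: dict  # set name -> (1 + #{null >= obs}) / (B + 1)
    p_lower: dict
    set_size: dict
    B: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.set_means:
            null = self.null_means[name]
            rows.append(
                {
                    "set": name,
                    "n": self.set_size[name],
                    "observed_mean": self.set_means[name],
                    "null_mean": float(np.mean(null)),
                    "null_sd": float(np.std(null)),
                    "p_upper": self.p_upper[name],
                    "p_lower": self.p_lower[name],
                }
            )
        return pd.DataFrame(rows).set_index("set")


def breadth_null(
    breadth: pd.Series,
    sets: Mapping[str, Sequence],
    *,
    set_size: int | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> BreadthResult:
    """Compare mean breadth of observed gene sets with resampled nulls.

    For each named set, ``B`` resamples without replacement of ``set_size``
    genes (default: the observed set's own size) from the whole gene list give
    the null distribution of mean breadths.  Empirical p-values use the
    (1 + exceedances) / (B + 1) estimator and so never reach 0.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    values = breadth.values.astype(float)
    n_genes = len(values)
    rng = np.random.default_rng(seed)
    set_means, null_means, p_up, p_lo, sizes = {}, {}, {}, {}, {}
    for name, genes in sets.items():
        genes = list(genes)
        obs = float(breadth.loc[genes].mean())
        size = len(genes) if set_size is None else int(set_size)
        if size > n_genes:
            raise ValueError(f"set_size {size} exceeds number of genes {n_genes}")
        null = np.empty(B)
        for b in range(B):
            null[b] = values[rng.choice(n_genes, size=size, replace=False)].mean()
        set_means[name] = obs
        null_means[name] = null
        # count float round-off ties as exceedances on both tails
        ties = np.isclose(null, obs, rtol=1e-9, atol=1e-12)
        p_up[name] = float((1 + ((null > obs) | ties).sum()) / (B + 1))
        p_lo[name] = float((1 + ((null < obs) | ties).sum()) / (B + 1))
        sizes[name] = size
    return BreadthResult(
        breadth=breadth,
        set_means=set_means,
        null_means=null_means,
        p_upper=p_up,
        p_lower=p_lo,
        set_size=sizes,
        B=B,
        seed=seed,
    )


def stage_usage(stage_profile: pd.DataFrame, min_fraction: float = 0.0) -> pd.DataFrame:
    """Earliest stage of expression and fraction of stages used, per gene.

    A gene counts as expressed at a stage when its stage profile exceeds
    ``min_fraction`` (default: active in at least one cell type there).
    All-zero genes get missing values for both fields.
    """
    prof = stage_profile.values.astype(float)
    n_genes, n_stages = prof.shape
    if n_stages == 0:
        raise ValueError("stage profile has no stage columns")
    with np.errstate(invalid="ignore"):
        act = prof > min_fraction
    any_active = act.any(axis=1)
    onset = np.full(n_genes, np.nan)
    onset[any_active] = act[any_active].argmax(axis=1)
    frac = act.sum(axis=1) / n_stages
    frac = np.where(any_active, frac, np.nan)
    n_silent = int((~any_active).sum())
    if n_silent:
        logger.info("stage_usage: %d genes never expressed (missing onset/fraction)", n_silent)
    return pd.DataFrame(
        {"onset_stage": onset, "stage_fraction": frac}, index=stage_profile.index
    )


@dataclass
class CoordinateEnrichment:
    """Per-coordinate enrichment of a gene set against resampled nulls."""

    table: pd.DataFrame  # coordinate, observed_mean, null_mean, null_sd, z, rank
    top: list  # top_n coordinate labels by z
    B: int
    seed: int


def coordinate_enrichment(
    dev: DevelopmentalMatrix,
    gene_set: Sequence,
    *,
    B: int = 10_000,
    seed: int = 0,
    top_n: int = 100,
) -> CoordinateEnrichment:
    """z-score of a gene set's mean activity fraction at each coordinate.

    The null at every coordinate is the mean activity of ``B`` resampled gene
    sets of the same size; z = (observed - null mean) / null sd, missing where
    the null sd is 0 (logged).  The top ``top_n`` coordinates by z are
    returned, ties broken by coordinate label.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    gene_index = pd.Index(dev.gene_ids)
    pos = gene_index.get_indexer(list(gene_set))
    if (pos < 0).any():
        raise ValueError("gene_set contains genes absent from the developmental matrix")
    values = dev.values
    n_genes = values.shape[0]
    size = len(pos)
    observed = values[pos].mean(axis=0)
    rng = np.random.default_rng(seed)
    sums = np.zeros(values.shape[1])
    sq_sums = np.zeros(values.shape[1])
    chunk = max(1, int(5_000_000 / max(1, size * values.shape[1])))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        idx = np.stack([rng.choice(n_genes, size=size, replace=False) for _ in range(m)])
        means = values[idx].mean(axis=1)  # m x coords
        sums += means.sum(axis=0)
        sq_sums += (means * means).sum(axis=0)
        done += m
    null_mean = sums / B
    null_sd = np.sqrt(np.maximum(sq_sums / B - null_mean**2, 0.0))
    z = np.full_like(observed, np.nan)
    okay = null_sd > 0
    z[okay] = (observed[okay] - null_mean[okay]) / null_sd[okay]
    degenerate_zero = (~okay) & np.isclose(observed, null_mean)
    z[degenerate_zero] = 0.0  # saturated case: observed equals a constant null
    truly_missing = (~okay) & ~degenerate_zero
    if truly_missing.any():
        logger.warning(
            "coordinate_enrichment: %d coordinates with zero null sd", int(truly_missing.sum())
        )
    table = pd.DataFrame(
        {
            "coordinate": dev.labels,
            "observed_mean": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
        }
    )
    order = table.sort_values(["z", "coordinate"], ascending=[False, True], na_position="last")
    ranks = np.empty(len(table), dtype=int)
    ranks[order.index.values] = np.arange(1, len(table) + 1)  # 1 = highest z
    table["rank"] = ranks
    table = table.set_index("coordinate")
    top = order["coordinate"].head(top_n).tolist()
    return CoordinateEnrichment(table=table, top=top, B=B, seed=seed)


def random_set_z_calibration(
    dev: DevelopmentalMatrix,
    set_size: int,
    *,
    n_sets: int = 1000,
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pooled mean and sd of coordinate z-scores over many random gene sets.

    Because a single random set shares one breadth level across every
    coordinate, its z-scores are strongly correlated; the unbiasedness of the
    resampling null is therefore checked pooled over ``n_sets`` independent
    random sets against one size-matched null.  Returns (mean z, sd z), which
    should be close to (0, 1).
    """
    rng = np.random.default_rng(seed)
    values = dev.values
    n_genes = values.shape[0]
    null = np.stack(
        [values[rng.choice(n_genes, size=set_size, replace=False)].mean(axis=0) for _ in range(B)]
    )
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0)
    okay = null_sd > 0
    zs = []
    for _ in range(n_sets):
        obs = values[rng.choice(n_genes, size=set_size, replace=False)].mean(axis=0)
        zs.append((obs[okay] - null_mean[okay]) / null_sd[okay])
    pooled = np.concatenate(zs)
    return float(pooled.mean()), float(pooled.std())


def pleiotropy_by_class(
    scores: pd.Series,
    labels: Mapping | pd.Series,
    classes: Sequence[str] = ("D-P", "D-p", "d-P"),
    grid_size: int = 200,
) -> dict:
    """Median, quartiles, and kernel density of the pleiotropy score per class.

    Classes smaller than 3 (or with zero variance) get summaries only, no
    density curve.
    """
    labels = pd.Series(labels)
    out: dict = {}
    for cls in classes:
        genes = labels.index[labels == cls]
        genes = scores.index.intersection(genes)
        vals = scores.loc[genes].values.astype(float)
        if len(vals) == 0:
            logger.warning("pleiotropy_by_class: class %s is empty", cls)
            out[cls] = None
            continue
        entry = {
            "n": int(len(vals)),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "density": None,
        }
        if len(vals) >= 3 and np.std(vals) > 0:
            kde = gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), grid_size)
            entry["density"] = pd.Series(kde(grid), index=grid)
        out[cls] = entry
    return out
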