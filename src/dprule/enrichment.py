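"""Term enrichment for gene sets: Fisher's exact test with per-namespace FDR.

Any gene set produced along the analysis (rule classes, pleiotropic sets,
mediator-linked genes) can be tested for over-represented ontology terms
against the analysis universe.  Each term gives a 2x2 table (in set and
annotated / in set not annotated / out annotated / out not annotated); the
hypergeometric Fisher p-value for the chosen tail and the table's odds ratio
are reported, with Benjamini-Hochberg adjustment applied independently within
each ontology namespace (e.g., GO aspect).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .phenotype_space import PhenotypeAnnotation

logger = logging.getLogger(__name__)

__all__ = ["fisher_enrichment", "fdr_adjust"]


def fisher_enrichment(
    gene_set: Sequence,
    annotation: PhenotypeAnnotation,
    universe: Sequence | None = None,
    tail: str = "greater",
    namespaces: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fisher's exact test of each term for a gene set within a universe.

    ``universe`` defaults to all annotated genes; the gene set must be a
    subset of it.  Terms with no annotated gene in the universe are skipped
    (counted in the log).  Returns one row per tested term with the 2x2
    counts, odds ratio, and p-value; run :func:`fdr_adjust` to add q-values.
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    frame = annotation.frame
    if universe is None:
        universe = list(frame.index)
    universe = list(dict.fromkeys(universe))
    missing = set(universe) - set(frame.index)
    if missing:
        raise ValueError(f"{len(missing)} universe genes lack annotation rows")
    gene_set = set(gene_set)
    if not gene_set <= set(universe):
        raise ValueError("gene_set must be a subset of the universe")
    sub = frame.loc[universe]
    in_set = sub.index.isin(gene_set)
    n_set = int(in_set.sum())
    n_universe = len(universe)
    ann_in = sub.values[in_set].sum(axis=0)
    ann_tot = sub.values.sum(axis=0)
    skipped = int((ann_tot == 0).sum())
    if skipped:
        logger.info("fisher_enrichment: skipped %d terms with no annotated universe gene", skipped)
    rows = []
    for j, term in enumerate(sub.columns):
        if ann_tot[j] == 0:
            continue
        a = int(ann_in[j])  # in set, annotated
        b = n_set - a  # in set, not annotated
        c = int(ann_tot[j]) - a  # out of set, annotated
        d = n_universe - n_set - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative=tail)
        rows.append(
            {
                "term_id": term,
                "namespace": (namespaces or {}).get(term, "default"),
                "a_in_set": a,
                "b_in_set": b,
                "a_out_set": c,
                "b_out_set": d,
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "p": float(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "namespace", "a_in_set", "b_in_set",
            "a_out_set", "b_out_set", "odds_ratio", "p",
        ],
    )


def fdr_adjust(results: pd.DataFrame, group_by: str = "namespace") -> pd.DataFrame:
    """Benjamini-Hochberg q-values, computed independently per namespace.

    Returns a copy of ``results`` with a ``q`` column; within each namespace
    q is monotone with respect to the p ranking, and q >= p.
    """
    out = results.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(group_by).groups.items():
        p = out.loc[idx, "p"].values
        if len(p):
            out.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
    return out.sort_values(["q", "p", "term_id"]).reset_index(drop=True)
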