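"""The D-P rule: pairwise similarities, trend tests, and rule-class labels.

Each gene gets a developmental vector (activity fractions over coordinates)
and a phenotypic vector (its NMF W row).  Cosine similarity compares genes
within one space; a gene's summary similarity <simD> or <simP> is the median
of its pairwise values against all other genes (the self pair excluded).  The
D-P rule predicts that <simP> increases with <simD>; the package tests it with
a sliding-window trend and a percentile-class contingency matrix, and then
classifies genes by their LOESS residuals into rule-followers (D-P) and the
two deviations: developmental divergence (D-p: broadly expressed, narrow
phenotype) and phenotypic degeneracy (d-P: narrow expression, systemic
phenotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "cosine_similarity",
    "pairwise_similarity",
    "median_similarity",
    "sliding_window_trend",
    "QuintileContingency",
    "quintile_contingency",
    "loess_fit_residuals",
    "classify_rule",
    "compute_profiles",
    "class_barcodes",
]

RULE_CLASSES = ("D-P", "D-p", "d-P", "other")


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """cos(u, v) = u.v / (||u|| ||v||); NaN (logged) for a zero vector.

    Symmetric, and in [0, 1] for non-negative inputs; proportional vectors
    have similarity 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu = np.sqrt(float(u @ u))
    nv = np.sqrt(float(v @ v))
    if nu == 0.0 or nv == 0.0:
        logger.warning("cosine_similarity: zero vector, similarity undefined")
        return float("nan")
    return float(min(1.0, max(-1.0, float(u @ v) / (nu * nv))))


def pairwise_similarity(matrix) -> pd.DataFrame | np.ndarray:
    """All-pairs cosine similarity between the rows of ``matrix``.

    Zero rows yield NaN rows/columns (logged); the diagonal is exactly 1 for
    nonzero rows.  A DataFrame input returns a DataFrame indexed by its rows.
    """
    ids = None
    if isinstance(matrix, pd.DataFrame):
        ids = matrix.index
        matrix = matrix.values
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    norms = np.sqrt((M * M).sum(axis=1))
    zero = norms == 0
    if zero.any():
        logger.warning("pairwise_similarity: %d zero rows set to NaN", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    N = M / safe[:, None]
    S = np.clip(N @ N.T, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S[zero, :] = np.nan
    S[:, zero] = np.nan
    if ids is not None:
        return pd.DataFrame(S, index=ids, columns=ids)
    return S


def median_similarity(sim) -> pd.Series | np.ndarray:
    """Per-gene median of off-diagonal similarities (self pair excluded).

    Missing entries are ignored; a gene whose off-diagonal values are all
    missing gets a missing median.
    """
    ids = None
    if isinstance(sim, pd.DataFrame):
        ids = sim.index
        sim = sim.values
    S = np.array(sim, dtype=float, copy=True)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    np.fill_diagonal(S, np.nan)
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(S, axis=1)
    if ids is not None:
        return pd.Series(med, index=ids)
    return med


def sliding_window_trend(
    median_simD: Sequence[float], median_simP: Sequence[float], window: int = 100
) -> pd.DataFrame:
    """Windowed mean <simD>/<simP> after sorting genes by <simD> ascending.

    Contiguous windows of size ``window`` with step 1; output has
    n - window + 1 rows.  Gene pairs with a missing median are dropped first.
    """
    d = np.asarray(median_simD, dtype=float)
    p = np.asarray(median_simP, dtype=float)
    ok = np.isfinite(d) & np.isfinite(p)
    d, p = d[ok], p[ok]
    n = len(d)
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}]")
    order = np.argsort(d, kind="stable")
    d, p = d[order], p[order]
    kernel = np.ones(window) / window
    return pd.DataFrame(
        {
            "simD_mean": np.convolve(d, kernel, mode="valid"),
            "simP_mean": np.convolve(p, kernel, mode="valid"),
        }
    )


@dataclass
class QuintileContingency:
    """Column-stochastic matrix of phenotypic class given developmental class."""

    matrix: np.ndarray  # rows: phenotypic class, cols: developmental class
    edges: tuple
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = _class_labels(self.edges)
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def _class_labels(edges: Sequence[float]) -> list:
    lo = [0.0, *edges]
    hi = [*edges, 100.0]
    return [f"p{int(a)}-p{int(b)}" for a, b in zip(lo, hi)]


def _percentile_class(x: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    thr = np.nanpercentile(x, list(edges))
    return np.searchsorted(thr, x, side="left")


def quintile_contingency(
    median_simD: Sequence[float],
    median_simP: Sequence[float],
    edges: Sequence[float] = (20, 40, 60, 80),
) -> QuintileContingency:
    """Fraction of each developmental percentile class per phenotypic class.

    Genes are binned independently by their <simD> and <simP> percentile
    classes ("<= 20th percentile", "20th-40th", ...); entry [p, d] is the
    fraction of genes in developmental class d falling in phenotypic class p,
    so every column sums to 1.
    """
    edges = tuple(edges)
    if not edges or any(not (0 < e < 100) for e in edges) or list(edges) != sorted(set(edges)):
        raise ValueError("edges must be strictly ascending percentiles inside (0, 100)")
    d = np.asarray(median_simD, dtype=float)
    p = np.asarray(median_simP, dtype=float)
    ok = np.isfinite(d) & np.isfinite(p)
    d, p = d[ok], p[ok]
    k = len(edges) + 1
    dc = _percentile_class(d, edges)
    pc = _percentile_class(p, edges)
    counts = np.zeros((k, k))
    np.add.at(counts, (pc, dc), 1)
    col = counts.sum(axis=0)
    matrix = np.full_like(counts, np.nan, dtype=float)
    nonempty = col > 0
    matrix[:, nonempty] = counts[:, nonempty] / col[nonempty]
    if (~nonempty).any():
        logger.warning("quintile_contingency: %d empty developmental classes", int((~nonempty).sum()))
    return QuintileContingency(matrix=matrix, edges=edges, counts=counts)


def loess_fit_residuals(
    median_simD: Sequence[float],
    median_simP: Sequence[float],
    span: float = 0.3,
    iterations: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS (local-linear, tricube) fit of <simP> on <simD> and its residuals.

    Returns (fitted, residual) arrays aligned with the input; genes with a
    missing median get NaN in both.  ``iterations`` robustifying passes
    down-weight outliers so the fit tracks the bulk trend.
    """
    d = np.asarray(median_simD, dtype=float)
    p = np.asarray(median_simP, dtype=float)
    ok = np.isfinite(d) & np.isfinite(p)
    n = int(ok.sum())
    if n < 10:
        raise ValueError("need at least 10 genes with non-missing medians")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if span * n < 2:
        raise ValueError(f"span {span} too small: minimum usable span is {2 / n:.4g}")
    fitted = np.full(len(d), np.nan)
    fitted[ok] = sm.nonparametric.lowess(
        p[ok], d[ok], frac=span, it=iterations, return_sorted=False
    )
    residual = p - fitted
    return fitted, residual


def classify_rule(
    median_simD: Sequence[float],
    median_simP: Sequence[float],
    residual: Sequence[float],
    simD_hi_pct: float = 70.0,
    simD_lo_pct: float = 30.0,
    resid_pct: float = 20.0,
) -> np.ndarray:
    """Label genes D-P, D-p, d-P, or other from medians and LOESS residuals.

    - D-P: <simD> and <simP> at/above their ``simD_hi_pct`` percentiles and
      residual inside the central [resid_pct, 100 - resid_pct] band;
    - D-p: <simD> at/above its high percentile, residual below the lower band;
    - d-P: <simD> at/below its ``simD_lo_pct`` percentile, residual above the
      upper band;
    - other: everything else (including genes with missing values, logged).
    """
    if not (0 <= simD_lo_pct < simD_hi_pct <= 100) or not (0 < resid_pct < 50):
        raise ValueError("invalid percentile thresholds")
    d = np.asarray(median_simD, dtype=float)
    p = np.asarray(median_simP, dtype=float)
    r = np.asarray(residual, dtype=float)
    ok = np.isfinite(d) & np.isfinite(p) & np.isfinite(r)
    if (~ok).any():
        logger.info("classify_rule: %d genes with missing values labeled 'other'", int((~ok).sum()))
    d_hi = np.nanpercentile(d[ok], simD_hi_pct)
    d_lo = np.nanpercentile(d[ok], simD_lo_pct)
    p_hi = np.nanpercentile(p[ok], simD_hi_pct)
    r_lo = np.nanpercentile(r[ok], resid_pct)
    r_hi = np.nanpercentile(r[ok], 100 - resid_pct)
    labels = np.full(len(d), "other", dtype=object)
    with np.errstate(invalid="ignore"):
        is_dp_low = ok & (d >= d_hi) & (r < r_lo)
        is_dP = ok & (d <= d_lo) & (r > r_hi)
        is_DP = ok & (d >= d_hi) & (p >= p_hi) & (r >= r_lo) & (r <= r_hi)
    labels[is_DP] = "D-P"
    labels[is_dp_low] = "D-p"
    labels[is_dP] = "d-P"
    for cls in ("D-P", "D-p", "d-P"):
        if not (labels == cls).any():
            logger.warning("classify_rule: class %s is empty", cls)
    return labels


def compute_profiles(
    dev_frame: pd.DataFrame,
    W: pd.DataFrame,
    *,
    span: float = 0.3,
    iterations: int = 2,
    simD_hi_pct: float = 70.0,
    simD_lo_pct: float = 30.0,
    resid_pct: float = 20.0,
) -> pd.DataFrame:
    """Per-gene similarity profile over the genes shared by both spaces.

    Convenience pipeline step: pairwise cosines in each space, median
    similarities, LOESS fit/residual, and rule-class labels, returned as one
    DataFrame (median_simD, median_simP, loess_fit, residual, rule_class).
    """
    common = dev_frame.index.intersection(W.index)
    if len(common) < len(dev_frame.index) or len(common) < len(W.index):
        logger.info(
            "compute_profiles: %d genes in both spaces (%d developmental, %d phenotypic)",
            len(common), len(dev_frame.index), len(W.index),
        )
    if len(common) < 10:
        raise ValueError("fewer than 10 genes shared between the two spaces")
    simD = median_similarity(pairwise_similarity(dev_frame.loc[common]))
    simP = median_similarity(pairwise_similarity(W.loc[common]))
    fit, resid = loess_fit_residuals(simD.values, simP.values, span=span, iterations=iterations)
    labels = classify_rule(
        simD.values, simP.values, resid,
        simD_hi_pct=simD_hi_pct, simD_lo_pct=simD_lo_pct, resid_pct=resid_pct,
    )
    return pd.DataFrame(
        {
            "median_simD": simD,
            "median_simP": simP,
            "loess_fit": fit,
            "residual": resid,
            "rule_class": labels,
        },
        index=common,
    )


def class_barcodes(
    stage_profile: pd.DataFrame,
    W: pd.DataFrame,
    labels: Mapping | pd.Series,
    classes: Sequence[str] = ("D-P", "D-p", "d-P"),
) -> dict:
    """Mean stage profile and mean W row ("barcodes") per rule class.

    Returns {class: {"stage": Series, "component": Series, "n_genes": int}};
    an empty class maps to None (logged).
    """
    labels = pd.Series(labels)
    out: dict = {}
    for cls in classes:
        genes = labels.index[labels == cls]
        stage_genes = stage_profile.index.intersection(genes)
        w_genes = W.index.intersection(genes)
        if len(stage_genes) == 0 and len(w_genes) == 0:
            logger.warning("class_barcodes: class %s has no genes", cls)
            out[cls] = None
            continue
        out[cls] = {
            "stage": stage_profile.loc[stage_genes].mean(axis=0) if len(stage_genes) else None,
            "component": W.loc[w_genes].mean(axis=0) if len(w_genes) else None,
            "n_genes": int(max(len(stage_genes), len(w_genes))),
        }
    return out
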