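"""Cell types as mediators of latent phenotypes.

For one NMF component, every cell gets two numbers: the fraction of analysed
genes it expresses, and the summed W weight of its expressed genes on that
component (optionally divided by the component's total W mass).  Cells with
more expressed genes carry more component weight, so an ordinary least-squares
line captures the overall trend; cells sitting above the line contribute
disproportionately.  A cell type whose residuals are stochastically larger
than those of all remaining cells -- a positive one-sided two-sample
Kolmogorov-Smirnov statistic with p below alpha -- is called a mediator of the
component.  The scan covers every component and every sufficiently large cell
type, and the resulting KS matrix is ordered by hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import ks_2samp

from .phenotype_space import NMFModel

logger = logging.getLogger(__name__)

__all__ = [
    "cell_contributions",
    "regression_residuals",
    "KSResult",
    "ks_one_sided",
    "MediatorResult",
    "mediator_scan",
    "ClusterOrder",
    "cluster_heatmap",
    "save_heatmap",
]


def cell_contributions(
    active: sp.spmatrix,
    W: pd.DataFrame | np.ndarray,
    component: int,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-cell expressed-gene fraction and component weight.

    expressed_fraction = (# active genes) / (# genes); component_weight =
    sum of W[g, component] over active genes g, divided by the component's
    total W mass when ``normalize`` is set.  Gene columns of ``active`` must
    align with the rows of ``W``.
    """
    active = sp.csr_matrix(active)
    w = W.values if isinstance(W, pd.DataFrame) else np.asarray(W)
    if w.ndim != 2 or active.shape[1] != w.shape[0]:
        raise ValueError("gene columns of the activity matrix must align with W rows")
    if not (0 <= component < w.shape[1]):
        raise ValueError(f"component {component} out of range")
    col = w[:, component].astype(float)
    frac = np.asarray(active.mean(axis=1)).ravel()
    weight = np.asarray(active @ col).ravel()
    if normalize:
        total = col.sum()
        if total == 0:
            raise ValueError(f"component {component} has zero total W mass; cannot normalize")
        weight = weight / total
    return pd.DataFrame({"expressed_fraction": frac, "component_weight": weight})


def regression_residuals(contribs: pd.DataFrame) -> np.ndarray:
    """OLS residuals of component weight on expressed fraction over all cells.

    residual = observed - predicted; residuals of the fit sum to ~0.
    """
    x = contribs["expressed_fraction"].values.astype(float)
    y = contribs["component_weight"].values.astype(float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 cells with distinct expressed fractions")
    if np.std(x) == 0:
        raise ValueError("zero variance in expressed fraction; regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_focal: int
    n_rest: int
    reliable: bool


def ks_one_sided(focal: Sequence[float], rest: Sequence[float]) -> KSResult:
    """One-sided two-sample KS: are focal values stochastically larger?

    statistic = sup over x of (ECDF of rest - ECDF of focal), floored at 0, so
    a focal sample shifted upward gives a large statistic (1 at complete
    separation, 0 for identical samples).  A focal sample of size < 2 is
    flagged unreliable.
    """
    focal = np.asarray(focal, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if focal.size == 0 or rest.size == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(rest, focal, alternative="greater", method="auto")
    return KSResult(
        statistic=float(max(0.0, res.statistic)),
        pvalue=float(res.pvalue),
        n_focal=int(focal.size),
        n_rest=int(rest.size),
        reliable=focal.size >= 2,
    )


@dataclass
class MediatorResult:
    """Cell-type x component matrices of one-sided KS statistics and p-values."""

    ks_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    alpha: float
    min_cells: int
    n_tests: int
    normalize: bool

    @property
    def significant_mask(self) -> pd.DataFrame:
        return self.p_matrix < self.alpha

    def significant_pairs(self) -> pd.DataFrame:
        """Long-format (cell type, component, KS, p) for significant pairs."""
        mask = self.significant_mask
        rows = [
            {
                "cell_type": t,
                "component": c,
                "ks": float(self.ks_matrix.loc[t, c]),
                "p": float(self.p_matrix.loc[t, c]),
            }
            for t in mask.index
            for c in mask.columns
            if bool(mask.loc[t, c])
        ]
        return pd.DataFrame(rows, columns=["cell_type", "component", "ks", "p"])


def mediator_scan(
    active: sp.spmatrix,
    model: NMFModel,
    cell_types: Sequence,
    *,
    min_cells: int = 50,
    alpha: float = 1e-4,
    normalize: bool = True,
) -> MediatorResult:
    """One-sided KS mediator test for every (cell type, component) pair.

    For each component, OLS residuals are computed over ALL cells; every cell
    type with more than ``min_cells`` labeled cells is then tested against the
    remaining cells.  No multiple-testing correction is applied; the raw test
    count is recorded on the result.
    """
    active = sp.csr_matrix(active)
    types = pd.Series(list(cell_types))
    if len(types) != active.shape[0]:
        raise ValueError("cell_types must have one entry per cell")
    counts = types[types.notna()].value_counts()
    eligible = sorted(counts.index[counts > min_cells])
    if not eligible:
        raise ValueError(f"no cell type has more than min_cells={min_cells} cells")
    comp_labels = list(model.W.columns)
    ks = np.zeros((len(eligible), len(comp_labels)))
    pv = np.ones_like(ks)
    type_masks = {t: (types == t).values for t in eligible}
    for j, comp in enumerate(comp_labels):
        contribs = cell_contributions(active, model.W, j, normalize=normalize)
        resid = regression_residuals(contribs)
        for i, t in enumerate(eligible):
            mask = type_masks[t]
            res = ks_one_sided(resid[mask], resid[~mask])
            ks[i, j] = res.statistic
            pv[i, j] = res.pvalue
    n_tests = ks.size
    logger.info(
        "mediator_scan: %d cell types x %d components = %d KS tests (alpha=%g, uncorrected)",
        len(eligible), len(comp_labels), n_tests, alpha,
    )
    return MediatorResult(
        ks_matrix=pd.DataFrame(ks, index=eligible, columns=comp_labels),
        p_matrix=pd.DataFrame(pv, index=eligible, columns=comp_labels),
        alpha=alpha,
        min_cells=min_cells,
        n_tests=n_tests,
        normalize=normalize,
    )


@dataclass
class ClusterOrder:
    row_order: list
    col_order: list
    row_newick: str | None
    col_newick: str | None


def _canonical_children(node, labels):
    """Children ordered by smallest leaf label, so leaf order does not depend
    on the input row order."""
    kids = [node.left, node.right]

    def min_label(n):
        if n.is_leaf():
            return labels[n.id]
        return min(min_label(n.left), min_label(n.right))

    return sorted(kids, key=min_label)


def _canonical_leaves(Z: np.ndarray, labels: Sequence[str]) -> list:
    root = to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return [labels[node.id]]
        first, second = _canonical_children(node, labels)
        return walk(first) + walk(second)

    return walk(root)


def _newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string for a scipy linkage matrix, cophenetic branch lengths."""
    root = to_tree(Z)

    def render(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        first, second = _canonical_children(node, labels)
        return f"({render(first, node.dist)},{render(second, node.dist)}):{length:.6g}"

    return render(root, root.dist) + ";"


def cluster_heatmap(
    result: MediatorResult,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ClusterOrder:
    """Hierarchically cluster the KS matrix rows and columns.

    Non-significant entries are zeroed before clustering; leaf orders are
    deterministic for a given method and metric.  With a single row or
    column the order is trivial and no dendrogram is produced.
    """
    matrix = result.ks_matrix.where(result.significant_mask, 0.0)
    if matrix.empty:
        raise ValueError("KS matrix is empty")

    def side(frame: pd.DataFrame):
        if len(frame) < 2:
            return list(frame.index), None
        Z = linkage(frame.values, method=linkage_method, metric=metric)
        order = _canonical_leaves(Z, list(frame.index))
        return order, _newick(Z, list(frame.index))

    row_order, row_newick = side(matrix)
    col_order, col_newick = side(matrix.T)
    return ClusterOrder(
        row_order=row_order, col_order=col_order,
        row_newick=row_newick, col_newick=col_newick,
    )


def save_heatmap(result: MediatorResult, order: ClusterOrder, path) -> None:
    """Render the clustered KS matrix as a simple heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = result.ks_matrix.where(result.significant_mask, 0.0)
    matrix = matrix.loc[order.row_order, order.col_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * matrix.shape[1]), max(4, 0.18 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=5)
    ax.set_xlabel("NMF phenotype component")
    ax.set_ylabel("cell type")
    fig.colorbar(im, ax=ax, label="one-sided KS statistic")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
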