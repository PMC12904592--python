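"""Phenotypic space: ontology parsing, ancestor closure, NMF, pleiotropy.

A gene perturbed in the organism is annotated to phenotype-ontology terms; by
the subsumption semantics of the ontology it is implicitly associated with
every broader term as well (ancestor closure).  The resulting binary gene x
term matrix is redundant by construction, so it is factorized with
non-negative matrix factorization V ~ W H: rows of W are the per-gene
phenotypic vectors g_P, rows of H describe each latent phenotype component in
terms of ontology terms.  The pleiotropy score of a gene is the row sum of W,
counting (in a soft sense) how many latent traits the gene influences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "PhenotypeAnnotation",
    "NMFModel",
    "PleiotropyResult",
    "read_ontology",
    "load_associations",
    "ancestor_closure",
    "factorize",
    "pleiotropy_scores",
    "annotate_component",
]


@dataclass
class Ontology:
    """A DAG of terms under the is_a relation."""

    term_ids: list
    parents: dict  # term -> frozenset of direct is_a parents
    roots: frozenset

    @classmethod
    def from_parents(cls, parents: dict) -> "Ontology":
        term_ids = sorted(parents)
        term_set = set(term_ids)
        for term, ps in parents.items():
            missing = set(ps) - term_set
            if missing:
                raise ValueError(f"term {term} has unknown parent id(s): {sorted(missing)}")
        graph = nx.DiGraph((t, p) for t, ps in parents.items() for p in ps)
        graph.add_nodes_from(term_ids)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology is_a relation contains a cycle: {cycle}")
        roots = frozenset(t for t in term_ids if not parents[t])
        return cls(term_ids=term_ids, parents={t: frozenset(p) for t, p in parents.items()}, roots=roots)

    def ancestors(self, term: str) -> frozenset:
        """All terms reachable from ``term`` by following is_a parents (exclusive)."""
        seen: set = set()
        frontier = list(self.parents[term])
        while frontier:
            t = frontier.pop()
            if t not in seen:
                seen.add(t)
                frontier.extend(self.parents[t])
        return frozenset(seen)

    def reachability(self) -> pd.DataFrame:
        """Boolean terms x terms matrix: [t, a] true iff a is t or an ancestor of t."""
        idx = {t: i for i, t in enumerate(self.term_ids)}
        n = len(self.term_ids)
        reach = np.zeros((n, n), dtype=bool)
        order = list(nx.topological_sort(
            nx.DiGraph([(t, p) for t, ps in self.parents.items() for p in ps]).reverse()
        ))
        # process parents before children so reach rows can be unioned
        covered = set(order)
        order.extend(t for t in self.term_ids if t not in covered)
        for t in order:
            i = idx[t]
            reach[i, i] = True
            for p in self.parents[t]:
                reach[i] |= reach[idx[p]]
        return pd.DataFrame(reach, index=self.term_ids, columns=self.term_ids)


def read_ontology(obo_path: str | Path) -> Ontology:
    """Parse an OBO file into a validated acyclic :class:`Ontology`.

    Obsolete terms are excluded; a cycle in the is_a relation is fatal.
    """
    graph = obonet.read_obo(str(obo_path))  # obsolete stanzas skipped by default
    parents: dict = {}
    for node in graph.nodes:
        parents.setdefault(node, set())
        for _, parent, key in graph.out_edges(node, keys=True):
            if key == "is_a":
                parents.setdefault(parent, set())
                parents[node].add(parent)
    return Ontology.from_parents(parents)


def load_associations(
    path: str | Path, ontology: Ontology | None = None
) -> pd.DataFrame:
    """Read a two-column (gene_id, term_id) TSV of direct annotations.

    Lines starting with '#' are comments.  With an ontology given, pairs
    referring to unknown terms are skipped with a logged count.
    """
    pairs = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene_id", "term_id"], dtype=str
    )
    if ontology is not None:
        known = pairs["term_id"].isin(set(ontology.term_ids))
        n_bad = int((~known).sum())
        if n_bad:
            logger.warning("load_associations: skipped %d pairs with unknown terms", n_bad)
            pairs = pairs[known]
    pairs = pairs.drop_duplicates().reset_index(drop=True)
    return pairs


def _pairs_to_matrix(pairs: pd.DataFrame, term_ids: list) -> pd.DataFrame:
    genes = sorted(pairs["gene_id"].unique())
    mat = pd.DataFrame(0, index=genes, columns=term_ids, dtype=np.uint8)
    known = pairs[pairs["term_id"].isin(set(term_ids))]
    mat.values[
        mat.index.get_indexer(known["gene_id"]), mat.columns.get_indexer(known["term_id"])
    ] = 1
    return mat


@dataclass
class PhenotypeAnnotation:
    """Ancestor-closed binary gene x term matrix."""

    frame: pd.DataFrame  # uint8, genes x terms

    @property
    def gene_ids(self) -> list:
        return list(self.frame.index)

    @property
    def term_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.values


def ancestor_closure(
    ontology: Ontology, direct: pd.DataFrame
) -> PhenotypeAnnotation:
    """Close direct annotations upward: gene-term 1s propagate to all ancestors.

    ``direct`` is a binary genes x terms DataFrame (or a two-column pair frame
    from :func:`load_associations`).  Columns referring to unknown terms are
    dropped with a logged count.  The operation is idempotent.
    """
    if set(direct.columns) == {"gene_id", "term_id"}:
        direct = _pairs_to_matrix(direct, ontology.term_ids)
    unknown = [c for c in direct.columns if c not in set(ontology.term_ids)]
    if unknown:
        logger.warning("ancestor_closure: dropping %d unknown term columns", len(unknown))
        direct = direct.drop(columns=unknown)
    reach = ontology.reachability()
    aligned = pd.DataFrame(0, index=direct.index, columns=ontology.term_ids, dtype=np.uint8)
    aligned[direct.columns] = direct.astype(np.uint8)
    closed = (aligned.values @ reach.values.astype(np.uint8)) > 0
    frame = pd.DataFrame(closed.astype(np.uint8), index=direct.index, columns=ontology.term_ids)
    empty = frame.sum(axis=1) == 0
    if empty.any():
        logger.warning("ancestor_closure: dropping %d genes with no annotations", int(empty.sum()))
        frame = frame[~empty]
    return PhenotypeAnnotation(frame=frame)


@dataclass
class NMFModel:
    """Best-of-restarts NMF factorization of the closed annotation matrix."""

    W: pd.DataFrame  # genes x k, rows are phenotypic vectors g_P
    H: pd.DataFrame  # k x terms
    k: int
    seed: int
    n_restarts: int
    reconstruction_error: float  # Frobenius norm of V - W H

    @property
    def gene_ids(self) -> list:
        return list(self.W.index)

    @property
    def term_ids(self) -> list:
        return list(self.H.columns)

    def save(self, outdir: str | Path, prefix: str = "nmf") -> None:
        outdir = Path(outdir)
        self.W.to_csv(outdir / f"{prefix}_W.tsv", sep="\t", float_format="%.10g")
        self.H.to_csv(outdir / f"{prefix}_H.tsv", sep="\t", float_format="%.10g")
        meta = {
            "k": self.k,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "reconstruction_error": self.reconstruction_error,
        }
        (outdir / f"{prefix}_meta.json").write_text(pd.Series(meta).to_json(indent=1))


def factorize(
    annotation: PhenotypeAnnotation,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    *,
    min_term_genes: int = 2,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> NMFModel:
    """Factorize the annotation matrix, returning the restart with least error.

    Terms annotated to fewer than ``min_term_genes`` genes are dropped first
    (then genes left with no annotation), preventing all-zero columns.  The
    first restart uses the deterministic NNDSVDa initialization; the remaining
    ``n_restarts - 1`` use random initializations seeded from ``seed``.
    """
    frame = annotation.frame
    keep_terms = frame.sum(axis=0) >= min_term_genes
    n_dropped = int((~keep_terms).sum())
    if n_dropped:
        logger.info("factorize: dropped %d terms below min_term_genes=%d", n_dropped, min_term_genes)
    frame = frame.loc[:, keep_terms]
    keep_genes = frame.sum(axis=1) > 0
    frame = frame.loc[keep_genes]
    if frame.empty:
        raise ValueError("annotation matrix is empty after filtering")
    V = frame.values.astype(float)
    if k < 1 or k > min(V.shape):
        raise ValueError(f"k={k} must lie in [1, min(genes, terms)={min(V.shape)}]")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    inits = [("nndsvda", seed)] + [("random", seed + i) for i in range(1, n_restarts)]
    for init, rs in inits:
        model = NMF(
            n_components=k, init=init, random_state=rs, max_iter=max_iter, tol=tol
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            W = model.fit_transform(V)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                logger.warning(
                    "factorize: restart init=%s seed=%d did not converge "
                    "(final error %.6g)", init, rs, float(np.linalg.norm(V - W @ model.components_))
                )
        H = model.components_
        err = float(np.linalg.norm(V - W @ H))
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    comp_labels = [f"c{i}" for i in range(k)]
    return NMFModel(
        W=pd.DataFrame(W, index=frame.index, columns=comp_labels),
        H=pd.DataFrame(H, index=comp_labels, columns=frame.columns),
        k=k,
        seed=seed,
        n_restarts=n_restarts,
        reconstruction_error=err,
    )


@dataclass
class PleiotropyResult:
    """Pleiotropy scores (row sums of W) and extreme-percentile gene sets."""

    scores: pd.Series
    pleiotropic: list
    non_pleiotropic: list
    upper_threshold: float
    lower_threshold: float

    def to_frame(self) -> pd.DataFrame:
        label = pd.Series("mid", index=self.scores.index)
        label[self.pleiotropic] = "pleiotropic"
        label[self.non_pleiotropic] = "non_pleiotropic"
        return pd.DataFrame({"pleiotropy": self.scores, "set": label})


def pleiotropy_scores(
    model: NMFModel, upper_pct: float = 95.0, lower_pct: float = 5.0
) -> PleiotropyResult:
    """Pleiotropy score per gene = sum of its W row; strict-percentile sets.

    Genes strictly above the empirical ``upper_pct`` percentile form the
    pleiotropic set, strictly below ``lower_pct`` the non-pleiotropic set;
    ties at a threshold belong to neither.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    scores = model.W.sum(axis=1)
    # thresholds are observed score values (lower interpolation), so the sets
    # match what sorting the scores and cutting at the percentile rank gives
    hi = float(np.percentile(scores.values, upper_pct, method="lower"))
    lo = float(np.percentile(scores.values, lower_pct, method="lower"))
    pleio = scores.index[scores.values > hi].tolist()
    non = scores.index[scores.values < lo].tolist()
    if scores.nunique() == 1:
        logger.warning("pleiotropy_scores: degenerate all-equal score distribution; empty sets")
    return PleiotropyResult(
        scores=scores,
        pleiotropic=pleio,
        non_pleiotropic=non,
        upper_threshold=hi,
        lower_threshold=lo,
    )


def annotate_component(model: NMFModel, component: int, top_n: int = 10) -> list:
    """Top ``top_n`` ontology terms of one component by H weight.

    Returns (term, weight) pairs in descending weight order, ties broken by
    term id.  An all-zero component yields an empty list (logged).
    """
    if not (0 <= component < model.k):
        raise ValueError(f"component {component} out of range for k={model.k}")
    row = model.H.iloc[component]
    if (row.values == 0).all():
        logger.warning("annotate_component: component %d has an all-zero H row", component)
        return []
    order = sorted(zip(row.index, row.values), key=lambda tw: (-tw[1], tw[0]))
    return [(t, float(w)) for t, w in order[:top_n] if w > 0]
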