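"""Synthetic atlases, ontologies, and annotations with planted D-P structure.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage has a ground-truth recovery test without external
downloads:

* an atlas on a cell-type x stage grid where *housekeeping* genes are active
  essentially everywhere and *specific* genes only in a small coordinate set;
* a rooted DAG ontology whose leaves partition into disjoint phenotype
  modules under a shared spine;
* gene-phenotype annotations where *systemic* genes draw leaves from many
  modules and *specific* genes from exactly one;
* optional mediator cell types that additionally activate all genes of one
  module, planting a cell-type/phenotype association.

Gene classes combine the two axes: housekeeping-systemic genes are D-P truth
(rule followers), housekeeping-specific are D-p truth (developmental
divergence), specific-systemic are d-P truth (phenotypic degeneracy), and
specific-specific genes form the bulk, whose phenotype-module count increases
monotonically with expression breadth (the planted form of the rule itself).
Systemic classes start expression at the first stage; bulk genes occupy a
contiguous stage window with random onset, so low breadth also means fewer
stages and typically later onset.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .atlas_space import ExpressionAtlas
from .phenotype_space import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_ontology",
    "generate_atlas",
    "generate_annotations",
    "generate_dataset",
    "write_dataset",
]

CLASS_NAMES = ("D-P", "D-p", "d-P", "other")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic D-P benchmark.

    Defaults are sized so that planted structure is recoverable with margin at
    5% noise while collapsing to chance when noise approaches 0.5.
    """

    n_genes: int = 500
    n_cell_types: int = 8
    n_stages: int = 6
    cells_per_coordinate: float = 20.0  # mean of the per-coordinate Poisson cell count
    class_proportions: dict = field(
        default_factory=lambda: {"D-P": 0.15, "D-p": 0.03, "d-P": 0.03, "other": 0.79}
    )
    n_phenotype_modules: int = 10
    terms_per_module: int = 8
    shared_root_depth: int = 2
    annotations_per_module: int = 6
    systemic_module_range: tuple = (10, 10)  # modules per systemic (D-P / d-P) gene
    bulk_max_modules: int = 5  # top of the breadth->module-count link for bulk genes
    bulk_breadth: tuple = (0.12, 0.70)  # coordinate-fraction range for bulk genes
    housekeeping_specific_breadth: tuple = (0.93, 0.97)  # D-p breadth range
    specific_systemic_coords: int = 2  # d-P genes: coordinates, all at the first stage
    annotation_noise: float = 0.05
    activity_noise: float = 0.05
    mediator_pairs: tuple = (("ct1", 0), ("ct5", 3))
    stage_minutes: float = 100.0
    count_lambda: float = 2.0  # counts for active cells are 1 + Poisson(count_lambda)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        for rate in (self.annotation_noise, self.activity_noise):
            if not (0 <= rate <= 1):
                raise ValueError("noise rates must lie in [0, 1]")
        if set(self.class_proportions) != set(CLASS_NAMES):
            raise ValueError(f"class_proportions must cover exactly {CLASS_NAMES}")

    @property
    def n_coordinates(self) -> int:
        return self.n_cell_types * self.n_stages

    @property
    def cell_types(self) -> list:
        return [f"ct{i + 1}" for i in range(self.n_cell_types)]

    @property
    def stage_edges(self) -> np.ndarray:
        return np.arange(self.n_stages + 1, dtype=float) * self.stage_minutes


@dataclass
class GroundTruth:
    """Planted per-gene labels and mediator pairs."""

    frame: pd.DataFrame  # index gene_id; columns true_class, modules, breadth, onset_stage
    mediator_pairs: list  # list of (cell_type, module index)

    def classes(self) -> pd.Series:
        return self.frame["true_class"]


@dataclass
class SyntheticDataset:
    atlas: ExpressionAtlas
    truth: GroundTruth
    ontology: Ontology
    module_map: dict  # module index -> list of leaf term ids
    annotations: pd.DataFrame  # direct (gene_id, term_id) pairs
    config: GeneratorConfig


def _term_id(kind: int, a: int = 0, b: int = 0) -> str:
    return f"SYN:{kind}{a:03d}{b:03d}"


def generate_ontology(
    n_modules: int,
    terms_per_module: int,
    shared_root_depth: int = 2,
    seed: int = 0,
) -> tuple[Ontology, dict]:
    """Rooted DAG with ``n_modules`` disjoint leaf subtrees under a shared spine.

    The spine is a chain of ``shared_root_depth`` terms ending at the root;
    each module contributes one head term attached to the spine bottom plus
    ``terms_per_module`` leaves under the head.  The module map partitions the
    leaves.  The structure is deterministic (``seed`` is accepted for API
    uniformity).
    """
    if n_modules < 1 or terms_per_module < 1 or shared_root_depth < 1:
        raise ValueError("ontology generator parameters must be positive")
    parents: dict = {}
    spine = [_term_id(0, 0, i) for i in range(shared_root_depth)]
    parents[spine[0]] = set()  # root
    for upper, lower in zip(spine, spine[1:]):
        parents[lower] = {upper}
    module_map: dict = {}
    for m in range(n_modules):
        head = _term_id(1, m, 0)
        parents[head] = {spine[-1]}
        leaves = []
        for l in range(terms_per_module):
            leaf = _term_id(2, m, l)
            parents[leaf] = {head}
            leaves.append(leaf)
        module_map[m] = leaves
    return Ontology.from_parents(parents), module_map


def _assign_classes(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    counts = {c: int(round(p * cfg.n_genes)) for c, p in cfg.class_proportions.items()}
    counts["other"] = cfg.n_genes - sum(v for c, v in counts.items() if c != "other")
    if counts["other"] < 0:
        raise ValueError("class proportions leave no room for the bulk class")
    labels = np.concatenate([[c] * n for c, n in counts.items()])
    rng.shuffle(labels)
    return labels


def _plant_gene(
    cls: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list, float]:
    """Planted (coordinate activity, modules, breadth) for one gene.

    Coordinates are laid out type-major: index = type * n_stages + stage.
    """
    C, T, S = cfg.n_coordinates, cfg.n_cell_types, cfg.n_stages
    active = np.zeros(C, dtype=bool)
    lo_m, hi_m = cfg.systemic_module_range
    if cls == "D-P":
        active[:] = True
        breadth = 1.0
        modules = rng.choice(cfg.n_phenotype_modules, size=rng.integers(lo_m, hi_m + 1), replace=False)
    elif cls == "D-p":
        breadth = rng.uniform(*cfg.housekeeping_specific_breadth)
        idx = rng.choice(C, size=max(1, round(breadth * C)), replace=False)
        active[idx] = True
        modules = rng.choice(cfg.n_phenotype_modules, size=1)
    elif cls == "d-P":
        k = min(cfg.specific_systemic_coords, T)
        if k < 1:
            raise ValueError("grid too small for the requested specific coordinate subsets")
        types = rng.choice(T, size=k, replace=False)
        active[types * S] = True  # stage 0: systemic classes start at the first stage
        breadth = k / C
        modules = rng.choice(cfg.n_phenotype_modules, size=rng.integers(lo_m, hi_m + 1), replace=False)
    else:  # bulk: breadth gradient with a monotone breadth -> module-count link
        b_lo, b_hi = cfg.bulk_breadth
        breadth = rng.uniform(b_lo, b_hi)
        width = int(np.ceil(breadth * S))
        onset = int(rng.integers(0, S - width + 1))
        window = np.arange(onset, onset + width)
        pool = (np.arange(T)[:, None] * S + window[None, :]).ravel()
        size = min(max(1, round(breadth * C)), len(pool))
        active[rng.choice(pool, size=size, replace=False)] = True
        level = 1 + int((breadth - b_lo) / (b_hi - b_lo) * (cfg.bulk_max_modules - 1e-9))
        level = min(level, cfg.bulk_max_modules)
        modules = rng.choice(cfg.n_phenotype_modules, size=level, replace=False)
    return active, sorted(int(m) for m in modules), float(breadth)


def generate_atlas(config: GeneratorConfig) -> tuple[ExpressionAtlas, GroundTruth]:
    """Sample an atlas on the type x stage grid with planted class structure.

    Cell-level activity flips the planted (gene, coordinate) state with
    probability ``activity_noise``; active cells get a shifted-Poisson UMI
    count (1 + Poisson(count_lambda)) so binary and count-threshold activity
    paths differ.  Mediator cell types additionally activate every gene of
    their paired module at all their coordinates.  Deterministic given seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    classes = _assign_classes(cfg, rng)

    planted = np.zeros((cfg.n_genes, cfg.n_coordinates), dtype=bool)
    modules: list = []
    breadths = np.zeros(cfg.n_genes)
    onsets = np.zeros(cfg.n_genes, dtype=int)
    for i, cls in enumerate(classes):
        active, mods, breadth = _plant_gene(cls, cfg, rng)
        planted[i] = active
        modules.append(mods)
        breadths[i] = breadth
        stages_hit = np.flatnonzero(active.reshape(cfg.n_cell_types, cfg.n_stages).any(axis=0))
        onsets[i] = int(stages_hit[0]) if stages_hit.size else -1

    # mediator planting: the paired cell type expresses the module's gene set
    type_index = {t: i for i, t in enumerate(cfg.cell_types)}
    for cell_type, module in cfg.mediator_pairs:
        if cell_type not in type_index:
            raise ValueError(f"mediator cell type {cell_type!r} not on the grid")
        t = type_index[cell_type]
        gene_mask = np.array([module in mods for mods in modules])
        cols = t * cfg.n_stages + np.arange(cfg.n_stages)
        planted[np.ix_(gene_mask, cols)] = True

    # sample cells coordinate by coordinate
    cells_per_coord = np.maximum(
        1, rng.poisson(cfg.cells_per_coordinate, size=cfg.n_coordinates)
    )
    blocks, cell_types, times = [], [], []
    for t in range(cfg.n_cell_types):
        for s in range(cfg.n_stages):
            c = t * cfg.n_stages + s
            n_c = int(cells_per_coord[c])
            base = planted[:, c]
            flips = rng.random((n_c, cfg.n_genes)) < cfg.activity_noise
            active_cells = base[None, :] ^ flips
            counts = np.zeros((n_c, cfg.n_genes), dtype=np.int64)
            n_active = int(active_cells.sum())
            if n_active:
                counts[active_cells] = 1 + rng.poisson(cfg.count_lambda, size=n_active)
            blocks.append(sp.csr_matrix(counts))
            cell_types.extend([cfg.cell_types[t]] * n_c)
            times.extend(rng.uniform(s * cfg.stage_minutes, (s + 1) * cfg.stage_minutes, size=n_c))
    counts = sp.vstack(blocks, format="csr")
    cell_ids = [f"cell{i:05d}" for i in range(counts.shape[0])]

    atlas = ExpressionAtlas(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_type=np.array(cell_types, dtype=object),
        embryo_time=np.array(times, dtype=float),
    )
    truth = GroundTruth(
        frame=pd.DataFrame(
            {
                "true_class": classes,
                "modules": modules,
                "breadth": breadths,
                "onset_stage": onsets,
            },
            index=gene_ids,
        ),
        mediator_pairs=list(cfg.mediator_pairs),
    )
    return atlas, truth


def generate_annotations(
    truth: GroundTruth,
    ontology: Ontology,
    module_map: dict,
    annotation_noise: float = 0.05,
    seed: int = 0,
    annotations_per_module: int = 6,
) -> pd.DataFrame:
    """Direct gene-term leaf annotations from planted module memberships.

    Each gene draws ``annotations_per_module`` leaves from every module it
    belongs to.  Noise removes each planted pair with the given rate (keeping
    at least one per gene) and adds, with the same rate per gene, one random
    leaf from anywhere.  Output is the two-column association dialect.
    """
    rng = np.random.default_rng(seed)
    all_leaves = [leaf for leaves in module_map.values() for leaf in leaves]
    rows: list = []
    for gene, mods in truth.frame["modules"].items():
        pairs = []
        for m in mods:
            leaves = module_map[m]
            k = min(annotations_per_module, len(leaves))
            for leaf in rng.choice(leaves, size=k, replace=False):
                pairs.append(leaf)
        if annotation_noise > 0:
            keep = rng.random(len(pairs)) >= annotation_noise
            if not keep.any():
                keep[rng.integers(0, len(pairs))] = True
            pairs = [p for p, k_ in zip(pairs, keep) if k_]
            if rng.random() < annotation_noise:
                pairs.append(all_leaves[rng.integers(0, len(all_leaves))])
        rows.extend((gene, term) for term in sorted(set(pairs)))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Atlas + ontology + annotations + ground truth, all from one config."""
    cfg = config or GeneratorConfig()
    ontology, module_map = generate_ontology(
        cfg.n_phenotype_modules, cfg.terms_per_module, cfg.shared_root_depth, cfg.seed
    )
    atlas, truth = generate_atlas(cfg)
    annotations = generate_annotations(
        truth,
        ontology,
        module_map,
        annotation_noise=cfg.annotation_noise,
        seed=cfg.seed + 1,
        annotations_per_module=cfg.annotations_per_module,
    )
    return SyntheticDataset(
        atlas=atlas,
        truth=truth,
        ontology=ontology,
        module_map=module_map,
        annotations=annotations,
        config=cfg,
    )


def _write_obo(ontology: Ontology, path: Path) -> None:
    lines = ["format-version: 1.2", "ontology: synthetic-phenotype", ""]
    for term in ontology.term_ids:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        for parent in sorted(ontology.parents[term]):
            lines.append(f"is_a: {parent} ! synthetic term {parent}")
        lines.append("")
    path.write_text("\n".join(lines))


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the dataset in the on-disk dialects the readers consume.

    Emits matrix.mtx (cells x genes), cells.tsv, genes.tsv, ontology.obo,
    associations.tsv, and ground_truth.json; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "cells": outdir / "cells.tsv",
        "genes": outdir / "genes.tsv",
        "ontology": outdir / "ontology.obo",
        "associations": outdir / "associations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(dataset.atlas.counts), field="integer")
    pd.DataFrame(
        {
            "cell_id": dataset.atlas.cell_ids,
            "cell_type": dataset.atlas.cell_type,
            "embryo_time": dataset.atlas.embryo_time,
        }
    ).to_csv(paths["cells"], sep="\t", index=False, float_format="%.10g")
    pd.DataFrame({"gene_id": dataset.atlas.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    _write_obo(dataset.ontology, paths["ontology"])
    with open(paths["associations"], "w") as fh:
        fh.write("# gene_id\tterm_id\n")
        dataset.annotations.to_csv(fh, sep="\t", index=False, header=False)
    truth_payload = {
        "classes": dataset.truth.frame["true_class"].to_dict(),
        "modules": {g: list(map(int, m)) for g, m in dataset.truth.frame["modules"].items()},
        "mediator_pairs": [[t, int(m)] for t, m in dataset.truth.mediator_pairs],
        "module_map": {str(k): v for k, v in dataset.module_map.items()},
        "seed": dataset.config.seed,
    }
    paths["ground_truth"].write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
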