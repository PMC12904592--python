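# dprule

Does similar gene activity during embryonic development imply similar
organismal phenotypes when those genes are perturbed?  `dprule` implements a
quantitative test of this *development-to-phenotype* (D-P) rule for
single-cell developmental atlases (such as the *C. elegans* embryo atlas,
GEO GSE126954) combined with a phenotype ontology (such as the WormBase Worm
Phenotype Ontology), and ships a synthetic-data generator with planted ground
truth so every stage of the analysis is testable without external downloads.

It is written for computational biologists who want to relate developmental
expression programs to perturbation phenotypes: the package reads the
standard formats (MatrixMarket counts + annotation TSVs, OBO ontologies,
gene-term association TSVs), and exposes both a Python API and a `dprule`
command-line pipeline.

## The method

Every gene *i* receives two vectors:

* a **developmental vector** g<sub>D<sub>i</sub></sub>, indexed by
  developmental coordinates (cell type × embryo-time bin), whose entries are
  the fraction of cells sampled at that coordinate in which the gene is
  active (UMI count ≥ 1 by default);
* a **phenotypic vector** g<sub>P<sub>i</sub></sub>, the gene's row of the
  feature matrix W from a non-negative matrix factorization V ≈ W·H of the
  ancestor-closed binary gene × phenotype-term matrix V (closure: a gene
  annotated to a term is implicitly annotated to every term subsuming it).

Similarity within a space is the cosine,
sim(g<sub>i</sub>, g<sub>j</sub>) = g<sub>i</sub>·g<sub>j</sub> /
(‖g<sub>i</sub>‖₂‖g<sub>j</sub>‖₂), and a gene's summary scores ⟨simD⟩ and
⟨simP⟩ are the medians of its pairwise similarities to all other genes
(self-pair excluded).  The D-P rule predicts ⟨simP⟩ increases with ⟨simD⟩;
the package quantifies this with a sliding-window trend, a percentile-class
contingency matrix (columns sum to 1), and Spearman correlation.

Deviations are classified from LOESS residuals of ⟨simP⟩ on ⟨simD⟩:

| class | ⟨simD⟩ | residual | interpretation |
|-------|--------|----------|----------------|
| D-P   | high   | inside central band, ⟨simP⟩ high | rule followers: housekeeping expression, systemic phenotypes |
| D-p   | high   | below lower band | developmental divergence: broad expression, specific phenotype |
| d-P   | low    | above upper band | phenotypic degeneracy: narrow expression, systemic phenotype |

Three follow-up analyses mirror the downstream biology:

* **Pleiotropy**: ℙ(gene) = Σ<sub>j</sub> W[gene, j]; genes above the 95th /
  below the 5th percentile form the pleiotropic / non-pleiotropic sets, which
  are profiled by expression breadth (fraction of all cells expressing the
  gene, against a resampling null of same-size gene sets), earliest stage and
  range of stages of expression, and per-coordinate enrichment z-scores.
* **Mediator cell types**: for each NMF component, the component weight
  carried by each cell's expressed genes is regressed (OLS) on its
  expressed-gene fraction; a cell type whose residuals are stochastically
  larger than all remaining cells' (one-sided two-sample Kolmogorov-Smirnov,
  p < 10⁻⁴, types with > 50 cells) mediates that phenotype.
* **Enrichment**: Fisher's exact test of ontology terms for any gene set
  against the analysis universe, with Benjamini-Hochberg FDR per namespace.

## Worked example

The synthetic generator plants the four gene classes (housekeeping-systemic,
housekeeping-specific, specific-systemic, specific-specific bulk with a
monotone breadth→phenotype link) plus two mediator cell types, then the full
pipeline recovers them:

```python
from dprule import GeneratorConfig, run_synthetic_analysis

run = run_synthetic_analysis(GeneratorConfig(seed=0))
m = run.metrics
print(f"Spearman(<simD>, <simP>):  {m['spearman_simD_simP']:.3f}")
print(f"class balanced accuracy:   {m['balanced_accuracy']:.3f}")
print("recall by class:           " +
      ", ".join(f"{c}={r:.2f}" for c, r in m["recall"].items()))
print(f"planted mediators found:   {m['mediator_top_hits']}")
```

prints

```
Spearman(<simD>, <simP>):  0.697
class balanced accuracy:   0.938
recall by class:           D-P=0.81, D-p=1.00, d-P=1.00
planted mediators found:   [True, True]
```

so on this run the planted proportionality between developmental and
phenotypic similarity is recovered (ρ = 0.70), 94% balanced accuracy over
the three planted rule classes, and both planted (cell type → phenotype
module) mediator pairs are the top KS hit of their component at p < 10⁻⁴.

The same pipeline runs from the shell against files on disk:

```bash
dprule --config config.yaml all        # simulate -> build -> ... -> mediators
dprule --config config.yaml enrich --gene-set my_genes.txt
```

where `config.yaml` points `data.*` at a counts matrix, cell/gene TSVs, an
OBO ontology, and an association TSV (or includes a `generator:` section to
run on synthetic data).  Outputs are TSV/JSON artifacts plus run metadata;
identical configs and seeds give byte-identical files.

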