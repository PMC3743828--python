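# devscreen

Screening mutant RNA-seq panels for developmentally important genes by
**transcriptional invariance**.

## The problem

In the social amoeba *Dictyostelium discoideum*, most single-gene knockouts
(for example in the large ABC-transporter family) develop almost normally,
so classical phenotype screens say little about which genes matter for
development. A panel of such mutants profiled by RNA-seq over a
developmental time course carries more information: each strain's
genome-wide expression profile is a quantitative *transcriptional
phenotype*. `devscreen` re-implements, as a tested and reusable pipeline,
a screen built on a simple idea — genes that stay **unperturbed in mutants
that develop normally** but are **perturbed in mutants whose development
is delayed or absent** are candidates for developmental importance.

The pipeline takes a raw count matrix (genes × samples), sample metadata
(strain, phenotype category, time point, replicate) and a gene catalog
(mappable exon lengths plus annotation flags), and provides:

* **RPKM normalization** — reads per kilobase of uniquely mappable exon
  per million uniquely mapped reads;
* **phenotype distances and MDS** — `d(a, b) = 1 − ρ_Spearman` between
  strain mean profiles (per time point, or all time points concatenated),
  embedded in 2-D by classical (Torgerson) MDS;
* **NDE/DE classification** — an empirical-Bayes two-model negative-
  binomial classifier: for each gene, the posterior probability
  ("likelihood") of a single shared mean (NDE) versus per-group means
  (DE), with a posterior-rank FDR (cumulative mean of `1 − likelihood`
  down the ranking). A gene is called NDE when FDR < 0.005 and
  likelihood > 0.90;
* **gene-set algebra** — A = NDE in the normal-development category at
  every developmental time point (6/12/18 h); B = NDE in the delayed *or*
  the no-development group; **C = A \ B**; **D = C ∩ conserved
  orthologs**; validated by one-sided hypergeometric enrichment of known
  developmental / non-developmental labels;
* **timing analysis** — each mutant's deviation curve
  (`1 − ρ` against wild type per time point) compared with the wild-type
  abundance peak of its mutated gene (precedes / equals / succeeds /
  no correlation);
* **cell-type panel fractions** — per mutant, the fraction of
  prespore/prestalk-enriched transcripts differentially abundant at 12 h
  or 18 h;
* a fully instrumented **synthetic-panel generator** (wild type +
  35 mutants, 0/6/12/18 h, two replicates, negative-binomial counts) that
  plants a core gene set, background perturbations, and annotation labels
  so every stage can be scored against ground truth.

## Worked example

```python
import devscreen as ds
from devscreen import nde as N

panel, catalog, truth = ds.simulate_panel(ds.SimulationParams(n_genes=2000, seed=0))
dispersions = N.estimate_panel_dispersions(panel)
tables = {}
for i, cat in enumerate(("normal", "delayed", "no_development")):
    for j, t in enumerate((6.0, 12.0, 18.0)):
        comp = N.make_category_comparison(panel, cat, t)
        tables[(cat, t)] = N.run_comparison(panel, comp, seed=100 * i + j,
                                            dispersions=dispersions)
result = ds.build_gene_sets(tables, catalog)
print(result.sizes)
```

prints (seed 0):

```
{'A': 1997, 'B': 1650, 'C': 350, 'D': 204}
```

Of the 2,000 genes, 1,997 are unperturbed in the normally developing
mutants (set A), 1,650 are also unperturbed in the failing mutants
(set B), leaving 350 genes unperturbed *exclusively* in normal developers
(set C); 204 of them carry the conserved-ortholog flag (set D). Scoring
against the planted truth and the planted labels:

```
planted core: 200; recovered in D: 161 (precision 0.79, recall 0.81)
set C: 16.9% developmental labels vs 9.7% background (hypergeometric p = 2.3e-06)
set D: 21.1% developmental labels vs 9.7% background (hypergeometric p = 1.6e-07)
```

Set D concentrates the planted developmentally important genes, and the
developmental-label enrichment (21% vs 10% background) mirrors the
screen's validation logic. See `examples/` for one narrative script per
capability, and `devscreen --help` for the command-line interface
(`simulate`, `normalize`, `distances`, `mds`, `timing`, `nde`, `run`,
`report`, `enrich`).

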