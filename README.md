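# metaprior

Multi-omics prioritization of under-studied metabolic genes in
estrogen-receptor negative (ERneg) breast tumors.

ERneg tumors are the aggressive breast-cancer subtype with the fewest
targeted therapy options, and transcriptomics screens of ERneg vs ERpos
cohorts produce long lists of significant genes dominated by a handful of
heavily published favorites. `metaprior` implements a screening workflow that
narrows such lists to *metabolic* genes with *consistent* cross-study
evidence and a *thin* literature record — the candidates most likely to be
overlooked therapeutic targets. It is aimed at computational biologists who
have per-study differential statistics (or raw abundance matrices) for
several cohorts and want a reproducible, tested prioritization pipeline.

## The method

1. **Per-study differential statistics** (`diffstat`). For each cohort and
   omics layer, every feature gets a raw two-sided p-value (Mann–Whitney *U*
   for metabolites and proteins, Welch *t* on log2 abundances for
   transcripts) and a fold change FC = mean(ERneg)/mean(ERpos). Proteomics
   features must be observed in at least 6 samples of *either* group
   (prevalence filter). No multiplicity correction is applied at this
   screening stage.

2. **Metabolic-gene selection** (`metabofilter`). Genes are kept when at
   least one of their Enzyme Commission numbers describes a small-molecule
   transformation; EC classes acting on proteins or nucleic acids (protein
   kinases EC 2.7.10–13, peptidases EC 3.4, polymerases, tRNA ligases, …)
   are excluded via an editable rule list.

3. **KS meta-analysis** (`ksmeta`). For each gene with p-values
   p₁,…,pₙ across n studies, the one-sided Kolmogorov–Smirnov statistic

   D⁺ = maxᵢ ( i/n − p₍ᵢ₎ )

   measures enrichment of small p-values relative to the Uniform(0,1) null.
   The meta p-value is the exact Birnbaum–Tingey tail

   P(D⁺ ≥ d) = d · Σ_{j=0}^{⌊n(1−d)⌋} C(n,j) (d + j/n)^{j−1} (1 − d − j/n)^{n−j},

   which is valid at n as small as 2 (asymptotics are not) and reaches the
   1e-15 magnitudes that arise when ten studies agree.

4. **Pathway over-representation** (`setenrich`). Significant genes,
   proteins and metabolites are pooled into a shared pathway namespace and
   tested per pathway with the hypergeometric upper tail and
   Benjamini–Hochberg correction; each pathway is flagged with the omics
   layers that support it.

5. **Biochemical network** (`bionet`). Genes, proteins, metabolites and
   enzymes (EC numbers) become typed nodes; edges are gene–enzyme,
   protein–enzyme, compound–enzyme, biochemical reactant pairs, and chemical
   similarity (Tanimoto > 0.7, strict). Greedy-modularity communities and
   Cytoscape-compatible GraphML/SIF export included.

6. **Literature ranking** (`litrank`). The top meta-analysis genes are
   annotated with PubMed abstract counts for `"<SYMBOL>" AND "breast
   cancer"` (offline fixture or live NCBI eutils) and flagged
   **under-studied** when fewer than 5 abstracts exist.

A synthetic-data module (`synthio`) generates multi-study compendia with
planted differential genes, partially overlapping panels, proteomics
missingness and literature counts independent of effect status, so every
stage is testable against known ground truth.

## Worked example

```python
from metaprior import (SimConfig, simulate_collection, run_differential,
                       meta_analyze, simulate_annotations,
                       select_metabolic_genes, default_rules, fetch_counts,
                       prioritize)
from metaprior.metabofilter import annotation_from_frame

cfg = SimConfig(n_studies=10, n_genes=1000, seed=42)   # 10% planted, 1-sigma effect
studies, truth = simulate_collection(cfg, "transcript")
tables = [run_differential(m, test="welch") for m in studies]

ann = simulate_annotations(cfg)
metabolic = select_metabolic_genes(annotation_from_frame(ann.ec_map),
                                   default_rules())
meta, _ = meta_analyze(tables, metabolic, min_studies=3)
counts = fetch_counts(sorted(metabolic), source="fixture",
                      fixture=ann.lit_counts)
top = prioritize(meta, counts, threshold=5, top_n=10)
print(top[["rank", "gene", "n_studies", "meta_p", "n_papers",
           "understudied"]].to_string(index=False))
```

prints

```
 rank  gene  n_studies       meta_p  n_papers  understudied
    1 G0933          6 9.949608e-19        23         False
    2 G0301          9 1.720744e-18         6         False
    3 G0352          8 1.882822e-17        17         False
    4 G0498          7 7.412884e-17         4          True
    5 G0517          9 9.246366e-17         0          True
    6 G0464          5 2.074809e-14        16         False
    7 G0991         10 2.423226e-14         0          True
    8 G0806          8 1.271088e-13         0          True
    9 G0718          6 1.551677e-13         0          True
   10 G0997          9 4.851677e-12         1          True
```

All ten are truly differential in this simulation's ground truth. Each row
is one metabolic gene: `n_studies` is the number of cohorts in which it was
measured, `meta_p` the exact KS tail of its p-value vector (1e-12–1e-19
magnitudes indicate strong cross-study consistency), and the six genes with
fewer than 5 fixture "publications" are flagged as under-studied candidates.

The same workflow is available from the shell:

```bash
metaprior simulate --out data/ --seed 42
metaprior full-run --out results/ --seed 42
```

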