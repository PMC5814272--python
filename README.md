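# immunoscope

Immunogenomic cohort analysis for tumor mutation + expression data:

- **Immunophenotyping** — per-sample immune cell infiltration calls from
  metagene gene sets, using a weighted Kolmogorov–Smirnov (GSEA-style)
  running-sum score, a gene-label permutation null, and per-sample
  Benjamini–Hochberg FDR at q ≤ 0.10; plus infiltration prevalence and
  pairwise Fisher co-occurrence.
- **Mutation burden & DNA repair** — per-sample nonsynonymous mutation
  counts, strand-collapsed substitution spectra, homologous-recombination
  / mismatch-repair / POLE pathway mutation status, median and
  top-quartile group splits, and oncogene positivity rules.
- **Neoantigen calling** — enumeration of every 9-mer (configurable k)
  covering a missense site, paired with its wildtype homolog, scored
  against the sample's six class-I HLA alleles, and filtered with strict
  inequalities: mutant IC50 < 500 nM, wildtype IC50 > 500 nM, positive
  gene expression. Per-sample load counts variants with ≥ 1 passing pair.
- **Association statistics** — pooled two-proportion z, Student/Welch t,
  Pearson correlation, BH FDR, Kaplan–Meier + log-rank, infiltration
  fold-change tables.
- **Synthetic cohort generator** — emits a complete cohort (MAF,
  expression TSV, protein FASTA, panel GMT, HLA TSV, clinical TSV) with
  planted ground truth: elevated Poisson burden in repair-mutant samples,
  log-expression shifts on infiltrated samples' metagene sets, immune
  genes linearly coupled to true neoantigen load, and survival hazard
  coupled to the neoantigen-high group. A deterministic position-weight
  toy binding predictor (packaged weight tables) stands in for an
  external MHC predictor; an adapter (`parse_predictor_output`) ingests
  real predictor tables instead.

## CLI

```sh
immunoscope config-init --out demo.yaml      # dump every default/threshold
immunoscope run-all --config demo.yaml --out out/ --seed 7
```

`run-all` executes the stages `io → phenotype → burden → neoantigen →
stats` into one run directory; each stage is also a subcommand
(`simulate`, `phenotype`, `burden`, `neoantigen`, `stats`) operating on
the same `--out` directory, so stages can be rerun individually. The run
is byte-identical under a fixed seed; `manifest.json` records the config
hash, seed and completed stages. Exit status: 0 success, 1 usage or
configuration error, 2 data error.

Key outputs (tab-separated): infiltration `enrichment`/`calls`/
`prevalence`/`cooccurrence`; `burden`, `repair_status`, `spectrum`;
`neoantigen_load`, `variant_calls`; and the stats tables
(burden/neoantigen fold changes, repair-vs-burden/load comparisons with
mean ± SEM, IFN-panel mutation rates, gene correlations, M1/M2 and
checkpoint expression splits, KM curves and the log-rank test).

## Python API

```python
from immunoscope import (CohortConfig, generate_cohort, call_infiltration,
                         CallingConfig, mutation_burden, classify_repair,
                         predict_cohort)

cohort, truth = generate_cohort(CohortConfig(n_samples=100, seed=1))
calls = call_infiltration(cohort.expression, cohort.panel,
                          CallingConfig(n_permutations=999, seed=1))
```

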