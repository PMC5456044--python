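# smoketc

Time-course analysis of smoke-exposure transcriptome and metabolome data,
built around three exposure groups (AC = air control, CS = chronic smoke,
SS = smoke then cessation) sampled at 1 day, 7 days and 1/3/6/9 months:

- **Differential expression** (`smoketc.de_core`): TMM normalization,
  quantile-adjusted conditional-ML dispersion estimation (common + shrunken
  tagwise), the conditional negative-binomial exact test, BH adjustment and
  independent filtering on the overall mean normalized count. Significance
  = q <= 0.10 and |FC| >= 1.5 by default.
- **Gene-set enrichment** (`smoketc.enrich`): per-gene log2 ratios over all
  treatment x control sample pairs, set-vs-background t statistics per
  pair, correlation-corrected Stouffer combination, separate up/down calls
  with BH per direction, and core ("influential") gene extraction.
- **Cessation patterns** (`smoketc.patterns`): classification of month-9
  genes and pathways into reversible / semi-reversible / persistent /
  semi-persistent / continuing from the CS-vs-AC, SS-vs-CS and SS-vs-AC
  contrasts; recovery-gene detection; summary tables with per-pattern
  percentages.
- **Time trends** (`smoketc.trends`): orthonormal polynomial contrasts over
  the (unequally spaced) exposure days, per-gene OLS on log2 CPM, and a
  protected highest-order-first testing procedure assigning trend
  categories (interactions before main effects, BH within tier).
- **Metabolome concordance** (`smoketc.concord`): Welch t-tests on log2
  metabolite abundances (missing values handled explicitly), Fisher
  combination per pathway (min-p alternative reported alongside), and the
  pathway x time-point concordance grid restricted to pathways recurrent
  in the transcriptome.
- **Synthetic data** (`smoketc.simdata`): NB count generator with gene-wise
  dispersion and planted cessation patterns, trend categories,
  pathway-coherent set effects and mirrored metabolite shifts — every
  downstream stage has recoverable ground truth.
- **Pipeline** (`smoketc.pipeline`, `smoketc.cli`): one-command orchestration
  with TSV outputs, summary tables and a JSON manifest (seed, thresholds,
  per-output hashes) for byte-identical reruns.

## CLI

```sh
# synthetic inputs with planted truth
smoketc simulate --out sim --seed 1 --n-genes 2000

# one DE contrast
smoketc de --counts sim/counts.tsv --design sim/design.tsv \
    --contrast CS:AC --time 9mo --fdr 0.10 --min-fc 1.5 --out de_9mo.tsv

# gene-set enrichment
smoketc enrich --counts sim/counts.tsv --design sim/design.tsv \
    --sets sim/sets.gmt --contrast CS:AC --time 9mo

# protected trend testing, metabolome concordance
smoketc trends --counts sim/counts.tsv --design sim/design.tsv
smoketc concord --metabolites sim/metabolites.tsv --map sim/metabolite_map.tsv \
    --design sim/design.tsv --grid results/enrich_grid.tsv

# full pipeline from a YAML config (either a simulate: block or
# counts/design/gene_sets/metabolites paths)
smoketc run config.yaml --out results
```

Exit codes: 0 ok, 2 config error, 3 data error. Samples at the 1-month
time point are excluded by default (QC exclusion mirrored from the study
design); set `include_excluded_times: true` to keep them.

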