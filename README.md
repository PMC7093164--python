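# genecoord

Two-group **coordination analysis** of gene expression. Given a genes ×
samples expression matrix and a two-group sample design (a reference group,
e.g. `NOR`, and a condition group, e.g. `FRA`), the pipeline:

1. selects **highly expressed genes** — aggregated reads in the reference
   group at least `min_reads` (default 70, inclusive);
2. computes within-group **pairwise Pearson correlation** among those genes
   and per-group coherence summaries (mean R, mean |R|);
3. builds each selected gene's **transcriptome correlation profile** per
   group — its Pearson R against every other gene, over one shared
   background (genes constant in either group are excluded from both);
4. computes the **composite correlation Pc** per gene: the correlation
   between its reference-group and condition-group profiles. High Pc means
   coordination is retained across groups; low Pc means it is lost;
5. **ranks** genes by ascending Pc and selects the `bottom_k` and `top_k`
   seeds (ties break lexicographically; undefined Pc ranks last);
6. extracts each selected seed's **correlated gene set** per group
   (background genes with R strictly greater than `r_cutoff`, default 0.5);
7. runs a local **over-representation analysis** of each set against a GMT
   annotation (one-sided hypergeometric test, Benjamini–Hochberg FDR) and
   compares the resulting per-group "function" sets through the
   **Function Retention Index** (FRI = common ÷ condition functions) and
   **Function Acquisition Index** (FAI = new ÷ condition functions), plus
   the cross-seed common-term intersection.

A synthetic-data module generates two-group count matrices via a Gaussian
copula over negative-binomial marginals with block co-expression modules, an
optional global coherence amplification in the condition group, and a planted
set of "rewired" seed genes whose module membership changes between groups —
so the whole pipeline is verifiable offline by parameter recovery.

## CLI

```bash
# generate a synthetic dataset (counts.tsv, design.tsv, truth.json, annotation.gmt)
genecoord simulate --out sim/ --config sim.yaml        # YAML of SimulationConfig fields
genecoord simulate --out sim/ --seed 7                 # defaults with a seed override

# run the full analysis
genecoord run --counts sim/counts.tsv --design sim/design.tsv \
    --gmt sim/annotation.gmt --out run/ \
    --min-reads 70 --r-cutoff 0.5 --bottom-k 3 --top-k 3 --save-matrices

# export heatmaps, per-seed violin panels and the FRI/FAI chart
genecoord figures --report run/report.json --out figs/
```

`run` writes `pc_ranking.tsv` (ascending Pc), per-seed
`correlated_set_<gene>.tsv` and `profile_<gene>.tsv` tables, and a JSON
`report.json` (config echo, group sizes, coherence, FRI/FAI, common terms).
Outputs are byte-stable for fixed inputs. `--save-matrices` additionally
stores the per-group pairwise correlation matrices, which `figures` needs
for heatmaps. Counts may be plain TSV or a GEO series-matrix-style file
(`--dialect series_matrix`). Exit status is 0 on success and 1 with a
stage-named message otherwise.

## Library

```python
from genecoord import (AnalysisConfig, SimulationConfig, simulate_dataset,
                       transcriptome_profiles, composite_correlation,
                       rank_by_pc, run_pipeline)
```

Each pipeline stage is an importable function (`filter_high_expression`,
`pairwise_correlation`, `coherence_summary`, `extract_correlated_set`,
`overrepresentation`, `compare_functions`, ...). Undefined statistics are
explicit: `None` for scalars, NaN plus a mask in matrices.

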