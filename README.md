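# netmark

Network-based biomarkers from gene expression and protein-protein
interaction data.

Given a labelled expression matrix (cancer / non-cancer samples) and one
or more interaction tables, `netmark`:

1. selects a differential protein pool (one-way ANOVA, Bonferroni) and
   augments it with interactors highly connected to it;
2. builds a degree-bounded **rough PPI network** over the pool (maximum
   degree kept below the smaller group's sample size);
3. fits a per-protein linear association model within each phenotype
   (no-intercept Gaussian MLE on z-scored rows), refined by AIC-gated
   backward elimination plus a t-test prune, and assembles two symmetric
   **association networks** (cancer and non-cancer);
4. scores every protein by the row sum of absolute differences between
   the two networks and attaches an empirical p-value from a
   structure-permutation null (edge count preserved);
5. classifies new samples by comparing mapping errors `||z - A z||`
   against both networks (smaller error wins, ties go to non-cancer).

A first-class synthetic-fixture module generates ground-truth network
pairs and model-consistent cohorts so the whole pipeline is testable
offline, plus baselines (random-network accuracy, stratified
cross-validation, cohort similarity).

## CLI

All stages write deterministic plain-text tables into a run directory and
can resume from each other's artifacts. A YAML config file can supply any
option; explicit flags win.

```bash
# synthetic fixture bundle (expression.tsv, labels.tsv, ppi_edges.tsv, truth, manifest)
netmark simulate --out-dir runs/fix --seed 7 --shared-fraction 0.5

# full pipeline
netmark run-all \
    --expression runs/fix/expression.tsv --labels runs/fix/labels.tsv \
    --ppi runs/fix/ppi_edges.tsv --ppi-dialect edgelist \
    --out-dir runs/demo --n-permutations 100000 --seed 7

# or stage by stage
netmark pool  --expression ... --labels ... --ppi ... --out-dir runs/demo
netmark fit   --expression ... --labels ... --out-dir runs/demo
netmark score --expression ... --labels ... --out-dir runs/demo --seed 7
netmark diagnose --query-expression new_cohort.tsv --out-dir runs/demo
netmark evaluate --diagnosis runs/demo/diagnosis.tsv --out metrics.json
```

PPI dialects: `biogrid_tab2` (official-symbol columns), `hprd`
(tab-delimited flat file, symbols in columns 1 and 4), `edgelist`
(two-column). Readers are gzip-transparent; sources are merged with
per-pair provenance. Exit codes: 0 success, 2 input error, 3
contract/pipeline error.

`netmark score --refit-null --refit-reps 100` swaps the fast
redistribution null for full regression refits on each permuted
structure (a slow fidelity check).

## Paper-scale recipe (optional, database-version-dependent)

The published application used the GEO series GSE4115 (primary set: 79
cancer / 73 non-cancer smokers) with circa-2010 BioGRID and HPRD
snapshots. The resulting counts (199 differential proteins, 339-protein
pool, 399/393 associations, 40 significant proteins) depend on those
snapshots and are not reproducible bit-for-bit with current databases.
To run it anyway:

1. download the GSE4115 series matrix and a sample→label table, and map
   probes to gene symbols (e.g. via the GPL96 annotation) into a
   tab-delimited symbols × samples matrix;
2. download current BioGRID TAB2 (human) and/or an HPRD flat file;
3. run `netmark run-all --expression gse4115.tsv --labels labels.tsv
   --ppi biogrid.tab2.txt --ppi-dialect biogrid_tab2 --ppi hprd.txt
   --ppi-dialect hprd --out-dir runs/gse4115 --n-permutations 100000`;
4. compare `pool.txt`, `manifest.txt` counts and `crv.tsv` against the
   published tables, expecting qualitative (not exact) agreement.

A helper `read_geo_series_matrix` parses series-matrix files directly.

## Library layout

| module | contents |
| --- | --- |
| `netmark.expression` | `ExpressionMatrix`, readers, z-normalization, gene→protein overlay |
| `netmark.interactions` | `InteractionSet` and dialect parsers |
| `netmark.pool` | ANOVA differential table, pool selection, rough network |
| `netmark.inference` | association-model fits, AIC/t refinement, network assembly |
| `netmark.scoring` | difference matrix, relevance scores, permutation nulls |
| `netmark.diagnosis` | mapping errors, classification, metrics, baselines, CV |
| `netmark.synthetic` | ground-truth generators and fixture bundles |
| `netmark.experiments` | seeded end-to-end experiments used by tests and the report |
| `netmark.cli` | click CLI |
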