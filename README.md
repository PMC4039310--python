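# oncoint

Interactome-perturbation analysis toolkit: assemble a bait–prey network
from TAP-MS peptide evidence, score phospho-site perturbation from
spectral counts, extend the network through a protein–protein interaction
reference, identify a multi-cell-line "core" dependency network from RNAi
viability screens, filter and rank drug–target records over that core,
and score drug-pair synergy with the Chou–Talalay combination index.

Every pipeline input can be generated synthetically with planted ground
truth (`oncoint.synthetic_data`), so the full analysis is testable
offline without any proteomics downloads.

## Modules

| module | what it does |
|---|---|
| `synthetic_data` | seeded generators for evidence/manifest tables, phospho counts, PPI graphs, viability screens, drug-affinity and dose–response tables, each with a `GroundTruth` record |
| `tap_assembly` | isoform collapsing, shared-peptide protein grouping, GFP-control subtraction, bait–prey network construction, annotation filtering |
| `phospho_perturb` | per-state 1-df Pearson χ² P-values, product score with inclusive 0.1 cutoff, PPI-based network extension |
| `rnai_screen` | control-well normalization, >50%-inhibition + t-test hit calling, core-network intersection, pair overlap, resistant-gain search, Wilcoxon rank-sum specificity (exact null for small groups), Spearman concordance, heatmaps |
| `drug_network` | per-source affinity cutoffs (Kd < 100 nM; BindingDB < 10 nM, strict), allele matching, bipartite drug–protein networks, exponential-decay shortest-path diffusion ranking |
| `synergy` | median-effect fitting (log-odds least squares) and combination index (mutually exclusive form); CI < 1 ⇒ synergy |
| `workflow` | TSV/GraphML/SIF/PSI-MITAB I/O, YAML pipeline config, deterministic end-to-end demo runner |

## CLI

```sh
# generate all synthetic inputs with planted truth
oncoint simulate --seed 1 --outdir data/

# TAP network from evidence + manifest
oncoint tap build --evidence data/evidence.tsv --manifest data/pulldowns.tsv \
    --out net.graphml --min-peptides 2

# phospho scoring and PPI extension
oncoint phospho score --counts data/phospho_counts.tsv --threshold 0.1 --out sites.tsv
oncoint phospho extend --net net.graphml --sites sites.tsv --ppi data/ppi.tsv \
    --out net_ext.graphml

# screen analysis
oncoint screen hits --in data/screen.tsv --out hits.tsv
oncoint screen core --hits hits.tsv --lines M01,M02,M03 --out core.txt
oncoint screen specificity --in data/screen.tsv --meta data/screen_meta.tsv --out spec.tsv

# drug network and diffusion ranking
oncoint drugnet filter --records data/drug_records.tsv --out filtered.tsv
oncoint drugnet build --records filtered.tsv --core core.txt --out drugnet.graphml
oncoint drugnet rank --net net.graphml --screen kinase_screen.tsv --alpha 0.5 --out rank.tsv

# synergy
oncoint synergy fit --in data/dose_response.tsv --out fits.tsv
oncoint synergy ci --in data/dose_response.tsv --drug1 DR1 --drug2 DR2 \
    --combo DR1+DR2 --ratio 1:1 --out ci.tsv

# end-to-end demo (simulate -> ... -> synergy) from a YAML config
oncoint run --config demo.yaml
```

A minimal `demo.yaml`:

```yaml
outdir: demo_out
phospho_threshold: 0.1
simulation:
  seed: 1
  n_baits: 8
  screen_n_lines: 17
  screen_n_mutant: 5
```

## Determinism

All randomness flows from a single seed through named
`numpy.random.SeedSequence` streams: one stream per generator, so adding
a generator never changes another's output, and two runs with the same
config produce byte-identical tabular outputs.
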