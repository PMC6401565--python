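# metnetprio

Candidate-metabolite prioritization on a heterogeneous
gene–metabolite–phenotype network via random walk with restart (RWR).

The pipeline integrates six weighted edge sets — gene–gene, metabolite–
metabolite, phenotype–phenotype, gene–metabolite, gene–phenotype and
metabolite–phenotype — into one three-layer network, derives a
column-stochastic transition model with a configurable cross-layer jump
probability, runs RWR from disease seed genes and a disease phenotype, and
ranks candidate metabolites. The gene layer can be restricted to
differentially expressed genes called from a two-group expression matrix
(per-gene t-test with Benjamini–Hochberg FDR). Reporting includes the
top-metabolite subnetwork, the top co-expressed genes (genes adjacent to
ranked metabolites, ordered by walk score) and unweighted degree tables.

A synthetic-data module generates three-layer networks with a planted
"disease neighborhood" (seed genes wired to a disease phenotype and to
true-positive metabolites) and expression matrices with planted
differential genes, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic input bundle with planted ground truth
metnetprio simulate --out-dir inputs --seed 1

# call differential genes
metnetprio deg --expression inputs/expression.tsv --labels inputs/labels.tsv \
    --out degs.tsv

# assemble the network, walk, rank, report
metnetprio build-net --in-dir inputs --out nodes.tsv
metnetprio rank --in-dir inputs --seeds inputs/seeds.tsv --out-dir ranked
metnetprio report --in-dir inputs --ranking ranked/metabolite_ranking.tsv \
    --seeds inputs/seeds.tsv --out-dir report

# or the whole pipeline from a flat key=value config file
metnetprio run-all --config run.cfg --out-dir results
```

A config file lists input paths and parameters, one `key = value` per line
(keys are the fields of `metnetprio.pipeline.PipelineConfig`), e.g.:

```
edges_gg = inputs/edges_gg.tsv
edges_mm = inputs/edges_mm.tsv
edges_pp = inputs/edges_pp.tsv
edges_gm = inputs/edges_gm.tsv
edges_gp = inputs/edges_gp.tsv
edges_mp = inputs/edges_mp.tsv
seeds = inputs/seeds.tsv
expression = inputs/expression.tsv
labels = inputs/labels.tsv
min_combine_score = 0.8   # gene-gene confidence cutoff
beta = 0.7                # restart probability
lambda_jump = 0.5         # cross-layer jump probability
```

`run-all` writes the DEG table, node table, per-node scores, metabolite
ranking, co-expressed gene list, subnetwork edge lists, degree tables and a
`manifest.json` (parameters, input checksums, iteration count, convergence
flag). Runs are deterministic: the same inputs and configuration give
byte-identical outputs.

## File formats

All files are UTF-8 TSV. Edge sets use a `#part=<tag>` header followed by
`node_a  node_b  weight` rows; the pipeline also accepts raw source
dialects (3-column scored files for gene/metabolite interactions — scores
are divided by `score_scale`, e.g. 1000 for 0–1000 confidence integers —
and 2-column pair files for the unit-weighted phenotype associations).
Seeds are two-column `kind  node_id` rows with kind in
gene/phenotype/metabolite. Expression matrices have gene IDs in column 1
and sample IDs in the header row, with a separate two-column
sample-ID/group label file.

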