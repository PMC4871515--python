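# mstmc

Statistical model checking of multiscale spatio-temporal simulation
traces.  `mstmc` evaluates probabilistic bounded temporal-logic
statements (`P > 0.99 [ G[0, 95] (...) ]`) against timed traces of
multilevel models, detecting and quantifying emergent spatial entities
(regions, clusters) in discretised spatial data along the way.

## Components

| module | purpose |
| --- | --- |
| `mstmc.magraph` | rooted-tree architecture graph of `scale.subsystem` vertices with the partial orders `<` and `<=` |
| `mstmc.traces` | trace data model, XML trace format reader/writer, CSV ingestion of raw simulator output |
| `mstmc.registry` | configurable registry of spatial entity types and measures (XML-configurable) |
| `mstmc.spatial` | region detection (8-connected, thresholded), DBSCAN clustering of regions, eleven spatial measures |
| `mstmc.logic` | parser and sample-based evaluator for the bounded spatio-temporal logic |
| `mstmc.checkers` | five verdict algorithms: exact-binomial black-box, Chernoff-bound estimation, Wald SPRT, Bayesian mean/variance, Bayes factor; on-demand trace generation |
| `mstmc.fixtures` | built-in test inputs: an exactly-enumerable toy cell model, synthetic shape grids, Bernoulli streams |
| `mstmc.cli` | `mstmc` command-line entry point |

## CLI

Generate five seeded traces of the built-in toy model and verify a
specification against them:

```sh
mstmc fixtures toy --n 5 --seed 7 --out traces/
cat > spec.pblmstl <<'EOF'
P > 0.9 [F[0,3] ({Energy}(scaleAndSubsystem =
    Intracellular.EnergyProductionReactionNetwork) > 0)]
EOF
mstmc check --spec spec.pblmstl --traces traces/ \
    --ma-graph traces/ma_graph.ma.xml --checker blackbox -o report.csv
```

The report is CSV (statement, holds, estimate, `n_total`/`n_true`/
`n_false`, confidence quantity) with a JSON sidecar.  Other subcommands:
`analyse` (grid CSVs → entity-annotated trace document), `validate`
(structural checks of trace/graph/config XML), and `check --generator
'<command>'` for on-demand trace generation (the command is invoked with
an output directory and must create one new trace file per call).

Checker parameters: `--epsilon/--delta` (chernoff),
`--alpha/--beta/--half-width` (sprt), `--prior-alpha/--prior-beta` plus
`--variance-threshold` (bayes-estimate) or `--bf-threshold`
(bayes-factor).

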