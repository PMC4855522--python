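# wmem

Exact solver and analysis pipeline for the **weighted mutually exclusive
maximum set cover** problem: given a universe of elements and a family of
weighted sets, find a pairwise-disjoint subfamily that covers as many
elements as possible and, among those, has the minimum total weight.

The package also ships the tumor-cohort pipeline that produces such
instances from somatic-alteration data: valid-SGA calling from mutation /
GISTIC / expression matrices, signature-based tumor partitioning into
abnormal (S_p) and normal-like (S_n) subsets, hypergeometric gene
weighting, candidate selection, and enrichment scoring of solved modules —
plus seeded synthetic-data generators so every stage is testable offline.

## Layout

- `src/wmem/instance_model.py` — instances, intersection graph, solutions,
  the "better solution" ordering.
- `src/wmem/exact_solver.py` — branch-and-bound solver (`solve`), the
  polynomial degree-≤2 component solver, the degree-3 branching rule, and a
  brute-force oracle; search-tree instrumentation (`SearchStats`).
- `src/wmem/sga_preprocess.py` — cohort → partition → weights → instance.
- `src/wmem/evaluation.py` — module enrichment p-values (−log2 reported).
- `src/wmem/synthetic_data.py` — random / graph-realized / planted solver
  instances and full synthetic cohorts with planted drivers.
- `src/wmem/cli_io.py`, `src/wmem/cli.py` — file dialects, YAML config,
  and the `wmem` command-line interface.

## CLI

```sh
# generate a synthetic cohort with 4 planted mutually exclusive drivers
wmem simulate cohort --seed 1 --out-dir sim/

# full per-signature pipeline: preprocess -> solve -> evaluate
wmem run-all --mutations sim/mutations.tsv --gistic sim/gistic.tsv \
    --expression sim/expression.tsv --samples sim/samples.tsv \
    --signatures sim/signatures.gmt --out-dir out/

# solve a standalone instance (TSV: set_id<TAB>weight<TAB>e1,e2,...)
wmem solve --instance out/SIG_MAIN.instance.json --out report.json --oracle-check
```

`wmem preprocess`, `wmem evaluate`, and `wmem simulate instance` expose the
individual stages; `--config cfg.yaml` overrides any pipeline threshold
(see `RunConfig` in `cli_io.py` for keys and defaults).

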