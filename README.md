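# mon

Essential-protein ranking on multiplex biological networks.

`mon` builds a three-layer multiplex network over the proteins of a
physical interaction network — a **co-neighbor** layer (squared
common-neighbor counts normalized by degrees), a **co-structure** layer
(products of min–max-normalized inverse-domain-frequency scores), and a
**co-expression** layer (absolute Pearson correlation of expression time
courses) — and scores proteins with a coupled random walk with restart
on the network's third-order tensor. The walk jointly estimates a
node-score vector `x` and a layer-importance vector `y`: nodes diffuse
through layers weighted by `y`, and each layer's importance is
re-estimated from the edge mass the current `x` places on it. The
restart distribution blends a conservative score (max-normalized
ortholog counts) with an externally supplied modular score, controlled
by `beta`; `alpha` is the walk/restart mixing weight (defaults
`alpha = 0.3`, `beta = 0.5`). Rankings are evaluated against a benchmark
essential-protein list via top-K precision, precision–recall curves,
jackknife curves, seeded random baselines, and ranking-overlap reports.

## Command line

All inputs are flat tab-separated text: a two-column interaction edge
list (defines the protein universe; self-interactions and duplicates are
dropped), a (protein, domain) membership table, an expression matrix
(gene id + numeric time points per row), a (protein, homolog-count)
table, an optional (protein, score-in-[0,1]) modular-score table, and a
one-id-per-line essential-protein list.

```sh
# generate a synthetic bundle with planted essentiality signal
mon simulate --seed 7 --outdir bundle/

# score and rank proteins (writes OUT.tsv + OUT.tsv.meta.yaml sidecar
# with layer importances, iterations, and the final residual)
mon rank --ppi bundle/ppi.tsv --domains bundle/domains.tsv \
    --expression bundle/expression.tsv --orthologs bundle/orthologs.tsv \
    --modular-scores bundle/modular_scores.tsv \
    --alpha 0.3 --beta 0.5 -o scores.tsv

# evaluate against the benchmark list
mon evaluate --ranking scores.tsv --essential bundle/essential.txt \
    --topk 20,50,100 --curves-out curves/
```

`mon simulate --config cfg.yaml` accepts a YAML file overriding any
generator knob (`n_proteins`, `n_modules`, `p_within`, `rho`,
`ortholog_shift`, ...); `--seed` overrides the config seed.

## Python API

```python
from mon import SyntheticConfig, generate, mon_rank, Benchmark, topk_precision

bundle = generate(SyntheticConfig(seed=1))
ranking = mon_rank(bundle.pin, bundle.domains, bundle.expression,
                   bundle.orthologs, ms=bundle.modular_scores)
print(topk_precision(ranking, bundle.benchmark, 20))
```

Lower-level pieces (`build_co_neighbor`, `build_transition_tensors`,
`run_rwr`, `pr_curve`, ...) are exported from `mon` as well.

## Layout

- `src/mon/network.py` — universe, interaction graph, domain/expression
  tables, the three layer builders, multiplex assembly.
- `src/mon/tensor.py` — sparse adjacency tensor, fiber-normalized
  transition tensors (uniform fallbacks handled in closed form), and the
  coupled walk.
- `src/mon/ranking.py` — restart vector assembly and the full pipeline.
- `src/mon/evaluation.py` — benchmark scoring and curves.
- `src/mon/simulate.py` — synthetic input generator with planted signal.
- `src/mon/io.py`, `src/mon/cli.py` — flat-file readers/writers and the
  `mon` command-line tool.
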