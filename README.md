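# omicsfusion

Anticancer drug response varies widely between tumours because their
molecular profiles differ. `omicsfusion` predicts a cancer cell line's
log IC50 response to a panel of drugs from several omics measurements at
once — mRNA expression, gene mutations, copy-number variation (CNV), RPPA
protein expression and metabolomics — using a deep network that builds one
sub-network per omics block and fuses them with a drug-specific attention
layer. It is aimed at computational pharmacogenomics work on cell-line
screens (CCLE/GDSC-style data), and ships a synthetic multi-omics generator
with a planted signal so the whole pipeline can be exercised and validated
without any downloads.

## The model

For omics block *m* with features *x<sub>m</sub>*, the sub-network is

```
y¹_m = f((W¹_m · A_m)ᵀ x_m + b¹_m)      graph embedding (interactome mask)
y¹_m = f((W¹_m)ᵀ x_m + b¹_m)            dense embedding (no interactome)
y²_m = f((W²_m)ᵀ y¹_m + b²_m)           hidden dense layer
h_m  = (Wʰ_m)ᵀ y²_m + bʰ_m              linear head, one output per drug
```

where `A_m` is the binary protein–protein interaction (PPI) adjacency over
the block's features (with self-loops) and `·` is the element-wise product:
each hidden unit of a graph embedding only sees features that interact with
it, a sparse connection informed by the interactome. `f` is the rectifier.

The M heads (each of size n_d, the drug count) are concatenated and fused by
an attention layer with raw weights `W³(d, m, i)` and a "kill matrix"
`k(d, i) = 1 iff d = i`:

```
W(d, m, i) = exp(W³(d,m,i)) · k(d,i) / Σ_m exp(W³(d,m,i))
ŷ_d        = Σ_m W(d, m, d) · h_m[d] + b_d
```

so drug *d*'s prediction is a convex combination of the per-omics
predictions for drug *d*, plus a bias. The normalized diagonal weights
`W(d, m, d)` are the per-omics **attention scores**: they sum to one over
omics and quantify how much each omics type contributes to each drug.

Training is two-stage: each sub-network is first fitted alone to all drug
responses (masked MSE, Adam); then every sub-network is frozen and only the
attention weights and output bias are learned. Evaluation uses MSE, the
per-drug-averaged coefficient of determination

R² = (1/n_d) Σ_j [ 1 − Σ_i (y_ij − ŷ_ij)² / Σ_i (y_ij − ȳ_j)² ],

and Top-1/Top-3 drug accuracy: the rate at which the truly most effective
drug (lowest observed log IC50) appears among the 1 or 3 lowest predicted
values.

## Worked example

```python
from omicsfusion import (DrugResponseModel, SimulationConfig,
                         TrainingConfig, simulate_dataset)

sim = SimulationConfig(
    n_cells=300,
    feature_counts={"expression": 60, "mutation": 80, "cnv": 40},
    embedding_kinds={"expression": "graph", "mutation": "graph", "cnv": "graph"},
    dominant_omics="mutation", dominance=0.9,
    n_drugs=10, noise_sd=0.3, missing_rate=0.03, seed=7,
)
dataset, truth = simulate_dataset(sim)

config = TrainingConfig(default_dropout=0.0,
                        dropout={"expression": 0.0, "mutation": 0.0, "cnv": 0.0},
                        early_stopping=True)
model = DrugResponseModel(dataset, config)
results = model.fit(seed=0)
print(results.summary())
cv = model.cross_validate(seed=0)
print(cv.summary())
```

prints

```
                 Multi-omics drug response fusion model
========================================================================
No. cell lines: 300      No. drugs: 10       Omics blocks: 3
Optimizer: Adam (lr=0.001)   Seed: 0
Epochs: graph 200 / dense 1000 / attention 200
------------------------------------------------------------------------
Training MSE: 0.2040   R2: 0.8096   Top-1: 65.3%   Top-3: 90.0%
------------------------------------------------------------------------
omics         embedding   n_feat  hidden  dropout    mean attention
expression    graph           60      64     0.00             0.096
mutation      graph           80      32     0.00             0.818
cnv           graph           40      32     0.00             0.086
========================================================================

cross-validation (mean +/- sd over folds)
  mse         0.5533 +/- 0.0772
  r2          0.4837 +/- 0.0399
  top1        48.6667 +/- 3.5119
  top3        79.0000 +/- 4.0000
```

The simulation planted 90% of the response signal in the mutation block, and
the fitted attention scores recover exactly that: mutation receives a mean
attention of 0.82, the other blocks split the rest. The cross-validation
block reports held-out performance (3 folds; standardization and both
training stages are fitted on training cells only).

`results.attention_scores_` is the (omics × drugs) score table,
`results.plot_attention("attention.png")` draws the heatmap,
`model.ablate(seed=0)` trains one attention stage per omics combination and
returns the combinations ranked best-first, and `results.save("ckpt/")`
writes a checkpoint that reloads bit-identically.

## Command line

Every step is also available as a subcommand over the same config file:

```
omicsfusion simulate --config config.yaml --seed 1 --out data/
omicsfusion train    --config config.yaml --seed 1 --out run/
omicsfusion evaluate --checkpoint run/checkpoint --config config.yaml --out eval/
omicsfusion ablate   --config config.yaml --seed 1 --out ablation/
omicsfusion attention-report --checkpoint run/checkpoint --out report/
```

Inputs are tab-separated matrices (rows = cell lines), a two-column PPI edge
list, and a response table with `NA` for untested drug/cell pairs. Each run
writes a `manifest.json` with the config snapshot, seed and input digests.

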