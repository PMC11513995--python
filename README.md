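# metagraph-soc

Predicting soil organic carbon (SOC, g kg⁻¹) from shotgun metagenomes by
linking each sample's microbial **species** to the **gene functions** (KEGG
orthologues, "K-numbers") their reads map to, representing every sample as a
weighted taxon–function graph, and regressing SOC on those graphs with a deep
graph convolutional network. A bespoke node-pair permutation importance
("impact score") then asks, for every species–function edge, how much the
model's prediction moves when that edge's weight is swept between its lowest
and highest value observed across the cohort — pointing at species whose
*genome content* (gene presence/absence, "genome streamlining") tracks carbon
stocks, not just their abundance.

The package is aimed at microbiome researchers who want to move beyond
abundance-only models: it covers the whole chain from multi-tool per-read
annotations to an interpreted graph model, plus a classic tabular-ML harness
for comparison, and a synthetic cohort generator so everything runs and is
testable without any sequencing download.

## What is inside

| module | role |
|---|---|
| `metagraph.synthetic` | synthetic metagenome cohorts with planted SOC signal and ground truth |
| `metagraph.annotation` | longest-mapping merge of multi-tool read annotations; count matrices; species–function read-pair counts |
| `metagraph.abundance` | CPM normalisation, rarefaction, alpha diversity (richness, Chao1, Pielou, Shannon, Simpson, Hill numbers q=0,1,2) |
| `metagraph.graphs` | per-sample `source,target,weight` edge lists and graphs at large/mid/small scale with 2-bit node features |
| `metagraph.dgcnn` | the 10-stage graph attention + graph convolution regressor, 85/15 split (random state 40), 5-fold CV, L1 training |
| `metagraph.impact` | impact scores, pair grouping, coverage-vs-SOC contrast, local explanations |
| `metagraph.baseline` | min–max scaling, univariate-F feature reduction schedule, scikit-learn regressors, MAE as % of target range |
| `metagraph.pipeline` / CLI `metagraph` | one-command orchestration with a reproducibility manifest |

The regression model is

> x⁽ˡ⁺¹⁾ = σ(GAT(x⁽ˡ⁾, A)) for four attention stages (2→32→32→32→128, one
> head), a weighted GCN stage (128→128), a node-wise max readout to one
> 128-vector per graph, a 128→128 transform, then dense 128→32→1,

trained with Adam (lr 0.001, decoupled weight decay 0.1, 100 epochs, batches
of 32) on L1 loss. Edge weights are species–function read-pair counts;
habitat nodes carry long-term environment values (20-year temperature and
soil-water means) on their edges.

## Worked example

```python
import numpy as np
from metagraph import (SyntheticConfig, generate_samples, GraphScale,
                       ModelConfig, train, impact_scores)
from metagraph.graphs import build_sample_graphs

cfg = SyntheticConfig(seed=1)          # 200 samples, SOC in 8-392 g/kg
_, _, _, pairs, meta, truth = generate_samples(cfg)

allow = [s for s, _ in truth.predictive_species] + [s for s, _ in truth.streamlined_pairs]
central = {f for _, f in truth.streamlined_pairs}
graphs = build_sample_graphs(pairs, meta, GraphScale.small(allow),
                             central_carbon_set=central)

model, report = train(graphs, ModelConfig(init_seed=1))
print(f"test MAE {report.test_mae:.1f} g/kg, CV MAE {report.cv_mean_mae:.1f} (SD {report.cv_sd_mae:.1f}), r {report.pearson_r:.2f}")

table = impact_scores(model, graphs)
print(table[["source", "target", "mean_impact", "rank"]].head(3).to_string(index=False))
```

Output from this exact run:

```
test MAE 38.9 g/kg, CV MAE 39.0 (SD 4.3), r 0.67
       source target  mean_impact  rank
Genus06 sp001 K00040    70.363182     1
Genus09 sp004 K00030     5.324893     2
Genus05 sp004 K00008     2.505822     3
```

The held-out MAE beats the predict-the-training-mean null model (53.2 g/kg
on this split), and the two top-ranked node pairs are exactly the two
genome-streamlined species–function pairs the generator planted
(`truth.streamlined_pairs`): samples lacking coverage of those functions were
simulated with lower SOC, and the interpreter recovers them. Interpretation
is seed-sensitive at this cohort size — on some initialisations a planted
pair's learned response inverts in sign (see `docs/methods.md`, Known
limitations) — which is why the stochastic checks in the test suite run
three seeds and require a majority.

The same flow is available from the shell:

```bash
metagraph run --out runs/demo          # simulate -> merge -> graphs -> train -> explain
metagraph simulate --out data --seed 1
metagraph merge --assignments data/read_assignments.tsv \
    --out-taxa taxa.csv --out-functions funcs.csv --out-pairs pairs.csv
```

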