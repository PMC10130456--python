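# mediatornet

Signature, network and multivariate analysis of multiplex serum
soluble-mediator panels in case-control pregnancy cohorts.

`mediatornet` is written for immunology groups profiling circulating
chemokines, cytokines and growth factors — here a fixed 27-plex bead-array
panel — in pregnant women with convalescent COVID-19 (COVID) against
trimester-matched healthy controls (HC). It implements the complete
analysis chain on top of pandas/scipy/networkx/scikit-learn, and ships a
Gaussian-copula cohort simulator so every stage runs and is testable
without access to patient data.

## The method

For each analyte *m* with concentration *x* (pg/mL), samples are
standardized as *z = (x − μ<sub>ref</sub>) / σ<sub>ref</sub>* over a
reference population (HC+COVID combined by default). The **cut-off** for
*m* is the median HC Z-score (pooled across trimesters, or
trimester-matched), and the **signature** of a subgroup is the percentage
of its subjects strictly above the cut-off — >50% flags an analyte as
increased, <50% decreased, =50% unaltered. The per-trimester ratio
%COVID/%HC is binned as decreased (≤0.3×), unaltered (0.4–2×) or
increased (≥3×).

**Networks** connect analyte pairs with strong significant correlations:
|ρ| ≥ 0.67 and p < 0.05 (Spearman by default; Pearson recorded alongside,
with exact permutation p-values when a subgroup has ≤9 samples).
Connectivity is counted as summed node degree per mediator category
(chemokines C, pro-inflammatory PROc, regulatory REGc, growth factors GF),
so the four category counts add up to twice the edge count. **Hubs** are
analytes with ≥5 edges; trimester-matched hub sets decompose into
*preserved* (HC∩COVID), *lost* (HC∖COVID) and *acquired* (COVID∖HC).
PCA scores on the PC2/PC3 plane summarise HC/COVID separation, and
univariate contrasts use Kruskal–Wallis + Dunn (within-group trimester
trajectories) and Mann–Whitney (HC vs COVID per trimester), all at p<0.05.

The simulator draws each subgroup from a Gaussian copula: target Spearman
matrices (with planted hub cliques, repaired to the PSD cone) are
converted to latent Pearson correlations via r = 2·sin(πρ/6), then pushed
through log-normal marginals with trimester trends and COVID fold changes
up to 15×.

## Worked example

```python
from mediatornet import (SubgroupKey, build_edges, connectivity,
                         correlation_matrix, generate_cohort, hub_set,
                         paperlike_config, venn_classify)

cohort = generate_cohort(paperlike_config(seed=1))   # 141 samples
hubs = {}
for group in ("HC", "COVID"):
    records = correlation_matrix(cohort, SubgroupKey(group, 3))
    network = build_edges(records, rule="spearman")
    print(group, connectivity(network).total_connections)
    hubs[group] = hub_set(network, k=5)
venn = venn_classify(hubs["HC"], hubs["COVID"], trimester=3)
print(sorted(venn.acquired))
```

prints

```
HC 154
COVID 42
['CCL2', 'CXCL8', 'IL-6']
```

i.e. the healthy 3rd-trimester network carries 154 strong correlations
against 42 in COVID, and IL-6, CXCL8 and CCL2 are COVID-selective hubs —
analytes that acquire ≥5 strong correlations only in the patient group.
The `examples/` directory has one short script per capability
(simulation, signatures/ratios, networks/hubs, PCA/tests, full pipeline);
each prints the numbers it computes with a note on what they mean.

A thin CLI wraps the pipeline:

```sh
mediatornet simulate --seed 1 --out cohort.csv
mediatornet analyze --input cohort.csv --outdir bundle
mediatornet report bundle
```

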