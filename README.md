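# drugmod

Network modules of drug sensitivity from pharmacogenomic cell-line
panels.

## The problem

Correlating the basal expression of every gene with the potency of
every drug across a panel of cancer cell lines yields transcriptional
*signatures* of drug sensitivity — but these signatures run to hundreds
of genes, mix mechanism with unspecific determinants (efflux pumps,
extracellular-matrix programs, tissue of origin), and are hard to
interpret or transfer between screening platforms. `drugmod` condenses
them into compact, network-coherent **drug modules**: per-drug gene
sets that are both correlated with the drug's response and strongly
interconnected on a protein-interaction network, so that they can be
related to mechanisms of action, compared to each other with network
distances, and used as gene sets in ordinary enrichment analyses.

It is written for computational biologists working with panels in the
GDSC/CTRP style: a log2 expression matrix (genes × cell lines), a
potency matrix (1−AUC, drugs × cell lines, missing values allowed), a
cell-line→tissue annotation, a STRING-style weighted interactome, and a
GMT pathway collection.

## The method in brief

For each drug–gene pair the panel yields a variance-stabilized
correlation

    z_cor = atanh(r) · sqrt(n − 3),

with `r` the Pearson correlation between basal expression and potency
over the `n` cells measured for that drug; |z_cor| > 3.2 defines the
positively / negatively correlated genes (PCGs / NCGs). After removing
*frequently correlated genes* (the 5% of genes correlated with
unusually many drugs) and genes outside GSEA-enriched pathways
(weighted Kolmogorov–Smirnov statistic on the z_cor ranking,
permutation p < 0.01), the surviving genes are placed as heat
h = |z_cor| on the interactome and diffused with the insulated operator

    F = β (I − (1−β) W)⁻¹,        E(i,j) = F(i,j) · h(j),

(β = 0.4, `W` the column-normalized adjacency). Thresholding the
exchanged heat `E` and extracting strongly connected components of ≥5
genes — the HotNet2 construction, iterated with a permutation
significance test — gives the positively / negatively correlated
modules (PCMs / NCMs); DIAMOnD expansion then recalls strongly
correlated genes that no pathway covered. Modules are characterized by
DIAMOnD-rank proximity of drug targets, size-normalized Menche network
distances between modules (d_net; negative = proximal), a GSEA-score
response predictor (AUROC against the top-n most sensitive lines), and
Fisher-exact / patient-level enrichment analyses.

Everything is validated on synthetic panels with planted ground truth;
`drugmod.synthetic` generates interactomes with planted communities,
linear-Gaussian expression/response panels, a confounded tissue,
promiscuous genes and pathway collections. See `docs/methods.md` for
the full model and all conventions.

## Worked example

```python
from drugmod import synthetic
from drugmod.model import DrugModuleModel, PipelineConfig

g, truth = synthetic.generate_interactome(n_nodes=700, n_planted=3,
                                          module_size=22, seed=7)
panel = synthetic.generate_panel(truth, n_cells=180, seed=7)
pathways = synthetic.generate_pathways(truth, universe=sorted(g.nodes()),
                                       seed=7)

model = DrugModuleModel(panel.expression, panel.response, panel.tissues,
                        g, pathways, targets=truth.planted_targets,
                        config=PipelineConfig(min_cells=100,
                                              drop_tissues="flagged"))
results = model.fit(seed=7)
print(results.summary())
```

prints

```
Drug module detection results
================================================================
cells: 157    genes: 550    drugs: 3
flagged tissues: T1
frequently correlated genes: 3 positive, 0 negative
drugs with a first PCM: 2    with a first NCM: 1
----------------------------------------------------------------
        n_pcg  n_ncg  n_pcg_filtered  n_ncg_filtered  pcm_size  pcm2_size  ncm_size  ncm2_size
drug01     26      4              18               0        18          0         0          0
drug02      3     25               0              18         0          0        18          0
drug03     26      3              18               0        18          0         0          0
```

The panel planted three 22-gene co-expression modules; the confounding
tissue T1 (globally shifted potency) was flagged and dropped, the three
promiscuous genes came out as frequently correlated, and each drug's
signature (≈26 significant genes) was condensed to an 18-gene network
module in the planted direction. The modules retain predictive power —
`results.evaluate_prediction(top_n_values=(25, 50))` ranks cell lines
by module enrichment score and scores them against the most sensitive
lines:

```
  drug     mode  top_n    auroc
drug01 pcm_only     25 0.882481
drug01 pcm_only     50 0.874808
drug02 ncm_only     25 0.932333
drug02 ncm_only     50 0.884421
drug03 pcm_only     25 0.869180
drug03 pcm_only     50 0.836907
```

`results.target_proximity()`, `results.module_distances()` and
`results.gene_set_enrichment()` expose the remaining analyses; the
`drugmod` command-line tool (`drugmod simulate`, `drugmod fit`,
`drugmod correlate`, ...) wraps the same pipeline for file-based use.

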