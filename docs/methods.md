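# Methods

This note describes the statistical machinery implemented in `drugmod`,
the choices made where the method leaves room, and what the synthetic
benchmark does and does not establish.

## Overview

`drugmod` turns a pharmacogenomic cell-line panel — basal expression
(genes × cell lines, log2), drug potency (1−AUC, drugs × cell lines) and
a tissue annotation — into compact, network-coherent *drug modules*:
per-drug, per-direction gene sets that are both correlated with the
drug's potency and strongly interconnected on a protein-interaction
network. The pipeline is:

1. **Panel cleaning.** Genes expressed below a log2 floor of 4.4 in
   (almost) all cells are removed; drugs measured in too few cell lines
   are dropped; tissues whose cells show unspecific sensitivity to every
   drug are flagged by a PCA diagnostic and can be excluded.
2. **Drug–gene correlations.** For each drug–gene pair, Pearson's r
   between basal expression and potency over the cells with a
   measurement, Fisher-transformed and scaled:
   `z_cor = atanh(r)·sqrt(n−3)`. The scaling variance-stabilizes the
   statistic so that drugs measured in different numbers of cells are
   comparable; under the null `z_cor ~ N(0,1)`, and the significance
   cutoff |z_cor| > 3.2 corresponds to a two-sided tail of ≈1.4×10⁻³.
   Genes beyond the cutoff are PCGs (positive) / NCGs (negative).
3. **Frequently correlated genes (FCGs).** Per gene and sign, the number
   of correlated drugs is counted; genes whose count strictly exceeds
   the 95th percentile of the count distribution (over genes correlated
   with ≥1 drug) are unspecific and removed.
4. **Pathway filter.** A weighted Kolmogorov–Smirnov GSEA is run on each
   drug's full z_cor ranking against a pathway collection (sets of ≥5
   genes); significant genes that belong to at least one enriched
   pathway (permutation p < 0.01, ES sign matching the direction)
   survive.
5. **Module detection.** Insulated heat diffusion in the HotNet2 style:
   `F = β(I − (1−β)W)⁻¹` on the interactome's largest connected
   component, with `W` the column-normalized adjacency and restart
   probability β = 0.4. Heat is |z_cor| on the filtered genes; exchanged
   heat `E(i,j) = F(i,j)·h(j)` is thresholded at δ and strongly
   connected components of size ≥5 are extracted. δ is the median, over
   heat permutations, of the smallest threshold at which the largest
   permuted component falls below 5; a component is accepted if its
   size is matched or beaten by at most 5% of heat permutations
   (add-one correction). Accepted genes are removed and the loop
   repeats; the first two accepted modules per drug/direction are kept.
6. **DIAMOnD recall.** Correlated genes missed by the pathway filter
   (because no pathway covers them) are recalled if they sit within the
   top 200 DIAMOnD-closest genes to the module; DIAMOnD greedily adds
   the node with the most significant hypergeometric connectivity
   `P(X ≥ k_s)`, `X ~ Hypergeom(N−1, s₀, k)`, with ties broken by
   higher `k_s`, then lexicographic gene id.

Downstream, the modules are characterized by: DIAMOnD-rank proximity of
drug targets (median target rank, decile of the ranked list, empirical
percentile against background gene sets); pairwise network distances
with a bespoke size-matched normalization (below); a GSEA-score response
predictor evaluated by AUROC; Fisher-exact enrichment in gene-set
collections; and patient-level module calls with driver-mutation
association.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| expression floor | 4.4 log2 units | minimum informative expression |
| keep fraction | 0.05 | fraction of cells that must reach the floor |
| drug coverage | 400 cells | minimum measured cells per drug |
| z_cor cutoff | 3.2 | two-sided ≈1.4×10⁻³ significance |
| FCG tail | 0.05 | promiscuity quantile |
| GSEA weight | 1 | hit weights \|score\|¹ |
| GSEA permutations | 1000 | gene-label permutation null |
| pathway p | 0.01 | enrichment threshold |
| β | 0.4 | diffusion restart probability |
| min module size | 5 | smallest reportable module |
| module p | 0.05 | permutation acceptance threshold |
| DIAMOnD recall | top 200 | recall window for uncovered genes |
| distance bins | width 5 | size bins for d_net normalization |
| random pairs | 100 | null pairs per bin pair |

All are exposed on `PipelineConfig`. The boundary conventions are:
the expression floor and drug coverage are inclusive ("at least"), the
z_cor cutoff and the FCG quantile are strict ("beyond").

## Statistical conventions

**GSEA p-values.** The general `gsea()` p-value is one-sided in the
direction of the observed ES and computed among same-sign permutations
with an add-one correction; under a random-set null this quantity is
uniform on (0,1], which the calibration tests verify by a KS test.
Patient-level module calls use a different convention: the direction is
fixed *a priori* by the module (up for PCM, down for NCM), and the
p-value is one-sided in that fixed direction over all permutations.
With the direction fixed, the null call rate equals the nominal
threshold exactly, which makes `P < 0.001` interpretable as a
patient-level false-positive rate; the implementation refuses fewer
than `1/p_max` permutations.

**Fisher enrichment.** Two-sided Fisher's exact p over the 2×2 table on
the declared gene universe; the reported odds ratio is the sample OR
with a Haldane 0.5 correction when a cell is empty. First and second
modules of a drug/direction are merged before gene-set enrichment.

**Module significance.** HotNet2's published release uses a two-stage
statistic over a network-permutation ensemble; here the null preserves
the heat values and permutes their assignment to network nodes, and
significance is the add-one fraction of permutations whose largest
component matches the observed size. This is simpler, deterministic
given a seed, and calibrates well on planted instances, but it is a
heat-permutation test, not a network-permutation test.

**Distance normalization (d_net).** The raw measure is the Menche set
distance: the mean, over genes of either module, of the shortest-path
distance to the closest gene of the other module. Size dependence is
removed by z-scoring against random modules that match each observed
module's radial profile (multiset of shortest distances to its most
central gene, measured on the full graph; "most central" = highest
closeness centrality of the induced subgraph, ties broken by degree and
then name). Random modules are grown ring-by-ring around random
centers; when a ring runs short the deficit (at most 50% of the module)
is filled by DIAMOnD expansion, and centers are kept distinct within a
pool — on small graphs two modules grown from the same center are
near-duplicates and put a heavy lower tail on the null. Modules are
pooled in size bins of width 5, and 100 random pairs per bin pair give
the null mean and SD. The separation score `s_AB` is available as an
alternative raw metric. Positively and negatively correlated modules
are never normalized against each other.

**Confounder diagnostic.** PCA is taken over the raw correlation matrix
with genes as observations and drugs as variables, so the first
component is a gene-indexed profile; a tissue whose cells all share an
unspecific sensitivity shift contributes the same profile to every
drug's correlations and therefore dominates this component. Each cell's
expression profile is correlated with the PC1 gene scores, tissue
medians are taken, and tissues more than 2 SD (sample SD) above the
across-tissue mean of medians are flagged. The sign of a principal axis
is arbitrary and the mean per-cell correlation is ≈0 by construction,
so the axis is oriented so that the tissue deviating most from the mean
sits on the positive side. Flagged tissues are only reported; removal
requires an explicit configuration choice (`drop_tissues="flagged"` or
an explicit list). With eight tissues, the studentized deviation of a
single extreme tissue is bounded near 2.5, so the default threshold of
2 flags only a dominant tissue.

## The synthetic benchmark

The generator (`drugmod.synthetic`) plants ground truth into every
layer so the pipeline can be tested end to end offline:

* **Interactome**: a planted-partition graph (default 2000 nodes, 8
  communities of 30, p_in = 0.3, p_out = 0.01), each community redrawn
  until connected; edge confidences are drawn above the 700 filter.
  Each drug receives a planted target: a background node wired to 5
  random members of its community.
* **Expression**: each community has a latent per-cell activity
  `a ~ N(0,1)`; member genes read `baseline + a` plus per-(tissue,gene)
  offsets (SD 0.5 over 8 tissues), background biological variability
  (SD 0.5) for genes without a planted role, and measurement noise with
  SD equal to 0.3 of the response noise. Baselines are uniform on
  (6, 12); 150 decoy genes sit below the 4.4 floor (baseline 0.5–3).
* **Response**: drug potency is `±0.6·a + 0.35·g0 + shift·1{confounding
  tissue} + η`, where `g0` is a global factor carried by 6 promiscuous
  genes (3 up, 3 down) and `η ~ N(0, noise_sd²)`. The default response
  noise SD is 0.25, i.e. a replicate reliability of ≈0.9 for the
  potency readout, in line with the reproducibility of large screening
  panels; the recovery stress test doubles down and uses noise SD 1.0,
  where the per-gene correlation drops to r ≈ 0.41. The default
  confounding shift is 2. Five percent of potencies are missing at
  random.
* **Pathways**: one covering pathway per planted module (80% of its
  genes plus random padding) and 50 random decoy sets of sizes 5–200.

Because the model is linear-Gaussian, member-gene correlations have the
closed form `r = α/sqrt(α² + σ²)` (up to the small expression noise),
which the tests check by simulation.

The `balanced` generator mode exists for one purpose: proving that the
ES-based predictor is *exactly* concordant with potency in the
noiseless limit. Exact concordance of a rank statistic requires the
multiset of background z-scores to be identical across cells; the
balanced mode achieves this by giving background genes cyclically
shifted copies of a fixed quantile grid and drawing latent activities
from an interleaved grid. With independent noise (the default), exact
concordance is provably unattainable for any rank-based score — between
two cells with nearly equal activity, the random background can invert
the ES order — so the noiseless AUROC check uses balanced single-drug
panels, and noisy panels are checked against thresholds instead.

**What the benchmark does not emulate**: microarray intensity
distributions and probe effects, correlated pathway structure among
background genes, dose–response curve fitting artifacts, copy-number
or methylation covariates, and realistic interactome topology
(scale-free degree distribution, clustering). Passing the planted
benchmark shows the machinery is correct and calibrated under the
declared generative model, not that modules recovered from a real panel
are biologically right.

## Numerical choices and degenerate inputs

* Pearson r is clipped to 1−10⁻¹² before `atanh`, so z_cor stays finite
  even in noiseless panels; pairs with fewer than 4 shared cells or
  zero variance are missing.
* GSEA rankings sort by score descending with ties broken by gene name;
  a set covering the whole ranking has ES 0 by convention; an all-zero
  score vector is an error; hit sets whose weights sum to 0 fall back
  to unweighted hits.
* Degenerate nulls (e.g. a target set equal to the random background)
  give an empirical z of 0 when the observed value equals the null
  mean; percentiles use the midrank convention so a degenerate null
  puts the observation at the 50th percentile.
* Gene pairs in different components contribute diameter+1 to the raw
  distance (logged); all diffusion and distance operations are
  restricted to the largest connected component.
* All stochastic steps take explicit seeds or `numpy` Generators, and
  the same seed reproduces bit-identical outputs.

## Problem sizes used in validation

The validation suite runs two full synthetic studies at the scale of
2000 genes × 300 cells × 8 drugs with 30-gene planted modules (one at
response noise 1.0 for recovery, one at the default noise for
prediction), oracle-equivalence sweeps on dozens of 30-node graphs,
calibration runs with 1000–1500 permuted patients, and distance
calibration with 100 null pairs per bin against 300 fresh pairs. These
sizes keep a complete run in a few minutes on one CPU while leaving all
statistical margins measurable.

## Known limitations

* Module significance is assessed against heat permutations only (see
  above); very dense graphs with near-equal heats give the test little
  power, and borderline modules (p ≈ 0.05) are seed-sensitive.
* The FCG quantile rule assumes the panel carries enough drugs for a
  count distribution to be meaningful; with a handful of drugs the 95th
  percentile saturates and nothing is flagged.
* The d_net normalization estimates each bin pair's null with 100 pairs
  drawn from finite pools (10 random modules per observed module); its
  mean and SD therefore carry sampling error of a few percent, which is
  visible in the calibration checks.
* The confounder diagnostic flags tissues relative to the others; if
  more than about a third of the panel shares the unspecific
  sensitivity, the "outlier" framing breaks down.
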