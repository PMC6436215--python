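"""Synthetic pharmacogenomic panels with planted ground truth.

The generator emulates the statistical structure of a cancer cell-line
(CCL) drug screen joined to a protein interaction network:

* an interactome drawn from a planted-partition model, where each planted
  community will act as the network module of one synthetic drug;
* a basal expression matrix in which the members of each planted module
  are co-expressed through a latent per-cell module activity;
* a drug response (1-AUC potency) matrix in which each drug's potency is
  a noisy linear function of its module's activity;
* a set of "promiscuous" genes whose expression loads on a global factor
  shared by every drug's potency (the frequently-correlated-gene
  phenomenon);
* one confounding tissue whose cells receive a constant potency shift on
  every drug (unspecific sensitivity), on top of ordinary tissue-specific
  expression offsets;
* a decoy set of low-expression genes below the expression floor; and
* a pathway collection that covers a tunable fraction of every planted
  module plus random decoy sets.

The model is linear-Gaussian throughout, so every Pearson correlation the
pipeline measures has a closed form that tests can check against.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import NEGATIVE, POSITIVE

logger = logging.getLogger("drugmod")

#: default latent-to-potency coupling (Pearson scale of the planted signal)
DEFAULT_EFFECT_SIZE = 0.6
#: default potency noise, in units of the (unit-variance) module activity;
#: gives a replicate reliability of ~0.9 for the potency readout
DEFAULT_NOISE_SD = 0.25
#: expression measurement noise as a fraction of the potency noise
DEFAULT_GENE_NOISE_FRAC = 0.3
#: loading of the global promiscuity factor on every drug's potency
DEFAULT_PROMISCUOUS_LOADING = 0.35
#: sd of per-(tissue, gene) expression offsets
DEFAULT_TISSUE_SD = 0.5
#: sd of gene-level biological variability of background genes
DEFAULT_BACKGROUND_SD = 0.5


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    planted_modules: dict  # drug -> frozenset of genes
    module_direction: dict  # drug -> "positive" | "negative"
    planted_targets: dict  # drug -> frozenset of genes (module-adjacent)
    promiscuous_positive: frozenset
    promiscuous_negative: frozenset
    low_expression_genes: frozenset
    confounding_tissue: str
    effect_size: float
    seed: int
    n_nodes: int

    @property
    def drugs(self) -> list:
        return sorted(self.planted_modules)

    @property
    def promiscuous_genes(self) -> frozenset:
        return self.promiscuous_positive | self.promiscuous_negative

    def to_json(self, path) -> None:
        payload = asdict(self)
        for key in ("planted_modules", "planted_targets"):
            payload[key] = {k: sorted(v) for k, v in payload[key].items()}
        for key in ("promiscuous_positive", "promiscuous_negative",
                    "low_expression_genes"):
            payload[key] = sorted(payload[key])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("planted_modules", "planted_targets"):
            payload[key] = {k: frozenset(v) for k, v in payload[key].items()}
        for key in ("promiscuous_positive", "promiscuous_negative",
                    "low_expression_genes"):
            payload[key] = frozenset(payload[key])
        return cls(**payload)


@dataclass
class SyntheticPanel:
    """Panel generated for a :class:`SyntheticTruth`."""

    expression: pd.DataFrame  # genes x cells, log2 units
    response: pd.DataFrame  # drugs x cells, 1-AUC potency, may contain NaN
    tissues: pd.Series  # cell -> tissue label
    activities: pd.DataFrame = None  # drug -> latent module activity per cell
    clean_response: pd.DataFrame = None  # potency without noise/confounding


def _gene_names(n: int) -> list:
    return [f"G{i:04d}" for i in range(n)]


def generate_interactome(n_nodes: int = 2000,
                         n_planted: int = 8,
                         module_size: int = 30,
                         p_in: float = 0.3,
                         p_out: float = 0.01,
                         seed: int = 0,
                         n_promiscuous: int = 6,
                         n_low_expression: int = 150,
                         n_targets_per_drug: int = 1,
                         target_links: int = 5,
                         effect_size: float = DEFAULT_EFFECT_SIZE,
                         confidence_range: tuple = (701, 1000),
                         ) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition interactome with one community per synthetic drug.

    Planted communities have internal edge probability ``p_in`` and the
    background ``p_out``; each community is redrawn until connected.  Each
    drug receives ``n_targets_per_drug`` planted targets: background nodes
    wired to ``target_links`` random members of the drug's community.
    Promiscuous and low-expression decoy genes are disjoint background
    nodes.  Edge confidences are drawn above the usual filter threshold.
    """
    if n_planted * module_size > n_nodes:
        raise ValidationError("n_planted * module_size exceeds n_nodes")
    if not p_in > p_out:
        raise ValidationError("planted-partition model requires p_in > p_out")
    n_background = n_nodes - n_planted * module_size
    if p_out > 0 and n_nodes * p_out < 1:
        logger.warning("expected background degree %.2f < 1: the graph is "
                       "likely disconnected", n_nodes * p_out)
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_nodes)
    g = nx.Graph()
    g.add_nodes_from(genes)

    member_count = n_planted * module_size
    modules = [genes[i * module_size:(i + 1) * module_size]
               for i in range(n_planted)]
    background = genes[member_count:]

    def _confidence():
        return int(rng.integers(confidence_range[0], confidence_range[1] + 1))

    # internal community edges, redrawn until connected
    for members in modules:
        for _ in range(200):
            sub = nx.Graph()
            sub.add_nodes_from(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < p_in:
                        sub.add_edge(members[i], members[j])
            if nx.is_connected(sub):
                break
        else:
            raise ValidationError(
                "could not draw a connected planted module; raise p_in")
        for a, b in sub.edges():
            g.add_edge(a, b, confidence=_confidence())

    # background edges (between communities and among background nodes)
    if p_out > 0:
        module_of = {}
        for k, members in enumerate(modules):
            for m in members:
                module_of[m] = k
        n = n_nodes
        # vectorized Bernoulli over the upper triangle in blocks
        idx = np.arange(n)
        for i in range(n):
            js = idx[i + 1:]
            mask = rng.random(js.size) < p_out
            gi = genes[i]
            ki = module_of.get(gi, -1)
            for j in js[mask]:
                gj = genes[j]
                if ki != -1 and module_of.get(gj, -2) == ki:
                    continue  # internal edges already drawn at p_in
                g.add_edge(gi, gj, confidence=_confidence())

    # choose disjoint background roles: targets, promiscuous, low-expression
    pool = list(background)
    rng.shuffle(pool)
    needed = n_planted * n_targets_per_drug + n_promiscuous + n_low_expression
    if needed > len(pool):
        raise ValidationError("not enough background nodes for targets, "
                              "promiscuous and low-expression genes")
    drugs = [f"drug{k + 1:02d}" for k in range(n_planted)]
    planted_targets = {}
    cursor = 0
    for k, drug in enumerate(drugs):
        targets = pool[cursor:cursor + n_targets_per_drug]
        cursor += n_targets_per_drug
        members = modules[k]
        for t in targets:
            links = rng.choice(len(members), size=min(target_links, len(members)),
                               replace=False)
            for li in links:
                g.add_edge(t, members[li], confidence=_confidence())
        planted_targets[drug] = frozenset(targets)
    promiscuous = pool[cursor:cursor + n_promiscuous]
    cursor += n_promiscuous
    low_expr = pool[cursor:cursor + n_low_expression]

    n_pos = (n_promiscuous + 1) // 2
    directions = {d: (POSITIVE if k % 2 == 0 else NEGATIVE)
                  for k, d in enumerate(drugs)}
    truth = SyntheticTruth(
        planted_modules={d: frozenset(modules[k]) for k, d in enumerate(drugs)},
        module_direction=directions,
        planted_targets=planted_targets,
        promiscuous_positive=frozenset(promiscuous[:n_pos]),
        promiscuous_negative=frozenset(promiscuous[n_pos:]),
        low_expression_genes=frozenset(low_expr),
        confounding_tissue="T1",
        effect_size=effect_size,
        seed=seed,
        n_nodes=n_nodes,
    )
    g.graph["lcc_size"] = max((len(c) for c in nx.connected_components(g)),
                              default=0)
    return g, truth


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _balanced_grids(n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Two interleaved Gaussian quantile grids of length ``n_cells``.

    Consecutive values of the first grid are separated by exactly one
    value of the second, so ranks of the first grid against the second are
    injective.  Both are standardized to mean 0, population sd 1.
    """
    q = stats.norm.ppf(np.arange(1, 2 * n_cells + 1) / (2 * n_cells + 1))
    return _standardize(q[0::2]), _standardize(q[1::2])


def generate_panel(truth: SyntheticTruth,
                   n_cells: int = 300,
                   n_drugs: int | None = None,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   confound_shift: float = 2.0,
                   seed: int = 0,
                   n_tissues: int = 8,
                   tissue_sd: float = DEFAULT_TISSUE_SD,
                   gene_noise_frac: float = DEFAULT_GENE_NOISE_FRAC,
                   promiscuous_loading: float = DEFAULT_PROMISCUOUS_LOADING,
                   background_sd: float = DEFAULT_BACKGROUND_SD,
                   baseline_range: tuple = (6.0, 12.0),
                   low_expression_range: tuple = (0.5, 3.0),
                   missing_frac: float = 0.05,
                   balanced: bool = False,
                   ) -> SyntheticPanel:
    """Expression / response / tissue panel for a planted truth.

    Each planted module ``m`` has a latent per-cell activity ``a_m ~
    N(0,1)``; member genes read ``baseline + a_m`` plus tissue offsets and
    measurement noise, and the potency of drug ``d`` is ``s_d * alpha *
    a_d + gamma * g0 + shift * 1{confounding tissue} + eta`` where ``s_d``
    is the module direction sign, ``g0`` the global promiscuity factor and
    ``eta ~ N(0, noise_sd^2)``.  Measurement noise on expression has sd
    ``gene_noise_frac * noise_sd``, so the noiseless limit is exactly
    deterministic.

    ``balanced=True`` replaces the i.i.d. background variability and
    latent draws by interleaved quantile grids, making the per-cell
    multiset of background z-scores identical across cells.  This mode
    exists for exact rank-concordance checks of the enrichment-score
    predictor in the noiseless limit.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    drugs = truth.drugs
    if n_drugs is None:
        n_drugs = len(drugs)
    if n_drugs > len(drugs):
        raise ValidationError("n_drugs exceeds the number of planted modules")
    drugs = drugs[:n_drugs]

    rng = np.random.default_rng(seed)
    cells = [f"C{i:03d}" for i in range(n_cells)]
    genes = _gene_names(truth.n_nodes)
    n_genes = len(genes)
    gene_index = {gene: i for i, gene in enumerate(genes)}

    # tissue labels: balanced assignment, shuffled
    tissue_names = [f"T{t + 1}" for t in range(n_tissues)]
    assignment = np.array([tissue_names[i % n_tissues] for i in range(n_cells)])
    rng.shuffle(assignment)
    tissues = pd.Series(assignment, index=cells, name="tissue")
    conf_mask = (tissues == truth.confounding_tissue).to_numpy()

    # latent activities, one per planted module, plus the global factor
    if balanced:
        a_grid, v_grid = _balanced_grids(n_cells)
        activities = {d: rng.permuted(a_grid) for d in truth.drugs}
        g0 = rng.permuted(a_grid)
    else:
        activities = {d: rng.standard_normal(n_cells) for d in truth.drugs}
        g0 = rng.standard_normal(n_cells)

    # baseline levels
    baseline = rng.uniform(*baseline_range, size=n_genes)
    for gene in truth.low_expression_genes:
        baseline[gene_index[gene]] = rng.uniform(*low_expression_range)

    expr = np.tile(baseline[:, None], (1, n_cells))

    member_of = {}
    for d, members in truth.planted_modules.items():
        for gene in members:
            member_of[gene] = d
    for gene, d in member_of.items():
        expr[gene_index[gene]] += activities[d]
    for gene in truth.promiscuous_positive:
        expr[gene_index[gene]] += g0
    for gene in truth.promiscuous_negative:
        expr[gene_index[gene]] -= g0

    # background biological variability for genes without a planted role
    special = set(member_of) | truth.promiscuous_genes
    bg_rows = np.array([i for i, gene in enumerate(genes) if gene not in special])
    if bg_rows.size:
        if balanced:
            if bg_rows.size % n_cells:
                logger.warning(
                    "balanced mode: %d background genes is not a multiple of "
                    "%d cells; per-cell background multisets will differ "
                    "slightly", bg_rows.size, n_cells)
            shifts = np.arange(bg_rows.size) % n_cells
            expr[bg_rows] += np.stack([np.roll(v_grid, s) for s in shifts])
        else:
            expr[bg_rows] += rng.normal(0.0, background_sd,
                                        size=(bg_rows.size, n_cells))

    # tissue-specific expression offsets
    if tissue_sd > 0:
        offsets = rng.normal(0.0, tissue_sd, size=(n_tissues, n_genes))
        t_idx = np.array([tissue_names.index(t) for t in assignment])
        expr += offsets[t_idx].T

    # measurement noise
    gene_noise_sd = gene_noise_frac * noise_sd
    if gene_noise_sd > 0:
        expr += rng.normal(0.0, gene_noise_sd, size=expr.shape)

    # potency
    alpha = truth.effect_size
    potency = np.empty((n_drugs, n_cells))
    clean = np.empty_like(potency)
    for k, d in enumerate(drugs):
        sign = 1.0 if truth.module_direction[d] == POSITIVE else -1.0
        clean[k] = sign * alpha * activities[d]
        potency[k] = clean[k] + promiscuous_loading * g0
        potency[k][conf_mask] += confound_shift
        if noise_sd > 0:
            potency[k] += rng.normal(0.0, noise_sd, size=n_cells)

    resp = pd.DataFrame(potency, index=drugs, columns=cells)
    if missing_frac > 0:
        mask = rng.random(resp.shape) < missing_frac
        # never blank out an entire drug
        for k in range(n_drugs):
            if mask[k].all():
                mask[k, rng.integers(n_cells)] = False
        resp = resp.mask(mask)

    return SyntheticPanel(
        expression=pd.DataFrame(expr, index=genes, columns=cells),
        response=resp,
        tissues=tissues,
        activities=pd.DataFrame({d: activities[d] for d in drugs},
                                index=cells).T,
        clean_response=pd.DataFrame(clean, index=drugs, columns=cells),
    )


def generate_pathways(truth: SyntheticTruth,
                      n_sets: int = 50,
                      overlap_frac: float = 0.8,
                      universe: list | None = None,
                      seed: int = 0,
                      decoy_size_range: tuple = (5, 200),
                      ) -> dict[str, set]:
    """Pathway collection: one covering pathway per planted module plus
    random decoy sets.

    The covering pathway of a module contains ``overlap_frac`` of its
    genes plus random padding up to the module size; decoys are uniform
    samples of sizes in ``decoy_size_range``.
    """
    if not 0 < overlap_frac <= 1:
        raise ValidationError("overlap_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = _gene_names(truth.n_nodes)
    universe = list(universe)
    collection: dict[str, set] = {}
    for d in truth.drugs:
        members = sorted(truth.planted_modules[d])
        n_cover = max(1, math.ceil(overlap_frac * len(members)))
        covered = list(rng.choice(members, size=n_cover, replace=False))
        non_members = [g for g in universe if g not in truth.planted_modules[d]]
        n_pad = max(0, len(members) - n_cover)
        n_pad = max(n_pad, 5 - n_cover)  # keep every set at size >= 5
        padding = list(rng.choice(non_members, size=n_pad, replace=False))
        collection[f"pathway_{d}"] = set(covered) | set(padding)
    lo, hi = decoy_size_range
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        collection[f"decoy{k + 1:03d}"] = set(
            rng.choice(universe, size=size, replace=False))
    return collection
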