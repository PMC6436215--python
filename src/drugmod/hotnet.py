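"""Insulated heat diffusion and hot-subnetwork extraction.

The detection machinery follows the HotNet2 construction: a random walk
with restart probability ``beta`` on the interactome's largest connected
component defines the diffusion operator ``F = beta * (I - (1 - beta) *
W)^-1`` with ``W`` the column-normalized adjacency.  Placing per-gene
heat ``h`` (|z_cor| of the pathway-filtered genes of one drug/direction)
on the network yields the exchanged heat ``E(i, j) = F(i, j) * h(j)``;
thresholding E at ``delta`` gives a directed graph whose strongly
connected components of size >= ``min_size`` are the hot subnetworks.
``delta`` is selected from heat permutations, and module significance is
assessed by the size of the largest permuted component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import ValidationError
from .io import DrugModule, NEGATIVE, PATHWAY_FILTERED, POSITIVE, largest_component

logger = logging.getLogger("drugmod")

DEFAULT_BETA = 0.4
DEFAULT_MIN_SIZE = 5
DEFAULT_N_PERM = 100
DEFAULT_P_MAX = 0.05
COLUMN_SUM_TOL = 1e-8


@dataclass
class DiffusionOperator:
    """Dense insulated-diffusion operator on a connected graph."""

    nodes: list
    beta: float
    F: np.ndarray
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def heat_vector(self, heats: dict) -> np.ndarray:
        """Dense heat vector from a gene -> heat mapping (>= 0, support
        restricted to the operator's nodes)."""
        h = np.zeros(self.n)
        for gene, value in heats.items():
            if value < 0:
                raise ValidationError(f"negative heat for {gene}")
            i = self.index.get(gene)
            if i is not None:
                h[i] = value
        return h


def build_diffusion(g: nx.Graph, beta: float = DEFAULT_BETA) -> DiffusionOperator:
    """Compute ``F = beta * (I - (1 - beta) W)^-1`` for a connected graph.

    ``W`` is the column-normalized (degree-normalized) adjacency of the
    unweighted graph, so each column of F sums to 1.
    """
    if not 0 < beta < 1:
        raise ValidationError("beta must be in (0, 1)")
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if not nx.is_connected(g):
        raise ValidationError(
            "diffusion requires a connected graph: restrict the interactome "
            "to its largest connected component first")
    nodes = sorted(g.nodes())
    A = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = A.sum(axis=0)
    W = A / deg[None, :]
    F = beta * np.linalg.inv(np.eye(len(nodes)) - (1.0 - beta) * W)
    colsums = F.sum(axis=0)
    if np.abs(colsums - 1.0).max() > COLUMN_SUM_TOL:
        raise ValidationError("diffusion operator columns do not sum to 1")
    return DiffusionOperator(nodes=nodes, beta=beta, F=F)


def exchanged_heat(op: DiffusionOperator, h: np.ndarray,
                   support: np.ndarray | None = None) -> np.ndarray:
    """E(i, j) = F(i, j) * h(j), restricted to the heat support.

    Only nodes carrying heat can belong to a strongly connected component
    of size > 1 (cold nodes have no outgoing edge), so E is returned on
    the support x support submatrix.
    """
    if support is None:
        support = np.flatnonzero(h > 0)
    return op.F[np.ix_(support, support)] * h[support][None, :]


def _max_scc_and_components(E: np.ndarray, delta: float,
                            min_size: int, want_components: bool):
    n = E.shape[0]
    if n == 0:
        return 0, []
    mask = E > delta
    np.fill_diagonal(mask, False)
    graph = csr_matrix(mask)
    n_comp, labels = connected_components(graph, directed=True,
                                          connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    if not want_components:
        return int(sizes.max(initial=0)), []
    comps = [np.flatnonzero(labels == c) for c in np.flatnonzero(sizes >= min_size)]
    return int(sizes.max(initial=0)), comps


def hot_subnetworks(op: DiffusionOperator, h: np.ndarray, delta: float,
                    min_size: int = DEFAULT_MIN_SIZE) -> list[set]:
    """Strongly connected components of the delta-thresholded exchanged
    heat graph, of size >= ``min_size``, sorted by size descending."""
    if not delta > 0:
        raise ValidationError("delta must be positive")
    support = np.flatnonzero(h > 0)
    E = exchanged_heat(op, h, support)
    _, comps = _max_scc_and_components(E, delta, min_size, True)
    sets = [{op.nodes[support[i]] for i in comp} for comp in comps]
    sets.sort(key=lambda s: (-len(s), min(s)))
    return sets


def _smallest_breaking_delta(E: np.ndarray, min_size: int) -> float:
    """Smallest threshold at which the largest SCC drops below min_size."""
    n = E.shape[0]
    off = ~np.eye(n, dtype=bool)
    values = np.unique(E[off & (E > 0)])
    candidates = np.concatenate(([0.0], values))
    lo, hi = 0, len(candidates) - 1
    # predicate(i): max SCC at delta = candidates[i] is < min_size (monotone)
    if _max_scc_and_components(E, candidates[lo], min_size, False)[0] < min_size:
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _max_scc_and_components(E, candidates[mid], min_size, False)[0] < min_size:
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])


def _permuted_heats(h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reassign the positive heats to uniformly random network nodes."""
    values = h[h > 0]
    out = np.zeros_like(h)
    pos = rng.choice(len(h), size=len(values), replace=False)
    out[pos] = rng.permuted(values)
    return out


def select_delta(op: DiffusionOperator, h: np.ndarray,
                 min_size: int = DEFAULT_MIN_SIZE,
                 n_perm: int = DEFAULT_N_PERM,
                 seed: int = 0,
                 rng: np.random.Generator | None = None) -> float:
    """Edge-weight threshold from heat permutations.

    For each permutation the heats are reassigned to random nodes and the
    smallest threshold at which the largest permuted component falls
    below ``min_size`` is recorded; delta is the median of those values.
    """
    support = np.flatnonzero(h > 0)
    if len(support) < min_size:
        raise ValidationError(f"need at least {min_size} positive heats")
    values = h[support]
    if np.allclose(values, values[0]):
        logger.warning("all heats equal: permutation null only moves the "
                       "support around")
    if rng is None:
        rng = np.random.default_rng(seed)
    deltas = np.empty(n_perm)
    for b in range(n_perm):
        hp = _permuted_heats(h, rng)
        sup = np.flatnonzero(hp > 0)
        E = exchanged_heat(op, hp, sup)
        deltas[b] = _smallest_breaking_delta(E, min_size)
    return float(np.median(deltas))


def component_size_pvalue(op: DiffusionOperator, h: np.ndarray, delta: float,
                          observed_size: int, n_perm: int = DEFAULT_N_PERM,
                          rng: np.random.Generator | None = None,
                          seed: int = 0) -> float:
    """Add-one permutation p for the largest observed component size."""
    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hp = _permuted_heats(h, rng)
        sup = np.flatnonzero(hp > 0)
        E = exchanged_heat(op, hp, sup)
        size, _ = _max_scc_and_components(E, delta, observed_size, False)
        if size >= observed_size:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def detect_modules(g: nx.Graph, tab, filtered_sets: dict,
                   beta: float = DEFAULT_BETA,
                   min_size: int = DEFAULT_MIN_SIZE,
                   p_max: float = DEFAULT_P_MAX,
                   n_perm: int = DEFAULT_N_PERM,
                   seed: int = 0,
                   op: DiffusionOperator | None = None,
                   max_rank: int = 2) -> list[DrugModule]:
    """Iterative hot-module extraction per drug and direction.

    Heat is |z_cor| on the pathway-filtered genes of the drug/direction.
    Each round selects delta from heat permutations, extracts the largest
    strongly connected component, and accepts it iff its size is at least
    ``min_size`` and its permutation p is at most ``p_max``; accepted
    genes are removed from the heat support and the loop repeats.  Only
    the first ``max_rank`` accepted modules per drug/direction are
    emitted (first and second modules, per convention).
    """
    if op is None:
        op = build_diffusion(largest_component(g), beta)
    ss = np.random.SeedSequence(seed)
    modules: list[DrugModule] = []
    for drug in sorted(filtered_sets):
        for direction in (POSITIVE, NEGATIVE):
            genes = filtered_sets[drug].get(direction, set())
            genes = {x for x in genes if x in op.index}
            if not genes:
                continue
            zrow = tab.zcor.loc[drug]
            heats = {x: abs(float(zrow.get(x, 0.0))) for x in genes}
            heats = {x: v for x, v in heats.items() if np.isfinite(v) and v > 0}
            rng = np.random.default_rng(ss.spawn(1)[0])
            rank = 0
            while len(heats) >= min_size:
                h = op.heat_vector(heats)
                delta = select_delta(op, h, min_size=min_size,
                                     n_perm=n_perm, rng=rng)
                if delta <= 0:
                    break
                comps = hot_subnetworks(op, h, delta, min_size=min_size)
                if not comps:
                    break
                top = comps[0]
                p = component_size_pvalue(op, h, delta, len(top),
                                          n_perm=n_perm, rng=rng)
                if len(top) < min_size or p > p_max:
                    break
                rank += 1
                if rank <= max_rank:
                    modules.append(DrugModule(
                        drug=drug, direction=direction, rank=rank,
                        genes=frozenset(top),
                        origin={x: PATHWAY_FILTERED for x in top}))
                for x in top:
                    heats.pop(x, None)
    return modules
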