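"""Network distances between modules with size-matched normalization.

The raw measure is the set distance of Menche et al.: the average, over
every gene of either module, of its shortest-path distance to the
closest gene of the other module (shared genes contribute 0).  Because
this measure depends strongly on module size, observed distances are
z-normalized against distances between random modules that match the
size profile of the observed ones: for each module a set of random
modules is sampled by reproducing the module's radial profile (the
multiset of shortest distances of its genes to its most central gene)
around random centers, modules are pooled into size bins, and the mean
and SD of random-pair distances within each bin pair provide the
normalization.  Negative normalized distances (d_net) denote proximity.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diamond import diamond_rank
from .exceptions import ValidationError
from .io import DrugModule

logger = logging.getLogger("drugmod")

DEFAULT_BIN_WIDTH = 5
DEFAULT_N_PAIRS = 100
DEFAULT_N_RANDOM = 10
DEFAULT_MAX_DIAMOND_FRAC = 0.5


def _bfs_from(g: nx.Graph, sources) -> dict:
    """Unweighted shortest-path length from a set of source nodes."""
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _graph_diameter(g: nx.Graph) -> int:
    """Diameter of the graph's largest component, cached on the graph."""
    cached = g.graph.get("_diameter")
    if cached is not None:
        return cached
    comp = max(nx.connected_components(g), key=len)
    d = nx.diameter(g.subgraph(comp))
    g.graph["_diameter"] = d
    return d


def raw_distance(g: nx.Graph, A, B) -> float:
    """Menche set distance: mean over all genes of either set of the
    minimum shortest-path distance to the other set.

    Gene pairs in different components contribute (diameter + 1), with a
    log message.
    """
    A, B = set(A), set(B)
    if not A or not B:
        raise ValidationError("both gene sets must be non-empty")
    missing = (A | B) - set(g.nodes())
    if missing:
        raise ValidationError(f"gene(s) not in the graph: {sorted(missing)[:5]}")
    dist_to_B = _bfs_from(g, B)
    dist_to_A = _bfs_from(g, A)
    contributions = []
    fallback = None
    for a in sorted(A):
        d = dist_to_B.get(a)
        if d is None:
            fallback = fallback if fallback is not None else _graph_diameter(g) + 1
            logger.info("node %s cannot reach the other set; using "
                        "diameter + 1 = %d", a, fallback)
            d = fallback
        contributions.append(d)
    for b in sorted(B):
        d = dist_to_A.get(b)
        if d is None:
            fallback = fallback if fallback is not None else _graph_diameter(g) + 1
            logger.info("node %s cannot reach the other set; using "
                        "diameter + 1 = %d", b, fallback)
            d = fallback
        contributions.append(d)
    return float(np.mean(contributions))


def separation_score(g: nx.Graph, A, B) -> float:
    """Menche separation s_AB = d_AB - (d_AA + d_BB) / 2, an alternative
    metric where within-set distances use the closest *other* gene."""

    def _mean_min_within(S):
        S = sorted(set(S))
        vals = []
        for x in S:
            others = set(S) - {x}
            if not others:
                vals.append(0.0)
                continue
            dist = _bfs_from(g, others)
            vals.append(dist.get(x, _graph_diameter(g) + 1))
        return float(np.mean(vals))

    def _mean_min_between(S, T):
        dist_to_T = _bfs_from(g, set(T))
        dist_to_S = _bfs_from(g, set(S))
        fallback = _graph_diameter(g) + 1
        vals = [dist_to_T.get(a, fallback) for a in sorted(set(S))]
        vals += [dist_to_S.get(b, fallback) for b in sorted(set(T))]
        return float(np.mean(vals))

    return _mean_min_between(A, B) - 0.5 * (_mean_min_within(A) +
                                            _mean_min_within(B))


def module_center(g: nx.Graph, genes) -> str:
    """Most central gene of the module's induced subgraph (highest
    closeness centrality; ties: higher degree in g, then lexicographic)."""
    genes = sorted(set(genes))
    if len(genes) < 1:
        raise ValidationError("empty module")
    sub = g.subgraph(genes)
    closeness = nx.closeness_centrality(sub)
    return min(genes, key=lambda x: (-closeness[x], -g.degree(x), x))


def radial_profile(g: nx.Graph, genes, center: str | None = None) -> Counter:
    """Multiset of shortest distances (in g) from module genes to the
    module's center."""
    genes = set(genes)
    if center is None:
        center = module_center(g, genes)
    dist = _bfs_from(g, {center})
    fallback = _graph_diameter(g) + 1
    return Counter(dist.get(x, fallback) for x in genes)


def sample_random_module(g: nx.Graph, template, n_needed: int = DEFAULT_N_RANDOM,
                         max_diamond_frac: float = DEFAULT_MAX_DIAMOND_FRAC,
                         seed: int = 0, retry_budget: int = 50,
                         rng: np.random.Generator | None = None,
                         used_centers: set | None = None) -> list[set]:
    """Random modules matching the radial profile of a template module.

    Each sample picks a random center and fills the template's distance
    rings from the center's BFS layers; when a ring runs short, the
    deficit (at most ``max_diamond_frac`` of the module size) is filled
    by DIAMOnD expansion of the partial module, otherwise the center is
    rejected and redrawn.

    ``used_centers`` (mutated in place) keeps centers distinct across
    calls, so that a pool of random modules never contains two modules
    grown from the same node -- on small graphs such coincident modules
    would put a heavy lower tail on the null distance distribution.
    """
    template = set(template)
    if len(template) < 2:
        raise ValidationError("template must have at least 2 genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    if used_centers is None:
        used_centers = set()
    profile = radial_profile(g, template)
    size = len(template)
    max_fill = int(max_diamond_frac * size)
    nodes = sorted(g.nodes())
    samples: list[set] = []
    for _ in range(n_needed):
        for _attempt in range(retry_budget):
            center = nodes[rng.integers(len(nodes))]
            if center in used_centers:
                continue
            layers: dict[int, list] = {}
            for node, d in _bfs_from(g, {center}).items():
                layers.setdefault(d, []).append(node)
            chosen: set = set()
            deficit = 0
            for r in sorted(profile):
                need = profile[r]
                ring = sorted(set(layers.get(r, [])) - chosen)
                take = min(need, len(ring))
                if take:
                    idx = rng.choice(len(ring), size=take, replace=False)
                    chosen.update(ring[i] for i in idx)
                deficit += need - take
            if deficit == 0:
                samples.append(chosen)
                used_centers.add(center)
                break
            if deficit <= max_fill and len(chosen) >= 1:
                fill = [x for x in diamond_rank(g, chosen, deficit + len(chosen))
                        if x not in chosen][:deficit]
                if len(fill) == deficit:
                    samples.append(chosen | set(fill))
                    used_centers.add(center)
                    break
        else:
            raise ValidationError(
                "could not sample a size-matched random module within the "
                "retry budget; relax max_diamond_frac or the profile")
    return samples


@dataclass
class DistanceNormalization:
    """Bin-pair null statistics for d_net normalization."""

    bin_width: int
    stats: dict = field(default_factory=dict)  # (bin_a, bin_b) -> (mu, sigma)
    pools: dict = field(default_factory=dict)  # bin -> list of random modules

    def bin_of(self, size: int) -> int:
        return size // self.bin_width

    def normalize(self, d: float, size_a: int, size_b: int) -> float:
        key = tuple(sorted((self.bin_of(size_a), self.bin_of(size_b))))
        if key not in self.stats:
            raise ValidationError(f"no null statistics for size-bin pair {key}")
        mu, sigma = self.stats[key]
        return (d - mu) / sigma


def build_normalization(g: nx.Graph, modules, bin_width: int = DEFAULT_BIN_WIDTH,
                        n_pairs: int = DEFAULT_N_PAIRS,
                        n_random_per_module: int = DEFAULT_N_RANDOM,
                        max_diamond_frac: float = DEFAULT_MAX_DIAMOND_FRAC,
                        seed: int = 0) -> DistanceNormalization:
    """Sample size-matched random modules and record per-bin-pair null
    mean and SD of raw distances."""
    rng = np.random.default_rng(seed)
    norm = DistanceNormalization(bin_width=bin_width)
    used_centers: set = set()
    for m in modules:
        genes = set(m.genes) if isinstance(m, DrugModule) else set(m)
        b = norm.bin_of(len(genes))
        norm.pools.setdefault(b, []).extend(
            sample_random_module(g, genes, n_needed=n_random_per_module,
                                 max_diamond_frac=max_diamond_frac, rng=rng,
                                 used_centers=used_centers))
    bins = sorted(norm.pools)
    if n_pairs < 2:  # pools only; no meaningful mean/SD estimate
        return norm
    for i, ba in enumerate(bins):
        for bb in bins[i:]:
            pool_a, pool_b = norm.pools[ba], norm.pools[bb]
            draws = np.empty(n_pairs)
            for t in range(n_pairs):
                a = pool_a[rng.integers(len(pool_a))]
                b_mod = pool_b[rng.integers(len(pool_b))]
                if ba == bb and len(pool_a) > 1:
                    while b_mod is a:
                        b_mod = pool_b[rng.integers(len(pool_b))]
                draws[t] = raw_distance(g, a, b_mod)
            mu, sigma = float(draws.mean()), float(draws.std(ddof=1))
            if sigma == 0:
                raise ValidationError(
                    f"zero null SD in size-bin pair ({ba}, {bb}); increase "
                    "n_pairs")
            norm.stats[(ba, bb)] = (mu, sigma)
    return norm


def normalized_distances(g: nx.Graph, modules: list,
                         bin_width: int = DEFAULT_BIN_WIDTH,
                         n_pairs: int = DEFAULT_N_PAIRS,
                         n_random_per_module: int = DEFAULT_N_RANDOM,
                         max_diamond_frac: float = DEFAULT_MAX_DIAMOND_FRAC,
                         seed: int = 0,
                         include_self: bool = False,
                         norm: DistanceNormalization | None = None,
                         ) -> tuple[pd.DataFrame, DistanceNormalization]:
    """Pairwise d_net between modules of ONE direction.

    Positively and negatively correlated modules must be normalized
    separately; this function does not mix directions and raises if the
    input modules disagree in direction.
    """
    if len(modules) < 2 and not include_self:
        raise ValidationError("need at least two modules")
    directions = {m.direction for m in modules if isinstance(m, DrugModule)}
    if len(directions) > 1:
        raise ValidationError("modules of both directions passed; normalize "
                              "PCMs and NCMs separately")
    if norm is None:
        norm = build_normalization(g, modules, bin_width=bin_width,
                                   n_pairs=n_pairs,
                                   n_random_per_module=n_random_per_module,
                                   max_diamond_frac=max_diamond_frac,
                                   seed=seed)
    records = []
    for i, ma in enumerate(modules):
        start = i if include_self else i + 1
        for mb in modules[start:]:
            ga = set(ma.genes) if isinstance(ma, DrugModule) else set(ma)
            gb = set(mb.genes) if isinstance(mb, DrugModule) else set(mb)
            d = raw_distance(g, ga, gb)
            d_net = norm.normalize(d, len(ga), len(gb))
            records.append({
                "module_a": ma.label if isinstance(ma, DrugModule) else str(i),
                "module_b": mb.label if isinstance(mb, DrugModule) else "b",
                "raw_distance": d, "d_net": d_net,
                "size_a": len(ga), "size_b": len(gb),
            })
    return pd.DataFrame(records), norm
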