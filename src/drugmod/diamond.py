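"""DIAMOnD: greedy module expansion by connectivity significance.

At each step the non-member node with the most significant hypergeometric
connectivity to the current set joins it.  For a node of degree ``k``
with ``k_s`` links into a set of size ``s0`` on a graph of ``N`` nodes,
the connectivity p-value is ``P(X >= k_s)`` with ``X ~ Hypergeometric``
drawing ``k`` from a population of ``N - 1`` containing ``s0``
successes.  Ties are broken by higher ``k_s``, then lexicographic node
id.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io import DIAMOND_RECALLED, DrugModule

logger = logging.getLogger("drugmod")

DEFAULT_TOP_K = 200


def connectivity_pvalue(n_nodes: int, set_size: int, degree: int,
                        links_to_set: int) -> float:
    """P(X >= links_to_set), X ~ Hypergeom(N-1 population, set_size
    successes, degree draws)."""
    return float(stats.hypergeom.sf(links_to_set - 1, n_nodes - 1,
                                    set_size, degree))


def diamond_rank(g: nx.Graph, seed_set, n_rank: int) -> list:
    """Ordered list of the first ``n_rank`` DIAMOnD additions to the seed.

    Seed genes absent from the graph are dropped with a warning.  The
    iteration stops early (with a warning) if no remaining node touches
    the current set.
    """
    if n_rank < 1:
        raise ValidationError("n_rank must be >= 1")
    present = {x for x in seed_set if x in g}
    absent = set(seed_set) - present
    if absent:
        logger.warning("%d seed gene(s) absent from the graph: %s",
                       len(absent), sorted(absent)[:5])
    if not present:
        raise ValidationError("no seed gene is present in the graph")
    n_nodes = g.number_of_nodes()
    current = set(present)
    # links into the current set, maintained incrementally
    ks = {}
    for s in current:
        for nb in g.neighbors(s):
            if nb not in current:
                ks[nb] = ks.get(nb, 0) + 1
    added: list = []
    while len(added) < n_rank:
        if not ks:
            logger.warning("DIAMOnD exhausted the seed component after %d "
                           "additions", len(added))
            break
        candidates = sorted(ks)
        k_arr = np.array([g.degree(c) for c in candidates])
        ks_arr = np.array([ks[c] for c in candidates])
        p_arr = stats.hypergeom.sf(ks_arr - 1, n_nodes - 1, len(current), k_arr)
        order = min(range(len(candidates)),
                    key=lambda i: (p_arr[i], -ks_arr[i], candidates[i]))
        best = candidates[order]
        added.append(best)
        current.add(best)
        del ks[best]
        for nb in g.neighbors(best):
            if nb not in current:
                ks[nb] = ks.get(nb, 0) + 1
    return added


def expand_module(m: DrugModule, sig_minus_fcg, pathway_universe, g: nx.Graph,
                  top_k: int = DEFAULT_TOP_K) -> DrugModule:
    """Recall strong correlations proximal to the module.

    A candidate joins the module iff it (i) is significantly correlated
    with the drug (FCGs removed), (ii) belongs to no pathway of the
    collection, and (iii) sits within the top ``top_k`` DIAMOnD-closest
    genes to the module.  Added genes are flagged ``diamond_recalled``.
    """
    ranked = diamond_rank(g, m.genes, top_k)
    additions = [x for x in ranked
                 if x in sig_minus_fcg and x not in pathway_universe]
    if not additions:
        return m
    if len(additions) > 0.2 * len(m.genes):
        # recall is expected to be a minor correction, not a rewrite
        logger.warning("module %s: DIAMOnD recall adds %d genes to %d "
                       "(>20%%)", m.label, len(additions), len(m.genes))
    origin = dict(m.origin)
    for x in additions:
        origin[x] = DIAMOND_RECALLED
    return DrugModule(drug=m.drug, direction=m.direction, rank=m.rank,
                      genes=frozenset(m.genes | set(additions)), origin=origin)
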