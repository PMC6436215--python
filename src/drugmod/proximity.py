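"""Network proximity of drug targets to drug modules.

Closeness is measured by DIAMOnD rank: the interactome genes are ordered
by their connectivity significance to the module, and a target's
proximity is its position in that list (the default list length, 1450,
is roughly 10% of a full interactome's largest connected component).  The observed median target rank is contrasted with random
draws from one or more background gene lists (proteome, druggable
genes, pharmacological targets, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .diamond import diamond_rank
from .exceptions import ValidationError
from .io import DrugModule

logger = logging.getLogger("drugmod")

DEFAULT_N_LIST = 1450


@dataclass
class ProximityResult:
    drug: str
    direction: str
    rank_of: dict  # target -> rank (0 = in module, inf = beyond list)
    in_module: frozenset
    median_rank: float
    decile: int | None
    n_list: int


@dataclass
class BackgroundResult:
    null_medians: np.ndarray

    def percentile(self, observed_median: float) -> float:
        """Midrank percentile of the observed median in the null: draws
        strictly below count fully, ties count half (so a degenerate null
        equal to the observation sits at the 50th percentile)."""
        below = float(np.mean(self.null_medians < observed_median))
        ties = float(np.mean(self.null_medians == observed_median))
        return 100.0 * (below + 0.5 * ties)


def _ranked_list(g: nx.Graph, m: DrugModule, n_list: int) -> list:
    if n_list > g.number_of_nodes():
        raise ValidationError("n_list exceeds the number of interactome nodes")
    return diamond_rank(g, m.genes, n_list)


def target_proximity(g: nx.Graph, m: DrugModule, targets,
                     n_list: int = DEFAULT_N_LIST,
                     ranked: list | None = None) -> ProximityResult:
    """Rank summary of a drug's targets in the module's DIAMOnD list.

    Targets inside the module get rank 0 and are reported separately;
    targets beyond the list get rank infinity.  The summary statistic is
    the median rank over targets, and its decile within the list is
    ``ceil(10 * median / n_list)`` when finite.
    """
    targets = set(targets)
    if not targets:
        raise ValidationError("empty target set")
    if ranked is None:
        ranked = _ranked_list(g, m, n_list)
    position = {x: i + 1 for i, x in enumerate(ranked)}
    rank_of = {}
    in_module = set()
    for t in sorted(targets):
        if t in m.genes:
            rank_of[t] = 0
            in_module.add(t)
        else:
            rank_of[t] = position.get(t, math.inf)
    median = float(np.median(list(rank_of.values())))
    decile = int(math.ceil(10.0 * median / n_list)) if math.isfinite(median) \
        else None
    return ProximityResult(drug=m.drug, direction=m.direction,
                           rank_of=rank_of, in_module=frozenset(in_module),
                           median_rank=median, decile=decile, n_list=n_list)


def proximity_background(g: nx.Graph, m: DrugModule, background,
                         n_targets: int, n_samples: int = 1000,
                         seed: int = 0, n_list: int = DEFAULT_N_LIST,
                         ranked: list | None = None) -> BackgroundResult:
    """Null distribution of median DIAMOnD ranks for random target sets.

    ``background`` is the gene list the random sets are drawn from (e.g.
    the whole proteome or the druggable genes).  The DIAMOnD list is
    computed once; each draw samples ``n_targets`` genes without
    replacement and records the median rank (in-module genes count 0,
    absent genes infinity).
    """
    background = sorted(set(background))
    missing = [x for x in background if x not in g]
    if missing:
        raise ValidationError("background gene(s) not in the interactome: "
                              f"{missing[:5]}")
    if len(background) < n_targets:
        raise ValidationError("background smaller than the target set")
    if ranked is None:
        ranked = _ranked_list(g, m, n_list)
    position = {x: i + 1 for i, x in enumerate(ranked)}
    ranks = np.array([0.0 if x in m.genes else position.get(x, math.inf)
                      for x in background])
    rng = np.random.default_rng(seed)
    medians = np.empty(n_samples)
    for b in range(n_samples):
        idx = rng.choice(len(background), size=n_targets, replace=False)
        medians[b] = np.median(ranks[idx])
    return BackgroundResult(null_medians=medians)
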