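"""Weighted Kolmogorov-Smirnov gene-set enrichment (GSEA) on ranked lists.

The enrichment score (ES) is the signed extremum of a running sum that
increases at member genes ("hits", weighted by |score|^weight_exponent,
normalized to the total hit weight) and decreases uniformly at non-member
genes ("misses").  Significance comes from a gene-label permutation null
that preserves the set size; the reported p-value is one-sided in the
direction of the observed ES and is computed among same-sign
permutations with an add-one correction, which makes it uniform on (0,1]
under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("drugmod")

DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1000


@dataclass
class GseaResult:
    name: str
    es: float
    p_value: float
    leading_edge: tuple
    n_perm: int
    set_size: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


class _Ranking:
    """A score vector sorted once, reusable across many gene sets."""

    def __init__(self, scores: pd.Series, weight_exponent: float = DEFAULT_WEIGHT):
        scores = scores.dropna()
        if len(scores) == 0:
            raise ValidationError("empty ranking")
        if not np.isfinite(scores.to_numpy()).all():
            raise ValidationError("scores must be finite")
        values = scores.to_numpy(dtype=float)
        genes = scores.index.to_numpy()
        # descending by score, ties broken by gene name for determinism
        order = np.lexsort((genes, -values))
        self.genes = genes[order]
        self.values = values[order]
        self.weights = np.abs(self.values) ** weight_exponent
        self.position = {g: i for i, g in enumerate(self.genes)}
        self.n = len(self.genes)
        self.weight_exponent = weight_exponent

    def hit_positions(self, gene_set) -> np.ndarray:
        pos = sorted(self.position[g] for g in gene_set if g in self.position)
        return np.asarray(pos, dtype=int)


def _es_from_positions(weights: np.ndarray, positions: np.ndarray,
                       n: int) -> tuple[float, int]:
    """ES and extremum hit index for sorted hit positions in a ranking."""
    k = len(positions)
    if k == 0:
        raise ValidationError("gene set does not intersect the ranking")
    if k == n:
        logger.warning("gene set covers the whole ranking; ES set to 0")
        return 0.0, -1
    w = weights[positions]
    total = w.sum()
    if total == 0:
        # hits all carry zero weight: fall back to unweighted hits
        w = np.ones(k)
        total = float(k)
    cum = np.cumsum(w) / total
    j = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    after = cum - (positions + 1 - j) * miss  # deviation just after each hit
    before = np.concatenate(([0.0], cum[:-1])) - (positions - (j - 1)) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = float(after[i_max])
    es_neg = float(before[i_min])
    if es_pos >= -es_neg:
        return es_pos, i_max
    return es_neg, i_min


def enrichment_score(scores: pd.Series, gene_set,
                     weight_exponent: float = DEFAULT_WEIGHT,
                     ranking: _Ranking | None = None,
                     ) -> tuple[float, tuple]:
    """ES of ``gene_set`` in the ranking defined by ``scores``.

    Returns the signed ES and the leading-edge genes (hits at or before
    the positive extremum, or at/after the negative one).
    """
    rk = ranking if ranking is not None else _Ranking(scores, weight_exponent)
    if np.all(rk.values == 0):
        raise ValidationError("all scores are zero; ES undefined")
    positions = rk.hit_positions(gene_set)
    es, i_ext = _es_from_positions(rk.weights, positions, rk.n)
    if i_ext < 0:
        return es, ()
    if es >= 0:
        leading = tuple(rk.genes[positions[: i_ext + 1]])
    else:
        leading = tuple(rk.genes[positions[i_ext:]])
    return es, leading


def _sample_position_sets(rng: np.random.Generator, n: int, k: int,
                          n_perm: int) -> np.ndarray:
    """(n_perm, k) matrix of sorted distinct positions in [0, n)."""
    idx = rng.integers(0, n, size=(n_perm, k))
    idx.sort(axis=1)
    for _ in range(64):
        bad = (np.diff(idx, axis=1) == 0).any(axis=1)
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
        idx.sort(axis=1)
    else:  # pragma: no cover - k close to n; fall back to exact sampling
        for row in np.flatnonzero((np.diff(idx, axis=1) == 0).any(axis=1)):
            idx[row] = np.sort(rng.choice(n, size=k, replace=False))
    return idx


def permutation_es(rk: _Ranking, k: int, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Null ES for random position sets of size ``k`` (vectorized)."""
    n = len(rk.genes)
    if k >= n:
        return np.zeros(n_perm)
    pos = _sample_position_sets(rng, n, k, n_perm)
    w = rk.weights[pos]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        total[zero] = float(k)
    cum = np.cumsum(w, axis=1) / total
    j = np.arange(1, k + 1)[None, :]
    miss = 1.0 / (n - k)
    after = cum - (pos + 1 - j) * miss
    before = np.concatenate((np.zeros((n_perm, 1)), cum[:, :-1]), axis=1) \
        - (pos - (j - 1)) * miss
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def signed_permutation_p(es_obs: float, es_null: np.ndarray) -> float:
    """Add-one permutation p among same-sign null scores, one-sided in
    the direction of the observed ES."""
    if es_obs >= 0:
        same = es_null > 0
        b = int(np.sum(es_null[same] >= es_obs))
    else:
        same = es_null < 0
        b = int(np.sum(es_null[same] <= es_obs))
    m = int(same.sum())
    return (b + 1) / (m + 1)


def directional_permutation_p(es_obs: float, es_null: np.ndarray,
                              direction: int) -> float:
    """Add-one permutation p one-sided in a FIXED direction (+1 or -1),
    computed over all permutations; uniform on (0,1] under the null."""
    if direction > 0:
        b = int(np.sum(es_null >= es_obs))
    else:
        b = int(np.sum(es_null <= es_obs))
    return (b + 1) / (len(es_null) + 1)


def gsea(scores: pd.Series, gene_set,
         weight_exponent: float = DEFAULT_WEIGHT,
         n_perm: int = DEFAULT_N_PERM,
         seed: int = 0,
         name: str = "",
         ranking: _Ranking | None = None,
         rng: np.random.Generator | None = None) -> GseaResult:
    """Weighted-KS enrichment of ``gene_set`` with a gene-permutation null."""
    rk = ranking if ranking is not None else _Ranking(scores, weight_exponent)
    if np.all(rk.values == 0):
        raise ValidationError("all scores are zero; ES undefined")
    es, leading = enrichment_score(None, gene_set, ranking=rk)
    k = len(rk.hit_positions(gene_set))
    if rng is None:
        rng = np.random.default_rng(seed)
    es_null = permutation_es(rk, k, n_perm, rng)
    p = signed_permutation_p(es, es_null)
    return GseaResult(name=name, es=es, p_value=p, leading_edge=leading,
                      n_perm=n_perm, set_size=k)


def pathway_filter_genes(sig, tab, pathways: dict,
                         min_set: int = 5,
                         p_max: float = 0.01,
                         weight_exponent: float = DEFAULT_WEIGHT,
                         n_perm: int = DEFAULT_N_PERM,
                         seed: int = 0,
                         ) -> tuple[dict, pd.DataFrame]:
    """Keep significantly correlated genes that sit in enriched pathways.

    For every drug and direction, GSEA runs on the drug's full z_cor
    ranking against every pathway of size >= ``min_set`` (within the
    ranked universe).  Pathways with permutation p < ``p_max`` and an ES
    sign matching the direction are "enriched"; the drug's significant
    genes that belong to at least one enriched pathway survive.

    Returns ``{drug: {"positive": set, "negative": set}}`` and a long-form
    report of enriched pathways.
    """
    rng = np.random.default_rng(seed)
    filtered: dict = {}
    records = []
    for drug in tab.drugs:
        scores = tab.zcor.loc[drug].dropna()
        if scores.empty or np.all(scores.to_numpy() == 0):
            filtered[drug] = {"positive": set(), "negative": set()}
            continue
        rk = _Ranking(scores, weight_exponent)
        universe = set(scores.index)
        null_cache: dict[int, np.ndarray] = {}
        enriched_up, enriched_down = set(), set()
        for pw_name in sorted(pathways):
            members = pathways[pw_name] & universe
            if len(members) < min_set:
                continue
            es, _ = enrichment_score(None, members, ranking=rk)
            k = len(members)
            if k not in null_cache:
                null_cache[k] = permutation_es(rk, k, n_perm, rng)
            p = signed_permutation_p(es, null_cache[k])
            if p < p_max:
                (enriched_up if es > 0 else enriched_down).update(members)
                records.append({"drug": drug, "pathway": pw_name,
                                "es": es, "p_value": p,
                                "direction": "positive" if es > 0 else "negative"})
        filtered[drug] = {
            "positive": sig.positive.get(drug, set()) & enriched_up,
            "negative": sig.negative.get(drug, set()) & enriched_down,
        }
    report = pd.DataFrame(records, columns=["drug", "pathway", "es",
                                            "p_value", "direction"])
    return filtered, report
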