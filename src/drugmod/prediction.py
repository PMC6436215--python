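"""GSEA-based drug response prediction from drug modules.

Cell lines are ranked by the enrichment score of the drug's module(s) in
their z-scored expression profile: sensitive cells should over-express a
positively correlated module (PCM) and under-express a negatively
correlated one (NCM).  Performance is summarized as the AUROC of that
ranking against the top-n most sensitive cells of the measured potency
profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError
from .gsea import _Ranking, enrichment_score
from .io import DrugModule

logger = logging.getLogger("drugmod")

MODES = ("pcm_only", "ncm_only", "combined", "best_es")
DEFAULT_TOP_N = (25, 50, 100)


def zscore_genes(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-gene z-score across the cell panel (population SD by default).

    Zero-variance genes are dropped with a warning.
    """
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d zero-variance gene(s) before z-scoring",
                       dropped)
    if not keep.any():
        raise ValidationError("no gene with nonzero variance")
    z = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def _cell_es(zexpr: pd.DataFrame, genes, weight_exponent: float) -> pd.Series:
    genes = set(genes) & set(zexpr.index)
    if not genes:
        return pd.Series(np.nan, index=zexpr.columns)
    out = {}
    for cell in zexpr.columns:
        scores = zexpr[cell]
        rk = _Ranking(scores, weight_exponent)
        es, _ = enrichment_score(None, genes, ranking=rk)
        out[cell] = es
    return pd.Series(out)


def rank_cells_by_es(zexpr: pd.DataFrame,
                     pcm: DrugModule | None = None,
                     ncm: DrugModule | None = None,
                     mode: str = "combined",
                     weight_exponent: float = 1.0) -> pd.DataFrame:
    """Score and rank cell lines by module enrichment.

    Scores: ``pcm_only`` = ES(PCM); ``ncm_only`` = -ES(NCM); ``combined``
    = ES(PCM) - ES(NCM) with absent modules contributing 0; ``best_es`` =
    max over available modules of the direction-adjusted ES.  Cells whose
    profile shares no gene with the modules score NaN and rank last.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    if pcm is None and ncm is None:
        raise ValidationError("at least one module is required")
    es_p = _cell_es(zexpr, pcm.genes, weight_exponent) if pcm is not None else None
    es_n = _cell_es(zexpr, ncm.genes, weight_exponent) if ncm is not None else None
    if mode == "pcm_only":
        if pcm is None:
            raise ValidationError("pcm_only requires a PCM")
        score = es_p
    elif mode == "ncm_only":
        if ncm is None:
            raise ValidationError("ncm_only requires an NCM")
        score = -es_n
    elif mode == "combined":
        parts = []
        if es_p is not None:
            parts.append(es_p.fillna(0.0) if es_n is not None else es_p)
        if es_n is not None:
            parts.append(-(es_n.fillna(0.0) if es_p is not None else es_n))
        score = sum(parts)
    else:  # best_es
        parts = [s for s in
                 ([es_p] if es_p is not None else []) +
                 ([-es_n] if es_n is not None else [])]
        score = pd.concat(parts, axis=1).max(axis=1)
    df = pd.DataFrame({"score": score})
    df = df.sort_values("score", ascending=False, na_position="last",
                        kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def evaluate_auroc(ranking: pd.DataFrame, resp: pd.DataFrame, drug: str,
                   top_n: int = 25) -> float:
    """AUROC of the module-based ranking against the top-n sensitive cells.

    Positives are the ``top_n`` cells with the highest measured potency
    (ties broken by cell id); the tie-aware rank formulation of the AUROC
    is used.  Only measured cells participate.
    """
    y = resp.loc[drug].dropna()
    cells = ranking.index.intersection(y.index)
    if top_n >= len(cells):
        raise ValidationError(
            f"top_n = {top_n} but only {len(cells)} scored measured cells")
    order = sorted(cells, key=lambda c: (-y[c], c))
    positives = set(order[:top_n])
    labels = np.array([1 if c in positives else 0 for c in cells])
    scores = ranking.loc[cells, "score"].to_numpy(dtype=float)
    finite_min = np.nanmin(scores) if np.isfinite(scores).any() else 0.0
    scores = np.where(np.isfinite(scores), scores, finite_min - 1.0)
    return float(roc_auc_score(labels, scores))


def predict_and_evaluate(zexpr: pd.DataFrame, resp: pd.DataFrame,
                         modules: list[DrugModule],
                         top_n_values=DEFAULT_TOP_N,
                         mode: str = "combined",
                         weight_exponent: float = 1.0) -> pd.DataFrame:
    """Within-panel evaluation using first modules only.

    For every drug with at least one first module, rank cells and report
    the AUROC at each ``top_n``.
    """
    first = {}
    for m in modules:
        if m.rank != 1:
            continue
        slot = first.setdefault(m.drug, {})
        slot[m.direction] = m
    records = []
    for drug in sorted(first):
        if drug not in resp.index:
            continue
        pcm = first[drug].get("positive")
        ncm = first[drug].get("negative")
        use_mode = mode
        if mode == "combined" and (pcm is None or ncm is None):
            use_mode = "pcm_only" if pcm is not None else "ncm_only"
        ranking = rank_cells_by_es(zexpr, pcm=pcm, ncm=ncm, mode=use_mode,
                                   weight_exponent=weight_exponent)
        for top_n in top_n_values:
            try:
                auroc = evaluate_auroc(ranking, resp, drug, top_n)
            except ValidationError:
                continue
            records.append({"drug": drug, "mode": use_mode, "top_n": top_n,
                            "auroc": auroc})
    return pd.DataFrame(records, columns=["drug", "mode", "top_n", "auroc"])
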