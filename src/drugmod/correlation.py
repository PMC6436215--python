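"""Drug-gene correlation statistics.

The central statistic is ``z_cor``: the Fisher z-transform of the Pearson
correlation between a gene's basal expression and a drug's potency
(1-AUC), scaled by ``sqrt(n - 3)``.  The scaling variance-stabilizes the
transform so that values are comparable across drugs measured in
different numbers of cell lines; under the null ``z_cor`` is
approximately standard normal, and the conventional significance cutoff
of |z_cor| > 3.2 corresponds to a two-sided tail probability of about
1.4e-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("drugmod")

DEFAULT_CUTOFF = 3.2
_R_CLIP = 1.0 - 1e-12


@dataclass
class CorrelationTable:
    """Drugs x genes matrix of z_cor values with per-pair sample counts."""

    zcor: pd.DataFrame
    n: pd.DataFrame
    cutoff: float = DEFAULT_CUTOFF

    @property
    def drugs(self) -> pd.Index:
        return self.zcor.index

    @property
    def genes(self) -> pd.Index:
        return self.zcor.columns

    def r(self) -> pd.DataFrame:
        """Back-transform to Pearson correlations."""
        with np.errstate(invalid="ignore"):
            return np.tanh(self.zcor / np.sqrt(self.n - 3))


@dataclass
class SignificantSets:
    """Per-drug positively (PCG) and negatively (NCG) correlated genes."""

    positive: dict = field(default_factory=dict)  # drug -> set of genes
    negative: dict = field(default_factory=dict)
    cutoff: float = DEFAULT_CUTOFF

    @property
    def drugs(self) -> list:
        return sorted(set(self.positive) | set(self.negative))

    def counts(self) -> pd.DataFrame:
        rows = {d: {"n_positive": len(self.positive.get(d, ())),
                    "n_negative": len(self.negative.get(d, ()))}
                for d in self.drugs}
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class FcgSets:
    """Frequently correlated genes, per sign, with per-gene drug counts."""

    positive: frozenset
    negative: frozenset
    positive_counts: pd.Series
    negative_counts: pd.Series
    threshold_positive: float = np.nan
    threshold_negative: float = np.nan

    @property
    def genes(self) -> frozenset:
        return self.positive | self.negative


def fisher_z(r, n):
    """Variance-stabilized Fisher transform: atanh(r) * sqrt(n - 3)."""
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    return np.arctanh(r) * np.sqrt(np.asarray(n, dtype=float) - 3.0)


def compute_zcor(expr: pd.DataFrame, resp: pd.DataFrame,
                 min_n: int = 4, cutoff: float = DEFAULT_CUTOFF,
                 ) -> CorrelationTable:
    """z_cor for every drug-gene pair over the shared cell axis.

    Per pair, only cells with a potency measurement contribute; pairs with
    fewer than ``min_n`` such cells, or zero variance in either variable,
    are missing.
    """
    cells = expr.columns.intersection(resp.columns)
    if len(cells) == 0:
        raise ValidationError("expression and response share no cell lines")
    E = expr[cells].to_numpy()
    z = np.full((len(resp), len(expr)), np.nan)
    counts = np.zeros((len(resp), len(expr)), dtype=int)
    for k, drug in enumerate(resp.index):
        y = resp.loc[drug, cells].to_numpy(dtype=float)
        mask = np.isfinite(y)
        n = int(mask.sum())
        counts[k] = n
        if n < min_n:
            logger.warning("drug %s: only %d measured cells (<%d); z_cor "
                           "missing", drug, n, min_n)
            continue
        ym = y[mask] - y[mask].mean()
        sy = np.sqrt((ym ** 2).sum())
        if sy == 0:
            logger.warning("drug %s: zero potency variance; z_cor missing", drug)
            continue
        X = E[:, mask]
        Xm = X - X.mean(axis=1, keepdims=True)
        sx = np.sqrt((Xm ** 2).sum(axis=1))
        valid = sx > 0
        r = np.full(len(expr), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            r[valid] = (Xm[valid] @ ym) / (sx[valid] * sy)
        z[k] = fisher_z(r, n)
    return CorrelationTable(
        zcor=pd.DataFrame(z, index=resp.index, columns=expr.index),
        n=pd.DataFrame(counts, index=resp.index, columns=expr.index),
        cutoff=cutoff,
    )


def call_significant(tab: CorrelationTable,
                     cutoff: float | None = None) -> SignificantSets:
    """Split each drug's genes into PCGs (z_cor > cutoff) and NCGs
    (z_cor < -cutoff); the inequality is strict ("beyond")."""
    cutoff = tab.cutoff if cutoff is None else cutoff
    if not cutoff > 0:
        raise ValidationError("cutoff must be positive")
    pos, neg = {}, {}
    z = tab.zcor
    for drug in z.index:
        row = z.loc[drug]
        pos[drug] = set(row.index[row > cutoff])
        neg[drug] = set(row.index[row < -cutoff])
    return SignificantSets(positive=pos, negative=neg, cutoff=cutoff)


def _fcg_one_sign(sets_by_drug: dict, genes: pd.Index, tail: float,
                  over_correlated_only: bool) -> tuple[frozenset, pd.Series, float]:
    counts = pd.Series(0, index=genes, dtype=float)
    for gene_set in sets_by_drug.values():
        idx = counts.index.intersection(list(gene_set))
        counts.loc[idx] += 1
    pool = counts[counts >= 1] if over_correlated_only else counts
    if len(pool) == 0:
        return frozenset(), counts, np.nan
    threshold = float(np.quantile(pool.to_numpy(), 1.0 - tail))
    flagged = frozenset(counts.index[counts > threshold])
    return flagged, counts, threshold


def find_fcgs(sig: SignificantSets, genes: pd.Index | None = None,
              tail: float = 0.05,
              over_correlated_only: bool = True) -> FcgSets:
    """Frequently correlated genes: per sign, genes whose correlated-drug
    count strictly exceeds the (1 - tail) quantile of the count
    distribution (computed over genes correlated with at least one drug
    by default)."""
    if not sig.drugs:
        raise ValidationError("need at least one drug")
    if genes is None:
        universe = set()
        for s in (*sig.positive.values(), *sig.negative.values()):
            universe |= s
        genes = pd.Index(sorted(universe))
    pos, pos_counts, thr_pos = _fcg_one_sign(sig.positive, genes, tail,
                                             over_correlated_only)
    neg, neg_counts, thr_neg = _fcg_one_sign(sig.negative, genes, tail,
                                             over_correlated_only)
    return FcgSets(positive=pos, negative=neg,
                   positive_counts=pos_counts, negative_counts=neg_counts,
                   threshold_positive=thr_pos, threshold_negative=thr_neg)


def remove_fcgs(sig: SignificantSets, fcgs: FcgSets) -> SignificantSets:
    """Drop FCGs from every drug's PCG/NCG sets (sign-wise)."""
    return SignificantSets(
        positive={d: s - fcgs.positive for d, s in sig.positive.items()},
        negative={d: s - fcgs.negative for d, s in sig.negative.items()},
        cutoff=sig.cutoff,
    )


def tissue_zcor(expr: pd.DataFrame, resp: pd.DataFrame, tissues: pd.Series,
                min_cells: int = 4, cutoff: float = DEFAULT_CUTOFF,
                ) -> tuple[dict, pd.DataFrame]:
    """Per-tissue correlation tables plus a median-consistency report.

    For every globally significant drug-gene pair, the report lists the
    median z_cor across tissues and whether its sign agrees with the
    global call.  Tissues with fewer than ``min_cells`` measured cells
    are skipped with a warning.
    """
    cells = expr.columns.intersection(resp.columns).intersection(tissues.index)
    tables: dict[str, CorrelationTable] = {}
    for tissue in sorted(tissues.loc[cells].unique()):
        members = cells[tissues.loc[cells] == tissue]
        if len(members) < min_cells:
            logger.warning("tissue %s has %d < %d cells; skipped",
                           tissue, len(members), min_cells)
            continue
        tables[tissue] = compute_zcor(expr[members], resp[members],
                                      min_n=min_cells, cutoff=cutoff)

    global_tab = compute_zcor(expr[cells], resp[cells], cutoff=cutoff)
    sig = call_significant(global_tab)
    records = []
    stacked = {t: tab.zcor for t, tab in tables.items()}
    for drug in global_tab.drugs:
        for sign_label, gene_sets in (("positive", sig.positive),
                                      ("negative", sig.negative)):
            for gene in sorted(gene_sets.get(drug, ())):
                per_tissue = [stacked[t].at[drug, gene] for t in stacked]
                median = float(np.nanmedian(per_tissue)) if per_tissue else np.nan
                global_z = float(global_tab.zcor.at[drug, gene])
                records.append({
                    "drug": drug, "gene": gene, "sign": sign_label,
                    "global_zcor": global_z, "median_tissue_zcor": median,
                    "sign_agrees": bool(np.sign(median) == np.sign(global_z))
                    if np.isfinite(median) else False,
                })
    report = pd.DataFrame(records, columns=["drug", "gene", "sign",
                                            "global_zcor",
                                            "median_tissue_zcor",
                                            "sign_agrees"])
    return tables, report


def target_correlation_z(tab: CorrelationTable, targets: dict,
                         n_samples: int = 1000, seed: int = 0) -> pd.Series:
    """Empirical z-score of the max target z_cor against random gene sets.

    Observed statistic: the maximum z_cor over a drug's annotated targets.
    Null: ``n_samples`` draws of equally many random genes (without
    replacement within a draw), keeping the maximum each time.  The
    empirical z is (observed - null mean) / null sd.
    """
    rng = np.random.default_rng(seed)
    genes = tab.genes
    out = {}
    for drug in tab.drugs:
        if drug not in targets:
            continue
        present = [t for t in sorted(targets[drug]) if t in genes]
        absent = set(targets[drug]) - set(present)
        if absent:
            logger.warning("drug %s: target(s) %s absent from the gene axis",
                           drug, sorted(absent))
        if not present:
            logger.warning("drug %s: no annotated target on the gene axis; "
                           "skipped", drug)
            continue
        row = tab.zcor.loc[drug]
        valid = row.dropna()
        obs = float(row.loc[present].max())
        if not np.isfinite(obs) or len(valid) < len(present):
            continue
        draws = np.empty(n_samples)
        values = valid.to_numpy()
        for i in range(n_samples):
            idx = rng.choice(len(values), size=len(present), replace=False)
            draws[i] = values[idx].max()
        sd = draws.std()
        if sd > 0:
            out[drug] = float((obs - draws.mean()) / sd)
        else:
            # degenerate null: observed equal to the null mean scores 0
            out[drug] = 0.0 if obs == draws.mean() else np.nan
    return pd.Series(out, name="target_correlation_z")
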