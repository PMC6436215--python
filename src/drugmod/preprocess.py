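"""Panel cleaning: expression floor, confounding-tissue detection, drug
coverage.

The cleaning steps mirror standard practice for pharmacogenomic panels:
genes whose expression sits below a log2 floor across (almost) the whole
panel are uninformative and removed; tissues whose cells show unspecific
sensitivity to every drug confound global drug-gene correlations and are
flagged by a PCA diagnostic; drugs measured in too few cell lines are
dropped because their correlations are unstable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import ValidationError

logger = logging.getLogger("drugmod")

DEFAULT_FLOOR = 4.4
DEFAULT_KEEP_FRAC = 0.05
DEFAULT_MIN_CELLS = 400
DEFAULT_FLAG_THRESHOLD = 2.0


def filter_low_expression(expr: pd.DataFrame,
                          floor: float = DEFAULT_FLOOR,
                          keep_frac: float = DEFAULT_KEEP_FRAC) -> pd.DataFrame:
    """Remove genes expressed below ``floor`` (log2 units) across the panel.

    A gene is retained iff the fraction of cells at or above the floor is
    at least ``keep_frac`` (boundary inclusive on both counts).
    """
    if not np.isfinite(floor):
        raise ValidationError("floor must be finite")
    if not 0 <= keep_frac <= 1:
        raise ValidationError("keep_frac must be in [0, 1]")
    frac_above = (expr.to_numpy() >= floor).mean(axis=1)
    keep = frac_above >= keep_frac
    removed = int((~keep).sum())
    if removed == len(expr):
        raise ValidationError("low-expression filter removed every gene")
    if removed:
        logger.info("low-expression filter removed %d of %d genes",
                    removed, len(expr))
    return expr.loc[keep]


def raw_correlations(expr: pd.DataFrame, resp: pd.DataFrame,
                     min_n: int = 4) -> pd.DataFrame:
    """Plain Pearson drug x gene correlation matrix on the shared cells.

    Per drug, only cells with a potency measurement contribute.  Pairs
    with fewer than ``min_n`` cells or zero variance are NaN.
    """
    cells = expr.columns.intersection(resp.columns)
    if len(cells) == 0:
        raise ValidationError("expression and response share no cell lines")
    E = expr[cells].to_numpy()
    out = np.full((len(resp), len(expr)), np.nan)
    for k, drug in enumerate(resp.index):
        y = resp.loc[drug, cells].to_numpy(dtype=float)
        mask = np.isfinite(y)
        n = int(mask.sum())
        if n < min_n:
            logger.warning("drug %s has %d < %d measured cells; correlations "
                           "set to missing", drug, n, min_n)
            continue
        ym = y[mask] - y[mask].mean()
        sy = np.sqrt((ym ** 2).sum())
        if sy == 0:
            logger.warning("drug %s has zero potency variance", drug)
            continue
        X = E[:, mask]
        Xm = X - X.mean(axis=1, keepdims=True)
        sx = np.sqrt((Xm ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xm @ ym) / (sx * sy)
        r[sx == 0] = np.nan
        out[k] = r
    return pd.DataFrame(out, index=resp.index, columns=expr.index)


def detect_confounding_tissues(raw_corr: pd.DataFrame,
                               expr: pd.DataFrame,
                               tissues: pd.Series,
                               flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
                               ) -> list[str]:
    """Flag tissues whose cells dominate the drug-gene correlation profile.

    The first principal component of the raw correlation matrix (genes as
    observations, drugs as variables) gives one loading per gene.  Each
    cell's expression profile is correlated with those loadings; tissues
    whose median cell correlation lies more than ``flag_threshold``
    standard deviations above the across-tissue mean of medians are
    returned.  The PC sign is oriented so the mean per-cell correlation
    is non-negative.
    """
    if tissues.nunique() < 2:
        raise ValidationError("confounder detection needs at least 2 tissues")
    genes = raw_corr.columns.intersection(expr.index)
    X = raw_corr[genes].to_numpy().T  # genes x drugs
    X = np.nan_to_num(X, nan=0.0)
    pca = PCA(n_components=1, svd_solver="full")
    loadings = pca.fit_transform(X)[:, 0]  # one score per gene
    if np.allclose(loadings.std(), 0):
        return []

    cells = expr.columns.intersection(tissues.index)
    E = expr.loc[genes, cells].to_numpy()
    Ec = E - E.mean(axis=0, keepdims=True)
    sd = Ec.std(axis=0)
    sd[sd == 0] = np.nan
    lc = loadings - loadings.mean()
    per_cell = (Ec.T @ lc) / (sd * len(genes)) / loadings.std()
    corr = pd.Series(per_cell, index=cells)

    medians = {}
    for tissue, members in tissues.loc[cells].groupby(tissues.loc[cells]):
        if len(members) < 2:
            logger.warning("tissue %s has <2 cells; excluded from confounder "
                           "flagging", tissue)
            continue
        medians[tissue] = float(corr.loc[members.index].median())
    if len(medians) < 2:
        return []
    values = pd.Series(medians)
    # The sign of a principal axis is arbitrary; a confounding tissue must be
    # flagged either way.  Orient the axis so that the tissue deviating most
    # from the across-tissue mean of medians sits on the positive side (the
    # overall mean correlation is ~0 by construction, so it cannot orient).
    deviation = values - values.mean()
    if deviation.loc[deviation.abs().idxmax()] < 0:
        values = -values
    sd_medians = values.std(ddof=1)
    if sd_medians == 0:
        return []
    z = (values - values.mean()) / sd_medians
    return sorted(values.index[z > flag_threshold])


def filter_drug_coverage(resp: pd.DataFrame,
                         min_cells: int = DEFAULT_MIN_CELLS) -> pd.DataFrame:
    """Keep drugs with potency measured in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    counts = resp.notna().sum(axis=1)
    keep = counts >= min_cells
    if not keep.any():
        raise ValidationError("drug coverage filter removed every drug")
    removed = int((~keep).sum())
    if removed:
        logger.info("coverage filter removed %d of %d drugs", removed, len(resp))
    return resp.loc[keep]


def remove_tissue_cells(expr: pd.DataFrame, resp: pd.DataFrame,
                        tissues: pd.Series, drop: list[str],
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Drop all cells belonging to the listed tissues from the panel."""
    keep_cells = tissues.index[~tissues.isin(drop)]
    expr_cells = expr.columns.intersection(keep_cells)
    resp_cells = resp.columns.intersection(keep_cells)
    return (expr[expr_cells], resp[resp_cells],
            tissues.loc[tissues.index.intersection(keep_cells)])
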