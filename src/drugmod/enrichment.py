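"""Downstream characterization of drug modules.

Three analyses: (i) hypergeometric (Fisher's exact) enrichment of module
genes in curated gene-set collections such as the Hallmarks; (ii)
patient-level module "expression" calls via GSEA on a patient's z-scored
expression profile, requiring the enrichment direction to match the
module direction; (iii) association between module calls and driver-gene
mutations across a patient cohort (Fisher's exact with an odds-ratio
flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .gsea import _Ranking, directional_permutation_p, enrichment_score, \
    permutation_es
from .io import DrugModule, POSITIVE

logger = logging.getLogger("drugmod")

DEFAULT_P_MAX = 0.001
DEFAULT_OR_MIN = 2.0


@dataclass
class EnrichmentRecord:
    name: str
    odds_ratio: float
    p_value: float
    table: tuple


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ad/bc with Haldane 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def set_enrichment(module_genes, gene_set, universe) -> EnrichmentRecord:
    """Fisher's exact enrichment of a module in a gene set over a universe.

    The 2x2 table counts genes in/out of the module against in/out of the
    set; the p-value is two-sided and the odds ratio is the sample OR
    with Haldane correction when a cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    module_genes = set(module_genes)
    gene_set = set(gene_set)
    if not module_genes <= universe or not gene_set <= universe:
        raise ValidationError("module and gene set must be subsets of the "
                              "universe")
    a = len(module_genes & gene_set)
    b = len(module_genes - gene_set)
    c = len(gene_set - module_genes)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentRecord(name="", odds_ratio=_odds_ratio(a, b, c, d),
                            p_value=float(p), table=(a, b, c, d))


def module_set_enrichment(modules: list[DrugModule], collections: dict,
                          universe) -> pd.DataFrame:
    """Enrichment of each drug/direction (first and second modules merged)
    in every gene set of the collection."""
    merged: dict[tuple, set] = {}
    for m in modules:
        merged.setdefault((m.drug, m.direction), set()).update(m.genes)
    universe = set(universe)
    records = []
    for (drug, direction), genes in sorted(merged.items()):
        genes = genes & universe
        if not genes:
            continue
        for name in sorted(collections):
            rec = set_enrichment(genes, set(collections[name]) & universe,
                                 universe)
            records.append({"drug": drug, "direction": direction,
                            "gene_set": name,
                            "odds_ratio": rec.odds_ratio,
                            "p_value": rec.p_value})
    return pd.DataFrame(records, columns=["drug", "direction", "gene_set",
                                          "odds_ratio", "p_value"])


def patient_module_call(patient_z, m: DrugModule,
                        p_max: float = DEFAULT_P_MAX,
                        n_perm: int | None = None,
                        seed: int = 0,
                        rng: np.random.Generator | None = None,
                        weight_exponent: float = 1.0,
                        ranking: _Ranking | None = None,
                        ) -> tuple[bool, float, float]:
    """Is the module "expressed" in a patient's z-scored profile?

    The ES of the module genes is computed in the patient's ranked
    profile; the permutation p-value is one-sided in the direction the
    module prescribes (up for PCM, down for NCM), so a call requires both
    significance and the matching ES sign.  ``n_perm`` must be at least
    ``1 / p_max`` to resolve the threshold.
    """
    min_perm = math.ceil(1.0 / p_max)
    if n_perm is None:
        n_perm = min_perm
    if n_perm < min_perm:
        raise ValidationError(
            f"n_perm = {n_perm} cannot resolve p_max = {p_max}; "
            f"use at least {min_perm} permutations")
    rk = ranking if ranking is not None else _Ranking(
        pd.Series(patient_z), weight_exponent)
    genes = set(m.genes) & set(rk.genes)
    if not genes:
        raise ValidationError("module shares no gene with the patient profile")
    es, _ = enrichment_score(None, genes, ranking=rk)
    if rng is None:
        rng = np.random.default_rng(seed)
    es_null = permutation_es(rk, len(genes), n_perm, rng)
    direction = 1 if m.direction == POSITIVE else -1
    p = directional_permutation_p(es, es_null, direction)
    called = (p < p_max) and (es * direction > 0)
    return called, float(es), float(p)


def cohort_module_calls(patient_z: pd.DataFrame, modules: list[DrugModule],
                        p_max: float = DEFAULT_P_MAX,
                        n_perm: int | None = None,
                        seed: int = 0,
                        weight_exponent: float = 1.0) -> pd.DataFrame:
    """Patients x modules boolean call matrix (columns are module labels)."""
    rng = np.random.default_rng(seed)
    calls = {}
    for patient in patient_z.columns:
        profile = patient_z[patient].dropna()
        rk = _Ranking(profile, weight_exponent)
        row = {}
        for m in modules:
            try:
                called, _, _ = patient_module_call(
                    None, m, p_max=p_max, n_perm=n_perm, rng=rng,
                    weight_exponent=weight_exponent, ranking=rk)
            except ValidationError as exc:
                if "resolve" in str(exc):
                    raise
                called = False
            row[m.label] = called
        calls[patient] = row
    return pd.DataFrame.from_dict(calls, orient="index").astype(bool)


def driver_association(calls: pd.DataFrame, mutations: pd.DataFrame,
                       or_min: float = DEFAULT_OR_MIN,
                       p_max: float = DEFAULT_P_MAX) -> pd.DataFrame:
    """Fisher association between module calls and driver mutations.

    Both inputs are patients x columns boolean frames sharing a patient
    axis.  Drivers mutated in zero or all patients are skipped with a
    warning; pairs with OR > ``or_min`` and p < ``p_max`` are flagged.
    """
    patients = calls.index.intersection(mutations.index)
    if len(patients) == 0:
        raise ValidationError("no shared patients")
    calls = calls.loc[patients].astype(bool)
    mutations = mutations.loc[patients].astype(bool)
    records = []
    for driver in mutations.columns:
        mut = mutations[driver].to_numpy()
        if mut.all() or not mut.any():
            logger.warning("driver %s mutated in %s patients; skipped",
                           driver, "all" if mut.all() else "no")
            continue
        for module in calls.columns:
            call = calls[module].to_numpy()
            if not call.any():
                logger.info("module %s called in no patient; skipped", module)
                continue
            a = int(np.sum(call & mut))
            b = int(np.sum(call & ~mut))
            c = int(np.sum(~call & mut))
            d = int(np.sum(~call & ~mut))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            odds = _odds_ratio(a, b, c, d)
            records.append({"module": module, "driver": driver,
                            "odds_ratio": odds, "p_value": float(p),
                            "flagged": bool(odds > or_min and p < p_max)})
    return pd.DataFrame(records, columns=["module", "driver", "odds_ratio",
                                          "p_value", "flagged"])
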