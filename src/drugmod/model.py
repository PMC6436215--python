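"""Model/Results interface over the drug-module pipeline.

:class:`DrugModuleModel` is constructed from a pharmacogenomic panel
(expression, response, tissue annotation), an interactome and a pathway
collection; :meth:`DrugModuleModel.fit` runs the full pipeline --
panel cleaning, drug-gene correlation, FCG removal, GSEA pathway
filtering, diffusion-based module detection and DIAMOnD recall -- and
returns a :class:`DrugModuleResults` carrying the modules together with
every intermediate table, plus methods for the downstream analyses
(response prediction, target proximity, inter-module distances, gene-set
and cohort enrichment) and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import correlation, distance, enrichment, gsea, hotnet, prediction, \
    preprocess, proximity
from .diamond import expand_module
from .exceptions import ValidationError
from .io import NEGATIVE, POSITIVE, DrugModule, largest_component, \
    write_modules_gmt

logger = logging.getLogger("drugmod")


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline, with the field's conventional
    defaults."""

    # preprocessing
    expression_floor: float = preprocess.DEFAULT_FLOOR
    keep_frac: float = preprocess.DEFAULT_KEEP_FRAC
    min_cells: int = preprocess.DEFAULT_MIN_CELLS
    flag_threshold: float = preprocess.DEFAULT_FLAG_THRESHOLD
    #: None = only report flagged tissues; "flagged" = drop what the
    #: detector flags; or an explicit list of tissue labels to drop.
    drop_tissues: object = None
    # correlation
    zcor_cutoff: float = correlation.DEFAULT_CUTOFF
    fcg_tail: float = 0.05
    fcg_over_correlated_only: bool = True
    # pathway filter
    min_set: int = 5
    pathway_p_max: float = 0.01
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    # module detection
    beta: float = hotnet.DEFAULT_BETA
    min_module_size: int = hotnet.DEFAULT_MIN_SIZE
    module_p_max: float = hotnet.DEFAULT_P_MAX
    module_n_perm: int = hotnet.DEFAULT_N_PERM
    diamond_top_k: int = 200


class DrugModuleModel:
    """Drug-module discovery model for a pharmacogenomic panel.

    Parameters
    ----------
    expression : DataFrame, genes x cells, log2 units (complete).
    response : DataFrame, drugs x cells, 1-AUC potency (NaN = missing).
    tissues : Series, cell -> tissue label.
    interactome : networkx.Graph of gene symbols (confidence-filtered).
    pathways : dict, gene-set name -> set of genes.
    targets : dict, drug -> set of target genes (optional).
    config : PipelineConfig (optional).
    """

    def __init__(self, expression, response, tissues, interactome,
                 pathways, targets=None, config: PipelineConfig | None = None):
        self.expression = expression
        self.response = response
        self.tissues = tissues
        self.interactome = interactome
        self.pathways = dict(pathways)
        self.targets = dict(targets or {})
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, expression_path, response_path, tissues_path,
                   interactome_path, pathways_path, targets_path=None,
                   min_confidence: int = 700,
                   config: PipelineConfig | None = None) -> "DrugModuleModel":
        from . import io
        return cls(
            expression=io.read_matrix(expression_path, "expression"),
            response=io.read_matrix(response_path, "response"),
            tissues=io.read_tissues(tissues_path),
            interactome=io.read_interactome(interactome_path, min_confidence),
            pathways=io.read_gmt(pathways_path),
            targets=io.read_targets(targets_path) if targets_path else None,
            config=config,
        )

    def fit(self, seed: int = 0) -> "DrugModuleResults":
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        seeds = ss.generate_state(4)

        expr = preprocess.filter_low_expression(
            self.expression, floor=cfg.expression_floor,
            keep_frac=cfg.keep_frac)

        raw = preprocess.raw_correlations(expr, self.response)
        flagged = preprocess.detect_confounding_tissues(
            raw, expr, self.tissues, flag_threshold=cfg.flag_threshold)
        if cfg.drop_tissues == "flagged":
            drop = list(flagged)
        elif cfg.drop_tissues:
            drop = list(cfg.drop_tissues)
        else:
            drop = []
        resp = self.response
        tissues = self.tissues
        if drop:
            logger.info("dropping tissue(s): %s", drop)
            expr, resp, tissues = preprocess.remove_tissue_cells(
                expr, resp, tissues, drop)
        resp = preprocess.filter_drug_coverage(resp, min_cells=cfg.min_cells)

        tab = correlation.compute_zcor(expr, resp, cutoff=cfg.zcor_cutoff)
        sig = correlation.call_significant(tab)
        fcgs = correlation.find_fcgs(
            sig, genes=tab.genes, tail=cfg.fcg_tail,
            over_correlated_only=cfg.fcg_over_correlated_only)
        sig_clean = correlation.remove_fcgs(sig, fcgs)

        filtered, enriched = gsea.pathway_filter_genes(
            sig_clean, tab, self.pathways, min_set=cfg.min_set,
            p_max=cfg.pathway_p_max, weight_exponent=cfg.gsea_weight,
            n_perm=cfg.gsea_n_perm, seed=int(seeds[0]) % (2 ** 31))

        lcc = largest_component(self.interactome)
        op = hotnet.build_diffusion(lcc, beta=cfg.beta)
        modules = hotnet.detect_modules(
            lcc, tab, filtered, beta=cfg.beta,
            min_size=cfg.min_module_size, p_max=cfg.module_p_max,
            n_perm=cfg.module_n_perm, seed=int(seeds[1]) % (2 ** 31), op=op)

        pathway_universe = set()
        for genes in self.pathways.values():
            pathway_universe |= set(genes)
        expanded = []
        for m in modules:
            sig_dir = (sig_clean.positive if m.direction == POSITIVE
                       else sig_clean.negative).get(m.drug, set())
            expanded.append(expand_module(m, sig_dir, pathway_universe,
                                          lcc, top_k=cfg.diamond_top_k))

        return DrugModuleResults(
            model=self, config=cfg, seed=seed,
            expression=expr, response=resp, tissues=tissues,
            flagged_tissues=list(flagged), correlations=tab,
            significant=sig, fcgs=fcgs, significant_clean=sig_clean,
            filtered_sets=filtered, enriched_pathways=enriched,
            modules=expanded, lcc=lcc, diffusion=op,
        )


@dataclass
class DrugModuleResults:
    """Fitted drug modules plus every intermediate pipeline product."""

    model: DrugModuleModel
    config: PipelineConfig
    seed: int
    expression: pd.DataFrame
    response: pd.DataFrame
    tissues: pd.Series
    flagged_tissues: list
    correlations: correlation.CorrelationTable
    significant: correlation.SignificantSets
    fcgs: correlation.FcgSets
    significant_clean: correlation.SignificantSets
    filtered_sets: dict
    enriched_pathways: pd.DataFrame
    modules: list
    lcc: nx.Graph
    diffusion: hotnet.DiffusionOperator
    _zexpr: pd.DataFrame = field(default=None, repr=False)

    # -- accessors ---------------------------------------------------------
    def module(self, drug: str, direction: str = POSITIVE,
               rank: int = 1) -> DrugModule | None:
        for m in self.modules:
            if (m.drug, m.direction, m.rank) == (drug, direction, rank):
                return m
        return None

    def first_modules(self, direction: str) -> list:
        return [m for m in self.modules
                if m.direction == direction and m.rank == 1]

    @property
    def zscored_expression(self) -> pd.DataFrame:
        if self._zexpr is None:
            object.__setattr__(self, "_zexpr",
                               prediction.zscore_genes(self.expression))
        return self._zexpr

    # -- summaries ---------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for drug in self.correlations.drugs:
            row = {
                "n_pcg": len(self.significant.positive.get(drug, ())),
                "n_ncg": len(self.significant.negative.get(drug, ())),
                "n_pcg_filtered": len(
                    self.filtered_sets.get(drug, {}).get(POSITIVE, ())),
                "n_ncg_filtered": len(
                    self.filtered_sets.get(drug, {}).get(NEGATIVE, ())),
            }
            for direction, tag in ((POSITIVE, "pcm"), (NEGATIVE, "ncm")):
                m1 = self.module(drug, direction, 1)
                m2 = self.module(drug, direction, 2)
                row[f"{tag}_size"] = len(m1) if m1 else 0
                row[f"{tag}2_size"] = len(m2) if m2 else 0
            rows[drug] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        frame = self.summary_frame()
        n_pcm = sum(1 for m in self.modules
                    if m.direction == POSITIVE and m.rank == 1)
        n_ncm = sum(1 for m in self.modules
                    if m.direction == NEGATIVE and m.rank == 1)
        lines = [
            "Drug module detection results",
            "=" * 64,
            f"cells: {self.expression.shape[1]}    "
            f"genes: {self.expression.shape[0]}    "
            f"drugs: {len(self.response)}",
            f"flagged tissues: {', '.join(self.flagged_tissues) or 'none'}",
            f"frequently correlated genes: {len(self.fcgs.positive)} positive"
            f", {len(self.fcgs.negative)} negative",
            f"drugs with a first PCM: {n_pcm}    with a first NCM: {n_ncm}",
            "-" * 64,
            frame.to_string(),
        ]
        return "\n".join(lines)

    # -- downstream analyses ----------------------------------------------
    def rank_cells(self, drug: str, mode: str = "combined",
                   zexpr: pd.DataFrame | None = None) -> pd.DataFrame:
        zexpr = self.zscored_expression if zexpr is None else zexpr
        pcm = self.module(drug, POSITIVE, 1)
        ncm = self.module(drug, NEGATIVE, 1)
        if mode == "combined" and (pcm is None or ncm is None):
            mode = "pcm_only" if pcm is not None else "ncm_only"
        return prediction.rank_cells_by_es(zexpr, pcm=pcm, ncm=ncm, mode=mode,
                                           weight_exponent=self.config.gsea_weight)

    def evaluate_prediction(self, top_n_values=prediction.DEFAULT_TOP_N,
                            mode: str = "combined",
                            zexpr: pd.DataFrame | None = None,
                            response: pd.DataFrame | None = None,
                            ) -> pd.DataFrame:
        zexpr = self.zscored_expression if zexpr is None else zexpr
        response = self.response if response is None else response
        return prediction.predict_and_evaluate(
            zexpr, response, self.modules, top_n_values=top_n_values,
            mode=mode, weight_exponent=self.config.gsea_weight)

    def target_proximity(self, targets: dict | None = None,
                         n_list: int | None = None) -> pd.DataFrame:
        targets = targets if targets is not None else self.model.targets
        if not targets:
            raise ValidationError("no drug-target annotation available")
        if n_list is None:
            n_list = min(proximity.DEFAULT_N_LIST,
                         max(1, self.lcc.number_of_nodes() // 10))
        records = []
        for m in self.modules:
            if m.rank != 1 or m.drug not in targets:
                continue
            res = proximity.target_proximity(self.lcc, m, targets[m.drug],
                                             n_list=n_list)
            records.append({"drug": m.drug, "direction": m.direction,
                            "median_rank": res.median_rank,
                            "decile": res.decile,
                            "n_in_module": len(res.in_module),
                            "n_list": n_list})
        return pd.DataFrame(records, columns=["drug", "direction",
                                              "median_rank", "decile",
                                              "n_in_module", "n_list"])

    def module_distances(self, direction: str = POSITIVE,
                         seed: int | None = None,
                         **kwargs) -> pd.DataFrame:
        mods = [m for m in self.modules if m.direction == direction]
        if len(mods) < 2:
            raise ValidationError(
                f"need at least two {direction} modules for distances")
        seed = self.seed if seed is None else seed
        df, _ = distance.normalized_distances(self.lcc, mods, seed=seed,
                                              **kwargs)
        return df

    def gene_set_enrichment(self, collections: dict,
                            universe=None) -> pd.DataFrame:
        universe = set(self.expression.index) if universe is None \
            else set(universe)
        return enrichment.module_set_enrichment(self.modules, collections,
                                                universe)

    def to_gmt(self, path) -> None:
        write_modules_gmt(self.modules, path)

    def provenance_frame(self) -> pd.DataFrame:
        """Long-form gene table: module label, gene, z_cor, origin flag."""
        records = []
        for m in self.modules:
            zrow = self.correlations.zcor.loc[m.drug] \
                if m.drug in self.correlations.zcor.index else None
            for gene in sorted(m.genes):
                records.append({
                    "module": m.label, "drug": m.drug,
                    "direction": m.direction, "rank": m.rank, "gene": gene,
                    "zcor": float(zrow.get(gene, np.nan)) if zrow is not None
                    else np.nan,
                    "origin": m.gene_origin(gene),
                })
        return pd.DataFrame(records, columns=["module", "drug", "direction",
                                              "rank", "gene", "zcor",
                                              "origin"])
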