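"""End-to-end convenience pipelines composing the module operations.

These are the code paths the command-line ``run-all`` uses and the ones
exercised by the simulation-based recovery checks: cohort counts →
FPKM-UQ → ssGSEA → consensus clustering → hot/cold call → smoking
enrichment; and metabolome + expression → DEMs/DEGs → overlap core.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import ContingencyResult, assign_hot_cold, chisq_enrichment
from .consensus import ConsensusParams, ConsensusResult, consensus_cluster
from .diffomics import DifferentialResult, differential_test
from .integration import IntegrationSignature, map_dems_to_genes, overlap_signature
from .io_formats import GeneSetCollection, SampleAnnotations
from .normalization import fpkm_uq, median_iqr_normalize
from .simulate import CohortSim, ExposureSim, MetabolomeSim
from .ssgsea import ScoreMatrix, SsgseaParams, ssgsea_scores

__all__ = ["CohortAnalysis", "analyze_cohort", "IntegrationAnalysis", "integrate_study"]


@dataclass
class CohortAnalysis:
    scores: ScoreMatrix  # leukocyte-signature ssGSEA scores
    clustering: ConsensusResult
    phenotype: pd.Series  # sample -> hot | cold
    contingency: ContingencyResult  # smoking exposure x phenotype
    profile: pd.DataFrame


def analyze_cohort(
    sim_or_counts,
    annotations: SampleAnnotations | None = None,
    gene_sets: GeneSetCollection | None = None,
    k: int = 3,
    n_resamples: int = 50,
    seed: int = 0,
    ssgsea_params: SsgseaParams = SsgseaParams(),
    exclude_sets: tuple[str, ...] = ("NRF2_SIG",),
) -> CohortAnalysis:
    """Immune phenotyping of a cohort: FPKM-UQ, leukocyte ssGSEA,
    consensus clustering of samples on the signature scores, hot/cold
    calling, and the chi-squared smoking-enrichment table."""
    if isinstance(sim_or_counts, CohortSim):
        counts = sim_or_counts.counts
        annotations = sim_or_counts.annotations
        gene_sets = sim_or_counts.gene_sets
    else:
        counts = sim_or_counts
        if annotations is None or gene_sets is None:
            raise ValueError("annotations and gene_sets are required")
    linear = fpkm_uq(counts)
    leuk_sets = GeneSetCollection(
        sets={n: g for n, g in gene_sets.items() if n not in exclude_sets},
        descriptions=dict(gene_sets.descriptions),
    )
    scores = ssgsea_scores(linear, leuk_sets, ssgsea_params)
    params = ConsensusParams(k=k, n_resamples=n_resamples, seed=seed, axis="samples")
    clustering = consensus_cluster(scores, params)
    phenotype, profile = assign_hot_cold(scores, clustering.labels)
    exposed = annotations.smoking_exposed()
    shared = [s for s in phenotype.index if s in exposed.index]
    observed = pd.crosstab(
        exposed.loc[shared].map({True: "exposed", False: "unexposed"}),
        phenotype.loc[shared],
    )
    contingency = chisq_enrichment(observed)
    return CohortAnalysis(
        scores=scores,
        clustering=clustering,
        phenotype=phenotype,
        contingency=contingency,
        profile=profile,
    )


@dataclass
class IntegrationAnalysis:
    dem_results: dict[str, DifferentialResult]
    deg_results: dict[str, DifferentialResult]
    dem_genes: dict[str, set[str]]
    deg_up: dict[str, set[str]]
    signature: IntegrationSignature


def integrate_study(
    exposure: ExposureSim,
    metabolome: MetabolomeSim,
    dem_fdr: float = 0.25,
    deg_fdr: float = 0.1,
    min_avg_log2: float = 2.0,
) -> IntegrationAnalysis:
    """Per-background DEM and DEG calls and their overlap core.

    Metabolite peak areas are log2-transformed and median-IQR
    normalized, then t-tested (BH, FDR ``dem_fdr``); DEM-associated
    genes come from the metabolite→gene map.  Expression matrices are
    filtered and t-tested (BH, FDR ``deg_fdr``); the per-background
    overlap is DEM genes ∩ upregulated DEGs, and the core is the
    intersection across backgrounds.
    """
    from .io_formats import MetaboliteTable, Space
    import numpy as np

    dem_results: dict[str, DifferentialResult] = {}
    deg_results: dict[str, DifferentialResult] = {}
    dem_genes: dict[str, set[str]] = {}
    deg_up: dict[str, set[str]] = {}
    for bg, mtable in metabolome.tables.items():
        log2_table = MetaboliteTable(values=np.log2(mtable.values), space=Space.log2)
        norm = median_iqr_normalize(log2_table)
        res = differential_test(
            norm,
            metabolome.treated[bg],
            metabolome.sham[bg],
            fdr_threshold=dem_fdr,
            apply_filter=False,
        )
        dem_results[bg] = res
        dems = set(res.significant_features)
        genes, _ = map_dems_to_genes(dems, metabolome.gene_map)
        dem_genes[bg] = genes
    for bg, etable in exposure.tables.items():
        res = differential_test(
            etable,
            exposure.treated[bg],
            exposure.sham[bg],
            fdr_threshold=deg_fdr,
            apply_filter=True,
            min_avg_log2=min_avg_log2,
        )
        deg_results[bg] = res
        deg_up[bg] = res.significant_up()
    signature = overlap_signature(dem_genes, deg_up)
    return IntegrationAnalysis(
        dem_results=dem_results,
        deg_results=deg_results,
        dem_genes=dem_genes,
        deg_up=deg_up,
        signature=signature,
    )
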