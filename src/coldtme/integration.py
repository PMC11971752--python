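"""Metabolomics–transcriptomics integration.

Differentially expressed metabolites (DEMs) are mapped to associated
genes through a user-supplied metabolite→gene table (HMDB-style, kept
offline for reproducibility); the mapped genes are tested for pathway
over-representation with the hypergeometric upper tail, and
cross-referenced against differentially expressed genes (DEGs) to form
an overlap signature per experimental background.  The core is the
intersection of the overlaps across all backgrounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import scipy.stats as sps

from .diffomics import bh_adjust
from .errors import ValidationError
from .io_formats import GeneSetCollection, MetaboliteGeneMap

log = logging.getLogger(__name__)

__all__ = [
    "OraResult",
    "IntegrationSignature",
    "map_dems_to_genes",
    "hypergeom_ora",
    "overlap_signature",
]


@dataclass
class OraResult:
    """Per-pathway over-representation statistics: overlap k out of a
    pathway of size K, a query of size n, in a universe of size N, with
    the hypergeometric upper-tail p and BH q."""

    table: pd.DataFrame  # columns: k, K, n, N, p, fdr_q, significant, overlap_genes
    fdr_threshold: float = 0.05

    def significant_pathways(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


@dataclass
class IntegrationSignature:
    dem_genes: set[str]  # union of DEM-associated genes over backgrounds
    deg_genes: set[str]  # union of upregulated DEGs over backgrounds
    overlap: set[str]  # dem_genes & deg_genes
    per_background: dict[str, set[str]] = field(default_factory=dict)
    core: set[str] = field(default_factory=set)


def map_dems_to_genes(
    dems: set[str],
    mgmap: MetaboliteGeneMap,
) -> tuple[set[str], list[str]]:
    """Union of genes associated with the given metabolites; metabolites
    without a mapping are reported, not errors."""
    genes: set[str] = set()
    unmapped: list[str] = []
    for met in sorted(dems):
        assoc = mgmap.genes_for(met)
        if met not in mgmap or not assoc:
            unmapped.append(met)
        genes |= set(assoc)
    if unmapped:
        log.info("map_dems_to_genes: %d metabolite(s) without gene associations",
                 len(unmapped))
    return genes, unmapped


def hypergeom_ora(
    query: set[str],
    pathways: GeneSetCollection,
    universe: set[str],
    fdr_threshold: float = 0.05,
) -> OraResult:
    """Hypergeometric over-representation of the query gene set in each
    pathway, restricted to the universe; BH across pathways.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N = |universe|,
    K = |pathway ∩ universe|, n = |query ∩ universe|, k = |overlap|.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    outside = set(query) - universe
    if outside:
        log.warning("hypergeom_ora: %d query gene(s) outside the universe dropped",
                    len(outside))
    query = set(query) & universe
    if not query:
        raise ValidationError("query is empty after restriction to the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in pathways.items():
        members = set(members) & universe
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((name, k, K, n, N, p, ",".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p", "overlap_genes"]
    ).set_index("pathway")
    table["fdr_q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr_q"] < fdr_threshold
    return OraResult(table=table, fdr_threshold=fdr_threshold)


def overlap_signature(
    dem_genes: dict[str, set[str]],
    deg_up: dict[str, set[str]],
) -> IntegrationSignature:
    """Per-background overlap of DEM-associated genes with upregulated
    DEGs, and the core intersection across all backgrounds."""
    if not dem_genes:
        raise ValidationError("need at least one background")
    if set(dem_genes) != set(deg_up):
        raise ValidationError(
            f"background names differ: {sorted(dem_genes)} vs {sorted(deg_up)}"
        )
    per_background = {
        bg: set(dem_genes[bg]) & set(deg_up[bg]) for bg in dem_genes
    }
    core = set.intersection(*per_background.values()) if per_background else set()
    return IntegrationSignature(
        dem_genes=set().union(*dem_genes.values()),
        deg_genes=set().union(*deg_up.values()),
        overlap=set().union(*dem_genes.values()) & set().union(*deg_up.values()),
        per_background=per_background,
        core=core,
    )
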