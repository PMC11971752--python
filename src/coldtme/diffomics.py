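"""Differential feature testing, BH adjustment, cross-experiment
consensus calls and signature set algebra.

Tests are two-sided pooled-variance Student's t per feature on log2 (or
median-IQR normalized) values; Welch's correction is available by flag.
BH runs within each experiment over filter-passing features only, since
low-expression features are removed before testing.  Fold changes are
ratios of geometric means: 2^(difference of log2 means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ValidationError
from .io_formats import ExpressionTable, MetaboliteTable, Space

log = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "ConsensusGeneReport",
    "bh_adjust",
    "filter_expressed",
    "differential_test",
    "cross_group_consensus",
    "annotate_against_signature",
    "intersect_collections",
]


@dataclass
class DifferentialResult:
    """Per-feature statistics.  Features failing the expression filter
    carry NaN test statistics.  ``zero_variance`` marks features whose
    pooled variance was zero; their p is set to 1."""

    table: pd.DataFrame  # columns: mean_log2_A, mean_log2_B, log2_fc,
    # fold_change, t_stat, p, fdr_q, passed_expression_filter,
    # zero_variance, significant
    fdr_threshold: float = 0.1
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    @property
    def significant_features(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False).astype(bool)]

    def significant_up(self) -> set[str]:
        t = self.table
        mask = t["significant"].fillna(False).astype(bool) & (t["log2_fc"] > 0)
        return set(t.index[mask])

    def significant_down(self) -> set[str]:
        t = self.table
        mask = t["significant"].fillna(False).astype(bool) & (t["log2_fc"] < 0)
        return set(t.index[mask])


@dataclass
class ConsensusGeneReport:
    """Per-gene cross-experiment tally: in how many experiments the gene
    was significantly changed past the fold threshold, and whether that
    count reaches the consensus minimum."""

    table: pd.DataFrame  # per gene: n_experiments_up, n_experiments_down,
    # consensus_call, plus per-experiment fold_change/significant columns
    fc_threshold: float = 1.3
    min_experiments: int = 3
    direction: str = "up"

    def consensus_genes(self) -> set[str]:
        return set(self.table.index[self.table["consensus_call"]])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), mapped
    back to the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def filter_expressed(
    table: ExpressionTable,
    group_a: list[str],
    group_b: list[str],
    min_avg_log2: float = 2.0,
) -> pd.Series:
    """Keep a gene iff its mean log2 value reaches ``min_avg_log2`` in at
    least one of the two groups."""
    if table.space is not Space.log2:
        raise ValidationError("expression filter operates on log2 values")
    _check_groups(table.values, group_a, group_b)
    mean_a = table.values[group_a].mean(axis=1)
    mean_b = table.values[group_b].mean(axis=1)
    keep = (mean_a >= min_avg_log2) | (mean_b >= min_avg_log2)
    keep.name = "passed_expression_filter"
    return keep


def _check_groups(values: pd.DataFrame, group_a, group_b) -> None:
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    missing = [s for s in [*group_a, *group_b] if s not in values.columns]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing}")


def differential_test(
    table: ExpressionTable | MetaboliteTable,
    group_a: list[str],
    group_b: list[str],
    fdr_threshold: float = 0.1,
    apply_filter: bool = True,
    min_avg_log2: float = 2.0,
    welch: bool = False,
) -> DifferentialResult:
    """Per-feature two-sided t test of group A vs group B with BH
    adjustment over the tested (filter-passing) features.

    log2_fc = mean_log2_A - mean_log2_B; fold_change = 2**log2_fc, the
    ratio of geometric means of the linear values.
    """
    _check_groups(table.values, group_a, group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs n >= 2 replicates")
    is_expr = isinstance(table, ExpressionTable)
    if apply_filter:
        if not is_expr:
            raise ValidationError("expression filter applies to ExpressionTable only")
        passed = filter_expressed(table, group_a, group_b, min_avg_log2)
    else:
        passed = pd.Series(True, index=table.values.index)

    a = table.values[group_a].to_numpy(dtype=float)
    b = table.values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    log2_fc = mean_a - mean_b

    if welch:
        denom = np.sqrt(var_a / na + var_b / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = (var_a / na + var_b / nb) ** 2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
    else:
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        denom = np.sqrt(pooled * (1 / na + 1 / nb))
        dof = np.full_like(denom, na + nb - 2)

    zero_var = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, log2_fc / np.where(zero_var, 1.0, denom))
        p = 2 * sps.t.sf(np.abs(t), dof)
    p = np.where(zero_var, 1.0, p)
    if zero_var.any():
        log.info("differential_test: %d zero-variance feature(s) set to p = 1",
                 int(zero_var.sum()))

    out = pd.DataFrame(
        {
            "mean_log2_A": mean_a,
            "mean_log2_B": mean_b,
            "log2_fc": log2_fc,
            "fold_change": np.exp2(log2_fc),
            "t_stat": t,
            "p": p,
            "passed_expression_filter": passed.to_numpy(),
            "zero_variance": zero_var,
        },
        index=table.values.index,
    )
    tested = out["passed_expression_filter"].to_numpy()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["fdr_q"] = q
    out.loc[~tested, ["t_stat", "p"]] = np.nan
    out["significant"] = (out["fdr_q"] < fdr_threshold) & tested
    return DifferentialResult(
        table=out, fdr_threshold=fdr_threshold,
        group_a=list(group_a), group_b=list(group_b),
    )


def cross_group_consensus(
    results: dict[str, DifferentialResult] | list[DifferentialResult],
    fc_threshold: float = 1.3,
    min_experiments: int = 3,
    direction: str = "up",
) -> ConsensusGeneReport:
    """Count, per gene, the experiments in which it was significant and
    changed by at least ``fc_threshold``-fold in each direction; call a
    consensus in ``direction`` at >= ``min_experiments``.

    The fold threshold is inclusive (fold_change >= fc counts as up,
    <= 1/fc as down); genes absent from an experiment simply do not count
    there.
    """
    if isinstance(results, list):
        results = {f"exp{i + 1}": r for i, r in enumerate(results)}
    if not results:
        raise ValidationError("no differential results supplied")
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    genes: pd.Index = pd.Index(sorted(set().union(*(r.table.index for r in results.values()))))
    n_up = pd.Series(0, index=genes)
    n_down = pd.Series(0, index=genes)
    cols = {}
    for name, res in results.items():
        t = res.table
        sig = t["significant"].fillna(False).astype(bool)
        up = sig & (t["fold_change"] >= fc_threshold)
        down = sig & (t["fold_change"] <= 1.0 / fc_threshold)
        n_up = n_up.add(up.reindex(genes, fill_value=False).astype(int), fill_value=0)
        n_down = n_down.add(down.reindex(genes, fill_value=False).astype(int), fill_value=0)
        cols[f"{name}:fold_change"] = t["fold_change"].reindex(genes)
        cols[f"{name}:significant"] = sig.reindex(genes)
    table = pd.DataFrame(cols, index=genes)
    table["n_experiments_up"] = n_up.astype(int)
    table["n_experiments_down"] = n_down.astype(int)
    count = table["n_experiments_up"] if direction == "up" else table["n_experiments_down"]
    table["consensus_call"] = count >= min_experiments
    return ConsensusGeneReport(
        table=table, fc_threshold=fc_threshold,
        min_experiments=min_experiments, direction=direction,
    )


def annotate_against_signature(
    gene_list: set[str],
    signature: set[str],
    background: set[str] | None = None,
) -> tuple[set[str], set[str], dict[str, int]]:
    """Partition a gene list by membership in a signature.  Returns
    (in_signature, out_of_signature, counts)."""
    gene_list = set(gene_list)
    signature = set(signature)
    if background is not None:
        gene_list &= set(background)
    inside = gene_list & signature
    outside = gene_list - signature
    counts = {
        "list_size": len(gene_list),
        "signature_size": len(signature),
        "in_signature": len(inside),
        "out_of_signature": len(outside),
    }
    return inside, outside, counts


def intersect_collections(collections: dict[str, set[str]]) -> tuple[pd.DataFrame, set[str]]:
    """Venn-style membership table across arbitrary gene collections and
    their full intersection."""
    if not collections:
        raise ValidationError("no collections supplied")
    universe = sorted(set().union(*collections.values()))
    membership = pd.DataFrame(
        {name: [g in genes for g in universe] for name, genes in collections.items()},
        index=universe,
    )
    common = set.intersection(*(set(v) for v in collections.values()))
    return membership, common
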