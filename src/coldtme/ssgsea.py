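"""Single-sample GSEA enrichment scores.

For one sample, genes are ordered by expression descending (ties broken
lexicographically by gene id) and given integer rank weights R = N..1.
The enrichment score is the running-sum difference between the weighted
in-set ECDF and the unweighted out-of-set ECDF:

    ES = sum_i [ sum_{j<=i, j in S} R_j^alpha / sum_{j in S} R_j^alpha
                 - #{j<=i, j not in S} / (N - |S|) ]

Because the weights are ranks, linear-space input determines only the
ordering, so scores are invariant under any strictly monotone transform
of the expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionTable, GeneSetCollection, Space

log = logging.getLogger(__name__)

__all__ = ["SsgseaParams", "ScoreMatrix", "enrichment_score", "ssgsea_scores"]


@dataclass(frozen=True)
class SsgseaParams:
    """alpha: exponent on the rank weights (0 gives the classical
    unweighted Kolmogorov–Smirnov running sum; 0.75 is the common ssGSEA
    default).  normalize_scores divides the final matrix by its overall
    max - min."""

    alpha: float = 0.75
    normalize_scores: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")


@dataclass
class ScoreMatrix:
    """Signature-by-sample enrichment scores plus a snapshot of the
    parameters that produced them."""

    values: pd.DataFrame
    params: SsgseaParams = field(default_factory=SsgseaParams)
    source: str | None = None

    @property
    def signature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _order_desc(values: np.ndarray, gene_order_key: np.ndarray) -> np.ndarray:
    """Indices ordering genes by value descending, gene id ascending on
    ties.  ``gene_order_key`` is the lexicographic rank of each gene id."""
    # np.lexsort sorts ascending with the LAST key primary.
    return np.lexsort((gene_order_key, -values))


def _es_from_order(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    n = order.size
    mask = in_set[order]
    m = int(mask.sum())
    if m == 0:
        raise ValidationError("gene set has no members in the expression vector")
    if m == n:
        raise ValidationError("gene set covers all genes; out-of-set ECDF undefined")
    ranks = np.arange(n, 0, -1, dtype=float)  # position 0 gets R = N
    w = np.where(mask, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~mask) / (n - m)
    return float(np.sum(p_in - p_out))


def enrichment_score(
    expression: pd.Series,
    gene_set: frozenset[str] | set[str],
    params: SsgseaParams = SsgseaParams(),
) -> float:
    """Enrichment score of one gene set in one sample's linear-space
    expression vector.  Set genes absent from the vector are dropped with
    a logged warning."""
    genes = expression.index
    present = set(gene_set) & set(genes)
    dropped = len(gene_set) - len(present)
    if dropped:
        log.warning("enrichment_score: %d set gene(s) absent from expression vector", dropped)
    if not present:
        raise ValidationError("gene set has no members in the expression vector")
    key = np.argsort(np.argsort(np.asarray(genes, dtype=object)))
    order = _order_desc(expression.to_numpy(dtype=float), key)
    in_set = np.fromiter((g in present for g in genes), dtype=bool, count=len(genes))
    return _es_from_order(order, in_set, params.alpha)


def ssgsea_scores(
    table: ExpressionTable,
    sets: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
) -> ScoreMatrix:
    """Enrichment score for every (signature, sample) pair of a
    linear-space expression matrix."""
    if table.space is not Space.linear:
        raise ValidationError(f"ssGSEA requires linear space, got {table.space.value}")
    genes = np.asarray(table.gene_ids, dtype=object)
    key = np.argsort(np.argsort(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    masks: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        mask = np.zeros(len(genes), dtype=bool)
        hit = [gene_pos[g] for g in members if g in gene_pos]
        dropped = len(members) - len(hit)
        if dropped:
            log.warning("set %r: %d gene(s) absent from matrix dropped", name, dropped)
        mask[hit] = True
        masks[name] = mask

    mat = table.values.to_numpy(dtype=float)
    out = np.empty((len(sets.sets), mat.shape[1]))
    set_names = list(sets.sets)
    for j, sample in enumerate(table.sample_ids):
        order = _order_desc(mat[:, j], key)
        for i, name in enumerate(set_names):
            try:
                out[i, j] = _es_from_order(order, masks[name], params.alpha)
            except ValidationError as exc:
                raise ValidationError(f"set {name!r}, sample {sample!r}: {exc}") from exc
    if params.normalize_scores:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    return ScoreMatrix(
        values=pd.DataFrame(out, index=set_names, columns=table.sample_ids),
        params=params,
    )
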