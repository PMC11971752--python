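"""Deterministic value-space transforms.

FPKM-UQ follows the TCGA harmonization convention: the per-sample scaling
factor is the 75th percentile of that sample's *nonzero* gene counts
(switchable to all genes), with a 1e9 numerator.  All percentiles and
quartiles across the package use linear interpolation between order
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionTable, MetaboliteTable, Space

log = logging.getLogger(__name__)

__all__ = ["ZMatrix", "fpkm_uq", "log2_offset", "zscore_rows", "median_iqr_normalize"]


@dataclass
class ZMatrix:
    """Per-gene sample-wise Z scores.  Rows that were constant in the
    source are set to all-zero and listed in ``flagged_genes``."""

    values: pd.DataFrame
    flagged_genes: list[str] = field(default_factory=list)
    source: str | None = None


def fpkm_uq(counts: ExpressionTable, include_zeros: bool = False) -> ExpressionTable:
    """FPKM with upper-quartile library normalization.

    value[g, s] = counts[g, s] * 1e9 / (length[g] * UQ_s) where UQ_s is the
    75th percentile (linear interpolation) of sample s's nonzero gene
    counts (all genes when ``include_zeros``).
    """
    if counts.space is not Space.counts:
        raise ValidationError(f"fpkm_uq requires counts space, got {counts.space.value}")
    lengths = counts.require_lengths().to_numpy()
    mat = counts.values.to_numpy(dtype=float)
    uq = np.empty(mat.shape[1])
    for j, sample in enumerate(counts.sample_ids):
        col = mat[:, j]
        pool = col if include_zeros else col[col > 0]
        if pool.size == 0:
            raise ValidationError(f"sample {sample!r} has all-zero counts")
        uq[j] = np.percentile(pool, 75)
        if uq[j] <= 0:
            raise ValidationError(f"sample {sample!r} has non-positive upper quartile")
    out = mat * 1e9 / (lengths[:, None] * uq[None, :])
    return ExpressionTable(
        values=pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        space=Space.linear,
        lengths=counts.lengths,
    )


def log2_offset(table: ExpressionTable, offset: float = 0.01) -> ExpressionTable:
    """log2(X + offset) transform from linear to log2 space."""
    if table.space is not Space.linear:
        raise ValidationError(f"log2_offset requires linear space, got {table.space.value}")
    if offset <= 0:
        raise ValidationError("offset must be > 0")
    if (table.values.to_numpy() < 0).any():
        raise ValidationError("log2_offset requires non-negative values")
    return ExpressionTable(
        values=np.log2(table.values + offset),
        space=Space.log2,
        lengths=table.lengths,
    )


def zscore_rows(table: ExpressionTable) -> ZMatrix:
    """Sample-wise Z score within each gene: (x - mean) / SD with
    population SD (divisor n).  Constant rows become all-zero and are
    flagged."""
    if table.values.shape[1] < 2:
        raise ValidationError("zscore_rows requires at least 2 samples")
    mat = table.values.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (mat - mean) / sd_safe
    z[constant, :] = 0.0
    flagged = [g for g, c in zip(table.values.index, constant) if c]
    if flagged:
        log.info("zscore_rows: %d constant gene(s) flagged", len(flagged))
    return ZMatrix(
        values=pd.DataFrame(z, index=table.values.index, columns=table.values.columns),
        flagged_genes=flagged,
        source=None,
    )


def median_iqr_normalize(table: MetaboliteTable) -> MetaboliteTable:
    """Per-sample median/IQR normalization of a log2 metabolite matrix:
    each column is centered by its median and scaled by its interquartile
    range (Q3 - Q1, linear-interpolation quartiles)."""
    if table.space is not Space.log2:
        raise ValidationError(
            f"median_iqr_normalize requires log2 space, got {table.space.value}"
        )
    if table.values.shape[0] < 4:
        raise ValidationError("median-IQR normalization needs at least 4 metabolites")
    mat = table.values.to_numpy(dtype=float)
    q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=0)
    iqr = q3 - q1
    zero = iqr == 0
    if zero.any():
        bad = table.values.columns[zero][0]
        raise ValidationError(f"sample {bad!r} has zero IQR")
    out = (mat - med[None, :]) / iqr[None, :]
    return MetaboliteTable(
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        space=Space.log2,
    )
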