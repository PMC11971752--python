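"""Resampling consensus hierarchical clustering (Ward linkage).

Monti-style procedure: repeatedly subsample the items without
replacement, Ward-cluster each subsample at k, and tally how often each
item pair lands in the same cluster relative to how often it was
co-sampled.  The final partition comes from Ward linkage on
1 - consensus.  Samples are clustered on per-gene Z scores; the same Z
matrix is transposed (not re-standardized) when clustering genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .normalization import ZMatrix
from .ssgsea import ScoreMatrix

log = logging.getLogger(__name__)

__all__ = ["ConsensusParams", "ConsensusResult", "consensus_cluster", "select_k"]


@dataclass(frozen=True)
class ConsensusParams:
    """k: number of clusters; n_resamples: subsampling iterations B;
    subsample_fraction: fraction of items drawn (without replacement)
    per iteration; axis: cluster samples (columns of Z) or genes (rows).
    Per-resample RNG streams are derived from (seed, b) so results are
    reproducible and unaffected by changing B."""

    k: int = 3
    n_resamples: int = 250
    subsample_fraction: float = 0.8
    linkage: str = "ward"
    distance: str = "euclidean"
    seed: int = 0
    axis: str = "samples"
    final_linkage: str = "ward"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValidationError("subsample_fraction must be in (0, 1]")
        if self.linkage != "ward" or self.distance != "euclidean":
            raise ValidationError("only Ward linkage on Euclidean distances is supported")
        if self.axis not in ("samples", "genes"):
            raise ValidationError("axis must be 'samples' or 'genes'")


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame  # item x item co-clustering frequency in [0, 1]
    cosample_counts: pd.DataFrame  # item x item times co-sampled
    labels: pd.Series  # item -> cluster id in 1..k
    cdf_area: dict[int, float] | None = None
    params: ConsensusParams | None = None


def _item_matrix(data, params: ConsensusParams) -> tuple[np.ndarray, list[str]]:
    """Items-by-features matrix for the requested axis."""
    if isinstance(data, ZMatrix):
        values = data.values
        if params.axis == "genes" and data.flagged_genes:
            values = values.drop(index=data.flagged_genes)
            log.info("excluding %d flagged constant gene(s) from gene-axis clustering",
                     len(data.flagged_genes))
    elif isinstance(data, ScoreMatrix):
        values = data.values
    elif isinstance(data, pd.DataFrame):
        values = data
    else:
        raise TypeError(f"cannot cluster object of type {type(data).__name__}")
    if params.axis == "samples":
        values = values.T  # items = samples (columns of the feature matrix)
    return values.to_numpy(dtype=float), list(values.index)


def _cut(linkage_matrix: np.ndarray, k: int) -> np.ndarray:
    return sch.fcluster(linkage_matrix, t=k, criterion="maxclust")


def _tally(X: np.ndarray, params: ConsensusParams, ks: list[int]):
    """One pass of resampling; per-resample Ward trees are cut at every
    requested k.  Returns (cosample, {k: cocluster})."""
    n = X.shape[0]
    size = ceil(params.subsample_fraction * n)
    cosample = np.zeros((n, n), dtype=np.int64)
    cocluster = {k: np.zeros((n, n), dtype=np.int64) for k in ks}
    for b in range(params.n_resamples):
        rng = np.random.default_rng([params.seed, b])
        idx = np.sort(rng.choice(n, size=size, replace=False))
        zlink = sch.linkage(X[idx], method="ward")
        sub = np.ix_(idx, idx)
        cosample[sub] += 1
        for k in ks:
            labels = _cut(zlink, k)
            same = labels[:, None] == labels[None, :]
            cocluster[k][sub] += same
    return cosample, cocluster


def _finalize(cosample: np.ndarray, cocluster: np.ndarray, items: list[str],
              params: ConsensusParams, k: int) -> ConsensusResult:
    n = len(items)
    never = (cosample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} item pair(s) never co-sampled; "
            "their consensus is set to 0 (increase n_resamples)",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2  # exact symmetry

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    zlink = sch.linkage(squareform(dist, checks=False), method=params.final_linkage)
    labels = _cut(zlink, k)
    # renumber clusters 1..k in order of first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[x] for x in labels])
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=items, columns=items),
        cosample_counts=pd.DataFrame(cosample, index=items, columns=items),
        labels=pd.Series(labels, index=items, name="cluster"),
        params=params,
    )


def consensus_cluster(data, params: ConsensusParams) -> ConsensusResult:
    """Consensus-cluster the samples (or genes) of a Z-score or
    signature-score matrix at the fixed k in ``params``."""
    X, items = _item_matrix(data, params)
    if params.k > len(items):
        raise ValidationError(f"k={params.k} exceeds the {len(items)} clustered items")
    cosample, cocluster = _tally(X, params, [params.k])
    return _finalize(cosample, cocluster[params.k], items, params, params.k)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus
    entries, integrated over [0, 1]."""
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(consensus[iu])
    m = vals.size
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[0.0], (np.arange(1, m + 1)) / m, [1.0]])
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def _pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    consensus entries strictly between ``lower`` and ``upper``."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def select_k(
    data,
    params: ConsensusParams,
    k_range,
    pac_threshold: float = 0.1,
) -> tuple[dict[int, float], int]:
    """Scan candidate cluster numbers on one resampling pass.

    Per-resample Ward trees are cut at every candidate k; for each k the
    consensus CDF area (Monti) and the proportion of ambiguous
    clustering (PAC: off-diagonal consensus entries in (0.1, 0.9)) are
    computed.  The recommended k is the largest candidate whose PAC is
    at most ``pac_threshold`` — the finest partition the resampling
    still reproduces crisply.  When no candidate is crisp (no
    reproducible structure beyond chance) the smallest candidate is
    returned.  Returns (per-k CDF area, recommended k).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("k_range is empty")
    X, items = _item_matrix(data, params)
    if ks[-1] > len(items) - 1 or ks[0] < 2:
        raise ValidationError("k_range must lie within [2, items - 1]")
    cosample, cocluster = _tally(X, params, ks)
    areas: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(cosample > 0, cocluster[k] / np.maximum(cosample, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        areas[k] = _cdf_area(cons)
        pac[k] = _pac(cons)
    crisp = [k for k in ks if pac[k] <= pac_threshold]
    if crisp:
        recommended = crisp[-1]
    else:
        log.info("select_k: no candidate k has PAC <= %.2f; no reproducible "
                 "structure detected", pac_threshold)
        recommended = ks[0]
    return areas, recommended
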