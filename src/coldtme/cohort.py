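"""Cohort-level statistics linking smoke exposure, KEAP1/NFE2L2 mutation
and the immune phenotype.

Covers: hot/cold phenotype calling from leukocyte-signature scores and
cluster labels; chi-squared enrichment of smoking in the cold cluster
(no continuity correction); Cohen's d with pooled SD; two-factor ANOVA
with interaction using Type II sums of squares (safe for unbalanced
strata); percentile stratification of activation scores; and
classification of NFE2L2 mutations by proximity to the DLG/ETGE KEAP1
degron motifs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError
from .ssgsea import ScoreMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "AnovaResult",
    "MotifConfig",
    "assign_hot_cold",
    "chisq_enrichment",
    "cohens_d",
    "twoway_anova",
    "percentile_stratify",
    "classify_nfe2l2_mutation",
]


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    low_expected_flag: bool


@dataclass
class AnovaResult:
    """Per-term Type II decomposition plus the cell means and the
    companion Cohen's d for the mutated-smoker vs mutated-nonsmoker
    contrast."""

    table: pd.DataFrame  # index: factor1, factor2, interaction, residual
    cell_means: pd.DataFrame
    cell_n: pd.DataFrame
    interaction_p: float
    cohens_d_mutated: float | None = None


@dataclass(frozen=True)
class MotifConfig:
    """KEAP1-binding degron motifs on NRF2 (human coordinates by
    default: DLG 29-31, ETGE 79-82) and the +/- vicinity window in amino
    acids that still counts as motif-proximal."""

    motifs: tuple[tuple[str, int, int], ...] = (("DLG", 29, 31), ("ETGE", 79, 82))
    vicinity_window: int = 5

    def __post_init__(self) -> None:
        if self.vicinity_window < 0:
            raise ValidationError("vicinity_window must be >= 0")
        spans = []
        for name, start, end in self.motifs:
            if start > end:
                raise ValidationError(f"motif {name!r}: start > end")
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(f"motifs {n1!r} and {n2!r} overlap")


def assign_hot_cold(
    scores: ScoreMatrix | pd.DataFrame,
    labels: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """Call each cluster hot or cold from leukocyte-signature scores.

    Signature scores are Z-scored across samples within each signature;
    the single cluster with the minimum overall mean Z is called cold,
    every other cluster hot.  Returns (sample -> 'hot'/'cold', cluster x
    signature mean-Z profile).
    """
    values = scores.values if isinstance(scores, ScoreMatrix) else scores
    samples = list(values.columns)
    missing = [s for s in samples if s not in labels.index]
    if missing:
        raise ValidationError(f"cluster labels missing for samples: {missing[:5]}")
    labels = labels.reindex(samples)
    if labels.nunique() < 2:
        raise ValidationError("need at least 2 clusters to call hot/cold")
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    z = (mat - mat.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    zdf = pd.DataFrame(z, index=values.index, columns=samples)
    profile = zdf.T.groupby(labels).mean()  # cluster x signature
    overall = profile.mean(axis=1)
    order = overall.sort_values()
    if len(order) > 1 and order.iloc[1] - order.iloc[0] < 1e-9:
        raise ValidationError(
            "tie between clusters for minimum mean leukocyte score; "
            "assign hot/cold manually"
        )
    cold_cluster = order.index[0]
    phenotype = labels.map(lambda c: "cold" if c == cold_cluster else "hot")
    phenotype.name = "phenotype"
    return phenotype, profile


def chisq_enrichment(observed: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-squared test of independence on an r x c count table,
    without continuity correction.  Expected counts are
    row_total x col_total / grand_total; any expected cell < 5 raises the
    low-expected flag."""
    obs = observed.to_numpy(dtype=float)
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValidationError("observed table must hold non-negative integers")
    if obs.sum() == 0:
        raise ValidationError("observed table is all zero")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("observed table has an all-zero row or column")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ContingencyResult(
        observed=observed,
        expected=pd.DataFrame(expected, index=observed.index, columns=observed.columns),
        chi2=chi2,
        df=df,
        p=p,
        low_expected_flag=bool((expected < 5).any()),
    )


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference (a minus b) over the pooled sample
    SD, Cohen's original formulation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var <= 0:
        raise ValidationError("pooled SD is zero; Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def twoway_anova(score, factor1, factor2) -> AnovaResult:
    """Two-factor ANOVA with interaction on a numeric response (e.g. the
    Nrf2 activation score) with binary smoke-exposure and mutation
    factors.  Type II sums of squares.  The companion Cohen's d contrasts
    factor1 = True vs False within factor2 = True (mutated smokers vs
    mutated nonsmokers)."""
    y = np.asarray(score, dtype=float)
    f1 = np.asarray(factor1, dtype=bool)
    f2 = np.asarray(factor2, dtype=bool)
    if not (y.size == f1.size == f2.size):
        raise ValidationError("score and factors must have equal length")
    df = pd.DataFrame({"y": y, "f1": f1, "f2": f2})
    cells = df.groupby(["f1", "f2"])["y"]
    counts = cells.count()
    for cell in [(a, b) for a in (False, True) for b in (False, True)]:
        if cell not in counts.index or counts[cell] == 0:
            raise ValidationError(f"empty design cell (factor1={cell[0]}, factor2={cell[1]})")
    model = smf.ols("y ~ C(f1) * C(f2)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {"C(f1)": "factor1", "C(f2)": "factor2", "C(f1):C(f2)": "interaction",
              "Residual": "residual"}
    aov = aov.rename(index=rename)[["sum_sq", "df", "F", "PR(>F)"]]
    aov.columns = ["sum_sq", "df", "F", "p"]
    cell_means = cells.mean().unstack()
    cell_n = counts.unstack()
    d = None
    a = df.loc[df.f1 & df.f2, "y"]
    b = df.loc[~df.f1 & df.f2, "y"]
    if len(a) >= 2 and len(b) >= 2:
        try:
            d = cohens_d(a, b)
        except ValidationError:
            d = None
    return AnovaResult(
        table=aov,
        cell_means=cell_means,
        cell_n=cell_n,
        interaction_p=float(aov.loc["interaction", "p"]),
        cohens_d_mutated=d,
    )


def percentile_stratify(scores: pd.Series, q: float = 10.0) -> tuple[pd.Series, float]:
    """Split scores at their qth percentile (linear interpolation):
    scores <= cutoff are 'marginal', the rest 'elevated'."""
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValidationError("percentile_stratify: empty input")
    if len(s) < 10:
        warnings.warn(f"only {len(s)} values; the {q}th percentile is unstable",
                      stacklevel=2)
    cutoff = float(np.percentile(s.to_numpy(), q))
    strata = pd.Series(np.where(s <= cutoff, "marginal", "elevated"), index=s.index,
                       name="stratum")
    if (strata == "marginal").all():
        warnings.warn("all scores fall at or below the cutoff", stacklevel=2)
    return strata, cutoff


def classify_nfe2l2_mutation(position: int, config: MotifConfig = MotifConfig()) -> str:
    """Classify an NFE2L2 protein mutation position as motif_proximal
    (inside a KEAP1-binding motif or within the vicinity window) or
    distal."""
    if position < 1:
        raise ValidationError("protein position must be >= 1")
    w = config.vicinity_window
    for _, start, end in config.motifs:
        if start - w <= position <= end + w:
            return "motif_proximal"
    return "distal"
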