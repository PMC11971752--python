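"""Seeded synthetic-data generators with full ground-truth records.

Three study designs are emulated:

* a TCGA-like bulk RNA-seq cohort with three planted immune clusters
  (two "hot", one "cold"), a smoking covariate whose cold-vs-hot odds
  ratio is controlled in expectation, and a KEAP1/NFE2L2 mutation
  covariate driving an Nrf2-signature expression shift with a
  smoke x mutation interaction (negative-binomial counts with effective
  gene lengths, RSEM-like);
* smoke-vs-sham cell-line experiments with a shared upregulated gene set
  plus line-specific up/down sets (Gaussian noise in log2 space, the
  post-normalization regime the differential tests operate in);
* per-background metabolite peak-area tables with planted DEMs, a
  metabolite→gene association map, and a cross-background core gene set.

Every generator is a pure function of its parameters and seed, and
returns the exact truth needed to score downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    ExpressionTable,
    GeneSetCollection,
    MetaboliteGeneMap,
    MetaboliteTable,
    MutationStatus,
    SampleAnnotations,
    SmokingCategory,
    Space,
)

__all__ = [
    "CohortTruth",
    "CohortSim",
    "ExperimentTruth",
    "ExposureSim",
    "MetabolomeTruth",
    "MetabolomeSim",
    "IntegrationSim",
    "simulate_cohort",
    "simulate_exposure_experiment",
    "simulate_metabolome",
    "simulate_integration_study",
]

#: span of NFE2L2 positions counted as motif-vicinity when planting
#: mutations (DLG 29-31 and ETGE 79-82, +/- 5 aa).
_MOTIF_VICINITY = list(range(24, 37)) + list(range(74, 88))
_NFE2L2_LENGTH = 605
_KEAP1_LENGTH = 624


@dataclass
class CohortTruth:
    cluster: pd.Series  # sample -> hot1 | hot2 | cold
    smoking_exposed: pd.Series  # sample -> bool
    mutated: pd.Series  # sample -> bool
    leukocyte_sets: dict[str, frozenset[str]]
    nrf2_set: frozenset[str]
    infiltration_shift: float
    beta_mut: float
    beta_smoke: float
    beta_int: float
    smoking_or: float
    seed: int


@dataclass
class CohortSim:
    counts: ExpressionTable  # counts space, with effective lengths
    annotations: SampleAnnotations
    gene_sets: GeneSetCollection  # 14 leukocyte sets + NRF2_SIG
    truth: CohortTruth


def simulate_cohort(
    n_samples: int = 300,
    n_genes: int = 1000,
    cluster_props: Sequence[float] = (0.40, 0.35, 0.25),
    infiltration_shift: float = 1.0,
    smoking_or: float = 4.0,
    beta_mut: float = 0.5,
    beta_smoke: float = 0.1,
    beta_int: float = 0.18,
    nb_dispersion: float = 0.2,
    mut_prob: float = 0.25,
    smoking_base_rate: float = 0.35,
    n_leukocyte_sets: int = 14,
    leukocyte_set_size: int = 30,
    nrf2_set_size: int = 138,
    seed: int = 0,
) -> CohortSim:
    """Simulate a TCGA-like cohort.

    Genes are partitioned into ``n_leukocyte_sets`` disjoint leukocyte
    signatures, one Nrf2 signature and background.  The per-sample log2
    mean is

        base_g + infiltration_shift * [g in leukocyte set] * [sample hot]
               + (beta_mut*mut + beta_smoke*smoke + beta_int*mut*smoke)
                 * [g in Nrf2 set]

    with counts drawn negative-binomial (variance mu + disp*mu^2).  The
    two hot clusters share elevated infiltration but differ in profile:
    hot2 receives 1.5x the shift on the second half of the leukocyte
    sets, making the three true clusters geometrically distinct.
    Smoking is assigned so the cold-vs-hot exposure odds ratio equals
    ``smoking_or`` in expectation.  Effect sizes are log2 shifts.
    """
    props = np.asarray(cluster_props, dtype=float)
    if props.size != 3 or not np.isclose(props.sum(), 1.0):
        raise ValidationError("cluster_props must be 3 proportions summing to 1")
    if smoking_or <= 0:
        raise ValidationError("smoking odds ratio must be > 0")
    planted = n_leukocyte_sets * leukocyte_set_size + nrf2_set_size
    if planted > n_genes:
        raise ValidationError(
            f"{planted} signature genes exceed n_genes={n_genes}"
        )
    odds_hot = smoking_base_rate / (1 - smoking_base_rate)
    p_cold = smoking_or * odds_hot / (1 + smoking_or * odds_hot)
    if not (0 < p_cold < 1):
        raise ValidationError("infeasible smoking odds ratio for the base rate")

    rng = np.random.default_rng([seed, 0])
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    # gene partition
    leukocyte_sets: dict[str, frozenset[str]] = {}
    pos = 0
    for s in range(n_leukocyte_sets):
        leukocyte_sets[f"LEUK_{s + 1:02d}"] = frozenset(
            genes[pos : pos + leukocyte_set_size]
        )
        pos += leukocyte_set_size
    nrf2_set = frozenset(genes[pos : pos + nrf2_set_size])
    pos += nrf2_set_size

    cluster = rng.choice(["hot1", "hot2", "cold"], size=n_samples, p=props)
    is_hot = cluster != "cold"
    p_smoke = np.where(is_hot, smoking_base_rate, p_cold)
    smoke = rng.random(n_samples) < p_smoke
    mut = rng.random(n_samples) < mut_prob

    # per-gene baseline and shift bookkeeping
    gene_idx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(5.0, 1.5, size=n_genes)
    leuk_mask = np.zeros(n_genes, dtype=bool)
    leuk_second_half = np.zeros(n_genes, dtype=bool)
    for s, (name, members) in enumerate(leukocyte_sets.items()):
        idx = [gene_idx[g] for g in sorted(members)]
        leuk_mask[idx] = True
        if s >= n_leukocyte_sets // 2:
            leuk_second_half[idx] = True
    nrf2_mask = np.zeros(n_genes, dtype=bool)
    nrf2_mask[[gene_idx[g] for g in sorted(nrf2_set)]] = True

    hot2 = cluster == "hot2"
    leuk_shift = (
        infiltration_shift * is_hot[None, :] * leuk_mask[:, None]
        + 0.5 * infiltration_shift * hot2[None, :] * leuk_second_half[:, None]
    )
    nrf2_effect = beta_mut * mut + beta_smoke * smoke + beta_int * (mut & smoke)
    log2_mean = base[:, None] + leuk_shift + nrf2_mask[:, None] * nrf2_effect[None, :]
    mu = np.exp2(log2_mean)
    size = 1.0 / nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(float)
    lengths = pd.Series(rng.uniform(500, 5000, size=n_genes), index=genes)

    # annotations
    exposed_draw = rng.random(n_samples)
    unexposed_draw = rng.random(n_samples)
    smoke_cat = [
        (SmokingCategory.current if exposed_draw[i] < 0.5 else SmokingCategory.reformed_le15)
        if smoke[i]
        else (SmokingCategory.never if unexposed_draw[i] < 0.7 else SmokingCategory.reformed_gt15)
        for i in range(n_samples)
    ]
    type_draw = rng.random(n_samples)
    status = [
        (MutationStatus.KEAP1_mut if type_draw[i] < 0.5 else MutationStatus.NFE2L2_mut)
        if mut[i]
        else MutationStatus.WT
        for i in range(n_samples)
    ]
    positions: list = []
    for i in range(n_samples):
        if not mut[i]:
            positions.append(pd.NA)
        elif status[i] is MutationStatus.NFE2L2_mut:
            if rng.random() < 0.8:
                positions.append(int(rng.choice(_MOTIF_VICINITY)))
            else:
                positions.append(int(rng.integers(100, _NFE2L2_LENGTH + 1)))
        else:
            positions.append(int(rng.integers(1, _KEAP1_LENGTH + 1)))
    annot = pd.DataFrame(
        {
            "smoking_category": smoke_cat,
            "mutation_status": status,
            "mutation_protein_position": pd.array(positions, dtype="Int64"),
            "group": [None] * n_samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    sets = dict(leukocyte_sets)
    sets["NRF2_SIG"] = nrf2_set
    descriptions = {name: "synthetic leukocyte signature" for name in leukocyte_sets}
    descriptions["NRF2_SIG"] = "synthetic Nrf2 activation signature"

    truth = CohortTruth(
        cluster=pd.Series(cluster, index=samples, name="true_cluster"),
        smoking_exposed=pd.Series(smoke, index=samples, name="smoking_exposed"),
        mutated=pd.Series(mut, index=samples, name="mutated"),
        leukocyte_sets=leukocyte_sets,
        nrf2_set=nrf2_set,
        infiltration_shift=infiltration_shift,
        beta_mut=beta_mut,
        beta_smoke=beta_smoke,
        beta_int=beta_int,
        smoking_or=smoking_or,
        seed=seed,
    )
    return CohortSim(
        counts=ExpressionTable(
            values=pd.DataFrame(counts, index=genes, columns=samples),
            space=Space.counts,
            lengths=lengths,
        ),
        annotations=SampleAnnotations(table=annot),
        gene_sets=GeneSetCollection(sets=sets, descriptions=descriptions),
        truth=truth,
    )


@dataclass
class ExperimentTruth:
    shared_up: frozenset[str]
    specific_up: dict[str, frozenset[str]]
    specific_down: dict[str, frozenset[str]]
    log2_shift: float
    noise_sd: float
    seed: int


@dataclass
class ExposureSim:
    tables: dict[str, ExpressionTable]  # per line, log2 space
    treated: dict[str, list[str]]
    sham: dict[str, list[str]]
    truth: ExperimentTruth


def simulate_exposure_experiment(
    n_lines: int = 4,
    n_reps: int = 4,
    n_genes: int = 2000,
    shared_up_size: int = 40,
    specific_up_size: int = 30,
    specific_down_size: int = 30,
    log2_shift: float = 2.0,
    noise_sd: float = 0.25,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
    line_names: Sequence[str] | None = None,
    gene_names: Sequence[str] | None = None,
) -> ExposureSim:
    """Simulate smoke-vs-sham replicate matrices for several cell lines.

    A shared set of genes is shifted up by ``log2_shift`` in every line;
    each line additionally gets its own up and down sets.  Values are
    Gaussian in log2 space around per-gene baselines.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    planted = shared_up_size + n_lines * (specific_up_size + specific_down_size)
    if planted > n_genes:
        raise ValidationError(f"{planted} planted genes exceed n_genes={n_genes}")
    if line_names is None:
        line_names = [f"LINE{i + 1}" for i in range(n_lines)]
    if len(line_names) != n_lines:
        raise ValidationError("line_names length must equal n_lines")
    if gene_names is None:
        gene_names = [f"G{i + 1:05d}" for i in range(n_genes)]
    if len(set(gene_names)) != n_genes:
        raise ValidationError("gene_names must be unique and match n_genes")
    genes = list(gene_names)

    pos = 0
    shared_up = frozenset(genes[:shared_up_size])
    pos += shared_up_size
    specific_up: dict[str, frozenset[str]] = {}
    specific_down: dict[str, frozenset[str]] = {}
    for line in line_names:
        specific_up[line] = frozenset(genes[pos : pos + specific_up_size])
        pos += specific_up_size
        specific_down[line] = frozenset(genes[pos : pos + specific_down_size])
        pos += specific_down_size

    rng = np.random.default_rng([seed, 1])
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    shift = np.zeros((n_genes, len(line_names)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, line in enumerate(line_names):
        for g in shared_up | specific_up[line]:
            shift[gene_idx[g], j] = log2_shift
        for g in specific_down[line]:
            shift[gene_idx[g], j] = -log2_shift

    tables: dict[str, ExpressionTable] = {}
    treated: dict[str, list[str]] = {}
    sham: dict[str, list[str]] = {}
    for j, line in enumerate(line_names):
        t_cols = [f"{line}_smoke_{r + 1}" for r in range(n_reps)]
        s_cols = [f"{line}_sham_{r + 1}" for r in range(n_reps)]
        mean_t = base + shift[:, j]
        vals = np.empty((n_genes, 2 * n_reps))
        vals[:, :n_reps] = mean_t[:, None] + rng.normal(0, noise_sd, (n_genes, n_reps))
        vals[:, n_reps:] = base[:, None] + rng.normal(0, noise_sd, (n_genes, n_reps))
        tables[line] = ExpressionTable(
            values=pd.DataFrame(vals, index=genes, columns=t_cols + s_cols),
            space=Space.log2,
        )
        treated[line] = t_cols
        sham[line] = s_cols

    truth = ExperimentTruth(
        shared_up=shared_up,
        specific_up=specific_up,
        specific_down=specific_down,
        log2_shift=log2_shift,
        noise_sd=noise_sd,
        seed=seed,
    )
    return ExposureSim(tables=tables, treated=treated, sham=sham, truth=truth)


@dataclass
class MetabolomeTruth:
    planted_dems: dict[str, frozenset[str]]  # per background
    core_genes: frozenset[str]
    metabolite_gene_map: MetaboliteGeneMap
    log2_shift: float
    seed: int


@dataclass
class MetabolomeSim:
    tables: dict[str, MetaboliteTable]  # per background, linear peak areas
    treated: dict[str, list[str]]
    sham: dict[str, list[str]]
    gene_map: MetaboliteGeneMap
    truth: MetabolomeTruth


def simulate_metabolome(
    n_backgrounds: int = 3,
    n_metabolites: int = 300,
    dem_size: int = 30,
    core_genes: Sequence[str] = ("GPX2", "GSR"),
    n_reps: int = 4,
    log2_shift: float = 2.0,
    noise_sd: float = 0.5,
    decoys_per_dem: int = 2,
    core_carriers: int = 3,
    seed: int = 0,
    background_names: Sequence[str] | None = None,
    deg_up_sets: dict[str, set[str]] | None = None,
) -> MetabolomeSim:
    """Simulate per-background metabolite peak-area tables plus a
    metabolite→gene map.

    The same DEM set is planted (shifted up in treated samples) in every
    background.  Each core gene is mapped from ``core_carriers`` planted
    DEMs — mirroring how a redox enzyme associates with several
    metabolites of its pathway in HMDB — and every planted DEM
    additionally maps to decoy genes (MGENE_*) that by construction
    never appear in any expression experiment.  When ``deg_up_sets`` is
    given, the core genes are checked to be planted upregulated DEGs in
    every background.
    """
    core = list(dict.fromkeys(core_genes))
    if core_carriers < 1:
        raise ValidationError("core_carriers must be >= 1")
    if dem_size > 0 and dem_size < len(core) * core_carriers:
        raise ValidationError(
            "dem_size must be >= number of core genes times core_carriers"
        )
    if background_names is None:
        background_names = [f"BG{i + 1}" for i in range(n_backgrounds)]
    if len(background_names) != n_backgrounds:
        raise ValidationError("background_names length must equal n_backgrounds")
    if deg_up_sets is not None:
        for bg, up in deg_up_sets.items():
            missing = set(core) - set(up)
            if missing:
                raise ValidationError(
                    f"inconsistent core: {sorted(missing)} not upregulated in {bg!r}"
                )

    rng = np.random.default_rng([seed, 2])
    mets = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    planted = frozenset(mets[:dem_size])

    mapping: dict[str, frozenset[str]] = {}
    for i, met in enumerate(mets):
        if met in planted:
            genes = {f"MGENE_{met}_{d + 1}" for d in range(decoys_per_dem)}
            if core and i < len(core) * core_carriers:
                genes.add(core[i % len(core)])
            mapping[met] = frozenset(genes)
        elif rng.random() < 0.5:  # some null metabolites map to decoys too
            mapping[met] = frozenset({f"MGENE_{met}_1"})
    gene_map = MetaboliteGeneMap(mapping=mapping)

    base = rng.normal(20.0, 2.0, size=n_metabolites)
    dem_mask = np.array([m in planted for m in mets])
    tables: dict[str, MetaboliteTable] = {}
    treated: dict[str, list[str]] = {}
    sham: dict[str, list[str]] = {}
    for bg in background_names:
        t_cols = [f"{bg}_smoke_{r + 1}" for r in range(n_reps)]
        s_cols = [f"{bg}_sham_{r + 1}" for r in range(n_reps)]
        log2_vals = np.empty((n_metabolites, 2 * n_reps))
        mean_t = base + log2_shift * dem_mask
        log2_vals[:, :n_reps] = mean_t[:, None] + rng.normal(
            0, noise_sd, (n_metabolites, n_reps)
        )
        log2_vals[:, n_reps:] = base[:, None] + rng.normal(
            0, noise_sd, (n_metabolites, n_reps)
        )
        tables[bg] = MetaboliteTable(
            values=pd.DataFrame(np.exp2(log2_vals), index=mets, columns=t_cols + s_cols),
            space=Space.linear,
        )
        treated[bg] = t_cols
        sham[bg] = s_cols

    truth = MetabolomeTruth(
        planted_dems={bg: planted for bg in background_names},
        core_genes=frozenset(core) if dem_size > 0 else frozenset(),
        metabolite_gene_map=gene_map,
        log2_shift=log2_shift,
        seed=seed,
    )
    return MetabolomeSim(
        tables=tables, treated=treated, sham=sham, gene_map=gene_map, truth=truth
    )


@dataclass
class IntegrationSim:
    exposure: ExposureSim
    metabolome: MetabolomeSim
    core_genes: frozenset[str]


def simulate_integration_study(
    seed: int = 0,
    n_backgrounds: int = 3,
    core_gene_names: Sequence[str] = ("GPX2", "GSR"),
    **kwargs,
) -> IntegrationSim:
    """Matched exposure + metabolome simulation for end-to-end
    integration: the named core genes are placed in the shared
    upregulated set of every background's expression experiment and
    mapped from planted DEMs."""
    exp_kwargs = {k[9:]: v for k, v in kwargs.items() if k.startswith("exposure_")}
    met_kwargs = {k[11:]: v for k, v in kwargs.items() if k.startswith("metabolome_")}
    n_genes = exp_kwargs.pop("n_genes", 2000)
    gene_names = [f"G{i + 1:05d}" for i in range(n_genes)]
    core = list(dict.fromkeys(core_gene_names))
    gene_names[: len(core)] = core  # first shared-up genes get the core names
    exposure = simulate_exposure_experiment(
        n_lines=n_backgrounds,
        n_genes=n_genes,
        gene_names=gene_names,
        line_names=[f"BG{i + 1}" for i in range(n_backgrounds)],
        seed=seed,
        **exp_kwargs,
    )
    metabolome = simulate_metabolome(
        n_backgrounds=n_backgrounds,
        core_genes=core,
        seed=seed,
        background_names=list(exposure.tables),
        deg_up_sets={bg: set(exposure.truth.shared_up) for bg in exposure.tables},
        **met_kwargs,
    )
    return IntegrationSim(
        exposure=exposure, metabolome=metabolome, core_genes=frozenset(core)
    )
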