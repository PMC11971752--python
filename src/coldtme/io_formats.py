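"""Readers, writers and domain containers for every external table the
pipeline touches.

Canonical dialect is TSV: a header row of sample ids, first column holding
feature ids.  Gene identifiers are opaque, case-sensitive strings — no
symbol/alias resolution is attempted.  Missing values are rejected, never
imputed, because every downstream statistic assumes complete matrices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Space",
    "ExpressionTable",
    "MetaboliteTable",
    "GeneSetCollection",
    "SmokingCategory",
    "MutationStatus",
    "SampleAnnotations",
    "MetaboliteGeneMap",
    "read_expression_table",
    "write_expression_table",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "read_metabolite_gene_map",
    "write_metabolite_gene_map",
]


class Space(str, enum.Enum):
    """Value space of a feature-by-sample matrix."""

    counts = "counts"
    linear = "linear"
    log2 = "log2"


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


def _check_matrix(values: pd.DataFrame, what: str) -> None:
    _check_unique(values.index, f"{what} row")
    _check_unique(values.columns, f"{what} column")
    bad = ~np.isfinite(values.to_numpy(dtype=float, copy=False))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"non-finite or missing value at row {values.index[i]!r}, "
            f"column {values.columns[j]!r}"
        )


@dataclass
class ExpressionTable:
    """Gene-by-sample numeric matrix with a declared value space.

    ``values`` is indexed by gene id with sample ids as columns.
    ``lengths`` holds per-gene effective lengths in bases (required before
    FPKM-UQ normalization of counts).
    """

    values: pd.DataFrame
    space: Space
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.space = Space(self.space)
        _check_matrix(self.values, "gene matrix")
        if self.space is Space.counts and (self.values.to_numpy() < 0).any():
            raise ValidationError("counts space requires all values >= 0")
        if self.lengths is not None:
            self.lengths = self.lengths.astype(float)
            if (self.lengths <= 0).any():
                bad = self.lengths.index[self.lengths <= 0][0]
                raise ValidationError(f"non-positive effective length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def require_lengths(self) -> pd.Series:
        if self.lengths is None:
            raise ValidationError("effective gene lengths are required but absent")
        missing = [g for g in self.values.index if g not in self.lengths.index]
        if missing:
            raise ValidationError(
                "genes missing an effective length: " + ", ".join(map(repr, missing))
            )
        return self.lengths.reindex(self.values.index)


@dataclass
class MetaboliteTable:
    """Metabolite-by-sample peak areas (or transformed values)."""

    values: pd.DataFrame
    space: Space

    def __post_init__(self) -> None:
        self.space = Space(self.space)
        _check_matrix(self.values, "metabolite matrix")
        if self.space is Space.linear and (self.values.to_numpy() < 0).any():
            raise ValidationError("peak areas must be >= 0")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (leukocyte subsets, the Nrf2 signature, pathway
    libraries) with per-set free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


class SmokingCategory(str, enum.Enum):
    current = "current"
    reformed_le15 = "reformed_le15"
    reformed_gt15 = "reformed_gt15"
    never = "never"
    unknown = "unknown"


class MutationStatus(str, enum.Enum):
    KEAP1_mut = "KEAP1_mut"
    NFE2L2_mut = "NFE2L2_mut"
    WT = "WT"
    unknown = "unknown"


#: categories counted as smoke-exposed when dichotomizing: current smokers
#: and those who quit within 15 years of diagnosis.
EXPOSED_CATEGORIES = frozenset({SmokingCategory.current, SmokingCategory.reformed_le15})
UNEXPOSED_CATEGORIES = frozenset({SmokingCategory.never, SmokingCategory.reformed_gt15})


@dataclass
class SampleAnnotations:
    """Per-sample clinical covariates: smoking category, KEAP1/NFE2L2
    mutation status (with protein position for mutants) and an optional
    free-form group label.  Extra columns are preserved opaquely in
    ``extra``."""

    table: pd.DataFrame  # index: sample_id; columns: smoking_category,
    # mutation_status, mutation_protein_position, group
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for s, row in self.table.iterrows():
            status = row["mutation_status"]
            pos = row["mutation_protein_position"]
            if pd.notna(pos):
                if status not in (MutationStatus.KEAP1_mut, MutationStatus.NFE2L2_mut):
                    raise ValidationError(
                        f"sample {s!r}: mutation_protein_position given but "
                        f"mutation_status is {status.value!r}"
                    )
                if int(pos) < 1:
                    raise ValidationError(f"sample {s!r}: protein position must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def smoking(self, sample: str) -> SmokingCategory:
        return self.table.loc[sample, "smoking_category"]

    def mutation(self, sample: str) -> MutationStatus:
        return self.table.loc[sample, "mutation_status"]

    def smoking_exposed(self) -> pd.Series:
        """Dichotomized smoke exposure: True for current/reformed<=15y,
        False for never/reformed>15y; samples with unknown history are
        dropped."""
        cat = self.table["smoking_category"]
        keep = cat != SmokingCategory.unknown
        return cat[keep].isin(EXPOSED_CATEGORIES)


@dataclass
class MetaboliteGeneMap:
    """Mapping metabolite id -> set of associated gene ids (HMDB-style).
    Unmapped metabolites may carry an empty set."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.mapping = {m: frozenset(g) for m, g in self.mapping.items()}

    def genes_for(self, metabolite: str) -> frozenset[str]:
        return self.mapping.get(metabolite, frozenset())

    def __contains__(self, metabolite: str) -> bool:
        return metabolite in self.mapping


# ---------------------------------------------------------------------------
# matrix I/O


def _read_matrix(path: str | Path, sep: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene/metabolite")
    _check_unique(df.columns, "sample")
    try:
        num = df.astype(float)
    except ValueError:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise FormatError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    if num.isna().to_numpy().any():
        ij = np.argwhere(num.isna().to_numpy())[0]
        raise FormatError(
            f"missing value at row {num.index[ij[0]]!r}, "
            f"column {num.columns[ij[1]]!r} in {path}"
        )
    return num


def _read_lengths(path: str | Path, sep: str) -> pd.Series:
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            gene, raw = parts
            try:
                val = float(raw)
            except ValueError:
                if lineno == 1:  # tolerate a header line
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric length {raw!r}") from None
            rows.append((gene, val))
    _check_unique([g for g, _ in rows], "length-file gene")
    return pd.Series(dict(rows), dtype=float)


def read_expression_table(
    path: str | Path,
    space: Space | str,
    lengths_path: str | Path | None = None,
    sep: str = "\t",
) -> ExpressionTable:
    """Read a gene-by-sample TSV matrix; optionally attach effective gene
    lengths from a two-column (gene, length) file.

    Genes present in the lengths file but absent from the matrix are
    ignored; matrix genes without a length are an error when
    ``space='counts'`` and lengths are supplied.
    """
    space = Space(space)
    values = _read_matrix(path, sep)
    lengths = None
    if lengths_path is not None:
        lengths = _read_lengths(lengths_path, sep)
        lengths = lengths[lengths.index.isin(values.index)]
        if space is Space.counts:
            missing = [g for g in values.index if g not in lengths.index]
            if missing:
                raise ValidationError(
                    "counts matrix genes missing an effective length: "
                    + ", ".join(map(repr, missing))
                )
    return ExpressionTable(values=values, space=space, lengths=lengths)


def write_expression_table(table: ExpressionTable, path: str | Path, sep: str = "\t") -> None:
    table.values.to_csv(path, sep=sep, index_label="gene_id")


def read_metabolite_table(path: str | Path, space: Space | str = Space.linear, sep: str = "\t") -> MetaboliteTable:
    return MetaboliteTable(values=_read_matrix(path, sep), space=Space(space))


def write_metabolite_table(table: MetaboliteTable, path: str | Path, sep: str = "\t") -> None:
    table.values.to_csv(path, sep=sep, index_label="metabolite_id")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line.
    Duplicate genes within a line are de-duplicated; duplicate set names
    are an error."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(parts)} fields (< 3)")
            name, desc, *genes = parts
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# annotations

_ANNOT_COLUMNS = [
    "smoking_category",
    "mutation_status",
    "mutation_protein_position",
    "group",
]


def _parse_enum(token, enum_cls, default, where: str):
    if token is None or (isinstance(token, float) and np.isnan(token)) or str(token).strip() == "":
        return default
    key = str(token).strip()
    for member in enum_cls:
        if member.value.lower() == key.lower():
            return member
    raise ValidationError(f"{where}: unrecognized {enum_cls.__name__} token {key!r}")


def read_annotations(path: str | Path, sep: str = "\t") -> SampleAnnotations:
    """Read a per-sample annotation TSV with columns ``sample_id,
    smoking_category, mutation_status, mutation_protein_position, group``.
    Enum tokens are parsed case-insensitively; blanks become
    unknown/absent.  Extra columns are preserved opaquely."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    _check_unique(raw["sample_id"], "sample")
    raw = raw.set_index("sample_id")
    out = pd.DataFrame(index=raw.index)
    out["smoking_category"] = [
        _parse_enum(v, SmokingCategory, SmokingCategory.unknown, f"sample {s!r}")
        for s, v in raw.get("smoking_category", pd.Series(index=raw.index, dtype=object)).items()
    ]
    out["mutation_status"] = [
        _parse_enum(v, MutationStatus, MutationStatus.unknown, f"sample {s!r}")
        for s, v in raw.get("mutation_status", pd.Series(index=raw.index, dtype=object)).items()
    ]
    pos_raw = raw.get("mutation_protein_position", pd.Series(index=raw.index, dtype=object))
    positions = []
    for s, v in pos_raw.items():
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            positions.append(np.nan)
        else:
            try:
                positions.append(int(float(v)))
            except ValueError:
                raise FormatError(f"sample {s!r}: non-integer protein position {v!r}") from None
    out["mutation_protein_position"] = pd.array(positions, dtype="Int64")
    grp = raw.get("group", pd.Series(index=raw.index, dtype=object))
    out["group"] = [None if (v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "") else str(v) for v in grp]
    extra_cols = [c for c in raw.columns if c not in _ANNOT_COLUMNS]
    extra = raw[extra_cols] if extra_cols else None
    return SampleAnnotations(table=out, extra=extra)


def write_annotations(annotations: SampleAnnotations, path: str | Path, sep: str = "\t") -> None:
    df = annotations.table.copy()
    df["smoking_category"] = [c.value for c in df["smoking_category"]]
    df["mutation_status"] = [m.value for m in df["mutation_status"]]
    if annotations.extra is not None:
        df = pd.concat([df, annotations.extra], axis=1)
    df.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# metabolite -> gene map


def read_metabolite_gene_map(path: str | Path, sep: str = "\t") -> MetaboliteGeneMap:
    """Read a two-column TSV ``metabolite_id<TAB>gene_id`` (one pair per
    line, header optional); repeated metabolite rows accumulate genes."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            met, gene = parts
            if lineno == 1 and met.lower() in ("metabolite_id", "metabolite"):
                continue
            mapping.setdefault(met, set())
            if gene:
                mapping[met].add(gene)
    return MetaboliteGeneMap(mapping={m: frozenset(g) for m, g in mapping.items()})


def write_metabolite_gene_map(mgmap: MetaboliteGeneMap, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"metabolite_id{sep}gene_id\n")
        for met in sorted(mgmap.mapping):
            genes = sorted(mgmap.mapping[met])
            if not genes:
                fh.write(f"{met}{sep}\n")
            for g in genes:
                fh.write(f"{met}{sep}{g}\n")
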