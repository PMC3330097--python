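"""Domain containers and plain-text I/O.

The pipeline works on five tabular objects: a genes x samples log2 expression
matrix, a matching boolean detection-flag matrix (per-array present/absent
calls), a sample table describing the experimental design (accession, day
after germination, flowering status, replicate), a daily weather series
(tmax, tmin, precipitation), and a per-sample phenotype table (rosette leaf
number, rosette diameter). Gene-set collections use the GMT dialect.

All on-disk formats are plain text: TSV with '.' decimals and '#' comment
lines for the matrices and tables, CSV for the weather series, GMT for gene
sets. Gene and sample order is preserved from file; alignment between the
expression matrix and the flag matrix is checked, never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "DetectionFlags",
    "SampleTable",
    "EnvironmentSeries",
    "PhenotypeTable",
    "GeneSet",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_flags",
    "write_flags",
    "read_samples",
    "write_samples",
    "read_environment",
    "write_environment",
    "read_phenotypes",
    "write_phenotypes",
    "read_gene_sets",
    "write_gene_sets",
    "join_design",
]

FLOWERING_STATES = ("vegetative", "flowering")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending row/column."""


class ValidationError(ValueError):
    """A container violated one of its invariants."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids, float values

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.floating):
            raise ValidationError("expression values must be floating point")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise ValidationError(f"unknown gene ids: {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df)


@dataclass(frozen=True)
class DetectionFlags:
    """Boolean present/absent call per gene per array; axes mirror the paired matrix."""

    data: pd.DataFrame  # same axes as ExpressionMatrix, dtype bool

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        if not self.data.dtypes.map(lambda d: d == bool).all():
            raise ValidationError("detection flags must be boolean")

    def check_aligned(self, matrix: ExpressionMatrix) -> None:
        if list(self.data.index) != matrix.gene_ids or list(self.data.columns) != matrix.sample_ids:
            raise ValidationError("detection flags are not aligned to the expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class SampleTable:
    """Experimental design: one row per array.

    Columns: sample_id, accession, day (days after germination),
    flowering_status ('vegetative' | 'flowering'), replicate (>= 1).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "accession", "day", "flowering_status", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample id")
        if (self.data["day"] < 0).any():
            raise ValidationError("negative day in sample table")
        if (self.data["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        bad = set(self.data["flowering_status"]) - set(FLOWERING_STATES)
        if bad:
            raise ValidationError(f"unknown flowering status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Replicate groups keyed by (accession, day, flowering_status)."""
        return self.data.groupby(["accession", "day", "flowering_status"], sort=False)


@dataclass(frozen=True)
class EnvironmentSeries:
    """Daily weather: day, tmax, tmin (deg C), precipitation (mm)."""

    data: pd.DataFrame

    REQUIRED = ("day", "tmax", "tmin", "precipitation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"environment series missing columns: {missing}")
        _check_unique(self.data["day"], "day")
        if (self.data["tmax"] < self.data["tmin"]).any():
            bad = self.data.loc[self.data["tmax"] < self.data["tmin"], "day"].tolist()
            raise ValidationError(f"tmax < tmin on days {bad}")
        if (self.data["precipitation"] < 0).any():
            raise ValidationError("negative precipitation")


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample phenotypes: rosette leaf number (rln) and diameter (rd).

    Missing values are permitted (encoded as NA on disk); operations that
    need complete covariates drop incomplete samples and say so.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "rln", "rd")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample id")
        for col in ("rln", "rd"):
            vals = self.data[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative {col}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT semantics). Unknown genes are retained; filtering
    against a universe happens at enrichment time."""

    sets: tuple[GeneSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set name")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def sizes(self) -> dict[str, int]:
        return {s.name: len(s) for s in self.sets}


# ---------------------------------------------------------------------------
# I/O


def _read_table(path, sep: str, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{what} file {path}: {exc}") from None
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{what} file {path}: duplicate column ids {dups}")
    return df


def _to_float(df: pd.DataFrame, path, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{what} file {path}: non-numeric value {bad.iloc[0]!r} "
                f"in column {col!r}, row {bad.index[0]}"
            ) from None
    return pd.DataFrame(out, index=df.index).astype(float)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids)."""
    df = _read_table(path, "\t", "expression")
    if df.shape[1] < 2:
        raise ParseError(f"expression file {path}: needs a gene-id column and >=1 sample")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ParseError(f"expression file {path}: repeated gene id {dup!r}")
    body = _to_float(df.drop(columns=gene_col), path, "expression")
    body.index = pd.Index(genes, name=gene_col)
    try:
        return ExpressionMatrix(body)
    except ValidationError as exc:
        raise ParseError(f"expression file {path}: {exc}") from None


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_flags(path) -> DetectionFlags:
    """Read a genes x samples TSV of 0/1 detection flags."""
    df = _read_table(path, "\t", "flags")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ParseError(f"flags file {path}: repeated gene id {dup!r}")
    body = df.drop(columns=gene_col)
    bad = ~body.isin(["0", "1", "True", "False"]).all(axis=None)
    if bad:
        raise ParseError(f"flags file {path}: flags must be 0/1")
    body = body.replace({"True": "1", "False": "0"}).astype(int).astype(bool)
    body.index = pd.Index(genes, name=gene_col)
    return DetectionFlags(body)


def write_flags(flags: DetectionFlags, path) -> None:
    flags.data.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path) -> SampleTable:
    df = _read_table(path, "\t", "samples")
    for col in ("day", "replicate"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return SampleTable(df)


def write_samples(samples: SampleTable, path) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


def read_environment(path) -> EnvironmentSeries:
    """Read the daily weather CSV with header day,tmax,tmin,precipitation."""
    df = _read_table(path, ",", "environment")
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    for col in ("tmax", "tmin", "precipitation"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return EnvironmentSeries(df)


def write_environment(env: EnvironmentSeries, path) -> None:
    env.data.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("rln", "rd"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace({"NA": None, "": None}), errors="raise")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member1 TAB member2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"gene set file {path}, line {lineno}: expected "
                    f"name<TAB>description<TAB>members, got {len(fields)} fields"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"gene set file {path}, line {lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, genes=tuple(members), description=description))
    return GeneSetCollection(tuple(sets))


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def join_design(
    samples: SampleTable,
    env: EnvironmentSeries | None = None,
    pheno: PhenotypeTable | None = None,
) -> pd.DataFrame:
    """One row per sample: design factors plus day-matched weather and phenotypes.

    The sample's `day` doubles as the plant-age covariate. Raises if any
    sample day has no weather row.
    """
    out = samples.data.copy()
    if env is not None:
        missing = sorted(set(out["day"]) - set(env.data["day"]))
        if missing:
            raise ValidationError(f"environment series missing sample days: {missing}")
        out = out.merge(env.data, on="day", how="left", validate="many_to_one")
    if pheno is not None:
        out = out.merge(pheno.data, on="sample_id", how="left", validate="one_to_one")
    if len(out) != len(samples.data):
        raise ValidationError("join produced duplicated sample rows")
    return out
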