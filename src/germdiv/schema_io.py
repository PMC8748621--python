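"""Trait schemas, phenotype matrices and table I/O.

A :class:`TraitSchema` declares, in a fixed order, which traits are qualitative
(coded classes, e.g. fruit shape) and which are quantitative (numeric with a
unit, e.g. fruit weight in g).  A :class:`PhenotypeMatrix` is the pipeline's
single input: one row per individual, one column per trait, read from
CSV/TSV with a leading ``id`` column and trait abbreviations as headers.
Columns are matched to the schema by abbreviation (case-sensitive), so input
column order never matters downstream.

Missing values are written as ``NA``; both ``NA`` and empty cells are accepted
on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DuplicateAbbreviationError,
    DuplicateIndividualError,
    InvalidClassesError,
    MatrixParseError,
    SchemaError,
    UnknownColumnError,
)

_MISSING_TOKENS = ("", "NA")

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"


@dataclass(frozen=True)
class TraitDef:
    """One trait: display name, stable abbreviation, kind, unit and class codes."""

    name: str
    abbreviation: str
    kind: str
    unit: str = ""
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (QUALITATIVE, QUANTITATIVE):
            raise SchemaError(f"unknown trait kind {self.kind!r} for {self.abbreviation!r}")
        if not self.abbreviation:
            raise SchemaError(f"trait {self.name!r} has an empty abbreviation")
        if self.kind == QUALITATIVE and len(self.classes) < 2:
            raise InvalidClassesError(
                f"qualitative trait {self.abbreviation!r} declares "
                f"{len(self.classes)} class(es); at least 2 required"
            )
        if self.kind == QUANTITATIVE and self.classes:
            raise InvalidClassesError(
                f"quantitative trait {self.abbreviation!r} must not declare classes"
            )


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of trait definitions; order is preserved end to end."""

    traits: tuple[TraitDef, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.traits:
            if t.abbreviation in seen:
                raise DuplicateAbbreviationError(
                    f"abbreviation {t.abbreviation!r} declared more than once"
                )
            seen.add(t.abbreviation)

    @property
    def abbreviations(self) -> list[str]:
        return [t.abbreviation for t in self.traits]

    @property
    def qualitative(self) -> list[TraitDef]:
        return [t for t in self.traits if t.kind == QUALITATIVE]

    @property
    def quantitative(self) -> list[TraitDef]:
        return [t for t in self.traits if t.kind == QUANTITATIVE]

    def __getitem__(self, abbreviation: str) -> TraitDef:
        for t in self.traits:
            if t.abbreviation == abbreviation:
                return t
        raise KeyError(abbreviation)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self.abbreviations

    def __len__(self) -> int:
        return len(self.traits)

    def subset(self, abbreviations: Iterable[str]) -> "TraitSchema":
        """Schema restricted to the given traits, keeping schema order."""
        keep = set(abbreviations)
        unknown = keep - set(self.abbreviations)
        if unknown:
            raise UnknownColumnError(f"unknown trait abbreviation(s): {sorted(unknown)}")
        return TraitSchema(tuple(t for t in self.traits if t.abbreviation in keep))


def _schema_from_mapping(doc: dict) -> TraitSchema:
    try:
        entries = doc["traits"]
    except (KeyError, TypeError):
        raise SchemaError("schema document must contain a 'traits' list")
    traits = []
    for entry in entries:
        traits.append(
            TraitDef(
                name=str(entry.get("name", entry["abbreviation"])),
                abbreviation=str(entry["abbreviation"]),
                kind=str(entry["kind"]),
                unit=str(entry.get("unit", "") or ""),
                classes=tuple(str(c) for c in entry.get("classes", []) or []),
            )
        )
    return TraitSchema(tuple(traits))


def default_schema() -> TraitSchema:
    """The bundled 37-trait schema: 8 qualitative + 29 quantitative traits."""
    text = resources.files("germdiv.data").joinpath("default_schema.yaml").read_text()
    return _schema_from_mapping(yaml.safe_load(text))


def load_trait_schema(path: str | Path | None = None) -> TraitSchema:
    """Read a trait schema from a YAML/JSON document; ``None`` loads the bundled default."""
    if path is None:
        return default_schema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"schema file not found: {path}")
    return _schema_from_mapping(yaml.safe_load(path.read_text()))


@dataclass
class PhenotypeMatrix:
    """Individuals x traits table.

    ``data`` is indexed by individual ID with columns in schema order;
    qualitative columns hold class-code strings (or ``None`` when missing),
    quantitative columns hold floats (``NaN`` when missing).
    """

    data: pd.DataFrame
    schema: TraitSchema

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateIndividualError(f"duplicated individual ID {dup!r}")
        self.data = self.data[self.schema.abbreviations]

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def quantitative_block(self, complete_cases: bool = False) -> pd.DataFrame:
        """Numeric sub-table of quantitative traits, optionally dropping any
        individual with a missing value."""
        block = self.data[[t.abbreviation for t in self.schema.quantitative]].astype(float)
        if complete_cases:
            block = block.dropna(axis=0, how="any")
        return block

    def qualitative_block(self) -> pd.DataFrame:
        return self.data[[t.abbreviation for t in self.schema.qualitative]]


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_phenotype_matrix(path: str | Path, schema: TraitSchema) -> PhenotypeMatrix:
    """Read a phenotype matrix, matching columns to ``schema`` by abbreviation.

    The file may contain any subset of schema traits in any column order; the
    returned matrix carries the sub-schema of the traits present, in schema
    order.
    """
    path = Path(path)
    raw = _read_delimited(path)
    if raw.shape[1] < 2:
        raise MatrixParseError(f"{path}: need an ID column plus at least one trait column")
    id_col = raw.columns[0]
    trait_cols = [c for c in raw.columns[1:]]
    for col in trait_cols:
        if col not in schema:
            raise UnknownColumnError(f"{path}: column {col!r} not in schema")
    sub = schema.subset(trait_cols)

    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DuplicateIndividualError(f"{path}: duplicated individual ID {dup!r}")

    columns: dict[str, object] = {}
    for trait in sub.traits:
        col = raw[trait.abbreviation]
        if trait.kind == QUANTITATIVE:
            parsed = []
            for row_idx, cell in enumerate(col):
                cell = cell.strip()
                if cell in _MISSING_TOKENS:
                    parsed.append(math.nan)
                    continue
                try:
                    value = float(cell)
                except ValueError:
                    raise MatrixParseError(
                        f"{path}: row {row_idx + 2}, column {trait.abbreviation!r}: "
                        f"cannot parse {cell!r} as a number"
                    ) from None
                if not math.isfinite(value):
                    raise MatrixParseError(
                        f"{path}: row {row_idx + 2}, column {trait.abbreviation!r}: "
                        f"non-finite value {cell!r}"
                    )
                parsed.append(value)
            columns[trait.abbreviation] = pd.array(parsed, dtype=float)
        else:
            columns[trait.abbreviation] = [
                None if c.strip() in _MISSING_TOKENS else c.strip() for c in col
            ]
    data = pd.DataFrame(columns, index=pd.Index(ids, name="id"))
    return PhenotypeMatrix(data=data, schema=sub)


def write_phenotype_matrix(matrix: PhenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as CSV/TSV (by extension); missing cells become ``NA``.

    Numeric cells are written at full round-trip precision.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out = matrix.data.copy()
    for trait in matrix.schema.quantitative:
        col = out[trait.abbreviation]
        out[trait.abbreviation] = [("NA" if pd.isna(v) else repr(float(v))) for v in col]
    for trait in matrix.schema.qualitative:
        out[trait.abbreviation] = [("NA" if v is None else v) for v in out[trait.abbreviation]]
    out.to_csv(path, sep=sep, index=True, index_label="id")


@dataclass(frozen=True)
class ValidationIssue:
    row: str | None
    column: str
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors


def validate_matrix(matrix: PhenotypeMatrix, schema: TraitSchema | None = None) -> ValidationReport:
    """Report (not raise) data problems: unknown class codes, all-missing
    traits, constant quantitative traits (CV/grading degenerate)."""
    schema = schema or matrix.schema
    report = ValidationReport()
    for trait in matrix.schema.traits:
        col = matrix.data[trait.abbreviation]
        if trait.kind == QUALITATIVE:
            allowed = set(schema[trait.abbreviation].classes)
            non_missing = 0
            for ind, value in col.items():
                if value is None:
                    continue
                non_missing += 1
                if value not in allowed:
                    report.errors.append(
                        ValidationIssue(
                            row=str(ind),
                            column=trait.abbreviation,
                            message=f"class code {value!r} not among declared classes",
                        )
                    )
            if non_missing == 0:
                report.warnings.append(
                    ValidationIssue(None, trait.abbreviation, "trait is entirely missing")
                )
        else:
            values = col.astype(float).dropna()
            if values.empty:
                report.warnings.append(
                    ValidationIssue(None, trait.abbreviation, "trait is entirely missing")
                )
            elif len(values) >= 2 and float(np.std(values, ddof=1)) == 0.0:
                report.warnings.append(
                    ValidationIssue(
                        None,
                        trait.abbreviation,
                        "constant quantitative trait: CV is zero and grading is degenerate",
                    )
                )
    return report


def write_table(frame: pd.DataFrame, path: str | Path, decimals: int = 3) -> None:
    """Write a result table as CSV with fixed decimal formatting."""
    frame.to_csv(Path(path), float_format=f"%.{decimals}f")
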