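"""Per-sample phenotype tables with explicit missing/non-meaningful semantics.

Public-repository metadata is messy: the same phenotype level is reported
under many spellings ("male", "M", "Male", "m"), and many entries carry
placeholder strings ("not collected", "Unknown") that are present but not
usable. This module canonicalizes raw values against a declared schema and
flags — never drops — the unusable ones, because the accuracy denominator
rules depend on *why* a sample is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class ValueStatus(str, Enum):
    OK = "ok"
    MISSING = "missing"
    NON_MEANINGFUL = "non_meaningful"


#: Synonym map for sex as reported across public archives.
SEX_SYNONYMS = {
    "male": "male",
    "m": "male",
    "female": "female",
    "f": "female",
}

#: Placeholder strings that are present but carry no usable phenotype value.
DEFAULT_NON_MEANINGFUL = {
    "not collected",
    "not determined",
    "unknown",
    "n/a",
    "na",
    "not applicable",
    "missing",
    "--",
}


@dataclass
class CategoricalColumn:
    """Schema for one categorical phenotype column.

    ``synonyms`` maps lower-cased raw strings to canonical levels;
    ``non_meaningful`` is a lower-cased set of unusable placeholder strings.
    The two must be disjoint. Raw values matching neither are treated as
    non-meaningful unless ``strict`` is set, in which case they error.
    """

    name: str
    synonyms: dict[str, str]
    non_meaningful: set = field(default_factory=lambda: set(DEFAULT_NON_MEANINGFUL))
    missing_values: set = field(default_factory=lambda: {"", "nan", "none"})
    strict: bool = False

    def __post_init__(self) -> None:
        self.synonyms = {str(k).strip().lower(): v for k, v in self.synonyms.items()}
        self.non_meaningful = {str(v).strip().lower() for v in self.non_meaningful}
        self.missing_values = {str(v).strip().lower() for v in self.missing_values}
        overlap = set(self.synonyms) & self.non_meaningful
        if overlap:
            raise ValueError(
                f"column {self.name!r}: synonym map and non-meaningful set "
                f"overlap on {sorted(overlap)}"
            )

    @property
    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lev in self.synonyms.values():
            seen.setdefault(lev, None)
        return list(seen)

    def canonicalize(self, raw) -> tuple[str | None, ValueStatus]:
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return None, ValueStatus.MISSING
        key = str(raw).strip().lower()
        if key in self.missing_values:
            return None, ValueStatus.MISSING
        if key in self.synonyms:
            return self.synonyms[key], ValueStatus.OK
        if key in self.non_meaningful:
            return None, ValueStatus.NON_MEANINGFUL
        if self.strict:
            raise ValueError(f"column {self.name!r}: unrecognized value {raw!r}")
        return None, ValueStatus.NON_MEANINGFUL


@dataclass
class ContinuousColumn:
    """Schema for one continuous phenotype column."""

    name: str
    missing_values: set = field(default_factory=lambda: {"", "nan", "none", "na", "n/a"})

    def __post_init__(self) -> None:
        self.missing_values = {str(v).strip().lower() for v in self.missing_values}

    def canonicalize(self, raw) -> tuple[float, ValueStatus]:
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return np.nan, ValueStatus.MISSING
        key = str(raw).strip().lower()
        if key in self.missing_values:
            return np.nan, ValueStatus.MISSING
        try:
            return float(raw), ValueStatus.OK
        except ValueError:
            return np.nan, ValueStatus.NON_MEANINGFUL


ColumnSchema = CategoricalColumn | ContinuousColumn


class PhenotypeTable:
    """Canonicalized per-sample phenotypes.

    Holds, per column, the raw values, the canonical values and a status
    code for every cell. Canonicalization is deterministic: the same raw
    table and schema always produce the same result.
    """

    def __init__(self, samples, columns: dict[str, ColumnSchema], raw: pd.DataFrame):
        self.samples = [str(s) for s in samples]
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in phenotype table")
        self.schema = dict(columns)
        self.raw = raw.copy()
        self.raw.index = pd.Index(self.samples)
        for name in self.schema:
            if name not in self.raw.columns:
                raise ValueError(f"schema column {name!r} absent from table")
        canon = {}
        status = {}
        for name, spec in self.schema.items():
            pairs = [spec.canonicalize(v) for v in self.raw[name]]
            canon[name] = [p[0] for p in pairs]
            status[name] = [p[1].value for p in pairs]
        self.canonical = pd.DataFrame(canon, index=self.raw.index)
        self.status = pd.DataFrame(status, index=self.raw.index)

    def is_categorical(self, column: str) -> bool:
        return isinstance(self.schema[column], CategoricalColumn)

    def levels(self, column: str) -> list[str]:
        spec = self.schema[column]
        if not isinstance(spec, CategoricalColumn):
            raise TypeError(f"column {column!r} is not categorical")
        return spec.levels

    def usable_mask(self, column: str) -> np.ndarray:
        """Boolean mask of samples whose value is present and meaningful."""
        return (self.status[column] == ValueStatus.OK.value).to_numpy()

    def values(self, column: str) -> np.ndarray:
        """Canonical values aligned to ``self.samples`` (None/NaN where unusable)."""
        return self.canonical[column].to_numpy()

    def subset(self, samples) -> "PhenotypeTable":
        samples = [str(s) for s in samples]
        missing = [s for s in samples if s not in set(self.samples)]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:10]}")
        return PhenotypeTable(samples, self.schema, self.raw.loc[samples])
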