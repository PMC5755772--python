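"""Clinical cohort schema, table container and CSV round-trip.

The study population is a cross-sectional cohort of postmenopausal women
characterised by 14 continuous variables (anthropometrics, bone-turnover
markers, densitometric bone-quantity and bone-quality indices, spine
deformity index) and two binary variables (Romberg balance test, morphometric
vertebral fracture status).  Each variable carries the published summary
statistics of that cohort (mean, SD, median, range) so that the synthetic
generator and the validators share a single declarative source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"


class CohortValidationError(ValueError):
    """A cohort table or CSV violates the schema contract."""


@dataclass(frozen=True)
class VariableSpec:
    """Declarative description of one clinical variable.

    ``high_label``/``low_label`` name the two complementary map nodes the
    variable expands into ("CTX high"/"CTX low" for continuous variables,
    "Fracture yes"/"Fracture no" for binary ones).  ``target_*`` are the
    cohort summary statistics the synthetic generator reproduces; for binary
    variables ``target_mean`` is the prevalence.
    """

    name: str
    kind: str
    units: str
    min_allowed: float
    max_allowed: float
    target_mean: float
    target_sd: float
    high_label: str
    low_label: str
    target_median: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == CONTINUOUS and not self.min_allowed < self.max_allowed:
            raise ValueError(f"{self.name}: min_allowed must be < max_allowed")
        if self.high_label == self.low_label:
            raise ValueError(f"{self.name}: high/low node labels must differ")


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of variable specs plus the record-identifier field."""

    variables: tuple[VariableSpec, ...]
    id_field: str = "patient_id"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        labels = [lab for v in self.variables for lab in (v.high_label, v.low_label)]
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique across the schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def continuous(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.kind == CONTINUOUS]

    @property
    def binary(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.kind == BINARY]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def drop(self, names: str | Iterable[str]) -> "CohortSchema":
        """Schema without the given variables (used for subgroup maps)."""
        if isinstance(names, str):
            names = [names]
        drop = set(names)
        missing = drop - set(self.names)
        if missing:
            raise KeyError(f"not in schema: {sorted(missing)}")
        keep = tuple(v for v in self.variables if v.name not in drop)
        return replace(self, variables=keep)


# Published cohort summary statistics (mean, SD, median, max, min) for the
# 14 continuous variables; binary prevalences were not reported and default
# to the generator's configurable values (fracture 0.25, Romberg 0.30).
_T = [
    # name, units, mean, sd, median, max, min, high label, low label
    ("Age", "yrs", 67.61, 10.80, 68.25, 87.81, 45.43, "Age high", "Age low"),
    ("YrsSinceMenopause", "yrs", 18.86, 11.13, 19.15, 46.29, 0.36, "Yrs MP high", "Yrs MP low"),
    ("BMI", "kg/m2", 24.86, 3.89, 24.49, 42.46, 16.89, "BMI high", "BMI low"),
    ("SDI", "", 2.03, 4.05, 0.00, 19.00, 0.00, "SDI high", "SDI low"),
    ("ALP", "U/L", 72.98, 23.96, 68.00, 158.00, 30.00, "ALP high", "ALP low"),
    ("BAP", "U/L", 48.97, 12.23, 48.00, 85.00, 17.00, "BAP high", "BAP low"),
    ("CTX", "pg/dl", 484.08, 323.24, 425.70, 2674.00, 63.65, "CTX high", "CTX low"),
    ("VitaminD25OH", "ng/ml", 25.27, 11.72, 24.20, 74.40, 4.00, "Vit D high", "Vit D low"),
    ("BMD_Lumbar", "g/cm2", 0.79, 0.15, 0.77, 1.43, 0.48, "BMD Lumbar high", "BMD Lumbar low"),
    ("BMD_Neck", "g/cm2", 0.59, 0.09, 0.58, 0.97, 0.41, "BMD Neck high", "BMD Neck low"),
    ("TBS", "", 1.15, 0.12, 1.16, 1.50, 0.82, "TBS high", "TBS low"),
    ("BS_Lumbar", "", 4.06, 2.21, 3.59, 11.95, 0.49, "BS Lumbar high", "BS Lumbar low"),
    ("Tscore_Neck", "SD", -1.88, 0.78, -1.90, 0.10, -3.60, "T-score Neck high", "T-score Neck low"),
    ("Zscore_Neck", "SD", -0.47, 0.94, -0.60, 1.70, -2.50, "Z-score Neck high", "Z-score Neck low"),
]

DEFAULT_FRACTURE_PREVALENCE = 0.25
DEFAULT_ROMBERG_PREVALENCE = 0.30


def default_schema() -> CohortSchema:
    """The 16-variable cohort schema: 14 continuous + Romberg + Fracture."""
    cont = tuple(
        VariableSpec(
            name=n, kind=CONTINUOUS, units=u,
            min_allowed=mn, max_allowed=mx,
            target_mean=mean, target_sd=sd, target_median=med,
            high_label=hi, low_label=lo,
        )
        for (n, u, mean, sd, med, mx, mn, hi, lo) in _T
    )
    binaries = (
        VariableSpec(
            name="Romberg", kind=BINARY, units="",
            min_allowed=0.0, max_allowed=1.0,
            target_mean=DEFAULT_ROMBERG_PREVALENCE, target_sd=float("nan"),
            high_label="Romberg positive", low_label="Romberg negative",
        ),
        VariableSpec(
            name="Fracture", kind=BINARY, units="",
            min_allowed=0.0, max_allowed=1.0,
            target_mean=DEFAULT_FRACTURE_PREVALENCE, target_sd=float("nan"),
            high_label="Fracture yes", low_label="Fracture no",
        ),
    )
    return CohortSchema(variables=cont + binaries)


@dataclass
class CohortTable:
    """Validated patient-by-variable table.

    ``data`` holds one column per schema variable plus the identifier column,
    in schema order, with the identifiers unique and every value inside its
    spec's allowed range.
    """

    schema: CohortSchema
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data[self.schema.id_field]

    def values(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def validate(self) -> None:
        df = self.data
        idf = self.schema.id_field
        cols = [idf] + self.schema.names
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing column(s): {missing}")
        self.data = df = df.loc[:, cols].reset_index(drop=True)
        if df[idf].duplicated().any():
            dup = df[idf][df[idf].duplicated()].iloc[0]
            raise CohortValidationError(f"duplicate record id {dup!r}")
        for v in self.schema.variables:
            col = df[v.name]
            if col.isna().any():
                row = int(col.index[col.isna()][0])
                raise CohortValidationError(
                    f"missing/non-numeric value in column {v.name!r}, row {row}"
                )
            if v.kind == BINARY:
                bad = ~col.isin([0, 1])
                if bad.any():
                    row = int(col.index[bad][0])
                    raise CohortValidationError(
                        f"binary column {v.name!r} has value {col[row]!r} "
                        f"outside {{0,1}} at row {row}"
                    )
            else:
                bad = (col < v.min_allowed) | (col > v.max_allowed)
                if bad.any():
                    row = int(col.index[bad][0])
                    raise CohortValidationError(
                        f"column {v.name!r} value {col[row]} out of range "
                        f"[{v.min_allowed}, {v.max_allowed}] at row {row}"
                    )

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.schema, self.data.loc[np.asarray(mask)].copy())

    def drop_variables(self, names: str | Iterable[str]) -> "CohortTable":
        sub = self.schema.drop(names)
        cols = [sub.id_field] + sub.names
        return CohortTable(sub, self.data.loc[:, cols].copy())


def read_cohort_csv(path: str | Path, schema: CohortSchema | None = None) -> CohortTable:
    """Read and validate a cohort CSV (comma-separated, dot decimal, header row).

    Header names must match the schema's variable names (order-insensitive).
    The identifier column is optional on input; sequential ids are synthesised
    when absent.  Any missing column, non-numeric cell, out-of-range value or
    binary-domain violation raises :class:`CohortValidationError` naming the
    offending row and column.
    """
    schema = schema or default_schema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [n for n in schema.names if n not in df.columns]
    if missing:
        raise CohortValidationError(f"missing column(s): {missing}")
    if schema.id_field not in df.columns:
        df[schema.id_field] = [f"P{i + 1:04d}" for i in range(len(df))]
    for v in schema.variables:
        coerced = pd.to_numeric(df[v.name], errors="coerce")
        bad = coerced.isna() & df[v.name].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise CohortValidationError(
                f"non-numeric value {df[v.name][row]!r} in column {v.name!r}, row {row}"
            )
        df[v.name] = coerced
    return CohortTable(schema, df)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV that round-trips through :func:`read_cohort_csv`.

    Floats are serialised at full round-trip precision, so reading the file
    back reproduces every value exactly.
    """
    table.validate()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)
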