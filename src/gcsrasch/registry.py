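"""Trauma-registry domain types, CSV I/O and record filtering.

A registry row carries demographics (age, sex), the Injury Severity Score
(ISS), the most severely injured body region, the three Glasgow Coma Scale
sub-scores (Eye 1-4, Verbal 1-5, Motor 1-6) and the 30-day outcome.  The
analysis cohort is formed by two sequential, disjoint exclusions: paediatric
cases (age < 18) first, then records without a complete GCS.  A reported
summed GCS of 3 or 15 with missing sub-scores is treated as complete, since
the breakdown is inferable (3 = E1 V1 M1, 15 = E4 V5 M6).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .pcm import ResponseMatrix

__all__ = [
    "REGIONS",
    "GCS_CATEGORY_MAXIMA",
    "GcsResponse",
    "TraumaRecord",
    "RecordSet",
    "ExclusionLog",
    "RegistryValidationError",
    "read_registry",
    "apply_exclusions",
    "drop_missing_outcome",
    "to_response_matrix",
]

REGIONS = ("Abdomen", "Chest", "Head", "Limbs", "Spine", "Multiple", "Other", "Face")
SEXES = ("male", "female")
OUTCOMES = ("alive", "dead", "missing")

#: highest category of each GCS sub-scale, in (eye, verbal, motor) order
GCS_CATEGORY_MAXIMA = (4, 5, 6)

_ITEM_COLS = ("eye", "verbal", "motor")
_COLUMNS = ("id", "age", "sex", "iss", "region", "eye", "verbal", "motor", "outcome")


class RegistryValidationError(ValueError):
    """Raised when CSV rows violate the registry schema; carries line numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        head = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"invalid registry rows: {head}{more}")


@dataclass(frozen=True)
class GcsResponse:
    """One GCS observation; any sub-score may be missing (partial response)."""

    eye: Optional[int] = None
    verbal: Optional[int] = None
    motor: Optional[int] = None

    def __post_init__(self):
        for name, val, m in zip(_ITEM_COLS, (self.eye, self.verbal, self.motor), GCS_CATEGORY_MAXIMA):
            if val is not None and not 1 <= int(val) <= m:
                raise ValueError(f"{name} category {val} outside 1..{m}")

    @property
    def complete(self) -> bool:
        return None not in (self.eye, self.verbal, self.motor)

    @property
    def total(self) -> Optional[int]:
        if not self.complete:
            return None
        return self.eye + self.verbal + self.motor


@dataclass(frozen=True)
class TraumaRecord:
    id: str
    age: float
    sex: str
    iss: int
    region: str
    gcs: Optional[GcsResponse]
    outcome30d: str

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if not 1 <= self.iss <= 75:
            raise ValueError("iss outside 1..75")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.outcome30d not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")


class RecordSet:
    """Ordered collection of trauma records, backed by a pandas DataFrame.

    The DataFrame is the canonical storage (fast path for the generator and
    the filters); :class:`TraumaRecord` objects are materialised on demand.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        df = df.reset_index(drop=True)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing registry columns: {missing}")
        if df["id"].duplicated().any():
            dup = df["id"][df["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate record id {dup!r}")
        self.df = df[list(_COLUMNS)]
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[TraumaRecord]:
        for row in self.df.itertuples(index=False):
            gcs_vals = {
                c: (None if pd.isna(getattr(row, c)) else int(getattr(row, c)))
                for c in _ITEM_COLS
            }
            gcs = None if all(v is None for v in gcs_vals.values()) else GcsResponse(**gcs_vals)
            yield TraumaRecord(
                id=str(row.id),
                age=float(row.age),
                sex=str(row.sex),
                iss=int(row.iss),
                region=str(row.region),
                gcs=gcs,
                outcome30d=str(row.outcome),
            )

    @property
    def complete_gcs_mask(self) -> np.ndarray:
        return self.df[list(_ITEM_COLS)].notna().all(axis=1).to_numpy()

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["age"] = out["age"].map(lambda a: f"{a:.1f}")
        out.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RecordSet(n={len(self)}, provenance={self.provenance!r})"


@dataclass(frozen=True)
class ExclusionLog:
    """Sequential, disjoint exclusion accounting for one filtering pass."""

    n_input: int
    n_paediatric: int
    n_incomplete_gcs: int
    n_retained: int

    def __post_init__(self):
        if self.n_input != self.n_paediatric + self.n_incomplete_gcs + self.n_retained:
            raise ValueError("exclusion counts do not sum to the input count")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def read_registry(path, provenance: str | None = None) -> RecordSet:
    """Read a registry CSV into a :class:`RecordSet`.

    Blank GCS sub-scores yield a partial/absent GCS; a blank outcome is
    recorded as ``missing``.  An optional ``gcs_total`` column of 3 or 15
    fills in the (unique) implied sub-scores when all three are blank.
    Out-of-range values raise :class:`RegistryValidationError` with the
    offending line numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise RegistryValidationError([(1, "missing 'id' column in header")])
    for col in ("age", "sex", "iss", "region", "outcome"):
        if col not in df.columns:
            raise RegistryValidationError([(1, f"missing {col!r} column in header")])
    for col in _ITEM_COLS:
        if col not in df.columns:
            df[col] = ""

    problems: list[tuple[int, str]] = []
    n = len(df)
    lines = np.arange(2, n + 2)  # CSV line number per row

    def numeric(col):
        return pd.to_numeric(df[col].mask(df[col].str.strip() == ""), errors="coerce")

    age = numeric("age")
    iss = numeric("iss")
    sub = {c: numeric(c) for c in _ITEM_COLS}

    if "gcs_total" in df.columns:
        tot = numeric("gcs_total")
        all_blank = np.logical_and.reduce([sub[c].isna() for c in _ITEM_COLS])
        inferred = {3: (1, 1, 1), 15: (4, 5, 6)}
        for t, (e, v, m) in inferred.items():
            mask = all_blank & (tot == t)
            sub["eye"] = sub["eye"].mask(mask, e)
            sub["verbal"] = sub["verbal"].mask(mask, v)
            sub["motor"] = sub["motor"].mask(mask, m)

    def flag(mask: pd.Series, msg: str):
        for ln in lines[np.asarray(mask, dtype=bool)]:
            problems.append((int(ln), msg))

    blank_age = df["age"].str.strip() == ""
    flag(blank_age | age.isna() | (age < 0), "age missing or negative")
    flag(~df["sex"].isin(SEXES), "sex must be male/female")
    flag(iss.isna() | (iss < 1) | (iss > 75) | (iss % 1 != 0), "iss outside 1..75")
    flag(~df["region"].isin(REGIONS), f"region not in {REGIONS}")
    for c, m in zip(_ITEM_COLS, GCS_CATEGORY_MAXIMA):
        present = df[c].str.strip() != ""
        bad = present & (sub[c].isna() | (sub[c] < 1) | (sub[c] > m) | (sub[c] % 1 != 0))
        flag(bad, f"{c} category outside 1..{m}")
    outcome = df["outcome"].str.strip().replace("", "missing")
    flag(~outcome.isin(OUTCOMES), "outcome must be alive/dead or blank")

    if problems:
        problems.sort()
        raise RegistryValidationError(problems)

    clean = pd.DataFrame(
        {
            "id": df["id"].astype(str),
            "age": age.astype(float),
            "sex": df["sex"].astype(str),
            "iss": iss.astype("int64"),
            "region": df["region"].astype(str),
            "eye": sub["eye"].astype("Int64"),
            "verbal": sub["verbal"].astype("Int64"),
            "motor": sub["motor"].astype("Int64"),
            "outcome": outcome.astype(str),
        }
    )
    return RecordSet(clean, provenance=provenance or str(path))


def apply_exclusions(rs: RecordSet) -> tuple[RecordSet, ExclusionLog]:
    """Apply the cohort filters: paediatric first, then incomplete GCS.

    The two exclusions are sequential and disjoint, so the log counts satisfy
    ``n_input = n_paediatric + n_incomplete_gcs + n_retained``.  Idempotent.
    """
    df = rs.df
    paediatric = (df["age"] < 18).to_numpy()
    complete = rs.complete_gcs_mask
    incomplete_adult = ~paediatric & ~complete
    keep = ~paediatric & complete
    log = ExclusionLog(
        n_input=len(df),
        n_paediatric=int(paediatric.sum()),
        n_incomplete_gcs=int(incomplete_adult.sum()),
        n_retained=int(keep.sum()),
    )
    return RecordSet(df[keep], provenance=rs.provenance), log


def drop_missing_outcome(rs: RecordSet) -> RecordSet:
    """Case-wise deletion of records whose 30-day outcome is missing."""
    keep = (rs.df["outcome"] != "missing").to_numpy()
    logging.getLogger(__name__).info(
        "drop_missing_outcome: retained %d of %d records", int(keep.sum()), len(rs)
    )
    return RecordSet(rs.df[keep], provenance=rs.provenance)


def to_response_matrix(rs: RecordSet, scoring=None) -> ResponseMatrix:
    """Rebase GCS categories to 0-based item scores (Eye, Verbal, Motor).

    Identity scoring maps category ``c`` to ``c - 1`` (maxima 3, 4, 5); a
    :class:`~gcsrasch.rescoring.CollapseMap` applies its recode instead.
    Row order is preserved.  All records must have a complete GCS.
    """
    if not rs.complete_gcs_mask.all():
        bad = int(np.flatnonzero(~rs.complete_gcs_mask)[0])
        raise ValueError(f"incomplete GCS at row {bad}; apply exclusions first")
    resp = rs.df[list(_ITEM_COLS)].to_numpy(dtype=np.int64) - 1
    matrix = ResponseMatrix(resp, tuple(m - 1 for m in GCS_CATEGORY_MAXIMA))
    if scoring is not None:
        from .rescoring import apply_collapse

        matrix = apply_collapse(matrix, scoring)
    return matrix
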