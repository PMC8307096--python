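"""Cohort data model, CSV I/O, validation and the CRLB quality filter.

The unit of data is one participant: group label (CHR = clinical high-risk,
HC = healthy control), glutathione concentration in mM with its Cramer-Rao
lower bound (CRLB, %) from spectral fitting, and the clinical scores used by
the analyses (SOFAS 0-100, SOPS total for CHR, CAST 6-30, AUDIT-C 0-12),
plus age and gender. Missing values are explicit (empty CSV cells); each
downstream analysis drops incomplete rows only on the variables it needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError

__all__ = ["ParticipantRecord", "CohortTable", "read_cohort", "write_cohort", "filter_by_crlb"]

GROUPS = ("CHR", "HC")
GENDERS = ("male", "female")

#: CSV schema, in column order
SCHEMA = ["id", "group", "gsh", "gsh_crlb", "sofas", "sops_total", "cast", "audit_c", "age", "gender"]

CAST_BOUNDS = (6, 30)
AUDIT_C_BOUNDS = (0, 12)
SOFAS_BOUNDS = (0, 100)

#: glutathione CRLB threshold (%) for inclusion; strictly-below is kept
CRLB_DEFAULT_THRESHOLD = 30.0


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


@dataclass
class ParticipantRecord:
    """One row of the cohort table. Optional fields are ``None`` when missing."""

    id: str
    group: str
    gsh: float | None = None
    gsh_crlb: float | None = None
    sofas: int = 0
    sops_total: int | None = None
    cast: int | None = None
    audit_c: int | None = None
    age: float = 0.0
    gender: str = "male"
    extras: dict = field(default_factory=dict)

    def validate(self, row: int | None = None) -> None:
        def err(msg, col):
            raise CohortValidationError(msg, row=row, column=col)

        if not str(self.id).strip():
            err("participant id must be non-empty", "id")
        if self.group not in GROUPS:
            err(f"group must be one of {GROUPS}, got {self.group!r}", "group")
        if self.gender not in GENDERS:
            err(f"gender must be one of {GENDERS}, got {self.gender!r}", "gender")
        if self.gsh is not None and not self.gsh > 0:
            err(f"gsh must be a positive concentration in mM, got {self.gsh}", "gsh")
        if self.gsh_crlb is not None and self.gsh_crlb < 0:
            err(f"gsh_crlb must be a nonnegative percent, got {self.gsh_crlb}", "gsh_crlb")
        if not SOFAS_BOUNDS[0] <= self.sofas <= SOFAS_BOUNDS[1]:
            err(f"sofas must lie in {SOFAS_BOUNDS}, got {self.sofas}", "sofas")
        if self.sops_total is not None and self.sops_total < 0:
            err(f"sops_total must be nonnegative, got {self.sops_total}", "sops_total")
        if self.cast is not None and not CAST_BOUNDS[0] <= self.cast <= CAST_BOUNDS[1]:
            err(f"cast must lie in {CAST_BOUNDS}, got {self.cast}", "cast")
        if self.audit_c is not None and not AUDIT_C_BOUNDS[0] <= self.audit_c <= AUDIT_C_BOUNDS[1]:
            err(f"audit_c must lie in {AUDIT_C_BOUNDS}, got {self.audit_c}", "audit_c")
        if not 0 < self.age < 130:
            err(f"age must be a plausible number of years, got {self.age}", "age")


@dataclass
class CohortTable:
    """Ordered collection of validated participant records."""

    records: list[ParticipantRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate participant ids: {dupes}", column="id")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def select(self, group: str) -> "CohortTable":
        return CohortTable(
            [r for r in self.records if r.group == group],
            provenance=f"{self.provenance}|group={group}",
        )

    def groups(self) -> list[str]:
        seen = []
        for r in self.records:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def values(self, column: str, group: str | None = None) -> np.ndarray:
        """Numeric column as a float array; missing values become NaN."""
        recs = self.records if group is None else [r for r in self.records if r.group == group]
        out = np.array(
            [np.nan if _is_missing(getattr(r, column)) else float(getattr(r, column)) for r in recs],
            dtype=float,
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        extra_cols: list[str] = []
        for r in self.records:
            row = {c: getattr(r, c) for c in SCHEMA}
            for k, v in r.extras.items():
                row[k] = v
                if k not in extra_cols:
                    extra_cols.append(k)
            rows.append(row)
        return pd.DataFrame(rows, columns=SCHEMA + extra_cols)


_INT_FIELDS = {"sofas", "sops_total", "cast", "audit_c"}
_FLOAT_FIELDS = {"gsh", "gsh_crlb", "age"}
_REQUIRED = {"id", "group", "sofas", "age", "gender"}


def _parse_cell(name: str, raw, row: int):
    if _is_missing(raw):
        if name in _REQUIRED:
            raise CohortValidationError("required value is missing", row=row, column=name)
        return None
    try:
        if name in _INT_FIELDS:
            f = float(raw)
            if f != int(f):
                raise ValueError
            return int(f)
        if name in _FLOAT_FIELDS:
            return float(raw)
    except (TypeError, ValueError):
        raise CohortValidationError(f"could not parse {raw!r} as a number", row=row, column=name)
    return str(raw).strip()


def read_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV.

    Group labels are case-insensitive and canonicalized to upper case; empty
    cells become explicit missing values; columns outside the schema are kept
    as opaque extras. Malformed rows raise :class:`CohortValidationError`
    naming the row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SCHEMA if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing schema columns: {missing_cols}")
    extra_cols = [c for c in df.columns if c not in SCHEMA]
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        kwargs = {}
        for name in SCHEMA:
            v = _parse_cell(name, row[name], idx)
            if name == "group" and v is not None:
                v = v.upper()
            if name == "gender" and v is not None:
                v = v.lower()
            if v is not None:
                kwargs[name] = v
        rec = ParticipantRecord(**kwargs, extras={c: row[c] for c in extra_cols})
        rec.validate(row=idx)
        records.append(rec)
    return CohortTable(records, provenance=str(path))


def write_cohort(table: CohortTable, path) -> None:
    """Write the cohort as the canonical CSV; bit-stable for identical input."""
    for i, r in enumerate(table.records, start=1):
        r.validate(row=i)
    df = table.to_frame()

    def fmt(v):
        if _is_missing(v):
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    out = df.map(fmt)
    out.to_csv(path, index=False, lineterminator="\n")


def filter_by_crlb(table: CohortTable, threshold: float = CRLB_DEFAULT_THRESHOLD) -> CohortTable:
    """Quality-control inclusion filter on the glutathione CRLB.

    Keeps records whose ``gsh_crlb`` is *strictly below* ``threshold``
    (percent); records with a missing CRLB are excluded. Order is preserved.
    An empty result is legal.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    kept = [r for r in table.records if r.gsh_crlb is not None and r.gsh_crlb < threshold]
    return CohortTable(kept, provenance=f"{table.provenance}|crlb<{threshold:g}")
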