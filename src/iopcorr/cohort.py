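"""Domain types, unit conventions and CSV I/O for per-eye tonometry records.

One row = one eye of one subject: biometry (age, central corneal thickness,
corneal curvature) plus a paired Goldmann-applanation (GAT) and
dynamic-contour (DCT) IOP reading, both in mmHg.  Central corneal thickness
is carried in micrometres at every boundary; corneal curvature may be given
as a radius in millimetres or as mean keratometry in diopters, related
through the keratometric index (default 1.3375, i.e. r = 337.5 / Km).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import RecordValidationError, SchemaError

#: Default keratometric index used to convert mean keratometry to a radius.
KERATOMETRIC_INDEX = 1.3375

#: Agreement tolerance (mm) when a row carries both a radius and a keratometry.
_R_KM_TOL_MM = 0.01

AGE_RANGE = (1.0, 120.0)
CCT_RANGE_UM = (350.0, 750.0)
IOP_RANGE_MMHG = (0.0, 80.0)  # open interval
RADIUS_RANGE_MM = (5.0, 11.0)

CSV_COLUMNS = ["subject_id", "age", "cct_um", "r_mm", "km_D", "iop_gat", "iop_dct"]

# Accepted header aliases (lower-cased) -> canonical name.
_COLUMN_ALIASES = {
    "subject_id": "subject_id",
    "id": "subject_id",
    "subject": "subject_id",
    "age": "age",
    "age_years": "age",
    "cct_um": "cct_um",
    "cct": "cct_um",
    "r_mm": "r_mm",
    "r": "r_mm",
    "radius_mm": "r_mm",
    "km_d": "km_D",
    "km": "km_D",
    "iop_gat": "iop_gat",
    "gat": "iop_gat",
    "iop_dct": "iop_dct",
    "dct": "iop_dct",
}

_MANDATORY = ("subject_id", "age", "cct_um", "iop_gat", "iop_dct")


def km_to_radius(km_D: float, index: float = KERATOMETRIC_INDEX) -> float:
    """Convert mean keratometry (diopters) to a corneal radius (mm).

    Uses r = 1000 * (index - 1) / Km; with the default index 1.3375 this is
    the familiar r = 337.5 / Km.

    Raises
    ------
    NumericError
        If ``km_D`` is not strictly positive.
    """
    from .errors import NumericError

    if not km_D > 0:
        raise NumericError(f"keratometry must be > 0 D, got {km_D}")
    return 1000.0 * (index - 1.0) / km_D


def radius_to_km(r_mm: float, index: float = KERATOMETRIC_INDEX) -> float:
    """Convert a corneal radius (mm) to mean keratometry (diopters)."""
    from .errors import NumericError

    if not r_mm > 0:
        raise NumericError(f"radius must be > 0 mm, got {r_mm}")
    return 1000.0 * (index - 1.0) / r_mm


def _check_range(name: str, value: float, low: float, high: float,
                 open_interval: bool = False) -> None:
    ok = low < value < high if open_interval else low <= value <= high
    if not (math.isfinite(value) and ok):
        bracket = "()" if open_interval else "[]"
        raise RecordValidationError(
            f"{name}={value!r} outside {bracket[0]}{low}, {high}{bracket[1]}"
        )


@dataclass(frozen=True)
class EyeRecord:
    """One eye's biometry and paired tonometry readings.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier, unique within a cohort (one eye/subject).
    age : float
        Age in years.
    cct_um : float
        Central corneal thickness in micrometres.
    iop_gat, iop_dct : float
        Goldmann-applanation and dynamic-contour IOP readings, mmHg.
    r_mm : float, optional
        Corneal radius of curvature, mm.
    km_D : float, optional
        Mean keratometry, diopters.  When both curvature fields are present
        they must agree through the keratometric index to within 0.01 mm.
    """

    subject_id: str
    age: float
    cct_um: float
    iop_gat: float
    iop_dct: float
    r_mm: float | None = None
    km_D: float | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise RecordValidationError("subject_id must be a non-empty string")
        _check_range("age", self.age, *AGE_RANGE)
        _check_range("cct_um", self.cct_um, *CCT_RANGE_UM)
        _check_range("iop_gat", self.iop_gat, *IOP_RANGE_MMHG, open_interval=True)
        _check_range("iop_dct", self.iop_dct, *IOP_RANGE_MMHG, open_interval=True)
        if self.r_mm is not None:
            _check_range("r_mm", self.r_mm, *RADIUS_RANGE_MM)
        if self.km_D is not None and not self.km_D > 0:
            raise RecordValidationError(f"km_D={self.km_D!r} must be > 0")
        if self.r_mm is not None and self.km_D is not None:
            implied = km_to_radius(self.km_D)
            if abs(implied - self.r_mm) > _R_KM_TOL_MM:
                raise RecordValidationError(
                    f"r_mm={self.r_mm} inconsistent with km_D={self.km_D} "
                    f"(implies r={implied:.4f} mm, tolerance {_R_KM_TOL_MM} mm)"
                )

    @property
    def radius_mm(self) -> float | None:
        """Corneal radius in mm, derived from km_D when r_mm is absent."""
        if self.r_mm is not None:
            return self.r_mm
        if self.km_D is not None:
            return km_to_radius(self.km_D)
        return None


@dataclass
class Cohort:
    """An ordered collection of :class:`EyeRecord` with unique subject ids."""

    records: list[EyeRecord] = field(default_factory=list)
    label: str = "cohort"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, rec in enumerate(self.records):
            if rec.subject_id in seen:
                raise RecordValidationError(
                    f"row {i}: duplicate subject_id {rec.subject_id!r}"
                )
            seen.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EyeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EyeRecord:
        return self.records[i]

    # -- column views -----------------------------------------------------

    def _column(self, getter) -> np.ndarray:
        return np.array([getter(r) for r in self.records], dtype=float)

    @property
    def age(self) -> np.ndarray:
        return self._column(lambda r: r.age)

    @property
    def cct_um(self) -> np.ndarray:
        return self._column(lambda r: r.cct_um)

    @property
    def iop_gat(self) -> np.ndarray:
        return self._column(lambda r: r.iop_gat)

    @property
    def iop_dct(self) -> np.ndarray:
        return self._column(lambda r: r.iop_dct)

    @property
    def radius_mm(self) -> np.ndarray:
        """Radii in mm; NaN where neither curvature field is present."""
        return self._column(
            lambda r: r.radius_mm if r.radius_mm is not None else math.nan
        )

    def has_radius(self) -> bool:
        return all(r.radius_mm is not None for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "cct_um": r.cct_um,
                "r_mm": r.r_mm,
                "km_D": r.km_D,
                "iop_gat": r.iop_gat,
                "iop_dct": r.iop_dct,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _COLUMN_ALIASES:
            mapping[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=mapping)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return df


def read_cohort(path, label: str | None = None, **read_csv_kwargs) -> Cohort:
    """Read a cohort from CSV.

    The header must name (possibly via documented aliases) subject_id, age,
    cct_um, iop_gat and iop_dct; r_mm and km_D are optional per row.  When a
    row carries km_D but no r_mm the radius is filled in from the
    keratometric conversion.  Row order is preserved.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    RecordValidationError
        If any value violates the record invariants; the message names the
        0-based row and field.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    df = _canonical_columns(df)
    records: list[EyeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()

        def opt(name):
            v = d.get(name)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        r_mm, km_D = opt("r_mm"), opt("km_D")
        if r_mm is None and km_D is not None:
            r_mm = km_to_radius(km_D)
        try:
            records.append(
                EyeRecord(
                    subject_id=str(d["subject_id"]),
                    age=float(d["age"]),
                    cct_um=float(d["cct_um"]),
                    iop_gat=float(d["iop_gat"]),
                    iop_dct=float(d["iop_dct"]),
                    r_mm=r_mm,
                    km_D=km_D,
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"row {i}: {exc}") from exc
    return Cohort(records=records, label=label or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to the standard CSV schema (UTF-8, '.' decimal)."""
    cohort.to_dataframe().to_csv(path, index=False)


def records_from_arrays(
    subject_ids: Sequence[str],
    age: np.ndarray,
    cct_um: np.ndarray,
    iop_gat: np.ndarray,
    iop_dct: np.ndarray,
    r_mm: np.ndarray | None = None,
) -> list[EyeRecord]:
    """Bulk-construct validated records from parallel arrays."""
    out = []
    for i, sid in enumerate(subject_ids):
        out.append(
            EyeRecord(
                subject_id=sid,
                age=float(age[i]),
                cct_um=float(cct_um[i]),
                iop_gat=float(iop_gat[i]),
                iop_dct=float(iop_dct[i]),
                r_mm=float(r_mm[i]) if r_mm is not None else None,
            )
        )
    return out


__all__ = [
    "EyeRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "records_from_arrays",
    "km_to_radius",
    "radius_to_km",
    "KERATOMETRIC_INDEX",
]
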