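"""Monthly cohort counts: data model, CSV I/O, and descriptive reductions.

The central container is :class:`CohortTable`, a validated collection of
monthly patient counts per hospital center, stratified by patient status
(newly vs previously diagnosed), tumor group, sex, and metastatic stage.
All downstream quantities of the delayed-diagnosis mortality model start
from the per-month reduction fractions computed here: for an observation
year versus a reference year, ``f_m = (ref_m - obs_m) / ref_m``, and the
month's "missing" patients ``max(ref_m - obs_m, 0)`` are interpreted as
patients whose diagnosis was delayed.

Months are calendar months ``(year, month)``; no day-level resolution
exists anywhere in the package because the source data are monthly tallies.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    IntegrityError,
    ParseError,
    UndefinedFractionError,
    UndefinedRatioError,
    ValidationError,
)

PATIENT_STATUSES = ("new", "previously_diagnosed", "all")
TUMOR_GROUPS = (
    "breast",
    "digestive",
    "thoracic/lung",
    "gynecological",
    "head_and_neck",
    "urological",
    "hematological",
    "skin",
    "other",
    "all",
)
SEXES = ("male", "female", "all")
STAGES = ("metastatic", "nonmetastatic", "all")

CSV_HEADER = [
    "center_id",
    "year",
    "month",
    "patient_status",
    "tumor_group",
    "sex",
    "stage",
    "count",
]


@dataclass(frozen=True)
class Stratum:
    """Categorical cell: ``all`` marks aggregation over that dimension."""

    patient_status: str = "new"
    tumor_group: str = "all"
    sex: str = "all"
    stage: str = "all"

    def __post_init__(self) -> None:
        for value, allowed, name in (
            (self.patient_status, PATIENT_STATUSES, "patient_status"),
            (self.tumor_group, TUMOR_GROUPS, "tumor_group"),
            (self.sex, SEXES, "sex"),
            (self.stage, STAGES, "stage"),
        ):
            if value not in allowed:
                raise ValidationError(f"invalid {name}: {value!r}")


@dataclass(frozen=True)
class CohortRecord:
    """One monthly count for one center and one stratum cell.

    Counts are non-negative. CSV ingest enforces integers; synthetic
    noiseless tables may carry fractional expected counts.
    """

    center_id: str
    year: int
    month: int
    stratum: Stratum
    count: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"month must be 1..12, got {self.month}")
        if self.count < 0:
            raise ValidationError(
                f"negative count {self.count} for center {self.center_id} "
                f"{self.year}-{self.month:02d}"
            )

    @property
    def key(self) -> tuple:
        return (self.center_id, self.year, self.month, self.stratum)


@dataclass
class CohortTable:
    """Validated collection of :class:`CohortRecord` with optional metadata.

    ``covid_zone`` maps center ids to ``"high"``/``"low"`` epidemic-incidence
    zones; when present it must cover every center in the table.
    """

    records: list[CohortRecord]
    source: str = ""
    covid_zone: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise IntegrityError(
                    f"duplicate record for center {rec.center_id} "
                    f"{rec.year}-{rec.month:02d} stratum {rec.stratum}"
                )
            seen.add(rec.key)
        if self.covid_zone is not None:
            missing = self.centers - set(self.covid_zone)
            if missing:
                raise ValidationError(
                    f"covid_zone does not cover centers: {sorted(missing)}"
                )
            bad = {z for z in self.covid_zone.values()} - {"high", "low"}
            if bad:
                raise ValidationError(f"invalid covid zones: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def centers(self) -> set[str]:
        return {rec.center_id for rec in self.records}

    @property
    def years(self) -> set[int]:
        return {rec.year for rec in self.records}

    def filter(self, stratum: Stratum | None = None, **dims) -> "CohortTable":
        """Subset records matching a stratum and/or record fields.

        ``dims`` may constrain ``center_id``, ``year`` or ``month`` (scalar
        or collection).
        """
        recs = self.records
        if stratum is not None:
            recs = [r for r in recs if r.stratum == stratum]
        for name, want in dims.items():
            if isinstance(want, (set, frozenset, list, tuple, range)):
                allowed = set(want)
                recs = [r for r in recs if getattr(r, name) in allowed]
            else:
                recs = [r for r in recs if getattr(r, name) == want]
        return CohortTable(list(recs), source=self.source, covid_zone=self.covid_zone)

    def monthly_totals(
        self, year: int, months: Sequence[int], stratum: Stratum
    ) -> np.ndarray:
        """Counts summed over centers for each month of ``months``.

        Raises if any requested month has no record at all.
        """
        by_month: dict[int, float] = {m: 0.0 for m in months}
        found: set[int] = set()
        for rec in self.records:
            if rec.year == year and rec.stratum == stratum and rec.month in by_month:
                by_month[rec.month] += rec.count
                found.add(rec.month)
        absent = set(months) - found
        if absent:
            raise ValidationError(
                f"no counts for year {year}, stratum {stratum}, "
                f"months {sorted(absent)}"
            )
        return np.array([by_month[m] for m in months], dtype=float)

    def validate_aggregates(self, tol: float = 0.5) -> list[str]:
        """Check that ``all`` rows equal the sum of their sub-strata.

        Performed per aggregation dimension, only where both an ``all`` row
        and a complete set of sub-stratum rows exist for the same
        (center, year, month) and same values on the other dimensions.
        Returns a list of human-readable discrepancy messages (empty when
        consistent) rather than raising, so known-inconsistent published
        tables can be loaded and inspected.
        """
        problems: list[str] = []
        index: dict[tuple, float] = {r.key: r.count for r in self.records}
        sublevels = {
            "patient_status": ("new", "previously_diagnosed"),
            "tumor_group": tuple(g for g in TUMOR_GROUPS if g != "all"),
            "sex": ("male", "female"),
            "stage": ("metastatic", "nonmetastatic"),
        }
        for rec in self.records:
            for dim, levels in sublevels.items():
                if getattr(rec.stratum, dim) != "all":
                    continue
                parts = [
                    index.get(
                        (
                            rec.center_id,
                            rec.year,
                            rec.month,
                            replace(rec.stratum, **{dim: lev}),
                        )
                    )
                    for lev in levels
                ]
                present = [p for p in parts if p is not None]
                if not present or len(present) < len(parts):
                    continue  # validated only when all sub-strata supplied
                if abs(sum(present) - rec.count) > tol:
                    problems.append(
                        f"center {rec.center_id} {rec.year}-{rec.month:02d}: "
                        f"'all' over {dim} is {rec.count} but sub-strata sum "
                        f"to {sum(present)}"
                    )
        return problems


@dataclass
class ReductionSeries:
    """Per-month reduction of an observation year versus a reference year.

    ``fractions`` are signed: negative values mean the observation year
    exceeded the reference. ``missing`` clamps deficits at zero so that only
    shortfall months contribute delayed patients (months with an increase
    contribute none).
    """

    ref_year: int
    obs_year: int
    months: list[int]
    ref_counts: np.ndarray
    obs_counts: np.ndarray
    stratum: Stratum = field(default_factory=Stratum)
    clamp: bool = True

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=float)
        self.obs_counts = np.asarray(self.obs_counts, dtype=float)
        if not (len(self.months) == len(self.ref_counts) == len(self.obs_counts)):
            raise ValidationError("months, ref_counts, obs_counts length mismatch")
        if len(self.months) == 0:
            raise ValidationError("empty reduction series")
        zero = [m for m, r in zip(self.months, self.ref_counts) if r == 0]
        if zero:
            raise UndefinedFractionError(
                f"reference count is zero in months {zero} of {self.ref_year}"
            )

    @property
    def fractions(self) -> np.ndarray:
        return (self.ref_counts - self.obs_counts) / self.ref_counts

    @property
    def missing(self) -> np.ndarray:
        deficits = self.ref_counts - self.obs_counts
        return np.maximum(deficits, 0.0) if self.clamp else deficits

    @property
    def missing_total(self) -> float:
        return float(self.missing.sum())

    def fraction_map(self) -> dict[tuple[int, int], float]:
        """Fractions keyed by ``(obs_year, month)`` for the model layer."""
        return {
            (self.obs_year, m): float(f) for m, f in zip(self.months, self.fractions)
        }

    def month_labels(self) -> list[tuple[int, int]]:
        return [(self.obs_year, m) for m in self.months]


@dataclass(frozen=True)
class CumulativeReduction:
    ref_total: float
    obs_total: float
    fraction: float


def _parse_count(text: str) -> float:
    value = int(text)
    if value < 0:
        raise ValidationError(f"negative count {value}")
    return float(value)


def read_cohort_csv(path: str | Path, source: str | None = None) -> CohortTable:
    """Read a tidy cohort CSV into a validated :class:`CohortTable`.

    Expected header: ``center_id,year,month,patient_status,tumor_group,
    sex,stage,count`` with the literal ``all`` for aggregated levels.
    Malformed rows raise :class:`ParseError` naming the line; duplicate
    keys raise :class:`IntegrityError`; negative counts raise
    :class:`ValidationError`.
    """
    path = Path(path)
    records: list[CohortRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header {CSV_HEADER}")
        if [h.strip() for h in header] != CSV_HEADER:
            raise ParseError(f"{path}: bad header {header}, expected {CSV_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(CSV_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(CSV_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                stratum = Stratum(
                    patient_status=row[3].strip(),
                    tumor_group=row[4].strip(),
                    sex=row[5].strip(),
                    stage=row[6].strip(),
                )
                rec = CohortRecord(
                    center_id=row[0].strip(),
                    year=int(row[1]),
                    month=int(row[2]),
                    stratum=stratum,
                    count=_parse_count(row[7]),
                )
            except ValidationError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return CohortTable(records, source=source or str(path))


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a :class:`CohortTable` back to the tidy CSV schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in sorted(
            table.records,
            key=lambda r: (r.center_id, r.year, r.month, r.stratum.patient_status,
                           r.stratum.tumor_group, r.stratum.sex, r.stratum.stage),
        ):
            count = rec.count
            out = int(count) if float(count).is_integer() else count
            writer.writerow(
                [
                    rec.center_id,
                    rec.year,
                    rec.month,
                    rec.stratum.patient_status,
                    rec.stratum.tumor_group,
                    rec.stratum.sex,
                    rec.stratum.stage,
                    out,
                ]
            )


def monthly_reduction(
    table: CohortTable,
    ref_year: int,
    obs_year: int,
    window: Sequence[int] = range(3, 8),
    stratum: Stratum | None = None,
    clamp: bool = True,
) -> ReductionSeries:
    """Per-month reduction fractions of ``obs_year`` versus ``ref_year``.

    Counts are aggregated over centers for the given stratum before the
    fraction is formed. A zero reference count in any month raises
    :class:`UndefinedFractionError` identifying the month.
    """
    stratum = stratum or Stratum()
    months = list(window)
    if not months:
        raise ValidationError("empty month window")
    ref = table.monthly_totals(ref_year, months, stratum)
    obs = table.monthly_totals(obs_year, months, stratum)
    return ReductionSeries(
        ref_year=ref_year,
        obs_year=obs_year,
        months=months,
        ref_counts=ref,
        obs_counts=obs,
        stratum=stratum,
        clamp=clamp,
    )


def cumulative_reduction(series: ReductionSeries) -> CumulativeReduction:
    """Window totals and overall fraction ``(sum ref - sum obs) / sum ref``."""
    ref_total = float(series.ref_counts.sum())
    obs_total = float(series.obs_counts.sum())
    return CumulativeReduction(
        ref_total=ref_total,
        obs_total=obs_total,
        fraction=(ref_total - obs_total) / ref_total,
    )


def ratio_series(
    table: CohortTable,
    year_pairs: Iterable[tuple[int, int]],
    window: Sequence[int] = range(1, 8),
    stratum: Stratum | None = None,
) -> dict[tuple[int, int], np.ndarray]:
    """Per-month ``obs/ref`` ratios for each ``(ref_year, obs_year)`` pair.

    The complement of :func:`monthly_reduction`: for every month,
    ``ratio = 1 - fraction``. A zero denominator raises
    :class:`UndefinedRatioError`.
    """
    stratum = stratum or Stratum()
    months = list(window)
    out: dict[tuple[int, int], np.ndarray] = {}
    for ref_year, obs_year in year_pairs:
        ref = table.monthly_totals(ref_year, months, stratum)
        obs = table.monthly_totals(obs_year, months, stratum)
        zero = [m for m, r in zip(months, ref) if r == 0]
        if zero:
            raise UndefinedRatioError(
                f"zero denominator in months {zero} of {ref_year}"
            )
        out[(ref_year, obs_year)] = obs / ref
    return out


def aggregate_ratio(ref_total: float, obs_total: float) -> float:
    """Window-level ratio ``obs/ref`` for published aggregate totals."""
    if ref_total == 0:
        raise UndefinedRatioError("zero reference total")
    return obs_total / ref_total
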