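"""Domain model and delimited-text ingestion for monthly condemnation records.

The unit of observation is the calendar month of a single slaughterhouse:
how many birds of each species category (turkey, griller chicken, heavy
chicken) were slaughtered, and how many condemnation records (partial and
total dispositions combined — the source spreadsheets cannot distinguish
them) were logged per cause. Months flagged as inconsistent by the
inspection service are carried but excluded from every downstream
statistic.

Condemnation causes are classified as *technological* (traceable to
catching, transport or slaughter-process failures: contamination,
contusion/traumatic injury, excessive scalding, delayed evisceration) or
non-technological (pathogen-, hygiene- or climate-associated). Seasonal
analysis is restricted to non-technological causes with enough volume;
cachexia and contagious epithelioma are excluded from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)


class MonthKey(NamedTuple):
    """A calendar month; orders lexicographically by (year, month)."""

    year: int
    month: int

    @classmethod
    def of(cls, year: int, month: int) -> "MonthKey":
        if not 1 <= int(month) <= 12:
            raise ValidationError(f"month must be in 1..12, got {month!r}")
        return cls(int(year), int(month))

    @classmethod
    def parse(cls, text: str) -> "MonthKey":
        """Parse 'YYYY-MM' (also tolerates 'YYYY/MM' and 'YYYYMM')."""
        s = str(text).strip().replace("/", "-")
        if "-" in s:
            y, m = s.split("-", 1)
        elif len(s) == 6 and s.isdigit():
            y, m = s[:4], s[4:]
        else:
            raise ValidationError(f"cannot parse month key {text!r}")
        return cls.of(int(y), int(m))

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


class Species(str, Enum):
    """Slaughtered species categories recorded by the inspection service."""

    TURKEY = "turkey"
    GRILLER = "griller"
    HEAVY = "heavy"


class GroupLabel(str, Enum):
    """Month classification by species mix.

    A: turkey slaughtered alongside griller or heavy chicken.
    B: only heavy chicken slaughtered.
    UNCLASSIFIED: anything else (excluded months, griller-only months, ...).
    """

    A = "A"
    B = "B"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class CauseDefinition:
    """A condemnation cause with its classification flags.

    ``technological`` marks process-failure causes; ``asi_eligible`` marks
    causes included in the seasonal-index analysis (non-technological
    causes, excluding low-occurrence cachexia/contagious epithelioma and
    the catch-all bucket).
    """

    code: str
    label: str
    technological: bool = False
    asi_eligible: bool = False

    def __post_init__(self):
        if self.technological and self.asi_eligible:
            raise ValidationError(
                f"cause {self.code!r}: technological causes are not eligible "
                "for seasonal-index analysis"
            )


#: The default cause registry: the twelve causes recorded in the source
#: spreadsheets (the 'others' bucket pools bloody meat, delayed
#: evisceration, contagious epithelioma and similar low-volume findings).
DEFAULT_CAUSES: tuple[CauseDefinition, ...] = (
    CauseDefinition("contamination", "Contamination", technological=True),
    CauseDefinition("contusion", "Contusion / Traumatic injury", technological=True),
    CauseDefinition("dermatosis", "Dermatosis", asi_eligible=True),
    CauseDefinition("aerosacculitis", "Aerosacculitis", asi_eligible=True),
    CauseDefinition("arthritis", "Arthritis", asi_eligible=True),
    CauseDefinition("septicemia", "Septicemia", asi_eligible=True),
    CauseDefinition("disgusting_aspects", "Disgusting aspects", asi_eligible=True),
    CauseDefinition("excessive_scalding", "Excessive scalding", technological=True),
    CauseDefinition("cellulitis", "Cellulitis", asi_eligible=True),
    CauseDefinition("ascitic_syndrome", "Ascitic syndrome", asi_eligible=True),
    CauseDefinition("cachexia", "Cachexia"),
    CauseDefinition("others", "Others"),
)


@dataclass
class MonthlyRecord:
    """One month's slaughter head counts per species and condemnation
    counts per cause (partial + total dispositions, never split)."""

    key: MonthKey
    slaughtered: dict[Species, int]
    condemned: dict[str, int]
    excluded: bool = False

    @property
    def total_slaughtered(self) -> int:
        return sum(self.slaughtered.values())

    @property
    def total_condemned(self) -> int:
        return sum(self.condemned.values())


@dataclass
class Dataset:
    """An ordered monthly series with its cause registry.

    Invariants: month keys strictly increasing (gaps allowed — a missing
    month is simply absent, which is distinct from an excluded one); every
    condemnation key is registered in ``causes``.
    """

    records: list[MonthlyRecord]
    causes: tuple[CauseDefinition, ...] = DEFAULT_CAUSES
    provenance: str = ""

    def __post_init__(self):
        self.causes = tuple(self.causes)
        codes = self.cause_codes()
        if len(set(codes)) != len(codes):
            raise IntegrityError("duplicate cause codes in registry")
        prev: MonthKey | None = None
        for rec in self.records:
            if prev is not None and rec.key <= prev:
                raise IntegrityError(
                    f"month keys not strictly increasing at {rec.key}"
                )
            prev = rec.key
            unknown = set(rec.condemned) - set(codes)
            if unknown:
                raise IntegrityError(
                    f"{rec.key}: condemnation keys not in registry: {sorted(unknown)}"
                )
            for cause, n in rec.condemned.items():
                if n < 0:
                    raise ValidationError(f"{rec.key}: negative count for {cause}")

    def cause_codes(self) -> list[str]:
        return [c.code for c in self.causes]

    def cause(self, code: str) -> CauseDefinition:
        for c in self.causes:
            if c.code == code:
                return c
        raise KeyError(code)

    def get(self, key: MonthKey) -> MonthlyRecord:
        for rec in self.records:
            if rec.key == key:
                return rec
        raise KeyError(key)

    def included(self) -> list[MonthlyRecord]:
        """Records not flagged as excluded."""
        return [r for r in self.records if not r.excluded]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: year, month, slaughtered_<species>, one column per
        cause code, excluded flag."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"year": rec.key.year, "month": rec.key.month}
            for sp in Species:
                row[f"slaughtered_{sp.value}"] = rec.slaughtered.get(sp, 0)
            for code in self.cause_codes():
                row[code] = rec.condemned.get(code, 0)
            row["excluded"] = rec.excluded
            rows.append(row)
        return pd.DataFrame(rows)


_SPECIES_COLUMNS = {f"slaughtered_{sp.value}": sp for sp in Species}


def read_dataset(
    path: str | Path,
    causes: Sequence[CauseDefinition] = DEFAULT_CAUSES,
    column_map: Mapping[str, str] | None = None,
    thousands: str | None = ",",
    provenance: str | None = None,
) -> Dataset:
    """Read a wide-form monthly CSV into a validated :class:`Dataset`.

    Expected columns: ``year``, ``month``, optional
    ``slaughtered_turkey``/``slaughtered_griller``/``slaughtered_heavy``
    (absent species default to zero head), one column per registered cause
    code, and an optional ``excluded`` flag. ``column_map`` renames
    non-standard columns onto cause codes (map several columns onto
    ``"others"`` to pool them); any column that cannot be resolved raises
    :class:`~avicond.errors.SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, thousands=thousands)
    df.columns = [str(c).strip() for c in df.columns]
    column_map = dict(column_map or {})
    codes = [c.code for c in causes]

    for required in ("year", "month"):
        if required not in df.columns:
            raise SchemaError(f"missing required column {required!r}")

    cause_cols: dict[str, str] = {}  # column -> cause code
    for col in df.columns:
        if col in ("year", "month", "excluded") or col in _SPECIES_COLUMNS:
            continue
        target = column_map.get(col, col)
        if target not in codes:
            raise SchemaError(
                f"unknown column {col!r}; map it to a registered cause "
                "(e.g. to 'others') via column_map"
            )
        cause_cols[col] = target

    records: list[MonthlyRecord] = []
    seen: set[MonthKey] = set()
    numeric_cols = list(_SPECIES_COLUMNS) + list(cause_cols)
    for idx, row in df.iterrows():
        for col in ("year", "month", *[c for c in numeric_cols if c in df.columns]):
            val = row[col]
            num = pd.to_numeric(pd.Series([val]), errors="coerce").iloc[0]
            if pd.isna(num):
                raise ValidationError(f"row {idx}: non-numeric value in {col!r}: {val!r}")
            if num < 0:
                raise ValidationError(f"row {idx}: negative count in {col!r}: {val!r}")
            if float(num) != int(num):
                raise ValidationError(f"row {idx}: non-integer count in {col!r}: {val!r}")
        key = MonthKey.of(int(row["year"]), int(row["month"]))
        if key in seen:
            raise IntegrityError(f"duplicate month {key}")
        seen.add(key)
        slaughtered = {
            sp: int(row[col])
            for col, sp in _SPECIES_COLUMNS.items()
            if col in df.columns
        }
        condemned: dict[str, int] = {code: 0 for code in codes}
        for col, code in cause_cols.items():
            condemned[code] += int(row[col])
        excluded = bool(row["excluded"]) if "excluded" in df.columns else False
        rec = MonthlyRecord(key, slaughtered, condemned, excluded)
        if rec.total_condemned > rec.total_slaughtered > 0:
            # A carcass can contribute several partial condemnation records,
            # so condemned > head count is suspicious but not impossible.
            logger.warning(
                "%s: condemned (%d) exceeds slaughtered (%d); keeping row",
                key, rec.total_condemned, rec.total_slaughtered,
            )
        records.append(rec)

    records.sort(key=lambda r: r.key)
    return Dataset(records, tuple(causes), provenance or str(path))


def write_dataset(ds: Dataset, path: str | Path) -> Path:
    """Write the wide CSV form read back bit-identically by
    :func:`read_dataset` (integer counts, comma-separated, UTF-8)."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False)
    return path


def flag_exclusions(ds: Dataset, months: Iterable[MonthKey | str]) -> Dataset:
    """Return a copy of ``ds`` with the given months flagged as excluded.

    Idempotent; months absent from the series are ignored with a warning.
    """
    wanted = {m if isinstance(m, MonthKey) else MonthKey.parse(m) for m in months}
    present = {r.key for r in ds.records}
    for m in sorted(wanted - present):
        logger.warning("exclusion %s not present in dataset; ignored", m)
    new_records = [
        replace(rec, excluded=True) if rec.key in wanted else replace(rec)
        for rec in ds.records
    ]
    return Dataset(new_records, ds.causes, ds.provenance)


def load_exclusions(path: str | Path) -> list[MonthKey]:
    """Read an exclusion list from YAML of the form ``exclude: [2017-06, ...]``."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return [MonthKey.parse(m) for m in doc.get("exclude", [])]


def assign_groups(ds: Dataset) -> dict[MonthKey, GroupLabel]:
    """Classify each month by its species mix.

    A month is Group A when turkeys were slaughtered together with griller
    or heavy chicken, Group B when only heavy chicken was slaughtered, and
    UNCLASSIFIED otherwise (excluded months are always UNCLASSIFIED).
    """
    labels: dict[MonthKey, GroupLabel] = {}
    for rec in ds.records:
        if rec.excluded:
            labels[rec.key] = GroupLabel.UNCLASSIFIED
            continue
        turkey = rec.slaughtered.get(Species.TURKEY, 0)
        griller = rec.slaughtered.get(Species.GRILLER, 0)
        heavy = rec.slaughtered.get(Species.HEAVY, 0)
        if turkey > 0 and (griller > 0 or heavy > 0):
            labels[rec.key] = GroupLabel.A
        elif heavy > 0 and turkey == 0 and griller == 0:
            labels[rec.key] = GroupLabel.B
        else:
            labels[rec.key] = GroupLabel.UNCLASSIFIED
    return labels
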