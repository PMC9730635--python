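"""Condemnation occurrence and seasonal indices.

Two statistics drive the analysis:

* **COI (Condemnation Occurrence Index)** — condemnation records (partial
  + total) divided by birds slaughtered in the period, scaled to
  per-million head by default:  ``COI = scale * condemned / slaughtered``.

* **ASI (Adjusted Seasonal Index)** — a two-stage ratio-to-annual-mean
  construction. Stage one divides each month's COI by the arithmetic mean
  of that year's usable monthly COIs (partial years use the months
  present), so every complete year's ratios average to exactly 1. Stage
  two averages, for each calendar month, its ratios across the years of
  the series. ASI = 1 means "as expected for the year"; 1.63 means 63%
  above the annual expectation.

Excluded months never contribute: they carry no COI value, enter no annual
mean, and reduce the number of years behind their calendar month's ASI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Mapping, Sequence

import pandas as pd

from .data import CauseDefinition, Dataset, MonthKey
from .errors import UndefinedRateError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Default COI scale: occurrences per one million birds slaughtered.
DEFAULT_SCALE = 1_000_000.0

#: Scope name for the all-causes-combined series.
OVERALL = "overall"


def compute_coi(condemned: float, slaughtered: float, scale: float = DEFAULT_SCALE) -> float:
    """Condemnation occurrence index: ``scale * condemned / slaughtered``."""
    if slaughtered == 0:
        raise UndefinedRateError("COI undefined: zero birds slaughtered")
    return scale * condemned / slaughtered


@dataclass
class CoiSeries:
    """Per-month COI values for one scope (overall or a single cause).

    ``values`` holds only usable (present, non-excluded) months.
    """

    scope: str
    values: dict[MonthKey, float]
    scale: float = DEFAULT_SCALE


def _scope_condemned(rec, scope: str) -> int:
    return rec.total_condemned if scope == OVERALL else rec.condemned.get(scope, 0)


def coi_series(ds: Dataset, scope: str = OVERALL, scale: float = DEFAULT_SCALE) -> CoiSeries:
    """Monthly COI series over the non-excluded months of ``ds``."""
    if scope != OVERALL and scope not in ds.cause_codes():
        raise KeyError(f"unknown scope {scope!r}")
    values = {
        rec.key: compute_coi(_scope_condemned(rec, scope), rec.total_slaughtered, scale)
        for rec in ds.included()
    }
    return CoiSeries(scope, values, scale)


def period_coi(
    ds: Dataset,
    scope: str = OVERALL,
    years: tuple[int, int] | None = None,
    scale: float = DEFAULT_SCALE,
) -> float:
    """Pooled COI over a year range (inclusive): total condemned over total
    slaughtered — not a mean of monthly indices."""
    recs = ds.included()
    if years is not None:
        lo, hi = years
        recs = [r for r in recs if lo <= r.key.year <= hi]
    if not recs:
        raise InsufficientDataError(f"no usable months in year range {years}")
    condemned = sum(_scope_condemned(r, scope) for r in recs)
    slaughtered = sum(r.total_slaughtered for r in recs)
    return compute_coi(condemned, slaughtered, scale)


@dataclass
class FrequencyTable:
    """Per-cause condemnation counts and percent shares.

    ``denominator_policy`` selects the percent denominator: the sum of the
    cause counts themselves (``sum_of_causes``, the default — internally
    consistent) or an externally reported grand total
    (``reported_total``).
    """

    table: pd.DataFrame  # columns: cause, label, technological, count, percent
    denominator_policy: str
    denominator: float


def frequency_from_counts(
    counts: Mapping[str, int],
    causes: Sequence[CauseDefinition],
    denominator_policy: str = "sum_of_causes",
    reported_total: float | None = None,
) -> FrequencyTable:
    """Build a frequency table from already-aggregated per-cause counts."""
    if denominator_policy == "sum_of_causes":
        denom = float(sum(counts.values()))
    elif denominator_policy == "reported_total":
        if reported_total is None:
            raise ValueError("reported_total required for that policy")
        denom = float(reported_total)
        if denom != sum(counts.values()):
            logger.warning(
                "reported total %.0f differs from sum of cause counts %.0f",
                denom, sum(counts.values()),
            )
    else:
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    if denom == 0:
        raise UndefinedRateError("frequency table denominator is zero")
    by_code = {c.code: c for c in causes}
    rows = [
        {
            "cause": code,
            "label": by_code[code].label if code in by_code else code,
            "technological": by_code[code].technological if code in by_code else False,
            "count": int(n),
            "percent": 100.0 * n / denom,
        }
        for code, n in counts.items()
    ]
    table = pd.DataFrame(rows).sort_values("count", ascending=False, kind="mergesort")
    return FrequencyTable(table.reset_index(drop=True), denominator_policy, denom)


def frequency_table(
    ds: Dataset,
    denominator_policy: str = "sum_of_causes",
    include_excluded: bool = True,
    reported_total: float | None = None,
) -> FrequencyTable:
    """Aggregate condemnation counts per cause over the whole series.

    Excluded months are included by default: the frequency accounting is a
    descriptive total of what was recorded, unlike the index statistics.
    """
    recs = ds.records if include_excluded else ds.included()
    counts = {code: 0 for code in ds.cause_codes()}
    for rec in recs:
        for code, n in rec.condemned.items():
            counts[code] += n
    return frequency_from_counts(counts, ds.causes, denominator_policy, reported_total)


def monthly_ratios(series: CoiSeries) -> dict[MonthKey, float]:
    """Stage one of the ASI: each month's COI divided by its year's mean
    monthly COI (over that year's usable months only)."""
    by_year: dict[int, list[MonthKey]] = {}
    for key in series.values:
        by_year.setdefault(key.year, []).append(key)
    ratios: dict[MonthKey, float] = {}
    for year, keys in sorted(by_year.items()):
        mean = sum(series.values[k] for k in keys) / len(keys)
        if mean == 0:
            raise UndefinedRateError(
                f"scope {series.scope!r}: annual mean COI is zero in {year}"
            )
        for k in keys:
            ratios[k] = series.values[k] / mean
    return ratios


@dataclass
class AsiResult:
    """Adjusted seasonal index for one scope.

    ``ratios`` are the stage-one per-(year, month) ratios; ``asi`` maps
    calendar month (1–12) to the across-year mean of its ratios;
    ``n_years_per_month`` records how many years backed each mean (excluded
    or missing months reduce it). Calendar months with no usable year are
    absent.
    """

    scope: str
    ratios: dict[MonthKey, float]
    asi: dict[int, float]
    n_years_per_month: dict[int, int] = field(default_factory=dict)


def compute_asi(series: CoiSeries) -> AsiResult:
    """Stage two of the ASI: average each calendar month's stage-one
    ratios across the years of the series."""
    years = {k.year for k in series.values}
    if len(years) < 2:
        raise InsufficientDataError("ASI needs at least two years of data")
    ratios = monthly_ratios(series)
    per_month: dict[int, list[float]] = {}
    for key, r in ratios.items():
        per_month.setdefault(key.month, []).append(r)
    asi: dict[int, float] = {}
    n_years: dict[int, int] = {}
    for m in range(1, 13):
        vals = per_month.get(m, [])
        if not vals:
            logger.warning("scope %r: no usable years for calendar month %d", series.scope, m)
            continue
        asi[m] = sum(vals) / len(vals)
        n_years[m] = len(vals)
    return AsiResult(series.scope, ratios, asi, n_years)
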