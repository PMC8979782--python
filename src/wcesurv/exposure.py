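"""Daily exposure reconstruction from pharmacy dispensing claims.

Dispensing claims record the date, strength and tablet count of each
prescription fill, but not the dose actually taken. For regular-use
analgesics in an elderly cohort the conventional reconstruction assumes
the maximum labelled daily dose on every covered day:

* 500 mg immediate-release tablets: 8 tablets/day = 4.0 g/day;
* 665 mg controlled-release tablets: 6 tablets/day = 3.99 g/day.

Days of supply is the tablet count divided by the tablets-per-day
assumption (floored, minimum one day). Early refills do not shorten
exposure: a fill dated before the end of the current supply period queues
its full supply after the current period ends ("supply extension"), while
a fill after a gap starts new coverage on its own date.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyExposureSeries",
    "days_of_supply",
    "build_daily_series",
    "build_binary_series",
    "DEFAULT_TABLETS_PER_DAY",
    "DEFAULT_DAILY_DOSE_G",
]

logger = logging.getLogger(__name__)

#: tablets per day by strength (mg); 8 x 500 mg = 4 g, 6 x 665 mg = 3.99 g
DEFAULT_TABLETS_PER_DAY: Mapping[int, int] = {500: 8, 665: 6}
#: grams per covered day by strength (mg)
DEFAULT_DAILY_DOSE_G: Mapping[int, float] = {500: 4.0, 665: 3.99}


@dataclass
class DailyExposureSeries:
    """Per-patient daily dose vector in g/day, indexed from an origin date.

    ``doses[t]`` is the dose on day ``origin + t``. In the survival model
    the dose on a given follow-up day contributes to risk from the next
    day onwards (minimum lag one day), so the final day's entry is never
    consumed by the model.
    """

    patient_id: object
    origin: date
    doses: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)

    def __len__(self) -> int:
        return self.doses.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per day with nonnegative dose."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "day": np.arange(self.doses.size),
                "dose_g": self.doses,
            }
        )


def days_of_supply(
    quantity: int,
    strength_mg: int,
    tablets_per_day: Mapping[int, int] | None = None,
) -> int:
    """Days of supply of one dispensing under the maximum-dose assumption.

    ``floor(quantity / tablets_per_day[strength])``, clamped to at least
    one day so that every dispensing contributes some exposure.
    """
    tpd = DEFAULT_TABLETS_PER_DAY if tablets_per_day is None else tablets_per_day
    if strength_mg not in tpd:
        raise ValueError(
            f"unsupported-formulation: strength {strength_mg} mg has no "
            f"tablets-per-day rule"
        )
    if quantity <= 0:
        raise ValueError("quantity must be positive")
    return max(1, math.floor(quantity / tpd[strength_mg]))


def _record_fields(rec):
    """Extract (supply_date, strength_mg, quantity) from a row or mapping.

    ``strength_mg`` may be blank/NaN for products whose strength is not
    dose-relevant (e.g. statins in a binary series); it parses to None.
    """
    if isinstance(rec, Mapping):
        raw, qty, when = rec["strength_mg"], rec["quantity"], rec["supply_date"]
    else:
        raw, qty, when = rec.strength_mg, rec.quantity, rec.supply_date
    try:
        strength = int(raw)
    except (TypeError, ValueError):
        strength = None
    return when, strength, int(qty)


def build_daily_series(
    dispensings,
    origin: date,
    end: date,
    patient_id=None,
    tablets_per_day: Mapping[int, int] | None = None,
    daily_dose_g: Mapping[int, float] | None = None,
) -> DailyExposureSeries:
    """Build the daily dose series for one patient on ``[origin, end)``.

    Parameters
    ----------
    dispensings : DataFrame or iterable of mappings/records
        Rows with ``supply_date``, ``strength_mg``, ``quantity``; any order.
    origin : date
        Day 0 of the series (cohort entry).
    end : date
        Exclusive end of follow-up; coverage is truncated here.

    Supply intervals are half-open ``[start, start + supply)`` in days.
    Fills are consumed first-dispensed-first, so the dose on a covered day
    is the daily dose of the fill whose (possibly deferred) supply
    interval covers it. Fills dated on or after ``end`` are skipped with a
    log message; fills before ``origin`` may still cover post-origin days.
    """
    dose_map = DEFAULT_DAILY_DOSE_G if daily_dose_g is None else daily_dose_g
    n_days = (end - origin).days
    if n_days < 0:
        raise ValueError("end must not precede origin")
    doses = np.zeros(n_days)

    if isinstance(dispensings, pd.DataFrame):
        rows: Iterable = dispensings.to_dict("records")
    else:
        rows = list(dispensings)
    parsed = []
    for rec in rows:
        supply_date, strength, qty = _record_fields(rec)
        supply_date = _as_date(supply_date)
        if supply_date >= end:
            logger.info(
                "out-of-window record skipped: patient %s dispensing on %s",
                patient_id, supply_date,
            )
            continue
        parsed.append((supply_date, strength, qty))
    parsed.sort(key=lambda r: r[0])

    covered_until = None  # day offset relative to origin, exclusive
    for supply_date, strength, qty in parsed:
        supply = days_of_supply(qty, strength, tablets_per_day)
        start = (supply_date - origin).days
        if covered_until is not None and start < covered_until:
            start = covered_until  # extension: queue after current coverage
        stop = start + supply
        covered_until = stop
        lo, hi = max(start, 0), min(stop, n_days)
        if lo < hi:
            doses[lo:hi] = dose_map[strength]
    return DailyExposureSeries(patient_id=patient_id, origin=origin,
                               doses=doses)


def build_binary_series(
    dispensings,
    origin: date,
    end: date,
    patient_id=None,
    tablets_per_day: Mapping[int, int] | None = None,
    default_supply_days: int = 30,
) -> np.ndarray:
    """Daily binary coverage indicator (e.g. statin use) on ``[origin, end)``.

    Uses the same supply-extension logic as :func:`build_daily_series`;
    dispensings whose strength has no tablets-per-day rule fall back to
    ``default_supply_days`` per fill.
    """
    n_days = (end - origin).days
    covered = np.zeros(max(n_days, 0))
    if isinstance(dispensings, pd.DataFrame):
        rows: Iterable = dispensings.to_dict("records")
    else:
        rows = list(dispensings)
    parsed = []
    for rec in rows:
        supply_date, strength, qty = _record_fields(rec)
        supply_date = _as_date(supply_date)
        if supply_date >= end:
            continue
        tpd = DEFAULT_TABLETS_PER_DAY if tablets_per_day is None else tablets_per_day
        if strength in tpd:
            supply = days_of_supply(qty, strength, tpd)
        else:
            supply = default_supply_days
        parsed.append(((supply_date - origin).days, supply))
    parsed.sort()
    covered_until = None
    for start, supply in parsed:
        if covered_until is not None and start < covered_until:
            start = covered_until
        stop = start + supply
        covered_until = stop
        lo, hi = max(start, 0), min(stop, int(n_days))
        if lo < hi:
            covered[lo:hi] = 1.0
    return covered


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()
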