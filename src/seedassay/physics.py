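"""Radioactive decay model and decay correction of well-chamber readings.

An I-125 seed assayed on a date other than the manufacturer's calibration
(reference) date must be decay-corrected before the reading is compared with
the nominal activity.  The correction uses the base-2 exponential form

    A(t) = A(0) * 2**(-t / T_half)

with T_half = 59.4 days for I-125.  "Corrected" here always means activity
*at the reference date*: a reading taken after the reference date is scaled
up, one taken before is scaled down.  Elapsed time is counted in whole
calendar days; the assay protocol records dates only, not times of day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .exceptions import InputFormatError, InvalidParameterError

__all__ = [
    "Isotope",
    "I125",
    "TimedReading",
    "decay_factor",
    "decay_correct",
    "parse_date",
]


@dataclass(frozen=True)
class Isotope:
    """A radionuclide identified by name and physical half-life in days."""

    name: str
    half_life_days: float

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise InvalidParameterError(
                f"half_life_days must be positive, got {self.half_life_days!r}"
            )


#: Iodine-125, the implant isotope this QA pipeline is built around.
I125 = Isotope("I-125", 59.4)


def parse_date(value: date | str) -> date:
    """Return ``value`` as a :class:`datetime.date`, accepting ISO 8601 text."""
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise InputFormatError(f"not an ISO 8601 date: {value!r}") from exc


@dataclass(frozen=True)
class TimedReading:
    """A chamber reading (MBq) with its measurement and reference dates."""

    reading_mbq: float
    measurement_date: date
    reference_date: date

    def __post_init__(self) -> None:
        if self.reading_mbq < 0:
            raise InvalidParameterError(
                f"reading_mbq must be nonnegative, got {self.reading_mbq!r}"
            )
        object.__setattr__(self, "measurement_date", parse_date(self.measurement_date))
        object.__setattr__(self, "reference_date", parse_date(self.reference_date))

    @property
    def elapsed_days(self) -> int:
        """Whole days from reference date to measurement date (signed)."""
        return (self.measurement_date - self.reference_date).days


def decay_factor(delta_days: float, half_life_days: float) -> float:
    """Fraction of activity remaining after ``delta_days`` of decay.

    Negative ``delta_days`` (a time *before* the reference) yields a factor
    above 1.  Strictly positive and strictly decreasing in ``delta_days``.
    """
    if not half_life_days > 0:
        raise InvalidParameterError(
            f"half_life_days must be positive, got {half_life_days!r}"
        )
    return 2.0 ** (-delta_days / half_life_days)


def decay_correct(reading: TimedReading, isotope: Isotope = I125) -> float:
    """Activity (MBq) at the reference date implied by ``reading``.

    Inverts the decay that occurred between the reference date and the
    measurement date: ``reading_mbq * 2**(+dt/T_half)`` with
    ``dt = measurement_date - reference_date`` in days.  Equal dates return
    the reading unchanged, and correcting then decaying back is the identity
    up to floating-point error.
    """
    dt = reading.elapsed_days
    return reading.reading_mbq / decay_factor(dt, isotope.half_life_days)
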