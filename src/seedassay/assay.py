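"""Detection-rate statistic, per-pack-size summaries and measurement-log I/O.

The batch assay measures all seeds of a blister pack together in a well-type
ionization chamber and reports the *detection rate*

    detection rate (%) = 100 * M / (A_nom * n)

where M is the (decay-corrected) chamber reading in MBq, A_nom the
manufacturer's nominal per-seed activity and n the number of packaged seeds.
Because adjacent seeds and the cartridge partially shield each other the rate
is well below 100% for large packs; quality control is therefore run against
the facility's cumulative per-n mean rather than against 100%.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence
import warnings

from .exceptions import InputFormatError, InvalidParameterError
from .physics import I125, Isotope, TimedReading, decay_correct, parse_date

__all__ = [
    "KNOWN_NOMINALS_MBQ",
    "BlisterPackRecord",
    "AssayResult",
    "PerNSummary",
    "RowError",
    "MeasurementLog",
    "detection_rate",
    "compute_rates",
    "per_source_rate",
    "summarize_by_n",
    "read_measurements",
    "write_measurements",
    "write_results",
    "write_summaries",
]

#: Commercially available nominal per-seed strengths for this product line.
KNOWN_NOMINALS_MBQ = (11.0, 13.1, 15.3)

MEASUREMENT_COLUMNS = (
    "pack_id",
    "n_seeds",
    "nominal_mbq",
    "measured_mbq",
    "measurement_date",
    "reference_date",
)


@dataclass
class BlisterPackRecord:
    """One measured blister pack from the facility log."""

    pack_id: str
    n_seeds: int
    nominal_mbq_per_seed: float
    measured_mbq: float
    measurement_date: date
    reference_date: date

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise InvalidParameterError(f"n_seeds must be >= 1, got {self.n_seeds}")
        if not self.nominal_mbq_per_seed > 0:
            raise InvalidParameterError(
                f"nominal_mbq_per_seed must be positive, got {self.nominal_mbq_per_seed}"
            )
        if self.measured_mbq < 0:
            raise InvalidParameterError(
                f"measured_mbq must be nonnegative, got {self.measured_mbq}"
            )
        self.measurement_date = parse_date(self.measurement_date)
        self.reference_date = parse_date(self.reference_date)
        if self.n_seeds > 20:
            warnings.warn(
                f"pack {self.pack_id!r}: n_seeds={self.n_seeds} outside the "
                "1-20 range of this product line",
                stacklevel=2,
            )
        if not any(
            abs(self.nominal_mbq_per_seed - a) < 1e-9 for a in KNOWN_NOMINALS_MBQ
        ):
            warnings.warn(
                f"pack {self.pack_id!r}: nominal {self.nominal_mbq_per_seed} MBq is "
                f"not one of the catalogue strengths {KNOWN_NOMINALS_MBQ}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AssayResult:
    pack_id: str
    n_seeds: int
    detection_rate_pct: float


@dataclass(frozen=True)
class PerNSummary:
    """Cumulative detection-rate summary for one pack size."""

    n_seeds: int
    count: int
    mean_rate_pct: float
    min_rate_pct: float
    max_rate_pct: float


def detection_rate(record: BlisterPackRecord) -> float:
    """Detection rate (%) of ``record`` from its stored reading.

    The stored ``measured_mbq`` is used as-is; apply decay correction first
    (see :func:`compute_rates`) when the measurement and reference dates
    differ.  Linear in the reading.
    """
    return 100.0 * record.measured_mbq / (record.nominal_mbq_per_seed * record.n_seeds)


def compute_rates(
    records: Iterable[BlisterPackRecord],
    isotope: Isotope = I125,
    correct_decay: bool = True,
) -> list[AssayResult]:
    """Run the assay pipeline: (optionally) decay-correct, then rate.

    ``correct_decay=False`` is provided for logs whose instrument already
    reports activity at the reference date via its isotope setting.
    """
    results = []
    for rec in records:
        measured = rec.measured_mbq
        if correct_decay:
            measured = decay_correct(
                TimedReading(rec.measured_mbq, rec.measurement_date, rec.reference_date),
                isotope,
            )
        results.append(
            AssayResult(
                pack_id=rec.pack_id,
                n_seeds=rec.n_seeds,
                detection_rate_pct=100.0
                * measured
                / (rec.nominal_mbq_per_seed * rec.n_seeds),
            )
        )
    return results


def per_source_rate(mean_rate_pct: float, n_seeds: int) -> float:
    """Mean detection rate divided by the pack size.

    This is the expected contribution of a single seed to the batch reading,
    and hence the signal that one dead seed would remove.
    """
    if n_seeds < 1:
        raise InvalidParameterError(f"n_seeds must be >= 1, got {n_seeds}")
    return mean_rate_pct / n_seeds


def summarize_by_n(results: Iterable[AssayResult]) -> list[PerNSummary]:
    """Aggregate assay results into one summary per distinct pack size."""
    by_n: dict[int, list[float]] = {}
    for res in results:
        by_n.setdefault(res.n_seeds, []).append(res.detection_rate_pct)
    summaries = []
    for n, rates in sorted(by_n.items()):
        lo, hi = min(rates), max(rates)
        # clamp against 1-ulp rounding of the sum so min <= mean <= max holds
        mean = min(max(sum(rates) / len(rates), lo), hi)
        summaries.append(
            PerNSummary(
                n_seeds=n, count=len(rates), mean_rate_pct=mean,
                min_rate_pct=lo, max_rate_pct=hi,
            )
        )
    return summaries


@dataclass(frozen=True)
class RowError:
    line_no: int
    message: str


@dataclass
class MeasurementLog:
    """Parsed measurement log: accepted records plus rejected-row diagnostics."""

    records: list[BlisterPackRecord]
    rejected: list[RowError]

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_measurements(path: str | Path) -> MeasurementLog:
    """Read a measurement-log CSV.

    Expected header: ``pack_id,n_seeds,nominal_mbq,measured_mbq,
    measurement_date,reference_date`` (UTF-8, '.' decimal separator, ISO
    dates).  Malformed rows are collected with their 1-based line numbers
    rather than aborting the whole file; a missing column aborts.
    """
    path = Path(path)
    records: list[BlisterPackRecord] = []
    rejected: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputFormatError(f"{path}: empty file, expected a CSV header")
        missing = set(MEASUREMENT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise InputFormatError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            line_no = reader.line_num
            try:
                records.append(
                    BlisterPackRecord(
                        pack_id=row["pack_id"],
                        n_seeds=int(row["n_seeds"]),
                        nominal_mbq_per_seed=float(row["nominal_mbq"]),
                        measured_mbq=float(row["measured_mbq"]),
                        measurement_date=parse_date(row["measurement_date"]),
                        reference_date=parse_date(row["reference_date"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                rejected.append(RowError(line_no, str(exc)))
    return MeasurementLog(records=records, rejected=rejected)


def write_measurements(path: str | Path, records: Sequence[BlisterPackRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.pack_id,
                    rec.n_seeds,
                    repr(rec.nominal_mbq_per_seed),
                    repr(rec.measured_mbq),
                    rec.measurement_date.isoformat(),
                    rec.reference_date.isoformat(),
                ]
            )


def write_results(path: str | Path, results: Sequence[AssayResult]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pack_id", "n_seeds", "detection_rate_pct"])
        for res in results:
            writer.writerow([res.pack_id, res.n_seeds, repr(res.detection_rate_pct)])


def write_summaries(path: str | Path, summaries: Sequence[PerNSummary]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["n_seeds", "count", "mean_rate_pct", "min_rate_pct", "max_rate_pct"]
        )
        for s in summaries:
            writer.writerow(
                [s.n_seeds, s.count, repr(s.mean_rate_pct), repr(s.min_rate_pct), repr(s.max_rate_pct)]
            )
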