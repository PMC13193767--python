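"""Control limits and pack classification for the batch assay.

Guideline practice uses two percentage bands around the facility's
cumulative mean detection rate for each pack size: an *acceptance*
(tolerance) limit of 3% and an *intervention* limit of 5%.  A pack whose
rate deviates from the per-n mean by more than the intervention limit must
be reported to the manufacturer.  Deviations are measured relative to the
cumulative mean, not to 100%, because shielding makes the expected rate
n-dependent.

A deviation exactly equal to a limit does not escalate to the next verdict:
a reduction exactly at the intervention threshold is the canonical
borderline case (one dead seed in a 20-pack) and is not reliably
detectable, so strict inequality defines violation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .assay import AssayResult, per_source_rate
from .exceptions import ConfigurationError, InvalidParameterError
from .rounding import round_half_away

__all__ = [
    "FACILITY_MEAN_RATES",
    "ACCEPTANCE_PCT",
    "INTERVENTION_PCT",
    "ControlLimits",
    "Verdict",
    "Classification",
    "build_limits",
    "classify",
    "classify_rate",
    "limits_table",
    "AuditReport",
    "audit",
]

#: Cumulative mean detection rate (%) by pack size accumulated at the
#: facility over its full delivery history (Jan 2020 - May 2023, 433 packs).
FACILITY_MEAN_RATES: dict[int, float] = {
    1: 102.5,
    2: 92.1,
    3: 87.5,
    4: 86.4,
    5: 85.1,
    20: 67.0,
}

ACCEPTANCE_PCT = 3.0
INTERVENTION_PCT = 5.0


@dataclass(frozen=True)
class ControlLimits:
    """A symmetric percentage band around a per-pack-size mean rate."""

    n_seeds: int
    mean_rate_pct: float
    tolerance_pct: float
    tol_abs_pct: float
    lower_pct: float
    upper_pct: float


class Verdict(str, Enum):
    WITHIN_ACCEPTANCE = "within_acceptance"
    INVESTIGATE = "investigate"
    INTERVENE = "intervene"


@dataclass(frozen=True)
class Classification:
    pack_id: str
    n_seeds: int
    rate_pct: float
    deviation_pct: float  # signed, in % of the per-n mean
    verdict: Verdict


def build_limits(mean_rate_pct: float, tolerance_pct: float, n_seeds: int) -> ControlLimits:
    """Band ``mean * (1 +/- tolerance/100)`` around the cumulative mean."""
    if not mean_rate_pct > 0:
        raise InvalidParameterError(f"mean_rate_pct must be positive, got {mean_rate_pct}")
    if not tolerance_pct > 0:
        raise InvalidParameterError(f"tolerance_pct must be positive, got {tolerance_pct}")
    tol_abs = mean_rate_pct * tolerance_pct / 100.0
    return ControlLimits(
        n_seeds=n_seeds,
        mean_rate_pct=mean_rate_pct,
        tolerance_pct=tolerance_pct,
        tol_abs_pct=tol_abs,
        lower_pct=mean_rate_pct - tol_abs,
        upper_pct=mean_rate_pct + tol_abs,
    )


def classify_rate(
    rate_pct: float,
    mean_rate_pct: float,
    acceptance_pct: float = ACCEPTANCE_PCT,
    intervention_pct: float = INTERVENTION_PCT,
    pack_id: str = "",
    n_seeds: int = 0,
) -> Classification:
    """Classify one detection rate against acceptance/intervention limits."""
    deviation = 100.0 * (rate_pct - mean_rate_pct) / mean_rate_pct
    if abs(deviation) <= acceptance_pct:
        verdict = Verdict.WITHIN_ACCEPTANCE
    elif abs(deviation) <= intervention_pct:
        verdict = Verdict.INVESTIGATE
    else:
        verdict = Verdict.INTERVENE
    return Classification(
        pack_id=pack_id,
        n_seeds=n_seeds,
        rate_pct=rate_pct,
        deviation_pct=deviation,
        verdict=verdict,
    )


def classify(
    rate_pct: float,
    limits_acceptance: ControlLimits,
    limits_intervention: ControlLimits,
    pack_id: str = "",
) -> Classification:
    """Classify a rate given explicit acceptance and intervention bands.

    Both bands must be centred on the same mean (they are nested bands of
    the same control chart).
    """
    if abs(limits_acceptance.mean_rate_pct - limits_intervention.mean_rate_pct) > 1e-9:
        raise InvalidParameterError(
            "acceptance and intervention limits must share the same mean "
            f"({limits_acceptance.mean_rate_pct} vs {limits_intervention.mean_rate_pct})"
        )
    return classify_rate(
        rate_pct,
        limits_acceptance.mean_rate_pct,
        acceptance_pct=limits_acceptance.tolerance_pct,
        intervention_pct=limits_intervention.tolerance_pct,
        pack_id=pack_id,
        n_seeds=limits_acceptance.n_seeds,
    )


def limits_table(
    means: Mapping[int, float], tolerance_pct: float = INTERVENTION_PCT
) -> pd.DataFrame:
    """Per-pack-size control-limit table.

    One row per pack size with the cumulative mean, the absolute tolerance
    (``tolerance_pct`` percent of the mean), the upper/lower limits and the
    per-source rate, each at full precision plus a 1-decimal display column
    (ties rounded away from zero).
    """
    rows = []
    for n in sorted(means):
        lim = build_limits(means[n], tolerance_pct, n)
        per_src = per_source_rate(lim.mean_rate_pct, n)
        row = {
            "n_seeds": n,
            "mean_rate_pct": lim.mean_rate_pct,
            "tol_abs_pct": lim.tol_abs_pct,
            "upper_pct": lim.upper_pct,
            "lower_pct": lim.lower_pct,
            "per_source_pct": per_src,
        }
        for key in list(row)[1:]:
            row[f"{key}_display"] = round_half_away(row[key], 1)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AuditReport:
    n_total: int
    counts: dict[Verdict, int]
    flags: list[Classification]  # investigate + intervene, in input order
    all_within_intervention: bool

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "counts": {v.value: self.counts[v] for v in Verdict},
            "flags": [
                {
                    "pack_id": c.pack_id,
                    "n_seeds": c.n_seeds,
                    "rate_pct": c.rate_pct,
                    "deviation_pct": c.deviation_pct,
                    "verdict": c.verdict.value,
                }
                for c in self.flags
            ],
            "all_within_intervention": self.all_within_intervention,
        }


def audit(
    results: Iterable[AssayResult],
    means: Mapping[int, float] | None = None,
    acceptance_pct: float = ACCEPTANCE_PCT,
    intervention_pct: float = INTERVENTION_PCT,
) -> AuditReport:
    """Classify every pack against its per-n limits and tally verdicts.

    ``means`` defaults to the facility's cumulative per-n means; every pack
    size present in ``results`` must have a mean.
    """
    if means is None:
        means = FACILITY_MEAN_RATES
    counts = {v: 0 for v in Verdict}
    flags: list[Classification] = []
    n_total = 0
    for res in results:
        if res.n_seeds not in means:
            raise ConfigurationError(
                f"no control mean configured for pack size n={res.n_seeds}"
            )
        cls = classify_rate(
            res.detection_rate_pct,
            means[res.n_seeds],
            acceptance_pct=acceptance_pct,
            intervention_pct=intervention_pct,
            pack_id=res.pack_id,
            n_seeds=res.n_seeds,
        )
        counts[cls.verdict] += 1
        n_total += 1
        if cls.verdict is not Verdict.WITHIN_ACCEPTANCE:
            flags.append(cls)
    return AuditReport(
        n_total=n_total,
        counts=counts,
        flags=flags,
        all_within_intervention=counts[Verdict.INTERVENE] == 0,
    )
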