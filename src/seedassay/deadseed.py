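"""Detectability of dead seeds (and other per-seed activity faults).

A dead seed removes one seed's expected contribution to the batch reading,
i.e. ``mean_rate / n`` percentage points per dead seed.  The fault is
reliably detectable when that expected reduction exceeds the intervention
tolerance (5% of the per-n mean); it is *borderline* when the two are equal
— the canonical case being one dead seed in a 20-pack, where the loss of
67.0/20 = 3.35 points exactly matches 5% of the 67.0% mean.

The Monte-Carlo escape probability quantifies how often a faulty pack
nevertheless reads inside the intervention band once per-seed activity
spread (seeds near +6% can cancel a dead seed's deficit), reading noise and
stainless-steel shielding are in play.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .qc import INTERVENTION_PCT
from .simulate import SimulationConfig, simulate_rates

__all__ = [
    "PowerResult",
    "expected_reduction",
    "detectability",
    "escape_probability",
    "power_analysis",
]

#: Tolerance for calling an expected reduction equal to the intervention
#: threshold (percentage points).
BORDERLINE_ATOL = 1e-9


@dataclass(frozen=True)
class PowerResult:
    """Deterministic margin, and optionally Monte-Carlo escape rate, for a
    dead-seed scenario."""

    n_seeds: int
    n_dead: int
    mean_rate_pct: float
    expected_reduction_pct_points: float
    intervention_tol_pct_points: float
    detectable: str  # "yes" | "borderline" | "no"
    escape_probability: float | None = None
    escape_stderr: float | None = None
    n_reps: int | None = None

    def to_dict(self) -> dict:
        d = {
            "n_seeds": self.n_seeds,
            "n_dead": self.n_dead,
            "mean_rate_pct": self.mean_rate_pct,
            "expected_reduction_pct_points": self.expected_reduction_pct_points,
            "intervention_tol_pct_points": self.intervention_tol_pct_points,
            "detectable": self.detectable,
        }
        if self.escape_probability is not None:
            d.update(
                escape_probability=self.escape_probability,
                escape_stderr=self.escape_stderr,
                n_reps=self.n_reps,
            )
        return d


def expected_reduction(mean_rate_pct: float, n_seeds: int, n_dead: int) -> float:
    """Expected detection-rate reduction (percentage points) from
    ``n_dead`` dead seeds in a pack of ``n_seeds``."""
    if n_seeds < 1:
        raise InvalidParameterError(f"n_seeds must be >= 1, got {n_seeds}")
    if not 0 <= n_dead <= n_seeds:
        raise InvalidParameterError(
            f"n_dead must be in [0, {n_seeds}], got {n_dead}"
        )
    return n_dead * mean_rate_pct / n_seeds


def detectability(
    mean_rate_pct: float,
    n_seeds: int,
    n_dead: int,
    intervention_pct: float = INTERVENTION_PCT,
) -> PowerResult:
    """Deterministic verdict: does the expected reduction exceed the
    intervention tolerance (``intervention_pct`` percent of the mean)?"""
    reduction = expected_reduction(mean_rate_pct, n_seeds, n_dead)
    tol = mean_rate_pct * intervention_pct / 100.0
    if abs(reduction - tol) <= BORDERLINE_ATOL:
        verdict = "borderline"
    elif reduction > tol:
        verdict = "yes"
    else:
        verdict = "no"
    return PowerResult(
        n_seeds=n_seeds,
        n_dead=n_dead,
        mean_rate_pct=mean_rate_pct,
        expected_reduction_pct_points=reduction,
        intervention_tol_pct_points=tol,
        detectable=verdict,
    )


def escape_probability(
    n_seeds: int,
    n_dead: int,
    config: SimulationConfig,
    n_reps: int,
    rng_seed: int,
    force_shielded: bool = False,
    intervention_pct: float = INTERVENTION_PCT,
) -> tuple[float, float]:
    """Monte-Carlo probability that a faulty pack escapes detection.

    Simulates ``n_reps`` packs of ``n_seeds`` with ``n_dead`` dead seeds
    under ``config`` and returns the fraction whose detection rate stays
    inside the intervention band around the configured per-n mean, together
    with the binomial standard error.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(rng_seed)
    rates = simulate_rates(
        n_seeds, config, n_reps, rng, n_dead=n_dead, force_shielded=force_shielded
    )
    mean = config.mean_rate(n_seeds)
    tol = mean * intervention_pct / 100.0
    # a deviation exactly at the limit does not escalate; the epsilon keeps
    # the exactly-borderline case (e.g. one dead seed in a 20-pack with no
    # noise) on the non-flagged side despite float rounding
    escaped = np.abs(rates - mean) <= tol + BORDERLINE_ATOL
    p = float(escaped.mean())
    stderr = float(np.sqrt(p * (1.0 - p) / n_reps))
    return p, stderr


def power_analysis(
    n_seeds: int,
    n_dead: int,
    config: SimulationConfig,
    n_reps: int = 10_000,
    rng_seed: int = 0,
    force_shielded: bool = False,
    intervention_pct: float = INTERVENTION_PCT,
) -> PowerResult:
    """Deterministic verdict plus Monte-Carlo escape probability."""
    mean = config.mean_rate(n_seeds)
    det = detectability(mean, n_seeds, n_dead, intervention_pct)
    p, se = escape_probability(
        n_seeds,
        n_dead,
        config,
        n_reps,
        rng_seed,
        force_shielded=force_shielded,
        intervention_pct=intervention_pct,
    )
    return PowerResult(
        n_seeds=n_seeds,
        n_dead=n_dead,
        mean_rate_pct=mean,
        expected_reduction_pct_points=det.expected_reduction_pct_points,
        intervention_tol_pct_points=det.intervention_tol_pct_points,
        detectable=det.detectable,
        escape_probability=p,
        escape_stderr=se,
        n_reps=n_reps,
    )
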