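"""Synthetic blister-pack measurement generator.

Generates measurement logs with the statistical structure the QA analysis
assumes, calibrated so the *expected* detection rate of a fault-free pack of
n seeds equals the facility's cumulative per-n mean.  The generative model
for a pack of n seeds is

    A_i     = A_nom * (1 + eps_i)          true per-seed activity
    reading = sum_i(e_i * A_i) * (1 + eta)  chamber reading (MBq)

with per-seed activity error ``eps_i ~ Uniform(-tol, +tol)`` (the
manufacturer's stated per-seed tolerance, tol = 6% by default; a truncated
normal is available), mean-zero multiplicative reading noise
``eta ~ Normal(0, noise_rel_sd)``, and per-seed detection efficiencies
``e_i`` calibrated to the per-n mean-rate table.  Neighbour-to-neighbour
attenuation is lumped into that n-dependent efficiency; the stainless-steel
cartridge section of 20-packs is modelled explicitly as ``k = 3`` seeds
whose efficiency is reduced by a transmission factor ``s``, with the
unshielded efficiency raised so the pack average still hits the table mean:

    e_unshielded = n * mean / (n - k + k*s),   e_shielded = s * e_unshielded.

Faults (dead seeds, wrong-strength deliveries, mismatched calibration
dates) can be injected per pack; every generated pack carries its ground
truth so detectability analyses can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assay import BlisterPackRecord
from .exceptions import ConfigurationError
from .physics import I125, decay_factor
from .qc import FACILITY_MEAN_RATES
from .regression import fit_log, predict

__all__ = [
    "DELIVERY_COUNTS",
    "FaultSpec",
    "SimulationConfig",
    "SimulatedPack",
    "efficiency_profile",
    "simulate_pack",
    "simulate_rates",
    "simulate_delivery",
    "write_ground_truth",
]

#: The facility's delivery history by pack size (433 packs total).
DELIVERY_COUNTS: dict[int, int] = {1: 20, 2: 15, 3: 18, 4: 30, 5: 197, 20: 153}

FAULT_KINDS = ("dead_seed", "wrong_strength", "date_offset_days")


@dataclass(frozen=True)
class FaultSpec:
    """A fault injected into one pack of a simulated delivery.

    ``pack_index`` is the 0-based position in generation order.  ``value``
    means: number of dead seeds for ``dead_seed`` (default 1); the true
    per-seed strength in MBq for ``wrong_strength`` (e.g. 13.1 or 15.3
    delivered against an 11.0 order); the calibration-date mismatch in days
    for ``date_offset_days`` (positive = true reference earlier than the
    recorded one, so the pack arrives more decayed than the log implies).
    """

    pack_index: int
    kind: str
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in FAULT_KINDS:
            raise ConfigurationError(
                f"unknown fault kind {self.kind!r}; expected one of {FAULT_KINDS}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Defaults reproduce the facility's conditions: 11.0 MBq nominal seeds
    within the +/-6% manufacturer tolerance, per-n mean detection rates from
    the cumulative table, three stainless-shielded seeds per 20-pack, and 1%
    multiplicative reading noise.
    """

    nominal_mbq_per_seed: float = 11.0
    activity_tolerance_frac: float = 0.06
    activity_error_dist: str = "uniform"  # or "truncated_normal"
    mean_rate_table: Mapping[int, float] = field(
        default_factory=lambda: dict(FACILITY_MEAN_RATES)
    )
    shielded_count: Mapping[int, int] = field(default_factory=lambda: {20: 3})
    stainless_transmission: float = 0.1
    noise_rel_sd: float = 0.01
    rng_seed: int = 0
    faults: tuple[FaultSpec, ...] = ()
    reference_date: date = date(2023, 1, 1)

    def __post_init__(self) -> None:
        if not 0 <= self.activity_tolerance_frac < 1:
            raise ConfigurationError(
                f"activity_tolerance_frac must be in [0, 1), got {self.activity_tolerance_frac}"
            )
        if not 0 < self.stainless_transmission <= 1:
            raise ConfigurationError(
                f"stainless_transmission must be in (0, 1], got {self.stainless_transmission}"
            )
        if self.noise_rel_sd < 0:
            raise ConfigurationError("noise_rel_sd must be nonnegative")
        if self.activity_error_dist not in ("uniform", "truncated_normal"):
            raise ConfigurationError(
                f"unknown activity_error_dist {self.activity_error_dist!r}"
            )
        for n, k in self.shielded_count.items():
            if k < 0 or k > n:
                raise ConfigurationError(
                    f"shielded_count[{n}] = {k} must lie in [0, {n}]"
                )

    def mean_rate(self, n_seeds: int) -> float:
        """Expected detection rate (%) for a pack of ``n_seeds``.

        Pack sizes absent from the table are interpolated with a log-linear
        fit to the table (the large-pack calibration family).
        """
        if n_seeds in self.mean_rate_table:
            return self.mean_rate_table[n_seeds]
        model = fit_log(sorted(self.mean_rate_table.items()))
        return float(predict(model, n_seeds))

    def to_dict(self) -> dict:
        return {
            "nominal_mbq_per_seed": self.nominal_mbq_per_seed,
            "activity_tolerance_frac": self.activity_tolerance_frac,
            "activity_error_dist": self.activity_error_dist,
            "mean_rate_table": {str(k): v for k, v in self.mean_rate_table.items()},
            "shielded_count": {str(k): v for k, v in self.shielded_count.items()},
            "stainless_transmission": self.stainless_transmission,
            "noise_rel_sd": self.noise_rel_sd,
            "rng_seed": self.rng_seed,
            "faults": [
                {"pack_index": f.pack_index, "kind": f.kind, "value": f.value}
                for f in self.faults
            ],
            "reference_date": self.reference_date.isoformat(),
            "rng_algorithm": "numpy.random.PCG64",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d.pop("rng_algorithm", None)
        if "mean_rate_table" in d:
            d["mean_rate_table"] = {int(k): float(v) for k, v in d["mean_rate_table"].items()}
        if "shielded_count" in d:
            d["shielded_count"] = {int(k): int(v) for k, v in d["shielded_count"].items()}
        if "faults" in d:
            d["faults"] = tuple(FaultSpec(**f) for f in d["faults"])
        if "reference_date" in d:
            d["reference_date"] = date.fromisoformat(d["reference_date"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulatedPack:
    """A generated pack: the log record plus its latent ground truth."""

    record: BlisterPackRecord
    true_mbq: np.ndarray  # per-seed true activity at the true reference date
    efficiency: np.ndarray  # per-seed detection efficiency
    dead_indices: tuple[int, ...]
    fault: str | None = None


def efficiency_profile(n_seeds: int, config: SimulationConfig) -> np.ndarray:
    """Per-seed detection efficiencies for a pack of ``n_seeds``.

    The first ``shielded_count[n]`` positions are the stainless-shielded
    ones.  By construction the profile averages exactly to
    ``mean_rate(n)/100``, so the generator stays calibrated to the per-n
    table for any transmission and shield count.
    """
    mean_eff = config.mean_rate(n_seeds) / 100.0
    k = config.shielded_count.get(n_seeds, 0)
    s = config.stainless_transmission
    if k == 0 or s == 1.0:
        return np.full(n_seeds, mean_eff)
    e_unshielded = n_seeds * mean_eff / (n_seeds - k + k * s)
    eff = np.full(n_seeds, e_unshielded)
    eff[:k] = s * e_unshielded
    return eff


def _draw_activity_errors(rng: np.random.Generator, shape, config: SimulationConfig):
    tol = config.activity_tolerance_frac
    if tol == 0:
        return np.zeros(shape)
    if config.activity_error_dist == "uniform":
        return rng.uniform(-tol, tol, shape)
    # truncated normal: sd = tol/2, resampled beyond the tolerance bound
    eps = rng.normal(0.0, tol / 2.0, shape)
    while True:
        bad = np.abs(eps) > tol
        if not bad.any():
            return eps
        eps[bad] = rng.normal(0.0, tol / 2.0, int(bad.sum()))


def simulate_pack(
    n_seeds: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    pack_id: str = "P0000",
    fault: FaultSpec | None = None,
) -> SimulatedPack:
    """Generate one pack (record + ground truth) under ``config``."""
    eff = efficiency_profile(n_seeds, config)
    eps = _draw_activity_errors(rng, n_seeds, config)
    true_mbq = config.nominal_mbq_per_seed * (1.0 + eps)
    dead: tuple[int, ...] = ()
    fault_label = None
    decay_scale = 1.0
    if fault is not None:
        fault_label = fault.kind
        if fault.kind == "wrong_strength":
            true_mbq = fault.value * (1.0 + eps)
            fault_label = f"wrong_strength:{fault.value}"
        elif fault.kind == "dead_seed":
            n_dead = int(fault.value)
            dead = tuple(rng.choice(n_seeds, size=n_dead, replace=False).tolist())
            true_mbq = true_mbq.copy()
            true_mbq[list(dead)] = 0.0
            fault_label = f"dead_seed:{n_dead}"
        elif fault.kind == "date_offset_days":
            # true calibration date earlier than recorded: extra decay
            decay_scale = decay_factor(fault.value, I125.half_life_days)
            fault_label = f"date_offset_days:{fault.value:g}"
    eta = rng.normal(0.0, config.noise_rel_sd) if config.noise_rel_sd > 0 else 0.0
    reading = float((eff * true_mbq).sum() * (1.0 + eta) * decay_scale)
    record = BlisterPackRecord(
        pack_id=pack_id,
        n_seeds=n_seeds,
        nominal_mbq_per_seed=config.nominal_mbq_per_seed,
        measured_mbq=max(reading, 0.0),
        measurement_date=config.reference_date,
        reference_date=config.reference_date,
    )
    return SimulatedPack(
        record=record,
        true_mbq=true_mbq,
        efficiency=eff,
        dead_indices=dead,
        fault=fault_label,
    )


def simulate_rates(
    n_seeds: int,
    config: SimulationConfig,
    n_packs: int,
    rng: np.random.Generator,
    n_dead: int = 0,
    force_shielded: bool = False,
) -> np.ndarray:
    """Detection rates (%) of ``n_packs`` simulated packs, vectorised.

    Fast path for Monte-Carlo studies: no record objects are built.
    ``n_dead`` seeds per pack are killed, at positions drawn uniformly
    without replacement, or restricted to the stainless-shielded positions
    when ``force_shielded`` (the worst case for detectability).
    """
    eff = efficiency_profile(n_seeds, config)
    eps = _draw_activity_errors(rng, (n_packs, n_seeds), config)
    activity = config.nominal_mbq_per_seed * (1.0 + eps)
    if n_dead > 0:
        if n_dead > n_seeds:
            raise ConfigurationError(f"n_dead={n_dead} exceeds n_seeds={n_seeds}")
        k = config.shielded_count.get(n_seeds, 0)
        if force_shielded:
            if n_dead > k:
                raise ConfigurationError(
                    f"cannot force {n_dead} dead seeds into {k} shielded positions"
                )
            n_positions = k
        else:
            n_positions = n_seeds
        # first n_dead of a random permutation of the eligible positions
        order = np.argsort(rng.random((n_packs, n_positions)), axis=1)[:, :n_dead]
        rows = np.repeat(np.arange(n_packs), n_dead)
        activity[rows, order.ravel()] = 0.0
    reading = activity @ eff
    if config.noise_rel_sd > 0:
        reading = reading * (1.0 + rng.normal(0.0, config.noise_rel_sd, n_packs))
    return 100.0 * np.maximum(reading, 0.0) / (config.nominal_mbq_per_seed * n_seeds)


def simulate_delivery(
    config: SimulationConfig,
    counts: Mapping[int, int] | None = None,
) -> list[SimulatedPack]:
    """Generate a full delivery history (default: the facility's 433 packs).

    Packs are generated in ascending pack-size order with sequential ids;
    the output is a pure function of ``config`` (including its seed), so a
    rerun reproduces the dataset byte-for-byte.
    """
    if counts is None:
        counts = DELIVERY_COUNTS
    rng = np.random.default_rng(config.rng_seed)
    faults_by_index = {f.pack_index: f for f in config.faults}
    packs: list[SimulatedPack] = []
    idx = 0
    for n in sorted(counts):
        if counts[n] < 0:
            raise ConfigurationError(f"counts[{n}] must be nonnegative")
        for _ in range(counts[n]):
            packs.append(
                simulate_pack(
                    n,
                    config,
                    rng,
                    pack_id=f"P{idx:04d}",
                    fault=faults_by_index.get(idx),
                )
            )
            idx += 1
    return packs


def write_ground_truth(path: str | Path, packs: Sequence[SimulatedPack]) -> None:
    """Per-seed ground-truth sidecar CSV for a simulated delivery."""
    import csv

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pack_id", "seed_index", "true_mbq", "efficiency", "is_dead", "fault"]
        )
        for pack in packs:
            for i in range(pack.record.n_seeds):
                writer.writerow(
                    [
                        pack.record.pack_id,
                        i,
                        repr(float(pack.true_mbq[i])),
                        repr(float(pack.efficiency[i])),
                        int(i in pack.dead_indices),
                        pack.fault or "",
                    ]
                )
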