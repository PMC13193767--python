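"""Least-squares calibration of detection rate versus packed-source count.

Two model families are used, mirroring how the expected batch-assay rate
behaves as packs grow:

* a cubic polynomial ``y = a*x**3 + b*x**2 + c*x + d`` for the small-pack
  regime (1-5 seeds), where mutual shielding between neighbouring seeds
  grows smoothly with the count, and
* a log-linear model ``y = a*ln(x) + b`` once 20-seed packs are included,
  whose stainless-steel cartridge section shields roughly three seeds and
  pulls the curve off the small-pack polynomial.

Fits are ordinary least squares on the per-n *mean* rates, unweighted; a
count-weighted variant is available via the ``weights`` argument.  The
normal equations are solved by SVD (``numpy.linalg.lstsq``), which doubles
as the orthogonal-basis fallback for conditioning; with x <= 20 the design
is benign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "CalibrationPoint",
    "RegressionModel",
    "SelectionResult",
    "r_squared",
    "fit_cubic",
    "fit_log",
    "fit_polynomial",
    "predict",
    "select_model",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One (pack size, mean detection rate) pair."""

    n_seeds: float
    mean_rate_pct: float


Points = Iterable["CalibrationPoint | tuple[float, float]"]


def _as_xy(points: Points) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in points:
        if isinstance(p, CalibrationPoint):
            xs.append(p.n_seeds)
            ys.append(p.mean_rate_pct)
        else:
            x, y = p
            xs.append(x)
            ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


@dataclass(frozen=True)
class RegressionModel:
    """A fitted calibration curve.

    ``coefficients`` are ordered (a, b, c, d) for the cubic
    ``a*x**3 + b*x**2 + c*x + d`` and (a, b) for ``a*ln(x) + b``.
    """

    kind: Literal["cubic_poly", "log_linear"]
    coefficients: tuple[float, ...]
    r_squared: float
    fit_domain: tuple[int, int]

    def __post_init__(self) -> None:
        expected = {"cubic_poly": 4, "log_linear": 2}[self.kind]
        if len(self.coefficients) != expected:
            raise InvalidParameterError(
                f"{self.kind} model needs {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def __call__(self, x):
        return predict(self, x)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": list(self.coefficients),
            "r_squared": self.r_squared,
            "fit_domain": list(self.fit_domain),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            kind=d["kind"],
            coefficients=tuple(d["coefficients"]),
            r_squared=d["r_squared"],
            fit_domain=tuple(d["fit_domain"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def r_squared(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SSE/SST`` (SST about the mean).

    Undefined for a constant response (SST = 0); raised as an error rather
    than silently returning NaN.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 2:
        raise InsufficientDataError("r_squared needs at least 2 points")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise InvalidParameterError("r_squared undefined for a constant response")
    sse = float(((y - y_hat) ** 2).sum())
    return 1.0 - sse / sst


def _fit_r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """R² for a fitted model; NaN when undefined (constant response)."""
    try:
        return min(r_squared(y, y_hat), 1.0)
    except InvalidParameterError:
        return float("nan")


def _lstsq_fit(design: np.ndarray, y: np.ndarray, weights: np.ndarray | None):
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        design = design * w[:, None]
        y = y * w
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def fit_polynomial(
    points: Points, degree: int, weights: Sequence[float] | None = None
) -> RegressionModel:
    """OLS polynomial of the given degree; returned coefficients are
    highest-order first.  Exposed mainly so nested-model diagnostics can
    compare degrees; :func:`fit_cubic` is the calibration entry point."""
    x, y = _as_xy(points)
    if np.unique(x).size < degree + 1:
        raise InsufficientDataError(
            f"degree-{degree} fit needs >= {degree + 1} distinct x values, "
            f"got {np.unique(x).size}"
        )
    design = np.vander(x, degree + 1)  # columns x^degree .. 1
    coef = _lstsq_fit(design, y, None if weights is None else np.asarray(weights))
    r2 = _fit_r2(y, design @ coef)
    model_kind = "cubic_poly" if degree == 3 else None
    if model_kind is None:
        # generic degrees reuse the cubic container only when they fit it
        raise InvalidParameterError("fit_polynomial returns models only for degree 3; "
                                    "use _poly_r2 for diagnostics")
    return RegressionModel(
        kind="cubic_poly",
        coefficients=tuple(float(c) for c in coef),
        r_squared=r2,
        fit_domain=(int(np.floor(x.min())), int(np.ceil(x.max()))),
    )


def poly_r2(points: Points, degree: int) -> float:
    """R-squared of an OLS polynomial of ``degree`` on ``points``.

    Diagnostic helper for nested-model comparisons (R² is non-decreasing in
    the degree for nested polynomial families).
    """
    x, y = _as_xy(points)
    if np.unique(x).size < degree + 1:
        raise InsufficientDataError(
            f"degree-{degree} fit needs >= {degree + 1} distinct x values"
        )
    design = np.vander(x, degree + 1)
    coef = _lstsq_fit(design, y, None)
    return r_squared(y, design @ coef)


def fit_cubic(points: Points, weights: Sequence[float] | None = None) -> RegressionModel:
    """OLS cubic ``y = a*x**3 + b*x**2 + c*x + d``.

    Requires at least four distinct x values; with exactly four the fit
    interpolates and R² = 1.
    """
    return fit_polynomial(points, 3, weights=weights)


def fit_log(points: Points, weights: Sequence[float] | None = None) -> RegressionModel:
    """Simple linear regression of the rate on ``ln(pack size)``."""
    x, y = _as_xy(points)
    if np.any(x < 1):
        raise InvalidParameterError("log-linear model requires all x >= 1")
    if np.unique(x).size < 2:
        raise InsufficientDataError("log fit needs >= 2 distinct x values")
    design = np.column_stack([np.log(x), np.ones_like(x)])
    coef = _lstsq_fit(design, y, None if weights is None else np.asarray(weights))
    r2 = _fit_r2(y, design @ coef)
    return RegressionModel(
        kind="log_linear",
        coefficients=(float(coef[0]), float(coef[1])),
        r_squared=r2,
        fit_domain=(int(np.floor(x.min())), int(np.ceil(x.max()))),
    )


def predict(model: RegressionModel, n_seeds):
    """Evaluate ``model`` at pack size ``n_seeds`` (scalar or array).

    Extrapolation outside the fitted domain is allowed but warned about;
    the log model is undefined below x = 1.
    """
    x = np.asarray(n_seeds, dtype=float)
    lo, hi = model.fit_domain
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn(
            f"predicting outside the fitted pack-size range [{lo}, {hi}]",
            stacklevel=2,
        )
    if model.kind == "cubic_poly":
        out = np.polyval(model.coefficients, x)
    else:
        if np.any(x < 1):
            raise InvalidParameterError("log-linear model is undefined for x < 1")
        a, b = model.coefficients
        out = a * np.log(x) + b
    return float(out) if np.isscalar(n_seeds) or out.ndim == 0 else out


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of automatic model choice, keeping both candidates' R²."""

    model: RegressionModel
    r2_by_kind: dict[str, float]


def select_model(points: Points) -> SelectionResult:
    """Choose the model family from the span of pack sizes.

    Cubic when every pack size is <= 5 and at least four distinct sizes are
    available (the small-pack regime); otherwise log-linear, which absorbs
    the stainless-shielded 20-pack regime.  Both R² values are recorded
    whenever both families are fittable.
    """
    x, y = _as_xy(points)
    pts = list(zip(x, y))
    r2s: dict[str, float] = {}
    cubic = None
    if np.unique(x).size >= 4:
        cubic = fit_cubic(pts)
        r2s["cubic_poly"] = cubic.r_squared
    log_model = None
    if np.all(x >= 1) and np.unique(x).size >= 2:
        log_model = fit_log(pts)
        r2s["log_linear"] = log_model.r_squared
    if cubic is not None and x.max() <= 5:
        return SelectionResult(model=cubic, r2_by_kind=r2s)
    if log_model is None:
        raise InsufficientDataError("no model family is fittable on these points")
    return SelectionResult(model=log_model, r2_by_kind=r2s)


def fit_means_table(means: dict[int, float], kind: str | None = None) -> RegressionModel:
    """Fit a calibration model to a per-n mean-rate table.

    ``kind`` forces 'cubic_poly' or 'log_linear'; ``None`` selects
    automatically from the pack-size span.
    """
    pts = sorted(means.items())
    if kind == "cubic_poly":
        return fit_cubic(pts)
    if kind == "log_linear":
        return fit_log(pts)
    if kind is None:
        return select_model(pts).model
    raise InvalidParameterError(f"unknown model kind {kind!r}")
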