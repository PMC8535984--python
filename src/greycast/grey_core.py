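"""Grey forecasting models: classical GM(1,1) and the Gaussian grey GGM(1,1).

Both models work on the accumulated (cumulative-sum) series x(1) of a
positive annual sequence x(0). A first-order grey difference equation

    x(0)(k) + a * z(1)(k) = rhs(k)

pairs each raw increment with a *background value* z(1)(k) built from
adjacent cumulative levels; least squares over k = 2..n estimates the
development coefficient ``a`` and the grey action quantity ``b``. The
whitened (continuous-time) solution of the matching differential equation
then yields a closed-form cumulative predictor, and first differences
restore fitted/forecast values on the original scale.

The two variants differ only in how time enters:

* **GM(1,1)** (classical): ``z(1)(k) = (x(1)(k) + x(1)(k-1)) / 2`` and a
  constant right-hand side ``b``; the cumulative predictor is the plain
  exponential ``(x(0)(1) - b/a) * exp(-a (k-1)) + b/a``.
* **GGM(1,1)** (Gaussian): the background value and the right-hand side are
  weighted by a linear-in-time Gaussian factor ``(k - mu) / sigma**2``, and
  the cumulative predictor becomes a Gaussian exponential
  ``(x(0)(1) - b/a) * exp(-a ((k-mu)^2 - (1-mu)^2) / (2 sigma^2)) + b/a``,
  whose increments rise and then fall — the shape of accident-count series
  that peak and decline.

Predictions are anchored so that the fitted cumulative value at k = 1
equals the first observation (``anchored=True``, the default); a
compatibility switch exposes the unanchored variant in which the two
exponential factors are both negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .exceptions import (
    DegenerateModelError,
    InadmissibleSeriesError,
    InternalConsistencyError,
    InvalidSeriesError,
    InvalidSpecError,
    OrderRatioWarning,
    SingularSystemError,
    ZeroDenominatorError,
)
from .series import RawSeries

__all__ = [
    "GaussianSpec",
    "OrderRatioReport",
    "DesignSystem",
    "ErrorReport",
    "GreyFit",
    "Forecast",
    "ShiftTransform",
    "LogTransform",
    "order_ratio_check",
    "accumulate",
    "background_values",
    "assemble_system",
    "estimate_parameters",
    "predict_cumulative",
    "restore_increments",
    "error_report",
    "fit_grey_model",
    "forecast",
]

Mode = Literal["gm", "ggm"]
Denominator = Literal["observed", "fitted"]


@dataclass(frozen=True)
class GaussianSpec:
    """Location ``mu`` and width ``sigma`` of the Gaussian time weighting.

    The standard model fixes ``mu = 0`` and ``sigma = 1``.
    """

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidSpecError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class OrderRatioReport:
    """Admissibility screen on the order ratios lambda(k) = x(k-1)/x(k).

    A series is *admissible* for grey modelling when every ratio falls in
    the open interval (exp(-2/(n+1)), exp(2/(n+1))). The check is advisory:
    inadmissible data can still be fitted (optionally after a transform).
    """

    ratios: np.ndarray  # lambda(k), k = 2..n
    lower_bound: float
    upper_bound: float
    violating_indices: tuple[int, ...]  # k positions, 2-based
    violating_years: tuple[int, ...]

    @property
    def admissible(self) -> bool:
        return len(self.violating_indices) == 0


class DesignSystem(NamedTuple):
    """Least-squares system: Y stacks x(0)(2..n), B the regressor rows."""

    B: np.ndarray
    Y: np.ndarray


@dataclass(frozen=True)
class ErrorReport:
    """Per-year signed relative errors plus summary statistics.

    ``signed[k] = (fitted - observed) / denominator`` where the denominator
    is the observed value (textbook convention) or the fitted value (the
    convention that matches published fit tables for this model family).
    ``delta`` is the mean of the absolute relative errors.
    """

    signed: np.ndarray
    delta: float
    max_abs: float
    denominator: Denominator


@dataclass(frozen=True)
class GreyFit:
    """Result of fitting a grey model to a :class:`RawSeries`."""

    series: RawSeries
    mode: Mode
    a: float
    b: float
    gaussian: GaussianSpec | None
    anchored: bool
    fitted_cumulative: np.ndarray
    fitted_values: np.ndarray
    errors: ErrorReport
    order_ratio: OrderRatioReport
    transform: "ShiftTransform | LogTransform | None" = None

    @property
    def mean_relative_error(self) -> float:
        return self.errors.delta

    @property
    def max_abs_relative_error(self) -> float:
        return self.errors.max_abs


@dataclass(frozen=True)
class Forecast:
    """Out-of-sample values paired with their calendar years."""

    years: np.ndarray
    values: np.ndarray


class ShiftTransform:
    """Add a constant before fitting; subtract it from predictions."""

    def __init__(self, offset: float):
        self.offset = float(offset)

    def forward(self, values: np.ndarray) -> np.ndarray:
        return values + self.offset

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values - self.offset

    def __repr__(self) -> str:
        return f"ShiftTransform({self.offset!r})"


class LogTransform:
    """Fit on log values; exponentiate predictions."""

    def forward(self, values: np.ndarray) -> np.ndarray:
        return np.log(values)

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.exp(values)

    def __repr__(self) -> str:
        return "LogTransform()"


def order_ratio_check(series: RawSeries, strict: bool = False) -> OrderRatioReport:
    """Screen a series for grey-model admissibility.

    Computes lambda(k) = x(0)(k-1) / x(0)(k) for k = 2..n and flags every
    ratio outside (exp(-2/(n+1)), exp(2/(n+1))). With ``strict=True`` an
    inadmissible series raises; otherwise a warning is emitted and the
    report is returned either way.
    """
    x = series.values
    n = series.n
    ratios = x[:-1] / x[1:]
    lower = math.exp(-2.0 / (n + 1))
    upper = math.exp(2.0 / (n + 1))
    outside = (ratios <= lower) | (ratios >= upper)
    ks = tuple(int(k) for k in (np.nonzero(outside)[0] + 2))
    years = tuple(int(series.years[k - 1]) for k in ks)
    report = OrderRatioReport(
        ratios=ratios,
        lower_bound=lower,
        upper_bound=upper,
        violating_indices=ks,
        violating_years=years,
    )
    if not report.admissible:
        message = (
            f"order-ratio admissibility violated at years {years}: "
            f"ratios outside ({lower:.4f}, {upper:.4f}); consider a shift or "
            "log transform"
        )
        if strict:
            raise InadmissibleSeriesError(message)
        warnings.warn(message, OrderRatioWarning, stacklevel=2)
    return report


def accumulate(values: Sequence[float] | np.ndarray | RawSeries) -> np.ndarray:
    """Accumulated generating operation: x(1)(k) = sum of x(0)(1..k)."""
    if isinstance(values, RawSeries):
        values = values.values
    return np.cumsum(np.asarray(values, dtype=np.float64))


def background_values(
    cumulative: np.ndarray, spec: GaussianSpec | None = None
) -> np.ndarray:
    """Background values z(1)(k) for k = 2..n.

    Classical mode (``spec is None``) takes the arithmetic mean of adjacent
    cumulative levels. Gaussian mode weights each level by its Gaussian
    time factor::

        z(1)(k) = ((k - mu)/sigma^2 * x(1)(k) + (k-1-mu)/sigma^2 * x(1)(k-1)) / 2
    """
    x1 = np.asarray(cumulative, dtype=np.float64)
    if len(x1) < 2:
        raise InvalidSeriesError("need at least two cumulative values")
    if spec is None:
        return 0.5 * (x1[1:] + x1[:-1])
    k = np.arange(2, len(x1) + 1, dtype=np.float64)
    s2 = spec.sigma**2
    return 0.5 * ((k - spec.mu) / s2 * x1[1:] + (k - 1 - spec.mu) / s2 * x1[:-1])


def assemble_system(
    values: np.ndarray | RawSeries,
    background: np.ndarray,
    spec: GaussianSpec | None = None,
) -> DesignSystem:
    """Stack the grey difference equations for k = 2..n as ``Y = B @ (a, b)``.

    Row k of B is ``[-z(1)(k), 1]`` in classical mode and
    ``[-z(1)(k), (k - 1/2 - mu)/sigma^2]`` in Gaussian mode.
    """
    if isinstance(values, RawSeries):
        values = values.values
    x0 = np.asarray(values, dtype=np.float64)
    z = np.asarray(background, dtype=np.float64)
    if len(z) != len(x0) - 1:
        raise InternalConsistencyError(
            f"background has {len(z)} entries for a series of length {len(x0)}"
        )
    if spec is None:
        rhs_col = np.ones_like(z)
    else:
        k = np.arange(2, len(x0) + 1, dtype=np.float64)
        rhs_col = (k - 0.5 - spec.mu) / spec.sigma**2
    return DesignSystem(B=np.column_stack([-z, rhs_col]), Y=x0[1:].copy())


def estimate_parameters(system: DesignSystem) -> tuple[float, float]:
    """Least-squares estimate (a, b) = (B'B)^{-1} B'Y."""
    B, Y = system
    if np.linalg.matrix_rank(B) < 2:
        raise SingularSystemError(
            "design matrix is rank deficient (background values collinear "
            "with the right-hand-side column)"
        )
    params, *_ = np.linalg.lstsq(B, Y, rcond=None)
    return float(params[0]), float(params[1])


def predict_cumulative(
    first_value: float,
    a: float,
    b: float,
    spec: GaussianSpec | None = None,
    k_max: int = 1,
    anchored: bool = True,
) -> np.ndarray:
    """Closed-form cumulative predictor x-hat(1)(k), k = 1..k_max.

    Classical mode: ``(first - b/a) * exp(-a (k-1)) + b/a``, which always
    satisfies x-hat(1)(1) = first. Gaussian mode multiplies the decay factor
    ``exp(-a (k-mu)^2 / (2 sigma^2))`` by ``exp(+a (1-mu)^2 / (2 sigma^2))``
    when ``anchored`` (so k = 1 again reproduces the first observation) or
    by ``exp(-a (1-mu)^2 / (2 sigma^2))`` in the unanchored compatibility
    variant.
    """
    if k_max < 1:
        raise InvalidSpecError(f"k_max must be >= 1, got {k_max}")
    if a == 0:
        raise DegenerateModelError("development coefficient a is zero; b/a undefined")
    k = np.arange(1, k_max + 1, dtype=np.float64)
    level = b / a
    if spec is None:
        return (first_value - level) * np.exp(-a * (k - 1)) + level
    s2 = 2.0 * spec.sigma**2
    first_factor = math.exp((a if anchored else -a) * (1 - spec.mu) ** 2 / s2)
    decay = np.exp(-a * (k - spec.mu) ** 2 / s2)
    return (first_value - level) * first_factor * decay + level


def restore_increments(cumulative: np.ndarray) -> np.ndarray:
    """Inverse of :func:`accumulate`: first value kept, then differences."""
    x1 = np.asarray(cumulative, dtype=np.float64)
    if len(x1) == 0:
        raise InvalidSeriesError("empty cumulative sequence")
    out = np.empty_like(x1)
    out[0] = x1[0]
    out[1:] = np.diff(x1)
    return out


def error_report(
    observed: np.ndarray | RawSeries,
    fitted: np.ndarray,
    denominator: Denominator = "observed",
    years: np.ndarray | None = None,
) -> ErrorReport:
    """Relative-error diagnostics between observed and fitted values.

    ``denominator="observed"`` gives the textbook convention
    (fitted - observed)/observed; ``"fitted"`` divides by the fitted value
    instead, which is how published fit tables for this model family report
    their error columns.
    """
    if isinstance(observed, RawSeries):
        years = observed.years if years is None else years
        observed = observed.values
    obs = np.asarray(observed, dtype=np.float64)
    fit = np.asarray(fitted, dtype=np.float64)
    if obs.shape != fit.shape:
        raise InternalConsistencyError(
            f"observed ({obs.shape}) and fitted ({fit.shape}) differ in shape"
        )
    denom = obs if denominator == "observed" else fit
    zero = denom == 0
    if np.any(zero):
        where = int(np.argmax(zero))
        label = int(years[where]) if years is not None else where
        raise ZeroDenominatorError(
            f"zero {denominator} denominator at position/year {label}"
        )
    signed = (fit - obs) / denom
    abs_err = np.abs(signed)
    return ErrorReport(
        signed=signed,
        delta=float(abs_err.mean()),
        max_abs=float(abs_err.max()),
        denominator=denominator,
    )


def fit_grey_model(
    series: RawSeries,
    mode: Mode = "gm",
    spec: GaussianSpec | None = None,
    error_denominator: Denominator = "observed",
    anchored: bool = True,
    transform: ShiftTransform | LogTransform | None = None,
    strict_order_ratio: bool = False,
) -> GreyFit:
    """Fit a grey model end to end.

    Runs the admissibility screen (advisory unless ``strict_order_ratio``),
    accumulates the series, builds background values and the least-squares
    system, estimates (a, b), evaluates the closed-form cumulative
    predictor over the observation window, restores increments, and
    computes error diagnostics on the original scale. ``transform``
    optionally shifts or logs the data before modelling, with the inverse
    applied to all predictions. Deterministic: identical inputs give
    bit-identical fits.

    Parameters
    ----------
    mode
        ``"gm"`` for the classical model, ``"ggm"`` for the Gaussian grey
        model (``spec`` defaults to the standard ``mu=0, sigma=1``).
    """
    if mode not in ("gm", "ggm"):
        raise InvalidSpecError(f"unknown mode {mode!r}")
    gaussian = None
    if mode == "ggm":
        gaussian = spec if spec is not None else GaussianSpec()
    report = order_ratio_check(series, strict=strict_order_ratio)

    work = series.values if transform is None else transform.forward(series.values)
    if transform is not None and not np.all(work > 0):
        raise InvalidSpecError(
            "transform produced non-positive working values; grey models "
            "need a positive series (increase the shift offset)"
        )
    x1 = accumulate(work)
    z = background_values(x1, gaussian)
    system = assemble_system(work, z, gaussian)
    a, b = estimate_parameters(system)
    cum = predict_cumulative(
        work[0], a, b, spec=gaussian, k_max=series.n, anchored=anchored
    )
    fitted_work = restore_increments(cum)
    fitted = fitted_work if transform is None else transform.inverse(fitted_work)
    errors = error_report(
        series.values, fitted, denominator=error_denominator, years=series.years
    )
    return GreyFit(
        series=series,
        mode=mode,
        a=a,
        b=b,
        gaussian=gaussian,
        anchored=anchored,
        fitted_cumulative=cum,
        fitted_values=fitted,
        errors=errors,
        order_ratio=report,
        transform=transform,
    )


def forecast(fit: GreyFit, horizon: int) -> Forecast:
    """Extend a fitted model ``horizon`` years past the observation window."""
    if horizon < 1:
        raise InvalidSpecError(f"horizon must be >= 1, got {horizon}")
    n = fit.series.n
    if fit.transform is None:
        work_first = float(fit.series.values[0])
    else:
        work_first = float(fit.transform.forward(fit.series.values[:1])[0])
    cum = predict_cumulative(
        work_first,
        fit.a,
        fit.b,
        spec=fit.gaussian,
        k_max=n + horizon,
        anchored=fit.anchored,
    )
    increments = restore_increments(cum)[n:]
    values = increments if fit.transform is None else fit.transform.inverse(increments)
    years = fit.series.years[-1] + 1 + np.arange(horizon)
    return Forecast(years=years, values=values)
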