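"""Nonlinear least-squares estimation of the survival-model parameters.

Two fitting problems arise when calibrating the dose-response model from
viability assays:

1. per-protocol sigmoid fits — estimate (E_c, A) of the Fermi sigmoid from
   replicate viability measurements over a grid of field strengths at one
   fixed (pulse count, pulse length);
2. parameter-function fits — estimate the four coefficients of the
   double-exponential E_c(x) or A(x) from the per-protocol estimates.

Both use bounded trust-region least squares (scipy.optimize.least_squares).
The double-exponential fit separates linearly in its amplitudes, so it is
solved by variable projection: the two rates are optimized over a
deterministic multi-start grid and the amplitudes follow from linear least
squares at each step.  Fits are performed on replicate-mean viability by
default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InsufficientDataError,
    IllPosedFitWarning,
    UnidentifiableFitError,
)
from .model_core import DoubleExponential, PelegFermiParams

__all__ = [
    "ViabilityObservation",
    "FitResult",
    "fit_peleg_fermi",
    "fit_double_exponential",
    "r_squared",
]


@dataclass(frozen=True)
class ViabilityObservation:
    """Replicate viability measurements for one pulse protocol.

    ``e_field`` is in V/cm; replicate viabilities are percentages in [0, 100]
    relative to untreated controls.
    """

    e_field: float
    pulse_count: int
    pulse_length_us: float
    replicates: tuple = field(default=())
    pulse_strength_v: float | None = None

    def __post_init__(self):
        reps = tuple(float(r) for r in self.replicates)
        object.__setattr__(self, "replicates", reps)
        if len(reps) < 1:
            raise InsufficientDataError("at least one replicate is required")
        if any(not (0.0 <= r <= 100.0) for r in reps):
            raise ValueError(f"replicate viability outside [0, 100]: {reps}")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be >= 1")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        if len(self.replicates) < 2:
            return 0.0
        return float(np.std(self.replicates, ddof=1))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit with goodness-of-fit diagnostics."""

    params: object
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    message: str = ""


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InsufficientDataError(
            "observed and predicted must have equal length >= 2"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UnidentifiableFitError("zero total variance: R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _sigmoid_kv(e_kv, ec, a):
    with np.errstate(over="ignore"):
        return 100.0 / (1.0 + np.exp((e_kv - ec) / a))


def fit_peleg_fermi(obs, *, weight_replicates: bool = False) -> FitResult:
    """Fit (E_c, A) of the Fermi sigmoid to viability observations.

    ``obs`` is a sequence of :class:`ViabilityObservation` at one fixed
    (pulse count, pulse length).  The fit minimizes squared deviations of
    replicate-mean viability from the sigmoid, with E_c, A > 0 enforced by
    bounds.  Fields are taken in V/cm and converted to kV/cm internally;
    the returned :class:`~irepf.model_core.PelegFermiParams` is in kV/cm.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct field strengths.
    UnidentifiableFitError
        All observations saturated near 0 % or 100 % survival.
    """
    obs = sorted(obs, key=lambda o: o.e_field)
    e_kv = np.array([o.e_field for o in obs], dtype=float) / 1000.0
    if weight_replicates:
        e_fit = np.concatenate(
            [np.full(len(o.replicates), e) for o, e in zip(obs, e_kv)]
        )
        y_fit = np.concatenate([np.asarray(o.replicates) for o in obs])
    else:
        e_fit = e_kv
        y_fit = np.array([o.mean for o in obs], dtype=float)

    if len(np.unique(e_kv)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct field strengths, got {len(np.unique(e_kv))}"
        )
    means = np.array([o.mean for o in obs], dtype=float)
    if (
        means.min() > 98.0
        or means.max() < 2.0
        or means.max() - means.min() < 2.0
    ):
        raise UnidentifiableFitError(
            "observations show no usable dose response (viability all near "
            "100 %, all near 0 %, or essentially flat); E_c is not "
            "identifiable from these data"
        )
    if not (means.min() < 50.0 < means.max()):
        warnings.warn(
            "viability does not span both sides of 50 %; the fitted E_c is "
            "an extrapolation",
            IllPosedFitWarning,
            stacklevel=2,
        )

    # E_c start: field where mean viability crosses 50 % (linear interpolation),
    # clipped into the observed field range; A start: quarter of the range.
    ec0 = float(np.interp(-50.0, -means, e_kv))  # means decreasing in E
    span = float(e_kv.max() - e_kv.min())
    a0 = max(span / 4.0, 1e-3)
    ec0 = min(max(ec0, e_kv.min()), e_kv.max())

    def resid(theta):
        return _sigmoid_kv(e_fit, theta[0], theta[1]) - y_fit

    sol = least_squares(
        resid,
        x0=[max(ec0, 1e-6), a0],
        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
        method="trf",
    )
    params = PelegFermiParams(ec=float(sol.x[0]), a_steep=float(sol.x[1]))
    pred = _sigmoid_kv(e_fit, params.ec, params.a_steep)
    try:
        r2 = r_squared(y_fit, pred)
    except UnidentifiableFitError:
        r2 = np.nan
    return FitResult(
        params=params,
        r_squared=r2,
        residuals=np.asarray(sol.fun),
        converged=bool(sol.success),
        n_points=int(y_fit.size),
        message=sol.message,
    )


def _amplitudes_for_rates(x, y, r1, r2):
    """Linear least-squares amplitudes for fixed rates (variable projection)."""
    with np.errstate(over="ignore"):
        basis = np.column_stack([np.exp(r1 * x), np.exp(r2 * x)])
    basis[~np.isfinite(basis)] = 0.0
    amps, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return amps, basis @ amps


def fit_double_exponential(
    xs, ys, *, allow_growth: bool = False, n_starts: int = 16
) -> FitResult:
    """Fit ``amp1*exp(rate1*x) + amp2*exp(rate2*x)`` to (xs, ys).

    Amplitudes are unconstrained in sign; rates are bounded <= 0 (pure decay)
    unless ``allow_growth`` releases them.  The rate pair is optimized by
    bounded least squares from a deterministic log-spaced multi-start grid,
    with the amplitudes eliminated by linear least squares at every step
    (variable projection); the best of all starts is returned.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 distinct x values, or duplicated x values.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("xs and ys must have equal length")
    if len(np.unique(x)) != x.size:
        raise InsufficientDataError(f"duplicate x values in {sorted(x)}")
    if x.size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct x values for 4 coefficients, got {x.size}"
        )

    xspan = float(x.max() - x.min())
    # Resolvable decay rates range from ~1/(10*span) to ~10/step.
    rmax = 10.0 / max(np.diff(np.sort(x)).min(), 1e-12)
    rmin = 0.1 / max(xspan, 1e-12)
    rate_grid = -np.geomspace(rmin, rmax, max(2, int(np.sqrt(n_starts))))
    lo, hi = -rmax, (rmax if allow_growth else 0.0)

    def proj_resid(rates):
        _, fit = _amplitudes_for_rates(x, y, rates[0], rates[1])
        return fit - y

    best = None
    for r1, r2 in itertools.product(rate_grid, repeat=2):
        sol = least_squares(
            proj_resid,
            x0=[float(r1), float(r2)],
            bounds=([lo, lo], [hi, hi]),
            method="trf",
        )
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, sol)
    sol = best[1]
    amps, pred = _amplitudes_for_rates(x, y, sol.x[0], sol.x[1])
    de = DoubleExponential(
        amp1=float(amps[0]),
        rate1=float(sol.x[0]),
        amp2=float(amps[1]),
        rate2=float(sol.x[1]),
    )
    try:
        r2v = r_squared(y, pred)
    except UnidentifiableFitError:
        r2v = np.nan
    return FitResult(
        params=de,
        r_squared=r2v,
        residuals=pred - y,
        converged=bool(sol.success),
        n_points=int(x.size),
        message=sol.message,
    )
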