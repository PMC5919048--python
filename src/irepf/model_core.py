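"""Peleg-Fermi survival model and its double-exponential parameter functions.

The survival of a cell population exposed to pulsed electric fields is modelled
by the Fermi-type sigmoid

    S(E) = 100 / (1 + exp((E - E_c) / A))        [percent]

where ``E_c`` is the field at which half the population is killed and ``A``
sets the steepness of the dose-response curve at ``E_c``.  Both parameters
depend on the pulse protocol: they are represented as sums of two exponentials
in either the number of pulses ``n`` (at fixed pulse length) or the pulse
length ``t`` in microseconds (at fixed pulse count).

Unit convention
---------------
All Peleg-Fermi quantities (``E``, ``E_c``, ``A`` and the double-exponential
amplitudes) are handled internally in kV/cm.  Interfaces that face the field
solver or report thresholds use V/cm and convert explicitly.  The packaged
coefficient tables store amplitudes in kV/cm and the tabulated rate constants
are applied verbatim as *signed* exponents, ``amp * exp(rate * x)``.

Coefficient families fitted on HeLa-cell viability data ship with the package
(`pulse_count_family`, `pulse_length_family`).  The fitted design covered
pulse counts 1..60 and pulse lengths 25..100 us; evaluation outside that range
is permitted but emits :class:`~irepf.errors.ExtrapolationWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSteepnessError,
    DomainError,
    ExtrapolationWarning,
    InvalidParameterError,
)

__all__ = [
    "PelegFermiParams",
    "DoubleExponential",
    "FamilyMode",
    "SurvivalFamily",
    "survival_percent",
    "eval_double_exponential",
    "survival_surface",
    "field_at_survival",
    "pulse_count_family",
    "pulse_length_family",
    "LN_99",
]

#: ln(99), the logit offset between 50 % and 1 % survival.
LN_99 = float(np.log(99.0))


@dataclass(frozen=True)
class PelegFermiParams:
    """Sigmoid parameters of one survival curve, in kV/cm.

    Attributes
    ----------
    ec:
        Field at 50 % survival (kV/cm); must be positive.
    a_steep:
        Steepness of the curve at ``ec`` (kV/cm); must be positive.
    """

    ec: float
    a_steep: float

    def __post_init__(self):
        if not (np.isfinite(self.ec) and np.isfinite(self.a_steep)):
            raise InvalidParameterError("Peleg-Fermi parameters must be finite")
        if self.a_steep <= 0:
            raise InvalidParameterError(
                f"steepness A must be > 0, got {self.a_steep!r}"
            )
        if self.ec <= 0:
            raise InvalidParameterError(f"E_c must be > 0, got {self.ec!r}")


@dataclass(frozen=True)
class DoubleExponential:
    """Sum of two exponentials ``amp1*exp(rate1*x) + amp2*exp(rate2*x)``.

    Amplitudes are in kV/cm; the rates are signed exponents per unit of the
    covariate (pulse count or microsecond).  Zero amplitudes are allowed, so a
    single exponential is the special case ``amp2 = rate2 = 0``.
    """

    amp1: float
    rate1: float
    amp2: float
    rate2: float

    def __post_init__(self):
        vals = (self.amp1, self.rate1, self.amp2, self.rate2)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("double-exponential coefficients must be finite")

    def __call__(self, x):
        return eval_double_exponential(x, self)


class FamilyMode(str, Enum):
    """Which covariate the parameter functions vary over."""

    VS_PULSE_NUMBER = "vs_pulse_number"
    VS_PULSE_LENGTH = "vs_pulse_length"


# Fitted covariate ranges of the packaged coefficient families.
_FITTED_RANGE = {
    FamilyMode.VS_PULSE_NUMBER: (1.0, 60.0),
    FamilyMode.VS_PULSE_LENGTH: (25.0, 100.0),
}


@dataclass(frozen=True)
class SurvivalFamily:
    """A Peleg-Fermi survival surface S(E, x) over one protocol covariate.

    ``ec_fn`` and ``a_fn`` map the covariate ``x`` (pulse count or pulse
    length, depending on ``mode``) to the sigmoid parameters.  ``fixed_other``
    records the held-constant covariate: the pulse length in microseconds when
    ``mode`` is ``VS_PULSE_NUMBER``, the pulse count otherwise.
    """

    ec_fn: DoubleExponential
    a_fn: DoubleExponential
    mode: FamilyMode
    fixed_other: float

    def params_at(self, x) -> PelegFermiParams:
        """Evaluate (E_c, A) at covariate ``x``, warning on extrapolation."""
        x = float(x)
        if x < 0:
            raise DomainError(f"covariate must be >= 0, got {x}")
        lo, hi = _FITTED_RANGE[FamilyMode(self.mode)]
        if not (lo <= x <= hi):
            warnings.warn(
                f"evaluating {self.mode} family at x={x:g}, outside the "
                f"fitted range [{lo:g}, {hi:g}]",
                ExtrapolationWarning,
                stacklevel=2,
            )
        ec = eval_double_exponential(x, self.ec_fn)
        a = eval_double_exponential(x, self.a_fn)
        if a <= 0:
            raise DegenerateSteepnessError(
                f"steepness A(x) = {a:g} <= 0 at x = {x:g}"
            )
        return PelegFermiParams(ec=float(ec), a_steep=float(a))


def survival_percent(e_field, params: PelegFermiParams):
    """Survival fraction (percent) at field ``e_field`` (kV/cm).

    Implements ``100 / (1 + exp((E - E_c)/A))``; strictly decreasing in the
    field.  Accepts scalars or arrays; large exponents saturate cleanly to
    0 % without overflow warnings.
    """
    e = np.asarray(e_field, dtype=float)
    if not np.all(np.isfinite(e)):
        raise InvalidParameterError("e_field must be finite")
    if np.any(e < 0):
        raise DomainError("e_field must be >= 0")
    z = (e - params.ec) / params.a_steep
    with np.errstate(over="ignore"):
        s = 100.0 / (1.0 + np.exp(z))
    return s if s.ndim else float(s)


def eval_double_exponential(x, de: DoubleExponential):
    """Evaluate ``amp1*exp(rate1*x) + amp2*exp(rate2*x)`` at ``x`` (>= 0)."""
    xa = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xa)):
        raise InvalidParameterError("x must be finite")
    if np.any(xa < 0):
        raise DomainError("x must be >= 0")
    with np.errstate(over="ignore"):
        y = de.amp1 * np.exp(de.rate1 * xa) + de.amp2 * np.exp(de.rate2 * xa)
    return y if y.ndim else float(y)


def survival_surface(e_field, x, fam: SurvivalFamily):
    """Survival (percent) at field ``e_field`` (kV/cm) and covariate ``x``.

    Composes the family's parameter functions with the Fermi sigmoid; raises
    :class:`~irepf.errors.DegenerateSteepnessError` if A(x) <= 0.
    """
    return survival_percent(e_field, fam.params_at(x))


def field_at_survival(s_target: float, params: PelegFermiParams) -> float:
    """Field (kV/cm) at which survival equals ``s_target`` percent.

    Analytic inversion of the sigmoid: ``E = E_c + A * ln((100 - S)/S)``.
    ``s_target`` must lie strictly inside (0, 100).
    """
    s = float(s_target)
    if not (0.0 < s < 100.0):
        raise DomainError(f"s_target must be in (0, 100), got {s!r}")
    return params.ec + params.a_steep * float(np.log((100.0 - s) / s))


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("irepf.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def _family_from_row(row, mode: FamilyMode, fixed: float) -> SurvivalFamily:
    return SurvivalFamily(
        ec_fn=DoubleExponential(
            row["ec_amp1"], row["ec_rate1"], row["ec_amp2"], row["ec_rate2"]
        ),
        a_fn=DoubleExponential(
            row["a_amp1"], row["a_rate1"], row["a_amp2"], row["a_rate2"]
        ),
        mode=mode,
        fixed_other=fixed,
    )


def pulse_count_family(pulse_length_us: float) -> SurvivalFamily:
    """Packaged S(E, n) family for one of the calibrated pulse lengths.

    Parameters
    ----------
    pulse_length_us:
        One of 25, 50, 75 or 100 microseconds.
    """
    df = _load_table("peleg_fermi_vs_pulse_count.csv")
    match = df[df["pulse_length_us"] == pulse_length_us]
    if match.empty:
        raise DomainError(
            f"no packaged coefficients for pulse length {pulse_length_us} us; "
            f"available: {sorted(df['pulse_length_us'])}"
        )
    return _family_from_row(
        match.iloc[0], FamilyMode.VS_PULSE_NUMBER, float(pulse_length_us)
    )


def pulse_length_family(pulse_count: int) -> SurvivalFamily:
    """Packaged S(E, t) family for one of the calibrated pulse counts (1/10/30/60)."""
    df = _load_table("peleg_fermi_vs_pulse_length.csv")
    match = df[df["pulse_count"] == pulse_count]
    if match.empty:
        raise DomainError(
            f"no packaged coefficients for pulse count {pulse_count}; "
            f"available: {sorted(df['pulse_count'])}"
        )
    return _family_from_row(
        match.iloc[0], FamilyMode.VS_PULSE_LENGTH, float(pulse_count)
    )
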