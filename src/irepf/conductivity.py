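"""Field-dependent electrical conductivity of cervical tumor tissue.

Electroporation raises tissue conductivity with field strength; the rise is
modelled by an asymmetric Gompertz sigmoid

    sigma(E) = sigma0 + (sigma_max - sigma0) * exp(-a * exp(-b * E)),

with ``E`` in V/cm.  ``sigma0`` is the baseline (no-electroporation)
conductivity and ``sigma_max`` the fully electroporated plateau.  The
displacement ``a`` and growth-rate ``b`` coefficients depend on the pulse
length ``t`` (microseconds) through fixed quadratics (`coeff_a`, `coeff_b`).

For cervical cancer the baseline is obtained from the healthy-cervix value
0.2033 S/m scaled by the malignancy factor 1.13, and the plateau from raising
the baseline by a further factor of 1.8 (i.e. sigma_max = 2.8 * sigma0).
``b`` carries implicit units of cm/V so that ``b * E`` is dimensionless with
``E`` in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError

__all__ = [
    "ConductivityParams",
    "coeff_a",
    "coeff_b",
    "cervical_cancer_params",
    "sigma_of_field",
    "HEALTHY_CERVIX_SIGMA",
    "MALIGNANCY_FACTOR",
    "SATURATION_INCREASE",
]

#: Conductivity of healthy cervical tissue at 1 Hz (S/m).
HEALTHY_CERVIX_SIGMA = 0.2033
#: Multiplicative tumor-vs-healthy conductivity factor.
MALIGNANCY_FACTOR = 1.13
#: Fractional increase from sigma0 to the saturated plateau (sigma_max = (1 + 1.8) * sigma0).
SATURATION_INCREASE = 1.8


@dataclass(frozen=True)
class ConductivityParams:
    """Gompertz conductivity parameters at one pulse length."""

    sigma0: float
    sigma_max: float
    a_coef: float
    b_coef: float
    pulse_length_us: float

    def __post_init__(self):
        if not 0 < self.sigma0 < self.sigma_max:
            raise InvalidParameterError(
                f"need 0 < sigma0 < sigma_max, got {self.sigma0}, {self.sigma_max}"
            )
        if self.a_coef <= 0 or self.b_coef <= 0:
            raise InvalidParameterError("a and b coefficients must be positive")


def coeff_a(t: float) -> float:
    """Displacement coefficient a(t) = -5e-6 t^2 + 4e-3 t + 2.803, t in us."""
    t = float(t)
    if t < 0:
        raise DomainError("pulse length must be >= 0")
    return -5e-6 * t * t + 0.004 * t + 2.803


def coeff_b(t: float) -> float:
    """Growth-rate coefficient b(t) = -7e-9 t^2 + 5e-6 t + 2e-3, t in us."""
    t = float(t)
    if t < 0:
        raise DomainError("pulse length must be >= 0")
    return -7e-9 * t * t + 5e-6 * t + 0.002


def cervical_cancer_params(t: float) -> ConductivityParams:
    """Gompertz parameters for cervical tumor tissue at pulse length ``t`` (us)."""
    if t <= 0:
        raise DomainError("pulse length must be > 0")
    sigma0 = HEALTHY_CERVIX_SIGMA * MALIGNANCY_FACTOR
    sigma_max = sigma0 * (1.0 + SATURATION_INCREASE)
    return ConductivityParams(
        sigma0=sigma0,
        sigma_max=sigma_max,
        a_coef=coeff_a(t),
        b_coef=coeff_b(t),
        pulse_length_us=float(t),
    )


def sigma_of_field(e_field, p: ConductivityParams):
    """Conductivity (S/m) at field magnitude ``e_field`` (V/cm).

    Monotone non-decreasing in ``E``; tends to ``sigma_max`` as ``b*E``
    grows large and to ``sigma0 + (sigma_max - sigma0) * exp(-a)`` at zero
    field.  Accepts scalars or arrays.
    """
    e = np.asarray(e_field, dtype=float)
    if not np.all(np.isfinite(e)):
        raise InvalidParameterError("e_field must be finite")
    if np.any(e < 0):
        raise DomainError("e_field must be >= 0")
    s = p.sigma0 + (p.sigma_max - p.sigma0) * np.exp(
        -p.a_coef * np.exp(-p.b_coef * e)
    )
    return s if s.ndim else float(s)
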