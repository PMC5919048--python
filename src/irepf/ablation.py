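"""Ablation-zone integration and equivalent electric-field thresholds.

Given a converged field solution and a Peleg-Fermi survival family, this
module maps the field magnitude to a predicted cell viability at every node,
integrates the dead region (viability at or below 1 %), books the transition
zone (viability strictly between the dead and intact bounds), and extracts
the equivalent electric-field threshold (EFT) — the single field value whose
binary super-level set reproduces the statistical model's ablation area.

Because viability is a strictly decreasing function of field magnitude, the
statistical 1 %-viability contour coincides with a field iso-contour, and the
EFT has the closed form E_c + A * ln(99) (the field at 1 % survival).  A
numerical cross-check that bisects the threshold until the binary area
matches the statistical area is provided (`equivalent_eft_by_area`).

Area integration defaults to sub-element linear interpolation of the level
set: within each triangle the clipping variable is taken linear and the
sub-polygon area is computed exactly.  Viability spans many decades across an
element near the dead contour, so the clipping variable is log-viability
(equivalently, a linear function of the field), which keeps the interpolation
well conditioned; the binary field-threshold area interpolates the field
magnitude directly.  An element-mean membership rule is available via
``method="element_mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, MeshError
from .model_core import SurvivalFamily, field_at_survival, survival_surface

__all__ = [
    "AblationResult",
    "viability_map",
    "ablation_area",
    "transition_zone_area",
    "eft_model_area",
    "equivalent_eft",
    "equivalent_eft_by_area",
    "run_protocol",
]

_LOG_FLOOR = 1e-280  # avoids log(0) where survival underflows to exactly 0 %


@dataclass(frozen=True)
class AblationResult:
    """Summary of one simulated protocol.

    ``protocol`` is (applied voltage V, pulse count, pulse length us,
    frequency Hz).  Areas in mm^2; EFT in V/cm (integer-rounded).
    """

    area_mm2: float
    eft_v_per_cm: int
    transition_area_mm2: float
    protocol: tuple
    eft_by_area_v_per_cm: float | None = None
    n_elements: int | None = None
    picard_iterations: int | None = None
    mesh_history: tuple = ()


def _mesh_of(obj):
    return obj.mesh if hasattr(obj, "mesh") else obj


def viability_map(sol, fam: SurvivalFamily, x) -> np.ndarray:
    """Per-node predicted viability (percent) for covariate value ``x``.

    The solver reports fields in V/cm; the survival model works in kV/cm, so
    the nodal magnitudes are scaled by 1/1000 before evaluating S(E, x).
    """
    return np.asarray(survival_surface(sol.e_mag_node / 1000.0, x, fam))


def _superlevel_area(mesh, w, w_thr) -> float:
    """Area where the nodal field ``w`` (taken linear per element) >= ``w_thr``."""
    tri = mesh.triangles
    if tri.size == 0:
        raise MeshError("empty mesh")
    v = w[tri]
    above = v >= w_thr
    cnt = above.sum(axis=1)
    area = float(mesh.areas[cnt == 3].sum())

    def corner_fraction(rows, corner_above):
        """Fraction of each triangle cut off at its single odd vertex."""
        vv = v[rows]
        odd = (above[rows] == corner_above).argmax(axis=1)
        idx = np.arange(len(rows))
        v0 = vv[idx, odd]
        v1 = vv[idx, (odd + 1) % 3]
        v2 = vv[idx, (odd + 2) % 3]
        d1 = np.where(v0 != v1, v0 - v1, np.inf)
        d2 = np.where(v0 != v2, v0 - v2, np.inf)
        return ((v0 - w_thr) / d1) * ((v0 - w_thr) / d2)

    one = np.flatnonzero(cnt == 1)
    if one.size:
        area += float((mesh.areas[one] * corner_fraction(one, True)).sum())
    two = np.flatnonzero(cnt == 2)
    if two.size:
        area += float((mesh.areas[two] * (1.0 - corner_fraction(two, False))).sum())
    return area


def ablation_area(
    mesh, viability, threshold: float = 1.0, *, method: str = "interpolate"
) -> float:
    """Area (mm^2) where viability is at or below ``threshold`` percent.

    ``mesh`` may be a :class:`~irepf.field_solver.Mesh` or a field solution.
    ``method="interpolate"`` (default) clips elements along the linearly
    interpolated log-viability contour; ``method="element_mean"`` counts whole
    elements whose mean nodal viability is below the threshold.
    """
    mesh = _mesh_of(mesh)
    v = np.asarray(viability, dtype=float)
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    if method == "element_mean":
        vm = v[mesh.triangles].mean(axis=1)
        return float(mesh.areas[vm <= threshold].sum())
    if method != "interpolate":
        raise ValueError(f"unknown method {method!r}")
    w = -np.log(np.clip(v, _LOG_FLOOR, None))
    return _superlevel_area(mesh, w, -np.log(threshold))


def transition_zone_area(
    mesh, viability, low: float = 1.0, high: float = 99.0
) -> float:
    """Area (mm^2) with viability strictly between ``low`` and ``high`` percent.

    The complement of the dead (<= low) and intact (>= high) regions; the
    intact region is clipped on log(100 - viability) for the same conditioning
    reason the dead region is clipped on log(viability).
    """
    mesh = _mesh_of(mesh)
    if low >= high:
        raise DomainError(f"need low < high, got {low} >= {high}")
    v = np.asarray(viability, dtype=float)
    dead = ablation_area(mesh, v, threshold=low)
    w_alive = -np.log(np.clip(100.0 - v, _LOG_FLOOR, None))
    alive = _superlevel_area(mesh, w_alive, -np.log(100.0 - high))
    return max(mesh.total_area - dead - alive, 0.0)


def eft_model_area(sol, threshold_v_per_cm: float) -> float:
    """Binary threshold-model area (mm^2): field magnitude >= threshold."""
    mesh = _mesh_of(sol)
    if threshold_v_per_cm <= 0:
        return mesh.total_area
    return _superlevel_area(mesh, sol.e_mag_node, float(threshold_v_per_cm))


def equivalent_eft(fam: SurvivalFamily, x, survival: float = 1.0) -> int:
    """Closed-form equivalent field threshold (V/cm, integer-rounded).

    The field at ``survival`` percent: E_c(x) + A(x) * ln((100 - s)/s); with
    the default 1 % this is E_c + A * ln(99).
    """
    e_kv = field_at_survival(survival, fam.params_at(x))
    return int(round(e_kv * 1000.0))


def equivalent_eft_by_area(
    sol, fam: SurvivalFamily, x, *, area_rtol: float = 1e-3
) -> float:
    """EFT (V/cm) found by matching the binary area to the statistical area.

    Bisects the field threshold until the super-level-set area equals the
    statistical ablation area to ``area_rtol``; cross-checks the closed form.
    """
    mesh = _mesh_of(sol)
    target = ablation_area(mesh, viability_map(sol, fam, x))
    if target <= 0:
        raise DomainError("statistical ablation area is zero; no matching EFT")
    emax = float(sol.e_mag_node.max())

    def gap(thr):
        return eft_model_area(sol, thr) - target

    lo, hi = 1.0, emax
    if gap(lo) < 0 or gap(hi) > 0:
        raise DomainError("field range does not bracket the target area")
    thr = brentq(gap, lo, hi, xtol=1e-3)
    if abs(gap(thr)) / target > 10 * area_rtol:
        raise DomainError("threshold search did not reach the area tolerance")
    return float(thr)


def run_protocol(
    voltage_v: float,
    pulse_count: int,
    pulse_length_us: float,
    frequency_hz: float = 1.0,
    *,
    family: SurvivalFamily | None = None,
    domain=None,
    start_resolution: float = 0.8,
    max_refinements: int = 12,
    cross_check_eft: bool = False,
):
    """Full treatment-planning pipeline for one pulse protocol.

    Solves the nonlinear field problem on a mesh refined to the 0.1 %
    area-change criterion, maps it to viability with the packaged (or a
    user-supplied) survival family at the given pulse count, and returns an
    :class:`AblationResult` together with the converged field solution.

    Pulse frequency and pulse count do not enter the quasi-static field
    problem; they parameterize only the survival model.
    """
    from .conductivity import cervical_cancer_params
    from .field_solver import SimulationDomain, converge_mesh
    from .model_core import pulse_count_family

    if family is None:
        family = pulse_count_family(pulse_length_us)
    if domain is None:
        domain = SimulationDomain(applied_voltage_v=float(voltage_v))
    cond = cervical_cancer_params(pulse_length_us)
    mesh, sol, history = converge_mesh(
        domain,
        cond,
        (family, pulse_count),
        start_resolution,
        max_refinements=max_refinements,
    )
    v = viability_map(sol, family, pulse_count)
    result = AblationResult(
        area_mm2=ablation_area(mesh, v),
        eft_v_per_cm=equivalent_eft(family, pulse_count),
        transition_area_mm2=transition_zone_area(mesh, v),
        protocol=(float(voltage_v), int(pulse_count), float(pulse_length_us), float(frequency_hz)),
        eft_by_area_v_per_cm=(
            equivalent_eft_by_area(sol, family, pulse_count) if cross_check_eft else None
        ),
        n_elements=mesh.n_elements,
        picard_iterations=sol.iterations,
        mesh_history=tuple(history),
    )
    return result, sol
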