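"""File I/O: viability tables, coefficient tables, field grids, run configs.

All delimited text is comma-separated, "."-decimal, UTF-8, with a mandatory
header row; lines starting with ``#`` are comments.  Output files carry a
provenance header (tool version, config hash, seed) so reruns can be checked
for reproducibility without timestamps entering the hash.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import TableFormatError
from .fitting import ViabilityObservation

__all__ = [
    "RunConfig",
    "read_viability_table",
    "write_viability_table",
    "write_coefficient_table",
    "write_field_grid",
    "write_ablation_summary",
    "read_config",
    "write_config",
    "config_hash",
]

_REQUIRED_COLUMNS = (
    "pulse_strength_V",
    "e_field_V_per_cm",
    "pulse_count",
    "pulse_length_us",
)


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (defaults mirror the study)."""

    voltage_v: float = 2500.0
    pulse_count: int = 90
    pulse_length_us: float = 100.0
    frequency_hz: float = 1.0
    domain_width_mm: float = 100.0
    domain_height_mm: float = 80.0
    electrode_diameter_mm: float = 1.0
    electrode_spacing_mm: float = 10.0
    start_resolution_mm: float = 0.8
    max_refinements: int = 12
    picard_tol: float = 1e-6
    dead_threshold_pct: float = 1.0
    transition_upper_pct: float = 99.0
    noise_sd_pct: float = 3.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        positive = (
            "voltage_v pulse_count pulse_length_us frequency_hz domain_width_mm "
            "domain_height_mm electrode_diameter_mm electrode_spacing_mm "
            "start_resolution_mm picard_tol dead_threshold_pct transition_upper_pct"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the configuration (timestamp-free)."""
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(cfg: RunConfig | None = None, seed: int | None = None) -> str:
    parts = [f"irepf {__version__}"]
    if cfg is not None:
        parts.append(f"config_hash={config_hash(cfg)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + "; ".join(parts) + "\n"


def read_viability_table(path) -> list[ViabilityObservation]:
    """Read a replicate viability table into observations.

    Expects the columns ``pulse_strength_V, e_field_V_per_cm, pulse_count,
    pulse_length_us`` plus one or more ``rep*`` replicate columns (``mean`` /
    ``sd`` columns, if present, are ignored and re-derived).  Rows with any
    replicate outside [0, 100] are rejected with their row numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: file is empty") from exc
    except ValueError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise TableFormatError(f"{path}: no replicate (rep*) columns")
    if df.empty:
        raise TableFormatError(f"{path}: table has a header but no data rows")

    for col in list(_REQUIRED_COLUMNS) + rep_cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise TableFormatError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row(s) {[int(i) + 2 for i in bad]}"
            )
        df[col] = pd.to_numeric(df[col])

    reps = df[rep_cols].to_numpy(dtype=float)
    bad_rows = np.flatnonzero(((reps < 0) | (reps > 100)).any(axis=1))
    if bad_rows.size:
        raise TableFormatError(
            f"{path}: replicate viability outside [0, 100] in data row(s) "
            f"{[int(i) + 2 for i in bad_rows]}"
        )

    return [
        ViabilityObservation(
            e_field=float(row.e_field_V_per_cm),
            pulse_count=int(row.pulse_count),
            pulse_length_us=float(row.pulse_length_us),
            replicates=tuple(reps[i]),
            pulse_strength_v=float(row.pulse_strength_V),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_viability_table(obs, path, *, cfg: RunConfig | None = None, seed=None):
    """Write observations as a replicate table with provenance header."""
    n_rep = max(len(o.replicates) for o in obs)
    rows = []
    for o in obs:
        row = {
            "pulse_strength_V": (
                o.pulse_strength_v if o.pulse_strength_v is not None else np.nan
            ),
            "e_field_V_per_cm": o.e_field,
            "pulse_count": o.pulse_count,
            "pulse_length_us": o.pulse_length_us,
        }
        for k in range(n_rep):
            row[f"rep{k + 1}"] = (
                o.replicates[k] if k < len(o.replicates) else np.nan
            )
        row["mean"] = o.mean
        row["sd"] = o.sd
        rows.append(row)
    _write_with_header(pd.DataFrame(rows), path, cfg, seed)


def write_coefficient_table(rows, path, *, covariate_name, cfg=None, seed=None):
    """Write fitted double-exponential families in the packaged-table layout.

    ``rows`` maps the held-fixed covariate value to a dict with keys
    ``ec`` / ``a`` (DoubleExponential) and ``ec_r2`` / ``a_r2``.
    """
    recs = []
    for fixed, d in sorted(rows.items()):
        recs.append(
            {
                covariate_name: fixed,
                "ec_amp1": d["ec"].amp1,
                "ec_rate1": d["ec"].rate1,
                "ec_amp2": d["ec"].amp2,
                "ec_rate2": d["ec"].rate2,
                "ec_r_squared": d["ec_r2"],
                "a_amp1": d["a"].amp1,
                "a_rate1": d["a"].rate1,
                "a_amp2": d["a"].amp2,
                "a_rate2": d["a"].rate2,
                "a_r_squared": d["a_r2"],
            }
        )
    _write_with_header(pd.DataFrame(recs), path, cfg, seed)


def write_field_grid(sol, path, *, viability=None, cfg=None, seed=None):
    """Export a field solution as nodal delimited text.

    Columns: x_mm, y_mm, phi_V, E_V_per_cm, sigma_S_per_m (element
    conductivity averaged to nodes) and optionally viability_pct.
    """
    mesh = sol.mesh
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(num, mesh.triangles[:, k], mesh.areas * sol.sigma_elem)
        np.add.at(den, mesh.triangles[:, k], mesh.areas)
    sigma_node = num / np.where(den > 0, den, 1.0)
    df = pd.DataFrame(
        {
            "x_mm": mesh.points[:, 0],
            "y_mm": mesh.points[:, 1],
            "phi_V": sol.phi,
            "E_V_per_cm": sol.e_mag_node,
            "sigma_S_per_m": sigma_node,
        }
    )
    if viability is not None:
        df["viability_pct"] = np.asarray(viability)
    _write_with_header(df, path, cfg, seed)


def write_ablation_summary(result, path, *, cfg=None, seed=None):
    """Write one protocol summary row (delimited) plus a JSON sidecar."""
    v0, n, t, f = result.protocol
    df = pd.DataFrame(
        [
            {
                "pulse_strength_V": v0,
                "pulse_count": n,
                "pulse_length_us": t,
                "frequency_Hz": f,
                "ablation_zone_mm2": result.area_mm2,
                "eft_V_per_cm": result.eft_v_per_cm,
                "transition_zone_mm2": result.transition_area_mm2,
                "n_elements": result.n_elements,
                "picard_iterations": result.picard_iterations,
            }
        ]
    )
    _write_with_header(df, path, cfg, seed)
    sidecar = Path(path).with_suffix(".json")
    payload = {
        "protocol": {
            "voltage_v": v0,
            "pulse_count": n,
            "pulse_length_us": t,
            "frequency_hz": f,
        },
        "ablation_zone_mm2": result.area_mm2,
        "eft_v_per_cm": result.eft_v_per_cm,
        "transition_zone_mm2": result.transition_area_mm2,
        "mesh_history": [list(h) for h in result.mesh_history],
    }
    sidecar.write_text(json.dumps(payload, indent=2) + "\n")


def _write_with_header(df: pd.DataFrame, path, cfg, seed):
    buf = _io.StringIO()
    buf.write(_provenance(cfg, seed))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file."""
    cfg = RunConfig()
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise TableFormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise TableFormatError(f"{path}:{lineno}: unknown config key {key!r}")
        current = getattr(cfg, key)
        try:
            kwargs[key] = type(current)(value) if not isinstance(current, str) else value
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: bad value for {key}: {exc}")
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path):
    """Serialize a config as a flat key = value file (round-trips read_config)."""
    lines = [f"{k} = {v}" for k, v in asdict(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")
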