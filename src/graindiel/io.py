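"""Reading and writing grain parameter files and permittivity curves.

Grain files are TOML (primary) or JSON (accepted, auto-detected by
extension) with sections ``[grain]``, ``[shape]``, ``[densities]``,
``[dielectric]``, ``[water]`` and optionally ``[composition]``.  Field
names follow the model symbols (aspect, k, rho_s, rho_b, eps_s, A_s,
M_c, T).  Densities default to g cm⁻³; a ``units = "kg/m3"`` tag in
``[densities]`` switches the section to SI.

Curves are written as plain CSV with ``#``-prefixed header comments
echoing every model parameter, so a curve file is self-describing and
round-trips exactly.
"""

from __future__ import annotations

import json
import tomllib
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np

from .grain import GrainSpec, PermittivityCurve
from .water import WaterPhaseParams

__all__ = [
    "load_grain_spec",
    "write_grain_spec",
    "write_curve",
    "read_curve",
    "bundled_path",
    "list_bundled",
    "load_table",
]

_DENSITY_UNITS = {"g/cm3": 1.0, "kg/m3": 1e-3}

CURVE_COLUMNS = ("M_v", "M_wb", "rho_b", "eps_water", "eps_eff")


class GrainFileError(ValueError):
    """A grain parameter file failed to parse or validate."""


def _read_mapping(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise GrainFileError(f"grain file not found: {path}")
    try:
        if path.suffix.lower() == ".json":
            with open(path, "rb") as fh:
                data = json.load(fh)
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
    except (tomllib.TOMLDecodeError, json.JSONDecodeError) as exc:
        raise GrainFileError(f"{path}: unparseable grain file: {exc}") from exc
    if not isinstance(data, dict) or not data:
        raise GrainFileError(f"{path}: empty or non-table grain file")
    return data


def _require(section: dict, table: str, key: str, path: Path) -> Any:
    if key not in section:
        raise GrainFileError(f"{path}: missing mandatory field [{table}].{key}")
    return section[key]


def load_grain_spec(path: str | Path) -> GrainSpec:
    """Load and validate a grain parameter file into a :class:`GrainSpec`."""
    path = Path(path)
    data = _read_mapping(path)
    grain = data.get("grain", {})
    shape = data.get("shape", {})
    dens = data.get("densities", {})
    diel = data.get("dielectric", {})
    water = data.get("water", {})

    unit = dens.get("units", "g/cm3")
    if unit not in _DENSITY_UNITS:
        raise GrainFileError(
            f"{path}: unknown density unit tag {unit!r} in [densities] "
            f"(expected one of {sorted(_DENSITY_UNITS)})"
        )
    scale = _DENSITY_UNITS[unit]

    if "M_wb" in water and not 0.0 <= water["M_wb"] < 1.0:
        raise GrainFileError(
            f"{path}: [water].M_wb = {water['M_wb']} violates 0 <= M_wb < 1"
        )

    wp_kwargs = {
        key: water[key] for key in ("r", "f_star", "alpha", "d", "c") if key in water
    }
    try:
        spec = GrainSpec(
            name=grain.get("name", path.stem),
            aspect=float(_require(shape, "shape", "aspect", path)),
            k=float(shape.get("k", 3.0)),
            rho_s=float(_require(dens, "densities", "rho_s", path)) * scale,
            rho_b=(float(dens["rho_b"]) * scale) if "rho_b" in dens else None,
            rho_w=float(dens.get("rho_w", 1.0 / scale)) * scale,
            eps_s=float(_require(diel, "dielectric", "eps_s", path)),
            eps_a=float(diel.get("eps_a", 1.0)),
            A_s=float(_require(water, "water", "A_s", path)),
            M_c=float(water["M_c"]) if "M_c" in water else None,
            T=float(water.get("T", 298.0)),
            water_params=WaterPhaseParams(**wp_kwargs),
        )
    except ValueError as exc:
        raise GrainFileError(f"{path}: {exc}") from exc
    return spec


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return '"' + str(value).replace('"', '\\"') + '"'


def write_grain_spec(spec: GrainSpec, path: str | Path) -> Path:
    """Serialize a GrainSpec to a TOML grain file (g cm⁻³ densities)."""
    path = Path(path)
    sections: dict[str, dict[str, Any]] = {
        "grain": {"name": spec.name},
        "shape": {"aspect": spec.aspect, "k": spec.k},
        "densities": {"units": "g/cm3", "rho_s": spec.rho_s, "rho_w": spec.rho_w},
        "dielectric": {"eps_s": spec.eps_s, "eps_a": spec.eps_a},
        "water": {"A_s": spec.A_s, "T": spec.T, "f_star": spec.water_params.f_star,
                  "r": spec.water_params.r},
    }
    if spec.rho_b is not None:
        sections["densities"]["rho_b"] = spec.rho_b
    if spec.M_c is not None:
        sections["water"]["M_c"] = spec.M_c
    lines = []
    for table, fields in sections.items():
        lines.append(f"[{table}]")
        for key, value in fields.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def write_curve(
    curve: PermittivityCurve,
    path: str | Path,
    seed: int | None = None,
    version: str | None = None,
) -> Path:
    """Write a permittivity curve as commented CSV.

    Header comment lines (``#``) echo the model, ordering, every grain
    parameter and, when given, the seed and package version; values
    round-trip through :func:`read_curve` exactly (full float precision).
    """
    path = Path(path)
    if version is None:
        from . import __version__ as version
    lines = [f"# model = {curve.model}"]
    if curve.ordering:
        lines.append(f"# ordering = {curve.ordering}")
    for key, value in sorted(curve.params.items()):
        lines.append(f"# {key} = {value}")
    if seed is not None:
        lines.append(f"# seed = {seed}")
    lines.append(f"# version = {version}")
    if len(curve.M_v) == 0:
        import warnings

        warnings.warn(f"writing header-only curve file (empty grid): {path}")
    lines.append(",".join(CURVE_COLUMNS))
    for i in range(len(curve.M_v)):
        lines.append(
            ",".join(
                format(getattr(curve, col)[i], ".17g") for col in CURVE_COLUMNS
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_curve(path: str | Path) -> PermittivityCurve:
    """Read a commented-CSV curve file back into a PermittivityCurve."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif not header_seen:
            header_seen = True  # column header
        elif line.strip():
            rows.append([float(v) for v in line.split(",")])
    data = np.array(rows, dtype=float).reshape(-1, len(CURVE_COLUMNS))
    return PermittivityCurve(
        M_v=data[:, 0],
        M_wb=data[:, 1],
        rho_b=data[:, 2],
        eps_water=data[:, 3],
        eps_eff=data[:, 4],
        model=meta.get("model", "unknown"),
        ordering=meta.get("ordering") or None,
        params={k: v for k, v in meta.items() if k not in ("model", "ordering", "version", "seed")},
    )


def bundled_path(name: str) -> Path:
    """Path of a bundled data file (grain parameter set or property table)."""
    root = resources.files("graindiel.data")
    candidate = root / name
    if not candidate.is_file():
        candidate = root / f"{name}.toml"
    if not candidate.is_file():
        raise FileNotFoundError(
            f"no bundled file {name!r}; available: {sorted(list_bundled())}"
        )
    return Path(str(candidate))


def list_bundled() -> list[str]:
    """Names of all bundled data files."""
    root = resources.files("graindiel.data")
    return sorted(p.name for p in root.iterdir() if p.name.endswith((".toml", ".json")))


def load_table(name: str) -> dict[str, Any]:
    """Load a bundled TOML property table as a plain mapping."""
    with open(bundled_path(name), "rb") as fh:
        return tomllib.load(fh)
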