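"""End-to-end permittivity pipelines for packed grain.

Three forward models turn a :class:`GrainSpec` into an effective
permittivity versus volumetric moisture curve:

* :func:`two_phase_grain_curve` — air+solid volume-averaged background
  with shaped water inclusions (the simplest useful picture);
* :func:`three_phase_grain_curve` — confocal core/shell/background
  ellipsoids under a chosen solid/water/air phase configuration;
* :func:`high_moisture_corn_curve` — an effective-medium blend of the
  SWA and WSA configurations, switching the destination of added water
  at a critical moisture M_c.  This reproduces the flattening of the
  permittivity rise observed in high-moisture corn.

All pipelines share the same water-phase physics: the film thickness
``t_w = M_v / (A_s rho_b)`` feeds the bound/free single-phase water
permittivity, so surface area and packing density propagate into every
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .mixtures import (
    ConfocalSpec,
    configuration_volume_fractions,
    confocal_three_phase,
    ema_blend,
    generalized_ellipsoid_mixture,
    swa_fraction,
)
from .moisture import bulk_density_model, bulk_porosity, kernel_density_vs_moisture
from .shape import depolarization_factors, porosity_from_shape
from .water import WaterPhaseParams, free_water_permittivity, water_phase_permittivity

__all__ = [
    "GrainSpec",
    "PermittivityCurve",
    "two_phase_grain_curve",
    "three_phase_grain_curve",
    "high_moisture_corn_curve",
    "stepped_surface_area_curve",
    "default_moisture_grid",
]

DEFAULT_GRID_POINTS = 81
DEFAULT_GRID_MAX = 0.40


@dataclass(frozen=True)
class GrainSpec:
    """A grain's shape, densities, permittivities and water binding.

    Densities in g cm⁻³ (the CLI converts from kg m⁻³), surface area in
    m² g⁻¹, temperature in Kelvin.  ``rho_b`` is optional: when given it
    overrides the shape/packing bulk-density model (measured packing
    beats the estimate); otherwise bulk density is modeled from
    ``rho_s``, the aspect ratio and the packing coefficient ``k``.
    """

    name: str
    aspect: float
    rho_s: float
    eps_s: float
    A_s: float
    T: float = 298.0
    eps_a: float = 1.0
    k: float = 3.0
    M_c: float | None = None
    rho_b: float | None = None
    rho_w: float = 1.0
    water_params: WaterPhaseParams = field(default_factory=WaterPhaseParams)

    def __post_init__(self) -> None:
        if self.aspect <= 0 or self.rho_s <= 0 or self.A_s < 0:
            raise ValueError("aspect, rho_s must be positive and A_s non-negative")
        if self.T <= 0:
            raise ValueError("temperature must be positive Kelvin")
        if self.rho_b is not None and self.rho_b <= 0:
            raise ValueError("explicit bulk density must be positive")
        if self.M_c is not None and self.M_c <= 0:
            raise ValueError("critical moisture M_c must be positive")


@dataclass
class PermittivityCurve:
    """A permittivity-vs-moisture curve with its intermediate quantities."""

    M_v: np.ndarray
    M_wb: np.ndarray
    rho_b: np.ndarray
    eps_water: np.ndarray
    eps_eff: np.ndarray
    model: str
    ordering: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.M_v) > 1 and not np.all(np.diff(self.M_v) > 0):
            raise ValueError("moisture grid must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "M_v": self.M_v,
                "M_wb": self.M_wb,
                "rho_b": self.rho_b,
                "eps_water": self.eps_water,
                "eps_eff": self.eps_eff,
                "model": self.model,
                "ordering": self.ordering or "",
            }
        )


def default_moisture_grid(
    upper: float = DEFAULT_GRID_MAX, points: int = DEFAULT_GRID_POINTS
) -> np.ndarray:
    """Default volumetric moisture grid: 81 points over [0, 0.40]."""
    return np.linspace(0.0, upper, points)


def _wet_basis_for_volumetric(spec: GrainSpec, M_v: float) -> tuple[float, float]:
    """Wet-basis moisture and bulk density (g cm⁻³) consistent with M_v.

    With an explicit bulk density the inversion of M_v = M_db rho_b/rho_w
    is direct.  With the modeled bulk density, rho_b itself depends on
    M_wb, so the pair is solved self-consistently (the map is monotone in
    M_wb; bracketed root find).
    """
    if M_v < 0:
        raise ValueError(f"volumetric moisture must be non-negative; got {M_v}")
    if spec.rho_b is not None:
        m_db = M_v * spec.rho_w / spec.rho_b
        return m_db / (1.0 + m_db), spec.rho_b
    if M_v == 0.0:
        return 0.0, bulk_density_model(spec.rho_s, 0.0, spec.aspect, spec.k, spec.rho_w)

    def residual(m_wb: float) -> float:
        rho_b = bulk_density_model(spec.rho_s, m_wb, spec.aspect, spec.k, spec.rho_w)
        m_db = m_wb / (1.0 - m_wb)
        return m_db * rho_b / spec.rho_w - M_v

    upper = 1.0 - 1e-9
    if residual(upper) < 0:
        raise ValueError(f"volumetric moisture {M_v} unreachable for {spec.name!r}")
    m_wb = brentq(residual, 0.0, upper, xtol=1e-14)
    return m_wb, bulk_density_model(spec.rho_s, m_wb, spec.aspect, spec.k, spec.rho_w)


def _pore_space(spec: GrainSpec, m_wb: float, rho_b: float) -> float:
    """Bulk porosity available to water at this moisture."""
    if spec.rho_b is not None:
        rho_k = kernel_density_vs_moisture(spec.rho_s, m_wb, spec.rho_w)
        return bulk_porosity(rho_b, rho_k)
    return porosity_from_shape(spec.aspect, spec.k)


def _water_eps(spec: GrainSpec, M_v: float, rho_b: float) -> float:
    """Single-phase water permittivity for the film at this moisture."""
    if M_v == 0.0:
        return 0.0
    if spec.A_s == 0.0:
        return free_water_permittivity(spec.T)
    rho_b_g_m3 = rho_b * 1e6  # g cm^-3 -> g m^-3
    t_w = M_v / (spec.A_s * rho_b_g_m3)
    return water_phase_permittivity(spec.T, t_w, spec.water_params)


def _point_quantities(spec: GrainSpec, M_v: float) -> tuple[float, float, float, float]:
    """(M_wb, rho_b, phi_b, eps_w) at one volumetric moisture."""
    m_wb, rho_b = _wet_basis_for_volumetric(spec, M_v)
    phi_b = _pore_space(spec, m_wb, rho_b)
    if M_v > phi_b + 1e-12:
        raise ValueError(
            f"M_v = {M_v:.4f} exceeds pore space phi_b = {phi_b:.4f} "
            f"for {spec.name!r}"
        )
    return m_wb, rho_b, phi_b, _water_eps(spec, M_v, rho_b)


def _dry_pack_permittivity(spec: GrainSpec, phi_b: float) -> float:
    """Dry grain pack: solid spheroid inclusions in an air background."""
    n = depolarization_factors(spec.aspect)
    return float(
        generalized_ellipsoid_mixture(spec.eps_a, spec.eps_s, 1.0 - phi_b, n)
    )


def two_phase_grain_curve(
    spec: GrainSpec, M_v_grid: Sequence[float] | np.ndarray
) -> PermittivityCurve:
    """Two-phase model: water inclusions in an averaged air+solid background.

    Air and solid, being close in permittivity, are merged into a single
    background by a volume-weighted arithmetic mean over their summed
    fraction; the water phase enters as spheroidal inclusions with the
    kernel's aspect ratio.
    """
    grid = np.asarray(M_v_grid, dtype=float)
    n = depolarization_factors(spec.aspect)
    m_wb = np.empty_like(grid)
    rho_b = np.empty_like(grid)
    eps_w = np.empty_like(grid)
    eps = np.empty_like(grid)
    for i, m_v in enumerate(grid):
        m_wb[i], rho_b[i], phi_b, eps_w[i] = _point_quantities(spec, float(m_v))
        phi_s = 1.0 - phi_b
        phi_a = max(phi_b - m_v, 0.0)
        eps_bg = (phi_a * spec.eps_a + phi_s * spec.eps_s) / (phi_a + phi_s)
        eps[i] = generalized_ellipsoid_mixture(eps_bg, eps_w[i], float(m_v), n)
    return PermittivityCurve(
        M_v=grid, M_wb=m_wb, rho_b=rho_b, eps_water=eps_w, eps_eff=eps,
        model="two-phase", params=_echo(spec),
    )


def _three_phase_point(
    spec: GrainSpec,
    m_v: float,
    phi_b: float,
    eps_w: float,
    ordering: str,
) -> float:
    """Confocal three-phase permittivity at one grid point."""
    if m_v == 0.0:
        # No water phase: every ordering degenerates to the dry pack.
        return _dry_pack_permittivity(spec, phi_b)
    n = depolarization_factors(spec.aspect)
    fr = configuration_volume_fractions(phi_b, m_v, ordering)
    eps_of = {"S": spec.eps_s, "W": eps_w, "A": spec.eps_a}
    eps_1 = eps_of[fr.shell]
    eps_2 = eps_of[fr.core]
    if fr.phi_1 == 0.0:
        eps_1 = eps_2  # zero-thickness shell: its permittivity cancels exactly
    if fr.phi_2 == 0.0:
        eps_2 = eps_1
    conf = ConfocalSpec(
        eps_0=eps_of[fr.background],
        eps_1=eps_1,
        eps_2=eps_2,
        phi_1=fr.phi_1,
        phi_2=fr.phi_2,
        N1=n,
        N2=n,
    )
    return float(confocal_three_phase(conf))


def three_phase_grain_curve(
    spec: GrainSpec,
    M_v_grid: Sequence[float] | np.ndarray,
    ordering: str = "SWA",
) -> PermittivityCurve:
    """Three-phase confocal model under a solid/water/air configuration.

    The ordering tag reads core -> shell -> background, so ``"SWA"``
    places the solid in the core, water as the shell coating it and air
    as the background.  Configurations with water outermost yield the
    highest permittivity at a given moisture; water buried in the core
    yields the lowest.
    """
    grid = np.asarray(M_v_grid, dtype=float)
    m_wb = np.empty_like(grid)
    rho_b = np.empty_like(grid)
    eps_w = np.empty_like(grid)
    eps = np.empty_like(grid)
    for i, m_v in enumerate(grid):
        m_wb[i], rho_b[i], phi_b, eps_w[i] = _point_quantities(spec, float(m_v))
        eps[i] = _three_phase_point(spec, float(m_v), phi_b, eps_w[i], ordering)
    return PermittivityCurve(
        M_v=grid, M_wb=m_wb, rho_b=rho_b, eps_water=eps_w, eps_eff=eps,
        model="three-phase", ordering=ordering.upper(), params=_echo(spec),
    )


def high_moisture_corn_curve(
    spec: GrainSpec, M_v_grid: Sequence[float] | np.ndarray
) -> PermittivityCurve:
    """SWA/WSA effective-medium blend for high-moisture grain.

    Water up to the critical moisture M_c coats the solid (SWA); water
    added beyond M_c embeds in the solid core (WSA).  The two
    configuration permittivities are combined with the symmetric
    Bruggeman effective-medium rule using fractions
    ``f_swa = min(1, M_c/M_v)``.  Below M_c the curve equals the pure SWA
    model; above it the slope relaxes toward the WSA curve, matching the
    reduced permittivity rise measured in wet corn.
    """
    if spec.M_c is None:
        raise ValueError(f"{spec.name!r} has no critical moisture M_c set")
    grid = np.asarray(M_v_grid, dtype=float)
    m_wb = np.empty_like(grid)
    rho_b = np.empty_like(grid)
    eps_w = np.empty_like(grid)
    eps = np.empty_like(grid)
    for i, m_v in enumerate(grid):
        m_wb[i], rho_b[i], phi_b, eps_w[i] = _point_quantities(spec, float(m_v))
        f_swa, f_wsa = swa_fraction(float(m_v), spec.M_c)
        e_swa = _three_phase_point(spec, float(m_v), phi_b, eps_w[i], "SWA")
        if f_wsa == 0.0:
            eps[i] = e_swa
        else:
            e_wsa = _three_phase_point(spec, float(m_v), phi_b, eps_w[i], "WSA")
            eps[i] = ema_blend(e_swa, e_wsa, f_swa, f_wsa)
    return PermittivityCurve(
        M_v=grid, M_wb=m_wb, rho_b=rho_b, eps_water=eps_w, eps_eff=eps,
        model="ema", ordering="SWA/WSA", params=_echo(spec),
    )


def stepped_surface_area_curve(
    spec: GrainSpec,
    M_v_grid: Sequence[float] | np.ndarray,
    A_s_high: float = 4.0e4,
) -> PermittivityCurve:
    """Legacy stepped-surface-area model for comparison with the blend.

    Holds the SWA configuration throughout but steps the surface area up
    to ``A_s_high`` beyond M_c, adding only the incremental (volume-
    weighted) water-phase permittivity to the value at M_c.  Kept as a
    comparison mode; the effective-medium blend is the preferred model.
    """
    if spec.M_c is None:
        raise ValueError(f"{spec.name!r} has no critical moisture M_c set")
    grid = np.asarray(M_v_grid, dtype=float)
    hi = replace(spec, A_s=A_s_high)
    m_wb = np.empty_like(grid)
    rho_b = np.empty_like(grid)
    eps_w = np.empty_like(grid)
    eps = np.empty_like(grid)
    _, rho_b_c, phi_b_c, eps_w_c = _point_quantities(spec, spec.M_c)
    eps_at_mc = _three_phase_point(spec, spec.M_c, phi_b_c, eps_w_c, "SWA")
    eps_w_hi_c = _water_eps(hi, spec.M_c, rho_b_c)
    for i, m_v in enumerate(grid):
        m_wb[i], rho_b[i], phi_b, eps_w[i] = _point_quantities(spec, float(m_v))
        if m_v <= spec.M_c:
            eps[i] = _three_phase_point(spec, float(m_v), phi_b, eps_w[i], "SWA")
        else:
            eps_w_hi = _water_eps(hi, float(m_v), rho_b[i])
            eps[i] = eps_at_mc + (m_v * eps_w_hi - spec.M_c * eps_w_hi_c)
    return PermittivityCurve(
        M_v=grid, M_wb=m_wb, rho_b=rho_b, eps_water=eps_w, eps_eff=eps,
        model="as-step", ordering="SWA", params=_echo(spec) | {"A_s_high": A_s_high},
    )


def _echo(spec: GrainSpec) -> dict:
    return {
        "name": spec.name,
        "aspect": spec.aspect,
        "rho_s": spec.rho_s,
        "eps_s": spec.eps_s,
        "eps_a": spec.eps_a,
        "A_s": spec.A_s,
        "T": spec.T,
        "k": spec.k,
        "M_c": spec.M_c,
        "rho_b": spec.rho_b,
        "f_star": spec.water_params.f_star,
        "r": spec.water_params.r,
    }
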