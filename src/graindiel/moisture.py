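"""Moisture-basis conversions and kernel/bulk density and porosity models.

Grain moisture is reported on three bases: wet basis (g water per g wet
matter), dry basis (g water per g dry matter) and volumetric (m³ water per
m³ bulk sample).  Dielectric mixture theory works with volumetric
fractions, so the conversions here — linked through the grain bulk density
``rho_b`` and the free-water density ``rho_w`` — sit under every
permittivity pipeline in this package.

Densities are carried in g cm⁻³ internally; the CLI converts from kg m⁻³
at its boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .shape import shape_ratio

__all__ = [
    "MoistureState",
    "KernelState",
    "CompositionEntry",
    "PorositySet",
    "DryingCurvePoint",
    "convert_moisture",
    "kernel_density_from_constituents",
    "kernel_density_vs_moisture",
    "bulk_porosity",
    "bulk_density_model",
    "relative_moisture",
]

MoistureBasis = Literal["wet", "dry", "volumetric"]


@dataclass(frozen=True)
class MoistureState:
    """One moisture observation on all three bases simultaneously.

    Invariants (enforced by :func:`convert_moisture`):
    ``M_db = M_wb/(1 - M_wb)`` and ``M_v = M_db * rho_b / rho_w``.
    """

    M_wb: float
    M_db: float
    M_v: float
    rho_b: float
    rho_w: float = 1.0


@dataclass(frozen=True)
class KernelState:
    """Mass/volume bookkeeping of a single kernel: solids plus water."""

    rho_s: float
    m_s: float
    m_w: float
    V_s: float
    V_w: float

    @property
    def rho_k(self) -> float:
        return (self.m_s + self.m_w) / (self.V_s + self.V_w)


@dataclass(frozen=True)
class CompositionEntry:
    """One kernel constituent: label, mass fraction and solid density."""

    name: str
    x_i: float
    rho_i: float


@dataclass(frozen=True)
class PorositySet:
    """Inter-kernel (bulk) and intra-kernel porosities."""

    phi_b: float
    phi_k: float = 0.0

    def __post_init__(self) -> None:
        for label, value in (("phi_b", self.phi_b), ("phi_k", self.phi_k)):
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{label} must lie in [0, 1); got {value}")


@dataclass(frozen=True)
class DryingCurvePoint:
    """A drying observation normalized between initial and equilibrium moisture."""

    M_db: float
    M_i: float
    M_e: float
    M_dr: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "M_dr", relative_moisture(self.M_db, self.M_i, self.M_e))


def convert_moisture(
    value: float,
    basis: MoistureBasis,
    rho_b: float,
    rho_w: float = 1.0,
) -> MoistureState:
    """Populate all three moisture bases from a single observation.

    Parameters
    ----------
    value : moisture content on the given basis (mass or volume fraction).
    basis : ``"wet"``, ``"dry"`` or ``"volumetric"``.
    rho_b : grain bulk density, g cm⁻³.
    rho_w : free-water density, g cm⁻³ (default 1.0).
    """
    if rho_b <= 0:
        raise ValueError(f"rho_b must be positive; got {rho_b}")
    if rho_w <= 0:
        raise ValueError(f"rho_w must be positive; got {rho_w}")
    if value < 0:
        raise ValueError(f"moisture ({basis}) must be non-negative; got {value}")

    if basis == "wet":
        if value >= 1.0:
            raise ValueError(f"M_wb must satisfy 0 <= M_wb < 1; got {value}")
        m_wb = value
        m_db = m_wb / (1.0 - m_wb)
        m_v = m_db * rho_b / rho_w
    elif basis == "dry":
        m_db = value
        m_wb = m_db / (1.0 + m_db)
        m_v = m_db * rho_b / rho_w
    elif basis == "volumetric":
        if value > 1.0:
            raise ValueError(f"M_v must satisfy 0 <= M_v <= 1; got {value}")
        m_v = value
        m_db = m_v * rho_w / rho_b
        m_wb = m_db / (1.0 + m_db)
    else:  # pragma: no cover - typing guards this
        raise ValueError(f"unknown moisture basis {basis!r}")

    if m_v > 1.0:
        raise ValueError(
            f"resulting volumetric moisture M_v = {m_v:.4f} exceeds 1; "
            "check rho_b and the input basis"
        )
    return MoistureState(M_wb=m_wb, M_db=m_db, M_v=m_v, rho_b=rho_b, rho_w=rho_w)


def kernel_density_from_constituents(
    comp: Sequence[CompositionEntry] | Iterable[CompositionEntry],
    *,
    normalize: bool = False,
    tol: float = 1e-6,
) -> float:
    """Kernel solid density as the harmonic mean of constituent densities.

    ``rho_k = 1 / sum(x_i / rho_i)``.  Mass fractions must sum to 1 within
    ``tol`` unless ``normalize`` is set, in which case they are re-scaled
    (published composition tables often omit minor constituents).
    """
    entries = list(comp)
    if not entries:
        raise ValueError("composition must contain at least one constituent")
    for e in entries:
        if e.x_i < 0:
            raise ValueError(f"mass fraction of {e.name!r} is negative: {e.x_i}")
        if e.rho_i <= 0:
            raise ValueError(f"density of {e.name!r} must be positive: {e.rho_i}")
    total = sum(e.x_i for e in entries)
    if normalize:
        entries = [CompositionEntry(e.name, e.x_i / total, e.rho_i) for e in entries]
    elif abs(total - 1.0) > tol:
        raise ValueError(
            f"constituent mass fractions sum to {total:.6f}, not 1 "
            "(pass normalize=True to re-scale)"
        )
    return 1.0 / sum(e.x_i / e.rho_i for e in entries)


def kernel_density_vs_moisture(rho_s: float, M_wb: float, rho_w: float = 1.0) -> float:
    """Moist-kernel density from the dry-solid density.

    ``rho_k = rho_s / (1 + (rho_s/rho_w - 1) * M_wb)`` — the solids dilute
    toward water density as moisture rises; equals ``rho_s`` when dry.
    """
    if not 0.0 <= M_wb < 1.0:
        raise ValueError(f"M_wb must lie in [0, 1); got {M_wb}")
    if rho_s <= 0 or rho_w <= 0:
        raise ValueError("densities must be positive")
    return rho_s / (1.0 + (rho_s / rho_w - 1.0) * M_wb)


def bulk_porosity(rho_b: float, rho_k: float) -> float:
    """Inter-kernel porosity ``phi_b = 1 - rho_b / rho_k``."""
    if rho_b <= 0 or rho_k <= 0:
        raise ValueError("densities must be positive")
    if rho_b > rho_k:
        raise ValueError(
            f"bulk density ({rho_b}) exceeds kernel density ({rho_k}); "
            "porosity would be negative"
        )
    return 1.0 - rho_b / rho_k


def bulk_density_model(
    rho_s: float,
    M_wb: float,
    aspect: float,
    k: float,
    rho_w: float = 1.0,
) -> float:
    """Bulk density of a grain pack from solid density, moisture and shape.

    Combines the moist-kernel density with the spheroid volume/surface
    shape ratio R(a/b) and an empirical packing coefficient ``k``:

    ``rho_b = k * rho_s * R(a/b) / (1 + (rho_s/rho_w - 1) * M_wb)``

    which is identically ``k * rho_k(M_wb) * R(a/b)``, so the implied bulk
    porosity ``1 - k*R`` is moisture-independent.
    """
    if k < 0:
        raise ValueError(f"packing coefficient k must be non-negative; got {k}")
    ratio = shape_ratio(aspect)  # validates the aspect range
    rho_k = kernel_density_vs_moisture(rho_s, M_wb, rho_w)
    return k * rho_k * ratio


def relative_moisture(M_db: float, M_i: float, M_e: float) -> float:
    """Dry-basis relative moisture ``(M_db - M_e) / (M_i - M_e)``.

    Normalizes a drying curve between its initial (``M_i``) and
    equilibrium (``M_e``) dry-basis moisture contents.
    """
    if math.isclose(M_i, M_e):
        raise ZeroDivisionError("M_i equals M_e; relative moisture is undefined")
    return (M_db - M_e) / (M_i - M_e)
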