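"""Water-binding surface-area estimators.

The water-accessible surface area A_s (m² g⁻¹) controls how much of a
grain's water is bound.  Three independent estimators are provided:

* protein accessible area scaled from molecular weight, summed over the
  four seed-protein classes (albumin, globulin, prolamin, glutelin);
* an empirical monolayer-moisture fit in protein and carbohydrate content;
* back-calculation of A_s from a measured monolayer water content via the
  molecular packing of the first water layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "AVOGADRO",
    "ProteinClassEntry",
    "MonolayerSpec",
    "protein_accessible_area",
    "protein_specific_surface",
    "monolayer_moisture_empirical",
    "molecular_spacing",
    "monolayer_area_constant",
    "surface_area_from_monolayer",
]

AVOGADRO = 6.022e23  # molecules per mole

K_TETRAHEDRAL = 28.21  # g Å³ cm⁻³, tetrahedral water packing
K_CUBIC = 29.92        # g Å³ cm⁻³, cubic water packing


@dataclass(frozen=True)
class ProteinClassEntry:
    """One seed-protein class: mass fraction within total protein and MW."""

    name: str
    MW: float        # molecular weight, g mol⁻¹
    f_i: float       # mass fraction of this class within total protein

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ValueError(f"molecular weight of {self.name!r} must be positive")
        if self.f_i < 0:
            raise ValueError(f"fraction of {self.name!r} must be non-negative")

    @property
    def M_i(self) -> float:
        """Molecular mass, g per molecule."""
        return self.MW / AVOGADRO


@dataclass(frozen=True)
class MonolayerSpec:
    """Monolayer water density and packing for surface-area back-calculation.

    rho_ml defaults to 1.48 g cm⁻³ (monolayer water is denser than free
    water); K_p to the tetrahedral packing constant.
    """

    rho_ml: float = 1.48
    K_p: float = K_TETRAHEDRAL

    def __post_init__(self) -> None:
        if self.rho_ml <= 0 or self.K_p <= 0:
            raise ValueError("rho_ml and K_p must be positive")


def protein_accessible_area(MW: float) -> float:
    """Water-accessible surface area of a protein molecule, Å² per molecule.

    Empirical two-thirds-power scaling ``A_a = 11.12 * MW^(2/3)``: surface
    grows like the molecule's outer area while mass fills its volume.
    """
    if MW <= 0:
        raise ValueError(f"molecular weight must be positive; got {MW}")
    return 11.12 * MW ** (2.0 / 3.0)


def protein_specific_surface(
    classes: Sequence[ProteinClassEntry] | Iterable[ProteinClassEntry],
    kernel_protein_fraction: float | None = None,
) -> float | tuple[float, float]:
    """Specific surface area of a grain's protein complement, m² g⁻¹.

    ``A_s = sum_i A_a(MW_i) * f_i / M_i`` with the per-molecule area in Å²
    converted to m².  Class fractions are normalized to sum to 1
    (published tables sometimes omit a few percent).

    When ``kernel_protein_fraction`` (percent of kernel mass that is
    protein) is given, returns ``(protein_only, within_kernel)``.
    """
    entries = list(classes)
    if not entries:
        raise ValueError("at least one protein class is required")
    total = sum(e.f_i for e in entries)
    if total <= 0:
        raise ValueError("protein class fractions sum to zero")
    protein_only = sum(
        protein_accessible_area(e.MW) * (e.f_i / total) / e.M_i for e in entries
    ) * 1e-20  # Å² -> m²
    if kernel_protein_fraction is None:
        return protein_only
    return protein_only, protein_only * kernel_protein_fraction / 100.0


def monolayer_moisture_empirical(P: float, C: float) -> float:
    """Monolayer (primary hydration) moisture content, g g⁻¹ dry basis.

    Empirical fit in protein content P and carbohydrate content C, both in
    percent of dry mass: ``exp(0.612 - 3.06e-5 P^3 - 4.03e-5 C^2.5)``.
    The underlying data span roughly 0.1–0.35 g g⁻¹; outputs outside
    [0, 0.5] carry an extrapolation warning.
    """
    if P < 0 or C < 0:
        raise ValueError("P and C must be non-negative percentages")
    m_ml = math.exp(0.612 - 3.06e-5 * P**3 - 4.03e-5 * C**2.5)
    if not 0.0 <= m_ml <= 0.5:
        warnings.warn(
            f"monolayer moisture {m_ml:.3f} g/g lies outside the fitted data "
            "range (~0.1-0.35); treat as extrapolation",
            stacklevel=2,
        )
    return m_ml


def molecular_spacing(rho: float, K_p: float = K_TETRAHEDRAL) -> float:
    """Water molecule spacing in Å from density and packing constant.

    ``s = (K_p / rho)^(1/3)`` with rho in g cm⁻³.  Free water under
    tetrahedral packing gives 3.04 Å; the denser monolayer (1.48 g cm⁻³)
    packs at 2.67 Å.
    """
    if rho <= 0:
        raise ValueError(f"water density must be positive; got {rho}")
    if K_p <= 0:
        raise ValueError(f"packing constant must be positive; got {K_p}")
    return (K_p / rho) ** (1.0 / 3.0)


def monolayer_area_constant(spec: MonolayerSpec = MonolayerSpec()) -> float:
    """Multiplier converting monolayer moisture (g g⁻¹ db) to A_s (m² g⁻¹).

    Derived from first principles: each monolayer molecule occupies s² =
    (K_p/rho_ml)^(2/3) Å² of surface and weighs K_p x 10⁻²⁴ g, giving

    ``A_s / M_ml = 1e4 / (rho_ml^(2/3) * K_p^(1/3))``

    ≈ 2529 m² g⁻¹ with the default monolayer density and tetrahedral
    packing.
    """
    return 1e4 / (spec.rho_ml ** (2.0 / 3.0) * spec.K_p ** (1.0 / 3.0))


def surface_area_from_monolayer(
    M_ml: float,
    spec: MonolayerSpec = MonolayerSpec(),
) -> float:
    """Specific surface area from a measured monolayer water content."""
    if M_ml < 0:
        raise ValueError(f"monolayer moisture must be non-negative; got {M_ml}")
    return M_ml * monolayer_area_constant(spec)
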