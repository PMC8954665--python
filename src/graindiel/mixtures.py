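"""Dielectric mixture models.

The effective permittivity of a grain pack is approximated from the
permittivities and volume fractions of its phases (solid, water, air)
arranged in an assumed geometry:

* Maxwell-Garnett / Clausius-Mossotti two-phase inclusions;
* a generalized ellipsoidal-inclusion family whose ``nu`` parameter
  selects Maxwell-Garnett (nu = 0), Polder-van Santen (nu = 1 - N per
  axis) or the coherent-potential rule (nu = 1);
* a three-phase confocal (core-shell-background) ellipsoid model with
  the six solid/water/air phase configurations (SWA, WSA, ...);
* the deLoor/Dobson four-phase formula with disk-like bound/free water
  and air inclusions in a solid host;
* a symmetric two-component Bruggeman (effective-medium) blend used to
  mix the SWA and WSA configurations above a critical moisture.

Complex permittivities (loss factor as negative imaginary part) are
accepted throughout; real inputs return real outputs.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Literal

from scipy.optimize import brentq

from .shape import DepolarizationTriple

__all__ = [
    "MixturePhase",
    "ConfocalSpec",
    "FourPhaseSpec",
    "PhaseConfiguration",
    "ConfigurationFractions",
    "maxwell_garnett",
    "generalized_ellipsoid_mixture",
    "confocal_three_phase",
    "deloor_four_phase",
    "configuration_volume_fractions",
    "swa_fraction",
    "ema_blend",
    "PHASE_ORDERINGS",
]

Number = complex | float

NuMode = Literal["maxwell_garnett", "polder_van_santen", "coherent_potential"]

SPHERE = DepolarizationTriple(N_p=1.0 / 3.0, N_n=1.0 / 3.0)

PHASE_ORDERINGS = ("SWA", "WSA", "ASW", "AWS", "SAW", "WAS")


def _maybe_real(value: complex) -> Number:
    """Collapse to float when the imaginary part is numerically zero."""
    if abs(value.imag) < 1e-12 * max(1.0, abs(value.real)):
        return value.real
    return value


@dataclass(frozen=True)
class MixturePhase:
    """A mixture constituent: label, permittivity, volume fraction."""

    label: str
    eps: Number
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"volume fraction of {self.label!r} must be in [0, 1]")


@dataclass(frozen=True)
class ConfocalSpec:
    """Inputs of the three-phase confocal ellipsoid model.

    eps_0/eps_1/eps_2 are background/shell/core permittivities; phi_1 and
    phi_2 the shell and core volume fractions; N1 and N2 the
    depolarization triples of the outer and inner ellipsoids.
    """

    eps_0: Number
    eps_1: Number
    eps_2: Number
    phi_1: float
    phi_2: float
    N1: DepolarizationTriple = SPHERE
    N2: DepolarizationTriple = SPHERE

    def __post_init__(self) -> None:
        if self.phi_1 < 0 or self.phi_2 < 0:
            raise ValueError("confocal volume fractions must be non-negative")
        if self.phi_1 + self.phi_2 > 1.0 + 1e-12:
            raise ValueError(
                f"phi_1 + phi_2 = {self.phi_1 + self.phi_2:.6f} exceeds 1"
            )


@dataclass(frozen=True)
class FourPhaseSpec:
    """Inputs of the four-phase (solid host) mixture formula."""

    eps_s: Number
    eps_fw: Number
    eps_bw: Number
    eps_a: Number
    phi_fw: float
    phi_bw: float
    phi_a: float

    def __post_init__(self) -> None:
        if min(self.phi_fw, self.phi_bw, self.phi_a) < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.phi_fw + self.phi_bw + self.phi_a > 1.0 + 1e-12:
            raise ValueError("inclusion volume fractions exceed 1")


@dataclass(frozen=True)
class PhaseConfiguration:
    """Blend state of two confocal phase configurations at one moisture."""

    ordering: str
    M_c: float
    f_swa: float
    f_wsa: float

    def __post_init__(self) -> None:
        if sorted(self.ordering) != ["A", "S", "W"]:
            raise ValueError(f"ordering must permute 'SWA'; got {self.ordering!r}")
        if abs(self.f_swa + self.f_wsa - 1.0) > 1e-12:
            raise ValueError("f_swa + f_wsa must equal 1")


@dataclass(frozen=True)
class ConfigurationFractions:
    """Core/shell/background volume fractions with their phase roles."""

    ordering: str
    phi_2: float          # core
    phi_1: float          # shell
    phi_0: float          # background
    core: str             # one of 'S', 'W', 'A'
    shell: str
    background: str


def maxwell_garnett(eps_0: Number, eps_1: Number, phi_1: float) -> Number:
    """Two-phase Maxwell-Garnett permittivity for spherical inclusions.

    Explicit solution of the Clausius-Mossotti relation
    ``(e - e0)/(e + 2 e0) = phi_1 (e1 - e0)/(e1 + 2 e0)``; exact at the
    dilute limit, recovers eps_0 at phi_1 = 0 and eps_1 at phi_1 = 1.
    """
    if not 0.0 <= phi_1 <= 1.0:
        raise ValueError(f"phi_1 must lie in [0, 1]; got {phi_1}")
    q = phi_1 * (eps_1 - eps_0) / (eps_1 + 2.0 * eps_0)
    return _maybe_real(complex(eps_0) * (1.0 + 2.0 * q) / (1.0 - q))


def _generalized_rhs(
    eps_eff: Number,
    eps_0: Number,
    eps_1: Number,
    phi_1: float,
    N: DepolarizationTriple,
    nu_axes: tuple[float, float, float],
) -> complex:
    """One evaluation of the generalized ellipsoid mixture right-hand side."""
    num = 0.0 + 0.0j
    den = 1.0 + 0.0j
    delta = complex(eps_1) - complex(eps_0)
    for n_i, nu_i in zip(N.axes, nu_axes):
        apparent = complex(eps_0) + nu_i * (complex(eps_eff) - complex(eps_0))
        d_i = apparent + n_i * delta
        num += phi_1 * delta * apparent / (3.0 * d_i)
        den -= phi_1 * n_i * delta / (3.0 * d_i)
    return complex(eps_0) + num / den


def generalized_ellipsoid_mixture(
    eps_0: Number,
    eps_1: Number,
    phi_1: float,
    N: DepolarizationTriple = SPHERE,
    nu_mode: NuMode = "maxwell_garnett",
    *,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> Number:
    """Isotropic mixture of aligned-axis-averaged ellipsoidal inclusions.

    Sums the polarizability over the three spheroid axes with
    depolarization triple ``N``.  ``nu_mode`` selects the family member:
    ``"maxwell_garnett"`` (nu = 0, explicit), ``"polder_van_santen"``
    (nu = 1 - N per axis) or ``"coherent_potential"`` (nu = 1); the latter
    two are implicit in eps_eff and solved by damped fixed-point iteration
    (damping 0.5), with a bisection fallback for real inputs.
    """
    if not 0.0 <= phi_1 <= 1.0:
        raise ValueError(f"phi_1 must lie in [0, 1]; got {phi_1}")
    if nu_mode == "maxwell_garnett":
        nu_axes = (0.0, 0.0, 0.0)
    elif nu_mode == "polder_van_santen":
        nu_axes = tuple(1.0 - n for n in N.axes)  # type: ignore[assignment]
    elif nu_mode == "coherent_potential":
        nu_axes = (1.0, 1.0, 1.0)
    else:
        raise ValueError(f"unknown nu_mode {nu_mode!r}")

    if nu_mode == "maxwell_garnett":
        return _maybe_real(_generalized_rhs(eps_0, eps_0, eps_1, phi_1, N, nu_axes))

    eps = complex(eps_0)
    for _ in range(max_iter):
        nxt = _generalized_rhs(eps, eps_0, eps_1, phi_1, N, nu_axes)
        step = nxt - eps
        eps = eps + 0.5 * step
        if abs(step) < tol:
            return _maybe_real(eps)

    # Fixed point failed to settle; bracket the root for real inputs.  The
    # residual can have poles inside [eps_0, eps_1], so scan for a clean
    # sign change rather than trusting the endpoints.
    if isinstance(eps_0, (int, float)) and isinstance(eps_1, (int, float)):
        lo, hi = sorted((float(eps_0), float(eps_1)))
        # In the concentrated regime the implicit rules (notably the
        # coherent potential) can place their root slightly outside the
        # constituent range; scan a widened bracket and report the root.
        lo, hi = max(1e-6, 0.2 * lo), 5.0 * hi

        def residual(e: float) -> float:
            return _generalized_rhs(e, eps_0, eps_1, phi_1, N, nu_axes).real - e

        grid = [lo + (hi - lo) * j / 2000 for j in range(2001)]
        values = []
        for e in grid:
            try:
                values.append(residual(e))
            except ZeroDivisionError:
                values.append(math.nan)
        for (e_a, r_a), (e_b, r_b) in zip(zip(grid, values), zip(grid[1:], values[1:])):
            if math.isfinite(r_a) and math.isfinite(r_b) and r_a * r_b <= 0:
                return float(brentq(residual, e_a, e_b, xtol=tol))
    raise ArithmeticError(
        f"generalized mixture iteration did not converge after {max_iter} "
        f"iterations; last residual {abs(step):.3g}"
    )


def confocal_three_phase(spec: ConfocalSpec) -> Number:
    """Effective permittivity of a dual confocal-ellipsoid mixture.

    A core (eps_2) inside a shell (eps_1) embedded in a background
    (eps_0), summed isotropically over the three spheroid axes.  Collapses
    to the two-phase ellipsoidal Maxwell-Garnett form when the core
    matches the shell or when phi_2 = 0.
    """
    e0 = complex(spec.eps_0)
    e1 = complex(spec.eps_1)
    e2 = complex(spec.eps_2)
    phi = spec.phi_1 + spec.phi_2
    if phi == 0.0:
        return _maybe_real(e0)
    core_ratio = spec.phi_2 / phi
    sum_a = 0.0 + 0.0j
    sum_na = 0.0 + 0.0j
    for n1, n2 in zip(spec.N1.axes, spec.N2.axes):
        inner_den = e1 + n2 * (e2 - e1)
        if inner_den == 0:
            raise ArithmeticError(
                "vanishing inner denominator in the confocal polarizability"
            )
        inner = (e2 - e1) * core_ratio / inner_den
        num = (e1 - e0) + (e1 + n1 * (e0 - e1)) * inner
        den = (e0 + n1 * (e1 - e0)) + n1 * (1.0 - n1) * (e1 - e0) * inner
        if den == 0:
            raise ArithmeticError(
                "vanishing outer denominator in the confocal polarizability"
            )
        a_i = phi * num / den
        sum_a += a_i
        sum_na += n1 * a_i
    blocker = 1.0 - sum_na / 3.0
    if blocker == 0:
        raise ArithmeticError("vanishing denominator in the confocal mixture sum")
    return _maybe_real(e0 + (e0 / 3.0) * sum_a / blocker)


def deloor_four_phase(spec: FourPhaseSpec) -> Number:
    """Four-phase mixture: solid host with disk-like water/air inclusions.

    ``eps = [3 es + 2 pfw (efw - es) + 2 pbw (ebw - es) + 2 pa (ea - es)]
    / [3 + pfw (es/efw - 1) + pbw (es/ebw - 1) + pa (es/ea - 1)]``.
    """
    es, efw, ebw, ea = (complex(v) for v in (spec.eps_s, spec.eps_fw, spec.eps_bw, spec.eps_a))
    num = (
        3.0 * es
        + 2.0 * spec.phi_fw * (efw - es)
        + 2.0 * spec.phi_bw * (ebw - es)
        + 2.0 * spec.phi_a * (ea - es)
    )
    den = 3.0 + 0.0j
    for phi, eps in ((spec.phi_fw, efw), (spec.phi_bw, ebw), (spec.phi_a, ea)):
        if phi != 0.0:
            if eps == 0:
                raise ArithmeticError("zero inclusion permittivity with non-zero fraction")
            den += phi * (es / eps - 1.0)
    if den == 0:
        raise ArithmeticError("vanishing denominator in the four-phase formula")
    return _maybe_real(num / den)


def configuration_volume_fractions(
    phi_b: float,
    M_v: float,
    ordering: str,
) -> ConfigurationFractions:
    """Map bulk solid/water/air fractions onto a confocal core/shell/background.

    The unit bulk volume partitions into solid (1 - phi_b), water (M_v)
    and air (phi_b - M_v); the 3-letter ordering tag (read core -> shell
    -> background, e.g. ``"SWA"`` = solid core, water shell, air
    background) assigns each phase its geometric role.  Conservation is
    exact by construction.
    """
    ordering = ordering.upper()
    if ordering not in PHASE_ORDERINGS:
        raise ValueError(
            f"ordering must be one of {PHASE_ORDERINGS}; got {ordering!r}"
        )
    if not 0.0 <= phi_b < 1.0:
        raise ValueError(f"bulk porosity must lie in [0, 1); got {phi_b}")
    if M_v < 0:
        raise ValueError(f"volumetric moisture must be non-negative; got {M_v}")
    if M_v > phi_b + 1e-12:
        raise ValueError(
            f"water exceeds pore space: M_v = {M_v:.4f} > phi_b = {phi_b:.4f}"
        )
    fractions = {"S": 1.0 - phi_b, "W": M_v, "A": max(phi_b - M_v, 0.0)}
    core, shell, background = ordering
    return ConfigurationFractions(
        ordering=ordering,
        phi_2=fractions[core],
        phi_1=fractions[shell],
        phi_0=fractions[background],
        core=core,
        shell=shell,
        background=background,
    )


def swa_fraction(M_v: float, M_c: float) -> tuple[float, float]:
    """Partition of water between the SWA and WSA phase configurations.

    All water up to the critical moisture M_c sits in the SWA (water as
    shell) configuration; water beyond M_c accrues to WSA (water as
    core).  Returns ``(f_swa, f_wsa)`` with ``f_swa = M_c / M_v`` above
    M_c — continuous at the junction.
    """
    if M_v < 0:
        raise ValueError(f"M_v must be non-negative; got {M_v}")
    if M_c <= 0:
        raise ValueError(f"M_c must be positive; got {M_c}")
    if M_v <= M_c:
        return 1.0, 0.0
    f_swa = M_c / M_v
    return f_swa, 1.0 - f_swa


def ema_blend(
    eps_swa: Number,
    eps_wsa: Number,
    f_swa: float,
    f_wsa: float,
) -> Number:
    """Symmetric two-component Bruggeman effective-medium blend.

    Closed form of the root of ``sum_i f_i (eps_i - eps)/(eps_i + 2 eps) = 0``:

    ``eps = beta/4 + sqrt((beta/4)^2 + eps_1 eps_2 / 2)`` with
    ``beta = f_1 (2 eps_1 - eps_2) + f_2 (2 eps_2 - eps_1)``.

    Treats both configurations symmetrically, returns the pure component
    at f = 1 and is invariant under swapping the two (f, eps) pairs.
    """
    if abs(f_swa + f_wsa - 1.0) > 1e-9:
        raise ValueError(f"blend fractions must sum to 1; got {f_swa + f_wsa}")
    if min(f_swa, f_wsa) < 0:
        raise ValueError("blend fractions must be non-negative")
    beta = f_swa * (2.0 * complex(eps_swa) - complex(eps_wsa)) + f_wsa * (
        2.0 * complex(eps_wsa) - complex(eps_swa)
    )
    disc = (beta / 4.0) ** 2 + complex(eps_swa) * complex(eps_wsa) / 2.0
    if disc.imag == 0 and disc.real < 0:
        raise ArithmeticError(
            "negative discriminant in the effective-medium blend for real inputs"
        )
    root = cmath.sqrt(disc)
    # Physical branch: positive real part for passive media.
    if root.real < 0:
        root = -root
    return _maybe_real(beta / 4.0 + root)
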