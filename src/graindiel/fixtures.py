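"""Synthetic grain-parameter generator for tests and demos.

Draws :class:`~graindiel.grain.GrainSpec` records uniformly from the
measured ranges of real cereals and legumes (aspect ratio 0.8–3.3, solid
density 1.34–1.47 g cm⁻³, water-binding surface area 80–990 m² g⁻¹,
solid permittivity 2.5–4).  Each generated spec passes all type
invariants, and a companion table carries independently recomputed
kernel density, bulk porosity and bound-water content for cross-checks.
Generation is bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grain import GrainSpec
from .io import write_grain_spec
from .moisture import kernel_density_vs_moisture
from .shape import porosity_from_shape
from .water import bound_water_content

__all__ = ["FixtureRange", "generate_fixtures", "write_fixtures"]


def _default_ranges() -> dict[str, tuple[float, float]]:
    return {
        "aspect": (0.8, 3.3),
        "rho_s": (1.34, 1.47),
        "A_s": (80.0, 990.0),
        "eps_s": (2.5, 4.0),
        "k": (2.7, 3.1),
        "T": (283.0, 313.0),
        "M_wb_ref": (0.10, 0.25),  # reference moisture for the companion table
    }


@dataclass(frozen=True)
class FixtureRange:
    """Per-parameter (min, max) sampling ranges."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=_default_ranges)

    def __post_init__(self) -> None:
        merged = _default_ranges() | dict(self.ranges)
        for name, (lo, hi) in merged.items():
            if lo > hi:
                raise ValueError(f"range for {name!r} has min > max: ({lo}, {hi})")
        object.__setattr__(self, "ranges", merged)

    def sample(self, name: str, rng: np.random.Generator) -> float:
        lo, hi = self.ranges[name]
        return float(rng.uniform(lo, hi))


def generate_fixtures(
    n: int,
    ranges: FixtureRange | None = None,
    seed: int = 0,
) -> tuple[list[GrainSpec], pd.DataFrame]:
    """Generate ``n`` synthetic grain specs plus a cross-check table.

    The companion DataFrame holds, per spec, the kernel density at the
    reference moisture, the shape-model bulk porosity and the bound
    volumetric water content — each recomputed here, independent of any
    pipeline, so tests can diff the two paths.
    """
    if n < 1:
        raise ValueError(f"fixture count must be >= 1; got {n}")
    ranges = ranges or FixtureRange()
    rng = np.random.default_rng(seed)
    specs: list[GrainSpec] = []
    rows: list[dict] = []
    for i in range(n):
        aspect = ranges.sample("aspect", rng)
        rho_s = ranges.sample("rho_s", rng)
        a_s = ranges.sample("A_s", rng)
        eps_s = ranges.sample("eps_s", rng)
        k = ranges.sample("k", rng)
        temp = ranges.sample("T", rng)
        m_wb = ranges.sample("M_wb_ref", rng)
        spec = GrainSpec(
            name=f"synthetic-{seed}-{i:03d}",
            aspect=aspect,
            rho_s=rho_s,
            eps_s=eps_s,
            A_s=a_s,
            T=temp,
            k=k,
        )
        specs.append(spec)
        rho_k = kernel_density_vs_moisture(rho_s, m_wb)
        phi_b = porosity_from_shape(aspect, k)
        rho_b = (1.0 - phi_b) * rho_k
        rows.append(
            {
                "name": spec.name,
                "aspect": aspect,
                "rho_s": rho_s,
                "A_s": a_s,
                "k": k,
                "T": temp,
                "M_wb_ref": m_wb,
                "rho_k": rho_k,
                "phi_b": phi_b,
                "rho_b": rho_b,
                "M_bw": bound_water_content(temp, a_s, rho_b * 1e6),
            }
        )
    return specs, pd.DataFrame(rows)


def write_fixtures(
    n: int,
    outdir: str | Path,
    ranges: FixtureRange | None = None,
    seed: int = 0,
) -> list[Path]:
    """Generate fixtures and write them as TOML grain files plus a CSV table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs, table = generate_fixtures(n, ranges, seed)
    paths = [
        write_grain_spec(spec, outdir / f"{spec.name}.toml") for spec in specs
    ]
    table_path = outdir / f"fixtures-{seed}.csv"
    with open(table_path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed = {seed}\n")
        table.to_csv(fh, index=False)
    paths.append(table_path)
    return paths
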