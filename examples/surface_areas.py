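"""Three independent routes to the water-binding surface area of grain
constituents: protein molecular weights, measured monolayer moisture,
and idealized constituent geometry."""

from graindiel import (
    HierarchyLevel,
    ProteinClassEntry,
    cumulative_specific_surface,
    monolayer_moisture_empirical,
    protein_specific_surface,
    surface_area_from_monolayer,
)

# 1. From protein class fractions and molecular weights (rice).
rice = [
    ProteinClassEntry("albumin", 12000.0, 0.05),
    ProteinClassEntry("globulin", 320000.0, 0.10),
    ProteinClassEntry("prolamin", 21000.0, 0.05),
    ProteinClassEntry("glutelin", 1e6, 0.80),
]
only, kernel = protein_specific_surface(rice, kernel_protein_fraction=9.0)
print(f"rice protein: {only:.0f} m2/g of protein, {kernel:.0f} m2/g of kernel")

# 2. From a measured monolayer water content (bovine serum albumin).
print(f"BSA monolayer 0.25 g/g -> A_s = {surface_area_from_monolayer(0.25):.0f} m2/g")
# and from composition alone when no measurement exists:
m_ml = monolayer_moisture_empirical(P=12.2, C=76.0)  # wheat-like
print(f"wheat-like composition -> monolayer {m_ml:.3f} g/g "
      f"-> A_s = {surface_area_from_monolayer(m_ml):.0f} m2/g")

# 3. From geometry, down the starch structural hierarchy.
levels = [
    HierarchyLevel("starch grain", "sphere", 1.0e-6),
    HierarchyLevel("large blocklets", "sphere", 2.5e-8),
    HierarchyLevel("small blocklets", "sphere", 1.0e-8),
    HierarchyLevel("amylopectin cluster", "cylinder", 5.0e-9),
    HierarchyLevel("amylopectin/amylose unit cell", "cylinder", 8.0e-10),
]
print("\nstarch hierarchy (A_s and running sum, m2/g):")
for name, a_s, cum in cumulative_specific_surface(levels, rho=1.52e6):
    print(f"  {name:32s} {a_s:7.0f} {cum:7.0f}")
# Water absorbs well into the amylopectin clusters: the cumulative area
# reaches the hundreds of m2/g inferred from monolayer measurements.
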