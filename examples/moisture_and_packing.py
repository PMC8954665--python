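"""Moisture bases and grain packing: convert a wet-basis moisture reading
to the volumetric basis mixture models need, and predict the bulk density
and porosity of a corn pack from kernel shape alone."""

from graindiel import (
    bulk_density_model,
    bulk_porosity,
    convert_moisture,
    kernel_density_vs_moisture,
    porosity_from_shape,
)

# A 20% wet-basis corn sample packed at 0.745 g/cm3.
state = convert_moisture(0.2, "wet", rho_b=0.745)
print(f"M_wb = {state.M_wb:.3f}  M_db = {state.M_db:.3f}  M_v = {state.M_v:.4f}")
# M_v is the water volume per bulk sample volume - the quantity a
# dielectric sensor actually responds to.

# Kernel density falls from the dry-solid value toward water density as
# the kernel wets; the bulk pack follows with a shape-dependent porosity.
rho_k = kernel_density_vs_moisture(rho_s=1.45, M_wb=0.2)
rho_b = bulk_density_model(rho_s=1.45, M_wb=0.2, aspect=1.4, k=3.0)
print(f"kernel density {rho_k:.3f} g/cm3, modeled bulk density {rho_b:.3f} g/cm3")
print(f"pack porosity from shape: {porosity_from_shape(1.4, 3.0):.3f}")
print(f"pack porosity from densities: {bulk_porosity(rho_b, rho_k):.3f}")
# The two porosities agree exactly by construction: the bulk-density
# model is kernel density times the moisture-independent packing factor.
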