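"""The dielectric mixture model family on a wet grain pack: two-phase
inclusions, the confocal core/shell/background geometry, and the
symmetric effective-medium blend."""

from graindiel import (
    ConfocalSpec,
    configuration_volume_fractions,
    confocal_three_phase,
    depolarization_factors,
    ema_blend,
    generalized_ellipsoid_mixture,
    maxwell_garnett,
    swa_fraction,
)

# Solid kernels (eps 3.3) packed at 60% in air:
print(f"Maxwell-Garnett solid-in-air: {maxwell_garnett(1.0, 3.3, 0.6):.3f}")
n = depolarization_factors(1.4)  # corn-kernel spheroid
print(f"same mixture, corn-shaped kernels: "
      f"{generalized_ellipsoid_mixture(1.0, 3.3, 0.6, n):.3f}")

# A three-phase pack: 40% porosity, 10% volumetric water.  Where the
# water sits (shell vs core) changes the answer substantially.
for ordering in ("SWA", "WSA", "ASW"):
    fr = configuration_volume_fractions(phi_b=0.4, M_v=0.10, ordering=ordering)
    eps_of = {"S": 3.3, "W": 78.54, "A": 1.0}
    eps = confocal_three_phase(ConfocalSpec(
        eps_0=eps_of[fr.background], eps_1=eps_of[fr.shell],
        eps_2=eps_of[fr.core], phi_1=fr.phi_1, phi_2=fr.phi_2, N1=n, N2=n,
    ))
    print(f"configuration {ordering} (water as {('core','shell','background')[ordering.index('W')]}): eps = {eps:.3f}")

# Above a critical moisture, added water shifts from the shell (SWA) to
# the core (WSA); the two configurations blend symmetrically:
f_swa, f_wsa = swa_fraction(M_v=0.24, M_c=0.16)
print(f"at M_v = 0.24 (M_c = 0.16): f_swa = {f_swa:.3f}, f_wsa = {f_wsa:.3f}")
print(f"blended permittivity: {ema_blend(5.0, 2.6, f_swa, f_wsa):.3f}")
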