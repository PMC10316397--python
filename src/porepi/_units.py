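"""Unit conventions and physical constants.

The package works in the MD-community unit system: lengths in Å, times in
ps, energies in kcal/mol, temperatures in K, charges in elementary charges
and voltages in volts.  A transmembrane voltage V applied across a box of
height Lz contributes a uniform axial force q*V*EV_TO_KCAL_PER_MOL/Lz
(kcal/mol/Å) on a charge of q elementary charges.
"""

# Boltzmann constant, kcal/mol/K (kB * 300 K = 0.596 kcal/mol)
KB_KCAL_PER_MOL_K = 0.0019872041

# CODATA elementary charge, coulomb
ELEMENTARY_CHARGE_C = 1.602176634e-19

# 1 eV expressed in kcal/mol (e * N_A / 4184)
EV_TO_KCAL_PER_MOL = 23.060548


def thermal_energy(temperature_K: float) -> float:
    """kB*T in kcal/mol."""
    return KB_KCAL_PER_MOL_K * temperature_K
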