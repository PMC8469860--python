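"""Physical constants and unit conversions.

Internal unit system: length in Å, time in fs, mass in amu, energy in
kcal/mol, charge in elementary charges.  All conversions to laboratory
units (GPa, g/cm³, K, bar) happen through the factors below and nowhere
else.
"""

# 1 amu in grams
AMU_G = 1.66053906660e-24

# kinetic-energy conversion: 1 amu·Å²/fs² expressed in kcal/mol
# (1.66053906660e-27 kg · 1e-20 m²/ 1e-30 s² · N_A / 4184 J/kcal)
MVV_TO_KCALMOL = 2390.0573615334906

# Boltzmann constant, kcal/(mol·K)
KB = 0.0019872042586408316

# Coulomb prefactor, kcal·Å/(mol·e²)
COULOMB_K = 332.06371

# 1 kcal/(mol·Å³) in GPa  (4184 / N_A / 1e-30 Pa)
KCAL_A3_TO_GPA = 6.947694845598684

# 1 kcal/(mol·Å³) in bar
KCAL_A3_TO_BAR = KCAL_A3_TO_GPA * 1.0e4

# 1 Pa in kcal/(mol·Å³)
PA_TO_KCAL_A3 = 1.0e-9 / KCAL_A3_TO_GPA

# Bondi van der Waals radii (Å) for the elements that occur in the blends
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
}

# atomic / united-atom masses (amu)
MASS = {
    "H": 1.008,
    "C": 12.011,
    "CH": 13.019,
    "CH2": 14.027,
    "CH3": 15.035,
    "N": 14.007,
    "O": 15.999,
}
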