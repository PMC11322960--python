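"""Internal unit system and physical constants.

Everything inside the package is kcal·mol⁻¹, Å, radians, and elementary
charges. Loaders convert on the way in; nothing downstream re-converts.
"""

# Coulomb constant in kcal·mol⁻¹·Å·e⁻²
COULOMB_CONSTANT = 332.0637

# Unit conversions applied when ingesting quantum-chemistry data.
HARTREE_TO_KCALMOL = 627.5094740631
BOHR_TO_ANGSTROM = 0.529177210903

# Boltzmann constant in kcal·mol⁻¹·K⁻¹
BOLTZMANN_KCALMOL = 0.0019872043

# Default 1-4 nonbonded scaling (small-molecule force-field lineage).
SCALE14_COULOMB = 1.0 / 1.2
SCALE14_LJ = 0.5
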