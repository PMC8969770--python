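"""Physical constants and unit conventions.

All solution concentrations in this package are expressed in micromolar
(uM).  The Langmuir equilibrium constant ``K`` is dimensionless because it
is referenced to the molar concentration of water; that reference enters
the equations only through :data:`WATER_MOLARITY_UM`.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K: float = 1.98720425e-3

#: Molar concentration of water (55.5 M) expressed in uM, the reference
#: concentration that makes the adsorption equilibrium constant dimensionless.
WATER_MOLARITY_UM: float = 55.5e6

#: Default absolute temperature (K) for thermodynamic derivations
#: ("ambient"; configurable everywhere it is used).
DEFAULT_TEMPERATURE_K: float = 293.0
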