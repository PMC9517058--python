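"""Physical constants and unit conventions.

Energies are in kcal/mol throughout the package; collective variables are in
radians (dihedral), reduced length units (encapsulation, bead systems) or a
dimensionless reaction coordinate on [0, 1].  Time in the Langevin sampler is
in reduced units (no mapping to seconds is attempted); printed residence
times taken from tabulated data keep their units of seconds.
"""

KB_KCAL_MOL_K: float = 0.0019872
"""Boltzmann constant in kcal mol^-1 K^-1."""

DEFAULT_TEMPERATURE: float = 300.0
"""Default simulation temperature in kelvin (room conditions)."""

HYDROXIDE_REFERENCE_CONC_M: float = 55.6
"""Reference OH- concentration (mol/L) of the constrained-reactant setup:
an anion permanently at solvation distance from the amide is equivalent to a
solution where every water molecule is replaced by OH- (pure-water molarity)."""


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL_MOL_K * temperature


def beta(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
    return 1.0 / kbt(temperature)
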