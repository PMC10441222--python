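"""Compounds, biomass composition and unit-bearing conversions.

Unit conventions used throughout the package: time in hours, volume in
litres, gas flow in normalised L/h, masses in grams, molar masses in g/mol.
A C-mol is one mole of carbon bound in a compound; carbon-balance arithmetic
is done entirely in C-mol so that substrates, biomass, CO2 and products are
commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Molar volume of an ideal gas at norm conditions [L/mol].
GAS_MOLAR_VOLUME = 22.414

#: Atomic mass of carbon [g/mol].
CARBON_MOLAR_MASS = 12.011

#: Glutamate is assayed as free glutamic acid; multiplying by 1.15 converts
#: the reading to monosodium glutamate (MSG), the form fed to the reactor.
#: Consistent with the anhydrous-MSG/glutamic-acid molar-mass ratio
#: 169.11 / 147.13 = 1.149.
GLUTAMATE_TO_MSG = 1.15

#: OD540 to dry cell weight correlation factor [absorbance per g/L]:
#: DCW = OD540 / 0.586.
OD540_PER_DCW = 0.586


@dataclass(frozen=True)
class Compound:
    """A carbon-bearing compound.

    Parameters
    ----------
    name : str
    molar_mass : float
        g/mol, must be positive.
    carbon_atoms : int
        Carbon atoms per molecule, non-negative.
    """

    name: str
    molar_mass: float
    carbon_atoms: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.carbon_atoms < 0:
            raise ValueError(f"{self.name}: carbon_atoms must be >= 0")


#: Compounds used by the default process. MSG is the anhydrous monosodium
#: salt (the 1.15 assay factor is consistent with this form).
GLUCOSE = Compound("D-glucose", 180.16, 6)
MSG = Compound("monosodium glutamate (anhydrous)", 169.11, 5)
GLUTAMIC_ACID = Compound("L-glutamic acid", 147.13, 5)
TREHALOSE = Compound("trehalose (anhydrous)", 342.30, 12)
CO2 = Compound("carbon dioxide", 44.01, 1)

COMPOUNDS: dict[str, Compound] = {
    "glucose": GLUCOSE,
    "msg": MSG,
    "glutamic_acid": GLUTAMIC_ACID,
    "trehalose": TREHALOSE,
    "co2": CO2,
}


def _biomass_carbon_fraction(c: float = 1.0, h: float = 1.8, o: float = 0.5,
                             n: float = 0.2) -> float:
    """Mass fraction of carbon in a CHON elemental biomass formula."""
    mw = c * 12.011 + h * 1.008 + o * 15.999 + n * 14.007
    return c * 12.011 / mw


@dataclass(frozen=True)
class BiomassComposition:
    """Elemental carbon content of dry biomass.

    The default is the standard microbial composition CH1.8O0.5N0.2
    (carbon fraction 0.4878 g C / g DCW); override via config when a
    measured elemental analysis is available.
    """

    carbon_fraction: float = _biomass_carbon_fraction()
    formula_label: str = "CH1.8O0.5N0.2"

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must be in (0, 1)")


DEFAULT_BIOMASS = BiomassComposition()


def mass_to_cmol(mass: float, compound: Compound) -> float:
    """Convert a mass [g] of a compound to C-mol.

    Raises if the compound carries no carbon (the conversion is undefined)
    or if the mass is negative.
    """
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if compound.carbon_atoms == 0:
        raise ValueError(f"compound {compound.name!r} carries no carbon")
    return mass / compound.molar_mass * compound.carbon_atoms


def cmol_to_mass(cmol: float, compound: Compound) -> float:
    """Inverse of :func:`mass_to_cmol`."""
    if cmol < 0:
        raise ValueError("cmol must be >= 0")
    if compound.carbon_atoms == 0:
        raise ValueError(f"compound {compound.name!r} carries no carbon")
    return cmol * compound.molar_mass / compound.carbon_atoms


def msg_from_glutamate(glutamate_conc: float) -> float:
    """Convert an assayed glutamic-acid concentration [g/L] to MSG [g/L]."""
    if glutamate_conc < 0:
        raise ValueError("glutamate concentration must be >= 0")
    return GLUTAMATE_TO_MSG * glutamate_conc


def dcw_from_od540(od540: float) -> float:
    """Dry cell weight [g/L] from OD540 via the 0.586 correlation factor."""
    if od540 < 0:
        raise ValueError("OD540 must be >= 0")
    return od540 / OD540_PER_DCW


def biomass_to_cmol(mass: float, comp: BiomassComposition = DEFAULT_BIOMASS) -> float:
    """Convert dry biomass [g] to C-mol via its elemental carbon fraction."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    return mass * comp.carbon_fraction / CARBON_MOLAR_MASS
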