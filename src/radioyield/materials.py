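"""Target materials: elemental composition, electron density and the
Bragg-rule mean excitation potential.

A :class:`Material` is a stoichiometric compound (e.g. Yb2O3) with a bulk
density.  From the composition it derives the quantities entering the
Bethe stopping-power formula: the electron density ``n_e`` and the mean
excitation potential ``<I>`` combined across elements with Bragg's
additivity rule,

    ln<I> = sum_i N_i Z_i ln I_i / sum_i N_i Z_i.

Isotopically enriched targets are modelled by giving the element its
actual isotopic molar mass (for a 99% enriched 176Yb target the Yb
molar mass is 175.94 g/mol rather than the natural 173.04 g/mol); this
changes the electron and atom number densities by ~1.5%, which is
resolvable in the printed ranges of the reference scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

from .constants import N_A

__all__ = [
    "Element",
    "Ion",
    "Material",
    "bragg_mean_excitation",
    "ELEMENTS",
    "DEUTERON",
    "yb2o3",
    "yb_metal",
]


@dataclass(frozen=True)
class Element:
    """A chemical element as seen by the stopping-power model.

    Parameters
    ----------
    symbol : str
    Z : int
        Atomic number.
    molar_mass : float
        g/mol.  May be an isotopic mass for enriched targets.
    I : float
        Mean excitation potential, eV.
    """

    symbol: str
    Z: int
    molar_mass: float
    I: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if self.I <= 0:
            raise ValueError(f"mean excitation potential must be positive, got {self.I}")


@dataclass(frozen=True)
class Ion:
    """Projectile ion: charge number and rest energy (MeV)."""

    symbol: str
    z: int
    rest_mass: float

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"charge number must be >= 1, got {self.z}")
        if self.rest_mass <= 0:
            raise ValueError(f"rest mass must be positive, got {self.rest_mass}")


def bragg_mean_excitation(composition: Iterable[Tuple[float, int, float]]) -> float:
    """Bragg-rule mean excitation potential of a compound, in eV.

    Parameters
    ----------
    composition : iterable of (count, Z, I_eV)
        Stoichiometric count, atomic number and mean excitation
        potential of each component element.

    Returns
    -------
    float
        exp( sum N_i Z_i ln I_i / sum N_i Z_i ), eV.  Lies between the
        smallest and largest component I.
    """
    comp = list(composition)
    if not comp:
        raise ValueError("empty composition")
    num = 0.0
    den = 0.0
    for count, Z, I in comp:
        if count < 1:
            raise ValueError(f"stoichiometric count must be >= 1, got {count}")
        if I <= 0:
            raise ValueError(f"mean excitation potential must be positive, got {I}")
        num += count * Z * math.log(I)
        den += count * Z
    return math.exp(num / den)


@dataclass(frozen=True)
class Material:
    """A stoichiometric target material.

    Parameters
    ----------
    name : str
    composition : sequence of (Element, count)
        Stoichiometric formula, e.g. ``[(Yb, 2), (O, 3)]`` for Yb2O3.
    density : float
        Bulk density, g/cm^3.
    """

    name: str
    composition: Tuple[Tuple[Element, int], ...]
    density: float

    def __init__(self, name: str, composition: Sequence[Tuple[Element, int]], density: float):
        if density <= 0:
            raise ValueError(f"density must be positive, got {density}")
        comp = tuple((el, int(n)) for el, n in composition)
        if not comp:
            raise ValueError("empty composition")
        for el, n in comp:
            if n < 1:
                raise ValueError(f"stoichiometric count must be >= 1, got {n}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "composition", comp)
        object.__setattr__(self, "density", density)

    @property
    def molar_mass(self) -> float:
        """Formula-unit molar mass, g/mol."""
        return sum(el.molar_mass * n for el, n in self.composition)

    @property
    def electrons_per_formula(self) -> float:
        return float(sum(el.Z * n for el, n in self.composition))

    @property
    def mean_excitation(self) -> float:
        """Bragg-rule mean excitation potential, eV."""
        return bragg_mean_excitation((n, el.Z, el.I) for el, n in self.composition)

    @property
    def formula_density(self) -> float:
        """Formula units per cm^3."""
        return self.density * N_A / self.molar_mass

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3."""
        return self.formula_density * self.electrons_per_formula

    def atom_number_density(self, symbol: str) -> float:
        """Atoms of the given element per cm^3 (all formula positions counted)."""
        count = sum(n for el, n in self.composition if el.symbol == symbol)
        if count == 0:
            raise KeyError(f"element {symbol!r} not in material {self.name!r}")
        return self.formula_density * count


# -- reference elements and materials ---------------------------------------

#: Elements used by the Lu-177 production scenario.  I values are the
#: elemental mean excitation potentials entering Bragg's rule.
ELEMENTS = {
    "Yb": Element("Yb", 70, 173.04, 684.0),
    "Yb176": Element("Yb", 70, 175.942574, 684.0),
    "O": Element("O", 8, 15.999, 95.0),
}

#: Deuteron projectile (rest energy in MeV).
DEUTERON = Ion("d", 1, 1875.613)


def yb2o3(enriched: bool = True, density: float = 9.2) -> Material:
    """Ytterbium sesquioxide target.

    With ``enriched=True`` (default) the Yb molar mass is that of 176Yb,
    appropriate for the 99% enriched production target; ``enriched=False``
    gives natural-abundance Yb2O3 (M = 394.08 g/mol).
    """
    yb = ELEMENTS["Yb176"] if enriched else ELEMENTS["Yb"]
    tag = "[176Yb]Yb2O3" if enriched else "Yb2O3"
    return Material(tag, [(yb, 2), (ELEMENTS["O"], 3)], density)


def yb_metal(enriched: bool = True, density: float = 6.9) -> Material:
    """Metallic ytterbium target (enriched 176Yb by default)."""
    yb = ELEMENTS["Yb176"] if enriched else ELEMENTS["Yb"]
    tag = "[176Yb]Yb" if enriched else "Yb"
    return Material(tag, [(yb, 1)], density)
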