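"""Nuclide registry: half-lives, molar masses and linear decay links.

The packaged table covers the 176Yb(d,x) production network around
177Lu.  Decay constants are derived once as lambda = ln 2 / t_half.
Metastable isomers are separate nuclides (isomer flag 'm'); isomeric
transition branches are not modelled -- chains are strictly linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

from .constants import to_seconds

__all__ = ["Nuclide", "load_nuclides", "get_nuclide"]


@dataclass(frozen=True)
class Nuclide:
    """One nuclear species (ground state or isomer)."""

    name: str
    element: str
    Z: int
    A: int
    isomer: str  # '', 'g' or 'm'
    half_life_s: Optional[float]  # None if stable
    molar_mass: float  # g/mol
    daughter: Optional[str]  # next chain member, None if stable

    def __post_init__(self) -> None:
        if self.half_life_s is not None and self.half_life_s <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_s}")
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")

    @property
    def stable(self) -> bool:
        return self.half_life_s is None

    @property
    def lam(self) -> float:
        """Decay constant, 1/s (0 for stable nuclides)."""
        if self.half_life_s is None:
            return 0.0
        return math.log(2.0) / self.half_life_s


_REGISTRY: Dict[str, Nuclide] = {}


def load_nuclides() -> Dict[str, Nuclide]:
    """Load (and cache) the packaged nuclide table."""
    if _REGISTRY:
        return _REGISTRY
    text = resources.files("radioyield.data").joinpath("nuclides.csv").read_text()
    header = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split(",")
            continue
        row = dict(zip(header, line.split(",")))
        stable = row["half_life"] == "stable"
        nuc = Nuclide(
            name=row["name"],
            element=row["element"],
            Z=int(row["Z"]),
            A=int(row["A"]),
            isomer=row["isomer"],
            half_life_s=None if stable else to_seconds(float(row["half_life"]), row["half_life_unit"]),
            molar_mass=float(row["molar_mass"]),
            daughter=row["daughter"] or None,
        )
        _REGISTRY[nuc.name] = nuc
    return _REGISTRY


def get_nuclide(name: str) -> Nuclide:
    """Look up a nuclide by name (e.g. 'Lu177g')."""
    reg = load_nuclides()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(f"unknown nuclide {name!r}; known: {', '.join(sorted(reg))}") from None
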