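"""Beam/target activation: flux, production rates and figures of merit.

The integrated beam flux on a target of matching face area is

    phi = epsilon * J / (q * pi r^2)        [ions/cm^2/s]

and the production rate of one reaction channel on a thin (fully
traversed) slab is

    Gamma = eta * epsilon * (J/q) * T * N * <sigma>_T(E)   [atoms/s]

with eta the isotopic enrichment of the active nuclide, T the slab
thickness (cm), N the number density of the active element's atoms
(both Yb sites of an Yb2O3 formula unit counted) and <sigma>_T the
thin-target averaged cross section (cm^2).  The beam area cancels
between flux and target face, so Gamma carries no explicit radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import pandas as pd

from .constants import MB_TO_CM2, Q_E
from .materials import DEUTERON, Ion, Material
from .stopping import ThickTargetError, cutoff_energy, residual_energy, thickness_for_interval
from .xs import ExcitationFunction, ReactionID, XSLibrary, burnup_xs, thin_target_avg_xs

__all__ = [
    "BeamSpec",
    "TargetSpec",
    "RateTable",
    "beam_flux",
    "production_rate",
    "rate_table",
    "figures_of_merit",
    "burnup_rate",
    "time_to_burnup_fraction",
]


@dataclass(frozen=True)
class BeamSpec:
    """Accelerator beam parameters.

    energy in MeV, current in mA, transmission as a fraction of the
    source current delivered to the target, radius in cm (beam area is
    assumed equal to the target face).
    """

    ion: Ion = DEUTERON
    energy: float = 18.0
    current_ma: float = 10.0
    transmission: float = 0.985
    radius_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("beam energy must be positive")
        if self.current_ma < 0:
            raise ValueError("beam current must be non-negative")
        if not 0.0 < self.transmission <= 1.0:
            raise ValueError("transmission must be in (0, 1]")
        if self.radius_cm <= 0:
            raise ValueError("beam radius must be positive")

    @property
    def particle_rate(self) -> float:
        """Ions per second leaving the source, J/q."""
        return self.current_ma * 1e-3 / (Q_E * self.ion.z)


@dataclass(frozen=True)
class TargetSpec:
    """Thin activation target.

    Exactly one of ``thickness_mm`` / ``exit_energy_mev`` is given; the
    other follows from the stopping model for a given beam.
    ``enrichment`` is the fraction of the active nuclide among its
    element's atoms.
    """

    material: Material
    radius_cm: float = 1.0
    thickness_mm: Optional[float] = None
    exit_energy_mev: Optional[float] = None
    enrichment: float = 0.99
    active_element: str = "Yb"

    def __post_init__(self) -> None:
        if (self.thickness_mm is None) == (self.exit_energy_mev is None):
            raise ValueError("specify exactly one of thickness_mm and exit_energy_mev")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")
        if self.radius_cm <= 0:
            raise ValueError("target radius must be positive")

    def resolve(self, beam: BeamSpec) -> Tuple[float, float]:
        """(thickness_mm, exit_energy_mev) for the given beam."""
        if self.thickness_mm is not None:
            e_t = residual_energy(self.material, beam.ion, beam.energy, self.thickness_mm)
            return self.thickness_mm, e_t
        t = thickness_for_interval(self.material, beam.ion, beam.energy, self.exit_energy_mev)
        return t, self.exit_energy_mev

    def active_atoms(self, beam: BeamSpec) -> float:
        """Total atoms of the active (enriched) nuclide in the slab."""
        t_mm, _ = self.resolve(beam)
        volume = math.pi * self.radius_cm**2 * (t_mm / 10.0)  # cm^3
        return self.enrichment * self.material.atom_number_density(self.active_element) * volume


@dataclass
class RateTable:
    """Per-reaction production rates (atoms/s) plus aggregates (reactions/s)."""

    rates: Dict[ReactionID, float]
    non_elastic: Optional[float] = None
    burnup: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": rid.label, "product": rid.product, "rate_atoms_per_s": rate}
            for rid, rate in self.rates.items()
        ]
        return pd.DataFrame(rows)


def beam_flux(beam: BeamSpec, include_transmission: bool = True) -> float:
    """Integrated flux on the target face, ions/cm^2/s."""
    eps = beam.transmission if include_transmission else 1.0
    area = math.pi * beam.radius_cm**2
    return eps * beam.particle_rate / area


def production_rate(
    beam: BeamSpec,
    target: TargetSpec,
    xs: Union[ExcitationFunction, float],
) -> float:
    """Production rate Gamma in atoms/s for one reaction channel.

    ``xs`` is either an excitation function (its thin-target average
    over the slab's energy interval is computed) or a fixed effective
    cross section in mb.
    """
    emin = cutoff_energy(target.material, beam.ion)
    try:
        t_mm, e_t = target.resolve(beam)
    except ThickTargetError as err:
        raise ThickTargetError(
            f"{err} -- production_rate requires the thin-target regime; "
            "use the stopping module to pick a thinner slab"
        ) from None
    if e_t <= emin:
        raise ThickTargetError(
            f"exit energy {e_t:.3f} MeV is below the stopping-model cutoff {emin:.3f} MeV"
        )
    if isinstance(xs, ExcitationFunction):
        sigma_mb = thin_target_avg_xs(xs, target.material, beam.ion, beam.energy, e_t)
    else:
        sigma_mb = float(xs)
    n_active = target.material.atom_number_density(target.active_element)
    return (
        target.enrichment
        * beam.transmission
        * beam.particle_rate
        * (t_mm / 10.0)
        * n_active
        * sigma_mb
        * MB_TO_CM2
    )


def rate_table(beam: BeamSpec, target: TargetSpec, library: XSLibrary) -> RateTable:
    """Production rates for every discrete channel of a library, plus the
    non-elastic and burn-up aggregates when the library carries them."""
    rates: Dict[ReactionID, float] = {}
    non_rate = None
    bu_rate = None
    for rid in library.reactions():
        if rid.ejectiles in ("anything", "d'", "n+p"):
            continue
        rates[rid] = production_rate(beam, target, library[rid])
    if ReactionID("Yb176", "anything", "*") in library:
        non_rate = production_rate(beam, target, library[ReactionID("Yb176", "anything", "*")])
        bu_rate = production_rate(beam, target, burnup_xs(library))
    return RateTable(rates, non_elastic=non_rate, burnup=bu_rate)


def figures_of_merit(
    intervals: Sequence[Tuple[float, float]],
    material: Material,
    xs: ExcitationFunction,
    ion: Ion = DEUTERON,
) -> pd.DataFrame:
    """Target-optimization table for candidate (E, E_T) intervals.

    Columns: slab thickness T (mm), deposited energy dE (MeV), heating
    proxy dE/T (MeV/mm), thin-target average <sigma>_T (mb), yield
    proxy T*<sigma>_T (mm*mb) and efficiency proxy T*<sigma>_T/E
    (mm*mb/MeV).
    """
    rows = []
    for e, e_t in intervals:
        if e_t >= e:
            raise ValueError(f"degenerate interval {e} -> {e_t} MeV (zero-thickness target)")
        t_mm = thickness_for_interval(material, ion, e, e_t)
        sig = thin_target_avg_xs(xs, material, ion, e, e_t)
        rows.append(
            {
                "E_mev": e,
                "E_T_mev": e_t,
                "T_mm": t_mm,
                "dE_mev": e - e_t,
                "dE_per_T_mev_per_mm": (e - e_t) / t_mm,
                "sigma_T_mb": sig,
                "T_sigma_mm_mb": t_mm * sig,
                "T_sigma_per_E_mm_mb_per_mev": t_mm * sig / e,
            }
        )
    return pd.DataFrame(rows)


def burnup_rate(
    beam: BeamSpec, target: TargetSpec, bu_xs: Union[ExcitationFunction, float]
) -> float:
    """Target burn-up rate in reactions/s (rate formula with sigma*)."""
    return production_rate(beam, target, bu_xs)


def time_to_burnup_fraction(
    beam: BeamSpec,
    target: TargetSpec,
    bu_xs: Union[ExcitationFunction, float],
    fraction: float,
) -> float:
    """Days of continuous irradiation to consume the given fraction of
    the active nuclide, from the exponential depletion law
    1 - exp(-phi <sigma>* t) = fraction.

    Returns ``inf`` if the burn-up rate is zero.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rate = burnup_rate(beam, target, bu_xs)
    if rate == 0.0:
        return math.inf
    # per-atom depletion constant phi*sigma* equals rate / initial atoms
    lam = rate / target.active_atoms(beam)
    return -math.log1p(-fraction) / lam / 86400.0
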