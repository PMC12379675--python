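"""Excitation functions and their stopping-power-weighted averages.

An :class:`ExcitationFunction` is one reaction's cross section table
sigma(E) (MeV, mb) with piecewise-linear interpolation, zero below its
grid, and no extrapolation above it.  Averages over the energy interval
spanned inside a target follow two conventions:

* range-averaged <sigma>(E): average over the full slowing-down path of
  an ion that stops in the target,

      <sigma> = int_0^E sigma/S dE' / int_0^E dE'/S

  (the "precise" mode; the "approximate" mode weights by E' instead of
  1/S, which is nearly equivalent because the logarithm in S varies
  slowly);

* thin-target averaged <sigma>_T(E): average over the interval E -> E_T
  spanned while fully traversing a slab of thickness
  T = R(E) - R(E_T),

      <sigma>_T = (1/T) int_{E_T}^E sigma/S dE'.

Integrals are evaluated segment-by-segment between the tabulated energy
nodes with fixed-order Gauss-Legendre quadrature, so results are exact
for the piecewise-linear tables up to the smoothness of 1/S.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy.integrate import fixed_quad

from .materials import Ion, Material
from .stopping import _stopping_mev_per_cm, cutoff_energy

__all__ = [
    "ReactionID",
    "ExcitationFunction",
    "XSLibrary",
    "ExtrapolationError",
    "range_averaged_xs",
    "thin_target_avg_xs",
    "burnup_xs",
    "read_excitation",
    "write_excitation",
]

logger = logging.getLogger(__name__)

_Z_BY_SYMBOL = {"n": 0, "H": 1, "He": 2, "O": 8, "Yb": 70, "Lu": 71, "Hf": 72}

#: ejectile labels that name aggregates rather than particle multisets
_AGGREGATE_EJECTILES = {"anything", "non", "burnup"}


class ExtrapolationError(ValueError):
    """Query above the tabulated energy grid."""


def _parse_nuclide(name: str) -> Tuple[int, int]:
    """'Yb176' or 'Lu177m' -> (Z, A); isomer suffix g/m ignored."""
    m = re.fullmatch(r"([A-Z][a-z]?)(\d+)([gm]?)", name)
    if not m:
        raise ValueError(f"cannot parse nuclide name {name!r}")
    sym, a, _ = m.groups()
    if sym not in _Z_BY_SYMBOL:
        raise ValueError(f"unknown element symbol {sym!r} in nuclide {name!r}")
    return _Z_BY_SYMBOL[sym], int(a)


def _ejectile_balance(label: str) -> Tuple[int, int]:
    """(Z, A) carried away by the ejectile multiset, e.g. '2ng' -> (0, 2).

    Tokens are separated by '+'; each token is an optional multiplicity
    followed by particle symbols drawn from n, p, d, g (gammas carry
    nothing).  A trailing prime (elastic-like re-emission) is ignored.
    """
    z = a = 0
    per_particle = {"n": (0, 1), "p": (1, 1), "d": (1, 2), "g": (0, 0)}
    for token in label.replace("'", "").split("+"):
        m = re.fullmatch(r"(\d*)([npdg]+)", token.strip())
        if not m:
            raise ValueError(f"cannot parse ejectile token {token!r} in {label!r}")
        mult = int(m.group(1) or 1)
        chars = m.group(2)
        dz, da = per_particle[chars[0]]
        z += mult * dz
        a += mult * da
        for c in chars[1:]:
            dz, da = per_particle[c]
            z += dz
            a += da
    return z, a


@dataclass(frozen=True)
class ReactionID:
    """Identifier of one deuteron-induced reaction channel.

    ``target`` and ``product`` are nuclide names like ``'Yb176'`` and
    ``'Lu177g'`` (isomer suffix g/m allowed); ``ejectiles`` is a label
    such as ``'p'``, ``'2ng'``, ``'n+p'`` or the aggregate
    ``'anything'``.  Charge and baryon number balance is validated for
    non-aggregate channels.
    """

    target: str
    ejectiles: str
    product: str

    def __post_init__(self) -> None:
        if self.ejectiles in _AGGREGATE_EJECTILES:
            return
        zt, at = _parse_nuclide(self.target)
        zp, ap = _parse_nuclide(self.product)
        ze, ae = _ejectile_balance(self.ejectiles)
        # projectile is a deuteron: Z=1, A=2
        if (zt + 1, at + 2) != (zp + ze, ap + ae):
            raise ValueError(
                f"unbalanced reaction {self.label}: target+d carries "
                f"(Z={zt + 1}, A={at + 2}) but ejectiles+product carry "
                f"(Z={zp + ze}, A={ap + ae})"
            )

    @property
    def label(self) -> str:
        zt, at = _parse_nuclide(self.target)
        sym_t = self.target.rstrip("0123456789gm")
        return f"{at}{sym_t}(d,{self.ejectiles}){self.product}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class ExcitationFunction:
    """One reaction's sigma(E) table with piecewise-linear interpolation.

    ``energies`` (MeV) must be strictly ascending; ``sigmas`` (mb) are
    non-negative.  Queries below the grid return 0 (below threshold);
    queries above the grid raise :class:`ExtrapolationError`.
    """

    reaction: ReactionID
    energies: np.ndarray
    sigmas: np.ndarray
    provenance: str = "file"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        if e.ndim != 1 or e.size < 2 or e.shape != s.shape:
            raise ValueError("energies and sigmas must be 1-D arrays of equal length >= 2")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly ascending")
        if np.any(s < 0):
            raise ValueError("cross sections must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "sigmas", s)

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    def __call__(self, E):
        """sigma at E (mb); scalar or array."""
        Earr = np.asarray(E, dtype=float)
        if np.any(Earr > self.e_max * (1.0 + 1e-12)):
            raise ExtrapolationError(
                f"energy {np.max(Earr):.4f} MeV is above the tabulated grid of "
                f"{self.reaction.label} (max {self.e_max:.4f} MeV); extrapolation is not allowed"
            )
        out = np.interp(Earr, self.energies, self.sigmas, left=0.0)
        return float(out) if np.isscalar(E) else out


@dataclass
class XSLibrary:
    """A named set of excitation functions, keyed by reaction."""

    name: str
    curves: Dict[ReactionID, ExcitationFunction] = field(default_factory=dict)

    def add(self, xs: ExcitationFunction) -> None:
        if xs.reaction in self.curves:
            raise ValueError(f"reaction {xs.reaction.label} already present in {self.name!r}")
        self.curves[xs.reaction] = xs

    def __getitem__(self, key) -> ExcitationFunction:
        if isinstance(key, ReactionID):
            return self.curves[key]
        for rid, xs in self.curves.items():
            if rid.label == key:
                return xs
        raise KeyError(f"no reaction {key!r} in library {self.name!r}")

    def __contains__(self, key) -> bool:
        try:
            self[key]
        except KeyError:
            return False
        return True

    def find_product(self, product: str) -> ExcitationFunction:
        for rid, xs in self.curves.items():
            if rid.product == product:
                return xs
        raise KeyError(f"no reaction producing {product!r} in library {self.name!r}")

    def reactions(self) -> Tuple[ReactionID, ...]:
        return tuple(self.curves)


# -- quadrature --------------------------------------------------------------


def _segmented_integral(f, a: float, b: float, nodes: np.ndarray, order: int = 12) -> float:
    """Integrate f over [a, b], splitting at the tabulated nodes inside."""
    if b <= a:
        return 0.0
    interior = nodes[(nodes > a) & (nodes < b)]
    edges = np.concatenate(([a], interior, [b]))
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = fixed_quad(f, lo, hi, n=order)
        total += val
    return total


def range_averaged_xs(
    xs: ExcitationFunction,
    material: Material,
    ion: Ion,
    E: float,
    mode: str = "precise",
) -> float:
    """Range-averaged cross section <sigma>(E) in mb, for stopping ions.

    ``mode='precise'`` weights by 1/S(E') over [E_min, E];
    ``mode='approximate'`` weights by E' over [0, E] (the stated
    near-equivalent for slowly varying logarithms).
    """
    emin = cutoff_energy(material, ion)
    if E <= emin:
        raise ValueError(f"energy {E} MeV must exceed the cutoff {emin:.4f} MeV")
    nodes = xs.energies
    if mode == "precise":
        num = _segmented_integral(
            lambda e: xs(e) / _stopping_mev_per_cm(material, ion, e), emin, E, nodes
        )
        den = _segmented_integral(
            lambda e: 1.0 / _stopping_mev_per_cm(material, ion, e), emin, E, nodes
        )
    elif mode == "approximate":
        num = _segmented_integral(lambda e: xs(e) * e, 0.0, E, nodes)
        den = E**2 / 2.0
    else:
        raise ValueError(f"mode must be 'precise' or 'approximate', got {mode!r}")
    return num / den


def thin_target_avg_xs(
    xs: ExcitationFunction,
    material: Material,
    ion: Ion,
    E: float,
    E_T: float,
) -> float:
    """Thin-target averaged cross section <sigma>_T over E -> E_T, in mb.

    Equals (1/T) int_{E_T}^E sigma/S dE' with T = R(E) - R(E_T); for
    E_T at the validity cutoff this reduces to the precise
    range-averaged form.  For E_T = E it degenerates to sigma(E).
    """
    emin = cutoff_energy(material, ion)
    if not (emin < E_T <= E):
        raise ValueError(
            f"invalid interval {E} -> {E_T} MeV: need E_min ({emin:.4f}) < E_T <= E"
        )
    if E_T == E:
        return xs(E)
    nodes = xs.energies
    num = _segmented_integral(
        lambda e: xs(e) / _stopping_mev_per_cm(material, ion, e), E_T, E, nodes
    )
    den = _segmented_integral(
        lambda e: 1.0 / _stopping_mev_per_cm(material, ion, e), E_T, E, nodes
    )
    return num / den


def burnup_xs(library: XSLibrary, target: str = "Yb176") -> ExcitationFunction:
    """Target burn-up cross section sigma*(E) = sigma_non - sigma(d,d') - sigma(d,n+p).

    The (d,d') and (d,n+p) channels re-emit the target nuclide and are
    subtracted from the non-elastic aggregate.  Curves are interpolated
    onto the union grid; negative differences are clipped to zero with a
    logged warning.
    """
    try:
        non = library[ReactionID(target, "anything", "*")]
    except KeyError:
        raise KeyError(
            f"library {library.name!r} has no non-elastic ('anything') curve for {target}"
        ) from None
    channels = []
    for ej in ("d'", "n+p"):
        try:
            channels.append(library[ReactionID(target, ej, target)])
        except KeyError:
            logger.info("burnup_xs: no (d,%s) channel in %r; treated as zero", ej, library.name)
    grids = [non.energies] + [c.energies for c in channels]
    grid = np.unique(np.concatenate(grids))
    grid = grid[grid <= non.e_max]
    sigma = non(grid).copy()
    for c in channels:
        sub_grid = np.minimum(grid, c.e_max)  # hold the channel at its last value beyond its grid
        sigma -= np.interp(sub_grid, c.energies, c.sigmas, left=0.0)
    n_neg = int(np.sum(sigma < 0))
    if n_neg:
        logger.warning(
            "burnup_xs: clipped %d negative points of sigma* to zero (channels exceed sigma_non)",
            n_neg,
        )
        sigma = np.clip(sigma, 0.0, None)
    rid = ReactionID(target, "burnup", target)
    return ExcitationFunction(rid, grid, sigma, provenance="composed")


# -- delimited-text round trip ----------------------------------------------


def write_excitation(xs: ExcitationFunction, path_or_buf) -> None:
    """Write a cross-section table as CSV with '#'-prefixed header lines."""
    header = (
        f"# reaction: {xs.reaction.target},{xs.reaction.ejectiles},{xs.reaction.product}\n"
        f"# units: MeV, mb\n"
        f"# provenance: {xs.provenance}\n"
        "energy,sigma\n"
    )
    body = "".join(f"{e:.17g},{s:.17g}\n" for e, s in zip(xs.energies, xs.sigmas))
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header + body)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header + body)


def read_excitation(path_or_buf) -> ExcitationFunction:
    """Read a cross-section table written by :func:`write_excitation`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    meta = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
        elif line[0].isdigit() or line[0] in "+-.":
            e_s = line.split(",")
            rows.append((float(e_s[0]), float(e_s[1])))
    if "reaction" not in meta:
        raise ValueError("missing '# reaction:' header line")
    target, ejectiles, product = (p.strip() for p in meta["reaction"].split(","))
    arr = np.array(rows)
    return ExcitationFunction(
        ReactionID(target, ejectiles, product),
        arr[:, 0],
        arr[:, 1],
        provenance=meta.get("provenance", "file"),
    )
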