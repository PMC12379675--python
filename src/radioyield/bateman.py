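"""Linear production-decay chains with a constant irradiation source.

During irradiation a chain fed at constant rate Gamma (atoms/s) into
its first member obeys

    dN_1/dt = Gamma            - L_1 N_1
    dN_j/dt = lambda_{j-1} N_{j-1} - L_j N_j        (j >= 2)

with loss constants L_j = lambda_j (plus an optional burn-up term
phi <sigma>*_j when the beam also consumes chain members).  The
closed-form solution for the n-th member is

    N_n(t) = (Gamma / L_n) sum_j (1 - e^{-L_j t}) prod_{k != j} L_k / (L_k - L_j).

When the target itself depletes (loss constant L_0 = phi <sigma>*_T on
the target nuclide) the source becomes Gamma e^{-L_0 t} and the general
product-sum form with the extra eigenvalue L_0 is used.  After the beam
stops, each member decays with in-growth from its surviving precursors:

    N_m(tau) = (1/lambda_m) sum_j N'_j sum_{k=j}^m lambda_k e^{-lambda_k tau}
               prod_{l != k, l >= j} lambda_l / (lambda_l - lambda_k).

Chains are strictly linear (no branching).  Near-degenerate loss
constants (relative gap < 1e-9) make the closed forms singular; such
chains are integrated numerically with a stiff ODE solver instead.
Stable chain members (lambda = 0) accumulate without decay.

All times in seconds, inventories in atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import N_A
from .nuclides import Nuclide

__all__ = [
    "ChainSpec",
    "Inventory",
    "YieldReport",
    "inventory_during_irradiation",
    "inventory_post_irradiation",
    "combine_routes",
    "target_depletion",
    "report",
]

#: relative eigenvalue gap below which the closed forms are abandoned
DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class ChainSpec:
    """A linear production-decay chain.

    ``members`` are the produced nuclides in decay order (the first is
    fed directly by the reaction at ``source_rate`` atoms/s).
    ``extra_loss`` holds optional per-member burn-up loss constants
    phi <sigma>*_j (1/s), applied only when the burn-up flag of
    :func:`inventory_during_irradiation` is on.  ``target_loss`` is the
    depletion constant phi <sigma>*_T of the target nuclide feeding the
    chain (source decays as e^{-target_loss * t} with burn-up on).
    """

    members: Tuple[Nuclide, ...]
    source_rate: float
    extra_loss: Tuple[float, ...] = ()
    target_loss: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("chain must have at least one member")
        if self.source_rate < 0:
            raise ValueError("source rate must be non-negative")
        if self.extra_loss and len(self.extra_loss) != len(self.members):
            raise ValueError("extra_loss must match the number of members")
        for nuc in self.members[:-1]:
            if nuc.stable:
                raise ValueError(
                    f"stable nuclide {nuc.name} cannot feed a downstream chain member"
                )

    def losses(self, burnup: bool) -> np.ndarray:
        lam = np.array([n.lam for n in self.members])
        if burnup and self.extra_loss:
            lam = lam + np.asarray(self.extra_loss)
        return lam


@dataclass
class Inventory:
    """Per-nuclide atom counts at one instant."""

    atoms: Dict[str, float]
    time: float = 0.0
    phase: str = "irradiating"  # or "cooling"

    def __post_init__(self) -> None:
        for name, n in self.atoms.items():
            if n < -1e-6:
                raise ValueError(f"negative inventory for {name}: {n}")

    def __getitem__(self, name: str) -> float:
        return self.atoms.get(name, 0.0)


def _nearly_degenerate(L: np.ndarray) -> bool:
    L = np.sort(np.asarray(L, dtype=float))
    scale = max(np.max(np.abs(L)), 1e-300)
    return bool(np.any(np.diff(L) < DEGENERACY_RTOL * scale))


def _ode_during(chain: ChainSpec, t: float, burnup: bool) -> np.ndarray:
    L = chain.losses(burnup)
    lam = np.array([n.lam for n in chain.members])
    l0 = chain.target_loss if burnup else 0.0

    def rhs(_t, y):
        dy = np.empty_like(y)
        src = chain.source_rate * math.exp(-l0 * _t)
        dy[0] = src - L[0] * y[0]
        for j in range(1, y.size):
            dy[j] = lam[j - 1] * y[j - 1] - L[j] * y[j]
        return dy

    sol = solve_ivp(rhs, (0.0, t), np.zeros(len(chain.members)), method="LSODA",
                    rtol=1e-12, atol=1e-3, dense_output=False)
    if not sol.success:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"ODE fallback failed: {sol.message}")
    return sol.y[:, -1]


def _closed_form_during(chain: ChainSpec, t: float, burnup: bool) -> np.ndarray:
    """Closed-form N_j(t) for every member j of the chain."""
    L = chain.losses(burnup)
    lam = np.array([n.lam for n in chain.members])
    l0 = chain.target_loss if burnup else 0.0
    out = np.empty(len(L))
    for n_idx in range(len(L)):
        Ln = L[: n_idx + 1]
        if l0 > 0.0:
            # depleting source: product-sum over eigenvalues {l0, L_1..L_n}
            eig = np.concatenate(([l0], Ln))
            gains = np.concatenate(([chain.source_rate], lam[:n_idx]))
            total = 0.0
            for k, lk in enumerate(eig):
                prod = 1.0
                for l, ll in enumerate(eig):
                    if l != k:
                        prod /= ll - lk
                total += math.exp(-lk * t) * prod
            out[n_idx] = float(np.prod(gains)) * total
        else:
            # constant source
            if Ln[-1] == 0.0:
                if n_idx == 0:
                    out[n_idx] = chain.source_rate * t
                    continue
                raise NotImplementedError(
                    "stable member below a radioactive precursor: use the ODE path"
                )
            total = 0.0
            for j, lj in enumerate(Ln):
                prod = 1.0
                for k, lk in enumerate(Ln):
                    if k != j:
                        prod *= lk / (lk - lj)
                total += -math.expm1(-lj * t) * prod
            out[n_idx] = chain.source_rate / Ln[-1] * total
    return out


def inventory_during_irradiation(
    chain: ChainSpec, t: float, burnup: bool = False
) -> Inventory:
    """Inventory of every chain member after irradiating for t seconds.

    With ``burnup`` off the loss constants are the decay constants and
    the source is constant; with ``burnup`` on the per-member burn-up
    losses and the exponential target depletion are included.
    """
    if t < 0:
        raise ValueError("irradiation time must be non-negative")
    if t == 0:
        return Inventory({n.name: 0.0 for n in chain.members}, 0.0, "irradiating")
    L = chain.losses(burnup)
    eig = np.concatenate(([chain.target_loss], L)) if burnup else L
    has_stable_mid = any(n.stable for n in chain.members[:-1])
    use_ode = _nearly_degenerate(eig[eig > 0]) if np.any(eig > 0) else False
    if burnup and chain.target_loss > 0 and chain.members[-1].stable:
        use_ode = True
    if has_stable_mid:
        use_ode = True
    if len(chain.members) > 1 and chain.members[-1].stable and not burnup:
        use_ode = True
    vals = _ode_during(chain, t, burnup) if use_ode else _closed_form_during(chain, t, burnup)
    atoms = {n.name: max(float(v), 0.0) for n, v in zip(chain.members, vals)}
    return Inventory(atoms, t, "irradiating")


def inventory_post_irradiation(chain: ChainSpec, inv: Inventory, tau: float) -> Inventory:
    """Decay an end-of-irradiation inventory for tau seconds (beam off).

    Each member receives in-growth from its surviving precursors along
    the chain (closed form above); stable members simply accumulate.
    """
    if tau < 0:
        raise ValueError("cooling time must be non-negative")
    lam = np.array([n.lam for n in chain.members])
    nprime = np.array([inv[n.name] for n in chain.members])
    if tau == 0:
        return Inventory(dict(zip((n.name for n in chain.members), nprime)),
                         inv.time, "cooling")
    if np.any(lam > 0) and _nearly_degenerate(lam[lam > 0]):
        sol = solve_ivp(
            lambda _t, y: np.concatenate(
                ([-lam[0] * y[0]],
                 [lam[j - 1] * y[j - 1] - lam[j] * y[j] for j in range(1, y.size)])
            ),
            (0.0, tau), nprime, method="LSODA", rtol=1e-12, atol=1e-3,
        )
        vals = sol.y[:, -1]
    else:
        vals = np.empty_like(nprime)
        for m in range(len(lam)):
            if lam[m] == 0.0:
                # stable: keeps what it had plus everything its precursors feed in;
                # for the bundled chains stable members are chain heads only.
                vals[m] = nprime[m]
                if m > 0:
                    raise NotImplementedError(
                        "stable member below a radioactive precursor: not supported"
                    )
                continue
            total = 0.0
            for j in range(m + 1):
                s = 0.0
                for k in range(j, m + 1):
                    prod = 1.0
                    for l in range(j, m + 1):
                        if l != k:
                            prod *= lam[l] / (lam[l] - lam[k])
                    s += lam[k] * math.exp(-lam[k] * tau) * prod
                total += nprime[j] * s
            vals[m] = total / lam[m]
    atoms = {n.name: max(float(v), 0.0) for n, v in zip(chain.members, vals)}
    return Inventory(atoms, inv.time + tau, "cooling")


def combine_routes(inventories: Iterable[Inventory]) -> Inventory:
    """Sum per-nuclide inventories over all contributing reaction routes."""
    total: Dict[str, float] = {}
    time = 0.0
    phase = "irradiating"
    for inv in inventories:
        time = max(time, inv.time)
        phase = inv.phase
        for name, n in inv.atoms.items():
            total[name] = total.get(name, 0.0) + n
    return Inventory(total, time, phase)


def target_depletion(n0: float, phi: float, sigma_star_mb: float, t: float) -> float:
    """Surviving target atoms N0 e^{-phi sigma* t} (phi in 1/cm^2/s, sigma* in mb)."""
    if min(n0, phi, sigma_star_mb, t) < 0:
        raise ValueError("all inputs must be non-negative")
    return n0 * math.exp(-phi * sigma_star_mb * 1e-27 * t)


# -- reporting ---------------------------------------------------------------


@dataclass
class YieldReport:
    """Per-nuclide yields plus purity and specific-activity aggregates.

    ``frame`` columns: atoms, mass_mg, activity_gbq, purity_pct (the
    radionuclidic purity, activity as a share of the summed activity of
    the reported set).  ``specific_activity_radionuclides`` divides the
    reference activity by the summed mass of the radioactive nuclides
    only; ``specific_activity_element`` divides by the total element
    mass including stable and effectively stable co-products.
    """

    frame: pd.DataFrame
    reference: str
    total_activity_gbq: float
    specific_activity_radionuclides: float
    specific_activity_element: float

    def row(self, name: str) -> pd.Series:
        return self.frame.loc[name]


def report(
    inv: Inventory,
    nuclides: Sequence[Nuclide],
    reference: str = "Lu177g",
    coproducts: Sequence[str] = (),
) -> YieldReport:
    """Build a yield report for the given nuclide set from an inventory.

    Radiopurity is normalized over the members of ``nuclides`` (stable
    entries contribute zero activity).  ``coproducts`` names stable or
    effectively stable carrier nuclides: they are excluded from the
    radionuclide-mass specific activity but dilute the element-mass one.
    """
    co = set(coproducts)
    rows = {}
    act_total = 0.0
    mass_radio = 0.0
    mass_all = 0.0
    for nuc in nuclides:
        n = inv[nuc.name]
        mass_mg = n * nuc.molar_mass / N_A * 1e3
        act_gbq = n * nuc.lam / 1e9
        act_total += act_gbq
        mass_all += mass_mg
        if not nuc.stable and nuc.name not in co:
            mass_radio += mass_mg
        rows[nuc.name] = {"atoms": n, "mass_mg": mass_mg, "activity_gbq": act_gbq}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame["purity_pct"] = (
        100.0 * frame["activity_gbq"] / act_total if act_total > 0 else 0.0
    )
    ref_act = rows.get(reference, {"activity_gbq": 0.0})["activity_gbq"]
    return YieldReport(
        frame=frame,
        reference=reference,
        total_activity_gbq=act_total,
        specific_activity_radionuclides=ref_act / mass_radio if mass_radio > 0 else math.inf,
        specific_activity_element=ref_act / mass_all if mass_all > 0 else math.inf,
    )
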