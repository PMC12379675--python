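"""Configuration-driven scenarios: one YAML file describes beam, target,
dataset selection, schedule and reporting; :func:`run_scenario` chains
the stopping, cross-section, activation and decay modules into the
stage outputs (range table, figures of merit, rate table, inventory
timeline, yield report).  Runs are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .activation import BeamSpec, TargetSpec, beam_flux, figures_of_merit, production_rate
from .bateman import (
    ChainSpec,
    Inventory,
    YieldReport,
    combine_routes,
    inventory_during_irradiation,
    inventory_post_irradiation,
    report,
)
from .constants import to_seconds
from .materials import DEUTERON, yb2o3, yb_metal
from .fixtures import fixture_curves
from .nuclides import Nuclide, get_nuclide
from .stopping import csda_range, thickness_for_interval
from .xs import XSLibrary

__all__ = ["Scenario", "ScenarioError", "ScenarioResult", "load_scenario", "run_scenario",
           "optimize_interval", "packaged_scenario_path"]


class ScenarioError(ValueError):
    """Configuration problem, reported with the offending field path."""


@dataclass
class Scenario:
    name: str
    beam: BeamSpec
    target: TargetSpec
    reactions: Dict[str, str]  # reaction label -> dataset name
    irradiation_s: float
    processing_s: float
    timeline_points: int
    report_nuclides: List[str]
    reference: str
    coproducts: List[str]
    raw: dict = field(default_factory=dict, repr=False)


def packaged_scenario_path() -> Path:
    """Path of the bundled reference scenario config."""
    return Path(str(resources.files("radioyield.data").joinpath("lu177_reference.yaml")))


def _require(cfg: dict, path: str):
    cur = cfg
    for part in path.split("."):
        if not isinstance(cur, dict) or part not in cur:
            raise ScenarioError(f"missing config field: {path}")
        cur = cur[part]
    return cur


def load_scenario(path) -> Scenario:
    """Parse and validate a scenario YAML (or TOML-like dict already loaded)."""
    if isinstance(path, dict):
        cfg = path
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    try:
        beam_cfg = _require(cfg, "beam")
        ion = beam_cfg.get("ion", "deuteron")
        if ion not in ("deuteron", "d"):
            raise ScenarioError(f"beam.ion: only deuterons are supported, got {ion!r}")
        beam = BeamSpec(
            ion=DEUTERON,
            energy=float(_require(cfg, "beam.energy_mev")),
            current_ma=float(_require(cfg, "beam.current_ma")),
            transmission=float(beam_cfg.get("transmission", 1.0)),
            radius_cm=float(beam_cfg.get("radius_cm", 1.0)),
        )
        tgt = _require(cfg, "target")
        mat_name = _require(cfg, "target.material")
        enriched = bool(tgt.get("enriched", True))
        density = float(tgt.get("density_g_cm3", 9.2 if mat_name == "yb2o3" else 6.9))
        if mat_name == "yb2o3":
            material = yb2o3(enriched=enriched, density=density)
        elif mat_name in ("yb", "yb_metal"):
            material = yb_metal(enriched=enriched, density=density)
        else:
            raise ScenarioError(f"target.material: unknown material {mat_name!r}")
        target = TargetSpec(
            material=material,
            radius_cm=float(tgt.get("radius_cm", 1.0)),
            thickness_mm=tgt.get("thickness_mm"),
            exit_energy_mev=tgt.get("exit_energy_mev"),
            enrichment=float(tgt.get("enrichment", 0.99)),
        )
        reactions = dict(_require(cfg, "reactions"))
        sched = _require(cfg, "schedule")
        irr = _require(cfg, "schedule.irradiation")
        irradiation_s = to_seconds(irr["value"], irr["unit"])
        proc = sched.get("processing", {"value": 0.0, "unit": "s"})
        processing_s = to_seconds(proc["value"], proc["unit"])
        if irradiation_s < 0 or processing_s < 0:
            raise ScenarioError("schedule durations must be non-negative")
        rep = cfg.get("report", {})
        return Scenario(
            name=cfg.get("name", "scenario"),
            beam=beam,
            target=target,
            reactions=reactions,
            irradiation_s=irradiation_s,
            processing_s=processing_s,
            timeline_points=int(sched.get("timeline_points", 50)),
            report_nuclides=list(rep.get("nuclides", [])),
            reference=rep.get("reference", "Lu177g"),
            coproducts=list(rep.get("coproducts", [])),
            raw=cfg,
        )
    except ScenarioError:
        raise
    except (KeyError, TypeError, ValueError) as err:
        raise ScenarioError(f"invalid scenario config: {err}") from err


def _build_chain(product: str, rate: float) -> ChainSpec:
    """Linear chain from a reaction product down to (but excluding) the
    first stable decay product."""
    members: List[Nuclide] = []
    nuc: Optional[Nuclide] = get_nuclide(product)
    while nuc is not None:
        members.append(nuc)
        if nuc.stable or nuc.daughter is None:
            break
        nxt = get_nuclide(nuc.daughter)
        if nxt.stable:
            break
        nuc = nxt
    return ChainSpec(tuple(members), rate)


@dataclass
class ScenarioResult:
    scenario: Scenario
    thickness_mm: float
    exit_energy_mev: float
    flux: float
    rates: pd.DataFrame
    figures_of_merit: pd.DataFrame
    timeline: pd.DataFrame
    end_of_irradiation: YieldReport
    after_processing: Optional[YieldReport]

    def write(self, outdir, fmt: str = "csv") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ranges = pd.DataFrame(
            [
                {
                    "quantity": "range_mm",
                    "energy_mev": self.scenario.beam.energy,
                    "value": csda_range(
                        self.scenario.target.material, self.scenario.beam.ion,
                        self.scenario.beam.energy,
                    ),
                },
                {"quantity": "thickness_mm", "energy_mev": self.scenario.beam.energy,
                 "value": self.thickness_mm},
                {"quantity": "exit_energy_mev", "energy_mev": self.scenario.beam.energy,
                 "value": self.exit_energy_mev},
            ]
        )
        tables = {
            "ranges": ranges,
            "figures_of_merit": self.figures_of_merit,
            "rates": self.rates,
            "inventory_timeline": self.timeline,
        }
        reports = {"yield_report": self.after_processing or self.end_of_irradiation}
        for name, df in tables.items():
            if fmt == "json":
                df.to_json(outdir / f"{name}.json", orient="records", indent=1)
            else:
                df.to_csv(outdir / f"{name}.csv", index=False)
        for name, rep in reports.items():
            df = rep.frame.reset_index(names="nuclide")
            if fmt == "json":
                df.to_json(outdir / f"{name}.json", orient="records", indent=1)
            else:
                df.to_csv(outdir / f"{name}.csv", index=False)


def _route_inventories(
    scenario: Scenario, rates: Dict[str, Tuple[str, float]], t: float
) -> Tuple[List[Tuple[ChainSpec, Inventory]], Inventory]:
    routes = []
    for label, (_ds, rate) in rates.items():
        product = label.split(")")[-1]
        chain = _build_chain(product, rate)
        routes.append((chain, inventory_during_irradiation(chain, t)))
    return routes, combine_routes(inv for _c, inv in routes)


def run_scenario(scenario: Scenario, outdir=None, fmt: str = "csv") -> ScenarioResult:
    """Execute every stage of a scenario; optionally write output files."""
    beam, target = scenario.beam, scenario.target
    try:
        libs = {name: fixture_curves(name) for name in set(scenario.reactions.values())}
    except ValueError as err:
        raise ScenarioError(f"reactions: {err}") from None
    t_mm, e_t = target.resolve(beam)

    # stage: rates
    rate_rows = []
    rates: Dict[str, Tuple[str, float]] = {}
    for label, ds in scenario.reactions.items():
        if ds not in libs:
            raise ScenarioError(f"reactions.{label}: unknown dataset {ds!r}")
        xs = libs[ds][label]
        gamma = production_rate(beam, target, xs)
        rates[label] = (ds, gamma)
        rate_rows.append({"reaction": label, "dataset": ds, "rate_atoms_per_s": gamma})
    rates_df = pd.DataFrame(rate_rows)

    # stage: figures of merit for the scenario interval, on the main channel
    main_label = ("176Yb(d,p)Yb177" if "176Yb(d,p)Yb177" in scenario.reactions
                  else next(iter(scenario.reactions)))
    main_xs = libs[scenario.reactions[main_label]][main_label]
    fom = figures_of_merit([(beam.energy, e_t)], target.material, main_xs, beam.ion)

    # stage: inventory timeline and reports
    t_irr, t_proc = scenario.irradiation_s, scenario.processing_s
    routes, end_inv = _route_inventories(scenario, rates, t_irr)
    # stable co-products accumulate linearly and survive processing
    co_atoms = {}
    for label, (_ds, rate) in rates.items():
        product = label.split(")")[-1]
        if product in scenario.coproducts and get_nuclide(product).lam * t_irr < 1e-6:
            co_atoms[product] = rate * t_irr

    npts = max(scenario.timeline_points, 2)
    times = [t_irr * i / (npts - 1) for i in range(npts)]
    if t_proc > 0:
        times += [t_irr + t_proc * i / (npts - 1) for i in range(1, npts)]
    tl_rows = []
    for tt in times:
        if tt <= t_irr:
            inv = combine_routes(
                inventory_during_irradiation(c, tt) for c, _ in routes
            )
        else:
            inv = combine_routes(
                inventory_post_irradiation(c, inventory_during_irradiation(c, t_irr), tt - t_irr)
                for c, _ in routes
            )
        row = {"time_s": tt, "phase": "irradiating" if tt <= t_irr else "cooling"}
        row.update({k: inv[k] for k in sorted(inv.atoms)})
        tl_rows.append(row)
    timeline = pd.DataFrame(tl_rows)

    nuc_set = [get_nuclide(n) for n in scenario.report_nuclides]
    nuc_set_b = nuc_set + [get_nuclide(n) for n in scenario.coproducts]

    def _report(inv: Inventory) -> YieldReport:
        full = Inventory({**inv.atoms, **co_atoms}, inv.time, inv.phase)
        return report(full, nuc_set_b, reference=scenario.reference,
                      coproducts=scenario.coproducts)

    eoi_report = _report(end_inv) if scenario.report_nuclides and t_irr > 0 else None
    after = None
    if t_proc > 0 and eoi_report is not None:
        cooled = combine_routes(
            inventory_post_irradiation(c, inventory_during_irradiation(c, t_irr), t_proc)
            for c, _ in routes
        )
        after = _report(cooled)
    if eoi_report is None:
        eoi_report = report(end_inv, nuc_set_b, reference=scenario.reference) \
            if nuc_set_b else YieldReport(pd.DataFrame(), scenario.reference, 0.0,
                                          math.inf, math.inf)

    result = ScenarioResult(
        scenario=scenario,
        thickness_mm=t_mm,
        exit_energy_mev=e_t,
        flux=beam_flux(beam),
        rates=rates_df,
        figures_of_merit=fom,
        timeline=timeline,
        end_of_irradiation=eoi_report,
        after_processing=after,
    )
    if outdir is not None:
        result.write(outdir, fmt)
    return result


def optimize_interval(
    scenario: Scenario,
    intervals: Sequence[Tuple[float, float]],
    rank_by: str = "T_sigma_per_E_mm_mb_per_mev",
) -> pd.DataFrame:
    """Rank candidate (E, E_T) intervals by a figure of merit.

    Default ranking key is the production efficiency proxy
    T*<sigma>_T/E; ``rank_by='T_sigma_mm_mb'`` ranks by raw yield
    instead.  Returns the figures-of-merit table sorted best-first with
    a boolean ``best`` column.
    """
    if not intervals:
        raise ScenarioError("optimize_interval needs at least one candidate interval")
    ds = scenario.reactions.get("176Yb(d,p)Yb177", "nagai")
    dp = fixture_curves(ds)["176Yb(d,p)Yb177"]
    fom = figures_of_merit(list(intervals), scenario.target.material, dp, scenario.beam.ion)
    if rank_by not in fom.columns:
        raise ScenarioError(f"unknown ranking key {rank_by!r}; columns: {list(fom.columns)}")
    fom = fom.sort_values(rank_by, ascending=False).reset_index(drop=True)
    fom["best"] = [i == 0 for i in range(len(fom))]
    return fom
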