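# Methods

## Scope and assumptions

`radioyield` models the activation of a thin, homogeneous,
stoichiometric target by a mono-energetic charged-particle beam, and
the subsequent build-up and decay of reaction products.  The governing
assumptions are:

* **Continuous slowing down.**  Ions lose energy deterministically at
  the rate given by the compact Bethe formula; energy and angular
  straggling are neglected.  This is adequate for thin targets that the
  beam fully traverses (the bundled scenario spans 18 → 8 MeV, well
  above the stopping-power maximum).
* **Mono-energetic, collimated beam matching the target face.**  The
  beam flux is φ = εJ/(qπr²) with the beam area equal to the target
  face, so the production rate Γ = ηε(J/q)TN⟨σ⟩_T carries no explicit
  area.  Imperfect collimation lengthens some ion paths; the model
  therefore carries a small known low bias in Γ.
* **Thin-target regime.**  The exit energy must stay above the
  stopping-model cutoff; stopping (thick) targets are rejected rather
  than approximated.
* **Linear decay chains.**  Production–decay networks are strictly
  linear; isomeric-transition branches (e.g. ¹⁷⁷ᵐLu → ¹⁷⁷ᵍLu, ¹⁷⁴ᵐLu →
  ¹⁷⁴ᵍLu) are not modelled.  At the activity ratios of the reference
  scenario these feeds are negligible.
* **Constant beam during irradiation**, zero afterwards; schedules are
  an irradiation phase followed by a processing (cooling) phase.

## Stopping model

S(E) = ωz²/β² · ln(κβ²) with ω = 4π n_e m_e c² r_e² and
κ = 2m_e c²/⟨I⟩.  β² is computed exactly from the kinetic energy and
rest mass (the dropped relativistic remainder −β² − ln(1−β²) is below
10⁻⁴ of the logarithm for deuterons under 20 MeV).  Shell and density
corrections are omitted.

**Low-energy cutoff.**  The formula peaks at κβ² = e and turns
unphysical below; the range integral from zero is logarithmically
divergent at κβ² = 1.  The package integrates adaptively from the
cutoff energy E_min (where κβ² = e; ≈1.28 MeV for deuterons in Yb₂O₃,
≈1.71 MeV in Yb) and continues below it with the stopping power frozen
at its maximum, adding the residual range E_min/S(E_min) (15–40 µm).
Slab thicknesses between energies above the cutoff are independent of
this choice; total ranges then reproduce the reference values to ~1%.

**Isotopic composition.**  Electron and atom number densities follow
from the actual isotopic molar masses.  For the 99% enriched ¹⁷⁶Yb
targets the Yb molar mass is 175.94 g/mol rather than the natural
173.04 g/mol — a 1.5% effect on n_e that is resolvable in the published
slab thicknesses, which the enriched composition reproduces within
~1%.  Natural-composition materials are available via
`yb2o3(enriched=False)`.

**Numerics.**  Ranges use `scipy.integrate.quad` with an absolute
tolerance of 10⁻⁶ mm (the reference tables print two decimals); the
quadrature's own error estimate is checked and a failure raises with
diagnostics.  The exit-energy map inverts R(E) − R(E_T) = T by Brent's
method bracketed on [E_min, E], verified to a residual below 10⁻⁹ mm.

## Cross-section handling

Excitation functions are tabulated (MeV, mb), interpolated
piecewise-linearly, zero below their grid and never extrapolated above
it — activation integrals must not invent cross section.  Averages are
integrated segment-by-segment between table nodes with 12-point
Gauss–Legendre quadrature, which is exact for the linear segments up to
the smoothness of 1/S; agreement with a brute-force 1 keV trapezoid
oracle is at the 10⁻⁶ level.

Two averaging conventions are exposed: the precise 1/S-weighted form
and the approximate E-weighted form.  On the bundled (d,p) fixture at
17.9 MeV they differ by ≈8% — the near-equivalence argument (slowly
varying logarithm) is qualitative, so the precise form is the default
everywhere.

The burn-up cross section σ* subtracts the target-retaining (d,d') and
(d,n+p) channels from the non-elastic aggregate on the union energy
grid; negative differences (possible with inconsistent inputs) are
clipped to zero with a logged warning.

## Synthetic fixture curves

The measured and evaluated ¹⁷⁶Yb(d,x) excitation functions are not
redistributable, so `fixture_curves` generates smooth parametric
stand-ins: threshold-clipped two-sided Gaussian peaks for discrete
channels, saturating sigmoids for the aggregate channels.  Shape
parameters are fixed once from coarse (d,xn) systematics (thresholds
rising with neutron multiplicity, peaks shifting to higher energy);
amplitudes are committed calibration constants chosen so that the
reference scenario reproduces the published anchors: the (d,p) curve
rises near 5 MeV and peaks at 230 mb at 12.5 MeV with thin-target
averages within 3% of the published 167.4/175.4/167.9 mb triple, each
minor channel's production rate matches its published value within 2%,
and the composed burn-up curve yields the published burn-up rates for
both target materials.

What the fixtures emulate: the magnitudes and energy windows relevant
to the 16–20 MeV design space.  What they do not: the true fine
structure, thresholds and high-energy tails of the real data, or their
uncertainties.  Tests passing on the fixtures therefore validate the
*formalism* (averaging, rates, inventories) and the published anchor
values — not predictions outside the calibrated window.  Users with
real tables load them via `read_excitation` (CSV with `#` header
lines); the writer emits the identical dialect, and round trips are
lossless.

The two datasets mirror the two published rate columns ("nagai" with
five measured reactions; "tendl_dagger" with the full evaluated set).
Both share one (d,p) curve — the published columns differ by 0.5% for
that channel, within the calibration tolerance.  The reference scenario
selects the dataset per reaction explicitly, because the published
inventory tables mix columns (the measured column where it exists, the
evaluated one for ¹⁷⁷ᵐLu, ¹⁷⁶ᵍLu and ¹⁷⁵Lu).

## Decay-chain solutions

During irradiation a chain fed at constant Γ uses the closed Bateman
product–sum; with target burn-up enabled the source decays as
e^(−φσ*t) and the general form with the extra eigenvalue is used.
After the beam stops, each member decays with in-growth from surviving
precursors.  `expm1` keeps the saturation factors accurate for
λt ≪ 1 (relevant for the 3.31 y and 3.76×10¹⁰ y species).

**Degenerate eigenvalues.**  The closed forms are singular when two
loss constants coincide; if any pair is closer than 10⁻⁹ relative, the
chain is integrated with a stiff ODE solver (LSODA, rtol 10⁻¹²)
instead.  Correctness is preferred over closed-form purity.

**Stable and effectively stable species.**  Stable single-member routes
accumulate as Γt.  The ¹⁷⁵Lu and ¹⁷⁶ᵍLu co-products enter only the
element-mass specific activity (variant b); the radionuclide-mass
variant (a) excludes them.

**Nuclide data.**  The bundled half-life table is chosen for internal
consistency of the reference scenario's published inventory tables:
¹⁷⁶ᵐLu is entered as 3.664 h (its saturation inventory and
post-processing activity are consistent only with hours, although
3.66 d appears in prose elsewhere) and ¹⁷⁴ᵐLu as 142.2 d (rather than
the evaluated 120.9 d, which the published activities do not match).
Both adjustments are noted in the data file.  Molar masses are isotopic
atomic masses.

## Scenario layer

YAML configs with explicit units in key names (energy_mev, current_ma,
thickness_mm); exactly one of slab thickness / exit energy is given and
the other is derived.  Runs are fully deterministic — repeated runs are
byte-identical.  Timelines evaluate the closed forms on a configurable
grid (default 60 points per phase).  CLI exit codes: 0 success, 2
configuration error, 3 numerical failure.

## Problem sizes

All computations are desk-scale: range integrals and averages are
one-dimensional quadratures (milliseconds), chains have ≤ 4 members,
and the full test suite (including randomized chain/ODE comparisons
with 20 + 10 chains and property-based inverse-map checks) runs in a
few seconds on one CPU.

## Known limitations

* No energy/angular straggling, nuclear stopping or Monte Carlo
  transport; no temperature dependence of stopping.
* No branching decay networks, gamma spectra or dose quantities.
* The approximate (E-weighted) average is retained for comparison only.
* Fixture curves are calibrated stand-ins; quantitative use outside the
  calibrated 16–20 MeV window requires real data tables.
* Beam-profile and collimation effects beyond the area-matched
  mono-energetic assumption are not modelled (small low bias in Γ).
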