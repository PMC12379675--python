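"""Production-decay chain solutions, route summation and yield reports."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import radioyield as ry
from radioyield.nuclides import Nuclide

LN2 = math.log(2.0)
HOUR, DAY = 3600.0, 86400.0


def make_nuclide(name, half_life_s, molar_mass=177.0, daughter=None):
    return Nuclide(name, "Lu", 71, 177, "", half_life_s, molar_mass, daughter)


def ode_oracle(source, lams, t, target_loss=0.0, extra_loss=None):
    """Independent stiff-ODE integration of the linear chain system."""
    lams = np.asarray(lams, dtype=float)
    losses = lams + (np.asarray(extra_loss) if extra_loss is not None else 0.0)

    def rhs(tt, y):
        dy = np.empty_like(y)
        dy[0] = source * math.exp(-target_loss * tt) - losses[0] * y[0]
        for j in range(1, y.size):
            dy[j] = lams[j - 1] * y[j - 1] - losses[j] * y[j]
        return dy

    scale = source * t if source > 0 else 1.0
    sol = solve_ivp(rhs, (0.0, t), np.zeros(len(lams)), method="Radau",
                    rtol=1e-12, atol=scale * 1e-13)
    assert sol.success
    return sol.y[:, -1]


@pytest.fixture(scope="module")
def yb177_chain():
    """Indirect route: source -> 177Yb (1.911 h) -> 177gLu (6.647 d)."""
    yb = ry.get_nuclide("Yb177")
    lu = ry.get_nuclide("Lu177g")
    return ry.ChainSpec((yb, lu), source_rate=1.065e13)


class TestDuringIrradiation:
    def test_zero_time(self, yb177_chain):
        inv = ry.inventory_during_irradiation(yb177_chain, 0.0)
        assert all(v == 0.0 for v in inv.atoms.values())

    def test_single_step_saturation(self):
        """N -> Gamma/lambda once production balances decay."""
        nuc = make_nuclide("X", 1000.0)
        chain = ry.ChainSpec((nuc,), source_rate=1e10)
        inv = ry.inventory_during_irradiation(chain, 50 * 1000.0)
        assert inv["X"] == pytest.approx(1e10 / nuc.lam, rel=1e-9)

    def test_single_step_closed_form(self):
        nuc = make_nuclide("X", 2 * HOUR)
        chain = ry.ChainSpec((nuc,), source_rate=3.0e9)
        t = 5 * HOUR
        expected = 3.0e9 / nuc.lam * (1 - math.exp(-nuc.lam * t))
        inv = ry.inventory_during_irradiation(chain, t)
        assert inv["X"] == pytest.approx(expected, rel=1e-12)

    def test_two_step_against_ode(self, yb177_chain):
        got = ry.inventory_during_irradiation(yb177_chain, 5 * DAY)
        oracle = ode_oracle(yb177_chain.source_rate,
                            [n.lam for n in yb177_chain.members], 5 * DAY)
        assert got["Yb177"] == pytest.approx(oracle[0], rel=1e-8)
        assert got["Lu177g"] == pytest.approx(oracle[1], rel=1e-8)

    def test_randomized_chains_match_ode(self):
        """Closed-form vs stiff-ODE oracle on random linear chains
        (n <= 4, decay constants spread over six decades)."""
        rng = np.random.default_rng(20260929)
        for _ in range(20):
            n = int(rng.integers(1, 5))
            lams = 10.0 ** rng.uniform(-7.0, -1.0, size=n)
            while np.min(np.abs(np.subtract.outer(lams, lams))[~np.eye(n, dtype=bool)] if n > 1
                         else [1.0]) < 1e-11:
                lams = 10.0 ** rng.uniform(-7.0, -1.0, size=n)
            source = 10.0 ** rng.uniform(8, 13)
            t = 10.0 ** rng.uniform(3, 6)
            members = tuple(make_nuclide(f"N{i}", LN2 / lam) for i, lam in enumerate(lams))
            chain = ry.ChainSpec(members, source_rate=source)
            got = ry.inventory_during_irradiation(chain, t)
            oracle = ode_oracle(source, lams, t)
            for i, m in enumerate(members):
                assert got[m.name] == pytest.approx(oracle[i], rel=1e-8, abs=source * t * 1e-10)

    def test_monotone_in_time(self, yb177_chain):
        """Inventories are nondecreasing during irradiation."""
        ts = np.linspace(0.0, 10 * DAY, 25)
        prev = {"Yb177": 0.0, "Lu177g": 0.0}
        for t in ts[1:]:
            inv = ry.inventory_during_irradiation(yb177_chain, t)
            assert inv["Yb177"] >= prev["Yb177"] - 1e-6
            assert inv["Lu177g"] >= prev["Lu177g"] - 1e-6
            prev = inv.atoms

    def test_degenerate_constants_fall_back(self):
        """Two identical decay constants are handled without NaN."""
        a = make_nuclide("A", 1000.0)
        b = make_nuclide("B", 1000.0)
        chain = ry.ChainSpec((a, b), source_rate=1e9)
        got = ry.inventory_during_irradiation(chain, 5000.0)
        oracle = ode_oracle(1e9, [a.lam, b.lam], 5000.0)
        assert np.isfinite(list(got.atoms.values())).all()
        assert got["B"] == pytest.approx(oracle[1], rel=1e-6)

    def test_atom_conservation(self, yb177_chain):
        """Without burn-up, Gamma*t equals the chain content plus the atoms
        decayed through the chain end (tracked by quadrature), to 1e-9."""
        t = 5 * DAY
        inv = ry.inventory_during_irradiation(yb177_chain, t)
        lam_end = yb177_chain.members[-1].lam

        def end_activity(tt):
            return lam_end * ry.inventory_during_irradiation(yb177_chain, tt)["Lu177g"]

        decayed, err = quad(end_activity, 0.0, t, limit=200, epsrel=1e-12)
        total = inv["Yb177"] + inv["Lu177g"] + decayed
        assert total == pytest.approx(yb177_chain.source_rate * t, rel=1e-9)

    def test_burnup_flag_depleting_source(self):
        """With burn-up on, the source decays as e^{-L0 t}; the closed form
        matches the analytic single-member solution."""
        nuc = make_nuclide("X", 2 * HOUR)
        l0 = 2e-6
        chain = ry.ChainSpec((nuc,), source_rate=1e12, target_loss=l0)
        t = 1 * DAY
        lam = nuc.lam
        expected = 1e12 * (math.exp(-l0 * t) - math.exp(-lam * t)) / (lam - l0)
        got = ry.inventory_during_irradiation(chain, t, burnup=True)
        assert got["X"] == pytest.approx(expected, rel=1e-10)
        off = ry.inventory_during_irradiation(chain, t, burnup=False)
        assert got["X"] < off["X"]


class TestPostIrradiation:
    def test_zero_cooling_identity(self, yb177_chain):
        inv = ry.inventory_during_irradiation(yb177_chain, 5 * DAY)
        cooled = ry.inventory_post_irradiation(yb177_chain, inv, 0.0)
        assert cooled.atoms == pytest.approx(inv.atoms)

    def test_orphan_exponential(self):
        """A nuclide with no precursor decays as N e^{-lambda tau}."""
        nuc = make_nuclide("X", 3 * HOUR)
        chain = ry.ChainSpec((nuc,), source_rate=1e12)
        inv = ry.Inventory({"X": 5e17})
        cooled = ry.inventory_post_irradiation(chain, inv, 7 * HOUR)
        assert cooled["X"] == pytest.approx(5e17 * math.exp(-nuc.lam * 7 * HOUR), rel=1e-12)

    def test_ingrowth_from_precursor(self, yb177_chain):
        """Cooling after irradiation matches the ODE continued with the
        source switched off."""
        t, tau = 5 * DAY, 2 * DAY
        inv = ry.inventory_during_irradiation(yb177_chain, t)
        cooled = ry.inventory_post_irradiation(yb177_chain, inv, tau)
        lams = [n.lam for n in yb177_chain.members]

        def rhs(tt, y):
            return [-lams[0] * y[0], lams[0] * y[0] - lams[1] * y[1]]

        sol = solve_ivp(rhs, (0, tau), [inv["Yb177"], inv["Lu177g"]], method="Radau",
                        rtol=1e-12, atol=1e3)
        assert cooled["Lu177g"] == pytest.approx(sol.y[1, -1], rel=1e-8)
        assert cooled["Yb177"] == pytest.approx(sol.y[0, -1], rel=1e-8)


class TestRoutesAndDepletion:
    def test_combine_routes_additive(self, yb177_chain):
        """Indirect plus direct production differ from indirect-only by
        exactly the direct term."""
        direct = ry.ChainSpec((ry.get_nuclide("Lu177g"),), source_rate=3.853e11)
        t = 5 * DAY
        ind = ry.inventory_during_irradiation(yb177_chain, t)
        dr = ry.inventory_during_irradiation(direct, t)
        combined = ry.combine_routes([ind, dr])
        assert combined["Lu177g"] == pytest.approx(ind["Lu177g"] + dr["Lu177g"], rel=1e-12)
        frac = dr["Lu177g"] / combined["Lu177g"]
        # direct route supplies ~3.5% of the atoms after 5 days
        assert 0.03 < frac < 0.04

    def test_empty_routes(self):
        inv = ry.combine_routes([])
        assert inv.atoms == {}

    def test_target_depletion_closed_form(self):
        n0, phi, sigma = 3e21, 1.96e16, 1000.0
        t = math.log(10.0 / 9.0) / (phi * sigma * 1e-27)
        assert ry.target_depletion(n0, phi, sigma, t) == pytest.approx(0.9 * n0, rel=1e-12)
        assert ry.target_depletion(n0, phi, sigma, 0.0) == n0


class TestReport:
    def test_single_nuclide_full_purity(self):
        lu = ry.get_nuclide("Lu177g")
        rep = ry.report(ry.Inventory({"Lu177g": 1e18}), [lu])
        assert rep.frame.loc["Lu177g", "purity_pct"] == pytest.approx(100.0)

    def test_purity_normalization(self):
        """Radiopurities over the reported set sum to 100%."""
        names = ["Lu177g", "Lu177m", "Lu176m", "Lu174g", "Lu174m"]
        inv = ry.Inventory({n: 10.0 ** (12 + i) for i, n in enumerate(names)})
        rep = ry.report(inv, [ry.get_nuclide(n) for n in names])
        assert rep.frame.purity_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_stable_nuclide_zero_activity(self):
        lu175 = ry.get_nuclide("Lu175")
        rep = ry.report(ry.Inventory({"Lu175": 1e19, "Lu177g": 1e18}),
                        [lu175, ry.get_nuclide("Lu177g")])
        assert rep.frame.loc["Lu175", "activity_gbq"] == 0.0

    def test_specific_activity_variants(self):
        """Variant (a) divides by radionuclide mass only; variant (b) adds
        the stable carrier mass."""
        lu_g = ry.get_nuclide("Lu177g")
        lu175 = ry.get_nuclide("Lu175")
        inv = ry.Inventory({"Lu177g": 1e18, "Lu175": 4e18})
        rep = ry.report(inv, [lu_g, lu175], reference="Lu177g", coproducts=["Lu175"])
        mass_g = 1e18 * lu_g.molar_mass / 6.02214076e23 * 1e3
        mass_175 = 4e18 * lu175.molar_mass / 6.02214076e23 * 1e3
        act = 1e18 * lu_g.lam / 1e9
        assert rep.specific_activity_radionuclides == pytest.approx(act / mass_g, rel=1e-12)
        assert rep.specific_activity_element == pytest.approx(act / (mass_g + mass_175), rel=1e-12)
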