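"""Growth-model fitting and the 5-year-step simulator."""

import numpy as np
import pandas as pd
import pytest

from sylvasim import growth as gw
from sylvasim import scenarios
from sylvasim.inventory_io import PlotState, TreeRecord
from sylvasim.management import ManagementThresholds, SpeciesThresholds
from sylvasim.stand_metrics import FitError


def make_plot(pid="P1", species="X", v=200.0, dg=25.0, di=0.6, age=60.0,
              mgmt="actively-managed", area=1.0, **kw):
    return PlotState(plot_id=pid, region="R0", main_species=species, V=v, Dg=dg,
                     DI=di, age=age, mgmt=mgmt, area=area, H100=25.0, **kw)


def simple_params(a0=2.0, a_di=0.5, a_age=-0.3, b0=-5.5, b_di=-0.2, b_age=0.1,
                  species="X"):
    return gw.GrowthParams({
        species: gw.SpeciesGrowth(species, {"": a0}, a_di, a_age, 0.0,
                                  {"": b0}, b_di, b_age, 0.0)
    })


def simple_thresholds(clearcut=40.0, ratio=0.05, species="X"):
    return ManagementThresholds({
        species: SpeciesThresholds({"": clearcut}, di_threshold=0.9,
                                   thinning_ratio=ratio)
    })


class TestFitGrowthModels:
    def _frame(self, n=200, sd=0.0, a=(2.0, 0.5, -0.3), b=(-5.5, -0.2, 0.1),
               seed=0, fert=("",)):
        rng = np.random.default_rng(seed)
        di = rng.uniform(0.3, 1.0, n)
        age = rng.uniform(20, 120, n)
        fc = rng.choice(fert, n)
        iv = np.exp(a[0] + a[1] * np.log(di) + a[2] * np.log(age) + rng.normal(0, sd, n))
        ir = np.exp(b[0] + b[1] * np.log(di) + b[2] * np.log(age) + rng.normal(0, sd, n))
        return pd.DataFrame({"species": "X", "fert_class": fc, "IV": iv, "Ir": ir,
                             "DI": di, "age": age})

    def test_noise_free_exact_recovery(self):
        gp = gw.fit_growth_models(self._frame())
        sg = gp.for_species("X")
        assert sg.a_h100[""] == pytest.approx(2.0, abs=1e-8)
        assert sg.a_di == pytest.approx(0.5, abs=1e-8)
        assert sg.a_age == pytest.approx(-0.3, abs=1e-8)
        assert sg.b_di == pytest.approx(-0.2, abs=1e-8)

    def test_null_density_slope_within_2se(self):
        df = self._frame(n=500, sd=0.1, a=(2.0, 0.0, -0.3), seed=1)
        sg = gw.fit_growth_models(df).for_species("X")
        # 2 SE of the DI slope under sigma=0.1
        X = np.column_stack([np.ones(len(df)), np.log(df.DI), np.log(df.age)])
        se = 0.1 * np.sqrt(np.linalg.inv(X.T @ X)[1, 1])
        assert abs(sg.a_di) < 2 * se

    def test_noisy_recovery_matches_normal_equations_oracle(self):
        df = self._frame(n=2000, sd=0.2, seed=2)
        sg = gw.fit_growth_models(df).for_species("X")
        X = np.column_stack([np.ones(len(df)), np.log(df.DI), np.log(df.age)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(df.IV))
        assert sg.a_h100[""] == pytest.approx(beta[0], rel=1e-9)
        assert sg.a_di == pytest.approx(beta[1], rel=1e-9)
        cov = 0.2**2 * np.linalg.inv(X.T @ X)
        for got, want, var in [(sg.a_h100[""], 2.0, cov[0, 0]),
                               (sg.a_di, 0.5, cov[1, 1]),
                               (sg.a_age, -0.3, cov[2, 2])]:
            assert abs(got - want) < 2 * np.sqrt(var)

    def test_fertility_class_intercepts(self):
        rng = np.random.default_rng(3)
        n = 300
        di = rng.uniform(0.3, 1.0, n)
        age = rng.uniform(20, 120, n)
        fc = rng.choice(["F1", "F2"], n)
        icpt = np.where(fc == "F1", 1.5, 2.5)
        df = pd.DataFrame({
            "species": "X", "fert_class": fc,
            "IV": np.exp(icpt + 0.5 * np.log(di) - 0.3 * np.log(age)),
            "Ir": np.exp(icpt - 6.0 - 0.2 * np.log(di) + 0.1 * np.log(age)),
            "DI": di, "age": age,
        })
        sg = gw.fit_growth_models(df).for_species("X")
        assert sg.a_h100["F1"] == pytest.approx(1.5, abs=1e-8)
        assert sg.a_h100["F2"] == pytest.approx(2.5, abs=1e-8)

    def test_too_few_plots_raise(self):
        with pytest.raises(FitError):
            gw.fit_growth_models(self._frame(n=10))


class TestMortality:
    def _tree(self, v, status, species="X"):
        return TreeRecord(tree_id="t", species=species, r_ab=0.1, ir_bb=0.0,
                          v_ab=v, w=1.0, status=status)

    def test_no_dead_trees_gives_zero(self):
        assert gw.mortality_rate([self._tree(1.0, "alive")]) == {"X": 0.0}

    def test_ratio_over_census_interval(self):
        trees = [self._tree(100.0, "alive"), self._tree(5.0, "dead")]
        assert gw.mortality_rate(trees)["X"] == pytest.approx(0.05 / 5)

    def test_generator_truth_recovered_exactly(self, noise_free_inventory):
        plots, trees, truth = noise_free_inventory
        rates = gw.mortality_rate(t for recs in trees.values() for t in recs)
        sp = truth.species["Fagus sylvatica"]
        assert rates["Fagus sylvatica"] == pytest.approx(sp.mortality, rel=1e-12)


class TestStepPlot:
    def test_zero_increment_zero_mortality(self):
        gp = gw.GrowthParams({"X": gw.SpeciesGrowth("X", {"": -np.inf}, 0, 0, 0,
                                                    {"": -np.inf}, 0, 0, 0)})
        p = gw.step_plot(make_plot(v=150.0), gp, {})
        assert p.V == pytest.approx(150.0)
        assert p.age == 65.0

    def test_pure_mortality_compounds_yearly(self):
        gp = gw.GrowthParams({"X": gw.SpeciesGrowth("X", {"": -np.inf}, 0, 0, 0,
                                                    {"": -np.inf}, 0, 0, 0)})
        p = gw.step_plot(make_plot(v=150.0), gp, {"X": 0.02})
        assert p.V == pytest.approx(150.0 * 0.98**5)

    def test_growth_matches_direct_model_evaluation(self):
        gp = simple_params()
        p0 = make_plot(v=100.0, di=0.6, age=60.0)
        p = gw.step_plot(p0, gp, {})
        iv = np.exp(2.0 + 0.5 * np.log(0.6) - 0.3 * np.log(60.0))
        ir = np.exp(-5.5 - 0.2 * np.log(0.6) + 0.1 * np.log(60.0))
        assert p.V == pytest.approx(100.0 + iv, rel=1e-12)
        assert p.Dg == pytest.approx(25.0 + 200 * ir, rel=1e-12)
        assert (p.DI, p.H100) == (p0.DI, p0.H100)

    def test_smearing_back_transform(self):
        sg = gw.SpeciesGrowth("X", {"": 2.0}, 0.5, -0.3, 0.4, {"": -5.5}, -0.2, 0.1, 0.0)
        on = gw.GrowthParams({"X": sg}, smearing=True)
        off = gw.GrowthParams({"X": sg}, smearing=False)
        p = make_plot()
        iv_on, _ = gw.predict_increments(p, on)
        iv_off, _ = gw.predict_increments(p, off)
        assert iv_on == pytest.approx(iv_off * np.exp(0.4**2 / 2))


class TestThinning:
    def test_zero_ratio_no_removal(self):
        p, removed = gw.apply_thinning(make_plot(v=200.0), 0.0)
        assert removed == 0.0 and p.V == 200.0

    def test_diameter_unchanged(self):
        p, _ = gw.apply_thinning(make_plot(v=200.0, dg=27.0), 0.08)
        assert p.Dg == 27.0

    def test_yearly_compounding_matches_loop_oracle(self):
        p, removed = gw.apply_thinning(make_plot(v=200.0), 0.08)
        v = 200.0
        taken = 0.0
        for _ in range(5):
            taken += v * 0.08
            v *= 0.92
        assert removed == pytest.approx(taken, rel=1e-12)
        assert p.V == pytest.approx(v, rel=1e-12)


class TestClearcut:
    lib = gw.RegrowthLibrary({"X": gw.RegrowthStand(8.0, 10.0, 5.0)},
                             gw.RegrowthStand(6.0, 5.0, 5.0))

    def test_full_volume_harvested_and_regrowth_installed(self):
        p0 = make_plot(v=300.0, dg=45.0)
        p, harvested = gw.apply_clearcut(p0, simple_thresholds(), self.lib)
        assert harvested == 300.0
        assert (p.V, p.Dg, p.age) == (10.0, 8.0, 5.0)

    def test_regrowth_keeps_di_h100_area(self):
        p0 = make_plot(v=300.0, dg=45.0, di=0.77, area=12.0)
        p, _ = gw.apply_clearcut(p0, simple_thresholds(), self.lib)
        assert (p.DI, p.H100, p.area) == (0.77, 25.0, 12.0)

    def test_species_missing_from_library_uses_fallback(self):
        th = simple_thresholds(species="Y")
        p0 = make_plot(species="Y", v=300.0, dg=45.0)
        p, _ = gw.apply_clearcut(p0, th, self.lib)
        assert (p.Dg, p.V) == (6.0, 5.0)

    def test_below_threshold_not_eligible(self):
        with pytest.raises(gw.ValidationError):
            gw.apply_clearcut(make_plot(dg=30.0), simple_thresholds(), self.lib)


class TestRegrowthLibrary:
    def test_qualifying_young_stands_averaged_per_species(self):
        plots = [make_plot(pid=f"P{i}", age=8.0, dg=d, v=v, N=300.0)
                 for i, (d, v) in enumerate([(8.0, 12.0), (10.0, 18.0)])]
        lib = gw.build_regrowth_library(plots)
        assert lib.species["X"].dg0 == pytest.approx(9.0)
        assert lib.species["X"].v0 == pytest.approx(15.0)

    def test_sparse_young_stands_excluded(self):
        plots = [make_plot(pid="P0", age=8.0, dg=8.0, v=12.0, N=100.0)]
        lib = gw.build_regrowth_library(plots)
        assert "X" not in lib.species

    def test_fallback_is_unweighted_mean_over_species(self):
        plots = [make_plot(pid="P0", species="X", age=8.0, dg=8.0, v=12.0, N=300.0),
                 make_plot(pid="P1", species="Y", age=8.0, dg=12.0, v=20.0, N=300.0)]
        lib = gw.build_regrowth_library(plots)
        assert lib.fallback.dg0 == pytest.approx(10.0)
        assert lib.fallback.v0 == pytest.approx(16.0)


class TestRunSimulation:
    def _setup(self):
        gp = simple_params()
        th = simple_thresholds(clearcut=30.0, ratio=0.08)
        lib = gw.RegrowthLibrary({}, gw.RegrowthStand(6.0, 5.0, 5.0))
        return gp, th, lib

    def test_bau_protected_plots_never_harvested(self):
        gp, th, lib = self._setup()
        plots = [make_plot(pid="HD", dg=50.0, mgmt="harvest-delayed"),
                 make_plot(pid="UX", dg=50.0, mgmt="unexploitable")]
        traj = gw.run_simulation(plots, gp, {}, th, lib,
                                 scenarios.build_scenario("BaU"), 30)
        assert traj.harvest.empty

    def test_bau_overstocked_not_thinned_but_clearcut_at_diameter(self):
        gp, th, lib = self._setup()
        plots = [make_plot(pid="OS", dg=35.0, mgmt="overstocked")]
        traj = gw.run_simulation(plots, gp, {}, th, lib,
                                 scenarios.build_scenario("BaU"), 10)
        assert set(traj.harvest["source"]) == {"clearcut"}

    def test_coppice_clearcut_tagged_coppice(self):
        gp, th, lib = self._setup()
        plots = [make_plot(pid="CP", dg=35.0, structure="coppice")]
        traj = gw.run_simulation(plots, gp, {}, th, lib,
                                 scenarios.build_scenario("BaU"), 10)
        assert set(traj.harvest["source"]) == {"coppice", "thinning"}

    def test_three_plot_thirty_year_hand_ledger(self):
        """Full trajectory equals an independently stepped spreadsheet."""
        gp, th, lib = self._setup()
        mr = {"X": 0.01}
        plots = [
            make_plot(pid="A", v=200.0, dg=26.0, di=0.6, age=60.0),
            make_plot(pid="B", v=150.0, dg=20.0, di=0.5, age=40.0,
                      mgmt="overstocked"),
            make_plot(pid="C", v=300.0, dg=45.0, age=120.0, mgmt="harvest-delayed"),
        ]
        traj = gw.run_simulation(plots, gp, mr, th, lib,
                                 scenarios.build_scenario("BaU"), 30)

        # independent re-computation, plain loops
        def iv5(di, age):
            return np.exp(2.0 + 0.5 * np.log(di) - 0.3 * np.log(age))

        def ir5(di, age):
            return np.exp(-5.5 - 0.2 * np.log(di) + 0.1 * np.log(age))

        exp_states = {p.plot_id: [p.V, p.Dg, p.age, p.mgmt] for p in plots}
        exp_flows = []
        for step in range(6):
            for pid, st in exp_states.items():
                V, Dg, age, mgmt = st
                di = {"A": 0.6, "B": 0.5, "C": 0.6}[pid]
                grown = V + iv5(di, age)
                V = grown * 0.99**5
                Dg = Dg + 200 * ir5(di, age)
                age += 5
                if mgmt == "actively-managed":
                    removed = V * (1 - 0.92**5)
                    V -= removed
                    exp_flows.append(("thinning", removed))
                if mgmt in ("actively-managed", "overstocked") and Dg >= 30.0:
                    exp_flows.append(("clearcut", V))
                    V, Dg, age = 5.0, 6.0, 5.0
                st[:] = [V, Dg, age, mgmt]
        got = sorted(zip(traj.harvest["source"], traj.harvest["volume_per_ha"]))
        want = sorted(exp_flows)
        assert len(got) == len(want)
        for (gs, gv), (ws, wv) in zip(got, want):
            assert gs == ws and gv == pytest.approx(wv, rel=1e-9)
        final = {p.plot_id: p for p in traj.states[-1]}
        for pid, (V, Dg, age, _) in exp_states.items():
            assert final[pid].V == pytest.approx(V, rel=1e-9)
            assert final[pid].Dg == pytest.approx(Dg, rel=1e-9)

    def test_volume_conservation_every_step(self, legacy_fixture):
        fx = legacy_fixture
        traj = gw.run_simulation(fx["plots"], fx["gp"], fx["mr"],
                                 fx["truth"].thresholds, fx["lib"],
                                 scenarios.build_scenario("D", 5), 50)
        b = traj.balance
        free = b[b.clearcut == 0]
        err = (free.V_after - (free.V_before + free.iv - free.mortality
                               - free.thinned)).abs()
        assert err.max() < 1e-9 * max(1.0, free.V_before.max())

    def test_determinism_identical_trajectories(self, legacy_fixture):
        fx = legacy_fixture
        args = (fx["plots"], fx["gp"], fx["mr"], fx["truth"].thresholds, fx["lib"],
                scenarios.build_scenario("A", 3), 30)
        t1, t2 = gw.run_simulation(*args), gw.run_simulation(*args)
        pd.testing.assert_frame_equal(t1.harvest, t2.harvest)
        pd.testing.assert_frame_equal(t1.balance, t2.balance)
        assert t1.states[-1] == t2.states[-1]

    def test_bell_shaped_harvest_transient_under_d(self, legacy_fixture, species_table):
        """Mobilizing accumulated stock: extra harvest rises then falls.

        The linear mobilization ramp pulls the legacy stock into harvest
        over the first decades; once consumed, the extra harvest over the
        reference declines toward the new equilibrium.
        """
        fx = legacy_fixture
        args = (fx["plots"], fx["gp"], fx["mr"], fx["truth"].thresholds, fx["lib"])
        d_traj = gw.run_simulation(*args, scenarios.build_scenario("D", 10), 100,
                                   species_table)
        bau_traj = gw.run_simulation(*args, scenarios.build_scenario("BaU"), 100,
                                     species_table)
        extra = (d_traj.harvest.groupby("year")["volume_m3"].sum()
                 - bau_traj.harvest.groupby("year")["volume_m3"].sum()).fillna(0.0)
        smoothed = extra.rolling(3, center=True, min_periods=1).mean().to_numpy()
        peak = int(np.argmax(smoothed))
        assert 0 < peak < len(smoothed) - 1
        assert smoothed[peak] > smoothed[0] and smoothed[peak] > smoothed[-1]
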