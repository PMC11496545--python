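"""Vesicle ODE simulator: equilibria, conservation, ionophore logic."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from protoflux import chem
from protoflux import vesicle as vs
from protoflux.traces import steady_state_level

DATA = Path(__file__).parent / "data"


def window_level(res):
    return steady_state_level(res.pH_in, res.time, res.schedule).level


class TestGeometry:
    def test_sphere_relations(self):
        v = vs.Vesicle(60.0, interior=None, exterior=None)
        assert v.area_over_volume_cm == pytest.approx(6.0 / (60e-7), rel=1e-6)
        # one proton in a 60 nm vesicle is ~15 uM
        assert v.per_proton_mM == pytest.approx(1.47e-2, rel=0.01)

    def test_thickness_constraint(self):
        with pytest.raises(ValueError):
            vs.Vesicle(6.0, bilayer_thickness_nm=4.0)

    def test_capacitor_scale(self):
        v = vs.Vesicle(60.0)
        # ~70 elementary charges per 100 mV for a 60 nm, 1 uF/cm^2 sphere
        assert 100 * v.capacitance_mM_per_mV / v.per_proton_mM == pytest.approx(70, rel=0.05)


class TestPresets:
    def test_library_roundtrip_and_aliases(self):
        lib = vs.load_presets()
        assert lib["version"] == 1
        wt = vs.get_preset("WT-Nqo13")
        assert wt.copies_per_vesicle == 1 and not wt.blocked
        assert vs.get_preset("WT-Nqo12ΔTH").name == "WT-Nqo12dTH"

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            vs.get_preset("Nqo99")

    def test_blocked_and_empty_have_zero_rate(self):
        for name in ("K235M-Nqo13", "E377Q-Nqo13", "K385I-Nqo12", "empty", "AqpZ"):
            p = vs.get_preset(name)
            assert p.rate_constant(attempt=1.0, cap=1e3) == 0.0

    def test_open_presets_faster_than_closed(self):
        k = {n: vs.get_preset(n).rate_constant(0.004, 1e3)
             for n in ("WT-Nqo13", "E123Q-Nqo13", "WT-Nqo12dTH", "E132Q-Nqo12")}
        assert k["E123Q-Nqo13"] > k["WT-Nqo13"]
        assert k["E132Q-Nqo12"] > k["WT-Nqo12dTH"]

    def test_electroneutral_initialisation(self):
        lib = vs.load_presets()
        ves = vs._acetate_vesicle(lib)
        q = ves.interior.implicit_counter_charge()
        # MOPS(-1 mM) + pyranine(~ -17 mM) + residual(~ -13 mM) anions need a
        # positive implicit counter-cation; KCl contributes zero net charge
        assert q > 0
        assert q == pytest.approx(1.0 + 5 * (3 + 0.443) + 22.6 * 0.586, rel=0.02)


class TestQuiescentAndControls:
    def test_empty_schedule_is_constant(self):
        lib = vs.load_presets()
        assay = vs.ProtonFluxAssay(
            vesicle=vs._acetate_vesicle(lib),
            preset=vs.get_preset("WT-Nqo13"),
            schedule=vs.EventSchedule([]),
            ionophores=[vs.Ionophore("valinomycin", active_from=0.0)],
            channel_attempt=lib["acetate_attempt"],
            leak_rate=lib["leak_rate_s"],
        )
        res = assay.run(t_end=120.0)
        assert np.max(np.abs(res.pH_in - res.pH_in[0])) < 1e-6
        assert np.max(np.abs(res.delta_psi)) < 1e-6

    def test_control_acidification_drop(self, control_acetate):
        res = control_acetate
        before = res.pH_in[res.time < 60.0][-1]
        drop = before - res.pH_in.min()
        assert drop == pytest.approx(0.3, abs=0.05)

    def test_control_slow_alkalinisation(self, control_acetate):
        res = control_acetate
        level = window_level(res)
        assert res.pH_in.min() < level <= 7.04

    def test_blocked_presets_match_empty_liposomes(self, control_acetate):
        for name in ("AqpZ", "K235M-Nqo13", "E377Q-Nqo13", "K385I-Nqo12"):
            res = vs.acetate_assay(name)
            assert np.max(np.abs(res.pH_in - control_acetate.pH_in)) < 1e-6


class TestConservation:
    def test_acetate_mass_balance(self, wt_acetate):
        """Interior acetate change equals the integrated membrane flux."""
        res = wt_acetate
        a = res.species["acetate_total_mM"]
        da = a[-1] - a[0]
        cum = res.cumulative_flux["cum_acid_in"][-1]
        assert abs(da - cum) / abs(da) < 1e-8

    def test_acetate_flux_trapezoid_oracle(self, wt_acetate):
        """Independent check: recompute the neutral-form flux from the saved
        trajectory and integrate it over a smooth stretch of the trace."""
        res = wt_acetate
        lib = vs.load_presets()
        sa_v = vs.Vesicle(60.0).area_over_volume_cm
        ha_out = 10.0 * (1 - float(chem.deprotonated_fraction(7.2, 4.8)))
        mask = (res.time >= 70.0) & (res.time <= 540.0)
        j = 6e-3 * sa_v * (ha_out - res.species["acetic_acid_mM"][mask])
        integral = np.trapezoid(j, res.time[mask])
        a = res.species["acetate_total_mM"]
        da = a[mask][-1] - a[mask][0]
        assert integral == pytest.approx(da, rel=1e-2)


class TestSteadyStates:
    def test_wt_reaches_printed_plateau(self, wt_acetate):
        assert window_level(wt_acetate) >= 7.1

    def test_open_ion_pair_variant_plateau(self, e123q_acetate):
        assert window_level(e123q_acetate) == pytest.approx(7.15, abs=0.02)

    def test_endpoint_independent_of_rate_magnitude(self):
        """The pre-nigericin plateau of fast channels is the thermodynamic
        (Donnan) endpoint, unchanged when the rate constant is scaled."""
        lib = vs.load_presets()
        levels, t50 = [], []
        for attempt in (0.05, 0.5):
            lib2 = dict(lib)
            lib2["acetate_attempt"] = attempt
            res = vs.acetate_assay("WT-Nqo13", library=lib2)
            levels.append(window_level(res))
            after = (res.time > 60.0) & (res.time < 540.0)
            reach = res.time[after][res.pH_in[after] >= 7.05]
            t50.append(reach[0] if len(reach) else np.inf)
        assert levels[0] == pytest.approx(levels[1], abs=5e-3)
        assert t50[1] < t50[0]  # faster channel reaches the plateau earlier

    def test_solver_tolerance_robustness(self):
        lib = vs.load_presets()
        assay = vs._weak_acid_assay("WT-Nqo13", "add_acetate", 10.0, 60.0, 540.0, 600.0, lib)
        r1 = assay.run(600.0, rtol=1e-8, atol=1e-10)
        assay2 = vs._weak_acid_assay("WT-Nqo13", "add_acetate", 10.0, 60.0, 540.0, 600.0, lib)
        r2 = assay2.run(600.0, rtol=5e-9, atol=5e-11)
        assert abs(window_level(r1) - window_level(r2)) < 1e-4


class TestDirectionality:
    def test_methylamine_reverses_transport(self, wt_acetate):
        """Weak base influx alkalinises the interior: the proton flux through
        the channel changes sign relative to the acetate assay."""
        res = vs.methylamine_assay("WT-Nqo13")
        assert res.pH_in.max() > 7.3  # interior alkalinises
        assert wt_acetate.pH_in.min() < 7.0  # acid assay acidifies
        # channel flux direction flips: cumulative channel flux has opposite sign
        assert res.cumulative_flux["cum_channel_in"][-1] > 0
        assert wt_acetate.cumulative_flux["cum_channel_in"][-1] < 0

    def test_nigericin_collapses_gradient(self, control_acetate):
        res = control_acetate
        pre = window_level(res)
        assert abs(res.pH_in[-1] - 7.2) < 0.1
        assert abs(res.pH_in[-1] - 7.2) < abs(pre - 7.2)


class TestAtpCompetition:
    def test_quench_plateaus(self, f1fo_atp, wt_atp):
        q_pump = 100 * (1 - steady_state_level(f1fo_atp.acma_F, f1fo_atp.time,
                                               f1fo_atp.schedule).level)
        q_wt = 100 * (1 - steady_state_level(wt_atp.acma_F, wt_atp.time,
                                             wt_atp.schedule).level)
        assert q_pump == pytest.approx(90.0, abs=5.0)
        assert q_wt == pytest.approx(30.0, abs=5.0)
        assert q_pump > q_wt  # the antiporter leak limits the pump

    def test_baseline_stable_before_atp(self, f1fo_atp):
        base = f1fo_atp.acma_F[f1fo_atp.time < 60.0]
        assert np.max(np.abs(base - 1.0)) < 1e-6

    def test_pump_stall_law(self):
        pump = vs.PumpATPase(turnover_max=2400.0, stall_pmf=4.0)
        assert pump.flux(0.0) == 2400.0
        assert pump.flux(4.0) == 0.0
        assert pump.flux(8.0) == 0.0
        assert pump.flux(2.0) == pytest.approx(1200.0)


class TestResultObject:
    def test_golden_trajectory_regression(self, wt_acetate):
        golden = pd.read_csv(DATA / "golden_wt_acetate.csv")
        df = wt_acetate.to_frame()
        sub = df[df["time_s"] % 12 < 1e-9].reset_index(drop=True)
        assert len(sub) == len(golden)
        for col in golden.columns:
            assert np.allclose(sub[col], golden[col], rtol=1e-4, atol=1e-4), col

    def test_frames_and_summary(self, wt_acetate):
        df = wt_acetate.to_frame()
        assert {"time_s", "pH_in", "dpsi_mV", "I404", "I454"} <= set(df.columns)
        tidy = wt_acetate.to_frame(tidy=True)
        assert set(tidy.columns) == {"time_s", "variable", "value"}
        assert "final pH_in" in wt_acetate.summary()

    def test_plot_smoke(self, wt_acetate):
        ax = wt_acetate.plot()
        assert ax.get_xlabel() == "time (s)"


class TestValidation:
    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            vs.EventSchedule([vs.Event(10.0, "add_acetate", 1.0),
                              vs.Event(5.0, "add_nigericin")])
        with pytest.raises(ValueError):
            vs.Event(0.0, "add_magic", 1.0)

    def test_reservoir_required(self):
        lib = vs.load_presets()
        ves = vs._acetate_vesicle(lib)
        ves.exterior.is_reservoir = False
        assay = vs.ProtonFluxAssay(ves, vs.get_preset("empty"), vs.EventSchedule([]))
        with pytest.raises(ValueError):
            assay.run(10.0)

    def test_events_within_horizon(self):
        lib = vs.load_presets()
        assay = vs.ProtonFluxAssay(
            vs._acetate_vesicle(lib), vs.get_preset("empty"),
            vs.EventSchedule([vs.Event(500.0, "add_acetate", 1.0)]),
        )
        with pytest.raises(ValueError):
            assay.run(100.0)
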