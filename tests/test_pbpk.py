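import numpy as np
import pytest

from lipopbpk.pbpk import (DoseEvent, ModelBuildError, build_model,
                           exposure_metrics, simulate)
from lipopbpk.synthetic import monkey_truth_model


def test_dose_events_validated():
    with pytest.raises(ValueError):
        DoseEvent("iv_bolus", -1.0, 0.0)
    with pytest.raises(ValueError):
        DoseEvent("iv_infusion", 10.0, 0.0, duration=0.0)
    with pytest.raises(ValueError):
        DoseEvent("oral", 10.0, 0.0)


def test_missing_kp_is_named(monkey_phys, monkey_truth):
    kps = dict(monkey_truth.kps)
    kps.pop("spleen")
    with pytest.raises(ModelBuildError, match="spleen"):
        build_model(monkey_phys, kps, 0.6)


def test_structural_audit_every_compartment_connected(monkey_truth):
    # every systemic tissue has nonzero flow and a Kp; venous collects them
    for t in monkey_truth.physiology.systemic_tissues:
        assert t.blood_flow > 0
        assert monkey_truth.kps[t.name] >= 0
    assert set(monkey_truth.compartments) >= {"lung", "arterial_blood",
                                              "venous_blood"}


def test_zero_clearance_conserves_dose(monkey_phys, monkey_truth):
    model = build_model(monkey_phys, monkey_truth.kps, 0.0,
                        dosing=[DoseEvent("iv_bolus", 10.0, 0.0)])
    sim = simulate(model, 6.0)
    totals = sim.amounts.sum(axis=0)
    assert np.allclose(totals, 10.0, rtol=1e-6)
    assert sim.eliminated[-1] == pytest.approx(0.0, abs=1e-9)


def test_mass_balance_through_elimination(monkey_sim_69mg):
    assert monkey_sim_69mg.mass_balance_error < 1e-6


def test_dose_superposition_linearity(monkey_truth):
    lo = simulate(monkey_truth.with_dosing([DoseEvent("iv_bolus", 10.0, 0.0)]), 8.0)
    hi = simulate(monkey_truth.with_dosing([DoseEvent("iv_bolus", 40.0, 0.0)]), 8.0)
    mask = lo.plasma_conc > lo.plasma_conc.max() * 1e-9
    ratio = hi.plasma_conc[mask] / lo.plasma_conc[mask]
    assert np.allclose(ratio, 4.0, rtol=1e-6)
    auc_lo = exposure_metrics(lo)["AUC_last"]
    auc_hi = exposure_metrics(hi)["AUC_last"]
    assert auc_hi / auc_lo == pytest.approx(4.0, rel=1e-6)


def test_auc_inf_equals_dose_over_cl(monkey_sim_69mg, monkey_truth):
    met = exposure_metrics(monkey_sim_69mg)
    assert met["AUC_inf"] * monkey_truth.clearance / 69.0 == pytest.approx(
        1.0, abs=5e-3)


def test_infusion_delivers_full_dose(monkey_truth):
    model = monkey_truth.with_dosing(
        [DoseEvent("iv_infusion", 12.0, start=0.0, duration=1.5)])
    sim = simulate(model, 6.0)
    assert sim.dose_administered[-1] == pytest.approx(12.0)
    assert sim.mass_balance_error < 1e-6
    # plasma peak at end of infusion, not at t=0
    met = exposure_metrics(sim, extrapolate=False)
    assert 0.5 < met["Tmax"] <= 1.5 + 1e-9


def test_tolerance_convergence(monkey_truth):
    model = monkey_truth.with_dosing([DoseEvent("iv_bolus", 69.0, 0.0)])
    a = exposure_metrics(simulate(model, 12.0))["AUC_inf"]
    b = exposure_metrics(simulate(model, 12.0, rtol=1e-9, atol=1e-11))["AUC_inf"]
    assert abs(a / b - 1) < 1e-3


def test_exposure_metrics_closed_forms():
    # mono-exponential series: AUC_inf = C0/k
    from lipopbpk.pbpk import SimulationResult
    t = np.arange(0, 30.0001, 0.01)
    c = 100.0 * np.exp(-0.6931 * t)
    res = SimulationResult(time=t, amounts=np.zeros((1, t.size)),
                           compartments=["venous_blood"],
                           eliminated=np.zeros(t.size),
                           dose_administered=np.zeros(t.size), plasma_conc=c)
    met = exposure_metrics(res)
    assert met["AUC_inf"] == pytest.approx(100.0 / 0.6931, rel=1e-3)
    # flat series over [0, 1]: AUC_last = 10
    t2 = np.linspace(0, 1, 101)
    res2 = SimulationResult(time=t2, amounts=np.zeros((1, 101)),
                            compartments=["venous_blood"],
                            eliminated=np.zeros(101),
                            dose_administered=np.zeros(101),
                            plasma_conc=np.full(101, 10.0))
    assert exposure_metrics(res2, extrapolate=False)["AUC_last"] == pytest.approx(10.0)


def test_random_models_mass_balance_and_dose_over_cl(monkey_truth, rng):
    for _ in range(5):
        cl = float(rng.uniform(0.1, 2.0))
        scale = float(rng.uniform(0.3, 3.0))
        dose = float(rng.uniform(5.0, 200.0))
        kps = {k: v * scale for k, v in monkey_truth.kps.items()}
        model = build_model(monkey_truth.physiology, kps, cl,
                            dosing=[DoseEvent("iv_bolus", dose, 0.0)])
        t_end = max(12.0, 9 * 0.693 * model.vss / cl)
        sim = simulate(model, t_end)
        assert sim.mass_balance_error < 1e-6
        met = exposure_metrics(sim)
        assert met["AUC_inf"] * cl / dose == pytest.approx(1.0, abs=5e-3)
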