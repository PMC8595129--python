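import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipopbpk.partition import (KpConfigurationError, PhyschemProfile,
                                TissueComposition, kp_lukacova,
                                kp_rodgers_single, load_tissue_composition,
                                vss_from_kps)
from lipopbpk.physiology import load_physiology

WATER_TISSUE = TissueComposition("toy", f_ew=0.4, f_iw=0.6, f_nl=0.0,
                                 f_np=0.0, ap_mg_per_g=0.0, albumin_ratio=0.0)
TOY_TISSUE = TissueComposition("toy", f_ew=0.3, f_iw=0.4, f_nl=0.05,
                               f_np=0.01, ap_mg_per_g=1.0, albumin_ratio=0.2)


def test_neutral_identity_case_kp_is_one():
    # no lipid, no protein, tissue water equals (unit) plasma water, fup=1
    drug = PhyschemProfile(100.0, "neutral", (), logp=-30.0, fup=1.0)
    assert kp_rodgers_single(drug, WATER_TISSUE) == pytest.approx(1.0)


def test_toy_neutral_drug_matches_hand_evaluation():
    # hand evaluation of the albumin-branch equation, P = 10, fup = 0.5:
    #   lipid_plasma = 10*0.0023 + 3.7*0.0013          = 0.02781
    #   Ka_PR        = 1/0.5 - 1 - 0.02781             = 0.97219
    #   lipid_tissue = 10*0.05 + 3.7*0.01              = 0.537
    #   Kpu          = 0.3 + 0.4 + 0.537 + 0.97219*0.2 = 1.431438
    #   Kp           = 0.5 * Kpu                       = 0.715719
    drug = PhyschemProfile(100.0, "neutral", (), logp=1.0, fup=0.5)
    assert kp_rodgers_single(drug, TOY_TISSUE) == pytest.approx(0.715719, abs=1e-6)


def test_strong_binding_raises_kp_when_protein_rich_tissue():
    # lean low-water tissue where the albumin term dominates
    tissue = TissueComposition("lean", 0.2, 0.2, 0.0, 0.0, 0.0,
                               albumin_ratio=1.0)
    bound = PhyschemProfile(100.0, "neutral", (), logp=-5.0, fup=0.01)
    free = PhyschemProfile(100.0, "neutral", (), logp=-5.0, fup=1.0)
    assert kp_rodgers_single(bound, tissue) > kp_rodgers_single(free, tissue)


def test_negative_logp_lean_tissue_kp_below_one():
    drug = PhyschemProfile(100.0, "neutral", (), logp=-3.0, fup=1.0)
    lean = TissueComposition("lean", 0.2, 0.5, 0.01, 0.001, 0.5,
                             albumin_ratio=0.05)
    assert kp_rodgers_single(drug, lean) <= 1.0


def test_lukacova_dispatch_matches_neutral_branch():
    drug = PhyschemProfile(100.0, "neutral", (), logp=0.5, fup=0.3)
    assert kp_lukacova(drug, TOY_TISSUE) == kp_rodgers_single(drug, TOY_TISSUE)


def test_polyanion_is_fully_ionized_acid_limit():
    # the polyanion branch must equal the acid branch with a very low pKa
    poly = PhyschemProfile(6044.4, "polyanion", (), logp=-2.0, fup=0.02)
    acid = PhyschemProfile(6044.4, "monoprotic_acid", (0.5,), logp=-2.0, fup=0.02)
    kp_p = kp_lukacova(poly, TOY_TISSUE)
    kp_a = kp_rodgers_single(acid, TOY_TISSUE)
    assert kp_p == pytest.approx(kp_a, rel=1e-3)


def test_missing_pka_is_configuration_error():
    with pytest.raises(KpConfigurationError):
        kp_rodgers_single(
            PhyschemProfile(100.0, "monoprotic_base", (), logp=1.0, fup=0.5),
            TOY_TISSUE)
    with pytest.raises(KpConfigurationError):
        kp_rodgers_single(
            PhyschemProfile(100.0, "monoprotic_acid", (), logp=1.0, fup=0.5),
            TOY_TISSUE)


def test_kp_monotone_in_logp_over_bundled_tissues():
    comp = load_tissue_composition()
    grid = np.linspace(-4, 4, 33)
    for tissue in comp.values():
        kps = [kp_rodgers_single(
            PhyschemProfile(300.0, "neutral", (), logp=lp, fup=0.5), tissue)
            for lp in grid]
        assert np.all(np.diff(kps) >= -1e-12), tissue.name


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    logp=st.floats(-5, 5),
    fup=st.floats(0.001, 1.0),
    cls=st.sampled_from(["neutral", "monoprotic_acid", "monoprotic_base",
                         "polyanion", "zwitterion"]),
    pka=st.floats(1.0, 12.0),
)
def test_kp_nonnegative_for_valid_inputs(logp, fup, cls, pka):
    pkas = {"neutral": (), "polyanion": (), "monoprotic_acid": (pka,),
            "monoprotic_base": (pka,), "zwitterion": (pka, max(pka - 4, 0.5))}
    drug = PhyschemProfile(500.0, cls, pkas[cls], logp=logp, fup=fup)
    assert kp_lukacova(drug, TOY_TISSUE) >= 0.0


def test_vss_arithmetic_and_linearity(monkey_phys):
    names = [t.name for t in monkey_phys.perfused_tissues]
    base = {n: 1.0 for n in names}
    v_tissue = sum(t.volume for t in monkey_phys.perfused_tissues)
    assert vss_from_kps({n: 0.0 for n in names}, monkey_phys) == pytest.approx(
        monkey_phys.plasma_volume)
    assert vss_from_kps(base, monkey_phys) == pytest.approx(
        monkey_phys.plasma_volume + v_tissue)
    # linear in each Kp
    bumped = dict(base, liver=base["liver"] + 2.0)
    dv = vss_from_kps(bumped, monkey_phys) - vss_from_kps(base, monkey_phys)
    assert dv == pytest.approx(2.0 * monkey_phys.tissue_map["liver"].volume)


def test_vss_missing_tissue_named(monkey_phys):
    kps = {t.name: 1.0 for t in monkey_phys.perfused_tissues}
    kps.pop("spleen")
    with pytest.raises(KeyError, match="spleen"):
        vss_from_kps(kps, monkey_phys)


def test_vss_toy_arithmetic():
    # plasma 3 L + 10 L at Kp 2 + 5 L at Kp 0.5 = 25.5 L
    import dataclasses
    phys = load_physiology("monkey")
    t1 = dataclasses.replace(phys.tissues[0], name="a", volume=10.0)
    t2 = dataclasses.replace(phys.tissues[0], name="b", volume=5.0)
    art = dataclasses.replace(phys.tissue_map["arterial_blood"], volume=2.5)
    ven = dataclasses.replace(phys.tissue_map["venous_blood"], volume=2.5)
    toy = dataclasses.replace(phys, hematocrit=0.4, tissues=(t1, t2, art, ven))
    assert toy.plasma_volume == pytest.approx(3.0)
    assert vss_from_kps({"a": 2.0, "b": 0.5}, toy) == pytest.approx(25.5)
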