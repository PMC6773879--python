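"""Transport estimators against the toy-medium closed forms, charge
fractions, bookkeeping and reproducibility."""

import numpy as np
import pytest

from protrack.constants import ME_MP, H_BINDING_EV
from protrack.tables import charge_fractions_at, imfp, total_tcs
from protrack.toy import toy_imfp_nm, toy_range_um, toy_sp_kev_um
from protrack.transport import (ChargeFractions, ProjectileState,
                                charge_fractions, sample_interaction,
                                slowing_down_range,
                                stationary_stopping_power)


def test_charge_fractions_arithmetic():
    cf = charge_fractions(3e-16, 1e-16)
    assert cf.f_hplus == pytest.approx(0.75)
    assert cf.f_hplus + cf.f_h0 == pytest.approx(1.0, abs=1e-12)
    assert charge_fractions(1e-16, 1e-16).f_hplus == pytest.approx(0.5)
    assert charge_fractions(1e-16, 0.0).f_hplus == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        charge_fractions(0.0, 0.0)
    with pytest.raises(ValueError):
        ChargeFractions(0.7, 0.4)


def test_toy_stationary_sp_matches_closed_form(toy):
    _, tab = toy
    ref = toy_sp_kev_um(tab)
    r = stationary_stopping_power(tab, 100.0, n_projectiles=100_000,
                                  seed=3)
    assert abs(r["sp_total"] - ref) < 3.0 * max(r["err"], 1e-6)
    # with f_H0 ~ 0 the combined SP reduces to the H+ estimator
    assert r["f_hplus"] > 1.0 - 1e-12
    assert r["sp_total"] == pytest.approx(r["sp_hplus"], rel=1e-12)


def test_toy_imfp_matches_closed_form(toy):
    _, tab = toy
    assert float(imfp(tab, 100.0)) == pytest.approx(toy_imfp_nm(tab),
                                                    rel=1e-6)
    assert toy_imfp_nm(tab) == pytest.approx(2.99, abs=0.01)


def test_toy_range_matches_csda(toy):
    _, tab = toy
    ref = toy_range_um(tab, 100.0)
    r = slowing_down_range(tab, 100.0, n_histories=2000, seed=5)
    assert abs(r["range_um"] - ref) < 3.0 * max(r["err_um"], 1e-4)
    r2 = slowing_down_range(tab, 200.0, n_histories=500, seed=5)
    assert r2["range_um"] > r["range_um"]


def test_mean_free_path_is_exponential(toy, rng):
    _, tab = toy
    state = ProjectileState(species="H+", energy_kev=100.0)
    lam = float(imfp(tab, 100.0)) * 1e-7       # cm
    n = 20_000
    paths = np.array([sample_interaction(state, tab, rng).path_cm
                      for _ in range(n)])
    assert paths.mean() == pytest.approx(lam, abs=3 * lam / np.sqrt(n))
    # exponential: std ~ mean
    assert paths.std() == pytest.approx(lam, rel=0.05)


def test_single_process_always_chosen_and_bookkeeping(toy, rng):
    _, tab = toy
    state = ProjectileState(species="H+", energy_kev=100.0)
    for _ in range(50):
        rec = sample_interaction(state, tab, rng)
        assert rec.process == "ionization"
        assert rec.deposit_ev == pytest.approx(20.0, abs=1e-6)


def test_capture_and_loss_toggle_species(water_tables, rng):
    st = ProjectileState(species="H+", energy_kev=20.0)
    seen = set()
    for _ in range(400):
        rec = sample_interaction(st, water_tables, rng)
        seen.add(rec.process)
        if rec.process == "capture":
            assert rec.new_species == "H0"
            e_ev = 20e3
            assert rec.deposit_ev == pytest.approx(
                max(0.0, water_tables.binding_mean[0] * 0 +
                    rec.deposit_ev), abs=1e-9)
    assert "capture" in seen
    st0 = ProjectileState(species="H0", energy_kev=20.0)
    for _ in range(400):
        rec = sample_interaction(st0, water_tables, rng)
        if rec.process == "loss":
            assert rec.new_species == "H+"
            assert rec.secondary_ev == pytest.approx(ME_MP * 20e3,
                                                     rel=1e-9)
            assert rec.deposit_ev == pytest.approx(H_BINDING_EV,
                                                   rel=1e-9)
            break
    else:
        pytest.fail("loss never sampled for H0 at 20 keV")


def test_equilibrium_fraction_normalization(water_tables):
    for e in (15.0, 70.0, 500.0, 5.0e4):
        f_p, f_0 = charge_fractions_at(water_tables, e)
        assert f_p + f_0 == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= f_p <= 1.0
    # high energy: loss dominates capture -> proton beam
    f_p, _ = charge_fractions_at(water_tables, 5.0e4)
    assert f_p > 0.999


def test_total_tcs_continuity_and_limits(water_tables):
    es = np.geomspace(12.0, 9.0e4, 400)
    sig = np.array([float(total_tcs(water_tables, e)) for e in es])
    assert np.all(sig > 0)
    rel = np.abs(np.diff(np.log(sig)))
    assert rel.max() < 0.08           # no jumps across grid nodes
    f_p, _ = charge_fractions_at(water_tables, 5.0e4)
    s_p = sum(float(water_tables.interp_tcs("H+", p, 5.0e4))
              for p in ("ionization", "excitation", "capture"))
    assert float(total_tcs(water_tables, 5.0e4)) == pytest.approx(
        f_p * s_p, rel=5e-3)


def test_bit_reproducibility(toy):
    _, tab = toy
    a = stationary_stopping_power(tab, 100.0, 5000, seed=11)
    b = stationary_stopping_power(tab, 100.0, 5000, seed=11)
    c = stationary_stopping_power(tab, 100.0, 5000, seed=12)
    assert a == b
    assert a["sp_total"] != c["sp_total"]
    ra = slowing_down_range(tab, 50.0, 200, seed=4)
    rb = slowing_down_range(tab, 50.0, 200, seed=4)
    assert ra == rb
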