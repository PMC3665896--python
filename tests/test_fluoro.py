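import numpy as np
import pytest

from mitotherm import fluoro, flux, suit, synth
from mitotherm.flux import IntervalFlux
from mitotherm.io import AnnotatedTrace, AssayMeta, EventMark


def _ros_trace(step=400.0, amount=400.0, drift=0.0, slopes=(),
               mass=2.0):
    """Resorufin spike at t=100 then one 300-s interval per slope."""
    t = np.arange(0.0, 100.0 + 300.0 * (len(slopes) + 1), 1.0)
    f = 50.0 + drift * t + step * (t >= 100.0)
    events = [EventMark(t=100.0, label="Resorufin", amount=amount,
                        unit="pmol")]
    ivs = []
    # titration intervals start one spacing after the calibration spike so
    # the step-height windows see flat signal on both sides
    for i, s in enumerate(slopes):
        t0 = 400.0 + 300.0 * i
        f = f + s * np.clip(t - t0, 0.0, 300.0)
        ivs.append(IntervalFlux(label=f"S{i}", t_start=t0,
                                t_end=t0 + 300.0, flux=1.0, sd=0.0, n=60))
    meta = AssayMeta(fibre_mass=mass)
    tr = AnnotatedTrace(time=t, channels={"fluo_ros": f},
                        events=events, meta=meta)
    return tr, ivs


def test_calibrate_ros_sensitivity_examples():
    tr, _ = _ros_trace(step=400.0, amount=400.0)
    assert fluoro.calibrate_ros(tr).sensitivity == pytest.approx(1.0)
    tr, _ = _ros_trace(step=100.0, amount=400.0)
    assert fluoro.calibrate_ros(tr).sensitivity == pytest.approx(0.25)


def test_calibrate_ros_drift_corrected():
    tr, _ = _ros_trace(step=320.0, amount=400.0, drift=0.05)
    assert fluoro.calibrate_ros(tr).sensitivity == pytest.approx(0.8,
                                                                 rel=1e-6)


def test_calibrate_ros_errors():
    tr, _ = _ros_trace()
    tr.events[0] = EventMark(t=100.0, label="Resorufin", amount=np.nan)
    with pytest.raises(fluoro.CalibrationError):
        fluoro.calibrate_ros(tr)
    tr, _ = _ros_trace(step=-10.0)
    with pytest.raises(fluoro.CalibrationError):
        fluoro.calibrate_ros(tr)


def test_ros_rate_unit_arithmetic():
    # slope 0.002 units/s, sensitivity 1.0, mass 2 mg -> 1 fmol (mg s)^-1
    tr, ivs = _ros_trace(step=400.0, amount=400.0, slopes=[0.002])
    cal = fluoro.calibrate_ros(tr)
    rates, flags = fluoro.ros_rate(tr, cal, ivs)
    assert rates["S0"] == pytest.approx(1.0, rel=1e-6)
    assert flags == []


def test_ros_rate_offset_invariance_and_mass():
    tr, ivs = _ros_trace(slopes=[0.004, 0.008])
    cal = fluoro.calibrate_ros(tr)
    r1, _ = fluoro.ros_rate(tr, cal, ivs)
    tr.channels["fluo_ros"] = tr.channels["fluo_ros"] + 1000.0
    r2, _ = fluoro.ros_rate(tr, cal, ivs)
    assert r2 == pytest.approx(r1)
    r_half, _ = fluoro.ros_rate(tr, cal, ivs, mass=1.0)
    for k in r1:
        assert r_half[k] == pytest.approx(2.0 * r1[k], rel=1e-6)


def test_ros_rate_background_and_floor():
    tr, ivs = _ros_trace(slopes=[0.004])
    cal = fluoro.calibrate_ros(tr)
    rates, _ = fluoro.ros_rate(tr, cal, ivs, background_slope=0.001)
    assert rates["S0"] == pytest.approx((0.004 - 0.001) / 1.0 / 2.0 * 1000)
    rates, flags = fluoro.ros_rate(tr, cal, ivs, background_slope=0.01)
    assert rates["S0"] == 0.0
    assert "NEGATIVE_RATE:S0" in flags


def test_calibrate_mgg_examples_and_gain_invariance():
    c = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    cal = fluoro.calibrate_mgg((c, 1.2 * c), (c, 1.92 * c),
                               temperature=20.0)
    assert cal.adp_slope == pytest.approx(1.2)
    assert cal.atp_to_adp_ratio == pytest.approx(1.6)
    assert cal.adp_pulse_signal == pytest.approx(12.0)
    cal3 = fluoro.calibrate_mgg((c, 3.6 * c), (c, 5.76 * c),
                                temperature=20.0)
    assert cal3.atp_to_adp_ratio == pytest.approx(1.6)


def test_calibrate_mgg_rejects_nonlinear():
    c = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    with pytest.raises(fluoro.CalibrationError):
        fluoro.calibrate_mgg((c, 0.2 * c ** 2), (c, 1.92 * c),
                             temperature=20.0)
    with pytest.raises(fluoro.CalibrationError):
        fluoro.calibrate_mgg((c[:2], 1.2 * c[:2]), (c, 1.92 * c),
                             temperature=20.0)


def _mgg_trace(quench_slope, mass=2.0, volume=2.0, temperature=20.0):
    t = np.arange(0.0, 400.0, 1.0)
    f = 1000.0 - quench_slope * t
    iv = IntervalFlux(label="ADP", t_start=50.0, t_end=350.0, flux=1.0,
                      sd=0.0, n=60)
    meta = AssayMeta(temperature=temperature, fibre_mass=mass,
                     chamber_volume=volume)
    return AnnotatedTrace(time=t, channels={"fluo_mgg": f},
                          meta=meta), [iv]


def test_atp_rate_unit_arithmetic():
    # 50 pmol s^-1 mg^-1 at mass 2 mg, volume 2 mL -> 0.05 uM/s, which
    # quenches at 0.05 * 1.2 * 1.6 = 0.096 units/s
    cal = fluoro.MgGCalibration(adp_slope=1.2, atp_to_adp_ratio=1.6,
                                temperature=20.0, adp_pulse_signal=12.0)
    tr, ivs = _mgg_trace(0.096)
    rates, flags = fluoro.atp_rate(tr, cal, ivs)
    assert rates["ADP"] == pytest.approx(50.0, rel=1e-9)
    assert flags == []


def test_atp_rate_temperature_mismatch():
    cal = fluoro.MgGCalibration(adp_slope=1.2, atp_to_adp_ratio=1.6,
                                temperature=25.0, adp_pulse_signal=12.0)
    tr, ivs = _mgg_trace(0.096, temperature=20.0)
    with pytest.raises(KeyError):
        fluoro.atp_rate(tr, cal, ivs)


def test_atp_o_ratio():
    assert fluoro.atp_o_ratio(35.28, 19.6) == pytest.approx(1.8)
    assert fluoro.atp_o_ratio(35.28, 19.6, per_o_atom=True) \
        == pytest.approx(3.6)
    with pytest.raises(ValueError):
        fluoro.atp_o_ratio(10.0, 0.0)


def _fig10_atp_o(preset, temperature, seed_root):
    """Mean ATP/O in OXP-I,II across the preset's n fish."""
    rng = np.random.default_rng(seed_root)
    concs = preset["mgg_titration_concs_um"]
    vals = []
    for _ in range(preset["n_per_temperature"]):
        s = int(rng.integers(0, 2**31 - 1))
        adp, atp = synth.gen_mgg_titrations(
            preset["adp_slope"][temperature],
            preset["atp_to_adp_ratio"][temperature], concs,
            preset["mgg_titration_noise_frac"], seed=s)
        cal = fluoro.calibrate_mgg(adp, atp, temperature=temperature)
        tr = synth.gen_suit_trace(preset, temperature, seed=s)
        fs = flux.compute_flux(tr)
        ivs, _ = flux.steady_state_flux(fs, tr.events)
        atp_rates, _ = fluoro.atp_rate(tr, cal, ivs)
        o2 = {iv.label: iv.flux for iv in ivs}
        vals.append(fluoro.atp_o_ratio(atp_rates["Succ"], o2["Succ"]))
    return float(np.mean(vals))


def test_fig10_atp_o_recovery(fig10_preset):
    ratio_20 = _fig10_atp_o(fig10_preset, 20.0, seed_root=5)
    ratio_hot = _fig10_atp_o(fig10_preset, 32.5, seed_root=6)
    truth = fig10_preset["truth"]
    assert ratio_20 == pytest.approx(truth["atp_o_20c"], rel=0.08)
    fold = ratio_20 / ratio_hot
    assert fold == pytest.approx(truth["atp_o_fold_20_over_32p5"], rel=0.15)
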