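"""Integrator, noise source, and parameter-manipulation behaviour."""

import numpy as np
import pytest

from pgcell.cell import CalciumPool, ParameterSet, build_cell
from pgcell.simulate import (NoiseSource, StimulusProtocol,
                             SimulationTrace, apply_pharmacology,
                             generate_colored_noise, run_current_clamp,
                             set_nicotinic, white_noise_samples)

LTS_GMAX = {"Na": 0.011, "K": 0.075, "K(A)": 0.025, "H": 3.58e-5,
            "Ca(T)": 0.002}


@pytest.fixture(scope="module")
def passive_cell():
    return build_cell(ParameterSet(label="passive", gmax={}))


def test_protocol_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(segments=((1.0, 0.0, 100.0), (2.0, 50.0, 100.0)),
                         total_ms=300.0)
    with pytest.raises(ValueError):
        StimulusProtocol(segments=((np.inf, 0.0, 100.0),), total_ms=300.0)
    p = StimulusProtocol.step(5.0, onset_ms=100, dur_ms=600, post_ms=300)
    assert p.onset_ms == 100 and p.offset_ms == 700 and p.total_ms == 1000
    i = p.current_array(np.array([50.0, 100.0, 699.9, 700.0]))
    assert list(i) == [0.0, 5.0, 5.0, 0.0]


def test_passive_step_linear_response(passive_cell):
    """-1 pA long step deflects the soma by -I * R_in = -0.775 mV."""
    proto = StimulusProtocol.step(-1.0, onset_ms=50, dur_ms=1500, post_ms=50)
    tr = run_current_clamp(passive_cell, proto, dt_ms=0.05)
    base = tr.v_soma[tr.t < 50].mean()
    ss = tr.v_soma[(tr.t > 1400) & (tr.t < 1550)].mean()
    assert base == pytest.approx(-70.0, abs=1e-6)
    assert (ss - base) == pytest.approx(-0.775, rel=2e-3)


def test_zero_stimulus_flat_at_rest(passive_cell):
    proto = StimulusProtocol(segments=(), total_ms=200.0)
    tr = run_current_clamp(passive_cell, proto, dt_ms=0.05)
    assert np.ptp(tr.v_soma) < 1e-9


def test_settled_active_cell_is_stationary():
    c = build_cell(ParameterSet(label="lts", gmax=LTS_GMAX))
    proto = StimulusProtocol(segments=(), total_ms=300.0)
    tr = run_current_clamp(c, proto, dt_ms=0.05)
    assert np.ptp(tr.v_soma) < 1e-6
    assert tr.metadata["settle_residual_mV_per_ms"] < 1e-6


# --- noise ------------------------------------------------------------------

def test_white_noise_statistics():
    nz = NoiseSource(seed=7)
    w = white_noise_samples(10**6, nz)
    se = nz.sd_fA * 1e-3 / np.sqrt(len(w))
    assert abs(w.mean()) < 3 * se
    sd_se = nz.sd_fA * 1e-3 / np.sqrt(2 * (len(w) - 1))
    assert abs(w.std(ddof=1) - 0.05) < 3 * sd_se


def test_colored_noise_autocorrelation_time():
    nz = NoiseSource(seed=3)
    dt = 0.05
    y = generate_colored_noise(400000, dt, nz)
    y = y - y.mean()
    lags = np.arange(0, int(15 / dt))
    ac = np.array([np.dot(y[:-k or None], y[k:]) / np.dot(y, y)
                   for k in lags])
    # fit log-linear decay over the first 10 ms
    keep = (ac > 0.05) & (lags * dt <= 10.0)
    slope = np.polyfit(lags[keep] * dt, np.log(ac[keep]), 1)[0]
    assert -1.0 / slope == pytest.approx(nz.tau_ms, rel=0.15)


def test_noise_determinism_and_dt_guard():
    nz = NoiseSource(seed=11)
    a = generate_colored_noise(1000, 0.05, nz)
    b = generate_colored_noise(1000, 0.05, nz)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, generate_colored_noise(1000, 0.05,
                                                        NoiseSource(seed=12)))
    with pytest.raises(ValueError):
        generate_colored_noise(100, 0.2, nz)


def test_noise_requires_fixed_backend(passive_cell):
    with pytest.raises(ValueError):
        run_current_clamp(passive_cell, StimulusProtocol.step(1.0),
                          noise=NoiseSource(seed=0), backend="adaptive")


def test_simulation_determinism():
    c = build_cell(ParameterSet(label="x", gmax={"Na": 0.02, "K": 0.01},
                                noise_enabled=True))
    proto = StimulusProtocol.step(5.0, onset_ms=20, dur_ms=100, post_ms=30)
    kw = dict(dt_ms=0.05, noise=NoiseSource(seed=42))
    a = run_current_clamp(c, proto, **kw)
    b = run_current_clamp(c, proto, **kw)
    assert np.array_equal(a.v_soma, b.v_soma)


# --- numerical soundness ----------------------------------------------------

def test_step_halving_convergence_passive(passive_cell):
    proto = StimulusProtocol.step(-1.0, onset_ms=20, dur_ms=200, post_ms=80)
    tr1 = run_current_clamp(passive_cell, proto, dt_ms=0.02)
    tr2 = run_current_clamp(passive_cell, proto, dt_ms=0.01)
    v1 = np.interp(tr2.t, tr1.t, tr1.v_soma)
    assert np.max(np.abs(v1 - tr2.v_soma)) < 0.05


def test_step_halving_convergence_lts_envelope():
    """Halving dt changes the (Na-blocked, smooth) LTS envelope < 0.05 mV."""
    params = ParameterSet(label="lts", gmax=LTS_GMAX,
                          ca_current_form="ghk").with_blocks({"Na": 0.0})
    c = build_cell(params)
    proto = StimulusProtocol.step(10.0, onset_ms=50, dur_ms=400, post_ms=150)
    tr1 = run_current_clamp(c, proto, dt_ms=0.02)
    tr2 = run_current_clamp(c, proto, dt_ms=0.01)
    v1 = np.interp(tr2.t, tr1.t, tr1.v_soma)
    assert np.max(np.abs(v1 - tr2.v_soma)) < 0.05


def test_fixed_step_matches_adaptive_backend():
    """Independent stiff-solver backend agrees with the Crank-Nicolson
    integrator on a smooth (spike-free) active response."""
    params = ParameterSet(label="lts", gmax=LTS_GMAX,
                          ca_current_form="ghk").with_blocks({"Na": 0.0})
    c = build_cell(params)
    proto = StimulusProtocol.step(10.0, onset_ms=50, dur_ms=300, post_ms=100)
    fixed = run_current_clamp(c, proto, dt_ms=0.01)
    adapt = run_current_clamp(c, proto, backend="adaptive", dt_ms=0.1,
                              rtol=1e-8, atol=1e-10)
    v_f = np.interp(adapt.t, fixed.t, fixed.v_soma)
    assert np.max(np.abs(v_f - adapt.v_soma)) < 0.05


def test_tripling_compartmentalization_invariance():
    """nseg x3 leaves the somatic voltage essentially unchanged.

    On smooth (non-regenerative) dynamics the max deviation stays under
    0.1 mV; on a spiking response the all-or-none events amplify any
    discretization difference, so there the invariance is that every spike
    time is preserved to well under a millisecond.
    """
    smooth = ParameterSet(label="sub",
                          gmax={"Na": 0.02, "K": 0.01, "K(A)": 0.01,
                                "H": 0.002})
    proto = StimulusProtocol.step(-10.0, onset_ms=20, dur_ms=300, post_ms=100)
    tr1 = run_current_clamp(build_cell(smooth), proto, dt_ms=0.02)
    tr3 = run_current_clamp(build_cell(smooth, nseg_factor=3), proto,
                            dt_ms=0.02)
    assert np.max(np.abs(tr1.v_soma - tr3.v_soma)) < 0.1

    spiking = ParameterSet(label="lts", gmax=LTS_GMAX, ca_current_form="ghk")
    proto = StimulusProtocol.step(10.0, onset_ms=20, dur_ms=300, post_ms=100)
    tr1 = run_current_clamp(build_cell(spiking), proto, dt_ms=0.02)
    tr3 = run_current_clamp(build_cell(spiking, nseg_factor=3), proto,
                            dt_ms=0.02)
    from pgcell.analysis import detect_spikes
    s1 = detect_spikes(tr1.t, tr1.v_soma)
    s3 = detect_spikes(tr3.t, tr3.v_soma)
    assert len(s1) == len(s3) > 0
    assert np.max(np.abs(s1 - s3)) < 1.0


# --- recording --------------------------------------------------------------

def test_record_conductances_bounded():
    params = ParameterSet(label="lts", gmax=LTS_GMAX, ca_current_form="ghk")
    c = build_cell(params)
    proto = StimulusProtocol.step(10.0, onset_ms=20, dur_ms=200, post_ms=50)
    tr = run_current_clamp(c, proto, dt_ms=0.05,
                           record_channels=["Na", "K(A)", "H"],
                           record_channel_comp="dend1",
                           record_calcium=True)
    g = tr.g["dend1[0]"]
    for chname in ("Na", "K(A)", "H"):
        assert np.all(g[chname] >= 0)
        assert np.all(g[chname] <= LTS_GMAX[chname] + 1e-15)
    assert np.all(tr.ca["soma[0]"] >= CalciumPool().basal_mM)


def test_record_absent_channel_rejected():
    c = build_cell(ParameterSet(label="x", gmax={"Na": 0.01}))
    with pytest.raises((ValueError, KeyError)):
        run_current_clamp(c, StimulusProtocol.step(1.0, post_ms=0.0),
                          dt_ms=0.1, record_channels=["CAN"])


def test_trace_round_trip(tmp_path):
    c = build_cell(ParameterSet(label="x", gmax={"Na": 0.02, "K": 0.01}))
    proto = StimulusProtocol.step(5.0, onset_ms=20, dur_ms=50, post_ms=30)
    tr = run_current_clamp(c, proto, dt_ms=0.05, record_channels=["Na"],
                           record_calcium=True)
    path = tmp_path / "trace.tsv"
    tr.save(path)
    back = SimulationTrace.load(path)
    assert np.allclose(back.t, tr.t)
    assert np.allclose(back.v_soma, tr.v_soma)
    assert np.allclose(back.g["dend1[0]"]["Na"], tr.g["dend1[0]"]["Na"])
    assert (path.parent / "trace.tsv.meta.yaml").exists()


# --- parameter manipulations ------------------------------------------------

def test_apply_pharmacology_is_pure():
    ps = ParameterSet(label="x", gmax=dict(LTS_GMAX))
    blocked = apply_pharmacology(ps, {"Ca(T)": 0.0, "K": 0.5})
    assert blocked.density("Ca(T)") == 0.0
    assert blocked.density("K") == pytest.approx(0.075 / 2)
    assert ps.density("Ca(T)") == 0.002
    with pytest.raises(KeyError):
        apply_pharmacology(ps, {"GABA": 0.0})


def test_nicotinic_conductance_raises_excitability():
    """The gemmule nicotinic conductance (E = +3.2 mV) increases evoked
    firing, and spreading the same total conductance uniformly over the
    cell produces an equivalent effect."""
    from pgcell.analysis import detect_spikes
    base = ParameterSet(label="acc", gmax={"Na": 0.01, "K": 0.001,
                                           "K(A)": 0.005, "H": 0.001,
                                           "Ca(T)": 4e-4},
                        ca_current_form="ghk")
    proto = StimulusProtocol.step(22.0, onset_ms=100, dur_ms=600,
                                  post_ms=100)
    counts = {}
    for tag, ps in (("off", base),
                    ("gemmule", set_nicotinic(base, True)),
                    ("uniform", set_nicotinic(base, True, scope="all"))):
        tr = run_current_clamp(build_cell(ps), proto, dt_ms=0.05)
        counts[tag] = len(detect_spikes(tr.t, tr.v_soma))
    assert counts["gemmule"] > counts["off"]
    assert abs(counts["uniform"] - counts["gemmule"]) <= 1


def test_zero_nicotinic_equals_disabled():
    base = ParameterSet(label="x", gmax={"Na": 0.02, "K": 0.01})
    proto = StimulusProtocol.step(5.0, onset_ms=20, dur_ms=100, post_ms=30)
    off = run_current_clamp(build_cell(set_nicotinic(base, False)), proto,
                            dt_ms=0.05)
    zero = run_current_clamp(build_cell(set_nicotinic(base, True, g=0.0)),
                             proto, dt_ms=0.05)
    assert np.array_equal(off.v_soma, zero.v_soma)
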