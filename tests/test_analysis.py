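"""Feature extraction and phenotype classification on synthetic traces."""

import numpy as np
import pytest

from pgcell import analysis
from pgcell.analysis import (ClassifierConfig, ResponseFeatures,
                             accommodation_ratio, classify_response,
                             detect_lts, detect_plateau, detect_spikes,
                             isi_cv, measure_input_resistance, sag_ratio,
                             spike_peaks)
from pgcell.cell import ParameterSet, build_cell
from pgcell.fixtures import make_synthetic_trace
from pgcell.simulate import StimulusProtocol


def _proto(onset=100.0, dur=600.0, amp=10.0, total=1300.0):
    return StimulusProtocol(segments=((amp, onset, dur),), total_ms=total)


# --- spike detection --------------------------------------------------------

def test_flat_trace_has_no_spikes():
    tr = make_synthetic_trace()
    assert len(detect_spikes(tr.t, tr.v_soma)) == 0


def test_three_deflections_three_spikes():
    tr = make_synthetic_trace(spike_times=(200, 300, 400))
    st = detect_spikes(tr.t, tr.v_soma)
    assert len(st) == 3
    assert st == pytest.approx([200, 300, 400], abs=2.0)


def test_refractory_merges_double_crossings():
    tr = make_synthetic_trace(spike_times=(200.0, 200.8, 400.0))
    assert len(detect_spikes(tr.t, tr.v_soma, refractory_ms=2.0)) == 2


def test_spike_peaks_recovered():
    tr = make_synthetic_trace(spike_times=(200, 300), spike_peaks_mv=(35, 20))
    st = detect_spikes(tr.t, tr.v_soma)
    assert spike_peaks(tr.t, tr.v_soma, st) == pytest.approx([35, 20],
                                                             abs=0.5)


def test_non_monotone_time_rejected():
    with pytest.raises(ValueError):
        detect_spikes([0.0, 1.0, 0.5], [-70, -70, -70])


# --- interval statistics ----------------------------------------------------

def test_accommodation_ratio_even_and_geometric():
    assert accommodation_ratio([100, 200, 300, 400, 500]) == pytest.approx(1.0)
    # geometric ISIs 50, 75, 112.5: last/first = 1.5^2
    st = [100.0, 150.0, 225.0, 337.5]
    assert accommodation_ratio(st) == pytest.approx(2.25)
    assert accommodation_ratio([100, 200]) is None


def test_isi_cv_zero_for_regular_train():
    assert isi_cv([0, 100, 200, 300]) == pytest.approx(0.0)
    assert isi_cv([0, 50, 250, 300]) > 0.5


def test_sag_ratio_on_synthetic_dip():
    tr = make_synthetic_trace(stim_deflection_mv=-10.0, sag_depth_mv=5.0,
                              sag_tau_ms=40.0)
    r = sag_ratio(tr.t, tr.v_soma, 100.0, 700.0)
    assert r == pytest.approx(1.5, abs=0.05)     # (-15)/(-10)
    flat = make_synthetic_trace()
    assert sag_ratio(flat.t, flat.v_soma, 100.0, 700.0) is None


# --- plateau ----------------------------------------------------------------

def test_plateau_detection_on_shelf():
    tr = make_synthetic_trace(stim_deflection_mv=15.0, shelf_mv=25.0,
                              shelf_ms=150.0)
    present, dur = detect_plateau(tr, 700.0)
    assert present
    assert dur == pytest.approx(150.0, abs=5.0)


def test_short_or_absent_shelf_is_not_a_plateau():
    none = make_synthetic_trace(stim_deflection_mv=15.0)
    assert detect_plateau(none, 700.0) == (False, None)
    short = make_synthetic_trace(shelf_mv=25.0, shelf_ms=60.0)
    assert detect_plateau(short, 700.0)[0] is False


def test_plateau_requires_post_offset_window():
    tr = make_synthetic_trace(total_ms=750.0)
    with pytest.raises(ValueError):
        detect_plateau(tr, 700.0)


# --- LTS --------------------------------------------------------------------

def test_lts_detected_on_transient_envelope():
    """A transient 25 mV hump that subsides before stimulus end is an LTS."""
    blocked = make_synthetic_trace(stim_deflection_mv=5.0)
    v = blocked.v["soma[0]"]
    hump = (blocked.t >= 120) & (blocked.t < 320)
    v[hump] += 25.0 * np.sin(np.pi * (blocked.t[hump] - 120) / 200.0)
    ctrl = make_synthetic_trace(stim_deflection_mv=5.0,
                                spike_times=(150.0,))
    present, amp, dur = detect_lts(ctrl, blocked, _proto())
    assert present
    assert amp > 10.0 and dur > 20.0


def test_sustained_depolarization_is_not_an_lts():
    """A maintained ohmic step (deflection ~ amp * R_in) has no envelope
    beyond the passive prediction, however large the step itself."""
    blocked = make_synthetic_trace(stim_deflection_mv=18.0)
    ctrl = make_synthetic_trace(stim_deflection_mv=18.0)
    present, _, _ = detect_lts(ctrl, blocked, _proto(amp=22.0))
    assert not present


def test_rebound_lts_detected_after_offset():
    blocked = make_synthetic_trace(stim_deflection_mv=-8.0)
    v = blocked.v["soma[0]"]
    hump = (blocked.t >= 710) & (blocked.t < 830)
    v[hump] += 20.0 * np.sin(np.pi * (blocked.t[hump] - 710) / 120.0)
    ctrl = make_synthetic_trace(stim_deflection_mv=-8.0)
    present, amp, dur = detect_lts(ctrl, blocked, _proto(amp=-10.0))
    assert present


def test_lts_protocol_mismatch_rejected():
    a = make_synthetic_trace()
    b = make_synthetic_trace(stim_offset_ms=500.0)
    with pytest.raises(ValueError):
        detect_lts(a, b, _proto())


# --- input resistance -------------------------------------------------------

@pytest.mark.parametrize("g_scale,expected", [(1.0, 775.0), (2.0, 391.0)])
def test_input_resistance_scales_with_leak(g_scale, expected):
    """Calibrated passive cell reads 775 MOhm; doubling the leak roughly
    halves it (391 MOhm from the passive network solve)."""
    from pgcell.cell import DEFAULT_G_LEAK
    c = build_cell(ParameterSet(label="p", gmax={},
                                g_leak=DEFAULT_G_LEAK * g_scale))
    rin = measure_input_resistance(c, dt_ms=0.1)
    assert rin == pytest.approx(expected, rel=0.01)


def test_input_resistance_sign_symmetric():
    c = build_cell(ParameterSet(label="p", gmax={}))
    plus = measure_input_resistance(c, amp_pA=0.5, dur_ms=500.0, dt_ms=0.1)
    minus = measure_input_resistance(c, amp_pA=-0.5, dur_ms=500.0, dt_ms=0.1)
    assert plus == pytest.approx(minus, rel=0.01)


# --- classification rules ---------------------------------------------------

def _features(**kw):
    base = dict(spike_times=np.array([]), spike_count=0,
                rebound_spike_count=0, accommodation_ratio=None, isi_cv=None,
                sag_ratio=None, decrementing=False, lts_present=False,
                lts_amplitude_mv=None, lts_duration_ms=None,
                plateau_present=False, plateau_duration_ms=None,
                noise_on=False)
    base.update(kw)
    return ResponseFeatures(**base)


@pytest.mark.parametrize("depol,hyper,label", [
    (dict(plateau_present=True, spike_count=3), dict(), "plateau"),
    # plateau label keys on the depolarizing member (a broad rebound LTS
    # can trip the hyper-side plateau detector without being one)
    (dict(), dict(plateau_present=True), "subthreshold"),
    (dict(lts_present=True, spike_count=1), dict(lts_present=True),
     "LTS-single-AP"),
    (dict(lts_present=True, spike_count=3, decrementing=True),
     dict(lts_present=True), "LTS-burst"),
    (dict(lts_present=True, spike_count=3, decrementing=False),
     dict(lts_present=True), "LTS-single-AP"),
    # LTS requires the envelope on both polarities: an H-current rebound
    # alone does not make an LTS cell
    (dict(spike_count=1), dict(lts_present=True), "single-spike"),
    (dict(lts_present=True, spike_count=1), dict(), "single-spike"),
    (dict(spike_count=5, accommodation_ratio=1.05), dict(),
     "non-accommodating"),
    (dict(spike_count=5, accommodation_ratio=2.4), dict(), "accommodating"),
    (dict(spike_count=1), dict(), "single-spike"),
    (dict(spike_count=6, accommodation_ratio=1.1, isi_cv=0.9, noise_on=True),
     dict(), "irregular"),
    (dict(spike_count=6, accommodation_ratio=1.1, isi_cv=0.9, noise_on=False),
     dict(), "non-accommodating"),     # irregular requires the noise source
    (dict(), dict(), "subthreshold"),
])
def test_classification_rules(depol, hyper, label):
    assert classify_response(_features(**depol), _features(**hyper)) == label


def test_extract_features_end_to_end_on_synthetic_train():
    tr = make_synthetic_trace(spike_times=(150, 250, 350, 450, 550),
                              stim_deflection_mv=10.0)
    feats = analysis.extract_features(tr, _proto())
    assert feats.spike_count == 5
    assert feats.accommodation_ratio == pytest.approx(1.0)
    assert not feats.plateau_present and not feats.lts_present
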