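"""Trace quantification and electrophysiological phenotype classification.

Extracts the features used to describe PG cell current-clamp responses --
spike times, accommodation, sag and rebound, low-threshold spike (LTS)
envelopes, plateau potentials, input resistance -- and maps a
depolarization/hyperpolarization response pair onto the phenotype
vocabulary: non-accommodating, accommodating, single-spike, irregular,
LTS-single-AP, LTS-burst, plateau.

The underlying recordings are classified in the literature by visual
correspondence; the quantitative thresholds here (spike threshold -20 mV,
accommodation ratio cut 1.3, LTS envelope 10 mV / 20 ms, plateau
20 mV / 100 ms, ISI CV cut 0.5) are this package's declared
operationalization and live in :class:`ClassifierConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cell import CellModel, ParameterSet, build_cell
from .simulate import SimulationTrace, StimulusProtocol, run_current_clamp

__all__ = [
    "ClassifierConfig", "ResponseFeatures", "detect_spikes", "spike_peaks",
    "accommodation_ratio", "isi_cv", "sag_ratio", "detect_lts",
    "detect_plateau", "measure_input_resistance", "classify_response",
    "extract_features",
]

PHENOTYPES = ("non-accommodating", "accommodating", "single-spike",
              "irregular", "LTS-single-AP", "LTS-burst", "plateau")


@dataclass(frozen=True)
class ClassifierConfig:
    spike_threshold_mv: float = -20.0
    refractory_ms: float = 2.0
    accommodation_cut: float = 1.3
    lts_amp_mv: float = 10.0          # envelope height above reference
    lts_min_width_ms: float = 20.0
    plateau_level_mv: float = 20.0    # above resting potential
    plateau_min_ms: float = 100.0
    cv_cut: float = 0.5
    #: input resistance used to predict the passive (ohmic) deflection a
    #: depolarizing step would cause; the LTS envelope must exceed that
    #: prediction, not merely the resting baseline
    rin_mohm: float = 775.0


@dataclass
class ResponseFeatures:
    """Quantified features of one depolarizing or hyperpolarizing trace."""
    spike_times: np.ndarray
    spike_count: int
    rebound_spike_count: int
    accommodation_ratio: Optional[float]
    isi_cv: Optional[float]
    sag_ratio: Optional[float]
    decrementing: bool
    lts_present: bool
    lts_amplitude_mv: Optional[float]
    lts_duration_ms: Optional[float]
    plateau_present: bool
    plateau_duration_ms: Optional[float]
    noise_on: bool = False


def detect_spikes(t, v, threshold_mv: float = -20.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Upward threshold-crossing times separated by at least the refractory."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    idx = np.nonzero((v[1:] >= threshold_mv) & (v[:-1] < threshold_mv))[0] + 1
    out = []
    last = -np.inf
    for i in idx:
        if t[i] - last >= refractory_ms:
            out.append(t[i])
            last = t[i]
    return np.asarray(out)


def spike_peaks(t, v, spike_times, window_ms: float = 10.0) -> np.ndarray:
    """Peak voltage within a short window after each threshold crossing."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    peaks = []
    for ts in spike_times:
        m = (t >= ts) & (t <= ts + window_ms)
        peaks.append(v[m].max() if m.any() else np.nan)
    return np.asarray(peaks)


def accommodation_ratio(spike_times) -> Optional[float]:
    """Last ISI / first ISI; defined only for >= 3 spikes (>= 2 intervals)."""
    st = np.asarray(spike_times, float)
    if len(st) < 3:
        return None
    isi = np.diff(st)
    return float(isi[-1] / isi[0])


def isi_cv(spike_times) -> Optional[float]:
    st = np.asarray(spike_times, float)
    if len(st) < 3:
        return None
    isi = np.diff(st)
    return float(np.std(isi) / np.mean(isi))


def sag_ratio(t, v, onset_ms, offset_ms) -> Optional[float]:
    """Peak/steady-state hyperpolarization ratio during a negative step.

    > 1 indicates an H-current sag (early dip deeper than the late steady
    level).  None if the trace does not hyperpolarize.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    base = v[t < onset_ms].mean()
    inwin = (t >= onset_ms) & (t < offset_ms)
    if not inwin.any():
        return None
    peak = v[inwin].min() - base
    late = (t >= offset_ms - 0.2 * (offset_ms - onset_ms)) & (t < offset_ms)
    steady = v[late].mean() - base
    if peak >= -0.5 or steady >= 0:
        return None
    return float(peak / steady)


def _longest_run_ms(mask, t):
    """Duration of the longest contiguous True run on a uniform-ish grid."""
    best = cur = 0
    for a in mask:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    if best == 0 or len(t) < 2:
        return 0.0
    return best * float(np.median(np.diff(t)))


def detect_lts(trace: SimulationTrace, na_blocked: SimulationTrace,
               protocol: StimulusProtocol,
               config: ClassifierConfig = ClassifierConfig()):
    """Detect a low-threshold calcium spike via its Na-blocked envelope.

    The LTS is a regenerative depolarizing envelope that survives removal
    of the fast sodium conductance.  On the Na-blocked companion trace
    (identical protocol, G_Na = 0) the envelope must rise more than
    ``lts_amp_mv`` above what the stimulus could produce ohmically -- the
    pre-stimulus baseline plus the passive deflection amp * R_in for a
    depolarizing step, the baseline itself for a post-release rebound --
    and stay there longer than ``lts_min_width_ms``.

    Returns (present, amplitude mV, duration ms).
    """
    if trace.metadata and na_blocked.metadata:
        p1 = trace.metadata.get("protocol")
        p2 = na_blocked.metadata.get("protocol")
        if p1 is not None and p2 is not None and p1 != p2:
            raise ValueError("control and Na-blocked traces used different "
                             "protocols")
    t = na_blocked.t
    v = na_blocked.v_soma
    on, off = protocol.onset_ms, protocol.offset_ms
    amp_pA = protocol.current_array(np.array([(on + off) / 2.0]))[0]
    base = v[t < on].mean()

    if amp_pA > 0:
        win = (t >= on) & (t < off)
        reference = base + amp_pA * config.rin_mohm * 1e-3
    else:
        win = t >= off
        reference = base
    hump = v[win] - reference
    mask = hump > config.lts_amp_mv
    dur = _longest_run_ms(mask, t[win])
    present = dur >= config.lts_min_width_ms
    amp = float(hump.max()) if present else None
    return present, amp, (float(dur) if present else None)


def detect_plateau(trace: SimulationTrace, offset_ms: float,
                   config: ClassifierConfig = ClassifierConfig()):
    """Detect a persistent post-stimulus plateau potential.

    Present when the post-offset membrane potential stays above
    rest + ``plateau_level_mv`` for longer than ``plateau_min_ms``; the
    duration is measured from stimulus offset to half-repolarization
    (the time V last falls through rest + level/2).

    Returns (present, duration ms).
    """
    t = trace.t
    v = trace.v_soma
    # resting level: mean over the pre-stimulus window when identifiable
    onset = offset_ms
    if trace.metadata:
        segs = trace.metadata.get("protocol", {}).get("segments")
        if segs:
            onset = min(s[1] for s in segs)
    rest = float(v[t < onset].mean()) if np.any(t < onset) else float(v[0])

    post = t >= offset_ms
    if not post.any() or t[-1] < offset_ms + config.plateau_min_ms:
        raise ValueError("trace must extend beyond the stimulus offset by "
                         "at least the minimum plateau duration")
    above = v[post] > rest + config.plateau_level_mv
    dur_above = _longest_run_ms(above, t[post])
    present = dur_above > config.plateau_min_ms
    if not present:
        return False, None
    half = rest + config.plateau_level_mv / 2.0
    t_post = t[post]
    above_half = np.nonzero(v[post] >= half)[0]
    # half-repolarization: the final time the trace sits above rest + level/2
    # (window-limited if the plateau outlasts the recording)
    t_half = t_post[above_half[-1]] if len(above_half) else t_post[-1]
    return True, float(t_half - offset_ms)


def measure_input_resistance(cell: CellModel, amp_pA: float = -1.0,
                             dur_ms: float = 2000.0, dt_ms: float = 0.05,
                             **kwargs) -> float:
    """Somatic input resistance (MOhm) from a small long current step.

    DeltaV_ss / DeltaI with the steady-state deflection averaged over the
    last 10% of the step; the default -1 pA, 2000 ms probe stays within the
    linear regime of the passive cell.
    """
    if amp_pA == 0:
        raise ValueError("probe current must be non-zero")
    proto = StimulusProtocol.step(amp_pA, onset_ms=100.0, dur_ms=dur_ms,
                                  post_ms=0.0)
    tr = run_current_clamp(cell, proto, dt_ms=dt_ms, **kwargs)
    t, v = tr.t, tr.v_soma
    base = v[t < 100.0].mean()
    ss = v[t >= 100.0 + 0.9 * dur_ms].mean()
    return float((ss - base) / amp_pA * 1e3)   # mV/pA -> MOhm


def classify_response(depol: ResponseFeatures, hyper: ResponseFeatures,
                      config: ClassifierConfig = ClassifierConfig()) -> str:
    """Phenotype label for a depolarization/hyperpolarization response pair.

    Decision order: plateau > LTS (single AP vs decrementing burst) >
    irregular (noise-driven ISI CV) > spike-count/accommodation rules.
    The pair must come from the same parameter set; only noise-driven
    responses can be labelled irregular.

    The plateau flag is read from the depolarizing member (the response
    type is defined by the depolarization-evoked plateau; a broad
    anode-break LTS can hold the release trace above the plateau level
    without being one).  The LTS branch requires the envelope on *both*
    polarities -- the defining T-current signature is the pair of a
    depolarization-evoked and a post-inhibitory rebound LTS; an H-current
    rebound overshoot alone (accommodating cells) does not qualify.
    """
    if depol.plateau_present:
        return "plateau"
    if depol.lts_present and hyper.lts_present:
        if depol.spike_count >= 2 and depol.decrementing:
            return "LTS-burst"
        return "LTS-single-AP"
    if (depol.noise_on and depol.isi_cv is not None
            and depol.isi_cv > config.cv_cut):
        return "irregular"
    if depol.spike_count >= 3:
        ratio = depol.accommodation_ratio
        if ratio is not None and ratio <= config.accommodation_cut:
            return "non-accommodating"
        return "accommodating"
    if depol.spike_count == 2:
        return "accommodating"
    if depol.spike_count == 1:
        return "single-spike"
    return "subthreshold"


def extract_features(trace: SimulationTrace, protocol: StimulusProtocol,
                     na_blocked: SimulationTrace | None = None,
                     config: ClassifierConfig = ClassifierConfig(),
                     noise_on: bool = False) -> ResponseFeatures:
    """Compute the full feature record for one trace."""
    t, v = trace.t, trace.v_soma
    on, off = protocol.onset_ms, protocol.offset_ms
    st = detect_spikes(t, v, config.spike_threshold_mv, config.refractory_ms)
    stim_spikes = st[(st >= on) & (st < off)]
    rebound = st[st >= off]
    peaks = spike_peaks(t, v, stim_spikes)
    decr = bool(len(peaks) >= 2 and np.all(np.diff(peaks) < 0))
    lts_present = False
    lts_amp = lts_dur = None
    if na_blocked is not None:
        lts_present, lts_amp, lts_dur = detect_lts(trace, na_blocked,
                                                   protocol, config)
    try:
        plat, plat_dur = detect_plateau(trace, off, config)
    except ValueError:
        plat, plat_dur = False, None
    return ResponseFeatures(
        spike_times=st,
        spike_count=int(len(stim_spikes)),
        rebound_spike_count=int(len(rebound)),
        accommodation_ratio=accommodation_ratio(stim_spikes),
        isi_cv=isi_cv(stim_spikes),
        sag_ratio=sag_ratio(t, v, on, off),
        decrementing=decr,
        lts_present=bool(lts_present),
        lts_amplitude_mv=lts_amp,
        lts_duration_ms=lts_dur,
        plateau_present=bool(plat),
        plateau_duration_ms=plat_dur,
        noise_on=noise_on,
    )
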