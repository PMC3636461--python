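"""Deterministic synthetic traces with known ground-truth features.

These waveform generators exercise the analysis layer (spike detection,
accommodation, sag, plateau metrics) without running the simulator.  They
are piecewise-analytic caricatures of current-clamp responses -- baseline,
step deflection, triangular spikes, exponential sag, post-offset shelf --
not biophysical output; every trace is labelled synthetic in its metadata.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .simulate import SimulationTrace

__all__ = ["make_synthetic_trace"]


def make_synthetic_trace(spike_times: Sequence[float] = (),
                         spike_peaks_mv: Sequence[float] | float = 30.0,
                         baseline_mv: float = -70.0,
                         stim_onset_ms: float = 100.0,
                         stim_offset_ms: float = 700.0,
                         stim_deflection_mv: float = 0.0,
                         sag_depth_mv: float = 0.0,
                         sag_tau_ms: float = 50.0,
                         shelf_mv: float = 0.0,
                         shelf_ms: float = 0.0,
                         spike_half_width_ms: float = 1.0,
                         total_ms: float = 1300.0,
                         dt_ms: float = 0.05) -> SimulationTrace:
    """Build a synthetic somatic voltage trace.

    ``spike_times`` places triangular spikes (rise/fall
    ``spike_half_width_ms``) with the given peak value(s) on top of the
    deflected baseline.  ``stim_deflection_mv`` offsets the trace between
    onset and offset; a positive ``sag_depth_mv`` adds an early
    exponentially-relaxing dip (H-current sag caricature) to the step.
    ``shelf_mv``/``shelf_ms`` raises the post-offset trace by a fixed amount
    for a fixed duration (plateau caricature) before snapping back.
    """
    t = np.arange(0.0, total_ms, dt_ms)
    v = np.full_like(t, baseline_mv)
    stim = (t >= stim_onset_ms) & (t < stim_offset_ms)
    v[stim] += stim_deflection_mv
    if sag_depth_mv:
        rel = t[stim] - stim_onset_ms
        v[stim] -= sag_depth_mv * np.exp(-rel / sag_tau_ms)
    if shelf_mv and shelf_ms > 0:
        shelf = (t >= stim_offset_ms) & (t < stim_offset_ms + shelf_ms)
        v[shelf] += shelf_mv
    spike_times = np.asarray(spike_times, float)
    peaks = np.broadcast_to(np.asarray(spike_peaks_mv, float),
                            spike_times.shape)
    for ts, pk in zip(spike_times, peaks):
        tri = np.maximum(0.0, 1.0 - np.abs(t - ts) / spike_half_width_ms)
        v = np.maximum(v, baseline_mv + tri * (pk - baseline_mv))
    meta = {
        "synthetic": True,
        "protocol": {"segments": [[0.0, stim_onset_ms,
                                   stim_offset_ms - stim_onset_ms]],
                     "total_ms": total_ms},
        "ground_truth": {
            "spike_times": spike_times.tolist(),
            "baseline_mv": baseline_mv,
            "shelf_mv": shelf_mv, "shelf_ms": shelf_ms,
        },
    }
    return SimulationTrace(t=t, v={"soma[0]": v}, metadata=meta)
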