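"""Current-clamp simulation of the compartmental PG cell.

The default backend advances the coupled voltage/gating/calcium system with
a fixed-step, second-order implicit scheme: membrane voltage by a
Crank-Nicolson step (the ionic and axial currents are linear in V once the
gating variables are frozen, so each step is one small linear solve) and
gating variables by the staggered exponential-Euler update

    x <- x + (x_inf - x) * (1 - exp(-dt * phi / tau_x)),

which is the exact solution of dx/dt = phi (x_inf - x)/tau_x over a step
with V held fixed.  Voltage-dependent steady states and time constants are
looked up in densely tabulated curves (0.01 mV grid) by default; exact
formula evaluation is available via ``use_tables=False``.

An adaptive stiff-solver backend (``backend="adaptive"``, scipy BDF) serves
as an independent numerical cross-check.  Noise simulations always use the
fixed-step backend so the stochastic process is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cell import (CellModel, ParameterSet, CalciumPool, FARADAY,
                   GAS_CONSTANT, TEMPERATURE_K, CA_OUT_MM, build_cell,
                   ghk_chord_conductance)
from .channels import CHANNELS

__all__ = [
    "StimulusProtocol", "NoiseSource", "SimulationTrace",
    "run_current_clamp", "generate_colored_noise", "white_noise_samples",
    "apply_pharmacology", "set_nicotinic", "settle_cell",
]

_KNERNST = 1e3 * GAS_CONSTANT * TEMPERATURE_K / (2.0 * FARADAY)   # mV

# tabulation grid for voltage-dependent gating curves
_V_GRID = np.arange(-150.0, 80.0 + 1e-9, 0.01)


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic current-clamp stimulus: piecewise-constant segments.

    ``segments`` is a tuple of (amplitude pA, onset ms, duration ms); the
    recorded window runs from t = 0 to ``total_ms`` (settling happens before
    t = 0 and is discarded unless requested).
    """
    segments: tuple = ()
    total_ms: float = 1300.0

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s[1])
        for (a, t0, d) in segs:
            if not (np.isfinite(a) and np.isfinite(t0) and d > 0):
                raise ValueError("segment amplitudes/times must be finite, "
                                 "durations > 0")
        for (_, t0, d), (_, t1, _) in zip(segs, segs[1:]):
            if t0 + d > t1 + 1e-9:
                raise ValueError("stimulus segments overlap")
        object.__setattr__(self, "segments", tuple(segs))

    @classmethod
    def step(cls, amp_pA: float, onset_ms: float = 100.0,
             dur_ms: float = 600.0, post_ms: float = 600.0):
        return cls(segments=((amp_pA, onset_ms, dur_ms),),
                   total_ms=onset_ms + dur_ms + post_ms)

    @property
    def onset_ms(self) -> float:
        return self.segments[0][1] if self.segments else 0.0

    @property
    def offset_ms(self) -> float:
        return max((t0 + d for _, t0, d in self.segments), default=0.0)

    def current_array(self, t: np.ndarray) -> np.ndarray:
        """Injected current (pA) evaluated on a time grid."""
        i = np.zeros_like(t)
        for amp, t0, dur in self.segments:
            i[(t >= t0) & (t < t0 + dur)] += amp
        return i


@dataclass(frozen=True)
class NoiseSource:
    """Colored current noise injected at the soma.

    Gaussian white noise (SD ``sd_fA``, band-limited to ``bandwidth_khz`` by
    its sampling rate) is convolved with a single-exponential kernel
    exp(-t/tau).  The convolution is performed at the white-noise sampling
    rate and the colored signal is linearly interpolated onto the simulation
    grid, so its statistics do not depend on the solver step.  The colored
    output's SD is whatever the convolution yields (not renormalized).
    """
    sd_fA: float = 50.0
    bandwidth_khz: float = 4.0
    tau_ms: float = 5.0
    seed: int = 0

    @property
    def white_dt_ms(self) -> float:
        # Nyquist sampling of the stated bandwidth
        return 1.0 / (2.0 * self.bandwidth_khz)


def white_noise_samples(n: int, noise: NoiseSource) -> np.ndarray:
    """The pre-coloring white-noise current, in pA, at the band-limited rate."""
    rng = np.random.default_rng(noise.seed)
    return rng.normal(0.0, noise.sd_fA * 1e-3, size=n)


def generate_colored_noise(n_steps: int, dt_ms: float,
                           noise: NoiseSource) -> np.ndarray:
    """Colored noise current (pA) on an ``n_steps`` grid of spacing ``dt_ms``.

    Requires dt <= the white-noise sampling interval (0.125 ms at 4 kHz) so
    the stated bandwidth is representable on the simulation grid.
    """
    dtw = noise.white_dt_ms
    if dt_ms > dtw + 1e-12:
        raise ValueError(f"dt must be <= {dtw} ms to represent the "
                         f"{noise.bandwidth_khz} kHz noise bandwidth")
    t_end = n_steps * dt_ms
    nw = int(np.ceil(t_end / dtw)) + 2
    w = white_noise_samples(nw, noise)
    a = np.exp(-dtw / noise.tau_ms)
    colored = np.empty(nw)
    acc = 0.0
    for i in range(nw):            # y[i] = sum_j w[i-j] exp(-j dtw/tau)
        acc = a * acc + w[i]
        colored[i] = acc
    tw = np.arange(nw) * dtw
    ts = np.arange(n_steps) * dt_ms
    return np.interp(ts, tw, colored)


@dataclass
class SimulationTrace:
    """Time-aligned simulation output.

    ``v`` maps compartment name to membrane potential (mV); ``g`` maps
    compartment name to {channel: conductance density S/cm^2}; ``ca`` maps
    compartment name to perimembrane [Ca] (mM).
    """
    t: np.ndarray
    v: dict
    g: dict = field(default_factory=dict)
    ca: dict = field(default_factory=dict)
    i_inj_pA: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        n = len(self.t)
        for series in (*self.v.values(), *self.ca.values(),
                       *(a for d in self.g.values() for a in d.values())):
            if len(series) != n:
                raise ValueError("all series must share the time grid")

    @property
    def v_soma(self) -> np.ndarray:
        return self.v["soma[0]"]

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.t}
        for name, arr in self.v.items():
            cols[f"V_{name}_mV"] = arr
        if self.i_inj_pA is not None:
            cols["I_inj_pA"] = self.i_inj_pA
        for comp, chans in self.g.items():
            for ch, arr in chans.items():
                cols[f"g_{ch}_{comp}_S_cm2"] = arr
        for comp, arr in self.ca.items():
            cols[f"Ca_{comp}_mM"] = arr
        return pd.DataFrame(cols)

    def save(self, path, metadata_sidecar: bool = True):
        """Write the trace as tab-delimited text (+ YAML metadata sidecar)."""
        import yaml
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.9g")
        if metadata_sidecar:
            with open(str(path) + ".meta.yaml", "w") as fh:
                yaml.safe_dump(self.metadata, fh, sort_keys=False)

    @classmethod
    def load(cls, path):
        import os
        import pandas as pd
        import yaml
        meta = {}
        sidecar = str(path) + ".meta.yaml"
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
        df = pd.read_csv(path, sep="\t")
        t = df["time_ms"].to_numpy()
        v, g, ca = {}, {}, {}
        i_inj = None
        for col in df.columns[1:]:
            arr = df[col].to_numpy()
            if col.startswith("V_"):
                v[col[2:-3]] = arr
            elif col == "I_inj_pA":
                i_inj = arr
            elif col.startswith("g_"):
                ch_comp = col[2:-len("_S_cm2")]
                ch, comp = ch_comp.rsplit("_", 1)
                g.setdefault(comp, {})[ch] = arr
            elif col.startswith("Ca_"):
                ca[col[3:-3]] = arr
        return cls(t=t, v=v, g=g, ca=ca, i_inj_pA=i_inj, metadata=meta)


# --------------------------------------------------------------------------
# runtime channel structures

class _GateTable:
    __slots__ = ("inf", "tau")

    def __init__(self, fn):
        self.inf, self.tau = fn(_V_GRID)


class _ChannelRT:
    """Per-simulation runtime data for one expressed channel."""
    __slots__ = ("name", "a", "b", "phi_m", "phi_h", "m_kind", "h_kind",
                 "m_fn", "h_fn", "m_tab", "h_tab", "dens", "e_fixed",
                 "dynamic_e", "carries_ca")

    def __init__(self, spec, dens, use_tables):
        self.name = spec.name
        self.a, self.b = spec.a, spec.b
        self.phi_m, self.phi_h = spec.phi_m, spec.phi_h
        self.m_kind, self.h_kind = spec.m_kind, spec.h_kind
        self.m_fn, self.h_fn = spec.m_curve, spec.h_curve
        self.dens = dens
        self.dynamic_e = spec.reversal == "ca_nernst"
        self.e_fixed = spec.reversal if not self.dynamic_e else None
        self.carries_ca = spec.carries_calcium
        self.m_tab = (_GateTable(spec.m_curve)
                      if use_tables and spec.m_kind == "voltage" else None)
        self.h_tab = (_GateTable(spec.h_curve)
                      if use_tables and spec.h_kind == "voltage" else None)


def _active_channels(cell: CellModel, use_tables: bool) -> list:
    out = []
    for name in ("Na", "K", "K(A)", "K(Ca)", "H", "Ca(L)", "Ca(T)", "CAN",
                 "nic"):
        dens = cell.density[name]
        if np.any(dens > 0):
            out.append(_ChannelRT(CHANNELS[name], dens, use_tables))
    return out


def _gate_curves(rt: _ChannelRT, which: str, v, ca):
    kind = rt.m_kind if which == "m" else rt.h_kind
    tab = rt.m_tab if which == "m" else rt.h_tab
    fn = rt.m_fn if which == "m" else rt.h_fn
    if kind == "calcium":
        return fn(ca)
    if tab is not None:
        return (np.interp(v, _V_GRID, tab.inf),
                np.interp(v, _V_GRID, tab.tau))
    return fn(v)


def _init_gates(channels, v, ca):
    gates = {}
    for rt in channels:
        m = h = None
        if rt.m_kind is not None:
            m, _ = _gate_curves(rt, "m", v, ca)
            m = np.array(m, float, copy=True)
        if rt.h_kind == "voltage":
            h, _ = _gate_curves(rt, "h", v, ca)
            h = np.array(h, float, copy=True)
        elif rt.h_kind == "instantaneous":
            h = 1.245 / (1.245 + ca)
        gates[rt.name] = [m, h]
    return gates


def _conductances(channels, gates):
    out = {}
    for rt in channels:
        g = rt.dens
        m, h = gates[rt.name]
        if rt.a > 0:
            g = g * m ** rt.a
        if rt.b > 0:
            g = g * h ** rt.b
        out[rt.name] = g if g is not rt.dens else rt.dens.copy()
    return out


def _e_of(rt: _ChannelRT, eca):
    return eca if rt.dynamic_e else rt.e_fixed


# --------------------------------------------------------------------------
# settling

def settle_cell(cell: CellModel, dt_ms: float = 0.5,
                settle_ms: float = 2000.0, tol_mv_ms: float = 1e-6,
                max_ms: float = 10000.0, use_tables: bool = True):
    """Relax the unstimulated cell to its resting fixed point.

    A damped fixed-point iteration on the steady-state circuit provides the
    initial guess; the system is then integrated without stimulus for
    ``settle_ms`` (extended up to ``max_ms`` if needed) until every
    compartment satisfies \\|dV/dt\\| < ``tol_mv_ms``.

    Returns ``(v, gates, ca, residual)`` where residual is the final
    max-norm of dV/dt in mV/ms.
    """
    channels = _active_channels(cell, use_tables)
    n = cell.n
    v = cell.e_leak.astype(float).copy()
    ca = np.full(n, cell.pool.basal_mM)

    m_ax = -cell.axial_gabs / cell.area_cm2[:, None]
    np.fill_diagonal(m_ax, cell.axial_gabs.sum(axis=1) / cell.area_cm2)

    # damped fixed point: V <- solve((diag(Gtot)+M_ax) V = sum g E)
    for _ in range(200):
        gates = _init_gates(channels, v, ca)
        g_by = _conductances(channels, gates)
        eca = _KNERNST * np.log(CA_OUT_MM / ca)
        form = cell.params.ca_current_form
        if form in ("ghk", "cat-ghk"):
            chord = ghk_chord_conductance(v, ca)
            for rt in channels:
                if rt.carries_ca and (form == "ghk" or rt.name == "Ca(T)"):
                    g_by[rt.name] = g_by[rt.name] * chord
        gsum = cell.density["leak"].copy()
        ge = cell.density["leak"] * cell.e_leak
        i_ca = np.zeros(n)
        for rt in channels:
            g = g_by[rt.name]
            e = _e_of(rt, eca)
            gsum = gsum + g
            ge = ge + g * e
            if rt.carries_ca:
                i_ca += g * (v - e)
        amat = m_ax + np.diag(gsum)
        v_new = np.linalg.solve(amat, ge)
        drive = np.maximum(-i_ca, 0.0) * 1e4 / (2 * FARADAY *
                                                cell.pool.shell_depth_um)
        ca_new = cell.pool.basal_mM + drive * cell.pool.decay_tau_ms
        dv = np.max(np.abs(v_new - v))
        v = 0.5 * v + 0.5 * v_new
        ca = np.maximum(0.5 * ca + 0.5 * ca_new, cell.pool.basal_mM)
        if dv < 1e-10:
            break

    gates = _init_gates(channels, v, ca)
    # dynamic polish
    simulated = 0.0
    residual = np.inf
    block = settle_ms
    while simulated < max_ms:
        n_steps = max(int(round(block / dt_ms)), 1)
        v, gates, ca, dvdt = _integrate(cell, channels, v, gates, ca,
                                        inj_pA=np.zeros(n_steps), dt=dt_ms)
        residual = dvdt
        simulated += n_steps * dt_ms
        if residual < tol_mv_ms:
            break
        block = 1000.0
    return v, gates, ca, residual


# --------------------------------------------------------------------------
# fixed-step integrator core

def _integrate(cell, channels, v, gates, ca, inj_pA, dt, recorder=None):
    """Advance the system len(inj_pA) steps; optionally record series.

    Returns (v, gates, ca, last |dV/dt|max) and fills the record dicts
    (preallocated by the caller) in place.
    """
    n = cell.n
    n_steps = len(inj_pA)
    soma = cell.soma_index
    area = cell.area_cm2
    cmdt = cell.cm_uf * 1e-3 / dt
    g_leak = cell.density["leak"]
    ge_leak = g_leak * cell.e_leak
    m_half = -0.5 * cell.axial_gabs / area[:, None]
    ax_diag = 0.5 * cell.axial_gabs.sum(axis=1) / area
    inj_density = np.zeros(n)
    pool = cell.pool
    k_ca = 1e4 / (2 * FARADAY * pool.shell_depth_um)
    decay = np.exp(-dt / pool.decay_tau_ms)
    any_ca = any(rt.carries_ca or rt.m_kind == "calcium" or
                 rt.h_kind == "instantaneous" for rt in channels)
    form = cell.params.ca_current_form
    ghk_mask = {rt.name for rt in channels if rt.carries_ca
                and (form == "ghk"
                     or (form == "cat-ghk" and rt.name == "Ca(T)"))}


    dvdt_last = np.inf
    eca = _KNERNST * np.log(CA_OUT_MM / ca)
    for it in range(n_steps):
        # staggered gate advance (exponential Euler, V and Ca frozen)
        for rt in channels:
            m, h = gates[rt.name]
            if rt.m_kind is not None:
                inf, tau = _gate_curves(rt, "m", v, ca)
                m += (inf - m) * -np.expm1(-dt * rt.phi_m / tau)
            if rt.h_kind == "voltage":
                inf, tau = _gate_curves(rt, "h", v, ca)
                h += (inf - h) * -np.expm1(-dt * rt.phi_h / tau)
            elif rt.h_kind == "instantaneous":
                gates[rt.name][1] = 1.245 / (1.245 + ca)

        g_by = _conductances(channels, gates)
        if ghk_mask:
            chord = ghk_chord_conductance(v, ca)
            for rt in channels:
                if rt.name in ghk_mask:
                    g_by[rt.name] = g_by[rt.name] * chord
        gsum = g_leak.copy()
        ge = ge_leak.copy()
        for rt in channels:
            g = g_by[rt.name]
            gsum += g
            ge += g * _e_of(rt, eca)

        inj_density[soma] = inj_pA[it] * 1e-9 / area[soma]
        amat = m_half.copy()
        amat[np.arange(n), np.arange(n)] += cmdt + 0.5 * gsum + ax_diag
        rhs = (cmdt - 0.5 * gsum - ax_diag) * v - m_half @ v + ge + inj_density
        v_new = np.linalg.solve(amat, rhs)
        dvdt_last = np.max(np.abs(v_new - v)) / dt
        v = v_new
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite membrane potential at step {it} "
                f"(t = {it * dt:.3f} ms); reduce dt or check parameters")

        if any_ca:
            i_ca = np.zeros(n)
            for rt in channels:
                if rt.carries_ca:
                    i_ca += g_by[rt.name] * (v - eca)
            drive = np.maximum(-i_ca, 0.0) * k_ca
            target = pool.basal_mM + drive * pool.decay_tau_ms
            ca = np.maximum(target + (ca - target) * decay, pool.basal_mM)
            eca = _KNERNST * np.log(CA_OUT_MM / ca)

        if recorder is not None:
            recorder(it, v, g_by, ca)
    return v, gates, ca, dvdt_last


def _split(comp_name):
    if "[" in comp_name:
        sec, idx = comp_name[:-1].split("[")
        return sec, int(idx)
    return comp_name, 0


def run_current_clamp(cell: CellModel, protocol: StimulusProtocol,
                      noise: NoiseSource | None = None,
                      dt_ms: float = 0.01,
                      record: Sequence[str] = ("soma",),
                      record_channels: Sequence[str] = (),
                      record_channel_comp: str = "dend1",
                      record_calcium: bool = False,
                      settle_ms: float = 2000.0,
                      settle_tol: float = 1e-6,
                      keep_settle: bool = False,
                      use_tables: bool = True,
                      backend: str = "fixed",
                      rtol: float = 1e-8, atol: float = 1e-8,
                      record_stride: int = 1) -> SimulationTrace:
    """Simulate a somatic current-clamp protocol on a settled cell.

    The cell is first relaxed to rest (no stimulus, no noise) until every
    compartment satisfies \\|dV/dt\\| < ``settle_tol`` mV/ms, then driven by
    ``protocol`` (current injected into the soma compartment only; colored
    noise added there when ``noise`` is given).  Voltage is recorded from
    the listed sections (compartment 0 unless an explicit ``sec[i]`` name is
    given); per-channel conductance densities g(t) = Gmax m^a h^b and the
    perimembrane calcium concentration can be recorded alongside.

    ``backend="adaptive"`` integrates the same equations with scipy's BDF
    stiff solver instead (not available with noise).
    """
    if backend not in ("fixed", "adaptive"):
        raise ValueError("backend must be 'fixed' or 'adaptive'")
    if noise is not None and backend != "fixed":
        raise ValueError("noise simulations require the fixed-step backend")

    record = [r if "[" in r else f"{r}[0]" for r in record]
    comp_g = (record_channel_comp if "[" in record_channel_comp
              else f"{record_channel_comp}[0]")
    for ch in record_channels:
        if ch not in cell.density:
            raise KeyError(f"unknown channel {ch!r}")
        if not np.any(cell.density[ch][cell.compartment_index(*_split(comp_g))]
                      > 0):
            raise ValueError(f"channel {ch} not expressed in {comp_g}")

    v, gates, ca, residual = settle_cell(cell, settle_ms=settle_ms,
                                         tol_mv_ms=settle_tol,
                                         use_tables=use_tables)
    channels = _active_channels(cell, use_tables)

    n_steps = int(round(protocol.total_ms / dt_ms))
    t_mid = (np.arange(n_steps) + 0.5) * dt_ms
    inj = protocol.current_array(t_mid)
    if noise is not None:
        inj = inj + generate_colored_noise(n_steps, dt_ms, noise)

    meta = {
        "preset": cell.params.label,
        "parameter_set": cell.params.to_dict(),
        "protocol": {"segments": [list(s) for s in protocol.segments],
                     "total_ms": protocol.total_ms},
        "noise": None if noise is None else {
            "sd_fA": noise.sd_fA, "bandwidth_khz": noise.bandwidth_khz,
            "tau_ms": noise.tau_ms, "seed": noise.seed},
        "dt_ms": dt_ms, "backend": backend, "use_tables": bool(use_tables),
        "settle_ms": settle_ms, "settle_residual_mV_per_ms": float(residual),
        "record_stride": record_stride,
    }

    if backend == "adaptive":
        return _run_adaptive(cell, channels, v, gates, ca, protocol,
                             dt_ms, record, record_channels, comp_g,
                             record_calcium, rtol, atol, meta)

    n_rec = (n_steps + record_stride - 1) // record_stride
    v_out = {name: np.empty(n_rec) for name in record}
    g_out = {comp_g: {ch: np.empty(n_rec) for ch in record_channels}} \
        if record_channels else {}
    ca_out = {name: np.empty(n_rec) for name in record} if record_calcium \
        else {}
    v_idx = {name: cell.compartment_index(*_split(name)) for name in record}
    gi = cell.compartment_index(*_split(comp_g))

    def recorder(it, vv, g_by, cca):
        if it % record_stride:
            return
        j = it // record_stride
        for name, idx in v_idx.items():
            v_out[name][j] = vv[idx]
        for ch in record_channels:
            g_out[comp_g][ch][j] = g_by[ch][gi]
        if record_calcium:
            for name, idx in v_idx.items():
                ca_out[name][j] = cca[idx]

    _integrate(cell, channels, v, gates, ca, inj, dt_ms, recorder=recorder)
    t = (np.arange(n_rec) * record_stride + 1.0) * dt_ms
    i_rec = protocol.current_array(t) if noise is None \
        else inj[::record_stride].copy()
    return SimulationTrace(t=t, v=v_out, g=g_out, ca=ca_out,
                           i_inj_pA=i_rec, metadata=meta)


# --------------------------------------------------------------------------
# adaptive (stiff ODE) backend

def _pack(v, gates, ca, channels):
    parts = [v]
    for rt in channels:
        m, h = gates[rt.name]
        if rt.m_kind is not None:
            parts.append(m)
        if rt.h_kind == "voltage":
            parts.append(h)
    parts.append(ca)
    return np.concatenate(parts)


def _unpack(y, n, channels):
    v = y[:n]
    pos = n
    gates = {}
    for rt in channels:
        m = h = None
        if rt.m_kind is not None:
            m = y[pos:pos + n]; pos += n
        if rt.h_kind == "voltage":
            h = y[pos:pos + n]; pos += n
        gates[rt.name] = [m, h]
    ca = y[pos:pos + n]
    return v, gates, ca


def _run_adaptive(cell, channels, v, gates, ca, protocol, dt_ms, record,
                  record_channels, comp_g, record_calcium, rtol, atol, meta):
    from scipy.integrate import solve_ivp

    n = cell.n
    area = cell.area_cm2
    soma = cell.soma_index
    cm = cell.cm_uf * 1e-3
    g_leak = cell.density["leak"]
    ge_leak = g_leak * cell.e_leak
    m_ax = -cell.axial_gabs / area[:, None]
    np.fill_diagonal(m_ax, cell.axial_gabs.sum(axis=1) / area)
    pool = cell.pool
    k_ca = 1e4 / (2 * FARADAY * pool.shell_depth_um)

    def rhs(t, y, inj_pA):
        vv, gg, cca = _unpack(y, n, channels)
        cca = np.maximum(cca, pool.basal_mM)
        eca = _KNERNST * np.log(CA_OUT_MM / cca)
        # instantaneous Ca(L) h gate
        for rt in channels:
            if rt.h_kind == "instantaneous":
                gg[rt.name][1] = 1.245 / (1.245 + cca)
        g_by = _conductances(channels, gg)
        form = cell.params.ca_current_form
        if form in ("ghk", "cat-ghk"):
            chord = ghk_chord_conductance(vv, cca)
            for rt in channels:
                if rt.carries_ca and (form == "ghk" or rt.name == "Ca(T)"):
                    g_by[rt.name] = g_by[rt.name] * chord
        gsum = g_leak.copy()
        ge = ge_leak.copy()
        i_ca = np.zeros(n)
        for rt in channels:
            g = g_by[rt.name]
            gsum += g
            e = _e_of(rt, eca)
            ge += g * e
            if rt.carries_ca:
                i_ca += g * (vv - e)
        inj_density = np.zeros(n)
        inj_density[soma] = inj_pA * 1e-9 / area[soma]
        dv = (-(gsum * vv - ge) - m_ax @ vv + inj_density) / cm
        dy = [dv]
        for rt in channels:
            m, h = gg[rt.name]
            if rt.m_kind == "voltage":
                inf, tau = rt.m_fn(vv)
                dy.append(rt.phi_m * (inf - m) / tau)
            elif rt.m_kind == "calcium":
                inf, tau = rt.m_fn(cca)
                dy.append(rt.phi_m * (inf - m) / tau)
            if rt.h_kind == "voltage":
                inf, tau = rt.h_fn(vv)
                dy.append(rt.phi_h * (inf - h) / tau)
        dca = np.maximum(-i_ca, 0.0) * k_ca - (cca - pool.basal_mM) \
            / pool.decay_tau_ms
        dy.append(dca)
        return np.concatenate(dy)

    # integrate piecewise over constant-stimulus intervals
    bounds = sorted({0.0, protocol.total_ms}
                    | {t0 for _, t0, _ in protocol.segments}
                    | {t0 + d for _, t0, d in protocol.segments})
    bounds = [b for b in bounds if 0.0 <= b <= protocol.total_ms]
    y = _pack(v, gates, ca, channels)
    ts, ys = [], []
    for t0, t1 in zip(bounds, bounds[1:]):
        amp = float(protocol.current_array(np.array([(t0 + t1) / 2.0]))[0])
        t_eval = np.arange(np.ceil(t0 / dt_ms), np.floor(t1 / dt_ms) + 1) \
            * dt_ms
        t_eval = t_eval[(t_eval >= t0) & (t_eval <= t1)]
        sol = solve_ivp(rhs, (t0, t1), y, method="BDF", args=(amp,),
                        t_eval=t_eval, rtol=rtol, atol=atol, max_step=5.0)
        if not sol.success:
            raise RuntimeError(f"adaptive solver failed: {sol.message}")
        y = sol.y[:, -1] if sol.y.size else y
        if sol.y.size:
            ts.append(sol.t)
            ys.append(sol.y)
    t = np.concatenate(ts)
    ymat = np.concatenate(ys, axis=1)
    keep = np.concatenate(([True], np.diff(t) > 0))
    t, ymat = t[keep], ymat[:, keep]

    v_out, g_out, ca_out = {}, {}, {}
    v_idx = {name: cell.compartment_index(*_split(name)) for name in record}
    for name, idx in v_idx.items():
        v_out[name] = ymat[idx]
    if record_channels:
        gi = cell.compartment_index(*_split(comp_g))
        g_out[comp_g] = {}
        for ch in record_channels:
            series = np.empty(len(t))
            for k in range(len(t)):
                vv, gg, cca = _unpack(ymat[:, k], n, channels)
                for rt in channels:
                    if rt.h_kind == "instantaneous":
                        gg[rt.name][1] = 1.245 / (1.245 + np.maximum(
                            cca, cell.pool.basal_mM))
                series[k] = _conductances(channels, gg)[ch][gi]
            g_out[comp_g][ch] = series
    if record_calcium:
        for name, idx in v_idx.items():
            ca_out[name] = np.maximum(ymat[ymat.shape[0] - n + idx],
                                      cell.pool.basal_mM)
    i_rec = protocol.current_array(t)
    return SimulationTrace(t=t, v=v_out, g=g_out, ca=ca_out,
                           i_inj_pA=i_rec, metadata=meta)


# --------------------------------------------------------------------------
# parameter-set manipulations

def apply_pharmacology(params: ParameterSet, block: dict) -> ParameterSet:
    """Scaled copy of a parameter set: gmax[ch] *= factor per block entry.

    Mimics channel blockers (e.g. Na -> 0 for intracellular QX314, Ca(T) -> 0
    for nickel); factors must lie in [0, 1] and nothing else changes.
    """
    return params.with_blocks(block)


def set_nicotinic(params: ParameterSet, enabled: bool, g: float = 0.005,
                  scope: str = "gemmule") -> ParameterSet:
    """Enable/disable the ohmic nicotinic cation conductance (E = +3.2 mV).

    Default density 5 mS/cm^2 = 0.005 S/cm^2 in the gemmule; ``scope="all"``
    spreads the same total conductance uniformly over the whole cell.
    """
    return params.with_nicotinic(enabled, g=g, scope=scope)
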