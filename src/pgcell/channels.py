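"""Channel catalogue and Hodgkin-Huxley current evaluation.

Every membrane mechanism of the PG cell model is described by a
:class:`ChannelSpec`: gating orders ``a`` (activation) and ``b``
(inactivation), per-gate temperature coefficients phi, the kind of kinetics
each gate follows (voltage-dependent, calcium-dependent, or instantaneous),
and a reversal-potential rule.  The current through a channel is

    I_x = Gmax * m^a * h^b * (V - E_x)        [mA/cm^2]

with Gmax in S/cm^2 and V, E in mV; positive values are outward.  Gating
variables obey dx/dt = phi * (x_inf - x) / tau_x with the steady states and
time constants of :mod:`pgcell.kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import kinetics as kin

__all__ = [
    "ChannelSpec", "GatingState", "GatingCurves", "CHANNELS", "channel_names",
    "gating_curves", "channel_current", "gating_derivative",
    "instantaneous_gates", "catalogue_records", "gating_curve_table",
]

#: fixed reversal potentials, mV
E_NA = 50.0
E_K = -85.0
E_H = 0.0
E_CAN = 0.0
E_NIC = 3.2


@dataclass(frozen=True)
class GatingCurves:
    """Steady states and time constants for one channel at one (V, Ca)."""
    m_inf: float
    tau_m: Optional[float]
    h_inf: Optional[float]
    tau_h: Optional[float]


@dataclass
class GatingState:
    """Activation/inactivation state of one channel instance; both in [0, 1]."""
    m: float = 0.0
    h: Optional[float] = None


@dataclass(frozen=True)
class ChannelSpec:
    """Static description of one membrane mechanism.

    ``m_kind`` / ``h_kind`` is one of ``"voltage"``, ``"calcium"``,
    ``"instantaneous"`` or ``None`` (gate absent).  ``reversal`` is either a
    fixed potential in mV or the string ``"ca_nernst"`` for the dynamically
    recomputed calcium Nernst potential.
    """
    name: str
    a: int
    b: int
    phi_m: float
    phi_h: Optional[float]
    m_kind: Optional[str]
    h_kind: Optional[str]
    reversal: object
    permeant_ion: str = ""
    m_curve: Optional[Callable] = field(default=None, repr=False, compare=False)
    h_curve: Optional[Callable] = field(default=None, repr=False, compare=False)

    @property
    def is_ohmic(self) -> bool:
        return self.a == 0 and self.b == 0

    @property
    def carries_calcium(self) -> bool:
        return self.permeant_ion == "ca"

    @property
    def needs_calcium(self) -> bool:
        return "calcium" in (self.m_kind, self.h_kind) or self.h_kind == "instantaneous"


CHANNELS: dict[str, ChannelSpec] = {
    "Na": ChannelSpec("Na", a=3, b=1, phi_m=0.24, phi_h=0.24,
                      m_kind="voltage", h_kind="voltage", reversal=E_NA,
                      permeant_ion="na", m_curve=kin.na_m, h_curve=kin.na_h),
    "K": ChannelSpec("K", a=4, b=0, phi_m=0.24, phi_h=None,
                     m_kind="voltage", h_kind=None, reversal=E_K,
                     permeant_ion="k", m_curve=kin.kdr_m),
    "K(A)": ChannelSpec("K(A)", a=1, b=1, phi_m=0.46, phi_h=0.46,
                        m_kind="voltage", h_kind="voltage", reversal=E_K,
                        permeant_ion="k", m_curve=kin.ka_m, h_curve=kin.ka_h),
    "K(Ca)": ChannelSpec("K(Ca)", a=2, b=0, phi_m=1.12, phi_h=None,
                         m_kind="calcium", h_kind=None, reversal=E_K,
                         permeant_ion="k", m_curve=kin.kca_m),
    "H": ChannelSpec("H", a=1, b=0, phi_m=0.35, phi_h=None,
                     m_kind="voltage", h_kind=None, reversal=E_H,
                     permeant_ion="mixed", m_curve=kin.h_m),
    "Ca(L)": ChannelSpec("Ca(L)", a=2, b=1, phi_m=1.0, phi_h=1.0,
                         m_kind="voltage", h_kind="instantaneous",
                         reversal="ca_nernst", permeant_ion="ca",
                         m_curve=kin.cal_m),
    "Ca(T)": ChannelSpec("Ca(T)", a=2, b=1, phi_m=0.85, phi_h=0.90,
                         m_kind="voltage", h_kind="voltage",
                         reversal="ca_nernst", permeant_ion="ca",
                         m_curve=kin.cat_m, h_curve=kin.cat_h),
    "CAN": ChannelSpec("CAN", a=2, b=0, phi_m=1.12, phi_h=None,
                       m_kind="calcium", h_kind=None, reversal=E_CAN,
                       permeant_ion="mixed", m_curve=kin.can_m),
    # purely ohmic conductances: no gating, m^0 h^0 = 1
    "nic": ChannelSpec("nic", a=0, b=0, phi_m=1.0, phi_h=None,
                       m_kind=None, h_kind=None, reversal=E_NIC,
                       permeant_ion="mixed"),
    "leak": ChannelSpec("leak", a=0, b=0, phi_m=1.0, phi_h=None,
                        m_kind=None, h_kind=None, reversal="e_leak",
                        permeant_ion="mixed"),
}


def channel_names() -> list[str]:
    return list(CHANNELS)


def _resolve(channel) -> ChannelSpec:
    if isinstance(channel, ChannelSpec):
        return channel
    try:
        return CHANNELS[channel]
    except KeyError:
        raise KeyError(f"unknown channel {channel!r}; known: {list(CHANNELS)}") from None


class CalciumRequiredError(ValueError):
    """A calcium-gated channel was queried without a calcium concentration."""


def gating_curves(channel, v: float, ca: float | None = None) -> GatingCurves:
    """Steady states (m_inf, h_inf) and time constants (tau_m, tau_h, ms).

    ``v`` in mV; ``ca`` (mM) is required for the calcium-gated channels
    K(Ca) and CAN and for the instantaneous Ca(L) inactivation gate.
    phi is *not* applied here (it scales the state-update equation only).
    """
    spec = _resolve(channel)
    if spec.needs_calcium and ca is None:
        raise CalciumRequiredError(
            f"channel {spec.name} is calcium-gated; pass ca (mM)")
    m_inf = tau_m = h_inf = tau_h = None
    if spec.m_kind == "voltage":
        m_inf, tau_m = spec.m_curve(v)
    elif spec.m_kind == "calcium":
        m_inf, tau_m = spec.m_curve(ca)
    if spec.h_kind == "voltage":
        h_inf, tau_h = spec.h_curve(v)
    elif spec.h_kind == "instantaneous":
        h_inf, tau_h = kin.cal_h_inf(ca), None
    return GatingCurves(m_inf, tau_m, h_inf, tau_h)


def channel_current(channel, state: GatingState | None, v: float, e: float,
                    gmax: float) -> float:
    """Current density Gmax * m^a * h^b * (V - E), mA/cm^2 (positive outward)."""
    spec = _resolve(channel)
    if gmax < 0:
        raise ValueError("gmax must be >= 0")
    g = gmax
    if spec.a > 0:
        g = g * state.m ** spec.a
    if spec.b > 0:
        g = g * state.h ** spec.b
    return g * (v - e)


def gating_derivative(channel, state: GatingState, v: float,
                      ca: float | None = None) -> tuple[float, float]:
    """(dm/dt, dh/dt) in 1/ms: phi * (x_inf - x) / tau_x.

    Instantaneous gates (the Ca(L) h gate) have zero derivative here; they
    are set algebraically each step via :func:`instantaneous_gates`.
    """
    spec = _resolve(channel)
    curves = gating_curves(spec, v, ca)
    dm = 0.0
    dh = 0.0
    if spec.m_kind in ("voltage", "calcium"):
        dm = spec.phi_m * (curves.m_inf - state.m) / curves.tau_m
    if spec.h_kind == "voltage":
        dh = spec.phi_h * (curves.h_inf - state.h) / curves.tau_h
    return dm, dh


def instantaneous_gates(channel, ca: float) -> float:
    """Algebraic gate value for channels with an instantaneous gate.

    Only Ca(L) has one: h = 1.245 / (1.245 + [Ca]_i), in (0, 1].
    """
    spec = _resolve(channel)
    if spec.h_kind != "instantaneous":
        raise ValueError(f"channel {spec.name} has no instantaneous gate")
    if ca < 0:
        raise ValueError("ca must be >= 0")
    return kin.cal_h_inf(ca)


def catalogue_records() -> list[dict]:
    """The channel catalogue as plain records (for config serialization)."""
    out = []
    for spec in CHANNELS.values():
        out.append({
            "name": spec.name,
            "activation_order": spec.a,
            "inactivation_order": spec.b,
            "phi_m": spec.phi_m,
            "phi_h": spec.phi_h,
            "m_kind": spec.m_kind,
            "h_kind": spec.h_kind,
            "reversal": spec.reversal,
            "permeant_ion": spec.permeant_ion,
        })
    return out


def gating_curve_table(channel, v_grid=None, ca: float = 2.4e-4):
    """Tabulate (V, m_inf, tau_m, h_inf, tau_h) for plotting/validation.

    Returns a dict of equal-length numpy arrays; calcium-gated channels are
    tabulated against ``v_grid`` at fixed ``ca`` for uniformity (their curves
    are V-independent).
    """
    if v_grid is None:
        v_grid = np.arange(-120.0, 60.0 + 1e-9, 0.5)
    v_grid = np.asarray(v_grid, float)
    cols = {"V_mV": v_grid}
    m_inf = np.empty_like(v_grid)
    tau_m = np.full_like(v_grid, np.nan)
    h_inf = np.full_like(v_grid, np.nan)
    tau_h = np.full_like(v_grid, np.nan)
    spec = _resolve(channel)
    for i, v in enumerate(v_grid):
        c = gating_curves(spec, v, ca if spec.needs_calcium else None)
        m_inf[i] = c.m_inf if c.m_inf is not None else np.nan
        tau_m[i] = c.tau_m if c.tau_m is not None else np.nan
        h_inf[i] = c.h_inf if c.h_inf is not None else np.nan
        tau_h[i] = c.tau_h if c.tau_h is not None else np.nan
    cols.update(m_inf=m_inf, tau_m_ms=tau_m, h_inf=h_inf, tau_h_ms=tau_h)
    return cols
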