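"""Six-section compartmental PG cell: geometry, passive properties, channels.

The model cell comprises a soma (8 um length and diameter), two 20 um
dendrites, a 1 um gemmule (spine) shaft plus 1 um gemmule body on one
dendrite, and a 50 um axon stub; all non-somatic sections are 1 um in
diameter.  Compartment counts follow the d_lambda rule (0.1 of the 100 Hz
AC length constant), which yields three axon compartments and a single
isopotential compartment for every other section.

Passive membrane: Cm = 1.2 uF/cm^2, axial resistivity 173 ohm-cm, leak
reversal -70 mV (one phenotype uses -55 mV).  The leak conductance density
is not an independent datum; it is calibrated once so that the passive
cell's somatic input resistance equals 775 MOhm, and the calibrated value
ships in the default config.

A 0.1 um perimembrane calcium shell is attached to every compartment that
expresses a calcium channel; calcium decays exponentially to a basal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .channels import CHANNELS

__all__ = [
    "FARADAY", "GAS_CONSTANT", "TEMPERATURE_K", "CA_OUT_MM",
    "CM_UF_CM2", "RA_OHM_CM", "E_LEAK_MV", "RIN_TARGET_MOHM", "RIN_TOL_MOHM",
    "DEFAULT_G_LEAK", "SECTION_GEOMETRY", "SECTION_ORDER",
    "SectionSpec", "CalciumPool", "ParameterSet", "CellModel",
    "dlambda_nseg", "build_cell", "calcium_step", "calcium_reversal",
    "passive_input_resistance", "calibrate_leak",
]

FARADAY = 96485.33212          # C/mol
GAS_CONSTANT = 8.31446262      # J/(mol K)
TEMPERATURE_K = 296.15         # 23 degC, slice recording temperature
CA_OUT_MM = 2.0                # external [Ca], standard ACSF

CM_UF_CM2 = 1.2
RA_OHM_CM = 173.0
E_LEAK_MV = -70.0
RIN_TARGET_MOHM = 775.0
RIN_TOL_MOHM = 55.0

#: uniform leak density (S/cm^2) calibrated so the passive cell's somatic
#: input resistance is 775 MOhm; see :func:`calibrate_leak`.
DEFAULT_G_LEAK = 2.649031e-4

#: channels that may carry non-zero density in a parameter set
ACTIVE_CHANNELS = ("Na", "K", "K(A)", "K(Ca)", "H", "Ca(L)", "Ca(T)", "CAN")

# name -> (length um, diameter um, parent, attachment)
# attachment "center" = parent mid node; "end" = parent distal (1) end
SECTION_GEOMETRY = {
    "soma":    (8.0, 8.0, None, None),
    "dend1":   (20.0, 1.0, "soma", "center"),
    "dend2":   (20.0, 1.0, "soma", "center"),
    "shaft":   (1.0, 1.0, "dend1", "end"),
    "gemmule": (1.0, 1.0, "shaft", "end"),
    "axon":    (50.0, 1.0, "soma", "center"),
}
SECTION_ORDER = ("soma", "dend1", "dend2", "shaft", "gemmule", "axon")


@dataclass(frozen=True)
class SectionSpec:
    """Geometry and passive membrane of one cable section."""
    name: str
    length_um: float
    diam_um: float
    parent: Optional[str]
    attachment: Optional[str]
    n_compartments: int
    membrane_capacitance: float = CM_UF_CM2   # uF/cm^2
    axial_resistivity: float = RA_OHM_CM      # ohm-cm

    def __post_init__(self):
        if self.length_um <= 0 or self.diam_um <= 0:
            raise ValueError(f"non-physical geometry for section {self.name}")
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")


@dataclass(frozen=True)
class CalciumPool:
    """Perimembrane calcium shell: 0.1 um deep, exponential decay to basal."""
    shell_depth_um: float = 0.1
    basal_mM: float = 2.4e-4
    decay_tau_ms: float = 200.0


@dataclass
class ParameterSet:
    """One phenotype's maximal-conductance vector plus model switches.

    ``gmax`` maps channel name to density in S/cm^2; channels absent from a
    phenotype are encoded as explicit zeros.  ``cat_scope`` restricts the
    T-type calcium channel to the soma (the default) or expresses it in all
    sections (``"all"``); the nicotinic conductance lives in the gemmule
    unless ``nic_scope`` is ``"all"`` (matched total conductance spread
    uniformly).
    """
    label: str = "custom"
    gmax: dict = field(default_factory=dict)
    e_leak: float = E_LEAK_MV
    g_leak: float = DEFAULT_G_LEAK
    noise_enabled: bool = False
    nicotinic_enabled: bool = False
    nic_g: float = 0.005      # S/cm^2 in the gemmule when enabled
    nic_scope: str = "gemmule"
    cat_scope: str = "soma"
    ca_current_form: str = "nernst"   # "nernst" (linear) or "ghk"

    def __post_init__(self):
        for name, g in self.gmax.items():
            if name not in ACTIVE_CHANNELS:
                raise KeyError(f"unknown channel {name!r} in parameter set")
            if g < 0:
                raise ValueError(f"negative conductance for {name}")

    def density(self, channel: str) -> float:
        return float(self.gmax.get(channel, 0.0))

    def with_blocks(self, blocks: dict) -> "ParameterSet":
        """Scaled copy: gmax[ch] *= factor for each (ch, factor) in blocks."""
        new = dict(self.gmax)
        for name, fac in blocks.items():
            if name not in ACTIVE_CHANNELS:
                raise KeyError(f"unknown channel {name!r}")
            if not 0.0 <= fac <= 1.0:
                raise ValueError("block scale factor must be in [0, 1]")
            new[name] = new.get(name, 0.0) * fac
        return replace(self, gmax=new)

    def with_nicotinic(self, enabled: bool, g: float = 0.005,
                       scope: str = "gemmule") -> "ParameterSet":
        if g < 0:
            raise ValueError("nicotinic conductance must be >= 0")
        return replace(self, nicotinic_enabled=enabled, nic_g=g, nic_scope=scope)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "gmax": {k: float(v) for k, v in self.gmax.items()},
            "e_leak": self.e_leak,
            "g_leak": self.g_leak,
            "noise_enabled": self.noise_enabled,
            "nicotinic_enabled": self.nicotinic_enabled,
            "nic_g": self.nic_g,
            "nic_scope": self.nic_scope,
            "cat_scope": self.cat_scope,
            "ca_current_form": self.ca_current_form,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)


def dlambda_nseg(length_um: float, diam_um: float,
                 ra_ohm_cm: float = RA_OHM_CM, cm_uf_cm2: float = CM_UF_CM2,
                 d_lambda: float = 0.1, freq_hz: float = 100.0) -> int:
    """Compartment count from the d_lambda rule.

    The AC length constant at ``freq_hz`` is
    ``lambda_f = 1e5 * sqrt(diam / (4 pi f Ra Cm))`` (um, with diam in um,
    Ra in ohm-cm, Cm in uF/cm^2); the section is split into the smallest odd
    number of compartments with length <= d_lambda * lambda_f.
    """
    if not 0 < d_lambda <= 1:
        raise ValueError("d_lambda must be in (0, 1]")
    if freq_hz <= 0:
        raise ValueError("frequency must be > 0")
    if length_um <= 0 or diam_um <= 0:
        raise ValueError("non-physical geometry")
    lam = 1e5 * np.sqrt(diam_um / (4.0 * np.pi * freq_hz * ra_ohm_cm * cm_uf_cm2))
    return int((length_um / (d_lambda * lam) + 0.9) / 2.0) * 2 + 1


def calcium_reversal(ca_i_mM, ca_o_mM: float = CA_OUT_MM,
                     temp_k: float = TEMPERATURE_K):
    """Calcium Nernst potential (RT/2F) ln(cao/cai), in mV."""
    ca_i = np.asarray(ca_i_mM, float)
    if np.any(ca_i <= 0) or ca_o_mM <= 0:
        raise ValueError("concentrations must be > 0")
    out = 1e3 * GAS_CONSTANT * temp_k / (2.0 * FARADAY) * np.log(ca_o_mM / ca_i)
    return out if out.ndim else float(out)


def calcium_step(ca_mM, i_ca_mA_cm2, dt_ms: float, pool: CalciumPool):
    """Advance the perimembrane calcium pool by one time step.

    d[Ca]/dt = max(-I_Ca, 0) * 1e4 / (2 F depth) - ([Ca] - basal) / tau,
    with I_Ca in mA/cm^2 (inward = negative, hence the sign flip) and depth
    in um; only influx charges the shell.  The linear ODE is advanced with
    its exact exponential update for the frozen influx term.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    ca = np.asarray(ca_mM, float)
    influx = np.maximum(-np.asarray(i_ca_mA_cm2, float), 0.0)
    drive = influx * 1e4 / (2.0 * FARADAY * pool.shell_depth_um)   # mM/ms
    target = pool.basal_mM + drive * pool.decay_tau_ms
    out = target + (ca - target) * np.exp(-dt_ms / pool.decay_tau_ms)
    out = np.maximum(out, pool.basal_mM)
    return out if out.ndim else float(out)


def ghk_chord_conductance(v_mV, ca_i_mM, ca_o_mM: float = CA_OUT_MM,
                          temp_k: float = TEMPERATURE_K):
    """Chord conductance (S/cm^2 per unit permeability) of the GHK calcium flux.

    The Goldman-Hodgkin-Katz current for a divalent ion,
    i = P z^2 F^2 V/(RT) (ci - co e^{-zFV/RT}) / (1 - e^{-zFV/RT}),
    crosses zero exactly at the calcium Nernst potential, so it can be
    expressed as i = P * chord(V, ca) * (V - E_Ca).  This returns that chord
    factor, letting a permeability-form calcium current slot into the same
    conductance * driving-force bookkeeping as the ohmic channels.
    """
    v = np.asarray(v_mV, float)
    ca_i = np.asarray(ca_i_mM, float)
    zf = 2.0 * FARADAY
    u = zf * v * 1e-3 / (GAS_CONSTANT * temp_k)
    # guard u ~ 0 (flux -> P z F (ci - co), slope form)
    small = np.abs(u) < 1e-9
    u_safe = np.where(small, 1.0, u)
    ratio = np.where(
        small,
        (ca_i - ca_o_mM) * 1e-6,
        (ca_i - ca_o_mM * np.exp(-u_safe)) * 1e-6 / -np.expm1(-u_safe))
    i_per_p = zf * u * ratio * 1e3                 # mA/cm^2 per cm/s
    e_ca = calcium_reversal(ca_i, ca_o_mM, temp_k)
    dv = v - e_ca
    # chord is smooth through E_Ca; fall back to a tiny offset there
    dv = np.where(np.abs(dv) < 1e-9, 1e-9, dv)
    out = i_per_p / dv
    return out if out.ndim else float(out)


class CellModel:
    """Discretized PG cell ready for simulation.

    Attributes of interest: ``n`` compartments, per-compartment ``area_cm2``,
    absolute axial conductance matrix ``axial_gabs`` (S), channel density
    arrays ``density[channel]`` (S/cm^2), leak reversal ``e_leak`` (mV),
    ``soma_index`` (injection and recording site) and the calcium ``pool``.
    """

    def __init__(self, params: ParameterSet, sections: list[SectionSpec],
                 pool: CalciumPool):
        self.params = params
        self.sections = {s.name: s for s in sections}
        self.pool = pool

        names, sec_of, areas, half_r = [], [], [], []
        first_comp, last_comp = {}, {}
        for sec in sections:
            dx_um = sec.length_um / sec.n_compartments
            area = np.pi * sec.diam_um * dx_um * 1e-8          # cm^2, cylinder side
            radius_cm = sec.diam_um / 2.0 * 1e-4
            rh = sec.axial_resistivity * (dx_um / 2.0 * 1e-4) / (np.pi * radius_cm**2)
            for i in range(sec.n_compartments):
                names.append(f"{sec.name}[{i}]")
                sec_of.append(sec.name)
                areas.append(area)
                half_r.append(rh)
            idx0 = len(names) - sec.n_compartments
            first_comp[sec.name] = idx0
            last_comp[sec.name] = len(names) - 1

        self.n = len(names)
        self.comp_names = names
        self.comp_section = sec_of
        self.area_cm2 = np.array(areas)
        self.cm_uf = np.full(self.n, CM_UF_CM2)
        self.soma_index = first_comp["soma"]

        # axial conductances between node pairs (dense, symmetric, S)
        g = np.zeros((self.n, self.n))

        def connect(i, j, r_ohm):
            g[i, j] += 1.0 / r_ohm
            g[j, i] += 1.0 / r_ohm

        for sec in sections:
            i0 = first_comp[sec.name]
            for k in range(sec.n_compartments - 1):
                connect(i0 + k, i0 + k + 1, half_r[i0 + k] + half_r[i0 + k + 1])
            if sec.parent is not None:
                if sec.parent not in first_comp:
                    raise ValueError(f"section {sec.name} attached to unknown "
                                     f"parent {sec.parent}")
                child = first_comp[sec.name]
                if sec.attachment == "center":
                    # parent mid node is a voltage node: child half only
                    pnode = (first_comp[sec.parent] + last_comp[sec.parent]) // 2
                    connect(child, pnode, half_r[child])
                else:  # distal end of parent
                    pnode = last_comp[sec.parent]
                    connect(child, pnode, half_r[pnode] + half_r[child])
        self.axial_gabs = g
        self._check_connected()

        # channel density per compartment
        dens = {}
        soma_mask = np.array([s == "soma" for s in sec_of])
        gem_mask = np.array([s == "gemmule" for s in sec_of])
        for ch in ACTIVE_CHANNELS:
            d = np.full(self.n, params.density(ch))
            if ch == "Ca(T)" and params.cat_scope == "soma":
                d = np.where(soma_mask, d, 0.0)
            dens[ch] = d
        nic = np.zeros(self.n)
        if params.nicotinic_enabled and params.nic_g > 0:
            if params.nic_scope == "gemmule":
                nic[gem_mask] = params.nic_g
            else:
                # uniform expression at matched total conductance
                total = params.nic_g * self.area_cm2[gem_mask].sum()
                nic[:] = total / self.area_cm2.sum()
        dens["nic"] = nic
        dens["leak"] = np.full(self.n, params.g_leak)
        self.density = dens
        self.e_leak = np.full(self.n, params.e_leak)

        self.ca_mask = (dens["Ca(L)"] + dens["Ca(T)"]) > 0

    def _check_connected(self):
        reach = {0}
        frontier = [0]
        adj = self.axial_gabs > 0
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(adj[i])[0]:
                if j not in reach:
                    reach.add(int(j))
                    frontier.append(int(j))
        if len(reach) != self.n:
            raise ValueError("cell topology is disconnected")

    def compartment_index(self, section: str, i: int = 0) -> int:
        name = f"{section}[{i}]"
        return self.comp_names.index(name)

    def conductance_table(self):
        """Per-compartment resolved channel densities (S/cm^2) as a DataFrame."""
        import pandas as pd
        data = {"compartment": self.comp_names,
                "area_cm2": self.area_cm2}
        for ch, d in self.density.items():
            data[f"g_{ch}_S_cm2"] = d
        return pd.DataFrame(data)


def build_sections(nseg_factor: int = 1, d_lambda: float = 0.1,
                   freq_hz: float = 100.0) -> list[SectionSpec]:
    if nseg_factor < 1 or nseg_factor % 2 == 0:
        raise ValueError("nseg_factor must be a positive odd integer")
    out = []
    for name in SECTION_ORDER:
        length, diam, parent, attach = SECTION_GEOMETRY[name]
        n = dlambda_nseg(length, diam, d_lambda=d_lambda, freq_hz=freq_hz)
        out.append(SectionSpec(name, length, diam, parent, attach,
                               n * nseg_factor))
    return out


def build_cell(params: ParameterSet, nseg_factor: int = 1,
               pool: CalciumPool | None = None) -> CellModel:
    """Assemble the six-section cell for one parameter set.

    ``nseg_factor`` multiplies every section's d_lambda compartment count
    (odd factors keep counts odd); used for discretization-invariance checks.
    """
    return CellModel(params, build_sections(nseg_factor),
                     pool if pool is not None else CalciumPool())


def passive_input_resistance(cell: CellModel, site: int | None = None) -> float:
    """Steady-state input resistance (MOhm) of the passive circuit at a node.

    Solves the resistive network (leak conductances to ground plus axial
    couplings) directly; equals the simulated DeltaV/DeltaI of a small long
    current step on the cell with all active conductances at zero.
    """
    site = cell.soma_index if site is None else site
    g = -cell.axial_gabs.copy()
    np.fill_diagonal(g, cell.axial_gabs.sum(axis=1)
                     + cell.density["leak"] * cell.area_cm2)
    rhs = np.zeros(cell.n)
    rhs[site] = 1.0                       # 1 A test current
    v = np.linalg.solve(g, rhs)           # volts
    return v[site] / 1e6                  # ohms -> MOhm


def calibrate_leak(target_mohm: float = RIN_TARGET_MOHM,
                   e_leak: float = E_LEAK_MV) -> float:
    """Uniform leak density (S/cm^2) giving the target somatic R_in.

    R_in is strictly decreasing in g_leak, so bisection (brentq) on the
    passive network solve converges to machine precision.
    """
    from scipy.optimize import brentq

    def resid(g):
        ps = ParameterSet(label="passive", gmax={}, g_leak=g, e_leak=e_leak)
        return passive_input_resistance(build_cell(ps)) - target_mohm

    return float(brentq(resid, 1e-6, 1e-2, xtol=1e-14, rtol=1e-14))
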