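"""Published phenotype presets and their current-clamp protocols.

The nine parameter sets (keyed ``fig2A`` ... ``fig3E``) ship as data in
``data/presets.yaml`` together with the stimulus amplitudes and durations of
the corresponding figure protocols.  ``load_preset`` resolves one into a
:class:`~pgcell.cell.ParameterSet` / :class:`ProtocolPreset` pair ready for
:func:`~pgcell.simulate.run_current_clamp`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .cell import CalciumPool, ParameterSet
from .simulate import NoiseSource, StimulusProtocol

__all__ = [
    "PRESET_KEYS", "ProtocolPreset", "load_config", "load_preset",
    "default_pool", "default_noise", "conductance_ratio_span",
    "preset_response_type",
]

PRESET_KEYS = ("fig2A", "fig2B", "fig2C", "fig2D",
               "fig3A", "fig3B", "fig3C", "fig3D", "fig3E")

#: channels whose gating depends on voltage (used for conductance-ratio
#: bookkeeping across presets)
VOLTAGE_DEPENDENT = ("Na", "K", "K(A)", "H", "Ca(L)", "Ca(T)")


@dataclass(frozen=True)
class ProtocolPreset:
    """Depolarizing/hyperpolarizing stimulus pair for one figure panel."""
    key: str
    depol_pA: float
    depol_ms: float
    hyper_pA: float
    hyper_ms: float

    def depol(self, onset_ms: float = 100.0,
              post_ms: float = 600.0) -> StimulusProtocol:
        return StimulusProtocol.step(self.depol_pA, onset_ms=onset_ms,
                                     dur_ms=self.depol_ms, post_ms=post_ms)

    def hyper(self, onset_ms: float = 100.0,
              post_ms: float = 600.0) -> StimulusProtocol:
        return StimulusProtocol.step(self.hyper_pA, onset_ms=onset_ms,
                                     dur_ms=self.hyper_ms, post_ms=post_ms)


def load_config() -> dict:
    """The raw preset/passive/calcium/noise configuration document."""
    with resources.files("pgcell.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_pool(config: dict | None = None) -> CalciumPool:
    ca = (config or load_config())["calcium"]
    return CalciumPool(shell_depth_um=ca["shell_depth_um"],
                       basal_mM=ca["basal_mM"],
                       decay_tau_ms=ca["decay_tau_ms"])


def default_noise(seed: int = 0, config: dict | None = None) -> NoiseSource:
    nz = (config or load_config())["noise"]
    return NoiseSource(sd_fA=nz["sd_fA"], bandwidth_khz=nz["bandwidth_khz"],
                       tau_ms=nz["tau_ms"], seed=seed)


def load_preset(key: str) -> tuple[ParameterSet, ProtocolPreset]:
    """Resolve one phenotype preset into parameters and protocol.

    Raises ``KeyError`` for unknown keys.  The fig2A preset carries its
    depolarized leak reversal (-55 mV); fig2D carries ``noise_enabled``.
    """
    cfg = load_config()
    try:
        doc = cfg["presets"][key]
    except KeyError:
        raise KeyError(f"unknown preset {key!r}; known: {PRESET_KEYS}") \
            from None
    passive = cfg["passive"]
    defaults = cfg["model_defaults"]
    params = ParameterSet(
        label=key,
        gmax={k: float(v) for k, v in doc["gmax"].items()},
        e_leak=float(doc.get("e_leak_mv", passive["e_leak_mv"])),
        g_leak=float(passive["g_leak_s_cm2"]),
        noise_enabled=bool(doc.get("noise_enabled", False)),
        nic_g=float(defaults["nic_g_s_cm2"]),
        cat_scope=str(defaults["cat_scope"]),
        ca_current_form=str(cfg["calcium"]["current_form"]),
    )
    p = doc["protocol"]
    proto = ProtocolPreset(key=key,
                           depol_pA=float(p["depol_pA"]),
                           depol_ms=float(p["depol_ms"]),
                           hyper_pA=float(p["hyper_pA"]),
                           hyper_ms=float(p["hyper_ms"]))
    return params, proto


def preset_response_type(key: str) -> str:
    """The published phenotype label for one preset key."""
    return load_config()["presets"][key]["response_type"]


def conductance_ratio_span(key_num: str = "fig3B",
                           key_den: str = "fig3A") -> tuple[float, float]:
    """(min, max) of elementwise Gmax ratios over shared voltage-dependent
    channels of two presets (channels absent from either are skipped)."""
    a, _ = load_preset(key_num)
    b, _ = load_preset(key_den)
    ratios = [a.density(ch) / b.density(ch) for ch in VOLTAGE_DEPENDENT
              if a.density(ch) > 0 and b.density(ch) > 0]
    if not ratios:
        raise ValueError("presets share no voltage-dependent channels")
    return min(ratios), max(ratios)
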