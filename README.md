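# pgcell

A reduced conductance-based model of olfactory bulb **periglomerular (PG)
cells** — small inhibitory interneurons of the glomerular layer whose
current-clamp responses are strikingly heterogeneous: some fire simple
non-accommodating or accommodating spike trains, some a single spike, some
produce T-type-calcium low-threshold spikes (LTS) crowned by one AP or a
decrementing burst, and a few show persistent CAN-current plateau
potentials. `pgcell` implements the hypothesis that this entire range of
phenotypes arises from a **single cell model** in which only the relative
expression levels (maximal conductance densities) of the membrane
mechanisms differ — channel kinetics and spatial layout stay fixed.

For computational neuroscientists and olfactory-bulb modellers who want a
lightweight, inspectable PG cell: a pure Python/NumPy implementation with
no simulator dependency, nine ready-made phenotype parameter presets, and
an analysis layer that classifies simulated responses into the
experimental phenotype vocabulary.

## The model

Six cable sections — soma (8 µm × 8 µm), two 20 µm dendrites, a 1 µm
gemmule (spine) shaft and gemmule on one dendrite, and a 50 µm axon — are
discretized by the d_lambda rule (3 axon compartments, 1 elsewhere;
C_m = 1.2 µF/cm², R_a = 173 Ω·cm, uniform leak calibrated so the passive
somatic input resistance is 775 MΩ). Each compartment carries
Hodgkin–Huxley mechanisms

```
I_x = Gmax_x · m^a · h^b · (V − E_x),      dx/dt = Φ (x_∞(V, [Ca]) − x)/τ_x(V, [Ca])
```

for fast Na, delayed-rectifier K, A-type K, Ca-activated K, the
hyperpolarization-activated cation current H, L- and T-type Ca currents, a
Ca-activated nonspecific cation current (CAN), an ohmic nicotinic
conductance confined to the gemmule, and leak. Kinetics are pinned at
23 °C via per-gate temperature coefficients Φ. The two calcium currents
default to the Goldman–Hodgkin–Katz permeability form (their density
parameters act as permeabilities, as in their source mechanisms; a linear
Nernst-driving form is available via `ParameterSet(ca_current_form=...)`).
Calcium accumulates in a 0.1 µm perimembrane shell and relaxes
exponentially to a 240 nM basal level; E_Ca is recomputed from the Nernst
equation every step.

The integrator is a fixed-step, second-order implicit scheme
(Crank–Nicolson voltage step with staggered exponential-Euler gating);
a SciPy BDF backend provides an independent numerical cross-check, and a
seeded colored-noise current source (50 fA white noise, 0–4 kHz,
exponentially filtered with τ = 5 ms) reproduces noise-driven firing.

## Worked example

Classify the "LTS with AP burst" preset under its published ±10 pA,
600 ms protocol pair (this also runs the Na-blocked companion simulations
used for LTS detection):

```python
from pgcell.cli import classify_preset
rec = classify_preset("fig3B", seed=1, dt_ms=0.05)
print(rec["label"], rec["depol"]["spike_count"],
      round(rec["depol"]["lts_amplitude_mv"], 1),
      rec["hyper"]["rebound_spike_count"])
```

prints

```
LTS-burst 2 30.6 1
```

— the depolarizing step evokes a low-threshold envelope (30.6 mV above
the passive prediction after Na block, lasting 216 ms) crowned by two
decrementing spikes, and release from hyperpolarization evokes a rebound
(anode-break) LTS with one spike, so the response pair is classified
`LTS-burst`, matching the published phenotype for this conductance set.

The same from the shell:

```sh
pgcell run --preset fig3B --out trace.tsv          # tab-delimited V(t)
pgcell analyze --preset fig3B                      # feature record (YAML)
pgcell classify-all                                # nine-preset regression
pgcell curve-dump --channel "Ca(T)" --out cat.tsv  # gating curves
```

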