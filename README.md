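# nmcirc

Firing-rate neural circuit models with explicit neuromodulator dynamics, and
in-silico pharmacology on top of them.

Neuromodulators — serotonin (5-HT), norepinephrine (NE), orexin (Ox) and the
like — act on slow timescales (seconds to a minute) through
receptor-mediated currents, and they are the targets of most psychiatric
drugs. `nmcirc` is for computational neuroscientists and
neuropharmacologists who want a circuit-level, data-constrained model of
such systems that runs in seconds: each brain region is one
population-averaged firing-rate node, each neuromodulator pathway carries an
explicit extracellular concentration with release/reuptake kinetics, and
drugs are declarative transformations of the model's kinetic and
receptor-response parameters.

## Model

Each population *i* maps its summed neuromodulator-induced afferent current
to a firing rate through a threshold-linear f–I curve

    f_i = K_i · [ I_total,i − I_0,i + I_bias,i ]₊

A neuromodulator *y* released by region *j* induces a current on region *i*
that relaxes towards a sigmoid function of the extracellular concentration
[y] (a four-parameter logistic in log₁₀ concentration, the standard
pharmacological dose–response form):

    τ · dI/dt = −I + G([y]),   G(c) = p_LR + (p_UR − p_LR) · σ((log₁₀c − p_LS)/p_S)

and the concentration follows its source population's firing rate with
saturating Michaelis–Menten reuptake,

    d[y]/dt = [y]_p · f_j − V_max·[y]/(K_m + [y])

or, where no reuptake measurements exist (orexin), a linear rise/decay form
d[y]/dt = α·f_j − η·[y]. Firing rates are algebraic (their ~10–100 ms
dynamics are far below the neuromodulator time constants); a reduced
"direct-rate" coupling mode for two-region models is also provided. The
coupled system is integrated by forward Euler at 1 ms until a stable steady
state.

The bundled preset is a three-region circuit of the lateral hypothalamic
area (LHA, orexin source), dorsal raphe nucleus (DRN, serotonin source) and
locus coeruleus (LC, norepinephrine source) with six pathways, built from
published electrophysiological, voltammetric and microdialysis
measurements; the free per-stimulus release parameters are calibrated so
the coupled steady state reproduces the experimentally observed basal rates
and concentrations (see `docs/methods.md`).

Drugs: selective reuptake inhibitors (SSRI/NRI) scale K_m of their
transporter; competitive antagonists shift a response curve laterally
(ED₅₀ up, maximum untouched); irreversible antagonists compress the
response range; and the bundled orexin-1 antagonist SB-334867-A applies its
measured parameter replacements verbatim.

## Worked example

```python
from nmcirc import SimulationConfig, apply_drug, steady_state
from nmcirc.preset import baseline_state, build_preset

bundle = build_preset()                      # build + calibrate the circuit
ss = steady_state(bundle.circuit, init=baseline_state(bundle),
                  cfg=SimulationConfig(dt=0.001, duration=600.0))
print({k: round(v, 3) for k, v in ss.rates.items()})

drugged = apply_drug(bundle.circuit, bundle.drugs["fluoxetine"])  # K_m,5-HT x5
ssri = steady_state(drugged, init=ss, cfg=SimulationConfig(dt=0.05, duration=40000.0))
print(round(ssri.concentrations["5-HT:DRN->LHA"], 2), round(ssri.rates["LHA"], 2))
```

prints

```
{'LHA': 2.3, 'DRN': 0.8, 'LC': 2.15}
7.59 1.44
```

— the calibrated circuit settles at the observed basal firing rates
(orexin neurons 2.3 Hz, serotonergic 0.8 Hz, noradrenergic 2.15 Hz), and a
fluoxetine-like SSRI (5× K_m on all serotonin transporters) raises
extracellular 5-HT at the LHA from its basal 1.6 nM to 7.6 nM, which slows
the orexin neurons from 2.3 to 1.4 Hz through their inhibitory
serotonergic GIRK current.

The same workflows are available from a shell:

```sh
nmcirc steady-state --preset -o baseline.csv
nmcirc steady-state --preset --drug fluoxetine --drug nri-x5 \
    --dt 0.05 --duration 40000 -o combo.csv
nmcirc drug-scan --preset --species 5-HT --levels 1,2,3,4,5 \
    --dt 0.05 --duration 40000 -o ssri_scan.csv
```

Each run writes a CSV plus a JSON manifest sufficient to replay it. The
circuit configuration dialect (YAML) is documented by the shipped preset at
`src/nmcirc/data/lha_drn_lc.yaml`, which round-trips byte-identically
through `nmcirc.read_config`/`write_config`.

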