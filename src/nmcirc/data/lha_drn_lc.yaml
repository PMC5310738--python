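baselines:
  concentrations:
    5-HT:DRN->LC: 1.1e-07
    5-HT:DRN->LHA: 1.6
    NE:LC->DRN: 2950.0
    NE:LC->LHA: 0.83
    Ox:LHA->DRN: 3.4
    Ox:LHA->LC: 0.56
  rates:
    DRN: 0.8
    LC: 2.15
    LHA: 2.3
circuit:
  populations:
  - bias: 11.5
    gain: 0.2
    name: LHA
    threshold: 0.0
  - bias: 24.82
    gain: 0.033
    name: DRN
    threshold: 24.82
  - bias: 37.41
    gain: 0.058
    name: LC
    threshold: 0.028
  projections:
  - coupling: current
    kinetics:
      k_m: 170.0
      kind: michaelis-menten
      release_per_stimulus: 20.97902097902098
      v_max: 1800.0
    response:
      lower: 0.8631504461970546
      mode: current
      shift: 1.5
      slope: 0.35
      upper: -35.0
    source: DRN
    species: 5-HT
    target: LHA
    tau: 2.0
  - coupling: current
    kinetics:
      k_m: 170.0
      kind: michaelis-menten
      release_per_stimulus: 1.455882351999135e-06
      v_max: 1800.0
    response:
      lower: 0.0
      mode: current
      shift: -8.3
      slope: 0.35
      upper: -55.363141612147594
    source: DRN
    species: 5-HT
    target: LC
    tau: 20.0
  - coupling: current
    kinetics:
      k_m: 400.0
      kind: michaelis-menten
      release_per_stimulus: 30.308920513710518
      v_max: 74.0
    response:
      lower: 0.0
      mode: current
      shift: 3.469822015978163
      slope: 0.5
      upper: 24.558925815554495
    source: LC
    species: NE
    target: DRN
    tau: 20.0
  - coupling: current
    kinetics:
      k_m: 400.0
      kind: michaelis-menten
      release_per_stimulus: 0.07127071791149643
      v_max: 74.0
    response:
      lower: 1.0167091173076945
      mode: current
      shift: 1.2
      slope: 0.4
      upper: -25.0
    source: LC
    species: NE
    target: LHA
    tau: 1.0
  - coupling: current
    kinetics:
      decay: 0.85
      kind: linear
      rise: 1.2565217391304346
    response:
      lower: 0.0
      mode: current
      shift: -2.08
      slope: 0.452
      upper: 12.0
    source: LHA
    species: Ox
    target: DRN
    tau: 60.0
  - coupling: current
    kinetics:
      decay: 0.85
      kind: linear
      rise: 0.20695652173913046
    response:
      lower: 3.8
      mode: current
      shift: -2.3
      slope: 0.341
      upper: 54.0
    source: LHA
    species: Ox
    target: LC
    tau: 20.0
drugs:
- km_factors:
    5-HT: 5.0
  name: fluoxetine
- km_factors:
    NE: 3.0
  name: nri-x3
- km_factors:
    NE: 5.0
  name: nri-x5
- name: sb-334867-a
  overrides:
    Ox:LHA->DRN:
      shift: -2.97
      slope: 0.367
    Ox:LHA->LC:
      lower: 2.0
      shift: -4.192
      slope: 0.592
      upper: 51.0
simulation:
  dt: 0.001
  duration: 600.0
  overflow: 1000000000000.0
  stride: 100
  sustain: 1.0
  tol_conc: !!float '1e-06'
  tol_current: !!float '1e-06'
  tol_rate: !!float '1e-06'
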