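# Baseline parameter table and autonomic condition transforms for the
# sanpop reduced mouse SAN pacemaker cell.
#
# parameters: baseline value + units. conditions: lists of multiplicative
# ("scale") or additive ("shift") effects on named parameters; kach_nm is the
# carbachol dose (nM) engaging the acetylcholine-activated K+ current.
# The CCh modeling dose defaults to 300 nM, the ex vivo superfusion dose used
# in isolated-atria pharmacology.

parameters:
  c_m:     {value: 25.0,   units: pF,    description: membrane capacitance}
  g_na:    {value: 4.0,    units: nS,    description: fast Na+ (Nav1.5) maximal conductance}
  g_cal:   {value: 14.0,    units: nS,    description: L-type Ca2+ maximal conductance}
  g_cat:   {value: 9.0,    units: nS,    description: T-type Ca2+ maximal conductance}
  g_to:    {value: 3.5,    units: nS,    description: transient-outward K+ maximal conductance}
  g_sus:   {value: 0.7,    units: nS,    description: sustained K+ maximal conductance}
  g_kr:    {value: 13.0,    units: nS,    description: rapid delayed-rectifier K+ maximal conductance}
  g_ks:    {value: 0.7,    units: nS,    description: slow delayed-rectifier K+ maximal conductance}
  g_f:     {value: 6.0,    units: nS,    description: funny-current maximal conductance}
  g_kach:  {value: 1.0,    units: nS,    description: acetylcholine-activated K+ maximal conductance}
  g_bna:   {value: 0.04,   units: nS,    description: background Na+ conductance}
  g_bca:   {value: 0.02,   units: nS,    description: background Ca2+ conductance}
  p_nak:   {value: 150.0,   units: pA,    description: Na+/K+ pump maximal current}
  v_ncx:   {value: 1.6e5,  units: pA,    description: Na+/Ca2+ exchanger maximal transport scale}
  v_ryr:   {value: 8.0,    units: 1/s,   description: ryanodine-receptor maximal release rate}
  v_up:    {value: 1.0,    units: mM/s,  description: SERCA maximal uptake rate}
  f_shift: {value: 0.0,    units: mV,    description: funny-current activation shift}
  ca_shift: {value: 0.0,   units: mV,    description: Ca2+ channel activation shift (negative = hyperpolarizing)}
  cch_nm:  {value: 0.0,    units: nM,    description: carbachol dose at the I_KACh receptor}

conditions:
  ISO:
    effects:
      - {parameter: g_cal,  kind: scale, value: 1.45}
      - {parameter: g_cat,  kind: scale, value: 1.10}
      - {parameter: g_ks,   kind: scale, value: 1.30}
      - {parameter: p_nak,  kind: scale, value: 1.20}
      - {parameter: v_up,   kind: scale, value: 1.40}
      - {parameter: f_shift, kind: shift, value: 7.0}
      - {parameter: ca_shift, kind: shift, value: -3.0}
  CCh:
    kach_nm: 300.0
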