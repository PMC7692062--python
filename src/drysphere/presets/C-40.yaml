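name: C-40
material:
  X0: 5.64
  d0_cm: 5.3
program:
  stages:
    - {label: C, duration_h: 130.0, T_inf_C: 40.0, RH_inf: 0.15, U_inf: 1.28}
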