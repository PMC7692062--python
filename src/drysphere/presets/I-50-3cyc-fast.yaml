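name: I-50-3cyc-fast
material:
  X0: 7.24
  d0_cm: 5.43
program:
  n_cycles: 3
  stages:
    - {label: C, duration_h: 10.0, T_inf_C: 50.0, RH_inf: 0.15, U_inf: 2.66}
    - {label: P1, duration_h: 7.0, T_inf_C: 50.0, RH_inf: 0.80, U_inf: 0.1}
    - {label: P2, duration_h: 7.0, T_inf_C: 17.0, RH_inf: 0.80, U_inf: 0.1}
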