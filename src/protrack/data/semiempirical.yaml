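# Miller-Green parameter sets.  Water excitation: Dingfelder set, a and J in
# eV.  The "Ryd C+D" a-value is typeset ambiguously in the source table
# (1692 vs 692); 1692 is the packaged default -- edit here to override.
# Electron loss: single-channel fit, a and J in keV, threshold W = 12.6 eV
# (outermost water binding energy).
water_excitation:
  - {state: "A1B1",        W_ev: 8.17,  a_ev: 876,  J_ev: 19820, Omega: 0.85, nu: 1.0}
  - {state: "B1A1",        W_ev: 10.13, a_ev: 2084, J_ev: 23490, Omega: 0.88, nu: 1.0}
  - {state: "RydAB",       W_ev: 11.31, a_ev: 1373, J_ev: 27770, Omega: 0.88, nu: 1.0}
  - {state: "RydCD",       W_ev: 12.91, a_ev: 1692, J_ev: 30830, Omega: 0.78, nu: 1.0}
  - {state: "DiffuseBands",W_ev: 14.50, a_ev: 900,  J_ev: 33080, Omega: 0.78, nu: 1.0}
electron_loss:
  {W_ev: 12.6, a_kev: 79.3, J_kev: 27.7, Omega: 0.652, nu: 0.943}
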