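# Full benchmark design: every family's Type-I grid plus the three power
# designs, at the study's replicate count.  Override --nsim for desk-scale runs.
nsim: 9999
classify_robust: false
grids:
  - {grid: type1, family: A, name: type1_A}
  - {grid: type1, family: B, name: type1_B}
  - {grid: type1, family: C, name: type1_C}
  - {grid: type1, family: D, name: type1_D}
  - {grid: type1, family: E, name: type1_E}
  - {grid: type1, family: F, name: type1_F}
  - {grid: power_concentration, family: A, name: powconc_A}
  - {grid: power_concentration, family: B, name: powconc_B}
  - {grid: power_concentration, family: C, name: powconc_C}
  - {grid: power_concentration, family: D, name: powconc_D}
  - {grid: power_concentration, family: E, name: powconc_E}
  - {grid: power_concentration, family: F, name: powconc_F}
  - {grid: power_direction, family: A, name: powdir_A}
  - {grid: power_direction, family: B, name: powdir_B}
  - {grid: power_direction, family: C, name: powdir_C}
  - {grid: power_direction, family: D, name: powdir_D}
  - {grid: power_direction, family: E, name: powdir_E}
  - {grid: power_direction, family: F, name: powdir_F}
  - {grid: power_disttype, which: uni-vs-axial, name: powtype_uni_vs_axial}
  - {grid: power_disttype, which: vm-vs-wsn, name: powtype_vm_vs_wsn}
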