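# Integration windows (cm-1) for second-derivative band areas.
# Limits are data, not code: adjust here, or point the pipeline at your own file.
# OH_total is a roll-up of the three hydroxyl components and is excluded from
# the "bands" reference set to avoid double counting.
bands:
  - {name: CH2_rocking,       lo_cm1: 710.0,  hi_cm1: 740.0,  in_reference: true}
  - {name: sugar_ring,        lo_cm1: 1010.0, hi_cm1: 1115.0, in_reference: true}
  - {name: amide_II,          lo_cm1: 1490.0, hi_cm1: 1580.0, in_reference: true}
  - {name: amide_I,           lo_cm1: 1600.0, hi_cm1: 1700.0, in_reference: true}
  - {name: carbonyl_1821,     lo_cm1: 1795.0, hi_cm1: 1850.0, in_reference: true}
  - {name: carbonyl_1929,     lo_cm1: 1900.0, hi_cm1: 1960.0, in_reference: true}
  - {name: water_combination, lo_cm1: 2080.0, hi_cm1: 2180.0, in_reference: true}
  - {name: thiol,             lo_cm1: 2450.0, hi_cm1: 2530.0, in_reference: true}
  - {name: CH_stretch,        lo_cm1: 2830.0, hi_cm1: 2990.0, in_reference: true}
  - {name: unsat_CH,          lo_cm1: 3000.0, hi_cm1: 3020.0, in_reference: true}
  - {name: strOH,             lo_cm1: 3200.0, hi_cm1: 3450.0, in_reference: true}
  - {name: syOH,              lo_cm1: 3450.0, hi_cm1: 3550.0, in_reference: true}
  - {name: asyOH,             lo_cm1: 3550.0, hi_cm1: 3700.0, in_reference: true}
  - {name: OH_total,          lo_cm1: 3000.0, hi_cm1: 3700.0, in_reference: false}
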