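# Per-group FTIR band presets for the synthetic spectrum generator.
# frac_pct = target percentage of the total rectified second-derivative
# spectral area (the quantity the band report measures); fractions per
# preset sum to 100.  Centres follow the group-characteristic positions:
# amide I 1666 (control/low), 1674 (mid/extreme), 1659 (high, 6-7 mA);
# strained-carbonyl (1821/1929) and thiol (2450-2530) bands appear only in
# the low-current (0.5-2 mA) preset; hydroxyl fractions decline with
# current from the control values 31.1/2.2/4.7 %.
presets:
  control:
    - {name: CH2_rocking,       center_cm1: 725.0,  fwhm_cm1: 24.0, frac_pct: 3.5}
    - {name: sugar_ring,        center_cm1: 1062.0, fwhm_cm1: 40.0, frac_pct: 10.0}
    - {name: amide_II,          center_cm1: 1527.0, fwhm_cm1: 26.0, frac_pct: 8.0}
    - {name: amide_I,           center_cm1: 1666.0, fwhm_cm1: 30.0, frac_pct: 14.0}
    - {name: water_combination, center_cm1: 2129.0, fwhm_cm1: 40.0, frac_pct: 1.0}
    - {name: CH_stretch,        center_cm1: 2925.0, fwhm_cm1: 56.0, frac_pct: 24.0}
    - {name: unsat_CH,          center_cm1: 3010.0, fwhm_cm1: 20.0, frac_pct: 1.5}
    - {name: strOH,             center_cm1: 3320.0, fwhm_cm1: 60.0, frac_pct: 31.1}
    - {name: syOH,              center_cm1: 3500.0, fwhm_cm1: 60.0, frac_pct: 2.2}
    - {name: asyOH,             center_cm1: 3620.0, fwhm_cm1: 60.0, frac_pct: 4.7}
  low_current:    # 0.5-2 mA
    - {name: CH2_rocking,       center_cm1: 725.0,  fwhm_cm1: 24.0, frac_pct: 2.0}
    - {name: sugar_ring,        center_cm1: 1062.0, fwhm_cm1: 40.0, frac_pct: 10.0}
    - {name: amide_II,          center_cm1: 1527.0, fwhm_cm1: 26.0, frac_pct: 8.0}
    - {name: amide_I,           center_cm1: 1666.0, fwhm_cm1: 30.0, frac_pct: 14.0}
    - {name: carbonyl_1821,     center_cm1: 1821.0, fwhm_cm1: 20.0, frac_pct: 1.2}
    - {name: carbonyl_1929,     center_cm1: 1929.0, fwhm_cm1: 20.0, frac_pct: 1.2}
    - {name: water_combination, center_cm1: 2129.0, fwhm_cm1: 40.0, frac_pct: 0.6}
    - {name: thiol,             center_cm1: 2490.0, fwhm_cm1: 30.0, frac_pct: 0.8}
    - {name: CH_stretch,        center_cm1: 2925.0, fwhm_cm1: 56.0, frac_pct: 17.5}
    - {name: unsat_CH,          center_cm1: 3010.0, fwhm_cm1: 20.0, frac_pct: 1.5}
    - {name: strOH,             center_cm1: 3320.0, fwhm_cm1: 60.0, frac_pct: 34.9}
    - {name: syOH,              center_cm1: 3500.0, fwhm_cm1: 60.0, frac_pct: 2.4}
    - {name: asyOH,             center_cm1: 3620.0, fwhm_cm1: 60.0, frac_pct: 5.9}
  mid_current:    # 3-5 mA
    - {name: CH2_rocking,       center_cm1: 725.0,  fwhm_cm1: 24.0, frac_pct: 2.5}
    - {name: sugar_ring,        center_cm1: 1062.0, fwhm_cm1: 40.0, frac_pct: 10.0}
    - {name: amide_II,          center_cm1: 1551.0, fwhm_cm1: 26.0, frac_pct: 8.0}
    - {name: amide_I,           center_cm1: 1674.0, fwhm_cm1: 30.0, frac_pct: 14.0}
    - {name: water_combination, center_cm1: 2129.0, fwhm_cm1: 40.0, frac_pct: 3.0}
    - {name: CH_stretch,        center_cm1: 2925.0, fwhm_cm1: 56.0, frac_pct: 25.5}
    - {name: unsat_CH,          center_cm1: 3010.0, fwhm_cm1: 20.0, frac_pct: 3.5}
    - {name: strOH,             center_cm1: 3320.0, fwhm_cm1: 60.0, frac_pct: 26.0}
    - {name: syOH,              center_cm1: 3500.0, fwhm_cm1: 60.0, frac_pct: 2.0}
    - {name: asyOH,             center_cm1: 3620.0, fwhm_cm1: 60.0, frac_pct: 5.5}
  high_current:   # 6-7 mA
    - {name: CH2_rocking,       center_cm1: 725.0,  fwhm_cm1: 24.0, frac_pct: 2.5}
    - {name: sugar_ring,        center_cm1: 1062.0, fwhm_cm1: 40.0, frac_pct: 10.0}
    - {name: amide_II,          center_cm1: 1512.0, fwhm_cm1: 26.0, frac_pct: 7.0}
    - {name: amide_I,           center_cm1: 1659.0, fwhm_cm1: 30.0, frac_pct: 14.0}
    - {name: water_combination, center_cm1: 2129.0, fwhm_cm1: 40.0, frac_pct: 3.0}
    - {name: CH_stretch,        center_cm1: 2925.0, fwhm_cm1: 56.0, frac_pct: 31.2}
    - {name: unsat_CH,          center_cm1: 3010.0, fwhm_cm1: 20.0, frac_pct: 3.5}
    - {name: strOH,             center_cm1: 3320.0, fwhm_cm1: 60.0, frac_pct: 22.0}
    - {name: syOH,              center_cm1: 3500.0, fwhm_cm1: 60.0, frac_pct: 1.8}
    - {name: asyOH,             center_cm1: 3620.0, fwhm_cm1: 60.0, frac_pct: 5.0}
  extreme:        # 500 mA damage model; amide II undetected
    - {name: CH2_rocking,       center_cm1: 725.0,  fwhm_cm1: 24.0, frac_pct: 2.0}
    - {name: sugar_ring,        center_cm1: 1062.0, fwhm_cm1: 40.0, frac_pct: 10.0}
    - {name: amide_I,           center_cm1: 1674.0, fwhm_cm1: 30.0, frac_pct: 12.0}
    - {name: water_combination, center_cm1: 2129.0, fwhm_cm1: 40.0, frac_pct: 5.0}
    - {name: CH_stretch,        center_cm1: 2925.0, fwhm_cm1: 56.0, frac_pct: 46.0}
    - {name: unsat_CH,          center_cm1: 3010.0, fwhm_cm1: 20.0, frac_pct: 4.5}
    - {name: strOH,             center_cm1: 3320.0, fwhm_cm1: 60.0, frac_pct: 15.0}
    - {name: syOH,              center_cm1: 3500.0, fwhm_cm1: 60.0, frac_pct: 1.5}
    - {name: asyOH,             center_cm1: 3620.0, fwhm_cm1: 60.0, frac_pct: 4.0}
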