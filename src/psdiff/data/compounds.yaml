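# Compound constants for the four model drugs.
# mw_dosed is the molar mass of the chemical form actually weighed out
# (topotecan was dosed as the HCl salt). rb is the whole-blood/plasma
# concentration ratio; doses are in mg/kg.
physiology:
  qpv_ml_min_kg: 106.6
compounds:
  ciprofloxacin:
    mw_dosed: 331.34
    rb: 1.20
    dose_iv: 1.0
    dose_oral: 1.0
  nitrofurantoin:
    mw_dosed: 238.16
    rb: 1.18
    dose_iv: 1.0
    dose_oral: 2.0
  topotecan:
    mw_dosed: 457.9
    rb: 0.94
    dose_iv: 1.0
    dose_oral: 1.0
  sulfasalazine:
    mw_dosed: 398.39
    rb: 1.28
    dose_iv: 1.0
    dose_oral: 5.0
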