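# Reference production scenario: 10 mA, 18 MeV deuterons on a 99% enriched
# [176Yb]Yb2O3 slab traversed down to 8 MeV, 5-day irradiation followed by a
# 48-hour processing (cooling) period.
name: lu177_reference
beam:
  ion: deuteron
  energy_mev: 18.0
  current_ma: 10.0
  transmission: 0.985
  radius_cm: 1.0
target:
  material: yb2o3
  enriched: true
  density_g_cm3: 9.2
  radius_cm: 1.0
  exit_energy_mev: 8.0
  enrichment: 0.99
# dataset per reaction: the measured-curve column where it exists, the
# evaluated (tendl_dagger) column for channels only present there
reactions:
  "176Yb(d,p)Yb177": nagai
  "176Yb(d,n)Lu177g": nagai
  "176Yb(d,ng)Lu177m": tendl_dagger
  "176Yb(d,2ng)Lu176m": nagai
  "176Yb(d,2n)Lu176g": tendl_dagger
  "176Yb(d,3n)Lu175": tendl_dagger
  "176Yb(d,4ng)Lu174m": nagai
  "176Yb(d,4n)Lu174g": nagai
schedule:
  irradiation: {value: 5.0, unit: d}
  processing: {value: 48.0, unit: h}
  timeline_points: 60
report:
  nuclides: [Lu177m, Lu177g, Lu176m, Lu174m, Lu174g]
  reference: Lu177g
  coproducts: [Lu175, Lu176g]
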