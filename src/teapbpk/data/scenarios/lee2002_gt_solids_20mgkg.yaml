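# Green-tea solids, 20 mg/kg (volunteers 45-85 kg; midpoint body weight
# used here). Per-catechin doses are the stated mg/kg values.
species: human
bw_kg: 65
t_end_h: 24.0
output_step_h: 0.05
members:
  - {catechin: EGCg, dose_mg_per_kg: 2.78, study: lee2002}
  - {catechin: EGC, dose_mg_per_kg: 2.20, study: lee2002}
  - {catechin: EC, dose_mg_per_kg: 0.64, study: lee2002}
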