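# Rat Polyphenon E mixture: EGCg 2500, ECg 650, EC 250 mg/kg
# (Sprague-Dawley rats, 210-230 g).
species: rat
bw_kg: 0.22
t_end_h: 24.0
output_step_h: 0.05
members:
  - {catechin: EGCg, dose_mg_per_kg: 2500, study: zhu2000}
  - {catechin: ECg, dose_mg_per_kg: 650, study: zhu2000}
  - {catechin: EC, dose_mg_per_kg: 250, study: zhu2000}
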