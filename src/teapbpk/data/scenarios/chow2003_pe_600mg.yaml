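# Polyphenon E containing EGCg 600 mg, EGC 111 mg, EC 93 mg taken by
# 72 kg volunteers (per-kg doses 8.3, 1.54, 1.29 mg/kg).
species: human
bw_kg: 72
t_end_h: 24.0
output_step_h: 0.05
members:
  - {catechin: EGCg, dose_mg_per_kg: 8.3, study: chow2003}
  - {catechin: EGC, dose_mg_per_kg: 1.54, study: chow2003}
  - {catechin: EC, dose_mg_per_kg: 1.29, study: chow2003}
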