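# Polyphenon E, 400 mg EGCg content, 70 kg assumed body weight. EGC and
# EC contents follow the PE composition ratio of the 600 mg study
# (EGC/EGCg = 111/600, EC/EGCg = 93/600).
species: human
bw_kg: 70
t_end_h: 24.0
output_step_h: 0.05
members:
  - {catechin: EGCg, dose_mg_per_kg: 5.714, study: chow2003}
  - {catechin: EGC, dose_mg_per_kg: 1.057, study: chow2003}
  - {catechin: EC, dose_mg_per_kg: 0.886, study: chow2003}
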