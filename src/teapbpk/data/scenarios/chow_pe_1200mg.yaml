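# Polyphenon E, 1200 mg EGCg content, 70 kg assumed body weight; EGC/EC
# from the 600 mg PE composition ratio.
species: human
bw_kg: 70
t_end_h: 24.0
output_step_h: 0.05
members:
  - {catechin: EGCg, dose_mg_per_kg: 17.143, study: chow2003}
  - {catechin: EGC, dose_mg_per_kg: 3.171, study: chow2003}
  - {catechin: EC, dose_mg_per_kg: 2.657, study: chow2003}
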