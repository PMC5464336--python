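# Species-level constants. co_coefficient: cardiac output allometric
# coefficient, L/h per kg^0.75. gut_lumen_volume_l: gut-content volume, L.
species_id,co_coefficient,gut_lumen_volume_l,hematocrit,reference_bw_kg
rat,14.0,0.0176,0.37,0.26
human,16.1,2.1,0.37,70
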