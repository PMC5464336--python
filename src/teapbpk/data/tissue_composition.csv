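# Fractional tissue composition (weight fractions): neutral fat (V_n),
# phospholipids (V_ph), water (V_w). Literature-sourced approximations for
# the rat, used by the tissue-composition partitioning equations as the
# alternative to the packaged partition-coefficient tables. The plasma row
# supplies the reference phase of the equations.
compartment,V_n,V_ph,V_w
adipose,0.8530,0.0020,0.1200
bone,0.0220,0.0011,0.4460
brain,0.0392,0.0533,0.7880
gut,0.0290,0.0138,0.7490
heart,0.0135,0.0106,0.7790
kidney,0.0121,0.0240,0.7710
liver,0.0138,0.0240,0.7050
lung,0.0219,0.0140,0.7900
muscle,0.0100,0.0090,0.7560
skin,0.0603,0.0080,0.6510
spleen,0.0077,0.0113,0.7710
rest_of_body,0.0100,0.0090,0.7560
plasma,0.00147,0.00083,0.9600
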