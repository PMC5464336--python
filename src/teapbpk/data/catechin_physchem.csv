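# Physicochemical properties and unbound fractions of the four major tea
# catechins (rat plasma). P_ow and D_vow are linear-scale partition /
# distribution coefficients; ic50_erod is the EROD-inhibition IC50 in
# human liver microsomes (umol/L).
catechin_id,P_ow,D_vow,pKa,f_up,f_ut,BLPLR,ic50_erod
EGCg,97.70,5.13,7.75,0.04,0.08,0.91,1175
ECg,468,29.3,7.75,0.03,0.06,0.99,530
EGC,4.84,0.26,9.54,0.25,0.40,0.88,1000
EC,3.09,0.16,9.54,0.25,0.40,0.88,2600
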