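# Rat pharmacokinetic parameters, stored in the printed per-minute / mL
# units; the loader converts to hours and litres. k_ac, k_rac, k_fc:
# 1/min * kg^0.3. tlag, R_t: min. CL_bc, CL_rc: mL/min * kg^-0.66.
# The rat EGCg bioavailability factor F was reported as a per-study range
# 0.0003-0.038; the upper end is packaged as the default and any other
# value must be supplied explicitly (see docs/methods.md).
catechin_id,study_id,k_ac,F,tlag,R_t,k_rac,k_fc,CL_bc,CL_rc
EGCg,zhu2000,0.003,0.038,10.00,3.00,0.67,0.13,9.13,0.36
ECg,zhu2000,0.002,0.06,10.00,0.30,0.41,0.13,12.60,0.30
EC,zhu2000,0.002,0.13,5.00,2.00,13.40,0.13,8.70,4.50
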