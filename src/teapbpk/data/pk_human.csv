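# Human pharmacokinetic parameters (hour / litre units as printed).
# k_ac, k_rac, k_fc: 1/h * kg^0.3. tlag, R_t: h. CL_bc, CL_rc:
# L/h * kg^-0.66. F and k_ac were fitted per source study; the study_id
# column keys the variants (chow2001: 400 mg pure EGCg; chow2003: PE
# studies; lee2002: green-tea solids).
catechin_id,study_id,k_ac,F,tlag,R_t,k_rac,k_fc,CL_bc,CL_rc
EGCg,chow2001,1.1,0.065,0.50,0.03,0.18,25.60,2.70,0.0023
EGCg,chow2003,0.85,0.12,0.50,0.03,0.18,25.60,2.70,0.0023
EGCg,lee2002,2.85,0.07,0.50,0.03,0.18,25.60,2.70,0.0023
EGC,chow2003,2.19,0.013,0.40,0.03,0.18,25.60,0.97,0.34
EGC,lee2002,2.19,0.052,0.40,0.03,0.18,25.60,0.97,0.34
EC,chow2003,1.86,0.01,0.40,0.03,0.18,25.60,1.03,0.56
EC,lee2002,1.86,0.1,0.40,0.03,0.18,25.60,1.03,0.56
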